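"""Shared fixtures: a small fast community and the full default run.

The small community (three genomes, ~0.5 Mb) keeps unit tests quick; the
session-scoped ``default_run`` executes the whole pipeline once on the
full default holobiont community and is shared by the end-to-end checks.
"""

import pathlib

import pytest
from hypothesis import HealthCheck, settings

from holopipe.community import CommunityProfile, GenomeModel
from holopipe.pipeline import RunConfig, run_all
from holopipe.simulate import simulate_community

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def small_profile(seed: int = 5) -> CommunityProfile:
    genomes = [
        GenomeModel("hostS", "host", 150_000, 0.40, tnf_seed=3,
                    coding_density_target=0.25),
        GenomeModel("bactA", "bacterium", 300_000, 0.46, tnf_seed=17,
                    coding_density_target=0.90),
        GenomeModel("bactB", "bacterium", 300_000, 0.56, tnf_seed=31,
                    coding_density_target=0.90),
    ]
    ab_a = {"hostS": 80.0, "bactA": 10.0, "bactB": 40.0}
    ab_b = {"hostS": 5.0, "bactA": 40.0, "bactB": 10.0}
    return CommunityProfile(genomes, ab_a, ab_b, seed=seed)


@pytest.fixture(scope="session")
def small_data():
    return simulate_community(small_profile(), n_core_families=30,
                              n_markers=12, study_genomes=["bactA"])


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> pathlib.Path:
    """Full pipeline run on the default ~12 Mb synthetic holobiont."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(seed=11, outdir=str(outdir),
                    pangenome={"bootstrap_n": 100})
    run_all(cfg)
    return outdir
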