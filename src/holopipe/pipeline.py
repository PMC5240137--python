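"""Stage orchestration: run the pipeline as named stages over a directory.

Each stage reads its declared inputs from the run directory, writes its
declared outputs there, and appends an entry (input checksums, parameters,
seed, package versions, timestamp) to ``manifest.json`` so a run is fully
reproducible from the manifest alone.  Stages check that their
prerequisites exist and fail naming the missing file.

Stage order: simulate -> features -> bin -> qc -> pangenome / enrich ->
report.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import align, binning, enrichment, features, io as hio, markers
from . import pangenome as pg
from . import phylogeny, simulate
from .community import default_community

STAGES = ("simulate", "features", "bin", "qc", "pangenome", "enrich", "report")


@dataclass
class RunConfig:
    """Run-wide seed plus per-stage parameter blocks (dict kwargs)."""

    seed: int = 0
    outdir: str = "run"
    community: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    binning: dict = field(default_factory=dict)
    pangenome: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(out: Path, *names: str) -> list[Path]:
    paths = [out / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing prerequisite file(s): {missing}")
    return paths


def _record(out: Path, stage: str, inputs: list[Path], outputs: list[Path],
            params: dict, seed: int) -> None:
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    manifest[stage] = {
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": [p.name for p in outputs],
        "params": params,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    for p in outputs:
        if not p.exists() or p.stat().st_size == 0:
            raise RuntimeError(f"stage {stage} declared output {p} missing/empty")
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def stage_simulate(config: RunConfig) -> dict[str, str]:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(config.community)
    # genome_scale shrinks every genome proportionally: a quick-look mode
    # for smoke runs; the full-size default community is the study condition
    scale = float(params.pop("genome_scale", 1.0))
    profile = default_community(seed=config.seed)
    if scale != 1.0:
        from dataclasses import replace
        profile = type(profile)(
            [replace(g, length=max(int(g.length * scale), 50_000))
             for g in profile.genomes],
            profile.abundance_unmodified, profile.abundance_fractionated,
            seed=profile.seed)
    data = simulate.simulate_community(profile, **params)
    paths = simulate.write_community(data, out)
    # BLAST-style coarse taxon labels for the contamination purge
    labels = pd.DataFrame(
        [{"contig_id": cid,
          "taxon": "eukaryote" if data.truth["genomes"][g]["kind"]
          in ("host", "alga") else "bacterium"}
         for cid, g in data.truth["contig_genome"].items()])
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    outputs = [Path(p) for p in paths.values()] + [out / "labels.tsv"]
    _record(out, "simulate", [], outputs, config.community, config.seed)
    return paths


def stage_features(config: RunConfig) -> Path:
    out = Path(config.outdir)
    ins = _require(out, "contigs.fasta", "depth.tsv", "genes.tsv", "markers.tsv")
    records = features.build_feature_table(*ins, **config.features)
    dest = out / "features.tsv"
    features.write_feature_table(records, dest)
    _record(out, "features", ins, [dest], config.features, config.seed)
    return dest


def stage_bin(config: RunConfig) -> Path:
    out = Path(config.outdir)
    ins = _require(out, "features.tsv", "links.tsv")
    cfg = binning.BinningConfig(**config.binning)
    table = features.read_feature_table(ins[0])
    links = pd.read_csv(ins[1], sep="\t")
    mat, ids, _ = binning.standardize_features(table, cfg)
    assignment = binning.cluster_contigs(mat, ids, cfg)
    assignment = binning.recruit_linked_contigs(assignment, links, cfg.min_links)

    labels_path = out / "labels.tsv"
    if labels_path.exists():
        labels = dict(pd.read_csv(labels_path, sep="\t")
                      .set_index("contig_id")["taxon"])
        genes = pd.read_csv(out / "genes.tsv", sep="\t") \
            if (out / "genes.tsv").exists() else None
        contig_markers: dict[str, list[str]] = {}
        if genes is not None and (out / "markers.tsv").exists():
            mk = pd.read_csv(out / "markers.tsv", sep="\t")
            merged = mk.merge(genes[["gene_id", "contig_id"]], on="gene_id")
            for cid, grp in merged.groupby("contig_id"):
                contig_markers[cid] = grp["marker_id"].tolist()
        for bin_id, cids in binning.bin_contig_lists(assignment).items():
            # only bacterial bins (carrying marker genes) are purged
            if not any(contig_markers.get(c) for c in cids):
                continue
            kept, removed = binning.purge_contaminants(cids, labels,
                                                       contig_markers)
            for c in removed:
                assignment[c] = binning.UNBINNED

    dest = out / "bins.tsv"
    pd.DataFrame(sorted(assignment.items()),
                 columns=["contig_id", "bin_id"]).to_csv(dest, sep="\t",
                                                         index=False)
    outputs = [dest]
    truth_path = out / "truth.json"
    if truth_path.exists():
        truth = hio.read_json(truth_path)
        tmap = dict(truth["contig_genome"])
        # strains are expected to co-bin; evaluate them as one label
        for gid, meta in truth["genomes"].items():
            if meta.get("strain_of"):
                pair = meta["strain_of"]
                tmap = {c: (pair if g == gid else g) for c, g in tmap.items()}
        contigs = hio.read_fasta(out / "contigs.fasta")
        lens = {c: len(s) for c, s in contigs.items()}
        ev = binning.evaluate_binning(assignment, tmap, lens,
                                      min_len=cfg.min_contig_len)
        ev.to_csv(out / "evaluation.tsv", sep="\t", index=False)
        outputs.append(out / "evaluation.tsv")
    _record(out, "bin", ins, outputs, cfg.__dict__ | {}, config.seed)
    return dest


def stage_qc(config: RunConfig) -> Path:
    out = Path(config.outdir)
    ins = _require(out, "bins.tsv", "contigs.fasta", "genes.tsv", "markers.tsv")
    bins_df = pd.read_csv(ins[0], sep="\t")
    assignment = dict(zip(bins_df["contig_id"], bins_df["bin_id"]))
    contigs = hio.read_fasta(ins[1])
    genes = pd.read_csv(ins[2], sep="\t")
    mk = pd.read_csv(ins[3], sep="\t")
    mset = markers.MarkerSet.from_iterable(mk["marker_id"].unique())
    report = markers.quality_report(binning.bin_contig_lists(assignment),
                                    contigs, genes, mk, mset)
    dest = out / "quality.tsv"
    report.to_csv(dest, sep="\t", index=False, float_format="%.2f")
    _record(out, "qc", ins, [dest], {"marker_set_size": mset.size}, config.seed)
    return dest


def stage_pangenome(config: RunConfig) -> Path:
    out = Path(config.outdir)
    ins = _require(out, "proteins.faa")
    params = dict(config.pangenome)
    genome_ids = params.pop("genomes", None)
    min_identity = params.pop("min_identity", 50.0)
    min_coverage = params.pop("min_coverage", 0.5)
    inflation = params.pop("inflation", 1.5)
    bootstrap_n = params.pop("bootstrap_n", 100)
    max_gap_fraction = params.pop("max_gap_fraction", 0.0)
    if params:
        raise ValueError(f"unknown pangenome parameters {sorted(params)}")

    seqs = hio.read_fasta(ins[0])
    by_genome: dict[str, dict[str, str]] = {}
    for pid, seq in seqs.items():
        genome_id, gene_id = pid.split("|", 1)
        by_genome.setdefault(genome_id, {})[gene_id] = seq
    if genome_ids is None:
        truth_path = out / "truth.json"
        if truth_path.exists():
            truth = hio.read_json(truth_path)
            genome_ids = sorted(g for g, meta in truth["genomes"].items()
                                if meta["kind"] == "bacterium")
        else:
            genome_ids = sorted(by_genome)
    proteomes = [pg.filter_proteins(pg.Proteome(g, by_genome[g]))[0]
                 for g in genome_ids]

    graph = pg.build_similarity_graph(proteomes, min_identity=min_identity,
                                      min_coverage=min_coverage)
    groups = pg.markov_cluster(graph, inflation=inflation)
    core, summary = pg.extract_core(groups, genome_ids)
    pg.groups_table(groups).to_csv(out / "groups.tsv", sep="\t", index=False)
    pg.presence_absence(groups, genome_ids).to_csv(out / "presence_absence.tsv",
                                                   sep="\t")
    summary.to_csv(out / "pangenome_summary.tsv", sep="\t", index=False)

    pdict = {p.genome_id: p for p in proteomes}
    core_seqs = pg.core_group_sequences(core, pdict)
    ident = pd.DataFrame(100.0, index=genome_ids, columns=genome_ids)
    for i, gx in enumerate(genome_ids):
        for gy in genome_ids[i + 1:]:
            v = pg.mean_core_identity(core_seqs, gx, gy)
            ident.at[gx, gy] = ident.at[gy, gx] = v
    ident.index.name = "genome_id"
    ident.to_csv(out / "core_identity.tsv", sep="\t", float_format="%.2f")

    aln, _ = align.align_and_concatenate(core_seqs,
                                         max_gap_fraction=max_gap_fraction)
    hio.write_fasta(aln, out / "core_alignment.fasta")
    tree, _ = phylogeny.nj_tree(aln, bootstrap_n=bootstrap_n, seed=config.seed)
    (out / "tree.nwk").write_text(phylogeny.to_newick(tree) + "\n")

    outputs = [out / n for n in ("groups.tsv", "presence_absence.tsv",
                                 "pangenome_summary.tsv", "core_identity.tsv",
                                 "core_alignment.fasta", "tree.nwk")]
    _record(out, "pangenome", ins, outputs,
            {"genomes": genome_ids, "min_identity": min_identity,
             "min_coverage": min_coverage, "inflation": inflation,
             "bootstrap_n": bootstrap_n, "max_gap_fraction": max_gap_fraction},
            config.seed)
    return out / "tree.nwk"


def stage_enrich(config: RunConfig) -> Path:
    out = Path(config.outdir)
    ins = _require(out, "ontology.obo", "go_annotations.tsv", "genes.tsv",
                   "categories.tsv")
    params = dict(config.enrichment)
    namespace = params.pop("namespace", "biological_process")
    study_genomes = params.pop("study_genomes", None)
    background_genomes = params.pop("background_genomes", None)
    add_bh = params.pop("add_bh", False)
    if params:
        raise ValueError(f"unknown enrichment parameters {sorted(params)}")

    genes = pd.read_csv(ins[2], sep="\t")
    truth_path = out / "truth.json"
    if study_genomes is None:
        if not truth_path.exists():
            raise FileNotFoundError(f"missing prerequisite file(s): "
                                    f"['{truth_path}'] (or set "
                                    f"enrichment.study_genomes)")
        truth = hio.read_json(truth_path)
        study_genomes = truth["study_genomes"]
        background_genomes = [g for g, meta in truth["genomes"].items()
                              if meta["kind"] == "bacterium"]
    if background_genomes is None:
        background_genomes = sorted(genes["genome_id"].unique())

    dag = enrichment.parse_obo(ins[0])
    annotations = pd.read_csv(ins[1], sep="\t")
    study = set(genes[genes["genome_id"].isin(set(study_genomes))]["gene_id"])
    background = set(genes[genes["genome_id"]
                           .isin(set(background_genomes))]["gene_id"])
    table = enrichment.enrich(study, background, annotations, dag,
                              namespace=namespace, add_bh=add_bh)
    dest = out / "enrichment.tsv"
    table.to_csv(dest, sep="\t", index=False)
    cats = pd.read_csv(ins[3], sep="\t")
    pct = enrichment.category_percentages(cats, list(background_genomes))
    pct.to_csv(out / "category_percentages.tsv", sep="\t", float_format="%.3f")
    _record(out, "enrich", ins, [dest, out / "category_percentages.tsv"],
            {"namespace": namespace, "study_genomes": list(study_genomes)},
            config.seed)
    return dest


def stage_report(config: RunConfig) -> Path:
    out = Path(config.outdir)
    ins = _require(out, "quality.tsv", "presence_absence.tsv", "tree.nwk",
                   "enrichment.tsv")
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    outputs = []
    for src in ins:
        dest = report_dir / src.name
        dest.write_text(src.read_text())
        outputs.append(dest)
    _record(out, "report", ins, outputs, {}, config.seed)
    return report_dir


_STAGE_FN = {
    "simulate": stage_simulate,
    "features": stage_features,
    "bin": stage_bin,
    "qc": stage_qc,
    "pangenome": stage_pangenome,
    "enrich": stage_enrich,
    "report": stage_report,
}


def run_subcommand(name: str, config: RunConfig):
    """Run one named stage; raises on unknown stage or missing prerequisites."""
    if name not in _STAGE_FN:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    return _STAGE_FN[name](config)


def run_all(config: RunConfig) -> None:
    for name in STAGES:
        run_subcommand(name, config)
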