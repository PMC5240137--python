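"""Synthetic holobiont generator: sequence statistics, depth, links,
annotations, and ground-truth consistency."""

import io

import networkx as nx
import numpy as np
import pytest

from holopipe import features as feat
from holopipe import simulate as sim
from holopipe.community import CommunityProfile, GenomeModel
from holopipe.enrichment import enrich, parse_obo
from holopipe.io import write_fasta


def bacterium(genome_id="b1", length=200_000, gc=0.47, seed=5, density=0.9,
              **kw):
    return GenomeModel(genome_id, "bacterium", length, gc, tnf_seed=seed,
                       coding_density_target=density, **kw)


class TestGenomeModelValidation:
    def test_bad_kind_and_bounds(self):
        with pytest.raises(ValueError):
            GenomeModel("x", "virus", 1000, 0.5, 1, 0.5)
        with pytest.raises(ValueError):
            GenomeModel("x", "host", 1000, 0.5, 1, 0.8)  # euk density cap
        with pytest.raises(ValueError):
            GenomeModel("x", "bacterium", -5, 0.5, 1, 0.5)

    def test_strain_must_reference_existing_parent(self):
        g = [bacterium("a"), bacterium("b", strain_of="ghost")]
        ab = {"a": 1.0, "b": 1.0}
        with pytest.raises(ValueError, match="ghost"):
            CommunityProfile(g, ab, ab)

    def test_differential_coverage_required(self):
        g = [GenomeModel("h", "host", 10_000, 0.4, 1, 0.2), bacterium("b")]
        flat = {"h": 10.0, "b": 10.0}
        with pytest.raises(ValueError, match="ratio"):
            CommunityProfile(g, flat, dict(flat))


class TestGenerateGenome:
    def test_gc_and_length_contract(self):
        b = sim.generate_genome(bacterium(), 1)
        assert len(b.sequence) == 200_000
        assert 0.45 <= feat.gc_content(b.sequence) <= 0.49

    def test_coding_density_target_for_bacteria(self):
        b = sim.generate_genome(bacterium(), 1)
        realized = sum(g.end - g.start for g in b.genes) / len(b.sequence)
        assert abs(realized - 0.9) <= 0.05

    def test_eukaryote_low_coding_density(self):
        h = sim.generate_genome(
            GenomeModel("h", "host", 200_000, 0.4, 7, 0.25), 2)
        realized = sum(g.end - g.start for g in h.genes) / len(h.sequence)
        assert realized <= 0.4

    def test_identical_seed_gives_byte_identical_fasta(self):
        outs = []
        for _ in range(2):
            b = sim.generate_genome(bacterium(), 1)
            buf = io.StringIO()
            write_fasta(b.contigs(), buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1] and outs[0].startswith(">b1_c0000")

    def test_contigs_partition_genome(self):
        b = sim.generate_genome(bacterium(), 3)
        assert "".join(b.contigs().values()) == b.sequence
        assert min(len(s) for s in b.contigs().values()) >= 1000

    def test_genes_do_not_span_contig_boundaries(self):
        b = sim.generate_genome(bacterium(), 3)
        bounds = {cid: (s, e) for cid, s, e in b.contig_bounds}
        table = b.gene_table()
        lens = {cid: e - s for cid, (s, e) in bounds.items()}
        assert (table["end"] <= table["contig_id"].map(lens)).all()
        assert (table["start"] >= 1).all()

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            sim.generate_genome(bacterium(length=100), 1)

    def test_strain_protein_identity_near_target(self):
        parent = sim.generate_genome(bacterium(), 1)
        strain = sim.generate_genome(
            bacterium("b1s", strain_of="b1", protein_identity_to_parent=0.974),
            2, parent=parent)
        idents = []
        for gp, gs in zip(parent.genes, strain.genes):
            p1, p2 = parent.proteins[gp.gene_id], strain.proteins[gs.gene_id]
            assert len(p1) == len(p2)
            idents.append(np.mean([a == b for a, b in zip(p1, p2)]))
        assert 0.96 <= float(np.mean(idents)) <= 0.99

    def test_strain_requires_parent(self):
        with pytest.raises(ValueError, match="parent"):
            sim.generate_genome(bacterium("s", strain_of="b1"), 1)


class TestTnfSeparation:
    def test_within_genome_tnf_distance_below_between(self, small_data):
        vecs = {}
        for b in small_data.builds:
            if b.model.kind != "bacterium":
                continue
            vecs[b.genome_id] = [feat.tetranucleotide_freq(s)
                                 for s in list(b.contigs().values())[:30]]
        (ga, va), (gb, vb) = vecs.items()
        within = [np.linalg.norm(x - y) for v in (va, vb)
                  for i, x in enumerate(v) for y in v[i + 1:]]
        between = [np.linalg.norm(x - y) for x in va for y in vb]
        assert np.median(within) < np.median(between)


class TestSimulateDepth:
    def profile_50_contigs(self):
        g = [GenomeModel("h", "host", 10_000, 0.4, 1, 0.2),
             bacterium("b", length=10_000)]
        prof = CommunityProfile(g, {"h": 0.0, "b": 10.0},
                                {"h": 0.0, "b": 40.0}, seed=4)
        contig_map = {f"b_c{i}": "b" for i in range(50)}
        contig_map.update({f"h_c{i}": "h" for i in range(10)})
        return prof, contig_map

    def test_depth_means_near_abundance(self):
        prof, cmap = self.profile_50_contigs()
        depth = sim.simulate_depth(prof, cmap)
        b = depth[depth.contig_id.str.startswith("b_")]
        assert 8 <= b["cov_A"].mean() <= 12
        assert 32 <= b["cov_B"].mean() <= 48
        assert (depth[["cov_A", "cov_B"]] >= 0).all().all()

    def test_zero_abundance_zero_depth(self):
        prof, cmap = self.profile_50_contigs()
        depth = sim.simulate_depth(prof, cmap)
        h = depth[depth.contig_id.str.startswith("h_")]
        assert (h[["cov_A", "cov_B"]] == 0).all().all()

    def test_unknown_genome_errors(self):
        prof, cmap = self.profile_50_contigs()
        cmap["weird"] = "nope"
        with pytest.raises(ValueError, match="nope"):
            sim.simulate_depth(prof, cmap)

    def test_strain_clouds_overlap_in_log_coverage(self):
        g = [GenomeModel("h", "host", 10_000, 0.4, 1, 0.2),
             bacterium("p", length=10_000),
             bacterium("q", length=10_000, strain_of="p",
                       protein_identity_to_parent=0.97)]
        prof = CommunityProfile(
            g, {"h": 50.0, "p": 10.0, "q": 12.0},
            {"h": 2.0, "p": 40.0, "q": 44.0}, seed=9)
        cmap = {f"{gid}_c{i}": gid for gid in ("p", "q") for i in range(60)}
        depth = sim.simulate_depth(prof, cmap)
        logcov = np.log10(depth[["cov_A", "cov_B"]].to_numpy() + 0.01)
        lab = depth.contig_id.str.startswith("p_").to_numpy()
        cp, cq = logcov[lab].mean(axis=0), logcov[~lab].mean(axis=0)
        radius = np.mean([logcov[lab].std(axis=0).mean(),
                          logcov[~lab].std(axis=0).mean()])
        assert np.linalg.norm(cp - cq) < radius


class TestSimulateLinks:
    def order(self):
        return {"g1": [f"g1_c{i}" for i in range(5)],
                "g2": [f"g2_c{i}" for i in range(8)]}

    def test_no_false_links_components_refine_genomes(self):
        links = sim.simulate_links(self.order(), seed=1, false_link_rate=0.0)
        g = nx.Graph(zip(links.contig_i, links.contig_j))
        for comp in nx.connected_components(g):
            genomes = {c.split("_")[0] for c in comp}
            assert len(genomes) == 1

    def test_chain_topology_links_all_adjacent_pairs(self):
        links = sim.simulate_links({"g": [f"c{i}" for i in range(5)]},
                                   seed=1, false_link_rate=0.0)
        adjacent = {(f"c{i}", f"c{i+1}") for i in range(4)}
        emitted = set(zip(links.contig_i, links.contig_j))
        assert adjacent <= emitted
        assert len(links) >= 4

    def test_false_link_fraction_near_rate(self):
        order = {f"g{k}": [f"g{k}_c{i}" for i in range(40)] for k in range(4)}
        links = sim.simulate_links(order, seed=2, false_link_rate=0.05)
        cross = (links.contig_i.str.split("_").str[0]
                 != links.contig_j.str.split("_").str[0])
        assert 0.02 <= cross.mean() <= 0.08


class TestEmitAnnotations:
    def test_bacteria_carry_each_marker_once(self, small_data):
        mk = small_data.markers.merge(
            small_data.genes[["gene_id", "genome_id"]], on="gene_id")
        counts = mk.groupby(["genome_id", "marker_id"]).size()
        for gid in ("bactA", "bactB"):
            per = counts.loc[gid]
            assert len(per) == 12 and (per == 1).all()

    def test_eukaryotes_carry_no_markers(self, small_data):
        mk = small_data.markers.merge(
            small_data.genes[["gene_id", "genome_id"]], on="gene_id")
        assert not (mk["genome_id"] == "hostS").any()

    def test_planted_term_detected_by_fisher(self, small_data, tmp_path):
        obo = tmp_path / "go.obo"
        obo.write_text(small_data.obo)
        dag = parse_obo(obo)
        genes = small_data.genes
        study = set(genes[genes.genome_id == "bactA"].gene_id)
        background = set(genes[genes.genome_id.isin(["bactA", "bactB"])].gene_id)
        assert len(study) >= 200 and len(background - study) >= 200
        table = enrich(study, background, small_data.go, dag)
        planted = list(small_data.planted_terms)[0]
        row = table[table.term == planted].iloc[0]
        assert row.p_value < 0.01

    def test_truth_map_is_partition(self, small_data):
        contigs = small_data.contigs()
        truth = small_data.truth["contig_genome"]
        assert set(truth) == set(contigs)

    def test_coding_density_separates_kingdoms(self, small_data):
        by_kind = {"host": [], "bacterium": []}
        for b in small_data.builds:
            kind = "host" if b.model.is_eukaryote else "bacterium"
            for s in list(b.contigs().values())[:25]:
                by_kind[kind].append(feat.coding_density(s))
        gap = np.median(by_kind["bacterium"]) - np.median(by_kind["host"])
        assert gap >= 0.3


class TestCommunityDeterminism:
    def test_regeneration_reproduces_identical_files(self, tmp_path):
        genomes = [GenomeModel("h", "host", 60_000, 0.4, 1, 0.2),
                   bacterium("b", length=80_000)]
        prof = CommunityProfile(genomes, {"h": 50.0, "b": 10.0},
                                {"h": 2.0, "b": 40.0}, seed=3)
        texts = []
        for run in range(2):
            data = sim.simulate_community(prof, n_core_families=15,
                                          n_markers=5)
            out = tmp_path / f"run{run}"
            paths = sim.write_community(data, out)
            texts.append({k: open(p, "rb").read() for k, p in paths.items()})
        assert texts[0] == texts[1]
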