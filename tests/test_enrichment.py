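"""OBO parsing, true-path propagation, Fisher enrichment, and category
percentage tables."""

import math

import numpy as np
import pandas as pd
import pytest

from holopipe import enrichment as en


def write_obo(tmp_path, text):
    p = tmp_path / "test.obo"
    p.write_text("format-version: 1.2\n\n" + text)
    return p

CHAIN = """[Term]
id: GO:0000001
name: A
namespace: biological_process

[Term]
id: GO:0000002
name: B
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
namespace: biological_process
is_a: GO:0000002
"""


class TestParseObo:
    def test_chain_parents_and_ancestors(self, tmp_path):
        dag = en.parse_obo(write_obo(tmp_path, CHAIN))
        assert dag.parents("GO:0000003") == {"GO:0000002"}
        assert dag.ancestors("GO:0000003") == {"GO:0000001", "GO:0000002"}

    def test_obsolete_term_skipped(self, tmp_path):
        text = CHAIN + """
[Term]
id: GO:0000009
name: dead
is_obsolete: true
"""
        dag = en.parse_obo(write_obo(tmp_path, text))
        assert "GO:0000009" not in dag.terms

    def test_diamond_ancestors_counted_once(self, tmp_path):
        text = """[Term]
id: GO:0000001
name: A
namespace: biological_process

[Term]
id: GO:0000002
name: B
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: D
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003
"""
        dag = en.parse_obo(write_obo(tmp_path, text))
        assert dag.ancestors("GO:0000004") == {"GO:0000001", "GO:0000002",
                                               "GO:0000003"}

    def test_cycle_detected(self, tmp_path):
        text = """[Term]
id: GO:0000001
name: A
is_a: GO:0000002

[Term]
id: GO:0000002
name: B
is_a: GO:0000001
"""
        with pytest.raises(ValueError, match="cycle"):
            en.parse_obo(write_obo(tmp_path, text))

    def test_dangling_parent_detected(self, tmp_path):
        text = """[Term]
id: GO:0000001
name: A
is_a: GO:0000077
"""
        with pytest.raises(ValueError, match="dangling"):
            en.parse_obo(write_obo(tmp_path, text))

    def test_part_of_toggle(self, tmp_path):
        text = """[Term]
id: GO:0000001
name: A

[Term]
id: GO:0000002
name: B
relationship: part_of GO:0000001
"""
        p = write_obo(tmp_path, text)
        assert en.parse_obo(p).ancestors("GO:0000002") == {"GO:0000001"}
        assert en.parse_obo(p, include_part_of=False) \
            .ancestors("GO:0000002") == frozenset()


class TestPropagate:
    def test_chain_closure(self, tmp_path):
        dag = en.parse_obo(write_obo(tmp_path, CHAIN))
        ann = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:0000003"]})
        assert en.propagate(ann, dag)["g1"] == {"GO:0000001", "GO:0000002",
                                                "GO:0000003"}

    def test_shared_ancestor_counted_once(self, tmp_path):
        dag = en.parse_obo(write_obo(tmp_path, CHAIN))
        ann = pd.DataFrame({"gene_id": ["g1", "g1"],
                            "go_id": ["GO:0000002", "GO:0000003"]})
        closure = en.propagate(ann, dag)["g1"]
        assert closure == {"GO:0000001", "GO:0000002", "GO:0000003"}

    def test_unknown_term_warns_and_skips(self, tmp_path):
        dag = en.parse_obo(write_obo(tmp_path, CHAIN))
        ann = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:9999999"]})
        with pytest.warns(UserWarning, match="not in ontology"):
            assert en.propagate(ann, dag) == {}

    def test_parent_counts_monotone_on_random_dag(self, tmp_path):
        rng = np.random.default_rng(0)
        lines = ["[Term]", "id: T0000", "name: root",
                 "namespace: biological_process", ""]
        for i in range(1, 50):
            lines += ["[Term]", f"id: T{i:04d}", f"name: t{i}",
                      "namespace: biological_process"]
            n_par = min(i, int(rng.integers(1, 3)))
            for p in rng.choice(i, size=n_par, replace=False):
                lines.append(f"is_a: T{p:04d}")
            lines.append("")
        dag = en.parse_obo(write_obo(tmp_path, "\n".join(lines)))
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "go_id": [f"T{rng.integers(50):04d}" for _ in range(200)]})
        closure = en.propagate(ann, dag)
        counts: dict[str, int] = {}
        for terms in closure.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        for child, parents in dag.parents_map.items():
            for p in parents:
                assert counts.get(p, 0) >= counts.get(child, 0)


def enumeration_oracle(K, k, n, N):
    """Exhaustive hypergeometric upper tail from binomial coefficients."""
    denom = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / denom


class TestFisherTerm:
    def test_worked_example(self):
        p, expected = en.fisher_term(4, 3, 5, 10)
        assert p == pytest.approx(66 / 252)
        assert expected == pytest.approx(2.0)

    def test_zero_overlap_p_one(self):
        p, _ = en.fisher_term(4, 0, 5, 10)
        assert p == 1.0

    def test_published_expected_count(self):
        # study fraction 607.32/2124 applied to 450 annotated genes
        _, expected = en.fisher_term(450, 216, 607_320, 2_124_000)
        assert expected == pytest.approx(128.67, abs=0.005)

    def test_matches_enumeration_on_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            N = int(rng.integers(1, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, K + n - N)
            k = int(rng.integers(lo, min(K, n) + 1))
            p, _ = en.fisher_term(K, k, n, N)
            assert p == pytest.approx(enumeration_oracle(K, k, n, N),
                                      rel=1e-9, abs=1e-12)

    def test_expected_linear_in_annotated(self):
        e1 = en.fisher_term(100, 0, 50, 1000)[1]
        e2 = en.fisher_term(200, 0, 50, 1000)[1]
        assert e2 == pytest.approx(2 * e1)

    def test_impossible_table_rejected(self):
        with pytest.raises(ValueError):
            en.fisher_term(5, 6, 10, 20)
        with pytest.raises(ValueError):
            en.fisher_term(25, 0, 10, 20)


class TestEnrich:
    @pytest.fixture()
    def dag(self, tmp_path):
        return en.parse_obo(write_obo(tmp_path, CHAIN))

    def test_study_equals_background_all_p_one(self, dag):
        ann = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                            "go_id": ["GO:0000003"] * 10})
        genes = {f"g{i}" for i in range(10)}
        table = en.enrich(genes, genes, ann, dag)
        assert (table["p_value"] == 1.0).all()

    def test_empty_study_rejected(self, dag):
        ann = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:0000003"]})
        with pytest.raises(ValueError, match="empty study"):
            en.enrich(set(), {"g1"}, ann, dag)

    def test_study_outside_background_rejected(self, dag):
        ann = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:0000003"]})
        with pytest.raises(ValueError, match="subset"):
            en.enrich({"gX"}, {"g1"}, ann, dag)

    def test_namespace_filter(self, tmp_path):
        text = CHAIN + """
[Term]
id: GO:0000008
name: mf-term
namespace: molecular_function
"""
        dag = en.parse_obo(write_obo(tmp_path, text))
        ann = pd.DataFrame({"gene_id": ["g1", "g1"],
                            "go_id": ["GO:0000003", "GO:0000008"]})
        table = en.enrich({"g1"}, {"g1"}, ann, dag)
        assert "GO:0000008" not in set(table["term"])

    def test_propagation_monotone_on_emitted_table(self, dag):
        rng = np.random.default_rng(2)
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "go_id": rng.choice(["GO:0000002", "GO:0000003"], size=40)})
        table = en.enrich({f"g{i}" for i in range(10)},
                          {f"g{i}" for i in range(40)}, ann, dag)
        counts = dict(zip(table["term"], table["annotated"]))
        assert counts["GO:0000001"] >= counts["GO:0000002"] \
            >= counts.get("GO:0000003", 0)

    def test_null_p_values_conservative(self):
        # planted-null terms: the p-value distribution is stochastically
        # >= uniform because of hypergeometric discreteness
        rng = np.random.default_rng(4)
        N, n = 500, 100
        ps = []
        for _ in range(2000):
            K = int(rng.integers(1, 50))
            genes = rng.choice(N, size=K, replace=False)
            k = int((genes < n).sum())   # study = first n genes
            ps.append(en.fisher_term(K, k, n, N)[0])
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 0.02


class TestCategoryPercentages:
    def test_single_category_is_100(self):
        t = pd.DataFrame({"genome_id": ["g"] * 10,
                          "gene_id": [f"x{i}" for i in range(10)],
                          "category": ["Carbohydrates"] * 10})
        pct = en.category_percentages(t)
        assert pct.loc["g", "Carbohydrates"] == 100.0

    def test_two_equal_categories_split_evenly(self):
        t = pd.DataFrame({"genome_id": ["g"] * 10,
                          "gene_id": [f"x{i}" for i in range(10)],
                          "category": ["A"] * 5 + ["B"] * 5})
        pct = en.category_percentages(t)
        assert pct.loc["g", "A"] == pct.loc["g", "B"] == 50.0

    def test_row_sums_and_duplication_invariance(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"genome_id": rng.choice(["g1", "g2"], size=60),
                          "gene_id": [f"x{i}" for i in range(60)],
                          "category": rng.choice(list("ABC"), size=60)})
        pct = en.category_percentages(t)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, atol=1e-6)
        doubled = pd.concat([t, t], ignore_index=True)
        pd.testing.assert_frame_equal(en.category_percentages(doubled), pct)
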