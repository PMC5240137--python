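"""GO-term enrichment of a study gene set against a background.

A minimal GO DAG (OBO 1.2 subset: id, name, namespace, is_a,
relationship: part_of, is_obsolete) is loaded and annotations are
propagated by the true-path rule: a gene annotated to a term is annotated
to all its ancestors.  Each term is then tested with a one-sided Fisher
exact test (hypergeometric upper tail) of the 2x2 table

    study x annotated-to-term,

reported with the term's "Annotated" (background genes carrying the term),
"Significant" (study genes carrying it) and "Expected"
(annotated x study-fraction) counts — the classic per-term layout.  Raw
p-values are reported; an optional Benjamini–Hochberg column is available
but off by default.  The gene universe is the set of background genes with
at least one propagated annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom


@dataclass
class GoDag:
    """Acyclic is_a (+ optional part_of) hierarchy of GO terms."""

    parents_map: dict[str, set[str]]
    names: dict[str, str]
    namespaces: dict[str, str]
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @property
    def terms(self) -> set[str]:
        return set(self.parents_map)

    def parents(self, term: str) -> set[str]:
        return set(self.parents_map[term])

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of a term (each counted once)."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents_map[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents_map[t])
        result = frozenset(out)
        self._ancestors[term] = result
        return result

    def namespace(self, term: str) -> str:
        return self.namespaces.get(term, "")


def parse_obo(path, include_part_of: bool = True) -> GoDag:
    """Load an OBO file into a validated :class:`GoDag`.

    Obsolete terms are skipped.  A parent reference to a term without a
    stanza (dangling) or a cycle in the hierarchy raises ``ValueError``.
    """
    graph = obonet.read_obo(str(path))
    dangling = [n for n, data in graph.nodes(data=True) if "name" not in data]
    if dangling:
        raise ValueError(f"dangling parent terms (no stanza): {sorted(dangling)}")
    parents: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for child, parent, rel in graph.edges(keys=True):
        if rel == "is_a" or (include_part_of and rel == "part_of"):
            parents[child].add(parent)
    check = nx.DiGraph()
    check.add_nodes_from(parents)
    check.add_edges_from((c, p) for c, ps in parents.items() for p in ps)
    if not nx.is_directed_acyclic_graph(check):
        cycle = nx.find_cycle(check)
        raise ValueError(f"cycle in ontology: {cycle}")
    return GoDag(
        parents_map=parents,
        names={n: d.get("name", "") for n, d in graph.nodes(data=True)},
        namespaces={n: d.get("namespace", "") for n, d in graph.nodes(data=True)},
    )


def propagate(annotations: pd.DataFrame, dag: GoDag) -> dict[str, set[str]]:
    """True-path closure: gene -> set of annotated terms plus all ancestors.

    ``annotations`` has columns gene_id, go_id.  Terms absent from the DAG
    are skipped with a warning.
    """
    known = dag.terms
    unknown = set(annotations["go_id"]) - known
    if unknown:
        warnings.warn(f"{len(unknown)} annotation terms not in ontology; skipped")
    out: dict[str, set[str]] = {}
    for gene, term in annotations[["gene_id", "go_id"]].itertuples(index=False):
        if term not in known:
            continue
        s = out.setdefault(gene, set())
        s.add(term)
        s.update(dag.ancestors(term))
    return out


def fisher_term(annotated: int, significant: int, n_study: int,
                n_background: int) -> tuple[float, float]:
    """One-sided Fisher (hypergeometric upper tail) p and expected count.

    ``annotated`` (K) background genes carry the term, ``significant`` (k)
    of the ``n_study`` (n) study genes carry it, out of ``n_background``
    (N) genes.  p = P(X >= k) for X ~ Hypergeom(N, K, n); expected = K*n/N.
    """
    K, k, n, N = annotated, significant, n_study, n_background
    if not (0 <= k <= min(K, n) and K <= N and n <= N and k >= K + n - N):
        raise ValueError(f"impossible 2x2 table: K={K}, k={k}, n={n}, N={N}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(p, 1.0), K * n / N


def enrich(study_genes, background_genes, annotations: pd.DataFrame,
           dag: GoDag, namespace: str = "biological_process",
           add_bh: bool = False) -> pd.DataFrame:
    """Per-term enrichment table of a study set within a background.

    Rows (one per term with at least one annotated background gene in the
    requested namespace) are sorted by ascending p-value.  Columns: term,
    name, annotated, significant, expected, p_value (+ p_bh if requested).
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    gene_terms = propagate(annotations, dag)
    universe = {g for g in background if gene_terms.get(g)}
    study_u = study & universe
    N = len(universe)
    n = len(study_u)
    if N == 0 or n == 0:
        raise ValueError("no annotated genes in background/study")
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in gene_terms[g]:
            term_genes.setdefault(t, set()).add(g)
    rows = []
    for term, genes in term_genes.items():
        if namespace and dag.namespace(term) != namespace:
            continue
        K = len(genes)
        k = len(genes & study_u)
        p, expected = fisher_term(K, k, n, N)
        rows.append({"term": term, "name": dag.names.get(term, ""),
                     "annotated": K, "significant": k,
                     "expected": expected, "p_value": p})
    table = pd.DataFrame(rows, columns=["term", "name", "annotated",
                                        "significant", "expected", "p_value"])
    table = table.sort_values(["p_value", "term"]).reset_index(drop=True)
    if add_bh and len(table):
        table["p_bh"] = false_discovery_control(table["p_value"], method="bh")
    return table


def category_percentages(categories: pd.DataFrame,
                         genomes: list[str] | None = None) -> pd.DataFrame:
    """Percent of each genome's annotated genes per functional category.

    ``categories`` has columns genome_id, gene_id, category (flat,
    subsystem-style labels).  Rows sum to 100 when categories are exclusive.
    """
    t = categories.drop_duplicates(["genome_id", "gene_id", "category"])
    if genomes is not None:
        t = t[t["genome_id"].isin(set(genomes))]
    counts = t.groupby(["genome_id", "category"]).size().unstack(fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.index.name = "genome_id"
    return pct
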