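"""Differential-coverage + composition binning of contigs.

Contigs are embedded in a standardized feature space (log-depth in the two
libraries, optionally GC and coding density, and the top principal
components of the tetranucleotide profile) and clustered with DBSCAN.  This
automates, with fixed parameters, the interactive coverage-plot contig
selection used in differential-coverage binning workflows.  Bins are then
refined by recruiting unbinned contigs through read-pair links and by
purging contigs labelled as eukaryotic.

Determinism: contigs are processed in lexicographic contig_id order; border
points join the first core cluster encountered in that order; bin labels
are numbered by order of first appearance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

UNBINNED = "unbinned"

FEATURE_CHOICES = ("logcovA", "logcovB", "gc", "coding_density",
                   "tnf_pc1", "tnf_pc2", "tnf_pc3")


@dataclass
class BinningConfig:
    """Parameters of the automated binning step.

    ``eps``/``min_pts`` are the DBSCAN neighbourhood radius (in standardized
    feature space) and core-point threshold (neighbour count including the
    point itself).  Contigs shorter than ``min_contig_len`` are excluded:
    composition features are unstable below ~1 kb.  ``pseudo_depth`` keeps
    zero-coverage contigs finite under the log transform.
    """

    eps: float = 0.5
    min_pts: int = 5
    min_contig_len: int = 1000
    features: tuple[str, ...] = ("logcovA", "logcovB", "coding_density",
                                 "tnf_pc1", "tnf_pc2", "tnf_pc3")
    pseudo_depth: float = 0.01
    min_links: int = 3

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.pseudo_depth <= 0:
            raise ValueError("pseudo_depth must be positive")
        unknown = set(self.features) - set(FEATURE_CHOICES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")


def standardize_features(table: pd.DataFrame, config: BinningConfig
                         ) -> tuple[np.ndarray, list[str], dict]:
    """Standardized feature matrix for the contigs passing the length filter.

    Returns ``(matrix, contig_ids, params)`` with rows in lexicographic
    contig_id order.  ``params`` records per-column centre/scale and the TNF
    PCA basis so the transform is reproducible.  Zero-variance columns are
    dropped with a warning.
    """
    t = table[table["length"] >= config.min_contig_len]
    t = t.sort_values("contig_id").reset_index(drop=True)
    if len(t) < 2:
        raise ValueError("fewer than 2 contigs pass the length filter")
    ids = t["contig_id"].tolist()
    tnf_cols = [c for c in t.columns if c.startswith("tnf_")]
    cols: dict[str, np.ndarray] = {}
    pca_params = None
    need_pcs = [f for f in config.features if f.startswith("tnf_pc")]
    if need_pcs:
        n_pc = max(int(f[-1]) for f in need_pcs)
        pca = PCA(n_components=n_pc, svd_solver="full")
        proj = pca.fit_transform(t[tnf_cols].to_numpy())
        # fix component sign: largest-magnitude loading positive
        for j in range(n_pc):
            comp = pca.components_[j]
            if comp[np.argmax(np.abs(comp))] < 0:
                pca.components_[j] = -comp
                proj[:, j] = -proj[:, j]
        for j in range(n_pc):
            cols[f"tnf_pc{j + 1}"] = proj[:, j]
        pca_params = {"mean": pca.mean_.tolist(),
                      "components": pca.components_.tolist()}
    for f in config.features:
        if f == "logcovA":
            cols[f] = np.log10(t["cov_A"].to_numpy() + config.pseudo_depth)
        elif f == "logcovB":
            cols[f] = np.log10(t["cov_B"].to_numpy() + config.pseudo_depth)
        elif f in ("gc", "coding_density"):
            cols[f] = t[f].to_numpy(dtype=float)

    kept, centred = [], []
    params = {"features": [], "center": [], "scale": [], "tnf_pca": pca_params}
    for f in config.features:
        x = cols[f]
        mu, sd = float(np.mean(x)), float(np.std(x))
        if sd == 0.0:
            warnings.warn(f"feature {f} has zero variance; dropped")
            continue
        kept.append(f)
        centred.append((x - mu) / sd)
        params["features"].append(f)
        params["center"].append(mu)
        params["scale"].append(sd)
    if not kept:
        raise ValueError("all selected features have zero variance")
    return np.column_stack(centred), ids, params


def cluster_contigs(matrix: np.ndarray, contig_ids: list[str],
                    config: BinningConfig) -> dict[str, str]:
    """DBSCAN clustering of the standardized matrix.

    Returns a contig_id -> bin_id map; noise contigs get the reserved
    ``unbinned`` label.  Input rows must already be in lexicographic
    contig_id order (as produced by :func:`standardize_features`).
    """
    if not np.all(np.isfinite(matrix)):
        raise ValueError("feature matrix contains non-finite values")
    labels = DBSCAN(eps=config.eps, min_samples=config.min_pts).fit_predict(matrix)
    if (labels == -1).all():
        warnings.warn("all contigs are density noise; nothing binned")
    relabel: dict[int, str] = {}
    out: dict[str, str] = {}
    for cid, lab in zip(contig_ids, labels):
        if lab == -1:
            out[cid] = UNBINNED
        else:
            if lab not in relabel:
                relabel[lab] = f"bin_{len(relabel) + 1:03d}"
            out[cid] = relabel[lab]
    return out


def recruit_linked_contigs(assignment: dict[str, str], links: pd.DataFrame,
                           min_links: int = 3) -> dict[str, str]:
    """Recruit unbinned contigs through read-pair links, to a fixed point.

    An unbinned contig whose summed link count reaches ``min_links`` for
    exactly one bin joins that bin; contigs reaching the threshold for two
    or more bins are ambiguous and stay unbinned.  Recruitment never removes
    a contig from a bin; it iterates until no contig moves.
    """
    out = dict(assignment)
    # adjacency with pooled pair counts
    adj: dict[str, dict[str, int]] = {}
    for ci, cj, n in links[["contig_i", "contig_j", "n_pairs"]].itertuples(index=False):
        if ci == cj:
            continue
        adj.setdefault(ci, {})[cj] = adj.setdefault(ci, {}).get(cj, 0) + int(n)
        adj.setdefault(cj, {})[ci] = adj.setdefault(cj, {}).get(ci, 0) + int(n)
    for _ in range(len(out)):
        moved = False
        for cid in sorted(out):
            if out[cid] != UNBINNED:
                continue
            per_bin: dict[str, int] = {}
            for other, n in adj.get(cid, {}).items():
                b = out.get(other, UNBINNED)
                if b != UNBINNED:
                    per_bin[b] = per_bin.get(b, 0) + n
            above = [b for b, n in per_bin.items() if n >= min_links]
            if len(above) == 1:
                out[cid] = above[0]
                moved = True
        if not moved:
            break
    return out


def purge_contaminants(bin_contigs: list[str], taxon_labels: dict[str, str],
                       contig_markers: dict[str, list[str]] | None = None
                       ) -> tuple[list[str], list[str]]:
    """Remove eukaryote-labelled contigs from a bacterial bin.

    ``taxon_labels`` maps contig_id to a coarse taxon label (may be partial);
    contigs labelled ``eukaryote`` are removed — unless they carry bacterial
    single-copy marker genes, a conflict resolved by keeping the contig with
    a warning.  Returns ``(kept, removed)``.
    """
    contig_markers = contig_markers or {}
    kept, removed = [], []
    for cid in bin_contigs:
        if taxon_labels.get(cid) == "eukaryote":
            if contig_markers.get(cid):
                warnings.warn(f"contig {cid} labelled eukaryote but carries "
                              f"marker genes; kept")
                kept.append(cid)
            else:
                removed.append(cid)
        else:
            kept.append(cid)
    return kept, removed


def evaluate_binning(assignment: dict[str, str], truth: dict[str, str],
                     contig_lengths: dict[str, int], min_len: int = 0
                     ) -> pd.DataFrame:
    """Length-weighted precision/recall/F1 per bin against the truth map.

    Precision: length from the bin's majority genome / total binned length.
    Recall: that same length / the genome's total contig length.  Contigs
    shorter than ``min_len`` are excluded from both sides.
    """
    missing = [c for c in assignment if c not in truth]
    if missing:
        raise ValueError(f"truth map missing contigs: {missing[:5]}")
    use = {c for c, ln in contig_lengths.items() if ln >= min_len}
    genome_total: dict[str, int] = {}
    for c, g in truth.items():
        if c in use:
            genome_total[g] = genome_total.get(g, 0) + contig_lengths[c]
    per_bin: dict[str, dict[str, int]] = {}
    for c, b in assignment.items():
        if b == UNBINNED or c not in use:
            continue
        per_bin.setdefault(b, {})[truth[c]] = \
            per_bin.setdefault(b, {}).get(truth[c], 0) + contig_lengths[c]
    rows = []
    for b in sorted(per_bin):
        comp = per_bin[b]
        total = sum(comp.values())
        genome, best = max(comp.items(), key=lambda kv: kv[1])
        precision = best / total
        recall = best / genome_total[genome] if genome_total.get(genome) else 0.0
        f1 = 2 * precision * recall / (precision + recall) \
            if precision + recall else 0.0
        rows.append({"bin_id": b, "majority_genome": genome,
                     "binned_length": total, "precision": precision,
                     "recall": recall, "f1": f1})
    return pd.DataFrame(rows,
                        columns=["bin_id", "majority_genome", "binned_length",
                                 "precision", "recall", "f1"])


def bin_contig_lists(assignment: dict[str, str]) -> dict[str, list[str]]:
    """Invert a contig -> bin map into bin -> sorted contig list (no noise)."""
    bins: dict[str, list[str]] = {}
    for cid, b in assignment.items():
        if b != UNBINNED:
            bins.setdefault(b, []).append(cid)
    return {b: sorted(cs) for b, cs in sorted(bins.items())}
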