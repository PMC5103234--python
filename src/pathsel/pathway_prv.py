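"""Positional rate variation along a pathway, and per-gene UPGMA trees.

Positional rate variation (PRV) is the expectation that evolutionary rates
(Ka/Ks) increase from upstream to downstream pathway positions because
upstream mutations are more pleiotropic.  The association is measured with
Kendall's tau-b (tie-corrected — pathway positions are heavily tied) plus a
leave-one-out robustness re-test dropping the single largest Ka/Ks value.

Trees are average-linkage (UPGMA) clusterings of per-site p-distances with
pairwise deletion; no multiple-hit correction is applied, as within-species
divergences are far below saturation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, HaplotypeAlignment, PathwayMap

logger = logging.getLogger(__name__)

__all__ = [
    "PRVResult", "kendall_tau", "prv_test",
    "pairwise_distance_matrix", "upgma", "ClusterNode",
]


@dataclass
class PRVResult:
    pathway: str
    group: str
    tau: float
    p_value: float
    n_genes: int
    dropped_gene: str | None = None
    tau_without_max: float | None = None
    p_without_max: float | None = None

    def __post_init__(self) -> None:
        assert abs(self.tau) <= 1 + 1e-12


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with a two-sided p-value.

    tau-b applies the standard tie correction
    (C - D) / sqrt((n0 - n1)(n0 - n2)).  For n <= 8 the p-value comes from
    exact enumeration of all permutations of one vector (valid under ties);
    larger samples use the normal approximation with tie-adjusted variance.
    An all-tied vector leaves tau undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("kendall_tau requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for an all-tied vector")
    tau, p_asym = stats.kendalltau(x, y, method="asymptotic")
    if n <= 8:
        # the tie structure (hence the tau-b denominator) is invariant under
        # permutation, so ranking |C - D| is equivalent to ranking |tau|
        sign_x = np.sign(x[:, None] - x[None, :])
        iu = np.triu_indices(n, 1)
        sx = sign_x[iu]

        def num(yv: np.ndarray) -> float:
            return float(np.sum(sx * np.sign(yv[:, None] - yv[None, :])[iu]))

        observed = abs(num(y))
        count = sum(1 for perm in itertools.permutations(y)
                    if abs(num(np.asarray(perm))) >= observed - 1e-9)
        p = count / math.factorial(n)
    else:
        p = p_asym
    return float(tau), float(p)


def prv_test(
    kaks_table: pd.DataFrame,
    pathway_map: PathwayMap,
    pathway: str,
    group: str,
) -> PRVResult:
    """Kendall tau-b between pathway position and Ka/Ks for one pathway/group.

    ``kaks_table`` needs columns gene, group, ratio; rows with undefined
    (NaN) ratios are excluded with a logged count.  The leave-one-out
    re-test drops the single maximum-ratio gene.  Fewer than 3 usable genes
    is an error.
    """
    sub = kaks_table[(kaks_table["group"] == group)
                     & kaks_table["gene"].isin(pathway_map.genes_in(pathway))].copy()
    n_undef = int(sub["ratio"].isna().sum())
    if n_undef:
        logger.info("%s/%s: excluded %d genes with undefined Ka/Ks", pathway, group, n_undef)
    sub = sub.dropna(subset=["ratio"])
    if len(sub) < 3:
        raise ValueError(f"{pathway}/{group}: {len(sub)} usable genes (need >= 3)")
    sub["ppi"] = [pathway_map.ppi(g) for g in sub["gene"]]
    tau, p = kendall_tau(sub["ppi"].to_numpy(), sub["ratio"].to_numpy())
    result = PRVResult(pathway=pathway, group=group, tau=tau, p_value=p, n_genes=len(sub))
    if len(sub) > 3:
        imax = sub["ratio"].idxmax()
        dropped = sub.loc[imax, "gene"]
        rest = sub.drop(index=imax)
        try:
            tau2, p2 = kendall_tau(rest["ppi"].to_numpy(), rest["ratio"].to_numpy())
            result.dropped_gene = dropped
            result.tau_without_max = tau2
            result.p_without_max = p2
        except ValueError:
            logger.info("%s/%s: leave-one-out tau undefined after dropping %s",
                        pathway, group, dropped)
    return result


# ---------------------------------------------------------------------------
# distances and UPGMA
# ---------------------------------------------------------------------------

def pairwise_distance_matrix(alignment: HaplotypeAlignment) -> np.ndarray:
    """Symmetric per-site p-distance matrix with pairwise deletion."""
    enc = alignment.encoded()
    n = enc.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    valid = enc != MISSING
    out = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            l_ij = int(both.sum())
            d = int((enc[i][both] != enc[j][both]).sum()) / l_ij if l_ij else 0.0
            out[i, j] = out[j, i] = d
    return out


@dataclass
class ClusterNode:
    """Node of a rooted ultrametric (UPGMA) tree."""

    height: float
    label: str | None = None
    children: tuple["ClusterNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [leaf for ch in self.children for leaf in ch.leaves()]

    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: ClusterNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{blen:.{precision}g}"
            inner = ",".join(fmt(ch, node.height) for ch in node.children)
            return f"({inner}):{blen:.{precision}g}"

        if self.is_leaf:
            return f"{self.label}:0;"
        inner = ",".join(fmt(ch, self.height) for ch in self.children)
        return f"({inner});"


def upgma(matrix: np.ndarray, labels: list[str]) -> ClusterNode:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Merges the closest pair iteratively with size-weighted average linkage;
    node heights are half the merge distance, so the tree is ultrametric.
    Ties on the minimum distance are broken deterministically by the
    lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest leaf).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(matrix < 0):
        raise ValueError("distances must be non-negative")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")

    clusters: dict[int, ClusterNode] = {
        i: ClusterNode(height=0.0, label=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    min_label = {i: labels[i] for i in range(n)}
    dist = {frozenset((i, j)): matrix[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n

    while len(clusters) > 1:
        best_key = min(
            dist,
            key=lambda k: (dist[k], tuple(sorted(min_label[i] for i in k))),
        )
        i, j = sorted(best_key, key=lambda k: min_label[k])  # children in label order
        d_ij = dist[best_key]
        node = ClusterNode(
            height=d_ij / 2.0,
            children=(clusters[i], clusters[j]),
        )
        si, sj = sizes[i], sizes[j]
        new_dists = {}
        for k in clusters:
            if k in (i, j):
                continue
            d_new = (si * dist[frozenset((i, k))] + sj * dist[frozenset((j, k))]) / (si + sj)
            new_dists[k] = d_new
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        del clusters[i], clusters[j], sizes[i], sizes[j]
        ml = min(min_label.pop(i), min_label.pop(j))
        clusters[next_id] = node
        sizes[next_id] = si + sj
        min_label[next_id] = ml
        for k, d_new in new_dists.items():
            dist[frozenset((next_id, k))] = d_new
        next_id += 1

    return clusters.popitem()[1]
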