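"""Conditional-inference-tree marker discovery.

A deliberately simple univariate conditional inference tree for class
labels: at each node every candidate gene is tested for association with
the label by a rank-based permutation test (a Kruskal–Wallis-type statistic
on ranks), the per-gene p-values are Bonferroni-adjusted across genes, and
the node splits on the most significant gene — at the cut-off maximizing a
two-sample association statistic over midpoints — only when the adjusted
p-value clears alpha. This mirrors the split/stop logic of the classical
conditional-inference framework without its full influence-function
machinery, and is documented as such.

Permutation p-values use exact enumeration when the number of distinct
label rearrangements is at most 10,000 and Monte-Carlo sampling otherwise.
The statistic is rank-based, so trees are invariant to strictly monotone
transforms of any gene and to sample order. The left branch always takes
values <= cut-off ("beneath the cut-off").
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import StatisticsError
from .nanostring_io import CountMatrix

_EXACT_LIMIT = 10_000
_TIE_EPS = 1e-9  # slack when comparing permuted statistics to the observed one
_SCREEN_PERMS = 999
_REFINE_COUNT = 20  # refine genes whose screen-stage exceedance count is <= this


# ---------------------------------------------------------------------------
# rank-association statistic and permutation machinery
# ---------------------------------------------------------------------------

def _group_layout(labels: Sequence) -> tuple[np.ndarray, list[tuple[int, int]], np.ndarray]:
    """Label codes, contiguous block bounds after sorting by group, sort order."""
    codes, _ = pd.factorize(np.asarray(labels), sort=False)
    order = np.argsort(codes, kind="stable")
    sizes = np.bincount(codes)
    bounds, start = [], 0
    for n_g in sizes:
        bounds.append((start, start + int(n_g)))
        start += int(n_g)
    return codes, bounds, order


def _h_statistic(ranks_sorted: np.ndarray, bounds: list[tuple[int, int]]) -> np.ndarray:
    """Kruskal–Wallis-type statistic (no tie correction) for label-sorted ranks.

    ``ranks_sorted`` may be (n,) or (genes, n) or (genes, perms, n); the
    statistic is computed over the trailing axis using the fixed group blocks.
    Without tie correction the statistic is a strictly increasing transform of
    the tie-corrected H for fixed data, so permutation p-values coincide.
    """
    ranks_sorted = np.asarray(ranks_sorted, dtype=float)
    n = ranks_sorted.shape[-1]
    acc = np.zeros(ranks_sorted.shape[:-1])
    for s, e in bounds:
        block_sum = ranks_sorted[..., s:e].sum(axis=-1)
        acc = acc + block_sum * block_sum / (e - s)
    return 12.0 / (n * (n + 1)) * acc - 3.0 * (n + 1)


def _n_distinct_relabellings(sizes: np.ndarray) -> int:
    total = math.factorial(int(sizes.sum()))
    for n_g in sizes:
        total //= math.factorial(int(n_g))
    return total


def _enumerate_assignments(n: int, sizes: Sequence[int]) -> list[np.ndarray]:
    """All distinct ways to partition n positions into ordered group blocks.

    Each result is a permutation-style index vector arranging samples so that
    the first ``sizes[0]`` positions form group 0, etc.
    """
    assignments: list[np.ndarray] = []

    def rec(remaining: tuple[int, ...], gi: int, acc: list[int]) -> None:
        if gi == len(sizes) - 1:
            assignments.append(np.array(acc + list(remaining)))
            return
        for chosen in itertools.combinations(remaining, sizes[gi]):
            rest = tuple(x for x in remaining if x not in chosen)
            rec(rest, gi + 1, acc + list(chosen))

    rec(tuple(range(n)), 0, [])
    return assignments


def _perm_h(ranks: np.ndarray, idx: np.ndarray, bounds, chunk_elems: int = 4_000_000):
    """H for many arrangements: ranks (G, n) gathered through idx (B, n)."""
    G, n = ranks.shape
    B = idx.shape[0]
    out = np.empty((G, B))
    chunk = max(1, chunk_elems // max(1, B * n))
    for g0 in range(0, G, chunk):
        gathered = ranks[g0:g0 + chunk][:, idx]  # (g, B, n)
        out[g0:g0 + chunk] = _h_statistic(gathered, bounds)
    return out


def association_p(
    values: Sequence[float],
    labels: Sequence,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
    method: str = "auto",
    return_stat: bool = False,
):
    """Permutation p-value of the rank association between values and labels.

    Exact enumeration over all distinct label rearrangements when their
    number is <= 10,000 (or ``method="exact"``), Monte-Carlo with ``n_perm``
    draws otherwise. Constant values give p = 1.
    """
    values = np.asarray(values, dtype=float)
    codes, bounds, order = _group_layout(labels)
    sizes = np.bincount(codes)
    if len(sizes) < 2:
        raise StatisticsError("need >= 2 distinct labels")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    if np.ptp(values) == 0.0:
        return (1.0, 0.0) if return_stat else 1.0

    ranks = rankdata(values)[order][None, :]  # label-sorted, shape (1, n)
    h_obs = float(_h_statistic(ranks[0], bounds))
    n = len(values)

    total = _n_distinct_relabellings(sizes)
    use_exact = method == "exact" or (method == "auto" and total <= _EXACT_LIMIT)
    if method not in ("auto", "exact", "mc"):
        raise ValueError(f"method must be auto|exact|mc, got {method!r}")

    if use_exact:
        idx = np.array(_enumerate_assignments(n, [int(s) for s in sizes]))
        h_all = _perm_h(ranks, idx, bounds)[0]
        p = float(np.mean(h_all >= h_obs - _TIE_EPS))
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        h_all = _perm_h(ranks, idx, bounds)[0]
        exceed = int(np.sum(h_all >= h_obs - _TIE_EPS))
        p = (1 + exceed) / (n_perm + 1)
    return (p, h_obs) if return_stat else p


def _scan_genes(
    X: np.ndarray,
    labels: Sequence,
    rng: np.random.Generator,
    n_perm: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p and observed statistic for every gene at one node.

    Shares one permutation set across genes. Monte-Carlo runs in two stages:
    a cheap screen for all genes, then a refinement at the full ``n_perm``
    budget for genes whose screen p could plausibly clear Bonferroni-adjusted
    alpha (their exceedance count is small).
    """
    G, n = X.shape
    codes, bounds, order = _group_layout(labels)
    sizes = np.bincount(codes)
    ranks = rankdata(X, axis=1)[:, order]
    h_obs = _h_statistic(ranks, bounds)
    constant = np.ptp(X, axis=1) == 0.0

    total = _n_distinct_relabellings(sizes)
    if total <= _EXACT_LIMIT:
        idx = np.array(_enumerate_assignments(n, [int(s) for s in sizes]))
        h_all = _perm_h(ranks, idx, bounds)
        p = np.mean(h_all >= h_obs[:, None] - _TIE_EPS, axis=1)
    else:
        b1 = min(_SCREEN_PERMS, n_perm)
        idx = np.argsort(rng.random((b1, n)), axis=1)
        h_all = _perm_h(ranks, idx, bounds)
        exceed = np.sum(h_all >= h_obs[:, None] - _TIE_EPS, axis=1)
        p = (1 + exceed) / (b1 + 1)
        if n_perm > b1:
            refine = np.flatnonzero((exceed <= _REFINE_COUNT) & ~constant)
            if refine.size:
                idx2 = np.argsort(rng.random((n_perm, n)), axis=1)
                h2 = _perm_h(ranks[refine], idx2, bounds)
                exceed2 = np.sum(h2 >= h_obs[refine, None] - _TIE_EPS, axis=1)
                p[refine] = (1 + exceed2) / (n_perm + 1)
    p[constant] = 1.0
    h_obs[constant] = 0.0
    return p, h_obs


# ---------------------------------------------------------------------------
# cut-off search
# ---------------------------------------------------------------------------

def best_cutoff(
    values: Sequence[float],
    labels: Sequence,
    min_per_side: int = 1,
) -> tuple[float, float]:
    """Cut-off maximizing the split-vs-label chi-square association.

    Candidates are midpoints between adjacent sorted unique values; ties in
    the statistic break toward the smaller cut-off. Raises on constant
    values; returns ``(nan, nan)`` if no candidate leaves ``min_per_side``
    samples on each side.
    """
    values = np.asarray(values, dtype=float)
    codes, _ = pd.factorize(np.asarray(labels), sort=False)
    uniq = np.unique(values)
    if uniq.size < 2:
        raise StatisticsError("all values equal; no cut-off exists")

    n = len(values)
    k = codes.max() + 1
    class_tot = np.bincount(codes, minlength=k).astype(float)
    best = (np.nan, -np.inf)
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = 0.5 * (lo + hi)
        left = values <= cut
        n_left = int(left.sum())
        if n_left < min_per_side or n - n_left < min_per_side:
            continue
        left_counts = np.bincount(codes[left], minlength=k).astype(float)
        stat = 0.0
        for side_tot, side_counts in ((n_left, left_counts), (n - n_left, class_tot - left_counts)):
            expected = class_tot * side_tot / n
            nz = expected > 0
            stat += float(np.sum((side_counts[nz] - expected[nz]) ** 2 / expected[nz]))
        if stat > best[1] + _TIE_EPS:
            best = (cut, stat)
    if not np.isfinite(best[1]):
        return (np.nan, np.nan)
    return best


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Split node (gene/cutoff/adjusted_p + children) or leaf (class counts)."""

    class_counts: dict[str, int]
    gene: str | None = None
    cutoff: float | None = None
    adjusted_p: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.gene is None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    def to_dict(self) -> dict:
        d: dict = {"n": self.n, "class_counts": dict(self.class_counts)}
        if not self.is_leaf:
            d.update(gene=self.gene, cutoff=self.cutoff, adjusted_p=self.adjusted_p,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d

    def render(self, indent: str = "") -> str:
        counts = ", ".join(f"{c}:{n}" for c, n in self.class_counts.items())
        if self.is_leaf:
            return f"{indent}leaf [{counts}]"
        head = (f"{indent}{self.gene} <= {self.cutoff:g} "
                f"(adj p = {self.adjusted_p:.4g}) [{counts}]")
        return "\n".join([head,
                          self.left.render(indent + "  "),
                          self.right.render(indent + "  ")])


def split_genes(tree: TreeNode) -> list[str]:
    """Split genes in breadth-first (tier) order."""
    out, queue = [], [tree]
    while queue:
        node = queue.pop(0)
        if not node.is_leaf:
            out.append(node.gene)
            queue += [node.left, node.right]
    return out


def fit_ctree(
    matrix: CountMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    min_node: int = 3,
    n_perm: int = 9999,
    seed: int = 0,
) -> TreeNode:
    """Grow a conditional inference tree on the Endogenous genes.

    At each node: permutation p per gene, Bonferroni adjustment across the
    candidate genes, split on the winner (ties by larger observed statistic)
    at :func:`best_cutoff` when the adjusted p <= alpha, else stop. Nodes
    with fewer than ``2 * min_node`` samples, pure nodes, and nodes with no
    admissible cut-off become leaves. Deterministic for a fixed seed.
    """
    if matrix.n_samples == 0 or matrix.n_probes == 0:
        raise StatisticsError("empty matrix")
    if min_node < 2:
        raise ValueError("min_node must be >= 2")
    labels = pd.Series(labels)
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise StatisticsError("need >= 2 classes")

    endo = matrix.class_index("Endogenous")
    genes = [matrix.probes[i].name for i in endo]
    col_of = {s: j for j, s in enumerate(matrix.samples)}
    cols = np.array([col_of[s] for s in labels.index])
    X = matrix.values[np.ix_(endo, cols)]
    y = labels.to_numpy()
    seq = np.random.SeedSequence(seed)

    def counts_of(idx: np.ndarray) -> dict[str, int]:
        return {c: int(np.sum(y[idx] == c)) for c in classes if np.sum(y[idx] == c)}

    def grow(idx: np.ndarray) -> TreeNode:
        node_counts = counts_of(idx)
        if len(node_counts) < 2 or len(idx) < 2 * min_node or alpha <= 0:
            return TreeNode(node_counts)
        rng = np.random.default_rng(seq.spawn(1)[0])
        p, h = _scan_genes(X[:, idx], y[idx], rng, n_perm)
        p_adj = np.minimum(1.0, p * len(genes))
        best = int(np.lexsort((np.arange(len(genes)), -h, p_adj))[0])
        if p_adj[best] > alpha:
            return TreeNode(node_counts)
        cut, _stat = best_cutoff(X[best, idx], y[idx], min_per_side=min_node)
        if not np.isfinite(cut):
            return TreeNode(node_counts)
        left_mask = X[best, idx] <= cut
        node = TreeNode(node_counts, gene=genes[best], cutoff=float(cut),
                        adjusted_p=float(p_adj[best]))
        node.left = grow(idx[left_mask])
        node.right = grow(idx[~left_mask])
        return node

    return grow(np.arange(len(y)))


def predict(tree: TreeNode, profile: Mapping[str, float]) -> dict[str, float]:
    """Route a sample profile down the tree; returns leaf class proportions.

    A value exactly at a cut-off routes left (the <= branch).
    """
    node = tree
    while not node.is_leaf:
        if node.gene not in profile:
            raise KeyError(f"profile is missing tree gene {node.gene!r}")
        node = node.left if profile[node.gene] <= node.cutoff else node.right
    total = node.n
    return {c: k / total for c, k in node.class_counts.items()}


def predict_class(tree: TreeNode, profile: Mapping[str, float]) -> str:
    dist = predict(tree, profile)
    return max(dist, key=lambda c: (dist[c], c))


def loocv_accuracy(matrix: CountMatrix, labels: pd.Series, **fit_kwargs) -> float:
    """Leave-one-out classification accuracy of the tree learner."""
    labels = pd.Series(labels)
    hits = 0
    for sample in matrix.samples:
        rest = [s for s in matrix.samples if s != sample]
        tree = fit_ctree(matrix.subset_samples(rest), labels[rest], **fit_kwargs)
        pred = predict_class(tree, matrix.sample_profile(sample))
        hits += pred == labels[sample]
    return hits / matrix.n_samples
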