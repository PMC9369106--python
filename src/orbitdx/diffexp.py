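"""Group-vs-rest differential expression with normality-gated tests.

For each disease entity, every expressed gene is compared entity-vs-rest:
Shapiro–Wilk decides between a two-sided Welch t-test (both arms normal)
and the Wilcoxon–Mann–Whitney rank-sum test; raw p-values are adjusted
within entity by Benjamini–Hochberg. Per-entity significant-gene sets are
summarized with pairwise Venn-style overlaps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import StatisticsError
from .nanostring_io import CountMatrix
from .normalization import NoiseMask


def _arm_is_normal(values: np.ndarray, alpha: float) -> bool:
    """Shapiro–Wilk gate for one arm; tiny or constant arms count as non-normal."""
    if len(values) < 3 or np.ptp(values) == 0.0:
        return False
    return stats.shapiro(values).pvalue >= alpha


def test_gene(
    values: np.ndarray,
    in_group: np.ndarray,
    alpha_normality: float = 0.05,
    method: str = "auto",
    equal_var: bool = False,
) -> tuple[float, str | None]:
    """Two-sample test of one gene, entity arm vs rest arm.

    Returns ``(raw_p, direction)`` where direction is ``"up"``/``"down"``
    (sign of mean(group) - mean(rest)) or None when the means are equal.

    ``method`` is normally ``"auto"`` (Shapiro-gated); ``"ttest"`` or
    ``"ranksum"`` force a branch. The t-test is Welch by default
    (``equal_var=False``).
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    a, b = values[in_group], values[~in_group]
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each arm needs >= 2 samples")

    diff = a.mean() - b.mean()
    direction = None if diff == 0 else ("up" if diff > 0 else "down")
    if np.ptp(values) == 0.0:  # all tied across both arms
        return 1.0, None

    if method == "auto":
        use_t = _arm_is_normal(a, alpha_normality) and _arm_is_normal(b, alpha_normality)
    elif method in ("ttest", "ranksum"):
        use_t = method == "ttest"
    else:
        raise ValueError(f"method must be auto|ttest|ranksum, got {method!r}")

    if use_t:
        p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    else:
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return float(p), direction


@dataclass(frozen=True)
class DEResult:
    gene: str
    entity: str
    direction: str | None
    raw_p: float
    adjusted_p: float
    significant: bool


def differential_genes(
    matrix: CountMatrix,
    labels: pd.Series,
    mask: NoiseMask | None = None,
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
    method: str = "auto",
) -> pd.DataFrame:
    """Entity-vs-rest screen over all expressed genes, BH-adjusted per entity.

    Returns a tidy frame (gene, entity, direction, raw_p, adjusted_p,
    significant). The mask restricts testing to genes expressed in >= 1
    group; with ``mask=None`` all Endogenous genes are tested.
    """
    labels = pd.Series(labels)
    entities = list(dict.fromkeys(labels))
    if len(entities) < 2:
        raise StatisticsError("need >= 2 entities")
    for e in entities:
        if (labels == e).sum() < 2:
            raise StatisticsError(f"entity {e!r} has < 2 samples")

    genes = mask.expressed_genes() if mask is not None else [
        matrix.probes[i].name for i in matrix.class_index("Endogenous")
    ]
    col_of = {s: j for j, s in enumerate(matrix.samples)}
    cols = np.array([col_of[s] for s in labels.index])
    rows: list[DEResult] = []
    for entity in entities:
        in_group = (labels == entity).to_numpy()
        raw, dirs = [], []
        for gene in genes:
            p, d = test_gene(matrix.row(gene)[cols], in_group,
                             alpha_normality=alpha_normality, method=method)
            raw.append(p)
            dirs.append(d)
        if raw:
            reject, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
        else:
            reject, adj = np.array([], dtype=bool), np.array([])
        for gene, d, p, q, sig in zip(genes, dirs, raw, adj, reject):
            rows.append(DEResult(gene, entity, d, p, float(q), bool(sig)))
    return pd.DataFrame(rows)


def significant_sets(results: pd.DataFrame) -> dict[str, set[str]]:
    """Per-entity sets of significant genes from a differential_genes frame."""
    return {
        entity: set(sub.loc[sub["significant"], "gene"])
        for entity, sub in results.groupby("entity", sort=False)
    }


@dataclass
class OverlapSummary:
    """Pairwise Venn overlaps between per-entity significant-gene sets."""

    sets: dict[str, set[str]]
    pairs: pd.DataFrame  # entity_a, entity_b, n_overlap, pct_of_a, pct_of_b

    def overlap(self, a: str, b: str) -> set[str]:
        return self.sets[a] & self.sets[b]


def overlap_sets(sets: dict[str, set[str]]) -> OverlapSummary:
    """All pairwise intersections with counts and both directional percentages."""
    rows = []
    for a, b in itertools.combinations(sets, 2):
        inter = len(sets[a] & sets[b])
        rows.append({
            "entity_a": a,
            "entity_b": b,
            "n_overlap": inter,
            "pct_of_a": 100.0 * inter / len(sets[a]) if sets[a] else 0.0,
            "pct_of_b": 100.0 * inter / len(sets[b]) if sets[b] else 0.0,
        })
    return OverlapSummary(sets=dict(sets), pairs=pd.DataFrame(rows))
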