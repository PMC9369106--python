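"""Three-step nCounter data processing.

1. Technical factorial normalization: per sample, the background
   ``mean + 2*SD`` of the negative-control counts is subtracted from every
   Endogenous and Housekeeping probe (floored at zero).
2. Biological normalization: each sample is rescaled so its housekeeping
   geometric mean matches the cohort-wide geometric mean of those means.
3. Basal-noise filtering: per gene and disease group, a one-sided one-sample
   t-test against the group's negative-control threshold; a gene counts as
   expressed if it clears the threshold (p <= alpha) in at least one group.

Steps run technical-first, then biological; scale factors use the geometric
mean (standard for housekeeping normalization) with a +1 pseudocount applied
only inside the log-mean so zero counts are tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import NormalizationError, StatisticsError
from .nanostring_io import CountMatrix


@dataclass
class NoiseMask:
    """Per-gene expression calls from the basal-noise filter.

    ``per_group`` is a genes x groups boolean frame; ``expressed`` is True
    for genes expressed in at least one group. ``pvalues`` holds the
    underlying one-sided p-values.
    """

    per_group: pd.DataFrame
    pvalues: pd.DataFrame

    @property
    def expressed(self) -> pd.Series:
        return self.per_group.any(axis=1)

    @property
    def genes(self) -> list[str]:
        return list(self.per_group.index)

    def expressed_genes(self) -> list[str]:
        return list(self.per_group.index[self.expressed])


def _negative_background(matrix: CountMatrix) -> np.ndarray:
    """Per-sample background: mean + 2*SD of the negative-control counts."""
    neg = matrix.class_values("Negative")
    if neg.shape[0] < 2:
        raise NormalizationError(
            f"technical normalization needs >= 2 Negative probes, found {neg.shape[0]}"
        )
    return neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)


def technical_normalize(matrix: CountMatrix) -> CountMatrix:
    """Subtract the per-sample negative-control background, floored at zero.

    Negative and Positive control probes pass through unchanged.
    """
    background = _negative_background(matrix)
    out = matrix.copy()
    target = np.isin(out.probe_classes, ("Endogenous", "Housekeeping"))
    out.values[target] = np.maximum(out.values[target] - background[None, :], 0.0)
    return out


def biological_scale_factors(matrix: CountMatrix) -> np.ndarray:
    """Per-sample scale factors from the housekeeping geometric means."""
    hk = matrix.class_values("Housekeeping")
    if hk.shape[0] < 1:
        raise NormalizationError("biological normalization needs >= 1 Housekeeping probe")
    all_zero = np.flatnonzero((hk == 0).all(axis=0))
    if all_zero.size:
        bad = matrix.samples[all_zero[0]]
        raise NormalizationError(
            f"sample {bad!r} has all housekeeping counts zero; cannot normalize"
        )
    per_sample_gm = np.exp(np.mean(np.log(hk + 1.0), axis=0))
    cohort_gm = np.exp(np.mean(np.log(per_sample_gm)))
    return cohort_gm / per_sample_gm


def biological_normalize(matrix: CountMatrix) -> CountMatrix:
    """Rescale each sample so housekeeping geometric means agree cohort-wide.

    Control probes (Negative/Positive) pass through unchanged; within-sample
    ratios of Endogenous probes are preserved exactly.
    """
    factors = biological_scale_factors(matrix)
    out = matrix.copy()
    target = np.isin(out.probe_classes, ("Endogenous", "Housekeeping"))
    out.values[target] = out.values[target] * factors[None, :]
    return out


def normalize(matrix: CountMatrix, skip_biological: bool = False) -> CountMatrix:
    """Technical then (optionally) biological normalization."""
    out = technical_normalize(matrix)
    if not skip_biological:
        out = biological_normalize(out)
    return out


def _one_sided_greater_p(values: np.ndarray, threshold: float) -> float:
    """p of a one-sample t-test with H1: mean > threshold.

    Zero-variance groups are resolved by position: strictly above the
    threshold -> expressed (p=0), strictly below -> not (p=1), exactly at
    the threshold -> p=0.5 (the t-statistic-0 limit).
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0.0:
        m = values[0]
        if m > threshold:
            return 0.0
        if m < threshold:
            return 1.0
        return 0.5
    res = stats.ttest_1samp(values, popmean=threshold, alternative="greater")
    return float(res.pvalue)


def noise_filter(matrix: CountMatrix, labels: pd.Series, alpha: float = 0.05) -> NoiseMask:
    """Call each Endogenous gene expressed / not expressed per group.

    The per-group threshold is the group's mean negative-control background
    (mean + 2*SD per sample, averaged over the group's samples). A gene is
    expressed overall iff its one-sided t-test clears alpha in >= 1 group.
    """
    labels = pd.Series(labels)
    background = _negative_background(matrix)
    col_of = {s: j for j, s in enumerate(matrix.samples)}
    groups = list(dict.fromkeys(labels))  # stable order
    endo_idx = matrix.class_index("Endogenous")
    genes = [matrix.probes[i].name for i in endo_idx]

    pvals = np.ones((len(genes), len(groups)))
    for gj, group in enumerate(groups):
        members = [col_of[s] for s in labels.index[labels == group]]
        if len(members) < 2:
            raise StatisticsError(
                f"group {group!r} has {len(members)} sample(s); the noise t-test needs >= 2"
            )
        threshold = float(background[members].mean())
        sub = matrix.values[np.ix_(endo_idx, members)]
        for gi in range(len(genes)):
            pvals[gi, gj] = _one_sided_greater_p(sub[gi], threshold)

    pframe = pd.DataFrame(pvals, index=genes, columns=groups)
    return NoiseMask(per_group=pframe <= alpha, pvalues=pframe)
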