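"""ROC/AUC performance with bootstrap internal validation.

The AUC is the trapezoidal area under the ROC curve from a threshold sweep
over the distinct score values; with the standard tie convention (half
credit for tied pairs) this equals the normalized Mann–Whitney U statistic.
Confidence intervals come from a stratified percentile bootstrap (class
balance preserved in every resample). ``validation_report`` assembles the
end-to-end cohort report: per-entity scores, model risks, ROC with CI,
GLM association p, a cross-score synopsis table and an alert list for
samples whose off-entity lymphoma score reaches a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .exceptions import StatisticsError
from .nanostring_io import CountMatrix
from .risk_models import RiskModel, glm_association_p, predict_risk
from .scoring import ScorePanel, score_cohort


@dataclass
class ROCResult:
    """ROC sweep, AUC and (optionally) a bootstrap percentile CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci: tuple[float, float] | None = None
    level: float | None = None
    n_boot: int | None = None
    seed: int | None = None


def _mann_whitney_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the normalized U statistic (ties get half credit)."""
    pos = scores[truth]
    neg = scores[~truth]
    # rank-sum formulation: O(n log n), exact tie handling via average ranks
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def roc_auc(scores: Sequence[float], labels: Sequence) -> ROCResult:
    """ROC curve and AUC for binary labels (truthy = positive class)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(labels).astype(bool)
    if truth.all() or not truth.any():
        raise StatisticsError("both classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(truth, scores, drop_intermediate=False)
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=_mann_whitney_auc(scores, truth),
    )


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> ROCResult:
    """Stratified percentile-bootstrap CI around the AUC."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(labels).astype(bool)
    base = roc_auc(scores, truth)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(truth)
    neg = np.flatnonzero(~truth)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(pos, pos.size, replace=True),
                               rng.choice(neg, neg.size, replace=True)])
        aucs[b] = _mann_whitney_auc(scores[take], truth[take])
    lo, hi = np.percentile(aucs, [50 * (1 - level), 100 - 50 * (1 - level)])
    base.ci = (float(lo), float(hi))
    base.level = level
    base.n_boot = n_boot
    base.seed = seed
    return base


@dataclass
class EntityValidation:
    """Per-entity slice of the validation report."""

    entity: str
    scores: pd.Series
    risks: pd.Series
    roc: ROCResult
    glm_p: float


@dataclass
class ValidationReport:
    per_entity: dict[str, EntityValidation]
    synopsis: pd.DataFrame  # sample x (three scores + label)
    alerts: pd.DataFrame  # samples whose off-entity score meets the alert threshold

    def auc(self, entity: str) -> float:
        return self.per_entity[entity].roc.auc


def validation_report(
    matrix: CountMatrix,
    labels: pd.Series,
    panels: Sequence[ScorePanel],
    models: Mapping[str, RiskModel],
    alert_entity: str = "MALT",
    alert_threshold: int = 1,
    n_boot: int = 1000,
    seed: int = 0,
) -> ValidationReport:
    """End-to-end validation-cohort report on a normalized matrix.

    For every panel: per-sample scores, model risks, bootstrap-backed ROC of
    entity vs rest, and the binomial GLM association p. The alert list flags
    samples outside ``alert_entity`` whose ``alert_entity`` score reaches
    ``alert_threshold`` (default: lymphoma score >= 1 in non-lymphoma
    samples — the pattern that identified progressing cases).
    """
    labels = pd.Series(labels)
    per_entity: dict[str, EntityValidation] = {}
    synopsis = pd.DataFrame({"entity": labels})
    for panel in panels:
        scores = pd.Series(score_cohort(matrix, panel), index=matrix.samples,
                           name=f"score_{panel.entity}")
        truth = (labels == panel.entity).to_numpy()
        model = models[panel.entity]
        roc = bootstrap_auc_ci(scores.to_numpy(), truth, n_boot=n_boot, seed=seed)
        per_entity[panel.entity] = EntityValidation(
            entity=panel.entity,
            scores=scores,
            risks=pd.Series(predict_risk(model, scores.to_numpy()),
                            index=matrix.samples, name=f"risk_{panel.entity}"),
            roc=roc,
            glm_p=glm_association_p(scores.to_numpy(), truth),
        )
        synopsis[scores.name] = scores

    alert_col = f"score_{alert_entity}"
    if alert_col in synopsis:
        flagged = synopsis[(synopsis["entity"] != alert_entity)
                           & (synopsis[alert_col] >= alert_threshold)]
        alerts = flagged[["entity", alert_col]].rename_axis("sample_id").reset_index()
    else:
        alerts = pd.DataFrame(columns=["sample_id", "entity", alert_col])
    return ValidationReport(per_entity=per_entity, synopsis=synopsis, alerts=alerts)


def plot_roc(results: Mapping[str, ROCResult], path=None):
    """ROC curves for several entities on one axis (matplotlib, optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for entity, res in results.items():
        label = f"{entity} (AUC {res.auc:.2f})"
        if res.ci is not None:
            label += f" [{res.ci[0]:.2f}, {res.ci[1]:.2f}]"
        ax.plot(1.0 - res.specificity, res.sensitivity, label=label)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
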