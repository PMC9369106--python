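"""Nonlinear logistic risk models mapping integer marker scores to risk.

Three published model forms, each a function of the score x with an
orientation sign s (default s = -1, i.e. risk increases with score — the
direction a binarized score is built to have):

* ``shift``    y = 1 / (1 + exp(s * (x - a)))          (lymphoma, a = 8.5)
* ``shift2``   y = 1 / (1 + exp(s * (x - a + b)))      (NSOI, a = 15.4536, b = 131.3080)
* ``plateau``  y = 1 / (a + exp(s * (x - b)))          (IgG4-ROD, a = 0.8164, b = 11.831)

In the shift form the risk crosses 1/2 exactly at x = a under either
orientation. In the shift2 form only the offset a - b is identifiable, so
fitting reports the offset; the published pair is stored verbatim. The
plateau form saturates at 1/a, which for the published a = 0.8164 exceeds 1
— "relative risk" there is not a probability, so raw values are exposed
alongside a [0, 1]-clamped companion. As literally printed (s = +1) the
shift forms *decrease* with score, which contradicts the construction of
the scores; s = +1 remains available for the verbatim curves.

Fitting: the empirical risk (fraction of the target entity) is computed per
distinct score value and the chosen form is fitted to those (score, risk)
pairs by weighted nonlinear least squares; a binomial GLM likelihood-ratio
test supplies the score-vs-label association p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .exceptions import RiskFitError
from .nanostring_io import CountMatrix
from .scoring import ScorePanel, score_cohort

FORMS = ("shift", "shift2", "plateau")
_EXP_CLIP = 700.0  # exp overflow guard


@dataclass(frozen=True)
class RiskModel:
    """One parametric risk curve (see module docstring for the forms)."""

    entity: str
    form: str
    a: float
    b: float | None = None
    orientation: int = -1

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")
        if self.form in ("shift2", "plateau") and self.b is None:
            raise ValueError(f"form {self.form!r} needs parameter b")
        if self.form == "plateau" and self.a <= 0:
            raise ValueError("plateau form requires a > 0")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")

    def predict_raw(self, score) -> np.ndarray | float:
        """Evaluate the curve; overflow-safe, may exceed 1 for the plateau form."""
        x = np.asarray(score, dtype=float)
        s = self.orientation
        if self.form == "shift":
            out = expit(-s * (x - self.a))
        elif self.form == "shift2":
            out = expit(-s * (x - self.a + self.b))
        else:
            z = np.clip(s * (x - self.b), -_EXP_CLIP, _EXP_CLIP)
            out = 1.0 / (self.a + np.exp(z))
        return float(out) if np.isscalar(score) else out


def predict_risk(model: RiskModel, score) -> np.ndarray | float:
    """Model risk clamped to [0, 1] (use ``model.predict_raw`` for raw values)."""
    raw = model.predict_raw(score)
    clipped = np.clip(raw, 0.0, 1.0)
    return float(clipped) if np.isscalar(score) else clipped


def published_models() -> dict[str, RiskModel]:
    """The three published models with their printed parameter estimates."""
    return {
        "NSOI": RiskModel("NSOI", "shift2", a=15.4536, b=131.3080),
        "MALT": RiskModel("MALT", "shift", a=8.5000),
        "IgG4-ROD": RiskModel("IgG4-ROD", "plateau", a=0.8164, b=11.831),
    }


@dataclass
class RiskFit:
    """Result of :func:`fit_risk_model`."""

    model: RiskModel
    glm_p: float
    per_score: pd.DataFrame  # score, n, empirical_risk, fitted_risk


def glm_association_p(scores: np.ndarray, target: np.ndarray) -> float:
    """Likelihood-ratio p of a binomial logit GLM, score vs intercept-only."""
    X = sm.add_constant(np.asarray(scores, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(np.asarray(target, dtype=float), X,
                     family=sm.families.Binomial()).fit(maxiter=200)
    lr = max(0.0, fit.null_deviance - fit.deviance)
    return float(stats.chi2.sf(lr, df=1))


def _curve(form: str):
    if form == "shift":
        return lambda x, a: expit(x - a)
    if form == "shift2":
        # only a-b identifiable: fit the offset, report it in a with b = 0
        return lambda x, a: expit(x - a)
    return lambda x, a, b: 1.0 / (a + np.exp(np.clip(-(x - b), -_EXP_CLIP, _EXP_CLIP)))


def fit_risk_model(
    scores,
    labels,
    form: str = "shift",
    entity: str | object = True,
) -> RiskFit:
    """Fit a risk curve to score/label data.

    ``labels`` may be boolean, or categorical with ``entity`` naming the
    positive class. Empirical risks per distinct score are fitted by
    nonlinear least squares weighted by the per-score sample counts.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    target = labels.astype(bool) if labels.dtype == bool else labels == entity
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise RiskFitError("need >= 2 distinct score values")
    if target.all() or not target.any():
        raise RiskFitError("both classes must be present")

    emp = np.array([target[scores == u].mean() for u in uniq])
    n_per = np.array([np.sum(scores == u) for u in uniq])
    func = _curve(form)
    x50 = float(np.interp(0.5, emp, uniq)) if emp[-1] >= emp[0] else float(np.median(uniq))
    if form in ("shift", "shift2"):
        p0, bounds = [x50], ([-np.inf], [np.inf])
    else:
        p0, bounds = [1.0, x50], ([1e-6, -np.inf], [np.inf, np.inf])
    try:
        popt, _ = optimize.curve_fit(
            func, uniq, emp, p0=p0, sigma=1.0 / np.sqrt(n_per),
            bounds=bounds, maxfev=20_000,
        )
    except RuntimeError as err:
        raise RiskFitError(f"nonlinear fit did not converge: {err}") from err

    entity_name = entity if isinstance(entity, str) else "event"
    if form == "plateau":
        model = RiskModel(entity_name, form, a=float(popt[0]), b=float(popt[1]))
    elif form == "shift2":
        model = RiskModel(entity_name, form, a=float(popt[0]), b=0.0)
    else:
        model = RiskModel(entity_name, form, a=float(popt[0]))

    per_score = pd.DataFrame({
        "score": uniq, "n": n_per, "empirical_risk": emp,
        "fitted_risk": predict_risk(model, uniq),
    })
    return RiskFit(model=model, glm_p=glm_association_p(scores, target), per_score=per_score)


def loocv_scores(
    matrix: CountMatrix,
    labels: pd.Series,
    panel: ScorePanel,
    form: str = "shift",
) -> pd.Series:
    """Held-out risk per sample: fit on the other n-1, evaluate the held-out score."""
    labels = pd.Series(labels)
    if matrix.n_samples < 3:
        raise RiskFitError("leave-one-out needs n >= 3")
    scores = pd.Series(score_cohort(matrix, panel), index=matrix.samples)
    out = {}
    for sample in matrix.samples:
        rest = [s for s in matrix.samples if s != sample]
        fit = fit_risk_model(scores[rest].to_numpy(),
                             labels[rest].to_numpy(), form=form, entity=panel.entity)
        out[sample] = predict_risk(fit.model, float(scores[sample]))
    return pd.Series(out, name="heldout_risk")
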