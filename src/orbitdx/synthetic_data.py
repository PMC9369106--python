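"""Synthetic nCounter-like cohorts with planted marker-gene effects.

No public expression data exist for the orbital-disease cohorts this
pipeline targets, so every downstream stage is exercised on simulated
counts that emulate the study design: a two-panel screening CodeSet
(1364 endogenous genes, 30 reference genes) profiled on a 12-sample
cohort (3 NSOI, 3 relapsing NSOI, 3 IgG4-ROD, 3 MALT), and a 36-target
custom CodeSet profiled on a 48-sample validation cohort
(24 NSOI, 11 IgG4-ROD, 13 MALT).

Count model
-----------
* Endogenous and Housekeeping probes: negative binomial with per-gene mean
  and a shared dispersion (variance = m + d*m^2).
* Negative controls: Poisson around a small background mean.
* Positive controls: a deterministic geometric spike-in ladder.
* A per-sample lognormal technical scale factor multiplies all probes, so
  reference-gene normalization has something to correct.

Entity effects are planted as log2 fold changes on named genes; relapsing
NSOI inherits the NSOI effect profile (the two were not distinguishable by
expression) but keeps its own label so the 4-group screening design is
representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nanostring_io import CountMatrix, ProbeDef
from . import scoring

# entity labels
NSOI = "NSOI"
RELAPSING_NSOI = "relapsing NSOI"
IGG4 = "IgG4-ROD"
MALT = "MALT"

#: effect-profile fallback: relapsing NSOI behaves like NSOI
ENTITY_ALIASES = {RELAPSING_NSOI: NSOI}

#: genes carrying the decision-tree structure (severe NSOI / IgG4-ROD / mild NSOI)
TREE_GENES = ("PLA2G2A", "RBM47", "AQP1")

_FILLER_PREFIX = "G"
_POSITIVE_LADDER_TOP = 4096.0  # top spike-in count; successive probes are 4x lower


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    Parameters
    ----------
    groups
        Ordered (entity label, sample count) pairs.
    baseline_mean
        Expected endogenous count for genes without a per-gene override.
    dispersion
        Negative-binomial dispersion d (variance = m + d*m^2).
    effects
        gene -> entity -> log2 fold change planted on that gene.
    gene_means
        Optional per-gene baseline overrides (needed so marker genes straddle
        their published cut-offs).
    scale_sigma
        Sigma of the lognormal per-sample technical scale factor.
    """

    groups: list[tuple[str, int]]
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    gene_means: Mapping[str, float] = field(default_factory=dict)
    neg_control_mean: float = 10.0
    hk_mean: float = 500.0
    scale_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for _, n in self.groups):
            raise ValueError("group sample counts must be >= 0")
        for name, value in (
            ("baseline_mean", self.baseline_mean),
            ("dispersion", self.dispersion),
            ("neg_control_mean", self.neg_control_mean),
            ("hk_mean", self.hk_mean),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)

    @property
    def entities(self) -> list[str]:
        return [e for e, _ in self.groups]


@dataclass
class LabeledCohort:
    """A simulated count matrix with its per-sample entity labels."""

    counts: CountMatrix
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.labels) != self.counts.n_samples:
            raise ValueError("label vector length must equal number of samples")


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def build_panel(
    n_endogenous: int,
    n_housekeeping: int = 0,
    n_negative: int = 0,
    n_positive: int = 0,
    required_genes: Sequence[str] = (),
    housekeeping_genes: Sequence[str] | None = None,
) -> list[ProbeDef]:
    """Deterministic probe panel: required genes first, filler symbols after.

    Filler endogenous symbols are zero-padded ordinals (``G0002``...) so the
    panel is bit-identical across calls. ``housekeeping_genes`` optionally
    names the reference probes (e.g. the validation CodeSet's five).
    """
    required = list(required_genes)
    if len(set(required)) != len(required):
        raise ValueError("required_genes contains duplicates")
    if n_endogenous < len(required):
        raise ValueError(
            f"n_endogenous={n_endogenous} < {len(required)} required genes"
        )
    taken = set(required)
    probes = [ProbeDef(g, "Endogenous") for g in required]
    ordinal = len(required)
    while len(probes) < n_endogenous:
        ordinal += 1
        name = f"{_FILLER_PREFIX}{ordinal:04d}"
        if name in taken:
            continue
        probes.append(ProbeDef(name, "Endogenous"))

    if housekeeping_genes is not None:
        if len(housekeeping_genes) != n_housekeeping:
            raise ValueError("housekeeping_genes length must equal n_housekeeping")
        probes += [ProbeDef(g, "Housekeeping") for g in housekeeping_genes]
    else:
        probes += [ProbeDef(f"HK{i:02d}", "Housekeeping") for i in range(1, n_housekeeping + 1)]
    probes += [ProbeDef(f"NEG{i:02d}", "Negative") for i in range(1, n_negative + 1)]
    probes += [ProbeDef(f"POS{i:02d}", "Positive") for i in range(1, n_positive + 1)]
    return probes


def screening_panel() -> list[ProbeDef]:
    """The two-panel screening target set: 1364 endogenous + 30 reference genes.

    All marker-panel genes and the decision-tree genes are guaranteed present.
    """
    required = sorted(set(scoring.panel_gene_union()) | set(TREE_GENES) | {"IRF4"})
    return build_panel(1364, n_housekeeping=30, n_negative=8, n_positive=6,
                       required_genes=required)


def validation_panel() -> list[ProbeDef]:
    """The custom validation CodeSet: 36 targets + 5 named reference genes."""
    codeset = scoring.validation_codeset()
    return build_panel(
        len(codeset["target_genes"]),
        n_housekeeping=len(codeset["reference_genes"]),
        n_negative=8,
        n_positive=6,
        required_genes=codeset["target_genes"],
        housekeeping_genes=codeset["reference_genes"],
    )


# ---------------------------------------------------------------------------
# effect and baseline presets
# ---------------------------------------------------------------------------

def default_marker_effects(strength: float) -> dict[str, dict[str, float]]:
    """Plant each published panel's directions on its own entity.

    Every NSOI-panel up gene gets +strength in NSOI (RPS27A -strength);
    every lymphoma-panel gene -strength in MALT; every IgG4-ROD-panel gene
    +strength in IgG4-ROD. Genes outside all panels carry no effect.
    """
    if strength <= 0:
        raise ValueError(f"strength must be > 0, got {strength}")
    effects: dict[str, dict[str, float]] = {}
    for panel in scoring.published_panels():
        for rule in panel.rules:
            sign = strength if rule.direction == "up" else -strength
            effects.setdefault(rule.gene, {})[panel.entity] = sign
    return effects


def decision_tree_effects(strength: float) -> dict[str, dict[str, float]]:
    """Effects that carve the three-tier decision-tree structure.

    PLA2G2A up in severe (relapsing) NSOI, RBM47 up in IgG4-ROD, AQP1 up in
    mild NSOI only (the explicit 0 stops relapsing NSOI from inheriting it).
    """
    if strength <= 0:
        raise ValueError(f"strength must be > 0, got {strength}")
    return {
        "PLA2G2A": {RELAPSING_NSOI: strength},
        "RBM47": {IGG4: strength},
        "AQP1": {NSOI: strength, RELAPSING_NSOI: 0.0},
    }


def marker_gene_baselines() -> dict[str, float]:
    """Per-gene baselines placed so planted effects cross the published cut-offs.

    For an up rule the non-target groups should sit below the cut-off
    (target: cutoff/2); for a down rule above it (target: 2*cutoff). Genes in
    several panels get the geometric mean of their per-rule targets, which
    satisfies all rules simultaneously for the shared genes (AQP1, CLIC4, NRP1)
    at planted strength >= 2.
    """
    targets: dict[str, list[float]] = {}
    for panel in scoring.published_panels():
        for rule in panel.rules:
            t = rule.cutoff / 2 if rule.direction == "up" else rule.cutoff * 2
            targets.setdefault(rule.gene, []).append(t)
    return {g: float(np.exp(np.mean(np.log(ts)))) for g, ts in targets.items()}


def tree_gene_baselines() -> dict[str, float]:
    """Baselines putting the planted tree cut-offs near their published values.

    A +2 log2FC from these baselines straddles roughly 610 / 38 / 30 counts.
    """
    return {"PLA2G2A": 305.0, "RBM47": 19.0, "AQP1": 15.0}


def screening_spec(strength: float = 2.0, seed: int = 0, n_per_group: int = 3) -> CohortSpec:
    """4-group screening cohort (NSOI, relapsing NSOI, IgG4-ROD, MALT)."""
    return CohortSpec(
        groups=[(NSOI, n_per_group), (RELAPSING_NSOI, n_per_group),
                (IGG4, n_per_group), (MALT, n_per_group)],
        effects=default_marker_effects(strength),
        gene_means=marker_gene_baselines(),
        seed=seed,
    )


def validation_spec(strength: float = 2.0, seed: int = 0) -> CohortSpec:
    """3-group validation cohort: 24 NSOI, 11 IgG4-ROD, 13 MALT."""
    return CohortSpec(
        groups=[(NSOI, 24), (IGG4, 11), (MALT, 13)],
        effects=default_marker_effects(strength),
        gene_means=marker_gene_baselines(),
        seed=seed,
    )


def tree_recovery_spec(strength: float = 2.0, seed: int = 0, n_per_group: int = 15) -> CohortSpec:
    """4-group cohort carrying only the decision-tree marker effects."""
    means = dict(marker_gene_baselines())
    means.update(tree_gene_baselines())
    return CohortSpec(
        groups=[(NSOI, n_per_group), (RELAPSING_NSOI, n_per_group),
                (IGG4, n_per_group), (MALT, n_per_group)],
        effects=decision_tree_effects(strength),
        gene_means=means,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion*mean^2."""
    n = 1.0 / dispersion
    p = n / (n + np.asarray(mean, dtype=float))
    return rng.negative_binomial(n, p).astype(float)


def _effect_for(effects: Mapping[str, Mapping[str, float]], gene: str, entity: str) -> float:
    per_gene = effects.get(gene)
    if per_gene is None:
        return 0.0
    if entity in per_gene:
        return float(per_gene[entity])
    alias = ENTITY_ALIASES.get(entity)
    if alias is not None and alias in per_gene:
        return float(per_gene[alias])
    return 0.0


def simulate_cohort(spec: CohortSpec, panel: Sequence[ProbeDef]) -> LabeledCohort:
    """Draw a labeled cohort from the count model; bit-reproducible per seed."""
    if not panel:
        raise ValueError("panel must be non-empty")
    allowed = set(spec.entities) | {ENTITY_ALIASES.get(e, e) for e in spec.entities}
    for gene, per_gene in spec.effects.items():
        unknown = set(per_gene) - allowed
        if unknown:
            raise ValueError(
                f"effects for gene {gene!r} reference entities not in the cohort: {sorted(unknown)}"
            )

    rng = np.random.default_rng(spec.seed)
    entities = [e for e, n in spec.groups for _ in range(n)]
    n_samples = len(entities)
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    scale = np.exp(rng.normal(0.0, spec.scale_sigma, size=n_samples))

    values = np.zeros((len(panel), n_samples))
    log2fc = np.log(2.0)
    pos_rank = 0
    for i, probe in enumerate(panel):
        if probe.probe_class == "Endogenous":
            base = float(spec.gene_means.get(probe.name, spec.baseline_mean))
            fold = np.array(
                [2.0 ** _effect_for(spec.effects, probe.name, e) for e in entities]
            )
            values[i] = _nb_draw(rng, base * fold * scale, spec.dispersion)
        elif probe.probe_class == "Housekeeping":
            values[i] = _nb_draw(rng, spec.hk_mean * scale, spec.dispersion)
        elif probe.probe_class == "Negative":
            values[i] = rng.poisson(spec.neg_control_mean * scale).astype(float)
        else:  # Positive: deterministic spike-in ladder, scaled per sample
            ladder = _POSITIVE_LADDER_TOP / (4.0 ** pos_rank)
            pos_rank += 1
            values[i] = np.round(ladder * scale)

    labels = pd.Series(entities, index=samples, name="entity")
    return LabeledCohort(CountMatrix(list(panel), samples, values), labels)
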