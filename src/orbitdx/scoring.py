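"""Binarized multi-gene diagnostic scores.

Each disease entity (NSOI, MALT lymphoma, IgG4-ROD) has a published marker
panel: a list of genes, each with a direction and a cut-off on the
normalized-count scale. A sample's score for a panel is the number of rules
that fire — an "up" rule fires when the gene's count is strictly above its
cut-off, a "down" rule when strictly below. Higher score = higher likelihood
of the panel's entity.

The panels ship as a version-controlled YAML config
(:data:`orbitdx/data/panels.yaml`) and are loaded by
:func:`published_panels`. Cut-off comparison strictness is centralized in
:func:`rule_fires` so the boundary convention can be flipped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

from .exceptions import ScoringError
from .nanostring_io import CountMatrix

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class MarkerRule:
    """One gene with a direction and a normalized-count cut-off."""

    gene: str
    direction: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")


@dataclass(frozen=True)
class ScorePanel:
    """Per-entity rule set; score range is [0, len(rules)]."""

    entity: str
    rules: tuple[MarkerRule, ...]

    def __post_init__(self) -> None:
        genes = [r.gene for r in self.rules]
        if len(set(genes)) != len(genes):
            raise ValueError(f"panel {self.entity}: duplicate genes")

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self.rules]


def _load_yaml(name: str):
    with resources.files("orbitdx.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def published_panels() -> list[ScorePanel]:
    """The three published marker panels (NSOI, MALT, IgG4-ROD).

    Loaded from the packaged config; 12, 12 and 15 rules respectively.
    """
    raw = _load_yaml("panels.yaml")
    return [
        ScorePanel(
            entry["entity"],
            tuple(
                MarkerRule(r["gene"], r["direction"], float(r["cutoff"]))
                for r in entry["rules"]
            ),
        )
        for entry in raw
    ]


def panel_gene_union(panels: Iterable[ScorePanel] | None = None) -> list[str]:
    """Sorted distinct genes across the panels (computed, never hard-coded)."""
    if panels is None:
        panels = published_panels()
    return sorted({r.gene for p in panels for r in p.rules})


def validation_codeset() -> dict[str, list[str]]:
    """The custom validation CodeSet: target genes + reference genes.

    Target genes are the union of the three marker panels; the five
    reference genes were the ones stably expressed in the screening cohort.
    """
    raw = _load_yaml("validation_codeset.yaml")
    return {
        "target_genes": panel_gene_union(),
        "reference_genes": list(raw["reference_genes"]),
    }


def rule_fires(rule: MarkerRule, count: float, strict: bool = True) -> bool:
    """Whether a rule scores 1 for the given normalized count.

    Strict inequalities by default: a count exactly at the cut-off scores 0
    for either direction.
    """
    if rule.direction == "up":
        return count > rule.cutoff if strict else count >= rule.cutoff
    return count < rule.cutoff if strict else count <= rule.cutoff


def compute_score(profile: Mapping[str, float], panel: ScorePanel, strict: bool = True) -> int:
    """Integer score of one sample profile under a panel.

    Parameters
    ----------
    profile
        gene symbol -> normalized count. Must contain every panel gene.
    """
    score = 0
    for rule in panel.rules:
        if rule.gene not in profile:
            raise ScoringError(f"gene {rule.gene!r} missing from profile (panel {panel.entity})")
        score += rule_fires(rule, profile[rule.gene], strict=strict)
    return score


def score_cohort(matrix: CountMatrix, panel: ScorePanel, strict: bool = True) -> np.ndarray:
    """Per-sample integer scores for a normalized cohort matrix."""
    names = matrix.probe_names
    rows = {}
    for rule in panel.rules:
        if rule.gene not in names:
            raise ScoringError(f"gene {rule.gene!r} missing from matrix (panel {panel.entity})")
        rows[rule.gene] = matrix.row(rule.gene)
    scores = np.zeros(matrix.n_samples, dtype=int)
    for rule in panel.rules:
        counts = rows[rule.gene]
        if rule.direction == "up":
            fired = counts > rule.cutoff if strict else counts >= rule.cutoff
        else:
            fired = counts < rule.cutoff if strict else counts <= rule.cutoff
        scores += fired.astype(int)
    return scores
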