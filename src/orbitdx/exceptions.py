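"""Exception hierarchy for orbitdx."""


class OrbitdxError(Exception):
    """Base class for all orbitdx errors."""


class FormatError(OrbitdxError):
    """A file does not conform to the expected format (RCC / CSV dialect)."""


class NormalizationError(OrbitdxError):
    """Normalization cannot proceed (missing controls, all-zero housekeeping...)."""


class StatisticsError(OrbitdxError):
    """A statistical routine received degenerate input (group too small, constant data...)."""


class ScoringError(OrbitdxError):
    """A marker panel cannot be evaluated on a profile (missing gene)."""


class RiskFitError(OrbitdxError):
    """Risk-model fitting failed (single score level, non-convergence)."""
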