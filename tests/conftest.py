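import numpy as np
import pytest

from orbitdx import normalization, synthetic_data
from orbitdx.nanostring_io import CountMatrix, ProbeDef


def make_matrix(endo=(), hk=(), neg=(), pos=(), samples=None):
    """Small CountMatrix from per-class {name: row} mappings."""
    probes, rows = [], []
    for cls, probeset in (("Endogenous", endo), ("Housekeeping", hk),
                          ("Negative", neg), ("Positive", pos)):
        for name, counts in dict(probeset).items():
            probes.append(ProbeDef(name, cls))
            rows.append(counts)
    values = np.array(rows, dtype=float)
    if samples is None:
        samples = [f"S{j}" for j in range(values.shape[1] if rows else 0)]
    return CountMatrix(probes, samples, values)


@pytest.fixture(scope="session")
def validation_cohort():
    """Planted 48-sample validation cohort (raw counts + labels)."""
    spec = synthetic_data.validation_spec(strength=2.0, seed=1)
    return synthetic_data.simulate_cohort(spec, synthetic_data.validation_panel())


@pytest.fixture(scope="session")
def validation_norm(validation_cohort):
    """The same cohort after technical + biological normalization."""
    return normalization.normalize(validation_cohort.counts)
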