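import numpy as np
import pytest

from isir.cohort import Cohort, PatientRecord, VariableSpec, cohort_from_arrays

TNM_SPECS = [
    VariableSpec("T", (1, 2, 3, 4)),
    VariableSpec("N", (0, 1, 2, 3)),
    VariableSpec("M", (0, 1)),
    VariableSpec("Gas6", (1, 2, 3, 4)),
    VariableSpec("CD68", (1, 2, 3, 4)),
]


@pytest.fixture
def tnm_specs():
    return list(TNM_SPECS)


@pytest.fixture
def rng():
    return np.random.default_rng(20110727)


def make_patient(pid="p", time=10.0, event=1, **covariates) -> PatientRecord:
    return PatientRecord(pid, time, event, covariates)


@pytest.fixture
def staged_cohort() -> Cohort:
    """Small deterministic cohort where stage drives survival: higher T/N/M,
    shorter survival; higher markers, longer survival."""
    T = [1, 1, 2, 2, 3, 3, 4, 4, 1, 2, 3, 4]
    N = [0, 0, 1, 1, 2, 2, 3, 3, 0, 1, 2, 3]
    M = [0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 1, 1]
    Gas6 = [4, 4, 3, 3, 2, 2, 1, 1, 4, 3, 2, 1]
    CD68 = [4, 3, 3, 2, 2, 1, 1, 1, 4, 3, 2, 1]
    times = [96.0, 90.0, 70.0, 64.0, 30.0, 24.0, 8.0, 6.0, 84.0, 60.0, 18.0, 4.0]
    events = [0, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1]
    return cohort_from_arrays(
        times, events, {"T": T, "N": N, "M": M, "Gas6": Gas6, "CD68": CD68}, TNM_SPECS
    )


@pytest.fixture
def random_patient_factory(tnm_specs):
    """Draw admissible random patients for property checks."""

    def factory(rng, n):
        out = []
        for i in range(n):
            cov = {
                s.name: int(rng.choice(s.admissible_values)) for s in tnm_specs
            }
            out.append(PatientRecord(f"r{i}", float(rng.uniform(1, 100)), 1, cov))
        return out

    return factory
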