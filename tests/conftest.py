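import numpy as np
import pandas as pd
import pytest

from pdelay.cohort import (
    Cohort,
    OutcomeSpec,
    apply_inclusion_filters,
    normalize_outcomes,
)
from pdelay.ltjmm import LTJMMSpec, fit
from pdelay.simulate import emulate_study_design, generate_cohort


@pytest.fixture
def tiny_cohort() -> Cohort:
    """One individual, one continuous outcome, three visits."""
    individuals = pd.DataFrame(
        {"age_at_diagnosis": [63.0], "sex": ["male"]},
        index=pd.Index(["p1"], name="individual_id"),
    )
    measurements = pd.DataFrame(
        {
            "individual_id": ["p1", "p1", "p1"],
            "outcome": ["updrs3"] * 3,
            "time_years": [0.0, 1.0, 2.0],
            "value": [20.0, 24.0, 28.0],
        }
    )
    specs = {"updrs3": OutcomeSpec("updrs3", "continuous", 0, 132, in_ltjmm=True)}
    return Cohort("tiny", individuals, measurements, specs)


@pytest.fixture(scope="session")
def denovo_cohort():
    """Default de-novo synthetic cohort (n=100), normalized and filtered."""
    params = emulate_study_design("denovo", 100, seed=42)
    cohort, truth = generate_cohort(params)
    prepared = apply_inclusion_filters(normalize_outcomes(cohort))
    return prepared, truth


@pytest.fixture(scope="session")
def denovo_fit(denovo_cohort):
    """Default-settings joint fit (4 chains, 1000 warmup + 1000 draws)."""
    prepared, truth = denovo_cohort
    post = fit(prepared, LTJMMSpec(seed=1))
    return post, prepared, truth
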