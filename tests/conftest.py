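import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from tilsig import ExpressionMatrix, Scale, SurvivalCohort

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, linear scale."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0], [5.0, 5.0, 5.0, 5.0]],
        index=["GENEA", "GENEB", "GENEC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(df, Scale.LINEAR_TPM)


@pytest.fixture
def small_cohort() -> SurvivalCohort:
    """8-patient cohort with events, censorings and one unusable row."""
    rng = np.random.default_rng(7)
    patients = [f"P{i}" for i in range(1, 9)]
    clinical = pd.DataFrame(
        {
            "dss_time": [100.0, 250.0, 300.0, 80.0, 500.0, 120.0, np.nan, 60.0],
            "dss_event": [1, 0, 1, 1, 0, 1, np.nan, 0],
            "stage": ["I", "II", "III", "IV", "II", "III", "I", "missing"],
            "age_band": ["<55", "55-64", "65-74", ">74", "<55", "65-74", "<55", "55-64"],
            "gender": ["male", "female"] * 4,
            "anatomic_location": ["cecum", "sigmoid", "rectum", "cecum",
                                  "sigmoid", "rectum", "cecum", "sigmoid"],
            "residual_disease": ["no", "no", "yes", "no", "no", "yes", "no", "no"],
        },
        index=pd.Index(patients, name="patient_id"),
    )
    expr = pd.DataFrame(rng.uniform(1, 100, size=(6, 8)),
                        index=[f"G{i}" for i in range(6)], columns=patients)
    return SurvivalCohort(clinical, ExpressionMatrix(expr, Scale.LINEAR_TPM))
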