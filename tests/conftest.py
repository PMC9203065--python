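import pandas as pd
import pytest

from proofbp.cohort import CohortConfig, generate_cohort
from proofbp.classification import classify_cohort
from proofbp.model import covariate_frame


@pytest.fixture(scope="session")
def default_cohort():
    """n=3000 cohort under the default (correctly specified) difference model."""
    cohort, truth = generate_cohort(CohortConfig(n_participants=3000, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = generate_cohort(CohortConfig(n_participants=500, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def classified_default(default_cohort):
    cohort, _ = default_cohort
    return classify_cohort(cohort)


@pytest.fixture(scope="session")
def developed_sbp(default_cohort):
    """Fitted SBP estimator on the default cohort (shared; fitting is the
    expensive step)."""
    from proofbp.development import ProofBPUSEstimator

    cohort, _ = default_cohort
    return ProofBPUSEstimator(outcome="sbp", random_state=42).fit(cohort)


@pytest.fixture(scope="session")
def developed_dbp(default_cohort):
    from proofbp.development import ProofBPUSEstimator

    cohort, _ = default_cohort
    return ProofBPUSEstimator(outcome="dbp", random_state=42).fit(cohort)


@pytest.fixture(scope="session")
def predictions_default(default_cohort, developed_sbp, developed_dbp):
    """Full-data predicted out-of-office SBP/DBP table for the default cohort."""
    cohort, _ = default_cohort
    cf = covariate_frame(cohort)
    return pd.DataFrame(
        {
            "id": cohort["id"],
            "pred_sbp": developed_sbp.model_.predict_out_of_office(cf),
            "pred_dbp": developed_dbp.model_.predict_out_of_office(cf),
        }
    )


@pytest.fixture(scope="session")
def observed_default(classified_default):
    return classified_default[["id", "awake_sbp", "awake_dbp"]]
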