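import numpy as np
import pandas as pd
import pytest

from sdgeval.cohort import Cohort, VariableMeta
from sdgeval.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def toy_cohort() -> Cohort:
    """A tiny hand-built cohort: 2 categorical + 1 continuous predictors."""
    df = pd.DataFrame(
        {
            "age": [34.0, 51.0, np.nan, 47.0, 29.0, 60.0],
            "sex": ["f", "m", "f", "m", "f", "m"],
            "smoker": ["no", "yes", "no", np.nan, "yes", "no"],
            "y": ["0", "1", "0", "1", "0", "1"],
        }
    )
    meta = [
        VariableMeta("age", "continuous", "core_predictor", is_qi=True,
                     is_parameter_of_interest=True),
        VariableMeta("sex", "categorical", "core_predictor", categories=["f", "m"],
                     is_qi=True),
        VariableMeta("smoker", "categorical", "adjunct", categories=["no", "yes"]),
        VariableMeta("y", "categorical", "outcome", categories=["0", "1"]),
    ]
    return Cohort(records=df, meta=meta, dataset_id="toy").validate()


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-size simulated cohort shared across metric tests."""
    spec = CohortSpec(dataset_id="shared", n_records=4000, n_core_predictors=5,
                      adjunct_pool_size=4, outcome_prevalence=0.3, seed=42)
    cohort, truth = simulate_cohort(spec)
    return cohort, truth
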