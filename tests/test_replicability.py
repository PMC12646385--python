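import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdgeval.cohort import Cohort, VariableMeta
from sdgeval.generators import SyntheticEnsemble, fit_copy, generate
from sdgeval.replicability import (
    EstimateCI,
    EstimateFailure,
    combine_estimates,
    ensemble_replicability,
    fit_logistic_estimate,
    replicability_metrics,
)
from sdgeval.simulate import CohortSpec, simulate_cohort


class TestLogisticEstimate:
    def test_parameter_recovery_against_ground_truth(self):
        spec = CohortSpec(dataset_id="fit", n_records=100_000, n_core_predictors=2,
                          beta=[0.8, -0.3], latent_correlation=np.eye(2),
                          categorical_fraction=0.0, missing_rate=0.0, seed=3)
        cohort, truth = simulate_cohort(spec)
        est = fit_logistic_estimate(cohort)
        assert est.ci_low <= truth.poi_coefficient <= est.ci_high

    def test_null_predictor_type_I(self):
        # ~95% of null fits should have |z| < 1.96 (checked loosely at 60 reps)
        hits = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(r)
            n = 800
            df = pd.DataFrame({
                "x1": rng.standard_normal(n),
                "y": rng.choice(["0", "1"], size=n),
            })
            meta = [VariableMeta("x1", "continuous", "core_predictor",
                                 is_parameter_of_interest=True),
                    VariableMeta("y", "categorical", "outcome", categories=["0", "1"])]
            est = fit_logistic_estimate(Cohort(df, meta, f"null{r}"))
            hits += not est.significant
        assert hits / reps > 0.85

    def test_constant_outcome_fails_distinguishably(self, toy_cohort):
        df = toy_cohort.records.copy()
        df["y"] = "1"
        bad = Cohort(df, list(toy_cohort.meta), "const")
        with pytest.raises(EstimateFailure):
            fit_logistic_estimate(bad)


class TestCombineEstimates:
    def test_single_estimate_is_identity(self):
        e = EstimateCI(1.2, 0.3, 1.2 - 1.959963984540054 * 0.3,
                       1.2 + 1.959963984540054 * 0.3)
        c = combine_estimates([e])
        assert c.estimate == pytest.approx(1.2)
        assert c.standard_error == pytest.approx(0.3)
        assert c.ci_low == pytest.approx(e.ci_low, abs=1e-9)

    def test_two_estimate_hand_example(self):
        # hand arithmetic: qbar=2, wbar=1, b=2, T = 1 + 2/2 = 2, SE=sqrt(2)
        es = [EstimateCI(1.0, 1.0, -1.0, 3.0), EstimateCI(3.0, 1.0, 1.0, 5.0)]
        c = combine_estimates(es)
        assert c.estimate == pytest.approx(2.0)
        assert c.standard_error == pytest.approx(np.sqrt(2.0))

    def test_identical_estimates_reduce_to_within_variance(self):
        es = [EstimateCI(0.5, 0.2, 0.1, 0.9)] * 4
        c = combine_estimates(es)
        assert c.standard_error == pytest.approx(0.2)
        assert c.df is None  # normal reference when b = 0

    def test_total_variance_never_below_within(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            m = rng.integers(2, 8)
            ests = [EstimateCI(float(rng.normal()), float(rng.uniform(0.1, 1.0)),
                               -10, 10) for _ in range(m)]
            for e in ests:
                e.ci_low, e.ci_high = e.estimate - 1, e.estimate + 1
            c = combine_estimates(ests)
            wbar = np.mean([e.standard_error ** 2 for e in ests])
            assert c.standard_error ** 2 >= wbar - 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_estimates([])


def _ci(lo, hi, alpha=0.05):
    q = (lo + hi) / 2
    se = max((hi - lo) / (2 * 1.959963984540054), 1e-9)
    return EstimateCI(q, se, lo, hi, alpha=alpha)


class TestAgreementMetrics:
    def test_identity_gives_all_ones(self):
        real = _ci(0.2, 1.0)
        res = replicability_metrics(real, real)
        assert (res.decision_agreement, res.estimate_agreement,
                res.standardized_difference_agreement) == (1, 1, 1)
        assert res.ci_overlap == pytest.approx(1.0)

    def test_half_overlap_hand_example(self):
        # overlap([0,1],[0.5,1.5]) = 0.5*(0.5/1 + 0.5/1) = 0.5
        res = replicability_metrics(_ci(0.0, 1.0), _ci(0.5, 1.5))
        assert res.ci_overlap == pytest.approx(0.5)

    def test_disjoint_opposite_signs_all_zero(self):
        res = replicability_metrics(_ci(0.5, 1.0), _ci(-1.0, -0.5))
        assert res.decision_agreement == 0
        assert res.estimate_agreement == 0
        assert res.ci_overlap == 0.0

    def test_overlap_symmetric_and_extremes(self):
        a, b = _ci(0.0, 1.0), _ci(0.25, 1.25)
        assert (replicability_metrics(a, b).ci_overlap
                == pytest.approx(replicability_metrics(b, a).ci_overlap))
        assert replicability_metrics(a, _ci(2.0, 3.0)).ci_overlap == 0.0

    def test_zero_width_real_ci_rejected(self):
        bad = EstimateCI(0.5, 0.0, 0.5, 0.5)
        with pytest.raises(ValueError, match="zero-width"):
            replicability_metrics(bad, _ci(0.0, 1.0))

    def test_mismatched_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            replicability_metrics(_ci(0, 1), _ci(0, 1, alpha=0.1))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    lo1=st.floats(-2, 2), w1=st.floats(0.1, 2), lo2=st.floats(-2, 2), w2=st.floats(0.1, 2)
)
def test_overlap_properties(lo1, w1, lo2, w2):
    a, b = _ci(lo1, lo1 + w1), _ci(lo2, lo2 + w2)
    res_ab = replicability_metrics(a, b)
    res_ba = replicability_metrics(b, a)
    assert res_ab.ci_overlap == pytest.approx(res_ba.ci_overlap, abs=1e-9)
    assert 0.0 <= res_ab.ci_overlap <= 1.0 + 1e-9


def test_copy_generator_end_to_end_agreement(sim_cohort):
    cohort, _ = sim_cohort
    train = Cohort(cohort.records.head(2500).reset_index(drop=True),
                   list(cohort.meta), "train").project(cohort.core_names)
    ens = generate(fit_copy(train, seed=1), n_rows=train.n, n_replicates=5, seed=2)
    res, real_est, combined, n_used = ensemble_replicability(train, ens)
    assert n_used == 5
    assert res.decision_agreement == 1
    assert res.estimate_agreement == 1
    assert res.standardized_difference_agreement == 1
    assert res.ci_overlap > 0.5
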