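import numpy as np
import pandas as pd
import pytest

from sdgeval.cohort import Cohort, VariableMeta
from sdgeval.generators import (
    fit_bayesian_network,
    fit_copy,
    fit_independent_marginals,
    fit_sequential_trees,
    generate,
    get_generator,
    register_generator,
)


def _binary_cohort(n, rng, rho_perfect=False):
    a = rng.choice(["0", "1"], size=n)
    b = a.copy() if rho_perfect else rng.choice(["0", "1"], size=n)
    df = pd.DataFrame({"a": a, "b": b, "y": rng.choice(["0", "1"], size=n)})
    meta = [
        VariableMeta("a", "categorical", "core_predictor", categories=["0", "1"]),
        VariableMeta("b", "categorical", "core_predictor", categories=["0", "1"]),
        VariableMeta("y", "categorical", "outcome", categories=["0", "1"]),
    ]
    return Cohort(df, meta, "bin")


def _phi(x, y):
    t = pd.crosstab(x, y).to_numpy(dtype=float)
    if t.shape != (2, 2):
        return 0.0
    num = t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]
    den = np.sqrt(t.sum(0).prod() * t.sum(1).prod())
    return num / den if den else 0.0


def _tv(a: pd.Series, b: pd.Series) -> float:
    pa = a.value_counts(normalize=True, dropna=False)
    pb = b.value_counts(normalize=True, dropna=False)
    cats = set(pa.index) | set(pb.index)
    return 0.5 * sum(abs(pa.get(c, 0.0) - pb.get(c, 0.0)) for c in cats)


class TestSequentialTrees:
    def test_single_column_is_marginal_bootstrap(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.choice(["0", "1"], size=500, p=[0.7, 0.3])})
        meta = [VariableMeta("y", "categorical", "outcome", categories=["0", "1"])]
        fitted = fit_sequential_trees(Cohort(df, meta, "one"), seed=1)
        sample = fitted.sample(10_000, seed=2)
        rate = (sample["y"] == "1").mean()
        assert abs(rate - (df["y"] == "1").mean()) < 3 * np.sqrt(0.3 * 0.7 / 10_000)

    def test_perfect_association_preserved(self):
        # oracle: contingency-table phi on the generated sample
        rng = np.random.default_rng(1)
        train = _binary_cohort(2000, rng, rho_perfect=True)
        fitted = fit_sequential_trees(train, seed=3)
        syn = fitted.sample(10_000, seed=4)
        assert _phi(syn["a"], syn["b"]) >= 0.95

    def test_determinism(self):
        rng = np.random.default_rng(2)
        train = _binary_cohort(500, rng)
        a = fit_sequential_trees(train, seed=5).sample(200, seed=6)
        b = fit_sequential_trees(train, seed=5).sample(200, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_table_rejected(self):
        df = pd.DataFrame({"y": pd.Series([], dtype=object)})
        meta = [VariableMeta("y", "categorical", "outcome", categories=["0", "1"])]
        with pytest.raises(Exception):
            fit_sequential_trees(Cohort(df, meta, "empty"), seed=0)

    def test_continuous_values_stay_in_training_support(self, sim_cohort):
        cohort, _ = sim_cohort
        train = Cohort(cohort.records.head(800).reset_index(drop=True),
                       list(cohort.meta), "sup")
        fitted = fit_sequential_trees(train, seed=7)
        syn = fitted.sample(2000, seed=8)
        for m in train.meta:
            if m.vtype == "continuous":
                tr = train.records[m.name].dropna()
                sv = syn[m.name].dropna()
                assert sv.min() >= tr.min() and sv.max() <= tr.max()

    def test_missingness_rates_reproduced(self, sim_cohort):
        cohort, _ = sim_cohort
        train = Cohort(cohort.records.head(2000).reset_index(drop=True),
                       list(cohort.meta), "mr")
        fitted = fit_sequential_trees(train, seed=9)
        syn = fitted.sample(4000, seed=10)
        for m in train.meta:
            train_rate = train.records[m.name].isna().mean()
            assert abs(syn[m.name].isna().mean() - train_rate) < 0.05


class TestBayesianNetwork:
    def test_independent_columns_marginals_match(self):
        # oracle: empirical MI on learned edges, TV distance on marginals
        rng = np.random.default_rng(3)
        n = 50_000
        df = pd.DataFrame({
            "a": rng.choice(["0", "1"], size=n),
            "b": rng.choice(["x", "y", "z"], size=n),
            "y": rng.choice(["0", "1"], size=n),
        })
        meta = [
            VariableMeta("a", "categorical", "core_predictor", categories=["0", "1"]),
            VariableMeta("b", "categorical", "core_predictor", categories=["x", "y", "z"]),
            VariableMeta("y", "categorical", "outcome", categories=["0", "1"]),
        ]
        train = Cohort(df, meta, "ind")
        fitted = fit_bayesian_network(train, seed=11)
        from sklearn.metrics import mutual_info_score

        for parent, chld in fitted.edges:
            assert mutual_info_score(df[parent], df[chld]) < 0.01
        syn = fitted.sample(50_000, seed=12)
        for c in df.columns:
            assert _tv(syn[c], df[c]) < 0.03

    def test_deterministic_chain_preserved(self):
        rng = np.random.default_rng(4)
        x = rng.choice(["0", "1"], size=3000)
        df = pd.DataFrame({"x": x, "y": x.copy()})
        meta = [VariableMeta("x", "categorical", "core_predictor", categories=["0", "1"]),
                VariableMeta("y", "categorical", "outcome", categories=["0", "1"])]
        fitted = fit_bayesian_network(Cohort(df, meta, "chain"), seed=13)
        syn = fitted.sample(10_000, seed=14)
        assert (syn["x"] == syn["y"]).mean() >= 0.98

    def test_single_category_always_sampled(self):
        df = pd.DataFrame({"c": ["only"] * 50, "y": ["0", "1"] * 25})
        meta = [VariableMeta("c", "categorical", "core_predictor", categories=["only"]),
                VariableMeta("y", "categorical", "outcome", categories=["0", "1"])]
        fitted = fit_bayesian_network(Cohort(df, meta, "const"), seed=15)
        syn = fitted.sample(500, seed=16)
        assert (syn["c"] == "only").all()

    def test_continuous_rematerialized_within_bin_range(self, sim_cohort):
        cohort, _ = sim_cohort
        train = Cohort(cohort.records.head(1000).reset_index(drop=True),
                       list(cohort.meta), "cont")
        fitted = fit_bayesian_network(train, seed=17)
        syn = fitted.sample(2000, seed=18)
        for m in train.meta:
            if m.vtype == "continuous":
                tr = train.records[m.name].dropna()
                sv = syn[m.name].dropna()
                assert sv.min() >= tr.min() - 1e-9 and sv.max() <= tr.max() + 1e-9


class TestBaselines:
    def test_independent_marginals_break_joint(self):
        rng = np.random.default_rng(5)
        train = _binary_cohort(3000, rng, rho_perfect=True)
        fitted = fit_independent_marginals(train, seed=19)
        syn = fitted.sample(10_000, seed=20)
        assert abs(_phi(syn["a"], syn["b"])) < 0.05

    def test_marginal_frequencies_within_binomial_error(self):
        rng = np.random.default_rng(6)
        train = _binary_cohort(5000, rng)
        fitted = fit_independent_marginals(train, seed=21)
        syn = fitted.sample(20_000, seed=22)
        for c in ["a", "b", "y"]:
            p = (train.records[c] == "1").mean()
            se = np.sqrt(p * (1 - p) / 20_000)
            assert abs((syn[c] == "1").mean() - p) < 3 * se

    def test_missing_cells_resampled_at_training_rate(self, sim_cohort):
        cohort, _ = sim_cohort
        fitted = fit_independent_marginals(cohort, seed=23)
        syn = fitted.sample(20_000, seed=24)
        for m in cohort.meta:
            rate = cohort.records[m.name].isna().mean()
            assert abs(syn[m.name].isna().mean() - rate) < 0.02

    def test_copy_generator_bootstraps_training_rows(self, toy_cohort):
        fitted = fit_copy(toy_cohort, seed=25)
        syn = fitted.sample(100, seed=26)
        train_keys = set(map(tuple, toy_cohort.records.fillna("NA").astype(str).values))
        syn_keys = set(map(tuple, syn.fillna("NA").astype(str).values))
        assert syn_keys <= train_keys


class TestEnsemble:
    def test_ensemble_shape_and_determinism(self, toy_cohort):
        fitted = fit_independent_marginals(toy_cohort, seed=27)
        ens = generate(fitted, n_rows=50, n_replicates=4, seed=28)
        assert len(ens) == 4
        assert all(rep.n == 50 for rep in ens.replicates)
        ens2 = generate(fitted, n_rows=50, n_replicates=4, seed=28)
        for a, b in zip(ens.replicates, ens2.replicates):
            pd.testing.assert_frame_equal(a.records, b.records)

    def test_replicates_differ_under_child_seeds(self, sim_cohort):
        cohort, _ = sim_cohort
        fitted = fit_independent_marginals(cohort, seed=29)
        ens = generate(fitted, n_rows=500, n_replicates=2, seed=30)
        assert not ens.replicates[0].records.equals(ens.replicates[1].records)

    def test_invalid_row_count_rejected(self, toy_cohort):
        fitted = fit_copy(toy_cohort, seed=31)
        with pytest.raises(ValueError):
            generate(fitted, n_rows=0, n_replicates=1, seed=0)

    def test_plugin_registry_roundtrip(self, toy_cohort):
        register_generator("plugin-test", fit_copy)
        fitted = get_generator("plugin-test")(toy_cohort, seed=1)
        assert fitted.sample(5, seed=2).shape == (5, 4)
        with pytest.raises(KeyError, match="unknown generator"):
            get_generator("nope")
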