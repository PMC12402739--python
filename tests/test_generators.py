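import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from tabhallu.audit import fit_binning_policy, hallucination_rate
from tabhallu.errors import ValidationError
from tabhallu.generators import (PluginContractError, fit_chow_liu_bn,
                                 fit_generator, fit_sequential_trees,
                                 register_plugin, sample_replicates)


def tv_distance(a: pd.Series, b: pd.Series) -> float:
    pa = a.value_counts(normalize=True, dropna=False)
    pb = b.value_counts(normalize=True, dropna=False)
    return float(0.5 * pa.sub(pb, fill_value=0).abs().sum())


@pytest.fixture(scope="module")
def mixed_train():
    rng = np.random.default_rng(77)
    n = 10_000
    a = rng.choice(["u", "v", "w"], n, p=[0.5, 0.3, 0.2]).astype(object)
    b = np.where(a == "u", rng.choice(["p", "q"], n, p=[0.8, 0.2]),
                 rng.choice(["p", "q"], n, p=[0.3, 0.7])).astype(object)
    x = rng.normal(np.where(a == "u", 0.0, 2.0), 1.0)
    y = (rng.random(n) < np.where(b == "p", 0.7, 0.3)).astype(np.int64)
    a[rng.random(n) < 0.02] = np.nan
    return pd.DataFrame({"a": a, "b": b, "x": x, "y": y})


class TestSequentialTrees:
    def test_single_column_reduces_to_empirical_marginal(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"a": rng.choice(["x", "y"], 5000, p=[0.6, 0.4])})
        gen = fit_sequential_trees(train, seed=1)
        rep = sample_replicates(gen, 10_000, 1, seed=2).replicates[0]
        frac = (rep["a"] == "x").mean()
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 10_000) + 0.01

    def test_perfectly_correlated_columns_yield_only_observed_combos(self):
        rng = np.random.default_rng(1)
        a = rng.choice(["x", "y"], 2000)
        train = pd.DataFrame({"a": a, "b": np.where(a == "x", "1", "0")})
        gen = fit_sequential_trees(train, seed=0)
        rep = sample_replicates(gen, 5000, 1, seed=0).replicates[0]
        combos = set(map(tuple, rep[["a", "b"]].to_numpy()))
        assert combos <= {("x", "1"), ("y", "0")}

    def test_fit_and_sampling_are_deterministic(self, mixed_train):
        g1 = fit_sequential_trees(mixed_train, seed=9)
        g2 = fit_sequential_trees(mixed_train, seed=9)
        r1 = sample_replicates(g1, 500, 2, seed=3)
        r2 = sample_replicates(g2, 500, 2, seed=3)
        for a, b in zip(r1.replicates, r2.replicates):
            pd.testing.assert_frame_equal(a, b)

    def test_constant_dataset_resamples_the_single_record(self):
        train = pd.DataFrame({"a": ["k"] * 50, "b": [1] * 50})
        gen = fit_sequential_trees(train, seed=0)
        rep = sample_replicates(gen, 20, 1, seed=0).replicates[0]
        assert (rep["a"] == "k").all() and (rep["b"] == 1).all()

    def test_explicit_visit_order_and_validation(self, mixed_train):
        gen = fit_sequential_trees(mixed_train, order_policy=["y", "x", "b", "a"])
        assert gen.state["order"] == ["y", "x", "b", "a"]
        with pytest.raises(ValidationError):
            fit_sequential_trees(mixed_train, order_policy=["a", "b"])


class TestChowLiu:
    def test_independent_variables_have_near_zero_mi_and_product_joint(self):
        rng = np.random.default_rng(5)
        n = 20_000
        train = pd.DataFrame({"a": rng.choice(["0", "1"], n),
                              "b": rng.choice(["0", "1"], n)})
        gen = fit_chow_liu_bn(train, seed=0)
        rep = sample_replicates(gen, 20_000, 1, seed=1).replicates[0]
        mi = mutual_info_score(rep["a"], rep["b"])
        assert mi < 0.001
        p_a = (rep["a"] == "1").mean()
        p_b = (rep["b"] == "1").mean()
        joint = ((rep["a"] == "1") & (rep["b"] == "1")).mean()
        assert abs(joint - p_a * p_b) < 0.02

    def test_chain_structure_is_recovered(self):
        """X->Y->Z with strong dependence: the exact mutual information of the
        generating law satisfies MI(X,Y), MI(Y,Z) > MI(X,Z), so the learned
        spanning tree must be the chain (either orientation)."""
        rng = np.random.default_rng(8)
        n = 20_000
        x = rng.choice([0, 1], n)
        y = np.where(rng.random(n) < 0.9, x, 1 - x)
        z = np.where(rng.random(n) < 0.9, y, 1 - y)
        train = pd.DataFrame({"x": x, "y": y, "z": z}).astype(str)
        gen = fit_chow_liu_bn(train, seed=0)
        cols = gen.state["cols"]
        edges = {frozenset((cols[i], cols[p]))
                 for i, p in gen.state["parent"].items() if p is not None}
        assert edges == {frozenset(("x", "y")), frozenset(("y", "z"))}

    def test_laplace_smoothing_gives_unseen_combinations_mass(self):
        train = pd.DataFrame({"a": ["0"] * 50 + ["1"] * 50,
                              "b": ["0"] * 50 + ["1"] * 50})
        gen = fit_chow_liu_bn(train, smoothing_alpha=1.0, seed=0)
        # every observed-level combination (incl. the never-seen 0/1 pairing)
        # has positive mass; the unobserved missing level stays at zero
        for i, cpt in gen.state["cpts"].items():
            cpt = np.atleast_2d(np.asarray(cpt))
            assert (cpt[:, :-1] > 0).all()
            assert (cpt[:, -1] == 0).all()

    def test_single_variable_falls_back_to_smoothed_marginal(self):
        train = pd.DataFrame({"a": ["p", "p", "q"]})
        gen = fit_chow_liu_bn(train, seed=0)
        rep = sample_replicates(gen, 100, 1, seed=0).replicates[0]
        assert set(rep["a"].dropna()) <= {"p", "q"}


class TestReplicates:
    def test_shapes_and_determinism(self, mixed_train):
        gen = fit_chow_liu_bn(mixed_train, seed=4)
        reps = sample_replicates(gen, 1000, 3, seed=6)
        assert reps.k == 3
        assert all(len(r) == 1000 for r in reps.replicates)
        assert all(list(r.columns) == list(mixed_train.columns)
                   for r in reps.replicates)
        again = sample_replicates(gen, 1000, 3, seed=6)
        for a, b in zip(reps.replicates, again.replicates):
            pd.testing.assert_frame_equal(a, b)
        # replicates differ from each other (independent sub-seeds)
        assert not reps.replicates[0].equals(reps.replicates[1])

    def test_single_row_single_replicate(self, mixed_train):
        gen = fit_sequential_trees(mixed_train, seed=0)
        rep = sample_replicates(gen, 1, 1, seed=0).replicates[0]
        assert len(rep) == 1
        assert rep["a"].iloc[0] in set(mixed_train["a"].dropna()) or \
            pd.isna(rep["a"].iloc[0])

    def test_schema_closure_for_categorical_levels(self, mixed_train):
        for fit in (fit_sequential_trees, fit_chow_liu_bn):
            gen = fit(mixed_train, seed=2)
            rep = sample_replicates(gen, 2000, 1, seed=1).replicates[0]
            for col in ("a", "b", "y"):
                observed = set(rep[col].dropna())
                assert observed <= set(mixed_train[col].dropna())

    def test_marginal_fidelity_tv_within_five_percent(self, mixed_train):
        policy = fit_binning_policy(mixed_train)
        from tabhallu.audit import canonicalize
        canon_train = canonicalize(mixed_train, policy)
        for fit in (fit_sequential_trees, fit_chow_liu_bn):
            gen = fit(mixed_train, seed=3)
            rep = sample_replicates(gen, 10_000, 1, seed=5).replicates[0]
            canon_rep = canonicalize(rep, policy)
            for col in mixed_train.columns:
                assert tv_distance(canon_train[col], canon_rep[col]) <= 0.05


class TestPlugins:
    def test_verbatim_training_plugin_has_zero_hr_against_population(self, rng):
        pop = pd.DataFrame({"a": rng.choice(list("abc"), 2000),
                            "b": rng.integers(0, 2, 2000)})
        train = pop.sample(500, random_state=0).reset_index(drop=True)
        handle = register_plugin(
            "verbatim",
            fit_fn=lambda tr, seed: tr,
            sample_fn=lambda state, n, r: state.sample(
                n, replace=True, random_state=int(r.integers(2**31))
            ).reset_index(drop=True))
        gen = fit_generator(handle, train, seed=0)
        reps = sample_replicates(gen, 300, 2, seed=1)
        policy = fit_binning_policy(pop)
        report = hallucination_rate(reps.replicates, pop, policy)
        assert report.mean_rate == 0.0  # S subset of T subset of P

    def test_wrong_column_set_is_rejected(self, rng):
        train = pd.DataFrame({"a": [1, 2, 3]})
        handle = register_plugin(
            "broken",
            fit_fn=lambda tr, seed: None,
            sample_fn=lambda state, n, r: pd.DataFrame({"zzz": range(n)}))
        gen = fit_generator(handle, train, seed=0)
        with pytest.raises(PluginContractError):
            sample_replicates(gen, 5, 1, seed=0)

    def test_unknown_plugin_name(self):
        with pytest.raises(ValidationError):
            fit_generator("plugin:nope", pd.DataFrame({"a": [1]}), seed=0)
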