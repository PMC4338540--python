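import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from oncodecon.survival import (
    GenotypePCPredictor,
    RidgeCoxPH,
    cox_partial_loglik,
    cross_validated_concordance,
    decompose_risk_variance,
    harrells_c,
    kaplan_meier_terciles,
    survival_design,
)


from oracles import brute_force_c, naive_newton_cox


def sim_survival_data(n=150, p=4, seed=0, censor_scale=1.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.linspace(0.8, -0.4, p)
    T = rng.exponential(np.exp(-(X @ beta)))
    C = rng.exponential(censor_scale, n)
    return X, np.minimum(T, C), (T <= C).astype(float)


class TestHarrellsC:
    def test_perfect_ordering(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrells_c(t, np.ones(4), -t) == 1.0

    def test_constant_risk_half(self):
        t = np.array([1.0, 2.0, 3.0])
        assert harrells_c(t, np.ones(3), np.zeros(3)) == 0.5

    def test_three_sample_example(self):
        # comparable pairs: (1,2), (1,3), (2,3); risks (3,1,2) -> 2 concordant
        c = harrells_c(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]),
                       np.array([3.0, 1.0, 2.0]))
        assert c == pytest.approx(2 / 3)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError, match="comparable"):
            harrells_c(np.array([1.0, 2.0]), np.array([0, 0]), np.array([1.0, 2.0]))

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(12)
        for trial in range(200):
            n = rng.integers(5, 25)
            time = rng.integers(1, 10, n).astype(float)  # frequent time ties
            status = rng.integers(0, 2, n).astype(float)
            risk = rng.integers(-3, 4, n).astype(float)  # frequent risk ties
            earlier = (time[:, None] < time[None, :]) & (status[:, None] == 1)
            if not earlier.any():
                continue
            assert harrells_c(time, status, risk) == brute_force_c(time, status, risk)


class TestRidgeCox:
    def test_tau_zero_matches_newton_oracle(self):
        X, t, s = sim_survival_data(n=80, p=3, seed=1)
        model = RidgeCoxPH(tau=0.0).fit(pd.DataFrame(X), t, s)
        oracle = naive_newton_cox(X, t, s)
        np.testing.assert_allclose(model.coef_.to_numpy(), oracle, atol=1e-6)

    def test_penalized_loglik_nondecreasing_and_gradient_small(self):
        X, t, s = sim_survival_data(n=120, p=5, seed=2)
        model = RidgeCoxPH(tau=2.0).fit(pd.DataFrame(X), t, s)
        # convergence criterion: per-event penalized gradient at the solution
        arr = (X - X.mean(0)) / X.std(0)
        from oncodecon.survival import _loglik_grad_hess
        _, grad, _ = _loglik_grad_hess(model.coef_std_, t, s, arr, 2.0)
        assert np.abs(grad).max() <= 1e-8
        assert model.grad_norm_ <= 1e-8

    def test_tau_infinite_shrinks_to_zero(self):
        X, t, s = sim_survival_data(seed=3)
        model = RidgeCoxPH(tau=1e10).fit(pd.DataFrame(X), t, s)
        assert np.abs(model.coef_.to_numpy()).max() < 1e-6
        assert harrells_c(t, s, np.zeros(len(t))) == 0.5

    def test_two_group_simulation_recovers_loghr(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        T = rng.exponential(np.exp(-x))
        C = rng.exponential(3.0, n)
        t, s = np.minimum(T, C), (T <= C).astype(float)
        model = RidgeCoxPH(tau=0.0).fit(pd.DataFrame({"x": x}), t, s)
        se = 2.0 / np.sqrt(s.sum())  # approx SE of a balanced binary log-HR
        assert abs(model.coef_["x"] - 1.0) < 3 * se

    def test_requires_events(self):
        X, t, _ = sim_survival_data(n=30)
        with pytest.raises(ValueError, match="events"):
            RidgeCoxPH().fit(pd.DataFrame(X), t, np.zeros(len(t)))

    def test_breslow_loglik_value(self):
        # two samples, one event: l = eta_1 - log(e^eta_1 + e^eta_2)
        X = np.array([[1.0], [0.0]])
        beta = np.array([0.7])
        ll = cox_partial_loglik(beta, np.array([1.0, 2.0]), np.array([1.0, 0.0]), X)
        assert ll == pytest.approx(0.7 - np.log(np.exp(0.7) + 1.0))


class TestCrossValidatedC:
    def test_null_covariates_give_half(self):
        rng = np.random.default_rng(5)
        n = 150
        X = pd.DataFrame(rng.normal(size=(n, 8)))
        t = rng.exponential(1.0, n)
        s = (rng.random(n) < 0.7).astype(float)
        rep = cross_validated_concordance(X, t, s, seed=1)
        assert 0.4 < rep["mean_c"] < 0.6

    def test_signal_beats_half(self):
        X, t, s = sim_survival_data(n=300, p=4, seed=6)
        rep = cross_validated_concordance(pd.DataFrame(X), t, s, seed=2)
        assert rep["mean_c"] > 0.6

    def test_seed_reproducible(self):
        X, t, s = sim_survival_data(n=120, seed=7)
        a = cross_validated_concordance(pd.DataFrame(X), t, s, seed=3)
        b = cross_validated_concordance(pd.DataFrame(X), t, s, seed=3)
        np.testing.assert_array_equal(a["fold_c"], b["fold_c"])


class TestRiskDecomposition:
    def test_orthogonal_groups_reduce_to_variances(self):
        rng = np.random.default_rng(8)
        n = 500
        Xa = rng.normal(size=n)
        Xb = rng.normal(size=n)  # independent
        X = pd.DataFrame({"a": Xa, "b": Xb})
        coef = pd.Series({"a": 0.8, "b": -0.5})
        dec = decompose_risk_variance(X, coef, {"a": "ga", "b": "gb"}).set_index("group")
        ra = 0.8 * (Xa - Xa.mean())
        # near-orthogonal: s_a ~ Var(r_a) up to the empirical cross term
        assert dec.loc["ga", "s_g"] == pytest.approx(np.var(ra), rel=0.1)
        assert dec["share"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_sum_to_var_r(self):
        rng = np.random.default_rng(9)
        n = 300
        base = rng.normal(size=n)
        X = pd.DataFrame({
            "a": base + 0.2 * rng.normal(size=n),
            "b": -base + 0.2 * rng.normal(size=n),
            "c": rng.normal(size=n),
        })
        coef = pd.Series({"a": 1.0, "b": 0.8, "c": -0.3})
        groups = {"a": "g1", "b": "g2", "c": "g3"}
        dec = decompose_risk_variance(X, coef, groups)
        r = sum((X[c] - X[c].mean()) * coef[c] for c in X.columns).to_numpy()
        assert dec["s_g"].sum() == pytest.approx(np.var(r), abs=1e-10)
        # correlated fixture: brute-force covariance arithmetic
        parts = {g: sum((X[c] - X[c].mean()) * coef[c]
                        for c in X.columns if groups[c] == g).to_numpy()
                 for g in ("g1", "g2", "g3")}
        for g in parts:
            expected = sum(np.mean(parts[g] * parts[h]) for h in parts)
            got = dec.set_index("group").loc[g, "s_g"]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_single_group_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="groups"):
            decompose_risk_variance(X, pd.Series({"a": 1.0}), {"a": "g"})


class TestKaplanMeierTerciles:
    def test_hand_computed_steps_no_censoring(self):
        # 9 samples, 3 obvious risk groups, all events
        risk = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3], dtype=float)
        time = np.array([30, 31, 32, 20, 21, 22, 10, 11, 12], dtype=float)
        status = np.ones(9)
        res = kaplan_meier_terciles(risk, time, status)
        surv = res["curves"]
        # high-risk group: events at 10,11,12 -> survival 2/3, 1/3, 0
        assert surv.loc[10.0, "high"] == pytest.approx(2 / 3)
        assert surv.loc[11.0, "high"] == pytest.approx(1 / 3)
        assert surv.loc[12.0, "high"] == pytest.approx(0.0)
        assert res["stochastically_ordered"]

    def test_no_events_flat_curves(self):
        rng = np.random.default_rng(10)
        risk = rng.normal(size=12)
        res = kaplan_meier_terciles(risk, np.full(12, 100.0), np.zeros(12))
        assert (res["curves"].to_numpy() == 1.0).all() if res["curves"].size else True

    def test_identical_risks_error(self):
        with pytest.raises(ValueError, match="tercile"):
            kaplan_meier_terciles(np.ones(12), np.arange(12.0), np.ones(12))

    def test_strong_signal_orders_curves(self):
        rng = np.random.default_rng(11)
        n = 300
        risk = rng.normal(size=n)
        T = rng.exponential(np.exp(-2 * risk))
        res = kaplan_meier_terciles(risk, T, np.ones(n))
        med = res["curves"].iloc[len(res["curves"]) // 2]
        assert med["high"] < med["low"]


class TestGenotypePrediction:
    def test_wild_type_predicts_intercept(self):
        rng = np.random.default_rng(13)
        n = 60
        lesions = pd.DataFrame({"A": (rng.random(n) < 0.3).astype(float),
                                "B": (rng.random(n) < 0.3).astype(float)},
                               index=[f"s{i}" for i in range(n)])
        scores = pd.DataFrame({"PC1": 2.0 * lesions["A"] + rng.normal(size=n)},
                              index=lesions.index)
        model = GenotypePCPredictor().fit(lesions, scores)
        wt = pd.DataFrame({"A": [0.0], "B": [0.0]}, index=["wt"])
        pred = model.predict(wt)
        assert pred.iloc[0, 0] == pytest.approx(model.coef_[0, 0])

    def test_column_mismatch_rejected(self):
        lesions = pd.DataFrame({"A": [0.0, 1.0]})
        scores = pd.DataFrame({"PC1": [0.1, -0.1]})
        model = GenotypePCPredictor().fit(lesions, scores)
        with pytest.raises(ValueError, match="missing"):
            model.predict(pd.DataFrame({"B": [1.0]}))

    def test_zero_effect_genotype_prediction_is_constant(self):
        rng = np.random.default_rng(14)
        n = 80
        lesions = pd.DataFrame({"A": (rng.random(n) < 0.3).astype(float)})
        scores = pd.DataFrame({"PC1": rng.normal(size=n)})  # unrelated to genotype
        pred = GenotypePCPredictor().fit(lesions, scores).predict(lesions)
        assert pred["pred_PC1"].std() < scores["PC1"].std() * 0.5


def test_survival_design_and_class_errors(small_bundle):
    from oncodecon.deconvolution import run_pca
    pca = run_pca(small_bundle.expression.values, k=5)
    X, groups = survival_design(small_bundle, pca.scores, ["genetic", "demographic"])
    assert set(groups.values()) == {"genetic", "demographic"}
    with pytest.raises(ValueError, match="unknown predictor class"):
        survival_design(small_bundle, pca.scores, ["nonsense"])
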