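"""Exponential model, parallel fitting, RPFs, concentration-addition prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq, minimize_scalar

from mixtk import schemas as S
from mixtk.dose_response import (
    ClassificationRule,
    ExponentialDoseResponse,
    ExponentialModelParams,
    MixtureSpec,
    NoCytotoxicitySignal,
    ParallelFitResult,
    RelativePotencySet,
    classify_additivity,
    compute_rpf,
    exponential_model,
    fit_parallel,
    fit_single,
    predict_ca_curve,
)
from mixtk.synthetic import generate_dose_response


class TestExponentialModel:
    @pytest.mark.parametrize("p", [
        ExponentialModelParams(100.0, 0.01, 0.2, 1.0),
        ExponentialModelParams(95.0, 0.5, 0.05, 2.3),
        ExponentialModelParams(110.0, 3.0, 0.8, 0.4),
    ])
    def test_value_at_zero_is_control_level(self, p):
        assert exponential_model(0.0, p) == pytest.approx(p.a, rel=1e-12)

    def test_flat_curve_when_c_is_one(self):
        p = ExponentialModelParams(100.0, 0.01, 1.0, 1.0)
        x = np.array([0.0, 1.0, 10.0, 1e4])
        assert exponential_model(x, p) == pytest.approx([100.0] * 4, rel=1e-12)

    def test_hand_evaluated_value(self):
        # 100 * [0.2 + 0.8 * exp(-1)] at b*x^d = 1
        p = ExponentialModelParams(100.0, 0.01, 0.2, 1.0)
        assert exponential_model(100.0, p) == pytest.approx(49.43, abs=5e-3)

    def test_monotone_non_increasing_for_toxic_curves(self, known_params):
        x = np.linspace(0.0, 500.0, 200)
        y = exponential_model(x, known_params)
        assert np.all(np.diff(y) <= 1e-12)

    def test_negative_concentration_rejected(self, known_params):
        with pytest.raises(ValueError, match="non-negative"):
            exponential_model(-1.0, known_params)

    @pytest.mark.parametrize("bad", [
        {"a": np.nan}, {"b": np.inf}, {"b": -0.1}, {"d": 0.0}, {"c": -0.5},
    ])
    def test_invalid_parameters_named_in_error(self, bad):
        kw = {"a": 100.0, "b": 0.01, "c": 0.2, "d": 1.0}
        kw.update(bad)
        name = next(iter(bad))
        with pytest.raises(ValueError, match=f"'{name}'"):
            ExponentialModelParams(**kw)


class TestSingleFit:
    def test_exact_recovery_on_noise_free_data(self, noise_free_data, known_params):
        est = fit_single(noise_free_data)
        for name in "abcd":
            true, got = getattr(known_params, name), getattr(est, name)
            assert got == pytest.approx(true, rel=1e-6), name

    def test_estimator_api_exposes_fitted_attributes(self, noise_free_data):
        means = noise_free_data.groupby(S.CONC)[S.VIABILITY].mean().reset_index()
        est = ExponentialDoseResponse().fit(means[S.CONC], means[S.VIABILITY])
        assert est.converged_
        assert est.rss_ == pytest.approx(0.0, abs=1e-12)
        assert est.predict([0.0])[0] == pytest.approx(est.a_)
        assert "fix_d" in est.get_params()

    def test_flat_data_raises_no_signal(self, grid):
        rows = [("flat", x, 100.0, f"b{i}", f"t{j}")
                for x in grid for i in range(3) for j in range(2)]
        df = pd.DataFrame(rows, columns=list(S.DOSE_RESPONSE_COLUMNS))
        with pytest.raises(NoCytotoxicitySignal, match="RPF 0"):
            fit_single(df)

    def test_too_few_concentrations_rejected(self, known_params):
        data = generate_dose_response(known_params, [0.0, 10.0, 50.0, 100.0],
                                      residual_sd=0.0, bio_intercept_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="5 distinct"):
            fit_single(data)


class TestParallelFit:
    def _dataset(self, b_values, seed=0, sd=0.0):
        frames = [
            generate_dose_response(
                {cid: ExponentialModelParams(100.0, b, 0.2, 1.0)},
                np.array([0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0]) * 0.01 / b,
                residual_sd=sd, bio_intercept_sd=0.0, seed=seed + i)
            for i, (cid, b) in enumerate(sorted(b_values.items()))
        ]
        return pd.concat(frames, ignore_index=True)

    def test_identical_compounds_get_equal_potencies(self):
        data = self._dataset({"u": 0.01, "v": 0.01, "w": 0.01})
        fit = fit_parallel(data, reference_id="u")
        bs = list(fit.per_compound_b.values())
        assert max(bs) / min(bs) == pytest.approx(1.0, rel=1e-6)

    def test_single_compound_reduces_to_fit_single(self, noise_free_data):
        single = fit_single(noise_free_data)
        joint = fit_parallel(noise_free_data.assign(), reference_id="compound")
        assert joint.a == pytest.approx(single.a, rel=1e-6)
        assert joint.d == pytest.approx(single.d, rel=1e-6)
        assert joint.per_compound_b["compound"] == pytest.approx(single.b, rel=1e-5)

    def test_shared_shape_potency_ratios_recovered(self):
        data = self._dataset({"ref": 0.01, "x2": 0.02, "x4": 0.04}, sd=1.0, seed=7)
        fit = fit_parallel(data, reference_id="ref")
        assert fit.per_compound_b["x2"] / fit.per_compound_b["ref"] == pytest.approx(2.0, rel=0.05)
        assert fit.per_compound_b["x4"] / fit.per_compound_b["ref"] == pytest.approx(4.0, rel=0.05)

    def test_joint_rss_not_improvable_per_compound(self):
        """At the joint optimum, re-optimising any single b alone cannot help."""
        data = self._dataset({"ref": 0.01, "x2": 0.02}, sd=2.0, seed=3)
        fit = fit_parallel(data, reference_id="ref")
        means = data.groupby([S.COMPOUND, S.CONC])[S.VIABILITY].mean().reset_index()
        for cid in fit.per_compound_b:
            sub = means[means[S.COMPOUND] == cid]

            def rss(log_b):
                y = exponential_model(sub[S.CONC].to_numpy(),
                                      a=fit.a, b=np.exp(log_b), c=fit.c, d=fit.d)
                return float(np.sum((y - sub[S.VIABILITY].to_numpy()) ** 2))

            best = minimize_scalar(rss, bracket=(np.log(fit.per_compound_b[cid]) - 2,
                                                 np.log(fit.per_compound_b[cid]) + 2))
            assert rss(np.log(fit.per_compound_b[cid])) <= best.fun + 1e-6

    def test_non_cytotoxic_compound_excluded_not_dropped(self, noise_free_data, grid):
        flat = generate_dose_response(
            {"inert": ExponentialModelParams(100.0, 1e-9, 0.999, 1.0)}, grid,
            residual_sd=0.0, bio_intercept_sd=0.0, seed=1)
        fit = fit_parallel(pd.concat([noise_free_data, flat]), reference_id="compound")
        assert fit.excluded == ("inert",)
        rpf = compute_rpf(fit)
        assert rpf.rpf["inert"] == 0.0


class TestRelativePotency:
    def _fit(self, b_map, d=1.0):
        return ParallelFitResult(a=100.0, c=0.2, d=d, per_compound_b=b_map,
                                 reference_id="ref", rss=0.0, converged=True)

    @pytest.mark.parametrize("b_i,d,expected", [
        (0.01, 1.0, 1.0),   # identity
        (0.02, 1.0, 2.0),   # linear case
        (0.04, 2.0, 2.0),   # d=2: RPF = sqrt(b_i / b_ref)
    ])
    def test_rpf_formula(self, b_i, d, expected):
        rpf = compute_rpf(self._fit({"ref": 0.01, "co": b_i}, d=d))
        assert rpf.rpf["co"] == pytest.approx(expected, rel=1e-12)
        assert rpf.rpf["ref"] == 1.0

    def test_rpf_is_exact_dose_rescaling(self):
        """x -> RPF*x maps the reference curve onto the compound's curve."""
        fit = self._fit({"ref": 0.01, "co": 0.04}, d=2.0)
        rpf = compute_rpf(fit).rpf["co"]
        x = np.linspace(0.0, 30.0, 50)
        y_co = exponential_model(x, fit.params_for("co"))
        y_ref_rescaled = exponential_model(rpf * x, fit.params_for("ref"))
        np.testing.assert_allclose(y_co, y_ref_rescaled, rtol=1e-10)

    def test_reference_relabelling_rescales_rpfs(self):
        b = {"ref": 0.01, "co": 0.03, "x": 0.002}
        d = 1.7
        rpf_ref = compute_rpf(self._fit(dict(b), d=d)).rpf
        fit_j = ParallelFitResult(a=100.0, c=0.2, d=d, per_compound_b=dict(b),
                                  reference_id="co", rss=0.0, converged=True)
        rpf_co = compute_rpf(fit_j).rpf
        for cid in b:
            assert rpf_co[cid] == pytest.approx(rpf_ref[cid] / rpf_ref["co"], rel=1e-10)

    def test_reference_must_map_to_one(self):
        with pytest.raises(ValueError, match="RPF 1"):
            RelativePotencySet(reference_id="ref", rpf={"ref": 2.0})


def brute_force_ca(fit: ParallelFitResult, mix: MixtureSpec, x: float,
                   rpf_zero: set[str] = frozenset()) -> float:
    """Independent CA oracle: solve sum_i dose_i / EC_y(i) = 1 for the response y."""
    a, c, d = fit.a, fit.c, fit.d
    if x == 0:
        return a

    def dose_for(b_i, y):
        frac = (c - y / a) / (c - 1.0)
        return (np.log(frac) / (-b_i)) ** (1.0 / d)

    def excess(y):
        total = 0.0
        for cid, rho in mix.components.items():
            if cid in rpf_zero or rho == 0.0:
                continue
            total += rho * x / dose_for(fit.per_compound_b[cid], y)
        return total - 1.0

    lo, hi = a * c + 1e-9, a - 1e-9
    return brentq(excess, lo, hi, xtol=1e-12, rtol=1e-14)


class TestCAPrediction:
    def _three_component_fit(self):
        fit = ParallelFitResult(
            a=100.0, c=0.2, d=1.3,
            per_compound_b={"ref": 0.01, "co1": 0.05, "co2": 0.002},
            reference_id="ref", rss=0.0, converged=True)
        mix = MixtureSpec(components={"ref": 1.0, "co1": 0.5, "co2": 3.0}, active_id="ref")
        return fit, compute_rpf(fit), mix

    def test_identity_mixture_returns_reference_curve(self):
        fit, rpf, _ = self._three_component_fit()
        mix = MixtureSpec(components={"ref": 1.0}, active_id="ref")
        x = np.linspace(0.0, 300.0, 40)
        np.testing.assert_array_equal(
            predict_ca_curve(fit, rpf, mix, x),
            exponential_model(x, fit.params_for("ref")))

    def test_inert_coformulants_leave_curve_unchanged(self):
        fit, rpf, _ = self._three_component_fit()
        rpf0 = RelativePotencySet("ref", {"ref": 1.0, "co1": 0.0, "co2": 0.0})
        mix = MixtureSpec(components={"ref": 1.0, "co1": 5.0, "co2": 9.0}, active_id="ref")
        x = np.linspace(0.0, 300.0, 40)
        np.testing.assert_allclose(
            predict_ca_curve(fit, rpf0, mix, x),
            exponential_model(x, fit.params_for("ref")), rtol=1e-12)

    def test_matches_brute_force_equivalent_dose_search(self):
        fit, rpf, mix = self._three_component_fit()
        x = np.array([0.5, 2.0, 8.0, 20.0, 60.0])
        predicted = predict_ca_curve(fit, rpf, mix, x)
        oracle = [brute_force_ca(fit, mix, xi) for xi in x]
        np.testing.assert_allclose(predicted, oracle, atol=1e-8)

    def test_two_component_rpf2_gives_triple_equivalent_dose(self):
        fit = ParallelFitResult(a=100.0, c=0.2, d=1.0,
                                per_compound_b={"ref": 0.01, "co": 0.02},
                                reference_id="ref", rss=0.0, converged=True)
        rpf = compute_rpf(fit)
        mix = MixtureSpec(components={"ref": 1.0, "co": 1.0}, active_id="ref")
        x = 10.0
        assert predict_ca_curve(fit, rpf, mix, [x])[0] == pytest.approx(
            exponential_model(3.0 * x, fit.params_for("ref")), abs=1e-10)
        assert predict_ca_curve(fit, rpf, mix, [x])[0] == pytest.approx(
            brute_force_ca(fit, mix, x), abs=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rho=st.floats(0.1, 5.0), x=st.floats(0.1, 100.0))
    def test_splitting_a_component_leaves_prediction_invariant(self, rho, x):
        fit = ParallelFitResult(a=100.0, c=0.2, d=1.1,
                                per_compound_b={"ref": 0.01, "co": 0.03, "co2": 0.03},
                                reference_id="ref", rss=0.0, converged=True)
        rpf = compute_rpf(fit)
        whole = MixtureSpec(components={"ref": 1.0, "co": rho}, active_id="ref")
        split = MixtureSpec(components={"ref": 1.0, "co": rho / 2, "co2": rho / 2},
                            active_id="ref")
        assert predict_ca_curve(fit, rpf, whole, [x])[0] == pytest.approx(
            predict_ca_curve(fit, rpf, split, [x])[0], rel=1e-12)

    def test_missing_component_raises_with_ids(self):
        fit, rpf, _ = self._three_component_fit()
        mix = MixtureSpec(components={"ref": 1.0, "mystery": 1.0}, active_id="ref")
        with pytest.raises(KeyError, match="mystery"):
            predict_ca_curve(fit, rpf, mix, [1.0])


class TestAdditivityClassifier:
    def _fixture(self):
        fit = ParallelFitResult(a=100.0, c=0.2, d=1.0,
                                per_compound_b={"ref": 0.01, "co": 0.02},
                                reference_id="ref", rss=0.0, converged=True)
        rpf = compute_rpf(fit)
        mix = MixtureSpec(components={"ref": 1.0, "co": 1.0}, active_id="ref")
        grid = np.array([0.0, 1.5, 3.0, 6.0, 12.0, 24.0, 48.0, 96.0])
        return fit, rpf, mix, grid

    def _observed(self, fit, dose_scale, grid, sd=0.0, seed=0):
        # responses drawn from the CA curve evaluated at dose_scale * x_eq
        b_eff = fit.per_compound_b["ref"] * (3.0 * dose_scale) ** fit.d
        params = ExponentialModelParams(fit.a, b_eff, fit.c, fit.d)
        return generate_dose_response({"mix": params}, grid, residual_sd=sd,
                                      bio_intercept_sd=sd, seed=seed)

    def test_data_on_curve_is_additive(self):
        fit, rpf, mix, grid = self._fixture()
        obs = self._observed(fit, 1.0, grid)
        assert classify_additivity(obs, fit, rpf, mix).label == "additive"

    def test_left_shift_is_more_than_additive(self):
        fit, rpf, mix, grid = self._fixture()
        obs = self._observed(fit, 2.0, grid, sd=2.0, seed=11)
        assert classify_additivity(obs, fit, rpf, mix).label == "more_than_additive"

    def test_right_shift_is_less_than_additive(self):
        fit, rpf, mix, grid = self._fixture()
        obs = self._observed(fit, 0.5, grid, sd=2.0, seed=11)
        assert classify_additivity(obs, fit, rpf, mix).label == "less_than_additive"

    def test_verdict_antisymmetric_under_shift_inversion(self):
        fit, rpf, mix, grid = self._fixture()
        labels = {
            scale: classify_additivity(self._observed(fit, scale, grid, sd=1.0, seed=5),
                                       fit, rpf, mix).label
            for scale in (2.0, 0.5)
        }
        assert labels == {2.0: "more_than_additive", 0.5: "less_than_additive"}

    def test_no_concentration_in_window_is_indeterminate(self):
        fit, rpf, mix, _ = self._fixture()
        tiny = np.array([0.0, 1e-4, 2e-4, 5e-4, 1e-3])  # all below 10% effect
        obs = self._observed(fit, 1.0, tiny)
        verdict = classify_additivity(obs, fit, rpf, mix)
        assert verdict.label == "indeterminate"

    def test_residual_table_reports_window(self):
        fit, rpf, mix, grid = self._fixture()
        verdict = classify_additivity(self._observed(fit, 1.0, grid), fit, rpf, mix)
        assert {"residual", "predicted", "in_window"} <= set(verdict.residuals.columns)
        assert verdict.n_concentrations >= 2
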