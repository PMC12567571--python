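"""Tests of stage fitting, the information criterion, ranking and bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from tabrom import selection
from tabrom.rational import ModelCombination, RationalParams, eval_rational
from tabrom.selection import (
    FitResult,
    StageConstraints,
    StageDataset,
    aic,
    bootstrap_ci,
    build_stage_dataset,
    fit_combination,
    overfit_flag,
    r_squared,
    select_model,
    sse,
    stage_predict,
)
from tabrom.synthetic import DEFAULT_GEOMETRY


class TestAic:
    def test_uncorrected_branch(self):
        # SSE = n makes the log term vanish: AIC = 2 Np
        assert aic(40.0, 40, 3) == pytest.approx(6.0)

    def test_small_sample_correction(self):
        # n=20, Np=3: 6 + 2*3*4/16 = 7.5
        assert aic(20.0, 20, 3) == pytest.approx(7.5)

    def test_boundary_n30_uses_uncorrected_branch(self):
        assert aic(30.0, 30, 3) == pytest.approx(6.0)
        assert aic(29.0, 29, 3) == pytest.approx(6.0 + 24.0 / 25.0)

    def test_perfect_fit_sentinel_and_errors(self):
        assert aic(0.0, 20, 3) == -math.inf
        with pytest.raises(ValueError):
            aic(1.0, 10, 9)  # correction denominator <= 0
        with pytest.raises(ValueError):
            aic(-1.0, 10, 2)


class TestGoodnessOfFit:
    def test_r_squared_anchors(self):
        resp = np.array([1.0, 2.0, 3.0])
        assert r_squared(0.0, resp) == 1.0
        # a constant prediction at the mean leaves SSE = SST
        sst = float(np.sum((resp - resp.mean()) ** 2))
        assert r_squared(sst, resp) == pytest.approx(0.0)

    def test_toy_sse_by_hand(self):
        # responses (1,2,3) vs predictions (1.5,2,2.5): SSE = 0.25+0+0.25
        pred = np.array([1.5, 2.0, 2.5])
        resp = np.array([1.0, 2.0, 3.0])
        assert float(np.sum((pred - resp) ** 2)) == pytest.approx(0.5)
        assert r_squared(0.5, resp) == pytest.approx(1.0 - 0.5 / 2.0)


def _bulk_dataset_from_variant8(p1=0.42, p4=0.25, q1=0.9, n=16, noise=0.0, seed=0):
    """Tiny bulk-density dataset generated from a variant-8 packing truth."""
    rng = np.random.default_rng(seed)
    c = np.linspace(0.05, 1.9, n)
    t = np.linspace(12.0, 29.0, n)[rng.permutation(n)]
    X, Y = c / (2.0 - c), t / (60.0 - t)
    phi = eval_rational(8, RationalParams(p1=p1, p4=p4, q1=q1), X, Y)
    rho_t = 1.5
    resp = phi * rho_t * 1e3
    if noise:
        resp = resp * (1.0 + noise * rng.standard_normal(n))
    pred = pd.DataFrame(
        {"concentration_pct": c, "mixing_time_min": t, "true_density_gcc": rho_t}
    )
    return StageDataset("bulk_density", pred, resp, x_max=2.0)


class TestLowerProblem:
    def test_variant8_parameter_recovery(self):
        """Noise-free data from a variant-8 truth is recovered to < 1%."""
        truth = dict(p1=0.42, p4=0.25, q1=0.9)
        ds = _bulk_dataset_from_variant8(**truth)
        fit = fit_combination(ds, ModelCombination("bulk_density", (8,)), seed=3, n_starts=8)
        sst = float(np.sum((ds.response - ds.response.mean()) ** 2))
        assert fit.sse / sst < 1e-10
        for name, want in truth.items():
            assert fit.theta[f"phi.{name}"] == pytest.approx(want, rel=1e-2)

    def test_aic_recomputable_from_stored_fields(self):
        ds = _bulk_dataset_from_variant8(noise=0.02, seed=1)
        fit = fit_combination(ds, ModelCombination("bulk_density", (8,)), seed=3, n_starts=4)
        assert fit.aic == aic(fit.sse, fit.n_data, fit.n_params)

    def test_seeded_determinism(self):
        ds = _bulk_dataset_from_variant8(noise=0.02, seed=1)
        combo = ModelCombination("bulk_density", (7,))
        f1 = fit_combination(ds, combo, seed=11, n_starts=6)
        f2 = fit_combination(ds, combo, seed=11, n_starts=6)
        assert f1.sse == f2.sse
        assert f1.theta == f2.theta

    def test_too_few_runs_rejected(self):
        ds = _bulk_dataset_from_variant8(n=4)
        with pytest.raises(ValueError):
            fit_combination(ds, ModelCombination("bulk_density", (1,)), seed=0)

    def test_infeasible_staged_bound_rejected(self):
        ds = _bulk_dataset_from_variant8()
        with pytest.raises(ValueError):
            fit_combination(
                ds, ModelCombination("bulk_density", (8,)),
                StageConstraints(lower_bounds={"phi": 1.5}), seed=0,
            )


class TestSelection:
    def test_constant_response_selects_constant_variant(self):
        ds = _bulk_dataset_from_variant8(p1=0.3 * 0.9, p4=0.3, q1=0.9)  # f == 0.3
        ranked = select_model(ds, seed=0, n_starts=4)
        assert ranked[0].label == "(9)"
        assert ranked[0].theta["phi.p4"] == pytest.approx(0.3, rel=1e-6)

    def test_ranking_ascending_and_nesting_dominance(self):
        ds = _bulk_dataset_from_variant8(noise=0.02, seed=7)
        ranked = select_model(ds, seed=0, n_starts=6)
        by_label = {f.label: f for f in ranked}
        # more general first-degree variants never fit worse (warm-started)
        tol = 1e-8 * max(f.sse for f in ranked)
        assert by_label["(7)"].sse <= by_label["(8)"].sse + tol
        assert by_label["(5)"].sse <= by_label["(7)"].sse + tol
        assert by_label["(3)"].sse <= by_label["(7)"].sse + tol
        assert by_label["(1)"].sse <= by_label["(3)"].sse + tol
        assert by_label["(1)"].sse <= by_label["(9)"].sse + tol

    def test_weight_stage_linear_selection(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0.9, 2.5, 24)
        f = rng.uniform(0.9, 1.6, 24)
        eta = 0.076 * s + 1.281 * f - 0.533 * f**2  # xi1 = xi5 = 0 truth
        pred = pd.DataFrame({"speed_ratio": s, "fill_ratio": f})
        ds = StageDataset("weight", pred, eta, x_max=2.0)
        ranked = select_model(ds, seed=0)
        assert ranked[0].label == "second_order_xi1=xi5=0"
        assert ranked[0].theta["xi3"] == pytest.approx(1.281, rel=1e-6)
        # ordered by the floored selection score; ties resolved to fewer params
        assert [f.aic_ranked for f in ranked] == sorted(f.aic_ranked for f in ranked)


class TestOverfitFlag:
    def _fit(self, theta):
        return FitResult(
            stage="tensile_strength", label="(3,3)", theta=theta, sse=1.0, r2=0.9,
            n_params=4, aic=0.0, n_data=30, seed=0,
        )

    def test_moderate_parameters_not_flagged(self):
        assert not overfit_flag(self._fit({"sigma0.p4": 9.4, "sigma0.p1": 335.0,
                                           "sigma0.q1": 125.1}))

    def test_huge_parameter_flagged(self):
        assert overfit_flag(self._fit({"sigma0.p4": 9.4, "sigma0.p1": 1e6 * 9.4}))


class TestStagePredict:
    def test_cs_tensile_reduces_to_sigma0_at_zero_porosity(self, cs_truth):
        """With no glidant the strength at full density is the printed sigma0."""
        combo = cs_truth.combination("tensile_strength")
        theta = cs_truth.theta("tensile_strength")
        pred = pd.DataFrame(
            {"concentration_pct": [0.0], "mixing_time_min": [20.0], "rho_tablet": [1.0]}
        )
        out = stage_predict("tensile_strength", combo, theta, pred, x_max=cs_truth.c_max)
        assert out[0] == pytest.approx(10.7)

    def test_constant_bulk_model_ignores_mixing(self):
        combo = ModelCombination("bulk_density", (9,))
        theta = {"phi.p4": 0.3}
        pred = pd.DataFrame(
            {"concentration_pct": [0.0, 1.0], "mixing_time_min": [11.0, 29.0],
             "true_density_gcc": [1.5, 1.5]}
        )
        out = stage_predict("bulk_density", combo, theta, pred, x_max=2.0)
        assert out[0] == out[1] == pytest.approx(450.0)

    def test_compaction_prediction_matches_rom_oracle(self, cs_truth, cs_runs_clean, geom):
        from tabrom import rom_core

        ds = build_stage_dataset(cs_runs_clean, "compaction", geom, cs_truth.c_max)
        theta = cs_truth.theta("compaction")
        out = stage_predict("compaction", cs_truth.combination("compaction"), theta,
                            ds.predictors, cs_truth.c_max, geom=geom)
        oracle = rom_core.kawakita_force(
            ds.predictors["rho_in_die"].to_numpy(), 0.824, 0.0104, 0.1977, 8.0
        )
        np.testing.assert_allclose(out, oracle, rtol=1e-12)


class TestCompiledResiduals:
    """The optimizer's fast residual closure must match the reference path."""

    @pytest.mark.parametrize(
        "stage,ids,extras",
        [
            ("bulk_density", (13,), ()),
            ("compaction", (9, 3, 3), ()),
            ("elastic_recovery", (6, 9), ("n_exp",)),
            ("tensile_strength", (3, 3), ()),
        ],
    )
    def test_matches_stage_predict_and_penalties(self, mgst_runs_clean, geom,
                                                 stage, ids, extras):
        from tabrom.selection import (
            _compiled_residuals,
            _layout,
            _penalties,
            _theta_from_internal,
        )

        combo = ModelCombination(stage, ids, extra_params=extras)
        ds = build_stage_dataset(mgst_runs_clean, stage, geom, 2.0)
        constraints = StageConstraints(lower_bounds={"rho_c_eps": 0.1, "rho_c_sigma": 0.2})
        specs = _layout(combo, constraints)
        fast = _compiled_residuals(ds, combo, constraints, specs, pen_w=100.0)
        rng = np.random.default_rng(0)
        lo = np.array([s.lo for s in specs])
        hi = np.array([s.hi for s in specs])
        for _ in range(25):
            z = lo + rng.random(len(specs)) * (hi - lo)
            theta = _theta_from_internal(z, specs, combo)
            ref = stage_predict(stage, combo, theta, ds.predictors, ds.x_max,
                                ds.y_max, ds.geom, strict=False) - ds.response
            pens = _penalties(combo, theta, ds, constraints, 100.0)
            expected = np.concatenate([ref, pens]) if pens else ref
            np.testing.assert_allclose(fast(z), expected, rtol=1e-12, atol=1e-12)


class TestBootstrap:
    def test_intervals_cover_point_estimate_and_reproduce(self):
        ds = _bulk_dataset_from_variant8(noise=0.01, seed=4)
        combo = ModelCombination("bulk_density", (8,))
        fit = fit_combination(ds, combo, seed=1, n_starts=6)
        ci1 = bootstrap_ci(ds, fit, B=12, seed=9, n_starts=1)
        ci2 = bootstrap_ci(ds, fit, B=12, seed=9, n_starts=1)
        assert ci1 == ci2
        lo, hi = ci1["phi.p4"]
        assert lo <= fit.theta["phi.p4"] * 1.02 and hi >= fit.theta["phi.p4"] * 0.98

    def test_interval_width_shrinks_with_noise(self):
        combo = ModelCombination("bulk_density", (8,))
        widths = []
        for noise in (0.0, 0.05):
            ds = _bulk_dataset_from_variant8(noise=noise, seed=4)
            fit = fit_combination(ds, combo, seed=1, n_starts=6)
            lo, hi = bootstrap_ci(ds, fit, B=10, seed=9, n_starts=1)["phi.p4"]
            widths.append(hi - lo)
        assert widths[0] < widths[1]
        assert widths[0] == pytest.approx(0.0, abs=1e-6)

    def test_invalid_b(self):
        ds = _bulk_dataset_from_variant8()
        fit = fit_combination(ds, ModelCombination("bulk_density", (9,)), seed=0, n_starts=2)
        with pytest.raises(ValueError):
            bootstrap_ci(ds, fit, B=0, seed=1)
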