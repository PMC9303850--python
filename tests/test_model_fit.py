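"""Tests for the grid-search fit, D search, bootstrap and model comparison."""

import numpy as np
import pandas as pd
import pytest

from collectivegame.empirical_scale import model_to_empirical
from collectivegame.game_core import (
    ErrorModel,
    GameParams,
    GroupComposition,
    expected_investment_with_error,
    optimal_investment,
)
from collectivegame.io import investment_summary
from collectivegame.model_fit import (
    FitConfig,
    FitResult,
    bootstrap_ci,
    fit_D,
    goodness_of_fit,
    grid_search_fit,
    model_compare_F,
    predict_for_compositions,
)
from collectivegame.synthetic_data import (
    SimulationSpec,
    design_nstrain,
    design_three_strain,
    simulate_assay,
)

SMALL = dict(b_grid=[8.0, 12.0, 14.0], c_grid=[1.0, 1.3, 1.6],
             e_grid=[0.0, 0.2, 0.5], t_grid=[0.25, 0.5, 1.0])


def small_config(**kw):
    return FitConfig(**{**SMALL, "prediction_scale": "exact", **kw})


@pytest.fixture(scope="module")
def nstrain_noiseless():
    spec = SimulationSpec(params=GameParams(12.0, 1.0, 0.15),
                          error=ErrorModel(0.2, 0.5), with_transdiff=True,
                          noise_cv=0.0, clonal_strain_cv=0.0,
                          replicates_per_composition=1, seed=11)
    return investment_summary(simulate_assay(design_nstrain(), spec))


class TestGridSearch:
    def test_objective_matches_independent_brute_force(self,
                                                       noiseless_three_strain_data):
        """The vectorised engine must agree with a plain per-point loop
        built directly on the quadrature primitive."""
        data = noiseless_three_strain_data.head(12)
        cfg = small_config()
        fit = grid_search_fit(data, cfg)
        comps = list(data["composition"])
        obs = data["observed_S"].to_numpy()
        best = (np.inf, None)
        for b in cfg.b_grid:
            for c in cfg.c_grid:
                p = GameParams(b, c)
                th = p.theta()
                for e in cfg.e_grid:
                    for t in cfg.t_grid:
                        err = ErrorModel(e, t)
                        pred = np.array([
                            model_to_empirical(
                                sum(r * expected_investment_with_error(
                                    r, p, err,
                                    lambda rho: optimal_investment(rho, p))
                                    for r in comp.frequencies) / th,
                                th, exact=True)
                            for comp in comps])
                        rss = float(((obs - pred) ** 2).sum())
                        if rss < best[0]:
                            best = (rss, (b, c, e, t))
        assert (fit.params.b, fit.params.c, fit.error.e, fit.error.t) == best[1]
        assert fit.rss == pytest.approx(best[0], rel=1e-6, abs=1e-12)

    def test_noiseless_data_recovers_generating_grid_point(
            self, noiseless_three_strain_data):
        fit = grid_search_fit(noiseless_three_strain_data, small_config())
        assert (fit.params.b, fit.params.c) == (12.0, 1.0)
        assert (fit.error.e, fit.error.t) == (0.2, 0.5)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_large_error_flattens_predictions_and_wins_on_flat_data(self):
        # with frequency-independent noise the perceived relatedness loses
        # its dependence on the true value as e grows, so the predicted
        # response across compositions flattens toward a constant; flat
        # observations at that constant are then best fit by the largest e
        comps = design_three_strain(["a", "b", "c"])[:15]
        p = GameParams(12.0, 1.0)
        spread = []
        for e in (0.0, 1.0, 3.0):
            pred = predict_for_compositions(comps, p, ErrorModel(e, 0.0),
                                            scale="exact")
            spread.append(float(pred.max() - pred.min()))
        assert spread[0] > spread[1] > spread[2]

        obs = float(np.mean(predict_for_compositions(comps, p,
                                                     ErrorModel(1.0, 0.0),
                                                     scale="exact")))
        data = pd.DataFrame({"composition": comps, "observed_S": obs})
        cfg = small_config(b_grid=[12.0], c_grid=[1.0],
                           e_grid=[0.0, 0.5, 1.0], t_grid=[0.0])
        fit = grid_search_fit(data, cfg)
        assert fit.error.e == 1.0

    def test_requires_distinct_compositions(self):
        comp = GroupComposition([("a", 0.5), ("b", 0.5)])
        data = pd.DataFrame({"composition": [comp, comp],
                             "observed_S": [0.8, 0.9]})
        with pytest.raises(ValueError, match="distinct"):
            grid_search_fit(data, small_config())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            FitConfig(b_grid=[])


class TestFitD:
    def test_recovers_generating_D(self, nstrain_noiseless):
        fit = fit_D(nstrain_noiseless, GameParams(12.0, 1.0),
                    ErrorModel(0.2, 0.5), small_config())
        assert fit.params.D == pytest.approx(0.15)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_no_enforcement_recovered_as_zero(self):
        spec = SimulationSpec(params=GameParams(12.0, 1.0, 0.0),
                              error=ErrorModel(0.2, 0.5), with_transdiff=True,
                              noise_cv=0.0, clonal_strain_cv=0.0,
                              replicates_per_composition=1, seed=3)
        data = investment_summary(simulate_assay(design_nstrain(), spec))
        fit = fit_D(data, GameParams(12.0, 1.0), ErrorModel(0.2, 0.5),
                    small_config())
        assert fit.params.D == 0.0

    def test_free_D_never_fits_worse_than_D_zero(self, nstrain_noiseless):
        data = nstrain_noiseless.copy()
        rng = np.random.default_rng(5)
        data["observed_S"] = data["observed_S"] * (1 + 0.05 * rng.normal(
            size=len(data)))
        cfg = small_config()
        free = fit_D(data, GameParams(12.0, 1.0), ErrorModel(0.2, 0.5), cfg)
        cfg0 = small_config(D_grid=[0.0])
        fixed = fit_D(data, GameParams(12.0, 1.0), ErrorModel(0.2, 0.5), cfg0)
        assert free.rss <= fixed.rss + 1e-12
        g_free = goodness_of_fit(free.predictions["observed_S"],
                                 free.predictions["predicted"])
        g_fixed = goodness_of_fit(fixed.predictions["observed_S"],
                                  fixed.predictions["predicted"])
        assert g_free["r_squared"] >= g_fixed["r_squared"]


class TestBootstrap:
    def test_zero_se_gives_zero_width_intervals(self, nstrain_noiseless):
        data = nstrain_noiseless.assign(se_S=0.0)
        res = bootstrap_ci(data, small_config(bootstrap_iterations=25),
                           fixed_params=GameParams(12.0, 1.0),
                           fixed_error=ErrorModel(0.2, 0.5))
        lo, hi = res.ci["D"]
        assert lo == hi == res.point.params.D

    def test_fixed_seed_is_bit_identical(self, nstrain_noiseless):
        data = nstrain_noiseless.assign(se_S=0.02)
        kw = dict(fixed_params=GameParams(12.0, 1.0),
                  fixed_error=ErrorModel(0.2, 0.5))
        a = bootstrap_ci(data, small_config(bootstrap_iterations=25, seed=9), **kw)
        b = bootstrap_ci(data, small_config(bootstrap_iterations=25, seed=9), **kw)
        assert a.ci == b.ci
        pd.testing.assert_frame_equal(a.deviations, b.deviations)

    def test_ci_contains_point_and_truth_under_noise(self, nstrain_noiseless):
        data = nstrain_noiseless.assign(se_S=0.01)
        res = bootstrap_ci(data, small_config(bootstrap_iterations=40, seed=2),
                           fixed_params=GameParams(12.0, 1.0),
                           fixed_error=ErrorModel(0.2, 0.5))
        lo, hi = res.ci["D"]
        assert lo <= res.point.params.D <= hi
        assert lo <= 0.15 <= hi

    def test_few_iterations_warn(self, nstrain_noiseless):
        data = nstrain_noiseless.assign(se_S=0.0)
        with pytest.warns(UserWarning, match="percentiles"):
            bootstrap_ci(data, small_config(bootstrap_iterations=5),
                         fixed_params=GameParams(12.0, 1.0),
                         fixed_error=ErrorModel(0.2, 0.5))


def _fake_fit(rss):
    return FitResult(params=GameParams(12.0, 1.0), error=ErrorModel(),
                     rss=rss, predictions=pd.DataFrame())


class TestModelCompareF:
    def test_identical_fits(self):
        res = model_compare_F(_fake_fit(1.0), _fake_fit(1.0), n=60)
        assert res.F == 0.0
        assert res.p == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        res = model_compare_F(_fake_fit(2.0), _fake_fit(1.0), n=60)
        assert res.F == pytest.approx((1.0 / 2) / (1.0 / 56))

    def test_perfect_full_fit_flagged(self):
        res = model_compare_F(_fake_fit(1.0), _fake_fit(0.0), n=60)
        assert np.isinf(res.F) and res.perfect_fit

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError, match="n >"):
            model_compare_F(_fake_fit(1.0), _fake_fit(0.5), n=4)

    def test_error_model_detected_on_noisy_strategy_data(self):
        """When data are generated with substantial perception error the
        imperfect-information model should win the F test."""
        spec = SimulationSpec(params=GameParams(12.0, 1.0),
                              error=ErrorModel(0.5, 0.5), noise_cv=0.03,
                              clonal_strain_cv=0.0,
                              replicates_per_composition=5, seed=21)
        data = investment_summary(
            simulate_assay(design_three_strain(["a", "b", "c"]), spec))
        full = grid_search_fit(data, small_config())
        restricted = grid_search_fit(
            data, small_config(e_grid=[0.0], t_grid=[0.0]))
        res = model_compare_F(restricted, full, n=len(data))
        assert res.p < 0.05


class TestGoodnessOfFit:
    def test_perfect_agreement(self):
        g = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert g["r_squared"] == pytest.approx(1.0)
        assert g["pearson_r"] == pytest.approx(1.0)
        assert g["paired_t"] == 0.0

    def test_anticorrelated_pairs(self):
        g = goodness_of_fit([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert g["pearson_r"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_prediction_helper_matches_direct_quadrature(params):
    comps = [GroupComposition([("a", 0.2), ("b", 0.3), ("c", 0.5)]),
             GroupComposition.equal(4)]
    err = ErrorModel(0.3, 1.0)
    got = predict_for_compositions(comps, params, err, scale="eq6")
    th = params.theta()
    for comp, val in zip(comps, got):
        x = sum(r * expected_investment_with_error(r, params, err)
                for r in comp.frequencies)
        assert val == pytest.approx(model_to_empirical(x / th, th))
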