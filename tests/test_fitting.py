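"""Data preparation, probit-scale fits, rate-line and auxiliary regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import germthresh as gt
from germthresh.fitting import NonIdentifiableError

from conftest import (
    ATT_ONE_PHASE,
    ATT_TWO_PHASE_HIGH,
    ATT_TWO_PHASE_LOW,
    MLT_PUBLISHED,
    MTT_PUBLISHED,
    THETA_A_BY_TEMP,
    TT_PUBLISHED,
)


def relerr(a, b):
    return abs(a - b) / abs(b)


def make_obs(rows):
    """rows: (T, p, t, rep, sown, germ)"""
    return pd.DataFrame(rows, columns=["temperature_C", "storage_days", "time_h",
                                       "replicate", "n_sown", "n_germ_cum"])


class TestPercentileTimes:
    def test_midpoint_interpolation(self):
        out = gt.percentile_times([10, 20], [40, 60], targets=(50,))
        assert out[50] == pytest.approx(15.0)

    def test_unreachable_target_missing(self):
        out = gt.percentile_times([10, 20], [30, 45], targets=(50,))
        assert np.isnan(out[50])

    def test_first_attainment_tie_break(self):
        # brute-force scan of the step curve: 30% is first reached at t=10
        out = gt.percentile_times([10, 20, 30], [30, 30, 60], targets=(30,))
        assert out[30] == pytest.approx(10.0)

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            gt.percentile_times([], [], targets=(50,))

    def test_table_long_format(self):
        obs = make_obs([(20, 0, 10, "R1", 50, 20), (20, 0, 20, "R1", 50, 30),
                        (20, 0, 30, "R1", 50, 40)])
        table = gt.percentile_times_table(obs, targets=(10, 50, 70))
        got = dict(zip(table["percent"], table["time_h"]))
        assert got[50] == pytest.approx(15.0)
        assert got[10] == pytest.approx(2.5)  # interpolated from the (0,0) origin
        assert got[70] == pytest.approx(25.0)  # between 60% at t=20 and 80% at t=30
        assert len(table) == 3


class TestCensoring:
    def test_final_five_percent_removed(self):
        obs = make_obs([(20, 0, t, "R1", 50, g) for t, g in
                        [(1, 37), (2, 38), (3, 40)]])  # 74%, 76%, 80%
        kept = gt.censor_final_five_percent(obs)
        assert kept["n_germ_cum"].tolist() == [37]

    def test_full_plateau_and_unity_fraction_removed(self):
        obs = make_obs([(20, 0, 1, "R1", 50, 25), (20, 0, 2, "R1", 50, 48),
                        (20, 0, 3, "R1", 50, 50)])  # 50%, 96%, 100%
        kept = gt.censor_final_five_percent(obs)
        assert kept["n_germ_cum"].tolist() == [25]

    def test_single_point_group_may_empty(self):
        obs = make_obs([(20, 0, 1, "R1", 50, 30)])
        assert gt.censor_final_five_percent(obs).empty

    def test_never_removes_below_half_plateau(self):
        # plateau 8%: the 5-point rule alone would cut to 3%, below half
        obs = make_obs([(5, 65, t, "R1", 100, g) for t, g in
                        [(1, 3), (2, 5), (3, 8)]])
        kept = gt.censor_final_five_percent(obs)
        assert 3 in kept["n_germ_cum"].tolist()
        pct = 100 * kept["n_germ_cum"] / kept["n_sown"]
        assert (pct >= 4.0 - 1e-9).all() | (pct <= 4.0 + 1e-9).all()

    def test_drop_repeated_counts(self):
        obs = make_obs([(20, 0, t, "R1", 50, g) for t, g in
                        [(1, 5), (2, 5), (3, 9), (4, 9), (5, 9)]])
        kept = gt.drop_repeated_counts(obs)
        assert kept["time_h"].tolist() == [1, 3]


class TestNormalizeMaxGermination:
    def test_plateau_half_doubles(self):
        obs = make_obs([(5, 0, 1, "R1", 50, 10), (5, 0, 2, "R1", 50, 25)])
        out = gt.normalize_max_germination(obs)
        assert out["n_germ_cum"].tolist() == [20.0, 50.0]

    def test_plateau_one_unchanged(self):
        obs = make_obs([(20, 0, 1, "R1", 50, 25), (20, 0, 2, "R1", 50, 50)])
        out = gt.normalize_max_germination(obs)
        assert out["n_germ_cum"].tolist() == [25.0, 50.0]

    def test_refit_after_rescaling_succeeds_and_differs(self):
        # low-temperature data rescaled to full germination changes the
        # fitted lifetime spread
        grid = gt.noiseless_grid(MLT_PUBLISHED[5],
                                 gt.SimulationDesign(temperatures=(5.0,),
                                                     recording_interval=4.0,
                                                     max_duration=960.0))
        raw = gt.fit_mlt(gt.regression_points(grid))
        scaled = gt.fit_mlt(gt.regression_points(gt.normalize_max_germination(grid)))
        assert raw.converged and scaled.converged
        assert abs(scaled.params.sigma_pmax - raw.params.sigma_pmax) > 0.1


class TestGoodness:
    def test_perfect_prediction(self):
        y = np.array([0.1, -0.5, 1.2, 0.7, -0.2])
        g = gt.goodness(y, y, k_params=2)
        assert g["rmse"] == 0.0
        assert g["adjusted_r2"] == 1.0

    def test_single_treatment_reduces_to_plain_rmse(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        x = y + 0.5
        with_groups = gt.goodness(y, x, 1, groups=["a"] * 4)
        assert with_groups["rmse"] == pytest.approx(0.5)

    def test_duplicating_treatments_leaves_rmse_unchanged(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.array([0.2, 0.9, 2.2, 2.8])
        g1 = gt.goodness(y, x, 1, groups=["a", "a", "b", "b"])
        g2 = gt.goodness(np.tile(y, 2), np.tile(x, 2), 1,
                         groups=["a", "a", "b", "b"] * 2)
        assert g2["rmse"] == pytest.approx(g1["rmse"])

    def test_order_invariance(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.array([0.2, 0.9, 2.2, 2.8])
        groups = ["a", "b", "a", "b"]
        perm = [3, 1, 0, 2]
        g1 = gt.goodness(y, x, 1, groups=groups)
        g2 = gt.goodness(y[perm], x[perm], 1, groups=[groups[i] for i in perm])
        assert g2["rmse"] == pytest.approx(g1["rmse"])

    def test_aic_penalizes_extra_parameters_at_equal_rss(self):
        y = np.arange(10.0)
        x = y + 0.3
        g_small = gt.goodness(y, x, 2)
        g_big = gt.goodness(y, x, 5)
        assert g_big["aic"] > g_small["aic"]

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            gt.goodness([1.0, 2.0], [1.0, 2.0], k_params=1)


class TestNoiselessRecovery:
    """Fitting exact model-generated curves returns the generating constants."""

    def test_tt(self, control_design):
        grid = gt.noiseless_grid(TT_PUBLISHED, control_design)
        fit = gt.fit_tt(gt.regression_points(grid))
        assert relerr(fit.params.theta_T50, 253.7) < 1e-3
        assert relerr(fit.params.T_b, 3.9) < 1e-3
        assert relerr(fit.params.sigma_lnTheta, 0.79) < 1e-3
        assert fit.r2 > 1 - 1e-9

    def test_mtt(self, control_design):
        grid = gt.noiseless_grid(MTT_PUBLISHED, control_design)
        low, high = gt.fit_mtt(gt.regression_points(grid))
        assert relerr(low.params.theta_Tm, 383.9) < 1e-3
        assert relerr(low.params.T_m50, 4.4) < 1e-3
        assert relerr(low.params.sigma_Tm, 3.79) < 1e-3
        assert relerr(high.params.theta_T50, 149.1) < 1e-3
        assert relerr(high.params.T_b, 9.5) < 1e-3
        assert relerr(high.params.sigma_lnTheta, 0.56) < 1e-3

    def test_mlt(self):
        grid = gt.noiseless_grid(MLT_PUBLISHED[15],
                                 gt.SimulationDesign(temperatures=(15.0,),
                                                     recording_interval=2.0))
        fit = gt.fit_mlt(gt.regression_points(grid))
        assert relerr(fit.params.p_max50, 32.88) < 1e-3
        assert relerr(fit.params.sigma_pmax, 19.30) < 1e-3
        assert relerr(fit.params.theta_A, 966.18) < 1e-3

    def test_att_one_phase(self, full_design):
        grid = gt.noiseless_grid(ATT_ONE_PHASE, full_design)
        fit = gt.fit_att_one_phase(gt.regression_points(grid))
        assert relerr(fit.params.p_max50, 25.53) < 1e-3
        assert relerr(fit.params.sigma_pmax, 21.58) < 1e-3
        assert relerr(fit.params.theta_AT, 6261.0) < 1e-3
        assert relerr(fit.params.T_b, 3.99) < 1e-3

    def test_att_two_phase(self):
        gl = gt.noiseless_grid(ATT_TWO_PHASE_LOW,
                               gt.SimulationDesign(temperatures=(5.0, 10.0),
                                                   recording_interval=2.0))
        gh = gt.noiseless_grid(ATT_TWO_PHASE_HIGH,
                               gt.SimulationDesign(temperatures=(15.0, 20.0, 25.0, 30.0),
                                                   recording_interval=2.0))
        low, high = gt.fit_att_two_phase(
            gt.regression_points(pd.concat([gl, gh], ignore_index=True)))
        ext = low.params.low_range_extension
        assert relerr(high.params.theta_AT, 4158.0) < 1e-2
        assert relerr(high.params.T_b, 10.26) < 1e-2
        assert relerr(low.params.theta_AT, 18114.0) < 1e-2
        assert relerr(low.params.T_b, 1.49) < 1e-2
        assert relerr(ext.k, 1.41) < 1e-2
        assert relerr(ext.T_i, 12.06) < 1e-2
        assert relerr(ext.p_maxi50, 30.79) < 1e-2
        assert relerr(low.params.sigma_pmax, 22.5) < 1e-2

    def test_pooling_invariance_on_identical_lots(self, control_design):
        grid = gt.noiseless_grid(TT_PUBLISHED, control_design)
        twin = grid.assign(replicate="expected2")
        doubled = pd.concat([grid, twin], ignore_index=True)
        f1 = gt.fit_tt(gt.regression_points(grid))
        f2 = gt.fit_tt(gt.regression_points(doubled))
        assert f2.params.theta_T50 == pytest.approx(f1.params.theta_T50, rel=1e-9)
        assert f2.params.T_b == pytest.approx(f1.params.T_b, abs=1e-7)


class TestStochasticRecovery:
    """Binomial lots of 50 seeds x 3 replicates, fixed generator seed."""

    def test_mlt_binomial(self):
        lot = gt.simulate_lot(MLT_PUBLISHED[15],
                              gt.SimulationDesign(temperatures=(15.0,), rng_seed=1))
        fit = gt.fit_mlt(gt.regression_points(lot))
        assert relerr(fit.params.p_max50, 32.88) < 0.10
        assert relerr(fit.params.sigma_pmax, 19.30) < 0.10
        assert relerr(fit.params.theta_A, 966.18) < 0.10

    def test_att_one_phase_binomial(self):
        lot = gt.simulate_lot(ATT_ONE_PHASE, gt.SimulationDesign(rng_seed=1))
        fit = gt.fit_att_one_phase(gt.regression_points(lot))
        assert relerr(fit.params.p_max50, 25.53) < 0.10
        assert relerr(fit.params.sigma_pmax, 21.58) < 0.10
        assert relerr(fit.params.theta_AT, 6261.0) < 0.10
        assert relerr(fit.params.T_b, 3.99) < 0.10


class TestNonIdentifiability:
    def test_tt_single_temperature(self, control_design):
        grid = gt.noiseless_grid(TT_PUBLISHED,
                                 gt.SimulationDesign(temperatures=(20.0,),
                                                     storage_days=(0.0,),
                                                     recording_interval=2.0))
        with pytest.raises(NonIdentifiableError):
            gt.fit_tt(gt.regression_points(grid))

    def test_mtt_low_single_temperature(self):
        grid = gt.noiseless_grid(MTT_PUBLISHED,
                                 gt.SimulationDesign(temperatures=(5.0, 20.0, 25.0),
                                                     storage_days=(0.0,),
                                                     recording_interval=2.0))
        with pytest.raises(NonIdentifiableError):
            gt.fit_mtt(gt.regression_points(grid))

    def test_mlt_storage_all_zero(self):
        grid = gt.noiseless_grid(MLT_PUBLISHED[15],
                                 gt.SimulationDesign(temperatures=(15.0,),
                                                     storage_days=(0.0,),
                                                     recording_interval=2.0))
        with pytest.raises(NonIdentifiableError):
            gt.fit_mlt(gt.regression_points(grid))

    def test_att_single_temperature(self):
        grid = gt.noiseless_grid(ATT_ONE_PHASE,
                                 gt.SimulationDesign(temperatures=(20.0,),
                                                     recording_interval=2.0))
        with pytest.raises(NonIdentifiableError):
            gt.fit_att_one_phase(gt.regression_points(grid))

    def test_att_two_phase_single_low_storage(self):
        gl = gt.noiseless_grid(ATT_TWO_PHASE_LOW,
                               gt.SimulationDesign(temperatures=(5.0, 10.0),
                                                   storage_days=(0.0,),
                                                   recording_interval=2.0))
        gh = gt.noiseless_grid(ATT_TWO_PHASE_HIGH,
                               gt.SimulationDesign(temperatures=(15.0, 25.0),
                                                   recording_interval=2.0))
        with pytest.raises(NonIdentifiableError):
            gt.fit_att_two_phase(
                gt.regression_points(pd.concat([gl, gh], ignore_index=True)))

    def test_att_two_phase_k_zero_reduces_to_one_phase(self):
        gl = gt.noiseless_grid(ATT_ONE_PHASE,
                               gt.SimulationDesign(temperatures=(5.0, 10.0),
                                                   recording_interval=2.0))
        gh = gt.noiseless_grid(ATT_ONE_PHASE,
                               gt.SimulationDesign(temperatures=(15.0, 25.0),
                                                   recording_interval=2.0))
        all_obs = gt.regression_points(pd.concat([gl, gh], ignore_index=True))
        low_fixed, _ = gt.fit_att_two_phase(all_obs, fix_k=0.0)
        low_alone = gt.fit_att_one_phase(
            all_obs[all_obs["temperature_C"] <= 12.5])
        assert low_fixed.params.theta_AT == pytest.approx(
            low_alone.params.theta_AT, rel=1e-12)
        assert low_fixed.params.low_range_extension.k == 0.0


class TestRateLines:
    def test_common_base_recovers_tt(self):
        # exact rates from the TT model at four percentiles
        rows = []
        for g in (0.1, 0.3, 0.5, 0.7):
            for T in (10.0, 15.0, 20.0, 25.0, 30.0):
                rows.append({"temperature_C": T, "storage_days": 0.0,
                             "replicate": "R1", "percent": int(g * 100),
                             "time_h": gt.time_to_percentile(TT_PUBLISHED, g, T=T)})
        fit = gt.fit_gr_lines(pd.DataFrame(rows), mode="common_base")
        assert fit.shared == pytest.approx(3.9, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        # slope of percentile g is 1/theta_T(g)
        assert fit.slopes[50] == pytest.approx(1 / 253.7, rel=1e-6)

    def test_common_slope_recovers_mtt_low(self):
        low = MTT_PUBLISHED.low
        rows = []
        for g in (0.1, 0.3, 0.5):
            for T in (5.0, 8.0, 10.0):
                rows.append({"temperature_C": T, "storage_days": 0.0,
                             "replicate": "R1", "percent": int(g * 100),
                             "time_h": gt.time_to_percentile(low, g, T=T)})
        fit = gt.fit_gr_lines(pd.DataFrame(rows), mode="common_slope")
        assert fit.shared == pytest.approx(1 / 383.9, rel=1e-9)
        # intercepts are the percentile minimum temperatures T_m(g)
        assert fit.intercepts[50] == pytest.approx(4.4, abs=1e-9)
        assert fit.intercepts[10] == pytest.approx(4.4 + 3.79 * gt.probit(0.1), abs=1e-9)

    def test_single_percentile_plain_regression(self):
        rows = [{"temperature_C": T, "storage_days": 0.0, "replicate": "R1",
                 "percent": 50, "time_h": gt.time_to_percentile(TT_PUBLISHED, 0.5, T=T)}
                for T in (15.0, 20.0, 25.0)]
        fit = gt.fit_gr_lines(pd.DataFrame(rows), mode="common_base")
        assert fit.shared == pytest.approx(3.9, abs=1e-6)


class TestInvThetaARegression:
    temps = sorted(THETA_A_BY_TEMP)
    theta = [THETA_A_BY_TEMP[T] for T in temps]

    def test_one_line_r2(self):
        out = gt.regress_inv_thetaA(self.temps, self.theta, form="one_line")
        assert round(out["r2"], 3) == pytest.approx(0.926, abs=0.001)

    def test_two_lines_pooled_r2(self):
        out = gt.regress_inv_thetaA(self.temps, self.theta, form="two_lines")
        assert round(out["r2"], 3) == pytest.approx(0.996, abs=0.001)

    def test_quadratic_r2(self):
        out = gt.regress_inv_thetaA(self.temps, self.theta, form="quadratic")
        assert out["r2"] == pytest.approx(0.998, abs=2e-3)

    def test_collinear_inputs_reproduce_generating_line(self):
        T = np.array([12.0, 18.0, 24.0, 30.0])
        theta_AT, T_b = 5000.0, 4.0
        theta_A = theta_AT / (T - T_b)
        out = gt.regress_inv_thetaA(T, theta_A, form="one_line")
        assert out["r2"] == pytest.approx(1.0, abs=1e-12)
        assert out["segments"][0]["theta_AT"] == pytest.approx(theta_AT, rel=1e-9)
        assert out["segments"][0]["T_b"] == pytest.approx(T_b, abs=1e-9)

    def test_two_points_one_line_errors(self):
        with pytest.raises(NonIdentifiableError):
            gt.regress_inv_thetaA([5.0, 10.0], [100.0, 50.0], form="one_line")


class TestViabilityFit:
    def test_noiseless_recovery(self):
        x = np.arange(0, 81, 5.0)
        y = norm.cdf((40.0 - x) / 15.0)
        fit = gt.fit_viability_normal(x, y)
        assert fit.mu == pytest.approx(40.0, abs=1e-6)
        assert fit.sigma == pytest.approx(15.0, abs=1e-6)

    def test_median_property(self):
        fit = gt.fit_viability_normal([0, 20, 40, 60, 80],
                                      norm.cdf((40.0 - np.array([0, 20, 40, 60, 80])) / 10))
        assert norm.cdf((fit.mu - fit.mu) / fit.sigma) == 0.5

    def test_increasing_viability_rejected(self):
        with pytest.raises(NonIdentifiableError):
            gt.fit_viability_normal([0, 10, 20, 30], [0.2, 0.4, 0.6, 0.8])

    def test_constant_viability_rejected(self):
        with pytest.raises(NonIdentifiableError):
            gt.fit_viability_normal([0, 10, 20], [0.5, 0.5, 0.5])
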