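"""Arrhenius fitting of chamber ramps and acclimation recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcticiso import (
    ChamberExperiment,
    c_sg,
    e_opt_sg,
    fit_acclimation,
    fit_arrhenius,
    gamma_t_sedge,
    history_correlation,
    q10,
    q10_from_steps,
)
from arcticiso import TemperatureHistory
from arcticiso.chamber import ArrheniusFit, read_chamber_csv
from arcticiso.params import GAS_CONSTANT_KJ

RAMP_C = np.array([15.0, 20.0, 25.0, 30.0, 35.0, 40.0])
RAMP_K = RAMP_C + 273.15


def make_exp(ea, ef30, temps_k=RAMP_K, noise=None, **kw):
    e = ef30 * np.exp(ea / GAS_CONSTANT_KJ * (1 / 303.15 - 1 / temps_k))
    if noise is not None:
        e = e * noise
    return ChamberExperiment("test", temps_k, e, **kw)


class TestFitArrhenius:
    @settings(deadline=None, max_examples=40)
    @given(ea=st.floats(20.0, 300.0), ef30=st.floats(0.1, 50.0))
    def test_exact_on_noise_free_data(self, ea, ef30):
        fit = fit_arrhenius(make_exp(ea, ef30))
        assert fit.ea == pytest.approx(ea, rel=1e-9)
        assert fit.ef30 == pytest.approx(ef30, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_point_closed_form_slope(self):
        exp = ChamberExperiment(
            "two", np.array([298.15, 308.15]), np.array([1.0, np.e])
        )
        expected = GAS_CONSTANT_KJ / (1 / 298.15 - 1 / 308.15)
        fit = fit_arrhenius(exp)
        assert fit.ea == pytest.approx(expected, rel=1e-12)
        assert fit.ea == pytest.approx(76.39, rel=1e-3)

    def test_upper_bound_excludes_hot_steps(self):
        fit = fit_arrhenius(make_exp(100.0, 5.0), t_max=308.15)
        assert fit.n_points == 5
        assert fit.n_excluded == 1
        assert fit.t_range == (288.15, 308.15)

    def test_nonpositive_step_dropped_with_warning(self):
        e = make_exp(100.0, 5.0).emissions.copy()
        e[0] = 0.0
        exp = ChamberExperiment("z", RAMP_K, e)
        with pytest.warns(RuntimeWarning, match="non-positive"):
            fit = fit_arrhenius(exp)
        assert fit.n_points == 4  # 40 °C excluded, 15 °C dropped

    def test_too_few_usable_steps_raises(self):
        exp = make_exp(100.0, 5.0, temps_k=np.array([310.15, 313.15]))
        with pytest.raises(ValueError, match="at least 2 usable"):
            fit_arrhenius(exp, t_max=308.15)


class TestQ10FromSteps:
    def test_plain_ratio(self):
        exp = ChamberExperiment(
            "r", np.array([298.15, 308.15]), np.array([1.0, 3.2])
        )
        assert q10_from_steps(exp) == pytest.approx(3.2)

    def test_flat(self):
        exp = ChamberExperiment(
            "f", np.array([298.15, 308.15]), np.array([2.0, 2.0])
        )
        assert q10_from_steps(exp) == pytest.approx(1.0)

    def test_matches_curve_q10_cross_module(self):
        t240 = 288.15
        curve = lambda T: float(
            gamma_t_sedge(TemperatureHistory(T, t240, t240))
        )
        exp = ChamberExperiment(
            "sedge", RAMP_K[:-1], np.array([curve(t) for t in RAMP_K[:-1]])
        )
        assert q10_from_steps(exp) == pytest.approx(q10(curve), rel=1e-12)
        # Closed form with C_sg(288.15) = 104.5 kJ mol⁻¹ over 25–35 °C.
        assert q10_from_steps(exp) == pytest.approx(3.928, rel=0.001)

    def test_missing_step_names_temperature(self):
        exp = ChamberExperiment(
            "m", np.array([288.15, 293.15]), np.array([1.0, 2.0])
        )
        with pytest.raises(ValueError, match="298.15"):
            q10_from_steps(exp)


def linear_history_fits(seed, n=20, ea_noise=0.5, lag=10):
    """Experiments whose Ea and EF30 are linear in the trailing lag-day mean."""
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n):
        days = rng.uniform(278.0, 291.0, 15) + rng.normal(0, 2, 15)
        m = days[:lag].mean()
        ea = 95.0 + 3.0 * (288.15 - m) + rng.normal(0, ea_noise)
        ef = 12.0 + 0.5 * (m - 288.15) + rng.normal(0, 0.05)
        fits.append(
            (ArrheniusFit(ea, max(ef, 0.01), 0.99, 5, (288.15, 308.15)), days)
        )
    return fits


class TestHistoryCorrelation:
    def test_exact_linear_dependence_selects_lag(self):
        fits = linear_history_fits(seed=0, ea_noise=0.0)
        tab = history_correlation(fits)
        assert tab.attrs["best_lag_ea"] == 10
        assert abs(tab.loc[10, "r_ea"]) > 0.9999
        assert tab.attrs["significant_ea"]

    def test_lag_selection_rate_over_replicates(self):
        hits = sum(
            history_correlation(linear_history_fits(seed)).attrs["best_lag_ea"]
            == 10
            for seed in range(200)
        )
        assert hits >= 0.95 * 200

    def test_null_responses_not_significant(self):
        rng = np.random.default_rng(7)
        fits = [
            (
                ArrheniusFit(rng.uniform(95, 300), rng.uniform(1, 20),
                             0.9, 5, (288.15, 308.15)),
                rng.uniform(278, 291, 15),
            )
            for _ in range(30)
        ]
        tab = history_correlation(fits)
        assert tab["r_ea"].abs().max() < 0.6
        assert not tab.attrs["significant_ea"]

    def test_requires_three_experiments(self):
        with pytest.raises(ValueError, match="at least 3"):
            history_correlation(linear_history_fits(0, n=2))

    def test_constant_response_reported_missing(self):
        fits = [
            (ArrheniusFit(100.0, 5.0, 0.9, 5, (288.15, 308.15)),
             np.full(15, 280.0 + i))
            for i in range(5)
        ]
        tab = history_correlation(fits)
        assert tab["r_ea"].isna().all()
        assert tab.attrs["best_lag_ea"] is None


class TestFitAcclimation:
    @staticmethod
    def pairs(t240s, noise_rng=None, sd=0.0):
        ea = np.asarray(c_sg(t240s))
        ef = 12.0 * np.asarray(e_opt_sg(t240s))
        if noise_rng is not None:
            ea = ea * noise_rng.lognormal(0, sd, len(ea))
            ef = ef * noise_rng.lognormal(0, sd, len(ef))
        return list(zip(t240s, ea)), list(zip(t240s, ef))

    def test_exact_recovery(self):
        t240s = np.linspace(279.15, 291.15, 10)
        pe, pf = self.pairs(t240s)
        params, diag = fit_acclimation(pe, pf)
        assert params.c_amp == pytest.approx(9.5, rel=1e-6)
        assert params.c_rate == pytest.approx(0.53, rel=1e-6)
        assert params.ef_rate == pytest.approx(0.12, rel=1e-9)
        assert diag["ef_ref"] == pytest.approx(12.0, rel=1e-9)

    def test_noisy_recovery_within_band(self):
        rng = np.random.default_rng(11)
        t240s = np.sort(rng.uniform(279.15, 291.15, 20))
        pe, pf = self.pairs(t240s, rng, sd=0.05)
        params, _ = fit_acclimation(pe, pf)
        assert params.c_amp == pytest.approx(9.5, rel=0.15)
        assert params.c_rate == pytest.approx(0.53, rel=0.15)
        assert params.ef_rate == pytest.approx(0.12, rel=0.15)

    def test_insufficient_span_raises(self):
        t240s = np.full(5, 285.15)
        pe, pf = self.pairs(t240s + np.linspace(0, 1, 5))
        with pytest.raises(ValueError, match="span"):
            fit_acclimation(pe, pf)


def test_fitted_population_reproduces_inverse_relationship(rng):
    # Across a synthetic population the fitted activation energy falls and
    # the fitted emission factor rises with the 10-day mean temperature.
    t240s = np.linspace(279.15, 292.15, 15)
    eas, efs = [], []
    for t240 in t240s:
        exp = make_exp(float(c_sg(t240)), 12.0 * float(e_opt_sg(t240)),
                       noise=rng.lognormal(0, 0.03, len(RAMP_K)))
        fit = fit_arrhenius(exp)
        eas.append(fit.ea)
        efs.append(fit.ef30)
    # Rank correlation: Ea–T240 is exponential, so Pearson understates it.
    from scipy.stats import spearmanr

    assert spearmanr(t240s, eas).statistic < -0.9
    assert spearmanr(t240s, efs).statistic > 0.9


def test_read_chamber_csv_blank_subtraction(tmp_path):
    steps = pd.DataFrame(
        {
            "experiment_id": ["a"] * 3,
            "species": ["carex"] * 3,
            "step_temp": [20.0, 25.0, 30.0],
            "emission_rate": [0.5, 2.0, 6.0],
            "ppfd": [1000.0] * 3,
            "blank_rate": [0.8, 0.5, 0.5],
        }
    )
    hist = pd.DataFrame(
        {
            "experiment_id": ["a"] * 15,
            "day_offset": range(1, 16),
            "daily_mean_temp": [10.0] * 15,
        }
    )
    steps.to_csv(tmp_path / "steps.csv", index=False)
    hist.to_csv(tmp_path / "hist.csv", index=False)
    with pytest.warns(RuntimeWarning, match="blank exceeds"):
        exps = read_chamber_csv(tmp_path / "steps.csv", tmp_path / "hist.csv")
    (exp,) = exps
    assert exp.emissions[0] == 0.0  # floored
    assert exp.emissions[1] == pytest.approx(1.5)
    assert exp.temps_k[0] == pytest.approx(293.15)  # °C converted
    assert exp.prior_daily_means[0] == pytest.approx(283.15)
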