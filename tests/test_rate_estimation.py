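"""Specific-rate estimators: round-trip recovery, gas balance, pooling."""

import numpy as np
import pytest

from physioflux.bioreactor import BioreactorSeries
from physioflux.exceptions import (
    DomainError,
    IncompatibleReplicatesError,
    InsufficientDataError,
    SteadyStateError,
    UndefinedRateError,
)
from physioflux.rate_estimation import (
    BatchPhysiologyModel,
    ChemostatPhysiologyModel,
    fit_mu_max,
    fit_specific_rate,
    gas_rates,
    pool_replicates,
    steady_state_check,
)
from physioflux.synthetic import (
    BatchScenario,
    ChemostatScenario,
    simulate_batch,
    simulate_chemostat,
)


class TestFitMuMax:
    @pytest.mark.parametrize("mu", [0.353, 0.266])
    def test_noise_free_recovery(self, mu):
        series = simulate_batch(BatchScenario(mu=mu))
        fit = fit_mu_max(series)
        assert fit.mu == pytest.approx(mu, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_biomass_gives_zero(self):
        series = BioreactorSeries("batch", time=np.arange(5.0),
                                  biomass=np.full(5, 1.3))
        assert fit_mu_max(series).mu == pytest.approx(0.0, abs=1e-12)

    def test_noisy_estimate_within_monte_carlo_band(self):
        # µ=0.266 with 5% multiplicative noise, 20 samples
        series = simulate_batch(BatchScenario(mu=0.266, noise_cv=0.05,
                                              n_samples=20, seed=7))
        fit = fit_mu_max(series, window=(series.time[0], series.time[-1]))
        assert 0.24 <= fit.mu <= 0.29

    def test_too_few_points_raises(self):
        series = BioreactorSeries("batch", time=[0.0, 1.0, 2.0, 3.0],
                                  biomass=[0.1, 0.2, 0.4, 0.8])
        with pytest.raises(InsufficientDataError):
            fit_mu_max(series, window=(0.0, 1.0))

    def test_nonpositive_biomass_in_window_raises(self):
        series = BioreactorSeries("batch", time=[0.0, 1.0, 2.0, 3.0],
                                  biomass=[0.0, 0.2, 0.4, 0.8])
        with pytest.raises(DomainError):
            fit_mu_max(series, window=(0.0, 3.0))


class TestFitSpecificRate:
    def test_noise_free_glucose_recovery(self):
        series = simulate_batch(BatchScenario())
        q = fit_specific_rate(series, "glucose", 0.353)
        assert q == pytest.approx(-14.42, rel=1e-9)

    def test_constant_compound_gives_zero(self):
        series = simulate_batch(BatchScenario())
        series.concentrations["acetate"] = np.full(series.n_obs, 0.5)
        assert fit_specific_rate(series, "acetate", 0.353) == \
            pytest.approx(0.0, abs=1e-12)

    def test_noisy_acetate_within_replicate_dispersion(self):
        # generated q=+1.38; noisy estimate within 3 replicate sd (±0.09)
        series = simulate_batch(BatchScenario.xfpk(noise_cv=0.02, seed=11))
        mu = fit_mu_max(series, (series.time[0], series.time[-1])).mu
        q = fit_specific_rate(series, "acetate", mu)
        assert q == pytest.approx(1.38, abs=0.09)
        assert q > 0

    def test_missing_channel_raises(self):
        series = simulate_batch(BatchScenario())
        del series.concentrations["acetate"]
        from physioflux.exceptions import MissingChannelError
        with pytest.raises(MissingChannelError):
            fit_specific_rate(series, "acetate", 0.353)


class TestGasRates:
    def test_noise_free_recovery_batch(self):
        series = simulate_batch(BatchScenario(balance="as-printed"))
        q_co2, q_o2 = gas_rates(series)
        assert q_co2 == pytest.approx(30.01, rel=1e-9)
        assert q_o2 == pytest.approx(-5.49, rel=1e-9)

    def test_noise_free_recovery_chemostat(self):
        series = simulate_chemostat(
            ChemostatScenario.xfpk(balance="as-printed"))
        q_co2, q_o2 = gas_rates(series)
        assert q_co2 == pytest.approx(3.34, rel=1e-9)
        assert q_o2 == pytest.approx(-3.35, rel=1e-9)

    def test_equal_in_and_outlet_fractions_give_zero(self):
        from physioflux.rate_estimation import INLET_Y_CO2, INLET_Y_O2
        series = BioreactorSeries(
            "batch", time=np.arange(4.0), biomass=np.full(4, 1.0),
            y_co2=np.full(4, INLET_Y_CO2), y_o2=np.full(4, INLET_Y_O2))
        assert gas_rates(series) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_intensive_in_volume(self):
        # same specific rates at a different working volume
        q_ref = gas_rates(simulate_batch(BatchScenario()))
        q_alt = gas_rates(simulate_batch(BatchScenario(volume=1.2)))
        assert q_alt == pytest.approx(q_ref, rel=1e-9)

    def test_zero_aeration_raises(self):
        series = simulate_batch(BatchScenario())
        series.aeration = 0.0
        with pytest.raises(UndefinedRateError):
            gas_rates(series)


class TestChemostat:
    def test_noise_free_round_trip(self):
        scenario = ChemostatScenario(balance="as-printed")
        result = ChemostatPhysiologyModel(simulate_chemostat(scenario)).fit()
        assert result.mu_max == pytest.approx(scenario.d, rel=1e-12)
        assert result.yield_biomass == pytest.approx(0.479, rel=1e-9)
        # q_glc = -D (S_feed - S_res) 1000 / (M X): magnitude ~1.2
        assert result.q["glucose"] == pytest.approx(-1.2053, abs=0.002)
        assert result.q["co2"] == pytest.approx(2.91, rel=1e-9)
        assert result.q["o2"] == pytest.approx(-2.61, rel=1e-9)

    def test_washout_limit_gives_zero_uptake(self):
        series = BioreactorSeries(
            "chemostat", time=np.linspace(0, 15, 8),
            biomass=np.full(8, 1.0),
            concentrations={"glucose": np.full(8, 7.5)},
            dilution_rate=0.104, feed={"glucose": 7.5})
        result = ChemostatPhysiologyModel(series).fit()
        assert result.q["glucose"] == pytest.approx(0.0, abs=1e-12)

    def test_growing_series_rejected_as_unsteady(self):
        t = np.linspace(0, 15, 10)
        series = BioreactorSeries(
            "chemostat", time=t, biomass=1.0 * np.exp(0.05 * t),
            concentrations={"glucose": np.zeros(10)},
            dilution_rate=0.104, feed={"glucose": 7.5})
        with pytest.raises(SteadyStateError):
            ChemostatPhysiologyModel(series).fit()


class TestSteadyStateCheck:
    @staticmethod
    def _series(drift: float, n: int = 13) -> BioreactorSeries:
        t = np.linspace(0.0, 15.0, n)
        trend = 1.0 + drift * (t - t[0]) / (1.0 / 0.104)
        return BioreactorSeries(
            "chemostat", time=t, biomass=3.6 * trend,
            y_co2=np.full(n, 0.01), y_o2=np.full(n, 0.2),
            dilution_rate=0.104, feed={"glucose": 7.5})

    def test_flat_series_is_steady(self):
        report = steady_state_check(self._series(0.0))
        assert report.is_steady and report.biomass_drift == pytest.approx(0.0)

    def test_three_percent_drift_passes_five_percent_threshold(self):
        report = steady_state_check(self._series(0.03))
        assert report.is_steady
        assert report.biomass_drift == pytest.approx(0.03, abs=0.005)

    def test_exponential_growth_fails(self):
        t = np.linspace(0.0, 15.0, 13)
        series = BioreactorSeries(
            "chemostat", time=t, biomass=1.0 * np.exp(0.1 * t),
            y_co2=np.full(13, 0.01), y_o2=np.full(13, 0.2),
            dilution_rate=0.104, feed={"glucose": 7.5})
        assert not steady_state_check(series).is_steady

    def test_insufficient_span_raises(self):
        series = self._series(0.0)
        series.time = series.time / 10  # now covers only 1.5 h << 1/D
        with pytest.raises(InsufficientDataError):
            steady_state_check(series)


class TestPoolReplicates:
    @staticmethod
    def _fit(seed: int, noise: float = 0.0):
        return BatchPhysiologyModel(
            simulate_batch(BatchScenario(noise_cv=noise, seed=seed))).fit()

    def test_identical_replicates_have_zero_dispersion(self):
        pooled = pool_replicates([self._fit(0)] * 4)
        assert pooled.n_replicates == 4
        assert all(sd == pytest.approx(0.0, abs=1e-12)
                   for sd in pooled.dispersion.values())

    def test_hand_computed_mean_and_sd(self):
        fits = [self._fit(0) for _ in range(4)]
        for fit, mu in zip(fits, [0.35, 0.36, 0.34, 0.37]):
            fit.mu_max = mu
        pooled = pool_replicates(fits)
        assert pooled.mu_max == pytest.approx(0.355)
        assert pooled.dispersion["mu_max"] == pytest.approx(0.012910, abs=1e-5)

    def test_single_replicate_rejected(self):
        with pytest.raises(IncompatibleReplicatesError):
            pool_replicates([self._fit(0)])

    def test_mixed_modes_rejected(self):
        chemo = ChemostatPhysiologyModel(
            simulate_chemostat(ChemostatScenario())).fit()
        with pytest.raises(IncompatibleReplicatesError):
            pool_replicates([self._fit(0), chemo])


class TestBatchModel:
    def test_full_round_trip_and_summary(self):
        result = BatchPhysiologyModel(simulate_batch(BatchScenario())).fit()
        assert result.mu_max == pytest.approx(0.353, rel=1e-9)
        assert result.yield_biomass == pytest.approx(0.1359, abs=2e-4)
        # q(biomass) = µ·1000/cmol_mass by definition
        assert result.q_biomass == pytest.approx(
            result.mu_max * 1000.0 / result.cmol_mass)
        text = result.summary()
        for label in ("µ(max)", "Y(x/s)", "q(Glucose)", "q(EtOH)",
                      "q(CO2)", "q(Biomass)", "q(O2)"):
            assert label in text

    def test_wrong_mode_rejected(self):
        series = simulate_chemostat(ChemostatScenario())
        with pytest.raises(DomainError):
            BatchPhysiologyModel(series)
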