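"""Normalized C-mol flux maps, balance closure and respiration partition."""

import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from physioflux.exceptions import IncompleteBalanceError, NormalizationError
from physioflux.flux_accounting import (
    carbon_balance,
    carbon_balance_sd,
    flux_difference,
    normalize_fluxes,
    respiration_partition,
)
from physioflux.rate_estimation import BatchPhysiologyModel
from physioflux.synthetic import BatchScenario, simulate_batch

from conftest import make_result


class TestNormalizeFluxes:
    def test_acetate_share_of_carbon(self, control_batch_result,
                                     xfpk_batch_result):
        # ~threefold overflow increase: 1.4% of glucose carbon -> 3.8%
        assert normalize_fluxes(xfpk_batch_result).normalized["acetate"] == \
            pytest.approx(3.8, abs=0.1)
        assert normalize_fluxes(control_batch_result).normalized["acetate"] == \
            pytest.approx(1.4, abs=0.1)

    def test_glucose_is_always_100(self, control_batch_result):
        assert normalize_fluxes(control_batch_result).normalized["glucose"] == 100.0

    def test_zero_products_normalize_to_zero(self):
        result = make_result("batch", mu=0.3, yield_biomass=0.14,
                             q={"glucose": -10.0, "ethanol": 0.0,
                                "acetate": 0.0, "co2": 5.0},
                             q_biomass=12.0, strain="s")
        fmap = normalize_fluxes(result)
        assert fmap.normalized["ethanol"] == 0.0
        assert fmap.normalized["acetate"] == 0.0

    def test_zero_glucose_uptake_raises(self, control_batch_result):
        control_batch_result.q["glucose"] = 0.0
        with pytest.raises(NormalizationError):
            normalize_fluxes(control_batch_result)

    @given(st.floats(0.1, 10.0))
    def test_scale_invariance(self, scale):
        base = make_result("batch", 0.3, 0.14,
                           {"glucose": -10.0, "ethanol": 12.0, "acetate": 0.5,
                            "co2": 20.0}, 12.0, "s")
        scaled = make_result("batch", 0.3, 0.14,
                             {k: scale * v for k, v in base.q.items()},
                             scale * 12.0, "s")
        ref = normalize_fluxes(base).normalized
        got = normalize_fluxes(scaled).normalized
        assert got == pytest.approx(ref, rel=1e-9)

    def test_edge_list_display_threshold_keeps_data(self, control_batch_result):
        fmap = normalize_fluxes(control_batch_result)
        # succinate: 0.02·4/86.52 ~ 0.09% — hidden in rendering only
        assert fmap.normalized["succinate"] < 0.1
        sinks = {sink for _, sink, _ in fmap.to_edge_list()}
        assert "succinate" not in sinks
        assert "succinate" in fmap.normalized


class TestCarbonBalance:
    def test_batch_closure_near_107(self, control_batch_result,
                                    xfpk_batch_result):
        assert carbon_balance(control_batch_result) == pytest.approx(107, abs=1.5)
        assert carbon_balance(xfpk_batch_result) == pytest.approx(107, abs=1.5)

    def test_chemostat_closures(self, control_chemostat_result,
                                xfpk_chemostat_result):
        assert carbon_balance(control_chemostat_result) == \
            pytest.approx(99, abs=1.5)
        assert carbon_balance(xfpk_chemostat_result) == pytest.approx(92, abs=1.5)

    def test_closed_mode_simulation_closes_exactly(self):
        result = BatchPhysiologyModel(
            simulate_batch(BatchScenario(balance="closed"))).fit()
        assert carbon_balance(result) == pytest.approx(100.0, abs=1e-9)

    def test_missing_co2_raises(self, control_batch_result):
        del control_batch_result.q["co2"]
        with pytest.raises(IncompleteBalanceError):
            carbon_balance(control_batch_result)

    def test_propagated_closure_sd(self, control_batch_result):
        # zero dispersion -> zero propagated sd
        assert carbon_balance_sd(control_batch_result) == 0.0
        # single uncertain output: sd follows the linear term exactly
        control_batch_result.dispersion = {"q:co2": 0.32}
        expected = 100.0 * 0.32 / (6 * 14.42)
        assert carbon_balance_sd(control_batch_result) == \
            pytest.approx(expected, rel=1e-9)
        # glucose uncertainty adds in quadrature and only increases it
        control_batch_result.dispersion["q:glucose"] = 0.36
        assert carbon_balance_sd(control_batch_result) > expected

    def test_out_of_band_closure_warns(self, caplog):
        result = make_result("batch", 0.3, 0.14,
                             {"glucose": -10.0, "co2": 80.0}, 12.0, "s")
        with caplog.at_level(logging.WARNING, logger="physioflux"):
            carbon_balance(result)
        assert any("outside" in rec.message for rec in caplog.records)


class TestRespirationPartition:
    def test_control_respiratory_co2(self, control_batch_result):
        fmap = normalize_fluxes(control_batch_result)
        resp, frac = respiration_partition(fmap, control_batch_result)
        # 30.01 - 0.5 · (2·21.46) C-mmol/gCDW/h
        assert resp == pytest.approx(8.55, abs=1e-9)
        assert frac == pytest.approx(100 * 8.55 / 86.52, abs=1e-6)

    def test_relative_increase_about_50_percent(self, control_batch_result,
                                                xfpk_batch_result):
        _, f_ctrl = respiration_partition(
            normalize_fluxes(control_batch_result), control_batch_result)
        _, f_xfpk = respiration_partition(
            normalize_fluxes(xfpk_batch_result), xfpk_batch_result)
        assert 100 * (f_xfpk - f_ctrl) / f_ctrl == pytest.approx(50, abs=3)

    def test_no_ethanol_means_fully_respiratory(self, control_chemostat_result):
        fmap = normalize_fluxes(control_chemostat_result)
        resp, _ = respiration_partition(fmap, control_chemostat_result)
        assert resp == pytest.approx(2.91)

    def test_partition_completeness(self, xfpk_batch_result):
        fmap = normalize_fluxes(xfpk_batch_result)
        resp, _ = respiration_partition(fmap, xfpk_batch_result)
        etoh_cmol = 2 * xfpk_batch_result.q["ethanol"]
        assert resp + 0.5 * etoh_cmol == pytest.approx(
            xfpk_batch_result.q["co2"])

    def test_negative_partition_flagged_not_raised(self, caplog):
        result = make_result("batch", 0.3, 0.14,
                             {"glucose": -10.0, "ethanol": 12.0, "co2": 5.0},
                             12.0, "s")
        fmap = normalize_fluxes(result)
        with caplog.at_level(logging.WARNING, logger="physioflux"):
            resp, _ = respiration_partition(fmap, result)
        assert resp < 0
        assert any("inconsistent" in rec.message for rec in caplog.records)


class TestFluxDifference:
    def test_acetate_difference_in_points(self, control_batch_result,
                                          xfpk_batch_result):
        diff = flux_difference(normalize_fluxes(xfpk_batch_result),
                               normalize_fluxes(control_batch_result),
                               "acetate")
        assert diff == pytest.approx(2.4, abs=0.2)

    def test_identical_maps_differ_by_zero(self, control_batch_result):
        fmap = normalize_fluxes(control_batch_result)
        assert flux_difference(fmap, fmap, "ethanol") == 0.0

    def test_glucose_channel_is_always_zero(self, control_batch_result,
                                            xfpk_batch_result):
        assert flux_difference(normalize_fluxes(xfpk_batch_result),
                               normalize_fluxes(control_batch_result),
                               "glucose") == 0.0

    def test_missing_compound_raises(self, control_batch_result,
                                     control_chemostat_result):
        with pytest.raises(KeyError):
            flux_difference(normalize_fluxes(control_batch_result),
                            normalize_fluxes(control_chemostat_result),
                            "ethanol")
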