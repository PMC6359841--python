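"""Shared fixtures: reference physiology results built from printed rates.

The reference values are the published per-strain physiological
parameters of a control and a phosphoketolase-expressing yeast strain
(quadruplicate batch and glucose-limited chemostat cultivations); they
are used as *inputs* to the accounting functions under test.
"""

import pytest
from hypothesis import HealthCheck, settings

from physioflux.rate_estimation import PhysiologyResults
from physioflux.stoichiometry import BiomassComposition

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

CMOL_MASS = BiomassComposition().cmol_mass


def make_result(mode, mu, yield_biomass, q, q_biomass, strain):
    return PhysiologyResults(mode=mode, mu_max=mu, yield_biomass=yield_biomass,
                             q=dict(q), q_biomass=q_biomass,
                             cmol_mass=CMOL_MASS, strain=strain)


@pytest.fixture
def control_batch_result():
    return make_result(
        "batch", mu=0.353, yield_biomass=0.135,
        q={"glucose": -14.42, "ethanol": 21.46, "acetate": 0.61,
           "glycerol": 1.13, "pyruvate": 0.13, "succinate": 0.02,
           "co2": 30.01, "o2": -5.49},
        q_biomass=14.37, strain="control")


@pytest.fixture
def xfpk_batch_result():
    return make_result(
        "batch", mu=0.266, yield_biomass=0.123,
        q={"glucose": -12.19, "ethanol": 17.26, "acetate": 1.38,
           "glycerol": 0.62, "pyruvate": 0.15, "succinate": 0.01,
           "co2": 28.16, "o2": -7.63},
        q_biomass=10.81, strain="xfpk")


@pytest.fixture
def control_chemostat_result():
    return make_result(
        "chemostat", mu=0.104, yield_biomass=0.479,
        q={"glucose": -1.18, "co2": 2.91, "o2": -2.61},
        q_biomass=4.13, strain="control")


@pytest.fixture
def xfpk_chemostat_result():
    return make_result(
        "chemostat", mu=0.103, yield_biomass=0.409,
        q={"glucose": -1.36, "co2": 3.34, "o2": -3.35},
        q_biomass=4.07, strain="xfpk")
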