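"""Synthetic bioreactor cultivations and metabolite panels.

Forward models of the data the estimators consume, so the whole pipeline
is testable end-to-end without external measurements:

* :func:`simulate_batch` — balanced exponential growth
  (X(t) = X0·e^{µt}) with constant signed specific rates; each
  concentration integrates dS/dt = q·M/1000·X and the off-gas mole
  fractions are back-computed from the gas balance the estimators
  invert.  The default parameters are a reference quadruplicate batch
  characterization of a control and a phosphoketolase-expressing yeast
  strain (2% glucose, pH 5, 36 L/h aeration, 0.6 L).
* :func:`simulate_chemostat` — a glucose-limited steady-state window
  (constant biomass, residual substrate and off-gas) at the scenario's
  dilution rate.
* :func:`simulate_panel` — quadruplicate sugar-phosphate pools with
  log-normal replicate noise, mean-preserving so the expected
  fold-change equals the configured map.

Carbon closure: printed specific-rate sets need not close the carbon
balance at exactly 100% (measurement bias), so scenarios carry a
``balance`` switch — ``"closed"`` rescales q(CO2) before simulation so
the generated data conserve carbon exactly, ``"as-printed"`` uses the
rates verbatim and reproduces their printed closure.

Randomness: one root seed per scenario; independent child streams are
spawned per channel in a fixed documented order (biomass, sorted
concentration channels, y_co2, y_o2; panels: control then test), so
adding a channel never perturbs the others.  Noise is multiplicative
Gaussian with a per-channel CV; for off-gas channels it is applied to
the inlet–outlet difference (the informative part of the signal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bioreactor import BioreactorSeries
from .exceptions import InvalidScenarioError
from .metabolites import MetabolitePanel
from .rate_estimation import INLET_Y_CO2, INLET_Y_O2, molar_gas_flow
from .stoichiometry import DEFAULT_REGISTRY, CompoundRegistry

logger = logging.getLogger(__name__)

#: reference batch specific rates, mmol gCDW^-1 h^-1 (signed)
CONTROL_BATCH_Q = {"glucose": -14.42, "ethanol": 21.46, "acetate": 0.61,
                   "glycerol": 1.13, "pyruvate": 0.13, "succinate": 0.02,
                   "co2": 30.01, "o2": -5.49}
XFPK_BATCH_Q = {"glucose": -12.19, "ethanol": 17.26, "acetate": 1.38,
                "glycerol": 0.62, "pyruvate": 0.15, "succinate": 0.01,
                "co2": 28.16, "o2": -7.63}
CONTROL_BATCH_MU = 0.353
XFPK_BATCH_MU = 0.266

#: reference chemostat parameters (glucose-limited, 7.5 g/L feed)
CONTROL_CHEMOSTAT = {"d": 0.104, "yield_biomass": 0.479,
                     "q_co2": 2.91, "q_o2": -2.61}
XFPK_CHEMOSTAT = {"d": 0.103, "yield_biomass": 0.409,
                  "q_co2": 3.34, "q_o2": -3.35}

#: reference control pool sizes, µmol/gCDW (order-of-magnitude plausible)
DEFAULT_BASE_POOLS = {"G1P": 0.2, "G6P": 2.0, "F6P": 0.5, "DHAP": 0.8,
                      "GAP": 0.04, "3PGA": 1.5, "2PGA": 0.2, "Ru5P": 0.1,
                      "R5P": 0.15, "X5P": 0.2, "E4P": 0.02, "S7P": 0.5}

#: phosphoketolase-strain fold-changes vs control (fractions of control)
DEFAULT_FOLD_MAP = {"G1P": 1.0, "G6P": 1.0, "F6P": 0.74, "DHAP": 2.0,
                    "GAP": 2.08, "3PGA": 1.0, "2PGA": 0.8, "Ru5P": 0.6,
                    "R5P": 1.0, "X5P": 0.26, "E4P": 5.42, "S7P": 0.7}


def _channel_streams(seed: int, channels: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(channels))
    return {ch: np.random.default_rng(ss) for ch, ss in zip(channels, children)}


def _mult_noise(values: np.ndarray, cv: float,
                rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return values
    noisy = values * (1.0 + cv * rng.standard_normal(values.shape))
    return np.maximum(noisy, 0.0)


@dataclass(frozen=True)
class BatchScenario:
    """Parameters of a synthetic exponential batch cultivation."""

    mu: float = CONTROL_BATCH_MU
    x0: float = 0.01                     # gCDW/L inoculum
    glucose_0: float = 20.0              # g/L, 2% glucose medium
    q: dict[str, float] = field(default_factory=lambda: dict(CONTROL_BATCH_Q))
    balance: str = "closed"              # "closed" | "as-printed"
    noise_cv: float = 0.0
    n_samples: int = 16
    seed: int = 0
    aeration: float = 36.0               # L/h (0.1 VVM)
    volume: float = 0.6                  # L
    ph: float = 5.0
    strain: str | None = "control"
    mu_ethanol: float | None = None      # optional second (ethanol) phase
    exhaustion_fraction: float = 0.97    # sample up to this share of t_exhaustion

    @classmethod
    def control(cls, **kw) -> "BatchScenario":
        return cls(**kw)

    @classmethod
    def xfpk(cls, **kw) -> "BatchScenario":
        kw.setdefault("strain", "xfpk")
        return cls(mu=XFPK_BATCH_MU, q=dict(XFPK_BATCH_Q), **kw)


@dataclass(frozen=True)
class ChemostatScenario:
    """Parameters of a synthetic glucose-limited chemostat steady state."""

    d: float = CONTROL_CHEMOSTAT["d"]
    feed_glucose: float = 7.5            # g/L
    yield_biomass: float = CONTROL_CHEMOSTAT["yield_biomass"]
    residual_glucose: float = 0.0        # g/L, glucose-limited
    q_co2: float = CONTROL_CHEMOSTAT["q_co2"]
    q_o2: float = CONTROL_CHEMOSTAT["q_o2"]
    balance: str = "closed"
    noise_cv: float = 0.0
    n_samples: int = 13
    residence_times: float = 1.5         # window length in units of 1/D
    seed: int = 0
    aeration: float = 36.0
    volume: float = 0.6
    ph: float = 5.0
    strain: str | None = "control"

    @classmethod
    def control(cls, **kw) -> "ChemostatScenario":
        return cls(**kw)

    @classmethod
    def xfpk(cls, **kw) -> "ChemostatScenario":
        kw.setdefault("strain", "xfpk")
        return cls(d=XFPK_CHEMOSTAT["d"],
                   yield_biomass=XFPK_CHEMOSTAT["yield_biomass"],
                   q_co2=XFPK_CHEMOSTAT["q_co2"],
                   q_o2=XFPK_CHEMOSTAT["q_o2"], **kw)

    @property
    def biomass(self) -> float:
        """Steady-state biomass, gCDW/L: Y(x/s) × glucose consumed."""
        return self.yield_biomass * (self.feed_glucose - self.residual_glucose)


@dataclass(frozen=True)
class PanelScenario:
    """Parameters of a synthetic test-vs-control metabolite panel pair."""

    base_pools: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_POOLS))
    fold_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLD_MAP))
    cv: float = 0.10
    n_replicates: int = 4
    seed: int = 0
    control_strain: str = "control"
    test_strain: str = "xfpk"


def _closed_q_co2(q: dict[str, float], mu: float,
                  registry: CompoundRegistry) -> float:
    """q(CO2) that closes the carbon balance at exactly 100%."""
    cmol = registry.biomass_composition.cmol_mass
    q_biomass = mu * 1000.0 / cmol
    uptake_c = abs(q["glucose"]) * registry.compound("glucose").carbon_number
    other_c = sum(abs(q[name]) * registry.compound(name).carbon_number
                  for name in q if name not in ("glucose", "co2", "o2"))
    closed = uptake_c - other_c - q_biomass
    if closed <= 0:
        raise InvalidScenarioError(
            "cannot close carbon balance: non-CO2 outputs already exceed uptake")
    return closed


def _offgas(q_co2: float, q_o2: float, biomass: np.ndarray, volume: float,
            aeration: float, temperature: float = 30.0
            ) -> tuple[np.ndarray, np.ndarray]:
    n_in = molar_gas_flow(aeration, temperature)
    inventory = biomass * volume
    y_co2 = INLET_Y_CO2 + q_co2 * inventory / (1000.0 * n_in)
    y_o2 = INLET_Y_O2 + q_o2 * inventory / (1000.0 * n_in)
    return y_co2, y_o2


def simulate_batch(scenario: BatchScenario,
                   registry: CompoundRegistry = DEFAULT_REGISTRY
                   ) -> BioreactorSeries:
    """Generate one batch cultivation series from a scenario.

    The sampling grid spans the exponential phase up to just before
    glucose exhaustion; with ``mu_ethanol`` set, a second growth segment
    on the accumulated ethanol is appended (cosmetic two-phase profile).
    Output depends only on (scenario, seed).
    """
    if scenario.mu <= 0:
        raise InvalidScenarioError(f"mu must be positive, got {scenario.mu}")
    if scenario.balance not in ("closed", "as-printed"):
        raise InvalidScenarioError(f"unknown balance mode {scenario.balance!r}")
    q = dict(scenario.q)
    if q.get("glucose", 0.0) >= 0:
        raise InvalidScenarioError("batch scenario needs q(glucose) < 0")
    if scenario.balance == "closed":
        q["co2"] = _closed_q_co2(q, scenario.mu, registry)

    glc_mass = registry.compound("glucose").molar_mass
    mu, x0, s0 = scenario.mu, scenario.x0, scenario.glucose_0
    # glucose exhausted when X - X0 = µ·S0·1000 / (|q_glc|·M)
    dx_exhaust = mu * s0 * 1000.0 / (abs(q["glucose"]) * glc_mass)
    t_exhaust = np.log((x0 + dx_exhaust) / x0) / mu
    t = np.linspace(0.0, scenario.exhaustion_fraction * t_exhaust,
                    scenario.n_samples)
    x = x0 * np.exp(mu * t)

    conc = {}
    for name, rate in q.items():
        if name in ("co2", "o2"):
            continue
        mass = registry.compound(name).molar_mass
        s_init = s0 if name == "glucose" else 0.0
        conc[name] = s_init + rate * mass / (1000.0 * mu) * (x - x0)
    y_co2, y_o2 = _offgas(q["co2"], q["o2"], x, scenario.volume,
                          scenario.aeration)

    if scenario.mu_ethanol is not None:
        t, x, conc, y_co2, y_o2 = _append_ethanol_phase(
            scenario, registry, q, t, x, conc, y_co2, y_o2)

    channels = ["biomass"] + sorted(conc) + ["y_co2", "y_o2"]
    streams = _channel_streams(scenario.seed, channels)
    cv = scenario.noise_cv
    x_obs = _mult_noise(x, cv, streams["biomass"])
    conc_obs = {name: _mult_noise(vals, cv, streams[name])
                for name, vals in conc.items()}
    y_co2_obs = INLET_Y_CO2 + _mult_noise(y_co2 - INLET_Y_CO2, cv,
                                          streams["y_co2"])
    y_o2_obs = INLET_Y_O2 + _mult_noise(y_o2 - INLET_Y_O2, cv, streams["y_o2"])

    return BioreactorSeries(
        mode="batch", time=t, biomass=x_obs, concentrations=conc_obs,
        y_co2=y_co2_obs, y_o2=y_o2_obs, aeration=scenario.aeration,
        volume=scenario.volume, ph=scenario.ph, strain=scenario.strain)


def _append_ethanol_phase(scenario, registry, q, t, x, conc, y_co2, y_o2):
    """Second exponential segment consuming the accumulated ethanol."""
    mu2 = scenario.mu_ethanol
    if mu2 <= 0:
        raise InvalidScenarioError("mu_ethanol must be positive when set")
    et_mass = registry.compound("ethanol").molar_mass
    x1, e1 = x[-1], conc["ethanol"][-1]
    # consume ethanol at a fixed specific rate; deplete most of the pool
    q_et2 = -5.0
    dx2 = mu2 * 0.9 * e1 * 1000.0 / (abs(q_et2) * et_mass)
    t2_end = np.log((x1 + dx2) / x1) / mu2
    t2 = np.linspace(t[-1] + t2_end / scenario.n_samples,
                     t[-1] + t2_end, scenario.n_samples)
    x2 = x1 * np.exp(mu2 * (t2 - t[-1]))
    t_full = np.concatenate([t, t2])
    x_full = np.concatenate([x, x2])
    for name, vals in conc.items():
        if name == "ethanol":
            seg = e1 + q_et2 * et_mass / (1000.0 * mu2) * (x2 - x1)
        else:
            seg = np.full_like(t2, vals[-1])
        conc[name] = np.concatenate([vals, np.maximum(seg, 0.0)])
    # respiratory gas exchange on ethanol: RQ ~ 0.65 for ethanol oxidation
    y2_co2, y2_o2 = _offgas(abs(q_et2) * 1.3, -abs(q_et2) * 2.0, x2,
                            scenario.volume, scenario.aeration)
    return (t_full, x_full, conc,
            np.concatenate([y_co2, y2_co2]), np.concatenate([y_o2, y2_o2]))


def simulate_chemostat(scenario: ChemostatScenario,
                       registry: CompoundRegistry = DEFAULT_REGISTRY
                       ) -> BioreactorSeries:
    """Generate a steady-state chemostat window from a scenario.

    Emits ≥1 residence time of constant biomass, residual glucose and
    off-gas fractions (plus per-channel noise); at zero noise the series
    satisfies the steady-state balance equations exactly.
    """
    if scenario.d <= 0:
        raise InvalidScenarioError(f"dilution rate must be positive, got {scenario.d}")
    if scenario.balance not in ("closed", "as-printed"):
        raise InvalidScenarioError(f"unknown balance mode {scenario.balance!r}")
    x_ss = scenario.biomass
    if x_ss <= 0:
        raise InvalidScenarioError("steady-state biomass must be positive")
    glc_mass = registry.compound("glucose").molar_mass
    consumed = scenario.feed_glucose - scenario.residual_glucose
    q_glc = -scenario.d * consumed * 1000.0 / (glc_mass * x_ss)
    q_co2 = scenario.q_co2
    if scenario.balance == "closed":
        q_co2 = _closed_q_co2({"glucose": q_glc, "co2": q_co2},
                              scenario.d, registry)

    span = scenario.residence_times / scenario.d
    t = np.linspace(0.0, span, scenario.n_samples)
    ones = np.ones_like(t)
    x = x_ss * ones
    conc = {"glucose": scenario.residual_glucose * ones}
    y_co2, y_o2 = _offgas(q_co2, scenario.q_o2, x, scenario.volume,
                          scenario.aeration)

    channels = ["biomass", "glucose", "y_co2", "y_o2"]
    streams = _channel_streams(scenario.seed, channels)
    cv = scenario.noise_cv
    x_obs = _mult_noise(x, cv, streams["biomass"])
    glc_obs = _mult_noise(conc["glucose"], cv, streams["glucose"])
    y_co2_obs = INLET_Y_CO2 + _mult_noise(y_co2 - INLET_Y_CO2, cv,
                                          streams["y_co2"])
    y_o2_obs = INLET_Y_O2 + _mult_noise(y_o2 - INLET_Y_O2, cv, streams["y_o2"])

    return BioreactorSeries(
        mode="chemostat", time=t, biomass=x_obs,
        concentrations={"glucose": glc_obs},
        y_co2=y_co2_obs, y_o2=y_o2_obs, aeration=scenario.aeration,
        volume=scenario.volume, ph=scenario.ph, strain=scenario.strain,
        dilution_rate=scenario.d, feed={"glucose": scenario.feed_glucose})


def simulate_panel(scenario: PanelScenario
                   ) -> tuple[MetabolitePanel, MetabolitePanel]:
    """Generate (control, test) metabolite panels from a scenario.

    Replicates are drawn log-normally around the base pool (control) and
    base × fold-change (test) with the configured CV; draws are
    mean-preserving, so the expected fold-change equals the configured
    map.  Returns ``(control, test)``.
    """
    if scenario.n_replicates < 2:
        raise InvalidScenarioError("need at least 2 replicates")
    for name, pool in scenario.base_pools.items():
        if pool <= 0:
            raise InvalidScenarioError(f"base pool of {name} must be positive")
    streams = _channel_streams(scenario.seed, ["control", "test"])
    sigma = np.sqrt(np.log1p(scenario.cv**2))

    def draw(means: dict[str, float], rng: np.random.Generator) -> pd.DataFrame:
        cols = {}
        for met in scenario.base_pools:
            z = rng.standard_normal(scenario.n_replicates)
            cols[met] = means[met] * np.exp(sigma * z - sigma**2 / 2.0)
        return pd.DataFrame(cols)

    control_means = dict(scenario.base_pools)
    test_means = {m: scenario.base_pools[m] * scenario.fold_map.get(m, 1.0)
                  for m in scenario.base_pools}
    control = MetabolitePanel(scenario.control_strain,
                              draw(control_means, streams["control"]))
    test = MetabolitePanel(scenario.test_strain,
                           draw(test_means, streams["test"]))
    return control, test
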