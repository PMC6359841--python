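"""Specific growth rates, yields and specific rates from bioreactor data.

The estimators turn a :class:`~physioflux.bioreactor.BioreactorSeries`
into the per-strain physiological parameters of a classical black-box
characterization: maximum specific growth rate µmax, biomass yield on
glucose Y(x/s), and signed specific rates q (mmol gCDW^-1 h^-1) for every
measured metabolite plus the gas-phase rates CER and OUR.

Two modes are supported.  In **batch** mode, µmax is the slope of
ln(biomass) vs time over the exponential window and each q is obtained by
regressing concentration against biomass (exact under balanced
exponential growth, and avoids differentiating noisy time-series):
``q = µ · (dS/dX) · 1000 / M``.  In **chemostat** mode the steady-state
balances apply directly: µ = D, ``q_glc = -D (S_feed - S_res) · 1000 /
(M · X)``, products analogously from their residual concentrations.

Gas rates use the inlet molar flow from the ideal-gas law (1 atm, broth
temperature) and the off-gas mole-fraction differences; inlet gas is air
(20.95% O2, 0.04% CO2) unless overridden.

The statsmodels-style entry points are :class:`BatchPhysiologyModel` and
:class:`ChemostatPhysiologyModel`; their ``fit()`` returns a
:class:`PhysiologyResults` with estimates, per-field dispersion (after
replicate pooling) and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bioreactor import BioreactorSeries
from .exceptions import (
    DomainError,
    IncompatibleReplicatesError,
    InsufficientDataError,
    SteadyStateError,
    UndefinedRateError,
)
from .stoichiometry import DEFAULT_REGISTRY, CompoundRegistry

logger = logging.getLogger(__name__)

R_GAS = 8.314          # J mol^-1 K^-1
PRESSURE = 101325.0    # Pa, ambient
#: inlet gas composition (air), mole fractions
INLET_Y_O2 = 0.2095
INLET_Y_CO2 = 0.0004

#: compounds whose concentration channels feed the specific-rate fits
RATE_COMPOUNDS = ("glucose", "ethanol", "acetate", "glycerol",
                  "pyruvate", "succinate")


# ---------------------------------------------------------------------------
# elementary estimators


@dataclass(frozen=True)
class MuFit:
    """Exponential-growth fit: µ (h^-1), R² and the window used."""

    mu: float
    r_squared: float
    window: tuple[float, float]
    n_points: int


def _linregress(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R² (R²=1 for a perfect/degenerate fit)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def select_exponential_window(series: BioreactorSeries,
                              r2_min: float = 0.995,
                              min_points: int = 4) -> tuple[float, float]:
    """Longest contiguous window where ln(biomass) vs time is log-linear.

    Scans window lengths from the full series downwards and returns the
    first window with ≥ ``min_points`` strictly positive biomass samples
    and R² ≥ ``r2_min``.  Falls back to the full positive-biomass series
    (with a warning) if no window qualifies.
    """
    pos = series.biomass > 0
    t, x = series.time[pos], series.biomass[pos]
    n = len(t)
    if n < min_points:
        raise InsufficientDataError(
            f"need ≥{min_points} positive-biomass points, have {n}")
    logx = np.log(x)
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            _, _, r2 = _linregress(t[sl], logx[sl])
            if r2 >= r2_min:
                return float(t[sl][0]), float(t[sl][-1])
    logger.warning("no window reached R^2 >= %.4g; using full series", r2_min)
    return float(t[0]), float(t[-1])


def fit_mu_max(series: BioreactorSeries,
               window: tuple[float, float] | None = None) -> MuFit:
    """Maximum specific growth rate from ln(biomass) vs time.

    ``window=None`` selects the exponential window automatically.
    """
    if window is None:
        window = select_exponential_window(series)
    mask = series.window_mask(window)
    t, x = series.time[mask], series.biomass[mask]
    if len(t) < 3:
        raise InsufficientDataError(
            f"need ≥3 biomass points in window, have {len(t)}")
    if np.any(x <= 0):
        raise DomainError("non-positive biomass inside the fit window")
    slope, _, r2 = _linregress(t, np.log(x))
    return MuFit(mu=slope, r_squared=r2,
                 window=(float(t[0]), float(t[-1])), n_points=len(t))


def fit_specific_rate(series: BioreactorSeries, compound: str, mu: float,
                      window: tuple[float, float] | None = None,
                      registry: CompoundRegistry = DEFAULT_REGISTRY) -> float:
    """Signed specific rate q (mmol gCDW^-1 h^-1) of one compound.

    Regresses concentration against biomass over the window; under
    balanced exponential growth dS/dX = q·M/(1000·µ), so
    q = µ · slope · 1000 / M.  The sign follows the data (consumed
    species give negative q).
    """
    if mu <= 0:
        raise DomainError(f"mu must be positive, got {mu}")
    conc = series.concentration(compound)
    mask = series.window_mask(window)
    x, s = series.biomass[mask], conc[mask]
    if len(x) < 2:
        raise InsufficientDataError("need ≥2 points for a rate fit")
    slope, _, _ = _linregress(x, s)
    molar_mass = registry.compound(compound).molar_mass
    return mu * slope * 1000.0 / molar_mass


def gas_rates(series: BioreactorSeries,
              window: tuple[float, float] | None = None,
              inlet_y_co2: float = INLET_Y_CO2,
              inlet_y_o2: float = INLET_Y_O2) -> tuple[float, float]:
    """(q_CO2, q_O2) in mmol gCDW^-1 h^-1 from the off-gas balance.

    CER per sample = n_in · (y_CO2,out − y_CO2,in), normalized by the
    biomass inventory X·V; OUR analogously (negative = consumption).
    The inlet molar flow n_in comes from the ideal-gas law at the broth
    temperature and 1 atm.  Point-wise rates are averaged over the window.
    """
    if series.aeration <= 0:
        raise UndefinedRateError("gas rates undefined at zero aeration")
    if series.y_co2 is None or series.y_o2 is None:
        raise UndefinedRateError("series carries no off-gas channels")
    mask = series.window_mask(window)
    x = series.biomass[mask]
    if np.any(x <= 0):
        raise DomainError("non-positive biomass in gas-rate window")
    n_in = molar_gas_flow(series.aeration, series.temperature)  # mol/h
    inventory = x * series.volume                               # gCDW
    q_co2 = n_in * (series.y_co2[mask] - inlet_y_co2) * 1000.0 / inventory
    q_o2 = n_in * (series.y_o2[mask] - inlet_y_o2) * 1000.0 / inventory
    return float(np.mean(q_co2)), float(np.mean(q_o2))


def molar_gas_flow(aeration_l_h: float, temperature_c: float = 30.0) -> float:
    """Inlet gas molar flow in mol/h (ideal gas, 1 atm)."""
    return PRESSURE * (aeration_l_h / 1000.0) / (R_GAS * (temperature_c + 273.15))


@dataclass(frozen=True)
class SteadyStateReport:
    """Outcome of the chemostat steady-state check with drift statistics."""

    is_steady: bool
    biomass_drift: float
    co2_drift: float
    span_hours: float
    threshold: float


def steady_state_check(series: BioreactorSeries,
                       span_residence_times: float = 1.0,
                       threshold: float = 0.05) -> SteadyStateReport:
    """Relative drift of biomass and off-gas CO2 over ≥ span residence times.

    Drift is |trend slope| × span / mean of the signal; steady state
    requires both drifts below ``threshold`` (default 5%).
    """
    if series.dilution_rate is None or series.dilution_rate <= 0:
        raise DomainError("steady-state check needs a positive dilution rate")
    span_h = span_residence_times / series.dilution_rate
    covered = series.time[-1] - series.time[0]
    if covered + 1e-12 < span_h:
        raise InsufficientDataError(
            f"series covers {covered:.2f} h < required span {span_h:.2f} h")
    t0 = series.time[-1] - span_h
    mask = series.time >= t0 - 1e-12

    def _drift(signal: np.ndarray) -> float:
        y = signal[mask]
        mean = float(np.mean(y))
        if mean == 0:
            return 0.0
        slope, _, _ = _linregress(series.time[mask], y)
        return abs(slope) * span_h / abs(mean)

    bio = _drift(series.biomass)
    co2 = _drift(series.y_co2 - INLET_Y_CO2) if series.y_co2 is not None else 0.0
    return SteadyStateReport(is_steady=(bio < threshold and co2 < threshold),
                             biomass_drift=bio, co2_drift=co2,
                             span_hours=span_h, threshold=threshold)


# ---------------------------------------------------------------------------
# results container


@dataclass
class PhysiologyResults:
    """Per-strain physiology: µmax, Y(x/s) and signed specific rates.

    ``q`` maps compound name -> mmol gCDW^-1 h^-1 (consumption negative);
    ``q_biomass`` is in C-mmol gCDW^-1 h^-1 (µ·1000/cmol_mass by
    definition).  ``dispersion`` holds sample standard deviations across
    replicates after :func:`pool_replicates` (empty for a single fit).
    """

    mode: str
    mu_max: float
    yield_biomass: float
    q: dict[str, float]
    q_biomass: float
    cmol_mass: float
    dispersion: dict[str, float] = field(default_factory=dict)
    window: tuple[float, float] | None = None
    diagnostics: dict[str, float] = field(default_factory=dict)
    strain: str | None = None
    n_replicates: int = 1

    _ROWS = [("mu_max", "µ(max) (1/h)"),
             ("yield_biomass", "Y(x/s) (gCDW/gGlucose)"),
             ("q:glucose", "q(Glucose) (mmol/gCDW/h)"),
             ("q:ethanol", "q(EtOH) (mmol/gCDW/h)"),
             ("q:acetate", "q(Acetate) (mmol/gCDW/h)"),
             ("q:glycerol", "q(Glycerol) (mmol/gCDW/h)"),
             ("q:pyruvate", "q(Pyruvate) (mmol/gCDW/h)"),
             ("q:succinate", "q(Succinate) (mmol/gCDW/h)"),
             ("q:co2", "q(CO2) (mmol/gCDW/h)"),
             ("q_biomass", "q(Biomass) (C-mmol/gCDW/h)"),
             ("q:o2", "q(O2) (mmol/gCDW/h)")]

    def _get(self, key: str) -> float | None:
        if key.startswith("q:"):
            return self.q.get(key[2:])
        return getattr(self, key)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-column-per-statistic table of all estimated parameters."""
        rows = []
        for key, label in self._ROWS:
            value = self._get(key)
            if value is None:
                continue
            rows.append({"parameter": label, "value": value,
                         "sd": self.dispersion.get(key, np.nan)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable parameter table (mean ± sd across replicates)."""
        frame = self.to_frame()
        lines = [f"Physiology results [{self.mode}"
                 + (f", strain {self.strain}" if self.strain else "")
                 + f", n={self.n_replicates}]",
                 "-" * 52]
        for _, row in frame.iterrows():
            sd = "" if np.isnan(row["sd"]) else f" ± {row['sd']:.4g}"
            lines.append(f"{row['parameter']:<34s}{row['value']: .4g}{sd}")
        if self.window is not None:
            lines.append(f"window: {self.window[0]:.2f}–{self.window[1]:.2f} h")
        return "\n".join(lines)


def pool_replicates(results: list[PhysiologyResults]) -> PhysiologyResults:
    """Field-wise mean ± sample standard deviation (n−1) across replicates."""
    if len(results) < 2:
        raise IncompatibleReplicatesError("need ≥2 replicates to pool")
    modes = {r.mode for r in results}
    if len(modes) > 1:
        raise IncompatibleReplicatesError(f"mixed cultivation modes: {modes}")

    keys = ["mu_max", "yield_biomass", "q_biomass"] + [
        f"q:{c}" for c in results[0].q]

    def collect(key: str) -> np.ndarray:
        return np.array([r._get(key) for r in results], dtype=float)

    means = {k: float(np.mean(collect(k))) for k in keys}
    sds = {k: float(np.std(collect(k), ddof=1)) for k in keys}
    pooled_q = {k[2:]: v for k, v in means.items() if k.startswith("q:")}
    return PhysiologyResults(
        mode=results[0].mode,
        mu_max=means["mu_max"],
        yield_biomass=means["yield_biomass"],
        q=pooled_q,
        q_biomass=means["q_biomass"],
        cmol_mass=results[0].cmol_mass,
        dispersion=sds,
        strain=results[0].strain,
        n_replicates=len(results),
    )


# ---------------------------------------------------------------------------
# model classes


class BatchPhysiologyModel:
    """Black-box physiology model for an exponential-phase batch culture.

    Parameters
    ----------
    series : BioreactorSeries
        One batch cultivation.
    window : (t0, t1), optional
        Exponential window override; selected automatically otherwise.
    registry : CompoundRegistry, optional
        Compound registry supplying molar masses and the C-mol mass.
    """

    def __init__(self, series: BioreactorSeries,
                 window: tuple[float, float] | None = None,
                 registry: CompoundRegistry = DEFAULT_REGISTRY) -> None:
        if series.mode != "batch":
            raise DomainError("BatchPhysiologyModel requires a batch series")
        self.series = series
        self.window = window
        self.registry = registry

    def fit(self) -> PhysiologyResults:
        series, registry = self.series, self.registry
        mu_fit = fit_mu_max(series, self.window)
        window = mu_fit.window
        q: dict[str, float] = {}
        for compound in RATE_COMPOUNDS:
            if compound in series.concentrations:
                q[compound] = fit_specific_rate(series, compound, mu_fit.mu,
                                                window, registry)
        if series.y_co2 is not None and series.y_o2 is not None:
            q["co2"], q["o2"] = gas_rates(series, window)
        cmol = registry.biomass_composition.cmol_mass
        glc_mass = registry.compound("glucose").molar_mass
        yield_biomass = np.nan
        if q.get("glucose"):
            # Y(x/s) = dX/d(-S) = µ·1000 / (|q_glc|·M_glc)
            yield_biomass = mu_fit.mu * 1000.0 / (abs(q["glucose"]) * glc_mass)
        return PhysiologyResults(
            mode="batch",
            mu_max=mu_fit.mu,
            yield_biomass=float(yield_biomass),
            q=q,
            q_biomass=mu_fit.mu * 1000.0 / cmol,
            cmol_mass=cmol,
            window=window,
            diagnostics={"r_squared": mu_fit.r_squared,
                         "n_points": mu_fit.n_points},
            strain=series.strain,
        )


class ChemostatPhysiologyModel:
    """Steady-state physiology of a glucose-limited chemostat.

    µ equals the dilution rate D; rates follow from the steady-state
    mass balances over feed and residual concentrations, gas rates from
    the off-gas balance.  ``fit()`` refuses series that fail the
    steady-state drift check (default 5% over one residence time).
    """

    def __init__(self, series: BioreactorSeries,
                 registry: CompoundRegistry = DEFAULT_REGISTRY,
                 drift_threshold: float = 0.05,
                 require_steady_state: bool = True) -> None:
        if series.mode != "chemostat":
            raise DomainError("ChemostatPhysiologyModel requires a chemostat series")
        if series.dilution_rate is None or series.dilution_rate <= 0:
            raise DomainError("chemostat series needs a positive dilution rate")
        self.series = series
        self.registry = registry
        self.drift_threshold = drift_threshold
        self.require_steady_state = require_steady_state

    def fit(self) -> PhysiologyResults:
        series, registry = self.series, self.registry
        report = steady_state_check(series, threshold=self.drift_threshold)
        if self.require_steady_state and not report.is_steady:
            raise SteadyStateError(
                f"not at steady state: biomass drift {report.biomass_drift:.3f}, "
                f"CO2 drift {report.co2_drift:.3f} (threshold {report.threshold})")
        d = float(series.dilution_rate)
        x = float(np.mean(series.biomass))
        s_feed = series.feed.get("glucose", 0.0)
        if "glucose" in series.concentrations:
            s_res = float(np.mean(series.concentration("glucose")))
        else:
            logger.warning("no residual-glucose channel; assuming 0 g/L "
                           "(glucose-limited)")
            s_res = 0.0
        glc_mass = registry.compound("glucose").molar_mass
        consumed = s_feed - s_res
        q = {"glucose": -d * consumed * 1000.0 / (glc_mass * x)}
        for compound in RATE_COMPOUNDS[1:]:
            if compound in series.concentrations:
                conc = float(np.mean(series.concentration(compound)))
                mass = registry.compound(compound).molar_mass
                q[compound] = d * conc * 1000.0 / (mass * x)
        if series.y_co2 is not None and series.y_o2 is not None:
            q["co2"], q["o2"] = gas_rates(series)
        cmol = registry.biomass_composition.cmol_mass
        return PhysiologyResults(
            mode="chemostat",
            mu_max=d,
            yield_biomass=x / consumed if consumed > 0 else 0.0,
            q=q,
            q_biomass=d * 1000.0 / cmol,
            cmol_mass=cmol,
            diagnostics={"biomass_drift": report.biomass_drift,
                         "co2_drift": report.co2_drift,
                         "residual_glucose": s_res},
            strain=series.strain,
        )


def chemostat_rates(series: BioreactorSeries,
                    registry: CompoundRegistry = DEFAULT_REGISTRY,
                    **kwargs) -> PhysiologyResults:
    """Functional wrapper around :class:`ChemostatPhysiologyModel`."""
    return ChemostatPhysiologyModel(series, registry, **kwargs).fit()
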