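"""C-mol flux accounting: normalized flux maps, balance closure, respiration.

Converts a :class:`~physioflux.rate_estimation.PhysiologyResults` into a
carbon-flux map in which every flux is expressed as a percentage of the
glucose-uptake carbon flux (glucose ≡ 100%), computes the carbon-balance
closure (percentage of substrate carbon recovered in all measured
products plus biomass), and partitions total CO2 production into a
fermentative part (released by pyruvate decarboxylase alongside ethanol,
i.e. half the C-mol flux of ethanol) and a respiratory remainder.

This is black-box accounting over extracellular rates only — no
metabolic-network flux estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import IncompleteBalanceError, NormalizationError
from .rate_estimation import PhysiologyResults
from .stoichiometry import DEFAULT_REGISTRY, CompoundRegistry

logger = logging.getLogger(__name__)

#: carbon-containing output species entering the balance
OUTPUT_COMPOUNDS = ("co2", "ethanol", "acetate", "glycerol",
                    "pyruvate", "succinate")

#: rendering threshold — fluxes below this are hidden in diagrams only,
#: never dropped from the data
DISPLAY_THRESHOLD_PCT = 0.1

#: closures outside this band trigger a warning
BALANCE_WARN_BAND = (90.0, 110.0)


@dataclass
class FluxMap:
    """Normalized C-mol flux distribution of one strain/condition.

    ``normalized`` maps compound -> % of glucose-uptake carbon (glucose
    itself ≡ 100); ``absolute`` maps compound -> C-mmol gCDW^-1 h^-1
    (magnitudes for outputs, glucose as uptake magnitude).
    """

    normalized: dict[str, float]
    absolute: dict[str, float]
    balance_closure: float
    respiration_fraction: float | None = None
    strain: str | None = None
    mode: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"compound": name,
                 "cmol_flux": self.absolute[name],
                 "percent_of_glucose_c": pct}
                for name, pct in self.normalized.items()]
        return pd.DataFrame(rows)

    def to_edge_list(self, threshold: float = DISPLAY_THRESHOLD_PCT
                     ) -> list[tuple[str, str, float]]:
        """(source, sink, percent) edges for diagram rendering.

        Fluxes below ``threshold`` percent are suppressed here only
        (display convention); the map itself always retains them.
        """
        edges = [("medium", "glucose", 100.0)]
        for name, pct in self.normalized.items():
            if name != "glucose" and pct >= threshold:
                edges.append(("glucose", name, round(pct, 2)))
        return edges


def _cmol_outputs(result: PhysiologyResults,
                  registry: CompoundRegistry) -> dict[str, float]:
    """Output C-mol fluxes (magnitudes), incl. biomass, C-mmol/gCDW/h."""
    out = {}
    for name in OUTPUT_COMPOUNDS:
        if name in result.q:
            carbon = registry.compound(name).carbon_number
            out[name] = abs(result.q[name]) * carbon
    out["biomass"] = abs(result.q_biomass)   # already C-mmol
    return out


def normalize_fluxes(result: PhysiologyResults,
                     registry: CompoundRegistry = DEFAULT_REGISTRY) -> FluxMap:
    """Express every flux as % of the glucose-uptake carbon flux.

    normalized_i = 100 · |q_i| · C_i / (|q_glc| · 6); biomass uses
    q_biomass directly (already carbon-molar).  Raises
    :class:`NormalizationError` when glucose uptake is zero.
    """
    q_glc = result.q.get("glucose", 0.0)
    if q_glc == 0.0:
        raise NormalizationError("cannot normalize: glucose uptake is zero")
    glc_carbon = registry.compound("glucose").carbon_number
    denom = abs(q_glc) * glc_carbon
    absolute = _cmol_outputs(result, registry)
    normalized = {name: 100.0 * flux / denom for name, flux in absolute.items()}
    absolute["glucose"] = denom
    normalized["glucose"] = 100.0
    closure = carbon_balance(result, registry)
    fmap = FluxMap(normalized=normalized, absolute=absolute,
                   balance_closure=closure,
                   strain=result.strain, mode=result.mode)
    resp = respiration_partition(fmap, result, registry)
    fmap.respiration_fraction = resp[1]
    return fmap


def carbon_balance(result: PhysiologyResults,
                   registry: CompoundRegistry = DEFAULT_REGISTRY) -> float:
    """Carbon-balance closure in percent.

    closure = 100 · Σ_out(C-mmol fluxes of CO2, ethanol, acetate,
    glycerol, pyruvate, succinate, biomass) / (6 · |q_glc|), assuming
    glucose is the sole carbon source (minimal medium).  CO2 and biomass
    dominate the balance, so their absence is an error rather than a
    silently low closure.
    """
    if "co2" not in result.q:
        raise IncompleteBalanceError("carbon balance needs a CO2 rate")
    q_glc = result.q.get("glucose", 0.0)
    if q_glc == 0.0:
        raise NormalizationError("carbon balance undefined at zero glucose uptake")
    outputs = _cmol_outputs(result, registry)
    denom = abs(q_glc) * registry.compound("glucose").carbon_number
    closure = 100.0 * sum(outputs.values()) / denom
    lo, hi = BALANCE_WARN_BAND
    if not lo <= closure <= hi:
        logger.warning("carbon balance closure %.1f%% outside [%g%%, %g%%]",
                       closure, lo, hi)
    return closure


def carbon_balance_sd(result: PhysiologyResults,
                      registry: CompoundRegistry = DEFAULT_REGISTRY) -> float:
    """First-order propagated standard deviation of the balance closure.

    Optional companion to :func:`carbon_balance`: propagates the
    replicate standard deviations in ``result.dispersion`` through
    closure = 100·Σ cᵢ|qᵢ| / (6·|q_glc|), treating the rates as
    independent.  Rates without a recorded dispersion contribute zero.
    """
    closure = carbon_balance(result, registry)
    denom = abs(result.q["glucose"]) * registry.compound("glucose").carbon_number
    var = 0.0
    for name in (*OUTPUT_COMPOUNDS, "biomass"):
        sd = result.dispersion.get("q_biomass" if name == "biomass"
                                   else f"q:{name}", 0.0)
        carbon = 1.0 if name == "biomass" else \
            registry.compound(name).carbon_number
        if name == "biomass" or name in result.q:
            var += (100.0 * carbon * sd / denom) ** 2
    sd_glc = result.dispersion.get("q:glucose", 0.0)
    var += (closure * sd_glc / abs(result.q["glucose"])) ** 2
    return var**0.5


def respiration_partition(fluxmap: FluxMap, result: PhysiologyResults,
                          registry: CompoundRegistry = DEFAULT_REGISTRY
                          ) -> tuple[float, float]:
    """Split total CO2 into fermentative and respiratory carbon.

    Pyruvate decarboxylation releases one CO2 per ethanol, i.e. half the
    C-mol flux of ethanol; the remainder of the CO2 flux is attributed
    to respiration:

        respiratory_CO2 = q_CO2(C-mol) − 0.5 · q_EtOH(C-mol)

    Returns ``(respiratory_CO2 [C-mmol/gCDW/h], fraction [% of glucose C])``.
    A negative respiratory flux signals inconsistent inputs and is
    returned with a warning rather than raised.
    """
    if "co2" not in result.q:
        raise IncompleteBalanceError("respiration partition needs a CO2 rate")
    co2_cmol = abs(result.q["co2"]) * registry.compound("co2").carbon_number
    etoh_cmol = abs(result.q.get("ethanol", 0.0)) * \
        registry.compound("ethanol").carbon_number
    respiratory = co2_cmol - 0.5 * etoh_cmol
    if respiratory < 0:
        logger.warning("ethanol-derived CO2 exceeds total CO2 flux "
                       "(respiratory flux %.3g < 0): inconsistent inputs",
                       respiratory)
    q_glc = result.q.get("glucose", 0.0)
    if q_glc == 0.0:
        raise NormalizationError("respiration fraction undefined at zero uptake")
    denom = abs(q_glc) * registry.compound("glucose").carbon_number
    return respiratory, 100.0 * respiratory / denom


def flux_difference(map_a: FluxMap, map_b: FluxMap, compound: str) -> float:
    """Percentage-point difference of one normalized flux between two maps."""
    try:
        return map_a.normalized[compound] - map_b.normalized[compound]
    except KeyError as exc:
        raise KeyError(f"compound {exc.args[0]!r} missing from a flux map") from None
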