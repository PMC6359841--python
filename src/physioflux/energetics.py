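"""Weak-acid speciation, ATP route ledgers and the two-substrate mixing model.

Three small quantitative tools around acetate overflow energetics:

* **Acid speciation** — the Henderson–Hasselbalch undissociated fraction
  of a monoprotic weak acid (acetic acid, pKa 4.76).  Only the neutral
  HA form crosses the membrane passively, so this fraction controls the
  proton-decoupling futile cycle.
* **ATP route ledgers** — net ATP cost per mole of acetate assimilated,
  for acetate made via lower glycolysis (native overflow: +1 ATP earned
  upstream, 2 spent on Acs activation, net 1) versus acetate made via
  phosphoketolase + acetyl-phosphate hydrolysis (upstream ATP bypassed,
  net 2); the phosphotransacetylase route skips activation entirely
  (net 0).  ATP→AMP counts as 2 ATP equivalents.
* **Mixing model** — treats an observed steady-state gas flux as a
  linear combination of reference fluxes under pure glucose and pure
  acetate limitation, and solves for the acetate-derived carbon
  fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import RegistryError, SingularModelError

DEFAULT_PKA_ACETIC = 4.76


@dataclass(frozen=True)
class AcidSpec:
    """Speciation of a monoprotic weak acid at a given pH."""

    pH: float
    pKa: float
    fraction_ha: float


@dataclass(frozen=True)
class RouteLedger:
    """Net ATP accounting of one acetate-to-acetyl-CoA route, per mole acetate."""

    route: str
    atp_generated_upstream: float
    atp_cost_activation: float

    @property
    def net_cost(self) -> float:
        return self.atp_cost_activation - self.atp_generated_upstream


#: registered acetate routes: (upstream ATP generated, activation ATP cost)
_ROUTES = {
    # lower glycolysis to pyruvate earns 1 ATP per acetate-equivalent;
    # Acs activation spends 2 (ATP -> AMP)
    "native": (1.0, 2.0),
    # phosphoketolase bypasses the ATP-generating half of glycolysis
    "xfpk": (0.0, 2.0),
    # phosphotransacetylase converts acetyl-P to acetyl-CoA directly
    "pta": (0.0, 0.0),
}


@dataclass(frozen=True)
class MixingModel:
    """Two-substrate linear gas-flux mixing model.

    ``q_ref_glucose`` and ``q_ref_acetate`` are the reference specific
    gas fluxes (mmol gCDW^-1 h^-1) under pure glucose and pure acetate
    limitation; ``q_observed`` is the measured flux to be decomposed.
    """

    q_ref_glucose: float
    q_ref_acetate: float
    q_observed: float


@dataclass(frozen=True)
class MixingSolution:
    fraction_acetate: float
    extrapolated: bool


def acid_speciation(pH: float, pKa: float = DEFAULT_PKA_ACETIC) -> float:
    """Undissociated (HA) fraction of a monoprotic weak acid.

    Henderson–Hasselbalch: fraction_HA = 1 / (1 + 10^(pH − pKa)).
    Total function of finite pH, pKa; equals 0.5 exactly at pH = pKa.
    """
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def atp_cost(route: str) -> RouteLedger:
    """ATP ledger for a registered acetate route ('native', 'xfpk', 'pta')."""
    try:
        upstream, activation = _ROUTES[route]
    except KeyError:
        raise RegistryError(
            f"unknown route {route!r}; known: {sorted(_ROUTES)}") from None
    return RouteLedger(route=route, atp_generated_upstream=upstream,
                       atp_cost_activation=activation)


def solve_mixing(model: MixingModel) -> MixingSolution:
    """Acetate-derived flux fraction y solving q_g·(1−y) + q_a·y = q_obs.

    Flags the solution as extrapolated when y falls outside [0, 1]
    (the observation is not bracketed by the references).
    """
    denom = model.q_ref_acetate - model.q_ref_glucose
    if denom == 0:
        raise SingularModelError(
            "reference fluxes are equal; mixing fraction is undetermined")
    y = (model.q_observed - model.q_ref_glucose) / denom
    return MixingSolution(fraction_acetate=y, extrapolated=not 0.0 <= y <= 1.0)


def mix(model_refs: tuple[float, float], y: float) -> float:
    """Forward mixing: gas flux of a glucose/acetate mixture with acetate share y."""
    q_g, q_a = model_refs
    return q_g * (1.0 - y) + q_a * y


def decoupling_atp_demand(q_acetate_leak: float, pH: float,
                          pKa: float = DEFAULT_PKA_ACETIC,
                          cost_per_cycle: float = 1.0) -> float:
    """ATP drain of the acetate proton-decoupling futile cycle.

    A minimal, transparent model (not a measured quantity): of the
    acetate leaked at ``q_acetate_leak`` (mmol gCDW^-1 h^-1), the
    undissociated fraction at the extracellular pH re-enters the cell,
    dissociates at cytosolic pH, and costs ``cost_per_cycle`` ATP
    equivalents per turn to re-export proton and anion:

        ATP flux = q_leak · fraction_HA(pH, pKa) · cost_per_cycle
    """
    if q_acetate_leak < 0 or cost_per_cycle < 0:
        raise ValueError("leak rate and cycle cost must be non-negative")
    return q_acetate_leak * acid_speciation(pH, pKa) * cost_per_cycle


def ledger_table() -> str:
    """Formatted ATP ledger of all registered routes."""
    lines = [f"{'route':<8s}{'upstream ATP':>14s}{'activation ATP':>16s}"
             f"{'net cost':>10s}",
             "-" * 48]
    for route in _ROUTES:
        led = atp_cost(route)
        lines.append(f"{route:<8s}{led.atp_generated_upstream:>14.0f}"
                     f"{led.atp_cost_activation:>16.0f}{led.net_cost:>10.0f}")
    return "\n".join(lines)
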