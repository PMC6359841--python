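"""Compounds, biomass composition and reaction stoichiometry.

Single source of truth for elemental compositions, carbon numbers, molar
masses and degrees of reduction of every species entering the black-box
carbon balance, plus the phosphoketolase-route reaction stoichiometries
used by the energetics ledgers.

Conventions
-----------
* Specific rates are signed: consumption negative, production positive.
* Biomass is a pseudo-compound of one carbon per formula unit
  (CH:math:`_{1.8}`\\ O\\ :math:`_{0.5}`\\ N\\ :math:`_{0.2}` by default),
  so its molar mass *is* the C-mol mass; ash is ignored.
* Formulas carry C/H/O/N atom counts only.  Phosphorylated intracellular
  intermediates (X5P, F6P, AcP, ...) are registered with their CHON
  content for carbon-balance checks of reactions; their molar masses
  (which omit the phosphate moiety) are never used for extracellular
  gram/mole conversions.  Acetyl-CoA counts the acetyl carbons only; the
  CoA thioester carrier is treated as a carbon-free cofactor, like Pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import InvalidCompositionError, RegistryError

# IUPAC 2021 standard atomic weights, fixed so results are bit-stable.
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


@dataclass(frozen=True)
class Compound:
    """A chemical species with its elemental composition.

    Parameters
    ----------
    name : str
        Registry identifier, lower case (``"glucose"``, ``"co2"``, ...).
    formula : mapping
        Atom counts for C/H/O/N.  Fractional counts are allowed (biomass).
    """

    name: str
    formula: Mapping[str, float]

    @property
    def carbon_number(self) -> float:
        return float(self.formula.get("C", 0.0))

    @property
    def molar_mass(self) -> float:
        """Formula weight in g/mol from the fixed atomic masses."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.formula.items())

    @property
    def degree_of_reduction(self) -> float | None:
        """Electrons per C-mol (4C + H - 2O - 3N over C); None if carbon-free.

        Nitrogen is referenced to ammonia, the nitrogen source in the
        minimal medium, giving biomass CH1.8O0.5N0.2 a value of 4.2.
        """
        c = self.carbon_number
        if c == 0:
            return None
        electrons = (
            4.0 * c
            + self.formula.get("H", 0.0)
            - 2.0 * self.formula.get("O", 0.0)
            - 3.0 * self.formula.get("N", 0.0)
        )
        return electrons / c


@dataclass(frozen=True)
class BiomassComposition:
    """Elemental biomass composition CH_h O_o N_n per carbon.

    Defaults to the standard yeast composition CH1.8O0.5N0.2.  The C-mol
    mass is always computed from the indices, never hard-coded; it is
    ash-free (no ash fraction is modelled).
    """

    h_per_c: float = 1.8
    o_per_c: float = 0.5
    n_per_c: float = 0.2

    def __post_init__(self) -> None:
        for label, v in (("h_per_c", self.h_per_c),
                         ("o_per_c", self.o_per_c),
                         ("n_per_c", self.n_per_c)):
            if v < 0:
                raise InvalidCompositionError(
                    f"{label} must be >= 0, got {v}")

    @property
    def cmol_mass(self) -> float:
        """Grams per C-mol of ash-free biomass."""
        return (ATOMIC_MASS["C"]
                + self.h_per_c * ATOMIC_MASS["H"]
                + self.o_per_c * ATOMIC_MASS["O"]
                + self.n_per_c * ATOMIC_MASS["N"])

    def as_compound(self) -> Compound:
        """Biomass as a one-carbon pseudo-compound."""
        return Compound("biomass", {"C": 1.0, "H": self.h_per_c,
                                    "O": self.o_per_c, "N": self.n_per_c})


def cmol_mass(composition: BiomassComposition) -> float:
    """Formula weight per carbon of a biomass composition, g per C-mol."""
    return composition.cmol_mass


def _default_compounds() -> dict[str, Compound]:
    specs: dict[str, dict[str, float]] = {
        # extracellular balance species
        "glucose":   {"C": 6, "H": 12, "O": 6},
        "ethanol":   {"C": 2, "H": 6, "O": 1},
        "acetate":   {"C": 2, "H": 4, "O": 2},      # as acetic acid
        "glycerol":  {"C": 3, "H": 8, "O": 3},
        "pyruvate":  {"C": 3, "H": 4, "O": 3},      # as pyruvic acid
        "succinate": {"C": 4, "H": 6, "O": 4},      # as succinic acid
        "co2":       {"C": 1, "O": 2},
        "o2":        {"O": 2},
        # intracellular reaction species (CHON content, phosphate omitted)
        "x5p":        {"C": 5, "H": 11, "O": 8},
        "f6p":        {"C": 6, "H": 13, "O": 9},
        "gap":        {"C": 3, "H": 7, "O": 6},
        "e4p":        {"C": 4, "H": 9, "O": 7},
        "acetyl_p":   {"C": 2, "H": 5, "O": 5},
        "acetyl_coa": {"C": 2, "H": 3, "O": 1},     # acetyl moiety only
        "pi":         {"H": 3, "O": 4},
        "coa":        {},                            # carrier, carbon-free here
    }
    table = {name: Compound(name, formula) for name, formula in specs.items()}
    table["biomass"] = BiomassComposition().as_compound()
    return table


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction over registered compounds.

    ``stoichiometry`` maps compound name -> signed coefficient
    (substrates negative, products positive).  ``atp_net`` counts net ATP
    equivalents per formula turnover with ATP->ADP = 1 and ATP->AMP = 2.
    """

    name: str
    stoichiometry: Mapping[str, float]
    atp_net: float = 0.0


class CompoundRegistry:
    """Mutable registry of compounds and reactions with sensible defaults.

    Users can register additional species (e.g. lactate) or override a
    formula; the defaults cover everything the carbon balance and the
    phosphoketolase-route ledgers need.
    """

    def __init__(self, biomass: BiomassComposition | None = None) -> None:
        self.biomass_composition = biomass or BiomassComposition()
        self._compounds = _default_compounds()
        self._compounds["biomass"] = self.biomass_composition.as_compound()
        self._reactions: dict[str, Reaction] = {}
        for rxn in _default_reactions():
            self.register_reaction(rxn)

    def __contains__(self, name: str) -> bool:
        return name in self._compounds

    def compound(self, name: str) -> Compound:
        try:
            return self._compounds[name]
        except KeyError:
            raise RegistryError(f"unknown compound {name!r}") from None

    def register(self, compound: Compound) -> None:
        self._compounds[compound.name] = compound

    def reaction(self, name: str) -> Reaction:
        try:
            return self._reactions[name]
        except KeyError:
            raise RegistryError(f"unknown reaction {name!r}") from None

    @property
    def reactions(self) -> dict[str, Reaction]:
        return dict(self._reactions)

    def register_reaction(self, reaction: Reaction) -> None:
        for name in reaction.stoichiometry:
            self.compound(name)  # raises RegistryError if unknown
        self._reactions[reaction.name] = reaction

    def to_config(self) -> dict:
        """Serializable registry content (names -> formulas), for configs."""
        return {
            "biomass": {"h_per_c": self.biomass_composition.h_per_c,
                        "o_per_c": self.biomass_composition.o_per_c,
                        "n_per_c": self.biomass_composition.n_per_c},
            "compounds": {c.name: dict(c.formula)
                          for c in self._compounds.values()},
        }

    @classmethod
    def from_config(cls, config: Mapping) -> "CompoundRegistry":
        bm = config.get("biomass", {})
        reg = cls(BiomassComposition(**bm) if bm else None)
        for name, formula in config.get("compounds", {}).items():
            if name != "biomass":
                reg.register(Compound(name, dict(formula)))
        return reg


def _default_reactions() -> list[Reaction]:
    """Phosphoketolase-route stoichiometries plus the native acetate route.

    ``glycolysis_lower`` lumps the ATP-generating half of glycolysis from
    half a glucose to one pyruvate-equivalent (+1 ATP); the xfpk reactions
    bypass it, which is what makes the acetate they feed energetically
    more expensive to re-assimilate.
    """
    return [
        Reaction("xfpk_x5p", {"x5p": -1, "pi": -1, "gap": 1, "acetyl_p": 1}),
        Reaction("xfpk_f6p", {"f6p": -1, "pi": -1, "e4p": 1, "acetyl_p": 1}),
        Reaction("pta", {"acetyl_p": -1, "coa": -1, "acetyl_coa": 1, "pi": 1}),
        Reaction("acp_hydrolysis", {"acetyl_p": -1, "acetate": 1, "pi": 1}),
        # Acs: acetate + CoA + ATP -> acetyl-CoA + AMP + PPi  (ATP->AMP = 2)
        Reaction("acs", {"acetate": -1, "coa": -1, "acetyl_coa": 1},
                 atp_net=-2.0),
        # lumped lower glycolysis: 0.5 glucose -> pyruvate, +1 ATP
        Reaction("glycolysis_lower", {"glucose": -0.5, "pyruvate": 1},
                 atp_net=+1.0),
    ]


DEFAULT_REGISTRY = CompoundRegistry()


def to_cmol_flux(q: float, compound: Compound | str,
                 registry: CompoundRegistry = DEFAULT_REGISTRY) -> float:
    """Convert a molar specific rate to a carbon-molar one.

    Parameters
    ----------
    q : float
        Specific rate in mmol gCDW^-1 h^-1, signed (consumption < 0).
    compound : Compound or registered name

    Returns
    -------
    float
        q x carbon_number, in C-mmol gCDW^-1 h^-1; sign preserved.
    """
    if isinstance(compound, str):
        compound = registry.compound(compound)
    return q * compound.carbon_number


def reaction_carbon_check(reaction: Reaction,
                          registry: CompoundRegistry = DEFAULT_REGISTRY,
                          tol: float = 1e-9) -> bool:
    """True iff the signed carbon sum of the reaction is zero."""
    total = sum(coeff * registry.compound(name).carbon_number
                for name, coeff in reaction.stoichiometry.items())
    return abs(total) <= tol
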