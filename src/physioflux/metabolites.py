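"""Sugar-phosphate panel statistics: fold-changes, Welch tests, equilibria.

Compares replicate metabolite pool sizes of a test strain against a
control: per-metabolite fold-change as percent of control (ratio of
arithmetic replicate means), a two-sided Welch t-test (unequal
variances, Welch–Satterthwaite degrees of freedom) with significance
tiers * (p < 0.05) and ** (p < 0.001), and thermodynamic-equilibrium
consistency checks (required fold-change of an unmeasured species under
a mass-action equilibrium constant; triose-phosphate isomerase
DHAP:GAP ratio against its literature equilibrium value of ~20).

No multiple-testing correction is applied by default (raw per-metabolite
tests, mirroring classical panel reporting); an optional
Benjamini–Hochberg adjustment is available on the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    UndefinedFoldChangeError,
    UnderdeterminedError,
)

#: the measured sugar-phosphate roster (acetyl-phosphate is not
#: quantifiable with the panel method and is deliberately absent)
DEFAULT_ROSTER = ("G1P", "G6P", "F6P", "DHAP", "GAP", "3PGA", "2PGA",
                  "Ru5P", "R5P", "X5P", "E4P", "S7P")

TPI_EQUILIBRIUM_RATIO = 20.0   # literature DHAP:GAP equilibrium, ~1:20 for GAP


@dataclass
class MetabolitePanel:
    """Replicate metabolite pool sizes for one strain.

    ``values`` is a DataFrame with one row per replicate and one column
    per metabolite, in any consistent per-CDW unit.  All pools must be
    positive; at least two replicates are needed for testing (the
    reference design uses four).
    """

    strain: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("all pool sizes must be positive")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_replicates(self) -> int:
        return len(self.values)

    def mean(self, metabolite: str) -> float:
        return float(self.values[metabolite].mean())


def fold_changes(test: MetabolitePanel, control: MetabolitePanel
                 ) -> dict[str, float]:
    """Per-metabolite pool size of the test strain as percent of control.

    100 × mean(test) / mean(control), on arithmetic replicate means,
    over the shared metabolite roster.
    """
    shared = [m for m in control.metabolites if m in test.metabolites]
    out = {}
    for met in shared:
        denom = control.mean(met)
        if denom == 0:
            raise UndefinedFoldChangeError(f"zero control mean for {met}")
        out[met] = 100.0 * test.mean(met) / denom
    return out


def significance_tier(p_value: float) -> str:
    """Asterisk tier: '**' for p<0.001, '*' for p<0.05, '' otherwise."""
    if p_value < 0.001:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def welch_test(test: np.ndarray, control: np.ndarray) -> tuple[float, str]:
    """Two-sided Welch t-test p-value and its significance tier.

    Unequal variances assumed; Welch–Satterthwaite degrees of freedom.
    Two identical groups (zero pooled variance) give p = 1 by convention.
    """
    a = np.asarray(test, dtype=float)
    b = np.asarray(control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("Welch test needs ≥2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return p, significance_tier(p)
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, significance_tier(p)


@dataclass(frozen=True)
class FoldChangeRow:
    metabolite: str
    fold_change_pct: float
    p_value: float
    tier: str


@dataclass
class FoldChangeResults:
    """Fold-change table of a test-vs-control panel comparison."""

    rows: list[FoldChangeRow]
    test_strain: str
    control_strain: str
    adjusted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def __getitem__(self, metabolite: str) -> FoldChangeRow:
        for row in self.rows:
            if row.metabolite == metabolite:
                return row
        raise KeyError(metabolite)

    def summary(self) -> str:
        lines = [f"Fold changes: {self.test_strain} vs {self.control_strain} "
                 f"(% of control; Welch two-sided"
                 + (", BH-adjusted)" if self.adjusted else ")"),
                 f"{'metabolite':<12s}{'% control':>10s}{'p':>12s}  tier",
                 "-" * 42]
        for r in self.rows:
            lines.append(f"{r.metabolite:<12s}{r.fold_change_pct:>10.1f}"
                         f"{r.p_value:>12.2e}  {r.tier}")
        return "\n".join(lines)


class FoldChangeModel:
    """Panel comparison model: fold-changes with Welch significance tiers.

    Parameters
    ----------
    test, control : MetabolitePanel
    adjust : bool
        Apply Benjamini–Hochberg FDR adjustment to the p-values before
        tier assignment (off by default; the classical panel report uses
        raw per-metabolite tests).
    """

    def __init__(self, test: MetabolitePanel, control: MetabolitePanel,
                 adjust: bool = False) -> None:
        self.test = test
        self.control = control
        self.adjust = adjust

    def fit(self) -> FoldChangeResults:
        fc = fold_changes(self.test, self.control)
        mets = list(fc)
        pvals = []
        for met in mets:
            p, _ = welch_test(self.test.values[met].to_numpy(),
                              self.control.values[met].to_numpy())
            pvals.append(p)
        if self.adjust:
            pvals = list(_benjamini_hochberg(np.array(pvals)))
        rows = [FoldChangeRow(met, fc[met], p, significance_tier(p))
                for met, p in zip(mets, pvals)]
        return FoldChangeResults(rows=rows, test_strain=self.test.strain,
                                 control_strain=self.control.strain,
                                 adjusted=self.adjust)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass(frozen=True)
class EquilibriumCheck:
    """A mass-action equilibrium relation K = Π[products] / Π[reactants].

    Used to ask what fold-change an unmeasured species would need for
    the equilibrium state to be maintained when the measured species
    shift.  Species appearing with stoichiometry > 1 are listed that
    many times.
    """

    name: str
    products: tuple[str, ...]
    reactants: tuple[str, ...]


#: fructose-1,6-bisphosphate aldolase: K = [DHAP][GAP] / [F-1,6-BP]
FBA_EQUILIBRIUM = EquilibriumCheck("aldolase", products=("DHAP", "GAP"),
                                   reactants=("F16BP",))


def equilibrium_required_foldchange(measured: dict[str, float],
                                    relation: EquilibriumCheck = FBA_EQUILIBRIUM
                                    ) -> float:
    """Fold-change of the single unmeasured species that keeps K invariant.

    For K = Π(products)/Π(reactants), K is unchanged iff
    Π(product fold-changes) = Π(reactant fold-changes); the equation is
    solved for the one species absent from ``measured``.  More than one
    unknown raises :class:`UnderdeterminedError`.
    """
    for name, f in measured.items():
        if f <= 0:
            raise ValueError(f"fold-change of {name} must be positive, got {f}")
    unknowns = [s for s in relation.products + relation.reactants
                if s not in measured]
    if len(set(unknowns)) != 1:
        raise UnderdeterminedError(
            f"relation {relation.name!r} has unknowns {sorted(set(unknowns))}; "
            "exactly one unmeasured species is required")
    unknown = unknowns[0]
    prod = math.prod(measured[s] for s in relation.products if s != unknown)
    reac = math.prod(measured[s] for s in relation.reactants if s != unknown)
    power = unknowns.count(unknown)
    if unknown in relation.products:
        return (reac / prod) ** (1.0 / power)
    return (prod / reac) ** (1.0 / power)


def tpi_ratio_check(dhap: float, gap: float,
                    equilibrium_ratio: float = TPI_EQUILIBRIUM_RATIO
                    ) -> tuple[float, float]:
    """Observed DHAP:GAP ratio and its log2 deviation from equilibrium.

    Triose-phosphate isomerase equilibrates DHAP and GAP at roughly
    20:1 in favour of DHAP.  Returns ``(ratio, log2(ratio/equilibrium))``;
    a deviation of 0 means the pools sit at the literature equilibrium.
    """
    if dhap <= 0 or gap <= 0:
        raise ValueError("pools must be positive")
    ratio = dhap / gap
    return ratio, math.log2(ratio / equilibrium_ratio)
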