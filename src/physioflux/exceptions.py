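"""Exception hierarchy.

Every error raised by this package derives from :class:`PhysiofluxError`,
so callers can catch one base class at pipeline level while tests can
assert on the specific failure mode.
"""


class PhysiofluxError(Exception):
    """Base class for all physioflux errors."""


class InvalidCompositionError(PhysiofluxError, ValueError):
    """A biomass elemental composition index is out of range."""


class RegistryError(PhysiofluxError, KeyError):
    """A compound, reaction or route name is not registered."""


class InsufficientDataError(PhysiofluxError, ValueError):
    """Too few observations for the requested estimate."""


class DomainError(PhysiofluxError, ValueError):
    """Input values outside the mathematical domain of an estimator."""


class MissingChannelError(PhysiofluxError, KeyError):
    """A required measurement channel is absent from a series."""


class UndefinedRateError(PhysiofluxError, ValueError):
    """A rate is undefined for the given operating conditions (e.g. no gas flow)."""


class SteadyStateError(PhysiofluxError, ValueError):
    """A chemostat series failed the steady-state check."""


class IncompatibleReplicatesError(PhysiofluxError, ValueError):
    """Replicates cannot be pooled (mixed modes or too few)."""


class NormalizationError(PhysiofluxError, ZeroDivisionError):
    """Flux normalization impossible (zero glucose uptake)."""


class IncompleteBalanceError(PhysiofluxError, KeyError):
    """A carbon balance is missing a dominant term (CO2 or biomass)."""


class SingularModelError(PhysiofluxError, ValueError):
    """The two-substrate mixing model is singular (equal reference fluxes)."""


class UnderdeterminedError(PhysiofluxError, ValueError):
    """An equilibrium relation has more than one unknown species."""


class UndefinedFoldChangeError(PhysiofluxError, ZeroDivisionError):
    """Fold change undefined (zero control mean)."""


class InvalidScenarioError(PhysiofluxError, ValueError):
    """A synthetic-data scenario violates its parameter constraints."""


class SchemaError(PhysiofluxError, ValueError):
    """An input file violates the documented CSV schema."""
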