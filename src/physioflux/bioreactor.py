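"""In-memory container for one bioreactor cultivation time-series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, MissingChannelError

#: expected unit per channel in the long-format CSV schema
CHANNEL_UNITS = {
    "biomass": "gCDW/L",
    "glucose": "g/L",
    "ethanol": "g/L",
    "acetate": "g/L",
    "glycerol": "g/L",
    "pyruvate": "g/L",
    "succinate": "g/L",
    "y_co2": "mol_fraction",
    "y_o2": "mol_fraction",
}


@dataclass
class BioreactorSeries:
    """Time-resolved liquid- and gas-phase measurements of one cultivation.

    Attributes
    ----------
    mode : {"batch", "chemostat"}
    time : array, h — strictly increasing sampling times.
    biomass : array, gCDW L^-1 (multiply OD600 by ``od_to_cdw`` upstream).
    concentrations : dict of compound name -> array, g L^-1.
    y_co2, y_o2 : arrays, off-gas mole fractions (None if no gas analysis).
    aeration : L h^-1 inlet gas flow; volume : L working volume.
    temperature : °C broth temperature, used in the ideal-gas molar flow.
    dilution_rate : h^-1 (chemostat only); feed : dict compound -> g L^-1.
    """

    mode: str
    time: np.ndarray
    biomass: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    y_co2: np.ndarray | None = None
    y_o2: np.ndarray | None = None
    aeration: float = 36.0
    volume: float = 0.6
    temperature: float = 30.0
    ph: float | None = None
    replicate_id: str | None = None
    strain: str | None = None
    dilution_rate: float | None = None
    feed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.mode not in ("batch", "chemostat"):
            raise DomainError(f"mode must be batch or chemostat, got {self.mode!r}")
        if self.time.ndim != 1 or len(self.time) != len(self.biomass):
            raise DomainError("time and biomass must be 1-d and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")
        if self.volume <= 0:
            raise DomainError("volume must be positive")
        if self.aeration < 0:
            raise DomainError("aeration must be non-negative")
        if np.any(self.biomass < 0):
            raise DomainError("biomass must be non-negative")
        self.concentrations = {k: np.asarray(v, dtype=float)
                               for k, v in self.concentrations.items()}
        for name, arr in self.concentrations.items():
            if len(arr) != len(self.time):
                raise DomainError(f"channel {name!r} length mismatch")
        for attr in ("y_co2", "y_o2"):
            val = getattr(self, attr)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if len(arr) != len(self.time):
                    raise DomainError(f"channel {attr!r} length mismatch")
                setattr(self, attr, arr)

    def concentration(self, compound: str) -> np.ndarray:
        try:
            return self.concentrations[compound]
        except KeyError:
            raise MissingChannelError(
                f"series has no concentration channel {compound!r}") from None

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        """Boolean mask selecting samples inside [t0, t1] (inclusive)."""
        if window is None:
            return np.ones_like(self.time, dtype=bool)
        t0, t1 = window
        return (self.time >= t0) & (self.time <= t1)

    @property
    def n_obs(self) -> int:
        return len(self.time)
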