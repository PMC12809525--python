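"""1D intensity containers: azimuthal I(chi) and radial I(q) profiles.

Both carry an explicit per-bin validity mask; detector module gaps are
masked, never interpolated.  CSV round-trips use fixed float formatting so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AzimuthalProfile", "RadialProfile"]

_FLOAT_FMT = "%.8g"


@dataclass
class AzimuthalProfile:
    """Azimuthal intensity profile I(chi).

    chi is the detector azimuth in radians, counterclockwise from the +x
    (horizontal) axis, ascending over [0, 2pi).
    """

    chi: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.chi.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.chi.shape == self.intensity.shape == self.valid.shape):
            raise ValueError("chi, intensity and valid must have equal length")
        if np.any(np.diff(self.chi) <= 0):
            raise ValueError("chi grid must be strictly ascending")

    @property
    def chi_deg(self) -> np.ndarray:
        return np.degrees(self.chi)

    def max_valid(self) -> float:
        """Largest intensity over valid bins (0 if none are valid)."""
        if not self.valid.any():
            return 0.0
        return float(np.max(self.intensity[self.valid]))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "chi_deg": np.degrees(self.chi),
                "intensity": self.intensity,
                "valid": self.valid.astype(int),
            }
        )
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(cls, path) -> "AzimuthalProfile":
        df = pd.read_csv(path)
        return cls(
            chi=np.radians(df["chi_deg"].to_numpy()),
            intensity=df["intensity"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
        )

    def plot(self, ax=None, **kwargs):
        """Plot I(chi) in degrees; gap bins are left blank."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = np.where(self.valid, self.intensity, np.nan)
        ax.plot(self.chi_deg, y, **kwargs)
        ax.set_xlabel("azimuth chi (deg)")
        ax.set_ylabel("intensity (counts)")
        return ax


@dataclass
class RadialProfile:
    """Azimuthally averaged radial intensity profile I(q), q in 1/nm."""

    q: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.q.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.q.shape == self.intensity.shape == self.valid.shape):
            raise ValueError("q, intensity and valid must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly ascending")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "q_invnm": self.q,
                "intensity": self.intensity,
                "valid": self.valid.astype(int),
            }
        )
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(cls, path) -> "RadialProfile":
        df = pd.read_csv(path)
        return cls(
            q=df["q_invnm"].to_numpy(),
            intensity=df["intensity"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = np.where(self.valid, self.intensity, np.nan)
        ax.plot(self.q, y, **kwargs)
        ax.set_xlabel("q (1/nm)")
        ax.set_ylabel("intensity (counts)")
        return ax
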