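"""Core containers for FTIR spectra.

A spectrum is absorbance sampled on a uniform wavenumber grid (cm^-1).
Internally wavenumbers are stored ascending; FTIR convention plots them
descending, which is a display concern only.

A :class:`SpectrumSet` moves through a strict processing state machine::

    raw -> cut -> second_derivative -> centered

After range cutting the grid is a list of disjoint uniform segments; every
downstream step (derivative filtering, model coefficients) respects segment
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

STATES = ("raw", "cut", "second_derivative", "centered")

#: allowed state transitions (see module docstring); "cut" -> "cut" supports
#: re-cutting with identical ranges, which is the identity.
_TRANSITIONS = {
    "raw": {"cut"},
    "cut": {"cut", "second_derivative"},
    "second_derivative": {"centered"},
    "centered": set(),
}


class StateError(RuntimeError):
    """Raised when an operation is applied to a set in the wrong state."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniformly spaced wavenumber axis in cm^-1, stored ascending.

    The default spans 700-4000 cm^-1 at 2 cm^-1 spacing: the acquisition
    range of a bench-top instrument scanning 4000-700 cm^-1, sampled twice
    per 4 cm^-1 instrumental resolution element.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        d = np.diff(v)
        if not np.all(d > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise ValueError("wavenumber grid must be uniformly spaced")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls, low: float = 700.0, high: float = 4000.0,
                spacing: float = 2.0) -> "WavenumberGrid":
        n = int(round((high - low) / spacing)) + 1
        return cls(low + spacing * np.arange(n))

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def n_points(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size


def _check_segment(seg: np.ndarray) -> np.ndarray:
    seg = np.asarray(seg, dtype=float)
    if seg.ndim != 1 or seg.size == 0:
        raise ValueError("empty grid segment")
    if seg.size > 1:
        d = np.diff(seg)
        if not (np.all(d > 0) and np.allclose(d, d[0], rtol=1e-9, atol=0.0)):
            raise ValueError("segment must be uniform and strictly increasing")
    return seg


@dataclass
class SpectrumSet:
    """Absorbance matrix [n_spectra x n_points] on one or more grid segments.

    Parameters
    ----------
    segments:
        Disjoint ascending uniform wavenumber arrays; a raw set has one.
    absorbance:
        Row per spectrum, column per grid point (segments concatenated in
        ascending order).
    meta:
        One row per spectrum: ``id``, ``species``, ``temperature_C``,
        ``level`` (``bulk`` or ``single-cell``).
    state:
        Position in the processing state machine.
    """

    segments: list[np.ndarray]
    absorbance: np.ndarray
    meta: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        self.segments = [_check_segment(s) for s in self.segments]
        for a, b in zip(self.segments, self.segments[1:]):
            if b[0] <= a[-1]:
                raise ValueError("grid segments must be disjoint and ordered")
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        n_pts = sum(s.size for s in self.segments)
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(0, n_pts)
        if self.absorbance.shape[1] != n_pts:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns, "
                f"grid has {n_pts} points")
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError("meta rows must match spectra")
        self.meta = self.meta.reset_index(drop=True)

    # -- views ------------------------------------------------------------
    @property
    def wavenumbers(self) -> np.ndarray:
        """All retained wavenumbers, ascending, segments concatenated."""
        return np.concatenate(self.segments)

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def segment_slices(self) -> Iterator[tuple[np.ndarray, slice]]:
        """Yield (wavenumbers, column slice) per segment."""
        start = 0
        for seg in self.segments:
            yield seg, slice(start, start + seg.size)
            start += seg.size

    def ids(self) -> list[str]:
        return [str(x) for x in self.meta["id"]]

    # -- state machine -----------------------------------------------------
    def _advance(self, new_state: str, segments: Sequence[np.ndarray],
                 absorbance: np.ndarray) -> "SpectrumSet":
        if new_state not in _TRANSITIONS[self.state]:
            raise StateError(
                f"cannot go from state {self.state!r} to {new_state!r}")
        return SpectrumSet(segments=list(segments), absorbance=absorbance,
                           meta=self.meta.copy(), state=new_state)

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise StateError(
                f"operation requires state in {allowed}, set is {self.state!r}")


def make_meta(ids: Sequence[str], species: Sequence[str] | str = "",
              temperature_C: Sequence[float] | float = np.nan,
              level: str = "bulk") -> pd.DataFrame:
    n = len(ids)
    return pd.DataFrame({
        "id": list(ids),
        "species": [species] * n if isinstance(species, str) else list(species),
        "temperature_C": [temperature_C] * n
        if np.isscalar(temperature_C) else list(temperature_C),
        "level": [level] * n,
    })
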