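"""Spectral preprocessing: range cutting, Savitzky-Golay second derivative,
mean centering.

The chain mirrors standard chemometric practice for biomass FTIR: keep the
C-H stretch window (3019-2819 cm^-1) and the fingerprint window
(1800-950 cm^-1), take the second derivative with a 9-point quadratic
Savitzky-Golay filter (suppresses baselines, resolves overlapping bands),
then mean-center. No intensity normalization (vector/SNV/EMSC) is applied.

Derivatives are taken with respect to wavenumber (divided by spacing^2), so
features are grid-invariant. Edge points lacking a full filter window are
dropped rather than padded: each contiguous segment shrinks by
``window - 1`` points, and the filter never runs across the gap between
segments.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectrumSet, StateError

DEFAULT_RANGES: tuple[tuple[float, float], ...] = ((3019.0, 2819.0),
                                                   (1800.0, 950.0))
DEFAULT_SG_WINDOW = 9
DEFAULT_SG_POLYORDER = 2


def _normalize_ranges(
    ranges: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    norm = sorted((min(a, b), max(a, b)) for a, b in ranges)
    for (lo1, hi1), (lo2, hi2) in zip(norm, norm[1:]):
        if lo2 <= hi1:
            raise ValueError(f"overlapping intervals {(lo1, hi1)} and "
                             f"{(lo2, hi2)}")
    return norm


def cut_ranges(
    sset: SpectrumSet,
    ranges: Sequence[tuple[float, float]] = DEFAULT_RANGES,
) -> SpectrumSet:
    """Retain only grid points inside the given closed wavenumber intervals.

    Intervals may be written in FTIR (descending) or ascending order. The
    output grid is a list of disjoint segments; cutting an already-cut set
    with the same ranges is the identity.
    """
    sset.require_state("raw", "cut")
    norm = _normalize_ranges(ranges)
    span_lo = sset.segments[0][0]
    span_hi = sset.segments[-1][-1]
    for lo, hi in norm:
        # a raw grid must contain the interval; a cut grid has already lost
        # its interval endpoints, so only a fully disjoint interval is an
        # error there (re-cutting with the same ranges stays the identity)
        outside = (lo < span_lo - 1e-9 or hi > span_hi + 1e-9) \
            if sset.state == "raw" else (hi < span_lo or lo > span_hi)
        if outside:
            raise ValueError(
                f"interval ({hi:g}, {lo:g}) cm^-1 outside grid span "
                f"({span_hi:g}, {span_lo:g})")

    new_segments: list[np.ndarray] = []
    new_columns: list[np.ndarray] = []
    for lo, hi in norm:
        for seg, cols in sset.segment_slices():
            mask = (seg >= lo) & (seg <= hi)
            if mask.any():
                new_segments.append(seg[mask])
                new_columns.append(sset.absorbance[:, cols][:, mask])
    if not new_segments:
        raise ValueError("cut ranges retain no grid points")
    order = np.argsort([s[0] for s in new_segments])
    new_segments = [new_segments[i] for i in order]
    new_columns = [new_columns[i] for i in order]
    return sset._advance("cut", new_segments, np.hstack(new_columns))


def savgol_second_derivative(
    sset: SpectrumSet,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
) -> SpectrumSet:
    """Segment-wise Savitzky-Golay second derivative d2A/dnu2.

    Each segment is filtered independently; the ``(window - 1) / 2`` edge
    points on each side lack a full window and are dropped. The raw second
    derivative is kept (absorption peaks appear as minima); no sign flip.
    """
    sset.require_state("cut")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd count >= 3")
    if polyorder < 2:
        raise ValueError("polyorder must be >= 2 for a second derivative")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    half = (window - 1) // 2

    new_segments: list[np.ndarray] = []
    new_columns: list[np.ndarray] = []
    for seg, cols in sset.segment_slices():
        if seg.size < window:
            raise ValueError(
                f"segment of {seg.size} points shorter than window {window}")
        spacing = seg[1] - seg[0]
        deriv = savgol_filter(sset.absorbance[:, cols], window_length=window,
                              polyorder=polyorder, deriv=2, delta=spacing,
                              axis=1)
        new_segments.append(seg[half:-half])
        new_columns.append(deriv[:, half:-half])
    return sset._advance("second_derivative", new_segments,
                         np.hstack(new_columns))


def mean_center(
    sset: SpectrumSet,
    reference_mean: np.ndarray | None = None,
) -> tuple[SpectrumSet, np.ndarray]:
    """Subtract the column mean (calibration) or a stored training mean
    (prediction); returns the centered set and the mean that was used."""
    sset.require_state("second_derivative")
    if reference_mean is None:
        mean = sset.absorbance.mean(axis=0)
    else:
        mean = np.asarray(reference_mean, dtype=float)
        if mean.shape != (sset.n_points,):
            raise ValueError(
                f"reference mean has {mean.size} entries, set has "
                f"{sset.n_points} features")
    centered = sset._advance("centered", sset.segments,
                             sset.absorbance - mean)
    return centered, mean


def preprocess(
    sset: SpectrumSet,
    ranges: Sequence[tuple[float, float]] = DEFAULT_RANGES,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
    reference_mean: np.ndarray | None = None,
) -> tuple[SpectrumSet, np.ndarray]:
    """Full chain: cut -> second derivative -> mean center."""
    if sset.state != "raw":
        raise StateError("preprocess expects a raw SpectrumSet")
    deriv = savgol_second_derivative(cut_ranges(sset, ranges), window,
                                     polyorder)
    return mean_center(deriv, reference_mean)
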