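"""Sulcal-fraction morphometry by dual histogram autothresholding.

On a skull-stripped brain-surface image the background is darkest, sulci are
intermediate, and the gyral surface is brightest.  Two classic
autothresholding algorithms then bracket the sulci: the triangle (Zack)
method places its threshold just above the background tail, so its
foreground covers the entire visible surface including sulci, while the
moment-preserving (Tsai) method places its threshold between sulci and
gyri, excluding the sulci.  The relative difference of the two foreground
areas is the percentage of the visible surface occupied by sulci:

    percent_sulci = 100 * (A_triangle - A_moments) / A_triangle

Foreground is pixels strictly greater than the threshold (fixed for
determinism; the comparison side is otherwise arbitrary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .groupstats import DiffResult, adaptive_group_test


@dataclass
class GrayImage:
    """8-bit intensity grid with a histogram mask (the field of view).

    ``brain_mask`` is optional ground-truth bookkeeping used by synthetic
    images; the measurement itself only uses ``pixels`` and ``mask``.
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixels")

    def histogram(self) -> np.ndarray:
        vals = self.pixels if self.mask is None else self.pixels[self.mask]
        if vals.size == 0:
            raise ValueError("empty mask: nothing to histogram")
        return np.bincount(vals.ravel(), minlength=256).astype(np.int64)


@dataclass
class SulcalMeasurement:
    subject: str
    area_triangle: int
    area_moments: int
    percent_sulci: float
    threshold_triangle: int
    threshold_moments: int
    flags: tuple[str, ...] = ()


def moments_threshold(histogram: Sequence[int]) -> int:
    """Tsai moment-preserving threshold.

    Finds the two-level image preserving the first three grayscale moments
    of the input, then returns the smallest intensity at which the
    cumulative histogram fraction reaches the computed below-fraction p0.
    Scale-invariant in the histogram counts.
    """
    h = np.asarray(histogram, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram has zero total count")
    nz = np.flatnonzero(h)
    if len(nz) == 1:
        warnings.warn("single-intensity histogram: degenerate moments threshold", stacklevel=2)
        return int(nz[0])
    p = h / total
    levels = np.arange(len(h), dtype=float)
    m1 = (p * levels).sum()
    m2 = (p * levels**2).sum()
    m3 = (p * levels**3).sum()
    cd = m2 - m1 * m1
    if cd <= 0:
        warnings.warn("zero-variance histogram: degenerate moments threshold", stacklevel=2)
        return int(nz[0])
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        warnings.warn("coincident representative levels: degenerate moments threshold", stacklevel=2)
        return int(nz[0])
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels at/below threshold
    cum = np.cumsum(p)
    # Tolerate float round-off at exact-fraction boundaries.
    idx = np.flatnonzero(cum >= p0 - 1e-12)
    return int(idx[0]) if len(idx) else int(len(h) - 1)


def triangle_threshold(histogram: Sequence[int]) -> int:
    """Zack geometric (triangle) threshold.

    A line is drawn from the histogram peak to the far end of the longer
    tail (the side of the peak with the greater intensity extent); the
    threshold is the bin between them maximizing the perpendicular distance
    from the histogram to that line.
    """
    h = np.asarray(histogram, dtype=float)
    if h.sum() <= 0:
        raise ValueError("histogram has zero total count")
    nz = np.flatnonzero(h)
    first, last = nz[0], nz[-1]
    peak = int(np.argmax(h))
    if first == last or np.all(h[nz] == h[nz[0]]) and len(nz) == last - first + 1:
        warnings.warn("flat or single-valued histogram: degenerate triangle threshold", stacklevel=2)
        return int(peak)
    # Tail side: greater extent from the peak (ties go to the bright side).
    tail_end = last if (last - peak) >= (peak - first) else first
    px, py = float(peak), h[peak]
    ex, ey = float(tail_end), h[tail_end]
    # Perpendicular distance of (b, h[b]) from the peak-to-tail-end line.
    dx, dy = ex - px, ey - py
    norm = np.hypot(dx, dy)
    best_b, best_d = peak, -1.0
    lo, hi = (peak, last) if tail_end == last else (first, peak)
    for b in range(lo, hi + 1):
        d = abs(dy * (b - px) - dx * (h[b] - py)) / norm
        if d > best_d + 1e-12:
            best_d, best_b = d, b
    return int(best_b)


def sulcal_fraction(image: GrayImage, subject: str = "") -> SulcalMeasurement:
    """Percent of the visible surface classified as sulci.

    Foreground areas are pixels strictly above each threshold within the
    image mask; negative differences (moments area exceeding triangle area)
    are clipped to zero and flagged.
    """
    hist = image.histogram()
    t_tri = triangle_threshold(hist)
    t_mom = moments_threshold(hist)
    vals = image.pixels if image.mask is None else image.pixels[image.mask]
    a_tri = int((vals > t_tri).sum())
    a_mom = int((vals > t_mom).sum())
    flags: list[str] = []
    if a_tri == 0:
        flags.append("empty-foreground")
        pct = 0.0
    else:
        pct = 100.0 * (a_tri - a_mom) / a_tri
        if pct < 0:
            flags.append("moments-exceeds-triangle")
            pct = 0.0
    return SulcalMeasurement(
        subject=subject, area_triangle=a_tri, area_moments=a_mom,
        percent_sulci=pct, threshold_triangle=t_tri, threshold_moments=t_mom,
        flags=tuple(flags),
    )


def compare_groups(
    measurements: Sequence[SulcalMeasurement],
    groups: Sequence[str],
    case_label: str = "AUD",
    control_label: str = "control",
) -> DiffResult:
    """Two-group comparison of percent-sulci values (clinical decision tree)."""
    pct = np.array([m.percent_sulci for m in measurements], dtype=float)
    g = np.asarray(groups)
    if len(pct) != len(g):
        raise ValueError("measurements and groups must align")
    return adaptive_group_test(
        pct[g == control_label], pct[g == case_label],
        mode="clinical", feature="percent_sulci",
    )
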