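"""Spectrum containers and intensity-field operations.

NMR spectra are represented as dense intensity fields on evenly spaced
chemical-shift (ppm) grids: 1D spectra as vectors, HSQC as a matrix over
the (1H, 13C) plane. Peak lists (shift, intensity) are the sparse
counterpart and can be rendered onto a grid with Gaussian line shapes.

Grids are stored ascending in ppm; the NMR display convention (high ppm
on the left) is purely a plotting concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "Nucleus",
    "PpmGrid",
    "Spectrum1D",
    "SpectrumHSQC",
    "PeakList1D",
    "PeakListHSQC",
    "DEFAULT_H1_GRID",
    "DEFAULT_C13_GRID",
    "DEFAULT_HSQC_H_GRID",
    "DEFAULT_HSQC_C_GRID",
    "DEFAULT_SOLVENT_WINDOWS",
    "normalize_instance",
    "render_peaklist_1d",
    "reconstruct_hsqc",
    "zero_windows",
]


class Nucleus(str, Enum):
    """Observed nucleus of a 1D spectrum."""

    H1 = "H1"
    C13 = "C13"


@dataclass(frozen=True)
class PpmGrid:
    """Evenly spaced discrete chemical-shift grid.

    Grid value at index ``j`` is ``start_ppm + j * step`` with
    ``step = (end_ppm - start_ppm) / (n_points - 1)``; both endpoints are
    grid points.
    """

    start_ppm: float
    end_ppm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("PpmGrid needs n_points >= 2")
        if self.start_ppm == self.end_ppm:
            raise ValueError("PpmGrid needs start_ppm != end_ppm")

    @property
    def step(self) -> float:
        return (self.end_ppm - self.start_ppm) / (self.n_points - 1)

    def values(self) -> np.ndarray:
        """All grid ppm values, ascending if start < end."""
        return self.start_ppm + self.step * np.arange(self.n_points)

    def index_of(self, ppm: float) -> int:
        """Index of the grid point nearest to ``ppm`` (clipped to range)."""
        j = round((ppm - self.start_ppm) / self.step)
        return int(min(max(j, 0), self.n_points - 1))

    def contains(self, ppm: float) -> bool:
        lo, hi = sorted((self.start_ppm, self.end_ppm))
        return lo <= ppm <= hi


# Defaults cover common organic shift ranges at the dense-vector resolution
# used throughout (10,000 points for 1D; 256x256 for HSQC).
DEFAULT_H1_GRID = PpmGrid(-2.0, 12.0, 10_000)
DEFAULT_C13_GRID = PpmGrid(-10.0, 230.0, 10_000)
DEFAULT_HSQC_H_GRID = PpmGrid(0.0, 12.0, 256)
DEFAULT_HSQC_C_GRID = PpmGrid(0.0, 200.0, 256)

#: Reference/solvent zero-out windows (ppm), per nucleus. These are this
#: package's defaults for CDCl3/TMS-style artifacts, not literature values.
DEFAULT_SOLVENT_WINDOWS = {
    Nucleus.H1: [(7.24, 7.28), (-0.05, 0.05)],
    Nucleus.C13: [(76.5, 77.5)],
}


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class Spectrum1D:
    """Dense 1D NMR spectrum: one intensity per grid point."""

    nucleus: Nucleus
    grid: PpmGrid
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"grid n_points {self.grid.n_points}"
            )
        _check_finite(self.intensities, "Spectrum1D.intensities")
        if self.normalized and self.intensities.size:
            if self.intensities.min() < -1e-12 or self.intensities.max() > 1 + 1e-12:
                raise ValueError("normalized Spectrum1D must lie in [0, 1]")


@dataclass
class SpectrumHSQC:
    """Dense 2D HSQC spectrum over (1H, 13C) grids.

    ``intensities[i, j]`` is the intensity at ``h_grid`` index ``i`` and
    ``c_grid`` index ``j``.
    """

    h_grid: PpmGrid
    c_grid: PpmGrid
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        expected = (self.h_grid.n_points, self.c_grid.n_points)
        if self.intensities.shape != expected:
            raise ValueError(
                f"intensities shape {self.intensities.shape} != grids {expected}"
            )
        _check_finite(self.intensities, "SpectrumHSQC.intensities")
        if self.normalized and self.intensities.size:
            if self.intensities.min() < -1e-12 or self.intensities.max() > 1 + 1e-12:
                raise ValueError("normalized SpectrumHSQC must lie in [0, 1]")


@dataclass
class PeakList1D:
    """Sparse 1D spectrum: (shift_ppm, intensity) pairs."""

    nucleus: Nucleus
    peaks: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (shift, inten) in enumerate(self.peaks):
            if not (np.isfinite(shift) and np.isfinite(inten)):
                raise ValueError(f"peak {i}: non-finite shift/intensity")
            if inten < 0:
                raise ValueError(f"peak {i}: intensity must be >= 0, got {inten}")


@dataclass
class PeakListHSQC:
    """Sparse HSQC cross-peaks: (h_ppm, c_ppm, intensity) triples."""

    peaks: List[Tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (h, c, inten) in enumerate(self.peaks):
            if not (np.isfinite(h) and np.isfinite(c) and np.isfinite(inten)):
                raise ValueError(f"peak {i}: non-finite value")
            if inten < 0:
                raise ValueError(f"peak {i}: intensity must be >= 0, got {inten}")


def normalize_instance(spectrum):
    """Instance-wise min-max normalization to the [0, 1] range.

    Each spectrum is rescaled independently, ``(x - min) / (max - min)``,
    which removes instrument/simulator-specific intensity scales and
    baseline offsets. A constant (blank) spectrum maps to all zeros with a
    warning so that batch pipelines survive degenerate inputs.

    Idempotent on already-normalized non-constant input.
    """
    x = spectrum.intensities
    _check_finite(x, "spectrum")
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        warnings.warn("constant spectrum: normalizing to all zeros", stacklevel=2)
        out = np.zeros_like(x, dtype=np.float64)
    else:
        out = (x - lo) / (hi - lo)
    return replace(spectrum, intensities=out, normalized=True)


def render_peaklist_1d(
    peaks: PeakList1D, grid: PpmGrid, line_sigma: float
) -> Spectrum1D:
    """Render a peak list onto a dense grid with Gaussian line shapes.

    Each peak contributes ``intensity * exp(-(delta_j - shift)^2 /
    (2 line_sigma^2))`` at every grid point; the sum is then min-max
    normalized. An empty peak list gives an all-zero, unnormalized
    spectrum with a warning.
    """
    if line_sigma <= 0:
        raise ValueError("line_sigma must be > 0")
    delta = grid.values()
    y = np.zeros(grid.n_points, dtype=np.float64)
    if not peaks.peaks:
        warnings.warn("empty peak list: rendering all-zero spectrum", stacklevel=2)
        return Spectrum1D(peaks.nucleus, grid, y, normalized=False)
    inv = 1.0 / (2.0 * line_sigma * line_sigma)
    for shift, inten in peaks.peaks:
        y += inten * np.exp(-((delta - shift) ** 2) * inv)
    return normalize_instance(Spectrum1D(peaks.nucleus, grid, y, normalized=False))


def reconstruct_hsqc(
    peaks: PeakListHSQC,
    h_grid: PpmGrid = DEFAULT_HSQC_H_GRID,
    c_grid: PpmGrid = DEFAULT_HSQC_C_GRID,
    h_sigma: float = 0.05,
    power: float = 0.3,
) -> SpectrumHSQC:
    """Reconstruct an HSQC intensity image from a cross-peak list.

    Each peak is deposited at its nearest cell along the 13C axis and
    broadened by a 1D Gaussian of width ``h_sigma`` (ppm) along the 1H
    axis only — a mild broadening that approximates the appearance of a
    continuous 2D spectrum when only processed cross-peak positions and
    intensities are available. Deposited intensities are raised
    elementwise to ``power`` (default 0.3, compressing the dynamic range
    so a few very intense cross-peaks do not dominate) *before* the final
    min-max normalization. Negative raw intensities (phase artifacts) are
    clipped to zero before exponentiation.

    Peaks outside both grid ranges are dropped with a warning; an empty
    list yields a zero matrix with a warning.
    """
    if h_sigma <= 0:
        raise ValueError("h_sigma must be > 0")
    if power <= 0:
        raise ValueError("power must be > 0")
    img = np.zeros((h_grid.n_points, c_grid.n_points), dtype=np.float64)
    kept = 0
    h_vals = h_grid.values()
    inv = 1.0 / (2.0 * h_sigma * h_sigma)
    for h, c, inten in peaks.peaks:
        if not (h_grid.contains(h) and c_grid.contains(c)):
            warnings.warn(
                f"HSQC peak ({h}, {c}) outside grid ranges: dropped", stacklevel=2
            )
            continue
        j = c_grid.index_of(c)
        img[:, j] += max(inten, 0.0) * np.exp(-((h_vals - h) ** 2) * inv)
        kept += 1
    if kept == 0:
        if not peaks.peaks:
            warnings.warn("empty HSQC peak list: zero matrix", stacklevel=2)
        return SpectrumHSQC(h_grid, c_grid, img, normalized=False)
    img = np.clip(img, 0.0, None) ** power
    return normalize_instance(SpectrumHSQC(h_grid, c_grid, img, normalized=False))


def zero_windows(
    spectrum: Spectrum1D, windows: Sequence[Tuple[float, float]] | None = None
) -> Spectrum1D:
    """Zero out fixed chemical-shift windows (reference/solvent removal).

    ``windows`` is a list of (lo_ppm, hi_ppm) intervals; by default the
    package's CDCl3/TMS windows for the spectrum's nucleus are used.
    """
    if windows is None:
        windows = DEFAULT_SOLVENT_WINDOWS.get(spectrum.nucleus, [])
    delta = spectrum.grid.values()
    y = spectrum.intensities.copy()
    for lo, hi in windows:
        if lo > hi:
            lo, hi = hi, lo
        y[(delta >= lo) & (delta <= hi)] = 0.0
    return replace(spectrum, intensities=y)
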