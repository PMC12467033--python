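"""Amide-I deconvolution and secondary-structure quantification.

The amide-I band (1600-1700 cm⁻¹, dominated by backbone C=O stretching) is
windowed, baseline-corrected with the straight line through the window
endpoints, decomposed into a sum of Gaussian sub-peaks, and each sub-peak is
assigned to a secondary-structure class by its center wavenumber:
β-sheet 1615-1637, antiparallel β-sheet 1638-1648, α-helix 1649-1660,
β-turn 1661-1680, random coil 1681-1692 cm⁻¹.  Class percentages are the
class areas normalized by the total assigned area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .datatypes import FtirSpectrum
from .errors import FitError, InvariantError

logger = logging.getLogger(__name__)

AMIDE_I_WINDOW = (1600.0, 1700.0)

# Contiguous class bins: each printed range keeps its own lower edge; the
# 1-cm^-1 gaps between printed ranges fall to the class below them.
_CLASS_EDGES = (1615.0, 1638.0, 1649.0, 1661.0, 1681.0, 1692.0)
_CLASS_ORDER = (
    "beta_sheet",
    "beta_antiparallel",
    "alpha_helix",
    "beta_turn",
    "random_coil",
)

STRUCTURE_CLASSES = _CLASS_ORDER + ("unassigned",)


def classify_center(center: float) -> str:
    """Secondary-structure class of a sub-peak center (cm⁻¹)."""
    if center < _CLASS_EDGES[0] or center > _CLASS_EDGES[-1]:
        return "unassigned"
    for klass, lo, hi in zip(_CLASS_ORDER, _CLASS_EDGES, _CLASS_EDGES[1:]):
        if lo <= center < hi:
            return klass
    return _CLASS_ORDER[-1]  # center == upper edge of the last bin


@dataclass(frozen=True)
class SubPeak:
    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    area: float  # absorbance * cm^-1

    def __post_init__(self):
        if not (AMIDE_I_WINDOW[0] <= self.center <= AMIDE_I_WINDOW[1]):
            raise InvariantError(
                f"SubPeak: center {self.center} outside the amide-I window"
            )
        if self.width <= 0 or self.area <= 0:
            raise InvariantError("SubPeak: width and area must be positive")

    @property
    def klass(self) -> str:
        return classify_center(self.center)


@dataclass(frozen=True)
class SecondaryStructure:
    """Secondary-structure class percentages (assigned classes sum to 100)."""

    fractions: dict[str, float]

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 0.1:
            raise InvariantError(
                f"SecondaryStructure: fractions sum to {total}, not 100"
            )
        if any(not (0.0 <= v <= 100.0) for v in self.fractions.values()):
            raise InvariantError("SecondaryStructure: fractions outside [0, 100]")


def extract_amide_I(spectrum: FtirSpectrum) -> FtirSpectrum:
    """Window the spectrum to 1600-1700 cm⁻¹ and remove a linear baseline.

    The baseline is the straight line through the two window endpoints;
    small negative residuals are clipped to zero (count logged).
    """
    x = np.asarray(spectrum.wavenumber, float)
    y = np.asarray(spectrum.absorbance, float)
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    lo, hi = AMIDE_I_WINDOW
    if x[0] > lo or x[-1] < hi:
        raise InvariantError(
            f"extract_amide_I: spectrum covers [{x[0]}, {x[-1]}], "
            f"needs [{lo}, {hi}]"
        )
    sel = (x >= lo) & (x <= hi)
    xw, yw = x[sel], y[sel]
    baseline = yw[0] + (yw[-1] - yw[0]) * (xw - xw[0]) / (xw[-1] - xw[0])
    corrected = yw - baseline
    negatives = int(np.sum(corrected < 0))
    if negatives:
        logger.info("extract_amide_I: clipped %d negative points to zero", negatives)
        corrected = np.clip(corrected, 0.0, None)
    return FtirSpectrum(tuple(xw), tuple(corrected))


def _gaussian_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x)
    for amp, center, sigma in params.reshape(-1, 3):
        y = y + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return y


def _seed_second_derivative(
    x: np.ndarray, y: np.ndarray, window: int, polyorder: int
) -> list[float]:
    window = min(window if window % 2 else window + 1, x.size - (1 - x.size % 2))
    d2 = signal.savgol_filter(y, window, polyorder, deriv=2)
    minima, _ = signal.find_peaks(-d2)
    centers = [float(x[i]) for i in minima if d2[i] < 0 and y[i] > 0.05 * y.max()]
    if not centers:
        centers = [float(x[np.argmax(y)])]
    return centers


def _seed_fixed_classes() -> list[float]:
    return [(lo + hi) / 2.0 for lo, hi in zip(_CLASS_EDGES, _CLASS_EDGES[1:])]


def deconvolve(
    windowed: FtirSpectrum,
    seeding: str = "second_derivative",
    smooth_window: int = 9,
    polyorder: int = 3,
) -> list[SubPeak]:
    """Decompose the baseline-corrected amide-I band into Gaussian sub-peaks.

    Candidate centers come either from minima of the Savitzky-Golay second
    derivative ('second_derivative') or from the five class-range midpoints
    ('fixed_classes'); amplitudes, centers (bounded to the window) and
    widths are then refined by nonlinear least squares on the Gaussian sum.
    """
    x = np.asarray(windowed.wavenumber, float)
    y = np.asarray(windowed.absorbance, float)
    if np.ptp(y) == 0 or y.max() <= 0:
        raise InvariantError("deconvolve: no signal in the amide-I window")
    if seeding == "second_derivative":
        centers = _seed_second_derivative(x, y, smooth_window, polyorder)
    elif seeding == "fixed_classes":
        centers = _seed_fixed_classes()
    else:
        raise InvariantError(f"deconvolve: unknown seeding {seeding!r}")

    def residual(params):
        return _gaussian_sum(x, params) - y

    def fit(centers):
        p0, lower, upper = [], [], []
        for c in centers:
            amp0 = max(float(np.interp(c, x, y)), 1e-3 * y.max())
            p0 += [amp0, c, 8.0]
            lower += [0.0, AMIDE_I_WINDOW[0], 1.0]
            upper += [5.0 * y.max(), AMIDE_I_WINDOW[1], 40.0]
        return optimize.least_squares(
            residual, np.asarray(p0), bounds=(lower, upper), max_nfev=20000
        )

    # heavily overlapped bands can hide from both seeders; add a component
    # at the largest residual until the fit explains the band
    result = fit(centers)
    while (
        len(centers) < 8
        and np.sqrt(np.mean(result.fun**2)) > 2e-3 * y.max()
    ):
        worst = float(x[np.argmax(np.abs(result.fun))])
        centers = sorted(centers + [worst])
        refined = fit(centers)
        if np.sum(refined.fun**2) >= 0.999 * np.sum(result.fun**2):
            break
        result = refined
    if not result.success:
        raise FitError(
            f"amide-I deconvolution did not converge: {result.message}",
            residuals=result.fun,
        )
    peaks = []
    total = float(np.trapezoid(y, x))
    for amp, center, sigma in result.x.reshape(-1, 3):
        area = amp * sigma * math.sqrt(2.0 * math.pi)
        if area > 1e-4 * total:  # drop numerically empty components
            peaks.append(SubPeak(float(center), float(sigma), float(area)))
    if not peaks:
        raise FitError("amide-I deconvolution resolved no sub-peaks")
    peaks.sort(key=lambda p: p.center)
    return peaks


def assign_structure(peaks: list[SubPeak]) -> SecondaryStructure:
    """Normalize sub-peak areas into secondary-structure percentages.

    Sub-peaks whose centers fall outside the class ranges (1600-1614.99 or
    1692.01-1700 cm⁻¹) are excluded from the denominator with a warning.
    """
    if not peaks:
        raise InvariantError("assign_structure: no sub-peaks")
    areas = {klass: 0.0 for klass in _CLASS_ORDER}
    unassigned = 0.0
    for p in peaks:
        klass = p.klass
        if klass == "unassigned":
            unassigned += p.area
        else:
            areas[klass] += p.area
    total = sum(areas.values())
    if total == 0:
        raise InvariantError("assign_structure: total assigned area is zero")
    if unassigned:
        logger.warning(
            "assign_structure: excluded %.3g area units outside class ranges",
            unassigned,
        )
    return SecondaryStructure(
        fractions={k: 100.0 * v / total for k, v in areas.items()}
    )
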