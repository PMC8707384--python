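"""UV-absorbance metrics for sunscreen screening.

Implements the spectrophotometric in vitro sun protection factor (an
erythemal-weighted absorbance sum, Mansur method), the critical
wavelength (90% cumulative-absorbance wavelength), the UVA/UVB integral
ratio, the Boots-style star rating, and the broad-spectrum claim test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import CoverageError, InputError, UndefinedMetricError

logger = logging.getLogger(__name__)

UVB_BAND = (290.0, 320.0)
UVA_BAND = (320.0, 400.0)
FULL_BAND = (290.0, 400.0)

#: Product of the erythemal action spectrum and solar intensity at the
#: seven 5-nm grid points of the Mansur sum.  Normalized to ~1.
MANSUR_WEIGHTS: Mapping[float, float] = {
    290.0: 0.0150,
    295.0: 0.0817,
    300.0: 0.2874,
    305.0: 0.3278,
    310.0: 0.1864,
    315.0: 0.0839,
    320.0: 0.0180,
}

CORRECTION_FACTOR = 10.0

#: Star-rating band edges on the UVA/UVB ratio (2008 Boots scheme, lower
#: historical 1-2 star bands collapsed into "no claim").
STAR_BANDS = ((0.9, 5), (0.8, 4), (0.6, 3))


@dataclass(frozen=True)
class ErythemalWeights:
    """Erythemal-effectiveness weights used by the SPFi sum."""

    weights: Mapping[float, float] = field(
        default_factory=lambda: dict(MANSUR_WEIGHTS)
    )
    correction_factor: float = CORRECTION_FACTOR

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise InputError("erythemal weights must be positive")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-3:
            raise InputError(
                f"erythemal weights must sum to ~1 (got {total:.4f})"
            )


@dataclass
class AbsorbanceSpectrum:
    """A sample's UV absorbance as a function of wavelength (nm, AU)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    concentration: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.absorbance.shape:
            raise InputError("wavelengths and absorbance must be 1-D and equal length")
        if self.wavelengths.size < 2:
            raise InputError("spectrum needs at least two points")
        if np.any(~np.isfinite(self.wavelengths)) or np.any(~np.isfinite(self.absorbance)):
            raise InputError("spectrum contains non-finite values")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InputError("wavelengths must be strictly increasing")

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.absorbance < 0))

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    def require_coverage(self, lo: float, hi: float) -> None:
        if not self.covers(lo, hi):
            gaps = []
            if self.wavelengths[0] > lo:
                gaps.append(f"{lo:g}-{min(self.wavelengths[0], hi):g} missing")
            if self.wavelengths[-1] < hi:
                gaps.append(f"{max(self.wavelengths[-1], lo):g}-{hi:g} missing")
            raise CoverageError(
                f"spectrum {self.sample_id!r} does not cover [{lo:g}, {hi:g}] nm: "
                + "; ".join(gaps)
            )

    def interp(self, wavelengths_nm: np.ndarray | float) -> np.ndarray:
        """Linearly interpolated absorbance at arbitrary wavelengths."""
        return np.interp(np.asarray(wavelengths_nm, dtype=float),
                         self.wavelengths, self.absorbance)

    def resample(self, step_nm: float, lo: float = FULL_BAND[0],
                 hi: float = FULL_BAND[1]) -> "AbsorbanceSpectrum":
        """Linear resampling onto a uniform grid with inclusive endpoints."""
        if step_nm <= 0:
            raise InputError("step must be positive")
        n = int(round((hi - lo) / step_nm)) + 1
        grid = lo + step_nm * np.arange(n)
        return AbsorbanceSpectrum(grid, self.interp(grid),
                                  sample_id=self.sample_id,
                                  concentration=self.concentration)

    def clipped(self) -> "AbsorbanceSpectrum":
        """Copy with negative absorbance (baseline artifacts) floored at 0."""
        if not self.has_negative:
            return self
        logger.warning(
            "spectrum %r: negative absorbance clipped to 0 for metric computation",
            self.sample_id,
        )
        return AbsorbanceSpectrum(self.wavelengths,
                                  np.clip(self.absorbance, 0.0, None),
                                  sample_id=self.sample_id,
                                  concentration=self.concentration)


@dataclass(frozen=True)
class UVMetrics:
    """Aggregate UV-protection metrics for one sample."""

    sample_id: str
    spfi: float
    lambda_c: float
    uva_uvb_ratio: float
    star_rating: int
    broad_spectrum: bool

    @property
    def lambda_c_nm_int(self) -> int:
        return int(round(self.lambda_c))


def spfi(spectrum: AbsorbanceSpectrum,
         weights: ErythemalWeights | None = None) -> float:
    """Erythemal-weighted absorbance sum times the correction factor.

    Absorbance is taken at the seven 5-nm grid points (290..320),
    linearly interpolated from the raw grid when absent.
    """
    weights = weights or ErythemalWeights()
    spectrum.require_coverage(*UVB_BAND)
    spectrum = spectrum.clipped()
    grid = np.array(sorted(weights.weights))
    a = spectrum.interp(grid)
    w = np.array([weights.weights[l] for l in grid])
    return float(weights.correction_factor * np.sum(w * a))


def _band_grid(spectrum: AbsorbanceSpectrum, lo: float, hi: float):
    """Spectrum points on [lo, hi] with interpolated endpoints inserted."""
    wl, a = spectrum.wavelengths, spectrum.absorbance
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(([spectrum.interp(lo)], a[inside], [spectrum.interp(hi)]))
    return xs, ys


def band_integral(spectrum: AbsorbanceSpectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of absorbance over [lo, hi] nm."""
    xs, ys = _band_grid(spectrum, lo, hi)
    return float(np.trapezoid(ys, xs))


def critical_wavelength(spectrum: AbsorbanceSpectrum,
                        fraction: float = 0.9) -> float:
    """Smallest wavelength accumulating `fraction` of the 290-400 nm integral.

    The absorbance is treated as piecewise linear between grid points, so
    the cumulative integral is quadratic within the bracketing segment and
    the crossing is solved exactly there.  Full precision is returned;
    report writers round to 0.1 nm.
    """
    spectrum.require_coverage(*FULL_BAND)
    xs, ys = _band_grid(spectrum.clipped(), *FULL_BAND)
    seg = 0.5 * (ys[1:] + ys[:-1]) * np.diff(xs)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    total = cum[-1]
    if total <= 0:
        raise UndefinedMetricError(
            f"critical wavelength undefined: spectrum {spectrum.sample_id!r} "
            "has zero absorbance integral on 290-400 nm"
        )
    target = fraction * total
    i = int(np.searchsorted(cum, target))
    if i >= len(xs):
        return float(xs[-1])
    i = max(i, 1)
    x0, x1 = xs[i - 1], xs[i]
    y0, y1 = ys[i - 1], ys[i]
    h = x1 - x0
    rem = target - cum[i - 1]
    # solve y0*t + (y1-y0)*t^2/(2h) = rem for t in [0, h]
    slope = (y1 - y0) / h
    if abs(slope) < 1e-15:
        t = rem / y0 if y0 > 0 else h
    else:
        disc = y0 * y0 + 2.0 * slope * rem
        t = (-y0 + math.sqrt(max(disc, 0.0))) / slope
    t = min(max(t, 0.0), h)
    return float(x0 + t)


def uva_uvb_ratio(spectrum: AbsorbanceSpectrum) -> float:
    """Integral of absorbance over 320-400 nm over the 290-320 nm integral."""
    spectrum.require_coverage(*FULL_BAND)
    spectrum = spectrum.clipped()
    uvb = band_integral(spectrum, *UVB_BAND)
    if uvb <= 0:
        raise UndefinedMetricError(
            f"UVA/UVB ratio undefined: spectrum {spectrum.sample_id!r} "
            "has zero UV-B integral"
        )
    return band_integral(spectrum, *UVA_BAND) / uvb


def star_rating(ratio: float,
                bands: tuple[tuple[float, int], ...] = STAR_BANDS) -> int:
    """Boots-style star rating from the UVA/UVB ratio (0 = no claim)."""
    if ratio < 0:
        raise InputError(f"UVA/UVB ratio must be nonnegative, got {ratio}")
    for cutoff, stars in bands:
        if ratio >= cutoff:
            return stars
    return 0


def broad_spectrum_claim(lambda_c: float, ratio: float,
                         lambda_c_cutoff_nm: float = 370.0,
                         uva_uvb_cutoff: float = 0.7) -> bool:
    """True iff the critical wavelength exceeds the cutoff and the ratio meets it."""
    return lambda_c > lambda_c_cutoff_nm and ratio >= uva_uvb_cutoff


def compute_uv_metrics(spectrum: AbsorbanceSpectrum,
                       weights: ErythemalWeights | None = None,
                       lambda_c_cutoff_nm: float = 370.0,
                       uva_uvb_cutoff: float = 0.7) -> UVMetrics:
    """All UV metrics for one spectrum."""
    s = spfi(spectrum, weights)
    lc = critical_wavelength(spectrum)
    ratio = uva_uvb_ratio(spectrum)
    return UVMetrics(
        sample_id=spectrum.sample_id,
        spfi=s,
        lambda_c=lc,
        uva_uvb_ratio=ratio,
        star_rating=star_rating(ratio),
        broad_spectrum=broad_spectrum_claim(lc, ratio,
                                            lambda_c_cutoff_nm, uva_uvb_cutoff),
    )
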