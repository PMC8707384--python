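"""Radical-scavenging assays, Trolox-equivalent capacity, and
phenolic/flavonoid equivalent quantitation.

Covers the DPPH and ABTS decolorization assays (radical scavenging
capacity as percent absorbance loss against the blank), conversion to
Trolox equivalents through a linear standard curve, and gallic-acid /
quercetin equivalent contents for TPC/TFC plates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AssayError, CurveError

logger = logging.getLogger(__name__)

#: Printed Trolox standard curves, response (RSC %) = slope * conc + intercept,
#: concentration in µmol/L.
TROLOX_CURVE_DPPH = ("Trolox-DPPH", 2.167, -0.5203)
TROLOX_CURVE_ABTS = ("Trolox-ABTS", 3.066, -1.356)


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: response = slope * concentration + intercept."""

    analyte: str
    slope: float
    intercept: float
    valid_range: tuple[float, float] | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise CurveError(f"standard curve {self.analyte!r} has zero slope")

    def concentration(self, response: float) -> float:
        """Invert the curve: concentration producing `response`."""
        return (response - self.intercept) / self.slope

    def response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def dpph_trolox_curve() -> StandardCurve:
    name, slope, intercept = TROLOX_CURVE_DPPH
    return StandardCurve(name, slope, intercept)


def abts_trolox_curve() -> StandardCurve:
    name, slope, intercept = TROLOX_CURVE_ABTS
    return StandardCurve(name, slope, intercept)


@dataclass
class RadicalAssayPlate:
    """Blank and per-sample replicate absorbances for one assay."""

    assay: str  # DPPH | ABTS | TPC | TFC
    blank_abs: np.ndarray
    sample_abs: Mapping[str, np.ndarray]
    sample_conc: Mapping[str, float] = field(default_factory=dict)
    read_wavelength: float | None = None

    def __post_init__(self) -> None:
        self.blank_abs = np.asarray(self.blank_abs, dtype=float)
        self.sample_abs = {k: np.asarray(v, dtype=float)
                           for k, v in self.sample_abs.items()}
        if self.blank_abs.size == 0:
            raise AssayError(f"{self.assay}: no blank wells")
        if any(v.size == 0 for v in self.sample_abs.values()):
            raise AssayError(f"{self.assay}: empty replicate group")

    @property
    def blank_mean(self) -> float:
        return float(np.mean(self.blank_abs))


@dataclass(frozen=True)
class RSCResult:
    """Radical scavenging capacity as percent of blank absorbance lost."""

    value_pct: float
    sd_pct: float
    negative: bool  # pro-oxidant / interference flag, value preserved


@dataclass(frozen=True)
class EquivalentsResult:
    content_mg_per_100g: float | None
    below_detection: bool


@dataclass
class AntioxidantResult:
    sample_id: str
    rsc_pct: float
    rsc_sd: float
    teac: float
    negative_rsc: bool = False
    extrapolated: bool = False


def radical_scavenging(a_c: Sequence[float], a_s: Sequence[float]) -> RSCResult:
    """Percent loss of blank absorbance: 100 * (mean A_C - mean A_S) / mean A_C.

    Negative values (sample absorbs more than the blank) are preserved and
    flagged, not clipped.  The SD is that of per-replicate values computed
    against the blank mean.
    """
    a_c = np.asarray(a_c, dtype=float)
    a_s = np.asarray(a_s, dtype=float)
    if a_c.size == 0 or a_s.size == 0:
        raise AssayError("empty replicate array")
    mc = float(np.mean(a_c))
    if mc <= 0:
        raise AssayError(f"blank mean must be positive, got {mc:g}")
    per_rep = 100.0 * (mc - a_s) / mc
    value = float(np.mean(per_rep))
    sd = float(np.std(per_rep, ddof=1)) if a_s.size > 1 else 0.0
    return RSCResult(value_pct=value, sd_pct=sd, negative=value < 0)


def teac(rsc_pct: float, curve: StandardCurve, sample_conc_g_per_l: float) -> float:
    """Trolox-equivalent antioxidant capacity, µmol TE per g dry weight.

    The Trolox concentration T (µmol/L) giving the same response is read
    off the inverted standard curve and divided by the sample
    concentration (g/L).
    """
    if sample_conc_g_per_l <= 0:
        raise AssayError("sample concentration must be positive")
    t_umol_per_l = curve.concentration(rsc_pct)
    return t_umol_per_l / sample_conc_g_per_l


def rsc_from_teac(teac_value: float, curve: StandardCurve,
                  sample_conc_g_per_l: float) -> float:
    """Inverse of :func:`teac` (round-trips to numerical precision)."""
    return curve.response(teac_value * sample_conc_g_per_l)


def fit_standard_curve(concentrations: Sequence[float],
                       responses: Sequence[float],
                       analyte: str = "standard") -> StandardCurve:
    """Ordinary least-squares line through calibration points.

    Requires at least three distinct concentrations; warns when R² < 0.98.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CurveError("concentrations and responses must be 1-D, equal length")
    if np.unique(x).size < 3:
        raise CurveError(
            f"need >= 3 distinct concentrations, got {np.unique(x).size}"
        )
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        raise CurveError("fitted slope is zero")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.98:
        logger.warning("standard curve %r: R^2 = %.4f < 0.98", analyte, r2)
    return StandardCurve(analyte, float(slope), float(intercept),
                         valid_range=(float(x.min()), float(x.max())),
                         r_squared=r2)


def equivalents_content(sample_response: float, curve: StandardCurve,
                        sample_conc_g_per_l: float) -> EquivalentsResult:
    """Standard-equivalent content in mg equivalents per 100 g dry weight.

    The equivalent concentration (µg/mL) from the inverted curve is
    divided by the sample concentration (converted to µg/mL) and scaled
    to a per-100-g basis (x 1e5).  Responses below the lowest calibration
    standard are reported as not detected.
    """
    if sample_conc_g_per_l <= 0:
        raise AssayError("sample concentration must be positive")
    c_eq_ug_per_ml = curve.concentration(sample_response)
    if curve.valid_range is not None:
        lowest_response = curve.response(curve.valid_range[0])
        below = (sample_response < lowest_response if curve.slope > 0
                 else sample_response > lowest_response)
        if below:
            return EquivalentsResult(content_mg_per_100g=None, below_detection=True)
    sample_ug_per_ml = sample_conc_g_per_l * 1000.0
    content = c_eq_ug_per_ml / sample_ug_per_ml * 1e5
    return EquivalentsResult(content_mg_per_100g=content, below_detection=False)


def analyze_plate(plate: RadicalAssayPlate, curve: StandardCurve) -> list[AntioxidantResult]:
    """RSC + TEAC for every sample group on a DPPH/ABTS plate."""
    out = []
    for sample_id, reps in plate.sample_abs.items():
        rsc = radical_scavenging(plate.blank_abs, reps)
        conc = plate.sample_conc.get(sample_id, 5.0)
        extrapolated = False
        if curve.valid_range is not None:
            lo, hi = (curve.response(curve.valid_range[0]),
                      curve.response(curve.valid_range[1]))
            lo, hi = min(lo, hi), max(lo, hi)
            extrapolated = not (lo <= rsc.value_pct <= hi)
        out.append(AntioxidantResult(
            sample_id=sample_id,
            rsc_pct=rsc.value_pct,
            rsc_sd=rsc.sd_pct,
            teac=teac(rsc.value_pct, curve, conc),
            negative_rsc=rsc.negative,
            extrapolated=extrapolated,
        ))
    return out
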