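"""MTT viability, dose-response IC50, and areal-dose conversion.

Viability is the treated/untreated formazan absorbance ratio.  IC50 is
read off a four-parameter log-logistic fit at absolute 50% viability,
with a log-linear interpolation fallback and right-censoring when the
series never crosses 50%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import AssayError, FitError, InputError

logger = logging.getLogger(__name__)

DEFAULT_WELL_VOLUME_UL = 200.0
DEFAULT_GROWTH_AREA_CM2 = 0.32


@dataclass
class ViabilityPlate:
    """Untreated-control and treated replicate absorbances (MTT)."""

    untreated_abs: np.ndarray
    treated_abs: Mapping[tuple[str, float], np.ndarray]  # (sample_id, conc µg/mL)
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.untreated_abs = np.asarray(self.untreated_abs, dtype=float)
        self.treated_abs = {k: np.asarray(v, dtype=float)
                            for k, v in self.treated_abs.items()}
        if self.untreated_abs.size == 0:
            raise AssayError("no untreated wells")
        if float(np.mean(self.untreated_abs)) <= 0:
            raise AssayError("untreated mean absorbance must be positive")

    def sample_ids(self) -> list[str]:
        return sorted({sid for sid, _ in self.treated_abs})

    def series(self, sample_id: str) -> "DoseResponseSeries":
        pairs = sorted((conc, reps) for (sid, conc), reps in self.treated_abs.items()
                       if sid == sample_id)
        if not pairs:
            raise AssayError(f"no treated wells for sample {sample_id!r}")
        concs = [c for c, _ in pairs]
        viab = [viability(reps, self.untreated_abs).value_pct for _, reps in pairs]
        return DoseResponseSeries(sample_id=sample_id,
                                  concentrations=np.array(concs),
                                  viability=np.array(viab))


@dataclass(frozen=True)
class ViabilityResult:
    value_pct: float
    sd_pct: float
    above_100: bool  # proliferation flag


@dataclass
class DoseResponseSeries:
    """Paired concentrations (µg/mL, ascending) and viabilities (%)."""

    sample_id: str
    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise InputError("concentrations and viability must align")
        if np.any(self.concentrations <= 0):
            raise InputError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            order = np.argsort(self.concentrations)
            self.concentrations = self.concentrations[order]
            self.viability = self.viability[order]
        if np.any(~np.isfinite(self.viability)):
            raise InputError("viability must be finite")


@dataclass(frozen=True)
class IC50Result:
    """Fitted or censored IC50.

    When `censored` is True the series never crossed 50% viability and
    `ic50` holds the lower bound (the highest tested concentration).
    """

    ic50: float
    censored: bool
    method: str  # "4pl" | "interpolation" | "censored"
    hill: float | None = None
    bottom: float | None = None
    top: float | None = None

    def __str__(self) -> str:
        if self.censored:
            return f"IC50 > {self.ic50:g}"
        return f"IC50 = {self.ic50:.4g}"


def viability(a_t: Sequence[float], a_u: Sequence[float]) -> ViabilityResult:
    """Cell viability: 100 * mean(treated) / mean(untreated).

    Values above 100% (proliferation) are permitted and flagged.
    """
    a_t = np.asarray(a_t, dtype=float)
    a_u = np.asarray(a_u, dtype=float)
    if a_t.size == 0 or a_u.size == 0:
        raise AssayError("empty replicate array")
    mu = float(np.mean(a_u))
    if mu <= 0:
        raise AssayError(f"untreated mean must be positive, got {mu:g}")
    per_rep = 100.0 * a_t / mu
    value = float(np.mean(per_rep))
    sd = float(np.std(per_rep, ddof=1)) if a_t.size > 1 else 0.0
    return ViabilityResult(value_pct=value, sd_pct=sd, above_100=value > 100.0)


def four_param_logistic(logc: np.ndarray, bottom: float, top: float,
                        log_ic50: float, hill: float) -> np.ndarray:
    """Descending 4PL in log10 concentration."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def _solve_absolute_50(bottom: float, top: float, log_infl: float,
                       hill: float) -> float | None:
    """log10 concentration where the fitted curve crosses 50% viability."""
    if not (min(bottom, top) < 50.0 < max(bottom, top)):
        return None
    frac = (top - bottom) / (50.0 - bottom) - 1.0
    if frac <= 0:
        return None
    return log_infl + math.log10(frac) / hill


def fit_ic50(series: DoseResponseSeries) -> IC50Result:
    """IC50 at absolute 50% viability from a four-parameter logistic fit.

    Falls back to log-linear interpolation between the bracketing doses
    when the fit does not converge; returns a censored bound when the
    series never drops to 50%.
    """
    conc = series.concentrations
    viab = series.viability
    if np.min(viab) > 50.0:
        return IC50Result(ic50=float(conc.max()), censored=True, method="censored")
    if conc.size < 4:
        return _interpolate_ic50(series)
    logc = np.log10(conc)
    p0 = [max(float(viab.min()), 0.0), float(viab.max()),
          float(np.mean(logc)), 1.0]
    try:
        popt, _ = curve_fit(four_param_logistic, logc, viab, p0=p0,
                            maxfev=20000)
        bottom, top, log_infl, hill = (float(v) for v in popt)
        log_ic50 = _solve_absolute_50(bottom, top, log_infl, hill)
        if log_ic50 is None or not np.isfinite(log_ic50):
            raise FitError("fitted curve does not cross 50%")
        return IC50Result(ic50=10.0 ** log_ic50, censored=False, method="4pl",
                          hill=hill, bottom=bottom, top=top)
    except (RuntimeError, FitError):
        logger.warning("4PL fit failed for %r; using log-linear interpolation",
                       series.sample_id)
        return _interpolate_ic50(series)


def _interpolate_ic50(series: DoseResponseSeries) -> IC50Result:
    """Log-linear interpolation between the doses bracketing 50% viability."""
    conc, viab = series.concentrations, series.viability
    for i in range(len(conc) - 1):
        v0, v1 = viab[i], viab[i + 1]
        if (v0 - 50.0) * (v1 - 50.0) <= 0 and v0 != v1:
            f = (v0 - 50.0) / (v0 - v1)
            log_ic50 = math.log10(conc[i]) + f * (math.log10(conc[i + 1])
                                                  - math.log10(conc[i]))
            return IC50Result(ic50=10.0 ** log_ic50, censored=False,
                              method="interpolation")
    if np.min(viab) > 50.0:
        return IC50Result(ic50=float(conc.max()), censored=True, method="censored")
    raise FitError(f"cannot bracket 50% viability for {series.sample_id!r}")


def areal_dose(concentration_ug_per_ml: float,
               volume_ul: float = DEFAULT_WELL_VOLUME_UL,
               area_cm2: float = DEFAULT_GROWTH_AREA_CM2) -> float:
    """Convert a well concentration to a dose per monolayer area (µg/cm²)."""
    if volume_ul <= 0 or area_cm2 <= 0:
        raise InputError("well volume and growth area must be positive")
    if concentration_ug_per_ml < 0:
        raise InputError("concentration must be nonnegative")
    return concentration_ug_per_ml * (volume_ul / 1000.0) / area_cm2


def nontoxic_flag(series: DoseResponseSeries,
                  viability_cutoff_pct: float = 75.0) -> bool:
    """True iff viability at the highest tested dose exceeds the cutoff."""
    top_idx = int(np.argmax(series.concentrations))
    return float(series.viability[top_idx]) > viability_cutoff_pct
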