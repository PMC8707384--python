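"""Candidate selection filters, composite radar-triangle score, ranking,
and content-activity correlation.

The composite score is the area of the triangle spanned, on three radar
axes 120 degrees apart, by the normalized SPFi and the two
radical-scavenging capacities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedMetricError

_SQRT3_4 = math.sqrt(3.0) / 4.0


@dataclass
class ScreeningRecord:
    """Per-isolate aggregate of all screening metrics."""

    isolate_id: str
    rsc_dpph: float | None = None
    rsc_abts: float | None = None
    teac_dpph: float | None = None
    teac_abts: float | None = None
    spfi: float | None = None
    spfi_pct_of_reference: float | None = None
    lambda_c: float | None = None
    uva_uvb: float | None = None
    stars: int | None = None
    viability_top_dose: float | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    status: str = "ok"  # ok | incomplete
    score: float | None = None
    rank: int | None = None


@dataclass(frozen=True)
class SelectionThresholds:
    """Pass/fail cutoffs applied by :func:`select_candidates`."""

    rsc_cutoff_pct: float = 50.0
    spfi_cutoff: float = 2.0
    lambda_c_cutoff_nm: float = 370.0
    uva_uvb_cutoff: float = 0.7


#: Criterion name -> (record attribute, comparison against the threshold)
_CRITERIA = (
    ("rsc_dpph", "rsc_dpph", "gt", "rsc_cutoff_pct"),
    ("rsc_abts", "rsc_abts", "gt", "rsc_cutoff_pct"),
    ("spfi", "spfi", "gt", "spfi_cutoff"),
    ("lambda_c", "lambda_c", "gt", "lambda_c_cutoff_nm"),
    ("uva_uvb", "uva_uvb", "ge", "uva_uvb_cutoff"),
)


def evaluate_criteria(record: ScreeningRecord,
                      thresholds: SelectionThresholds) -> dict[str, bool | None]:
    """Per-criterion pass flags; None marks a missing metric."""
    flags: dict[str, bool | None] = {}
    for name, attr, op, thr_attr in _CRITERIA:
        value = getattr(record, attr)
        threshold = getattr(thresholds, thr_attr)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            flags[name] = None
        elif op == "gt":
            flags[name] = value > threshold
        else:
            flags[name] = value >= threshold
    return flags


def select_candidates(records: Iterable[ScreeningRecord],
                      thresholds: SelectionThresholds | None = None,
                      audit: list[dict] | None = None) -> list[ScreeningRecord]:
    """Records passing every selection criterion.

    Records missing any required metric are marked ``status="incomplete"``
    (and excluded) rather than silently dropped.  When `audit` is given,
    one row per record with all per-criterion flags is appended to it.
    """
    thresholds = thresholds or SelectionThresholds()
    selected = []
    for record in records:
        flags = evaluate_criteria(record, thresholds)
        incomplete = any(v is None for v in flags.values())
        record.flags = {k: bool(v) for k, v in flags.items() if v is not None}
        record.status = "incomplete" if incomplete else "ok"
        passed = not incomplete and all(flags.values())
        if audit is not None:
            audit.append({"isolate_id": record.isolate_id, **flags,
                          "status": record.status, "selected": passed})
        if passed:
            selected.append(record)
    return selected


def triangle_score(spfi_pct: float, rsc_dpph: float, rsc_abts: float) -> float:
    """Area of the radar triangle with vertices at the three axis values.

    Axes are 120 degrees apart, so the area is
    (sqrt(3)/4) * (v1*v2 + v2*v3 + v3*v1); symmetric in its arguments.
    All three values must be nonnegative and on a common 0-100 scale
    (SPFi expressed as percent of the reference UV filter).
    """
    values = (spfi_pct, rsc_dpph, rsc_abts)
    if any(v < 0 for v in values):
        raise InputError(
            f"triangle_score requires nonnegative axis values, got {values}"
        )
    v1, v2, v3 = values
    return _SQRT3_4 * (v1 * v2 + v2 * v3 + v3 * v1)


def score_records(records: Sequence[ScreeningRecord],
                  floor_negative: bool = True) -> list[ScreeningRecord]:
    """Attach triangle scores; negative RSC axes are floored to 0 and flagged."""
    out = []
    for record in records:
        axes = [record.spfi_pct_of_reference, record.rsc_dpph, record.rsc_abts]
        if any(a is None for a in axes):
            raise InputError(
                f"{record.isolate_id}: triangle score needs spfi_pct_of_reference,"
                " rsc_dpph and rsc_abts"
            )
        if floor_negative and any(a < 0 for a in axes):
            record.flags["negative_axis_floored"] = True
            axes = [max(a, 0.0) for a in axes]
        record.score = triangle_score(*axes)
        out.append(record)
    return out


def rank_records(records: Sequence[ScreeningRecord]) -> list[ScreeningRecord]:
    """Deterministic descending ranking by score.

    Ties are broken by higher normalized SPFi, then lexicographic
    isolate id, so re-running on shuffled input yields identical output.
    """
    if any(r.score is None for r in records):
        raise InputError("all records need scores before ranking")
    ordered = sorted(
        records,
        key=lambda r: (-r.score, -(r.spfi_pct_of_reference or 0.0), r.isolate_id),
    )
    for i, record in enumerate(ordered, start=1):
        record.rank = i
    return ordered


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value from the t distribution.

    Computed from first principles (t = r * sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom) rather than delegating the whole test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise InputError(f"need n >= 3, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("non-finite values")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.sum(xd ** 2)))
    sy = float(np.sqrt(np.sum(yd ** 2)))
    if sx == 0 or sy == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    r = float(np.sum(xd * yd)) / (sx * sy)
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (optional; raw p is the default report)."""
    m = len(p_values)
    return [min(p * m, 1.0) for p in p_values]
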