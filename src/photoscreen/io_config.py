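"""CSV readers/writers, run configuration, and the audit log.

All containers are plain CSV with a header row.  Spectra are two-column
(wavelength nm, absorbance AU); plate tables are long-format wells with
role/replicate columns; feature tables carry one feature per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .antioxidant import RadicalAssayPlate
from .cytotoxicity import ViabilityPlate
from .errors import AdductError, CoverageError, EmptyPlateError, FormatError, FormulaError, InputError
from .ms_features import Feature, FeatureTable, normalize_adduct, parse_formula
from .uv_metrics import AbsorbanceSpectrum

logger = logging.getLogger(__name__)

RADICAL_ASSAYS = ("DPPH", "ABTS", "TPC", "TFC")
VIABILITY_ASSAYS = ("MTT",)


@dataclass
class RunConfig:
    """Pipeline-wide grids, cutoffs, and tolerances."""

    wavelength_step_nm: float = 1.0
    spf_band: tuple[float, float] = (290.0, 320.0)
    full_band: tuple[float, float] = (290.0, 400.0)
    rsc_cutoff_pct: float = 50.0
    spfi_cutoff: float = 2.0
    spfi_most_active_cutoff: float = 5.0
    lambda_c_cutoff_nm: float = 370.0
    uva_uvb_cutoff: float = 0.7
    viability_cutoff_pct: float = 75.0
    ppm_tolerance: float = 10.0
    rt_tolerance_min: float = 0.2
    mw_threshold_da: float = 330.0
    reference_spfi: float | None = None  # SPFi of the reference UV filter
    well_volume_ul: float = 200.0
    growth_area_cm2: float = 0.32
    rng_seed: int = 0

    def __post_init__(self) -> None:
        numeric = [self.wavelength_step_nm, self.rsc_cutoff_pct,
                   self.spfi_cutoff, self.lambda_c_cutoff_nm,
                   self.uva_uvb_cutoff, self.viability_cutoff_pct,
                   self.ppm_tolerance, self.rt_tolerance_min,
                   self.mw_threshold_da]
        if any(not np.isfinite(v) for v in numeric):
            raise InputError("all config cutoffs must be finite")
        if self.wavelength_step_nm <= 0:
            raise InputError("wavelength_step_nm must be positive")
        if self.ppm_tolerance <= 0:
            raise InputError("ppm_tolerance must be positive")
        lo, hi = self.full_band
        slo, shi = self.spf_band
        if not (lo <= slo < shi <= hi):
            raise InputError("spf_band must lie within full_band")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a key=value config file (''#'' comments allowed)."""
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in ("spf_band", "full_band"):
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key == "rng_seed":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class SampleRecord:
    """Identity and assay concentration of one end-product sample."""

    sample_id: str
    isolate_id: str
    medium: str = "other"  # GYM | Zobell | other
    concentration: float = 5.0  # g/L

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise InputError(f"{self.sample_id}: concentration must be positive")


class AuditLog:
    """Machine-readable trail of every filter decision."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def record(self, stage: str, subject: str, decision: str, **details) -> None:
        self.rows.append({"stage": stage, "subject": subject,
                          "decision": decision, **details})

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.rows).to_csv(path, sep="\t", index=False)


def read_spectrum(path: str | Path,
                  dialect: Mapping[str, str] | None = None,
                  sample_id: str | None = None) -> AbsorbanceSpectrum:
    """Read a two-column wavelength/absorbance CSV.

    `dialect` maps the logical names ``wavelength``/``absorbance`` to the
    file's column headers.  Wavelengths in descending order are sorted
    ascending with a warning; non-monotone grids are rejected.  The
    spectrum is restricted to 290-400 nm, which must be fully covered.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    else:
        df.columns = [c.strip().lower() for c in df.columns]
        if "wavelength" not in df.columns and len(df.columns) == 2:
            df.columns = ["wavelength", "absorbance"]
    for col in ("wavelength", "absorbance"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    wl = df["wavelength"].to_numpy(dtype=float)
    ab = df["absorbance"].to_numpy(dtype=float)
    diffs = np.diff(wl)
    if np.all(diffs < 0):
        logger.warning("%s: descending wavelengths, sorting ascending", path)
        wl, ab = wl[::-1], ab[::-1]
    elif np.any(diffs <= 0):
        raise FormatError(f"{path}: wavelengths are not strictly monotone")
    sid = sample_id or path.stem
    if wl[0] > 290.0 or wl[-1] < 400.0:
        gaps = []
        if wl[0] > 290.0:
            gaps.append(f"290-{min(wl[0], 400) - 1:g} missing")
        if wl[-1] < 400.0:
            gaps.append(f"{max(wl[-1], 290) + 1:g}-400 missing")
        raise CoverageError(f"{path}: spectrum does not cover 290-400 nm: "
                            + "; ".join(gaps))
    keep = (wl >= 290.0) & (wl <= 400.0)
    spectrum = AbsorbanceSpectrum(wl[keep], ab[keep], sample_id=sid)
    if spectrum.has_negative:
        logger.warning("%s: negative absorbance values present", path)
    return spectrum


def write_spectrum(spectrum: AbsorbanceSpectrum, path: str | Path) -> None:
    """Write a spectrum back to two-column CSV (6-decimal round trip)."""
    pd.DataFrame({
        "wavelength": np.round(spectrum.wavelengths, 6),
        "absorbance": np.round(spectrum.absorbance, 6),
    }).to_csv(path, index=False)


_PLATE_COLUMNS = ("role", "replicate", "absorbance")
_RADICAL_ROLES = {"blank", "sample"}
_VIABILITY_ROLES = {"untreated", "treated"}


def _load_plate_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyPlateError(f"{path}: empty plate file") from None
    if df.empty:
        raise EmptyPlateError(f"{path}: plate file has no rows")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _PLATE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df["role"] = df["role"].astype(str).str.strip().str.lower()
    return df


def _radical_plate(df: pd.DataFrame, assay: str, source: str) -> RadicalAssayPlate:
    bad = set(df["role"]) - _RADICAL_ROLES
    if bad:
        raise FormatError(f"{source}: unknown role labels {sorted(bad)} "
                          f"for assay {assay} (expected blank/sample)")
    blanks = df[df["role"] == "blank"]["absorbance"].to_numpy(dtype=float)
    samples: dict[str, np.ndarray] = {}
    concs: dict[str, float] = {}
    sample_rows = df[df["role"] == "sample"]
    if "sample_id" not in df.columns and not sample_rows.empty:
        raise FormatError(f"{source}: sample rows need a sample_id column")
    for sid, grp in sample_rows.groupby("sample_id"):
        samples[str(sid)] = grp["absorbance"].to_numpy(dtype=float)
        if "concentration" in grp.columns and grp["concentration"].notna().any():
            concs[str(sid)] = float(grp["concentration"].dropna().iloc[0])
    return RadicalAssayPlate(assay=assay, blank_abs=blanks, sample_abs=samples,
                             sample_conc=concs)


def _viability_plate(df: pd.DataFrame, source: str) -> ViabilityPlate:
    bad = set(df["role"]) - _VIABILITY_ROLES
    if bad:
        raise FormatError(f"{source}: unknown role labels {sorted(bad)} "
                          "for MTT (expected untreated/treated)")
    untreated = df[df["role"] == "untreated"]["absorbance"].to_numpy(dtype=float)
    treated: dict[tuple[str, float], np.ndarray] = {}
    trows = df[df["role"] == "treated"]
    if not trows.empty:
        for col in ("sample_id", "concentration"):
            if col not in trows.columns:
                raise FormatError(f"{source}: treated rows need {col!r}")
        for (sid, conc), grp in trows.groupby(["sample_id", "concentration"]):
            treated[(str(sid), float(conc))] = grp["absorbance"].to_numpy(dtype=float)
    return ViabilityPlate(untreated_abs=untreated, treated_abs=treated)


def read_plate_table(path: str | Path, assay: str
                     ) -> RadicalAssayPlate | ViabilityPlate:
    """Read a long-format plate CSV for a single assay.

    Files carrying an ``assay`` column are filtered to the requested
    assay; see :func:`read_plate_tables` for the per-assay split.
    """
    assay = assay.strip().upper()
    df = _load_plate_frame(path)
    if "assay" in df.columns:
        df = df[df["assay"].astype(str).str.strip().str.upper() == assay]
        if df.empty:
            raise EmptyPlateError(f"{path}: no rows for assay {assay}")
    if assay in VIABILITY_ASSAYS:
        return _viability_plate(df, str(path))
    if assay in RADICAL_ASSAYS:
        return _radical_plate(df, assay, str(path))
    raise FormatError(f"unknown assay {assay!r}")


def read_plate_tables(path: str | Path) -> dict[str, RadicalAssayPlate | ViabilityPlate]:
    """Split a mixed plate file on its ``assay`` column, one plate per assay."""
    df = _load_plate_frame(path)
    if "assay" not in df.columns:
        raise FormatError(f"{path}: mixed-plate reads need an 'assay' column")
    out: dict[str, RadicalAssayPlate | ViabilityPlate] = {}
    for assay, grp in df.groupby(df["assay"].astype(str).str.strip().str.upper()):
        if assay in VIABILITY_ASSAYS:
            out[assay] = _viability_plate(grp, str(path))
        elif assay in RADICAL_ASSAYS:
            out[assay] = _radical_plate(grp, assay, str(path))
        else:
            raise FormatError(f"{path}: unknown assay label {assay!r}")
    return out


def read_feature_table(path: str | Path,
                       extract_id: str | None = None) -> FeatureTable:
    """Read an LC-MS feature CSV (feature_id, rt_min, mz_observed[, formula, adduct]).

    Rows with unparseable formulas or adduct labels are skipped with a
    logged error; surviving features are sorted by RT then m/z.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("feature_id", "rt_min", "mz_observed"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    eid = extract_id or path.stem
    features: list[Feature] = []
    errors: list[str] = []
    for _, row in df.iterrows():
        formula = row.get("formula")
        adduct = row.get("adduct")
        formula = None if pd.isna(formula) else str(formula)
        adduct = None if pd.isna(adduct) else str(adduct)
        try:
            if formula is not None:
                parse_formula(formula)
            feat = Feature(feature_id=str(row["feature_id"]),
                           rt=float(row["rt_min"]),
                           mz_observed=float(row["mz_observed"]),
                           formula=formula, adduct=adduct)
        except (FormulaError, AdductError, InputError) as exc:
            errors.append(str(exc))
            logger.error("%s: skipping row %r: %s", path, row["feature_id"], exc)
            continue
        features.append(feat)
    table = FeatureTable(extract_id=eid, features=features).sorted()
    if errors:
        logger.warning("%s: skipped %d rows", path, len(errors))
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    pd.DataFrame([{
        "feature_id": f.feature_id,
        "rt_min": f.rt,
        "mz_observed": f.mz_observed,
        "formula": f.formula or "",
        "adduct": f.adduct or "",
    } for f in table.features]).to_csv(path, index=False)
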