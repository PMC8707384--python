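"""LC-MS feature-table characterization.

Theoretical adduct m/z from molecular formulas (fixed monoisotopic
element masses, proton mass for +1 charge), ppm mass accuracy,
permeation-relevant mass fractions, greedy cross-extract feature
matching with exact UpSet-style intersection counts, and a ppm-window
annotation matcher against a user-supplied compound table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .errors import AdductError, FormulaError, InputError

#: Monoisotopic element masses (Da).
ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376151,
    "S": 31.97207069,
}

PROTON_MASS = 1.00727646
#: Monoisotopic mass of acetonitrile (C2H3N).
ACN_MASS = 2 * ELEMENT_MASSES["C"] + 3 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["N"]


@dataclass(frozen=True)
class AdductSpec:
    """A singly-charged positive-mode adduct: m/z = M + mass_shift."""

    label: str
    mass_shift: float
    charge: int = 1


ADDUCTS: Mapping[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", PROTON_MASS),
    "[M+ACN+H]+": AdductSpec("[M+ACN+H]+", ACN_MASS + PROTON_MASS),
    "[M+2ACN+H]+": AdductSpec("[M+2ACN+H]+", 2 * ACN_MASS + PROTON_MASS),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def normalize_adduct(label: str) -> str:
    """Canonicalize an adduct label (whitespace/case tolerant)."""
    compact = re.sub(r"\s+", "", label).upper()
    for canonical in ADDUCTS:
        if compact == canonical.upper():
            return canonical
    raise AdductError(
        f"unknown adduct {label!r}; supported: {', '.join(ADDUCTS)}"
    )


def parse_formula(formula: str) -> dict[str, int]:
    """Elemental composition from a Hill-style formula string."""
    counts: dict[str, int] = {}
    pos = 0
    stripped = formula.strip()
    for match in _FORMULA_TOKEN.finditer(stripped):
        if match.start() != pos:
            raise FormulaError(
                f"cannot parse formula {formula!r} at position {pos}"
            )
        pos = match.end()
        element = match.group(1)
        if element not in ELEMENT_MASSES:
            raise FormulaError(
                f"unsupported element {element!r} in formula {formula!r}"
            )
        counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
    if pos != len(stripped):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic neutral mass (Da) of a molecular formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    for element in counts:
        if element not in ELEMENT_MASSES:
            raise FormulaError(f"unsupported element {element!r}")
    return sum(ELEMENT_MASSES[el] * n for el, n in counts.items())


def adduct_mz(formula: str | Mapping[str, int], adduct: str | AdductSpec) -> float:
    """Theoretical m/z of a formula under a singly-charged adduct."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[normalize_adduct(adduct)]
    return (monoisotopic_mass(formula) + adduct.mass_shift) / adduct.charge


def round_half_up(value: float, decimals: int = 4) -> float:
    """Decimal half-up rounding, matching printed m/z tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def ppm_error(mz_observed: float, mz_calculated: float) -> float:
    """|observed - calculated| / calculated * 1e6 (calculated denominator)."""
    if mz_calculated <= 0:
        raise InputError("calculated m/z must be positive")
    return abs(mz_observed - mz_calculated) / mz_calculated * 1e6


@dataclass
class Feature:
    """One LC-MS feature (retention time + observed m/z)."""

    feature_id: str
    rt: float
    mz_observed: float
    formula: str | None = None
    adduct: str | None = None
    identification_level: int | None = None  # 3, 4 or None

    def __post_init__(self) -> None:
        if self.mz_observed <= 0:
            raise InputError(f"feature {self.feature_id}: m/z must be positive")
        if self.rt < 0:
            raise InputError(f"feature {self.feature_id}: RT must be >= 0")
        if self.adduct is not None:
            self.adduct = normalize_adduct(self.adduct)

    @property
    def neutral_mass(self) -> float | None:
        """Adduct-corrected neutral mass, when the adduct is known."""
        if self.adduct is None:
            return None
        return self.mz_observed - ADDUCTS[self.adduct].mass_shift


@dataclass
class FeatureTable:
    """All features detected in one extract."""

    extract_id: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise InputError(f"duplicate feature ids in extract {self.extract_id!r}")

    def __len__(self) -> int:
        return len(self.features)

    def sorted(self) -> "FeatureTable":
        return FeatureTable(self.extract_id,
                            sorted(self.features, key=lambda f: (f.rt, f.mz_observed)))


def mass_fraction_above(table: FeatureTable, threshold_da: float = 330.0,
                        use_neutral_mass: bool = False) -> float:
    """Percent of features at or above the mass threshold.

    With `use_neutral_mass`, features with a known adduct are compared on
    their adduct-corrected neutral mass instead of the observed m/z.
    """
    if len(table) == 0:
        raise InputError(f"extract {table.extract_id!r}: empty feature table")
    count = 0
    for feat in table.features:
        mass = feat.mz_observed
        if use_neutral_mass and feat.neutral_mass is not None:
            mass = feat.neutral_mass
        if mass >= threshold_da:
            count += 1
    return 100.0 * count / len(table)


@dataclass
class FeatureGroup:
    """A cross-extract group of mutually matching features."""

    members: dict[str, Feature]  # extract_id -> feature

    @property
    def presence(self) -> frozenset[str]:
        return frozenset(self.members)

    @property
    def mz(self) -> float:
        return sum(f.mz_observed for f in self.members.values()) / len(self.members)


def match_features(tables: Sequence[FeatureTable], ppm_tol: float = 10.0,
                   rt_tol_min: float = 0.2) -> list[FeatureGroup]:
    """Greedy grouping of features across extracts.

    Features are pooled and scanned in ascending m/z; each ungrouped
    feature seeds a group that absorbs, per other extract, the nearest
    ungrouped feature within both the ppm window and the RT window.
    The result is an exhaustive, disjoint partition.
    """
    if len(tables) < 2:
        raise InputError("need at least two feature tables")
    if ppm_tol <= 0 or rt_tol_min < 0:
        raise InputError("tolerances must be positive")
    pool = [(t.extract_id, f) for t in tables for f in t.features]
    pool.sort(key=lambda ef: (ef[1].mz_observed, ef[1].rt, ef[0]))
    grouped = [False] * len(pool)
    groups: list[FeatureGroup] = []
    for i, (extract_i, seed) in enumerate(pool):
        if grouped[i]:
            continue
        grouped[i] = True
        members = {extract_i: seed}
        window = seed.mz_observed * ppm_tol * 1e-6
        # candidates per extract, nearest m/z first
        best: dict[str, tuple[float, int]] = {}
        for j in range(i + 1, len(pool)):
            extract_j, feat = pool[j]
            dmz = feat.mz_observed - seed.mz_observed
            if dmz > window:
                break
            if grouped[j] or extract_j in members:
                continue
            if abs(feat.rt - seed.rt) > rt_tol_min:
                continue
            if extract_j not in best or abs(dmz) < best[extract_j][0]:
                best[extract_j] = (abs(dmz), j)
        for extract_j, (_, j) in best.items():
            grouped[j] = True
            members[extract_j] = pool[j][1]
        groups.append(FeatureGroup(members=members))
    return groups


def intersection_counts(groups: Iterable[FeatureGroup]) -> dict[frozenset[str], int]:
    """Exact UpSet-style counts: each group counts once, under its full
    presence set, so counts sum to the number of groups."""
    counts: dict[frozenset[str], int] = {}
    for group in groups:
        key = group.presence
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass(frozen=True)
class Annotation:
    """Annotation of one feature against a compound table."""

    feature_id: str
    level: int | None  # 3 = single candidate structure, 4 = formula only
    candidates: tuple[str, ...]
    formula: str | None
    adduct: str | None
    isomer_coincidence: int
    ppm: float | None


def annotate(features: Iterable[Feature],
             compound_table: Sequence[Mapping[str, str]],
             adducts: Sequence[str] | None = None,
             ppm_tol: float = 10.0) -> list[Annotation]:
    """Match observed m/z against every compound x adduct within a ppm window.

    Identification levels follow the high-resolution-MS confidence
    convention: level 3 when exactly one candidate structure matches,
    level 4 when several isomers of a single formula match (the isomer
    count is reported).  Matches spanning different formulas yield no
    level.
    """
    adduct_labels = [normalize_adduct(a) for a in (adducts or list(ADDUCTS))]
    # precompute theoretical m/z per (compound, adduct)
    theoretical = []
    for entry in compound_table:
        formula = entry["formula"]
        counts = parse_formula(formula)
        for label in adduct_labels:
            theoretical.append(
                (entry["name"], formula, label, adduct_mz(counts, label))
            )
    out = []
    for feat in features:
        hits = []
        for name, formula, label, mz_calc in theoretical:
            err = ppm_error(feat.mz_observed, mz_calc)
            if err <= ppm_tol:
                hits.append((name, formula, label, err))
        if not hits:
            out.append(Annotation(feat.feature_id, None, (), None, None, 0, None))
            continue
        formulas = {formula for _, formula, _, _ in hits}
        names = tuple(sorted({name for name, _, _, _ in hits}))
        best_ppm = min(err for _, _, _, err in hits)
        if len(hits) == 1:
            name, formula, label, err = hits[0]
            out.append(Annotation(feat.feature_id, 3, (name,), formula, label, 1, err))
        elif len(formulas) == 1:
            formula = next(iter(formulas))
            label = hits[0][2]
            out.append(Annotation(feat.feature_id, 4, names, formula, label,
                                  len(names), best_ppm))
        else:
            out.append(Annotation(feat.feature_id, None, names, None, None,
                                  len(names), best_ppm))
    return out
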