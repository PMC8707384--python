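"""Synthetic inputs with known ground truth for every pipeline stage.

Spectra are sums of Gaussian absorbance bands on the 290-400 nm grid;
plates are back-computed from true radical-scavenging capacities and
true four-parameter-logistic viability curves with additive Gaussian
well noise; feature tables plant formulas/adducts with controlled ppm
jitter and cross-extract overlap.  All generators take explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .antioxidant import RadicalAssayPlate
from .cytotoxicity import DoseResponseSeries, ViabilityPlate, four_param_logistic
from .errors import InputError
from .ms_features import Feature, FeatureTable, adduct_mz
from .uv_metrics import AbsorbanceSpectrum

DEFAULT_DOSES_UG_PER_ML = (3.13, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0)


@dataclass(frozen=True)
class Band:
    center_nm: float
    sigma_nm: float
    peak_au: float

    def __post_init__(self) -> None:
        if not 250.0 <= self.center_nm <= 450.0:
            raise InputError("band center must lie in [250, 450] nm")
        if self.sigma_nm <= 0:
            raise InputError("band width must be positive")


@dataclass(frozen=True)
class SpectrumModel:
    """Smooth multi-band absorbance model with additive Gaussian noise."""

    bands: tuple[Band, ...]
    baseline_au: float = 0.0
    noise_sd_au: float = 0.0
    grid_step_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd_au < 0:
            raise InputError("noise_sd must be >= 0")
        if self.grid_step_nm <= 0:
            raise InputError("grid step must be positive")

    def clean_absorbance(self, wavelengths: np.ndarray) -> np.ndarray:
        """Noise-free band sum (closed form, usable as an oracle)."""
        a = np.full_like(np.asarray(wavelengths, dtype=float), self.baseline_au)
        for band in self.bands:
            a = a + band.peak_au * np.exp(
                -((wavelengths - band.center_nm) ** 2) / (2.0 * band.sigma_nm ** 2)
            )
        return a


@dataclass(frozen=True)
class ViabilityTruth:
    """True 4PL viability curve parameters for one sample."""

    bottom: float = 0.0
    top: float = 100.0
    ic50_ug_per_ml: float | None = None  # None -> flat at `top` (nontoxic)
    hill: float = 1.5

    def viability_at(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if self.ic50_ug_per_ml is None:
            return np.full_like(conc, self.top)
        return four_param_logistic(np.log10(conc), self.bottom, self.top,
                                   np.log10(self.ic50_ug_per_ml), self.hill)


@dataclass
class IsolateTruth:
    """Ground truth for one synthetic isolate."""

    isolate_id: str
    rsc_dpph: float
    rsc_abts: float
    spectrum: SpectrumModel
    viability: ViabilityTruth = field(default_factory=ViabilityTruth)
    should_pass: bool = False


@dataclass
class PanelDesign:
    """A full synthetic screen with a designated pass set."""

    isolates: list[IsolateTruth]
    seed: int
    noise_sd: float = 0.0
    n_replicates: int = 3
    blank_mean: float = 0.70
    sample_conc_g_per_l: float = 5.0
    doses_ug_per_ml: tuple[float, ...] = DEFAULT_DOSES_UG_PER_ML

    @property
    def pass_set(self) -> frozenset[str]:
        return frozenset(i.isolate_id for i in self.isolates if i.should_pass)


def make_spectrum(model: SpectrumModel, seed: int,
                  sample_id: str = "synthetic") -> AbsorbanceSpectrum:
    """Realize a spectrum on the 290-400 nm grid (clipped at 0)."""
    rng = np.random.default_rng(seed)
    n = int(round(110.0 / model.grid_step_nm)) + 1
    grid = 290.0 + model.grid_step_nm * np.arange(n)
    a = model.clean_absorbance(grid)
    if model.noise_sd_au > 0:
        a = a + rng.normal(0.0, model.noise_sd_au, size=a.shape)
    return AbsorbanceSpectrum(grid, np.clip(a, 0.0, None), sample_id=sample_id)


#: Band sets used by the panel generator.  The passing profile has a strong
#: UV-B band plus a broad UV-A band (SPFi > 2, lambda_C > 370, ratio >= 0.7);
#: the UV-B-only profile fails the UV-A criteria.
PASSING_BANDS = (Band(305.0, 12.0, 0.8), Band(370.0, 22.0, 1.1))
UVB_ONLY_BANDS = (Band(305.0, 8.0, 0.9),)


def make_panel_design(n_isolates: int = 35, n_pass: int = 10,
                      seed: int = 0, noise_sd: float = 0.0) -> PanelDesign:
    """A screen where exactly `n_pass` isolates satisfy every filter.

    Failing isolates each violate at least one criterion (low DPPH, low
    ABTS, or a UV-B-only spectrum failing the UV-A requirements).
    """
    if not 0 <= n_pass <= n_isolates:
        raise InputError("n_pass must lie in [0, n_isolates]")
    rng = np.random.default_rng(seed)
    isolates: list[IsolateTruth] = []
    width = len(str(n_isolates))
    for i in range(n_isolates):
        isolate_id = f"S{i + 1:0{width}d}"
        passing = i < n_pass
        if passing:
            rsc_d = float(rng.uniform(60.0, 90.0))
            rsc_a = float(rng.uniform(60.0, 90.0))
            scale = float(rng.uniform(0.8, 1.6))
            bands = tuple(Band(b.center_nm, b.sigma_nm, b.peak_au * scale)
                          for b in PASSING_BANDS)
            viability = ViabilityTruth(ic50_ug_per_ml=None, top=float(rng.uniform(85, 99)))
        else:
            mode = i % 3
            if mode == 0:  # fails DPPH
                rsc_d = float(rng.uniform(5.0, 40.0))
                rsc_a = float(rng.uniform(55.0, 85.0))
                bands = PASSING_BANDS
            elif mode == 1:  # fails ABTS
                rsc_d = float(rng.uniform(55.0, 85.0))
                rsc_a = float(rng.uniform(5.0, 40.0))
                bands = PASSING_BANDS
            else:  # fails the UV-A criteria
                rsc_d = float(rng.uniform(55.0, 85.0))
                rsc_a = float(rng.uniform(55.0, 85.0))
                bands = UVB_ONLY_BANDS
            viability = ViabilityTruth(ic50_ug_per_ml=None, top=float(rng.uniform(80, 95)))
        isolates.append(IsolateTruth(
            isolate_id=isolate_id,
            rsc_dpph=rsc_d,
            rsc_abts=rsc_a,
            spectrum=SpectrumModel(bands=bands, noise_sd_au=noise_sd),
            viability=viability,
            should_pass=passing,
        ))
    return PanelDesign(isolates=isolates, seed=seed, noise_sd=noise_sd)


def make_spectra(design: PanelDesign) -> dict[str, AbsorbanceSpectrum]:
    return {
        iso.isolate_id: make_spectrum(iso.spectrum,
                                      seed=design.seed * 10007 + k,
                                      sample_id=iso.isolate_id)
        for k, iso in enumerate(design.isolates)
    }


def make_plates(design: PanelDesign) -> dict[str, RadicalAssayPlate | ViabilityPlate]:
    """Radical-assay plates (DPPH/ABTS) and the MTT viability plate.

    Blank wells are drawn near 0.70 AU; sample wells are back-computed
    from the true RSC through the percent-loss relation; viability wells
    come from the true 4PL curve, all with additive Gaussian noise.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_replicates
    plates: dict[str, RadicalAssayPlate | ViabilityPlate] = {}
    for assay, attr in (("DPPH", "rsc_dpph"), ("ABTS", "rsc_abts")):
        blank = design.blank_mean + rng.normal(0.0, design.noise_sd, size=n)
        blank_mean = float(np.mean(blank))
        samples = {}
        for iso in design.isolates:
            true_rsc = getattr(iso, attr)
            clean = blank_mean * (1.0 - true_rsc / 100.0)
            samples[iso.isolate_id] = clean + rng.normal(0.0, design.noise_sd, size=n)
        plates[assay] = RadicalAssayPlate(
            assay=assay, blank_abs=blank, sample_abs=samples,
            sample_conc={iso.isolate_id: design.sample_conc_g_per_l
                         for iso in design.isolates},
        )
    untreated = 0.80 + rng.normal(0.0, design.noise_sd, size=n)
    untreated_mean = float(np.mean(untreated))
    treated: dict[tuple[str, float], np.ndarray] = {}
    doses = np.asarray(design.doses_ug_per_ml, dtype=float)
    for iso in design.isolates:
        true_v = iso.viability.viability_at(doses)
        for dose, v in zip(doses, true_v):
            clean = untreated_mean * v / 100.0
            treated[(iso.isolate_id, float(dose))] = (
                clean + rng.normal(0.0, design.noise_sd, size=n)
            )
    plates["MTT"] = ViabilityPlate(untreated_abs=untreated, treated_abs=treated)
    return plates


def make_viability_series(truth: ViabilityTruth,
                          doses: Sequence[float] = DEFAULT_DOSES_UG_PER_ML,
                          noise_sd_pct: float = 0.0, seed: int = 0,
                          sample_id: str = "synthetic") -> DoseResponseSeries:
    """Direct dose-response series from a true 4PL curve + Gaussian noise."""
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    v = truth.viability_at(doses)
    if noise_sd_pct > 0:
        v = v + rng.normal(0.0, noise_sd_pct, size=v.shape)
    return DoseResponseSeries(sample_id=sample_id, concentrations=doses,
                              viability=v)


@dataclass(frozen=True)
class PlantedCompound:
    """A feature to plant: formula + adduct, optionally shared across extracts."""

    formula: str
    adduct: str
    extracts: tuple[str, ...]


def make_feature_tables(planted: Sequence[PlantedCompound],
                        extract_ids: Sequence[str],
                        ppm_jitter: float = 0.0,
                        seed: int = 0,
                        rt_range_min: tuple[float, float] = (2.0, 26.0),
                        ) -> list[FeatureTable]:
    """Feature tables with known composition and cross-extract overlap.

    Observed m/z = theoretical adduct m/z x (1 + eps), eps uniform on
    +-`ppm_jitter` ppm; a shared compound keeps one retention time across
    all extracts it occurs in (jittered independently per extract in m/z).
    """
    rng = np.random.default_rng(seed)
    tables: dict[str, list[Feature]] = {eid: [] for eid in extract_ids}
    for idx, compound in enumerate(planted):
        mz_theory = adduct_mz(compound.formula, compound.adduct)
        rt = float(rng.uniform(*rt_range_min))
        for eid in compound.extracts:
            if eid not in tables:
                raise InputError(f"planted compound references unknown extract {eid!r}")
            eps = float(rng.uniform(-ppm_jitter, ppm_jitter)) * 1e-6
            tables[eid].append(Feature(
                feature_id=f"{eid}_F{idx + 1}",
                rt=rt,
                mz_observed=mz_theory * (1.0 + eps),
                formula=compound.formula,
                adduct=compound.adduct,
            ))
    return [FeatureTable(extract_id=eid, features=feats).sorted()
            for eid, feats in tables.items()]
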