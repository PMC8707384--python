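# photoscreen

A screening pipeline for photoprotective microbial extracts: from raw
UV-Vis absorbance spectra and microplate assay readouts to in vitro sun
protection metrics, antioxidant capacity, cytotoxicity, a composite
photoprotection ranking, and LC-MS feature-table characterization.

## What it computes

- **uv_metrics** — in vitro SPF (erythemal-weighted absorbance sum,
  Mansur method, CF = 10), critical wavelength (90% cumulative
  absorbance on 290–400 nm), UVA/UVB integral ratio, Boots-style star
  rating, and the broad-spectrum claim (λ_C > 370 nm and ratio ≥ 0.7).
- **antioxidant** — DPPH/ABTS radical scavenging capacity
  (percent blank-absorbance loss), Trolox-equivalent antioxidant
  capacity through linear standard curves, and gallic-acid/quercetin
  equivalent contents (TPC/TFC) with below-detection handling.
- **cytotoxicity** — MTT viability (treated/untreated ratio),
  four-parameter-logistic IC50 at absolute 50% viability with a
  log-linear interpolation fallback and right-censoring, areal-dose
  conversion (µg/mL → µg/cm² on the monolayer), non-toxicity flagging.
- **screening_rank** — selection filters (RSC > 50% in both assays,
  SPFi > 2, λ_C > 370 nm, UVA/UVB ≥ 0.7, all configurable), the radar
  triangle-area composite score `(√3/4)·(v1·v2 + v2·v3 + v3·v1)`,
  deterministic ranking, and Pearson correlation with t-based p-values.
- **ms_features** — theoretical adduct m/z from molecular formulas
  (monoisotopic element masses + proton; [M+H]+, [M+ACN+H]+,
  [M+2ACN+H]+), ppm mass accuracy, mass fractions above a permeation
  threshold (330 Da), greedy cross-extract feature matching with exact
  UpSet-style intersection counts, and a ppm-window annotation matcher
  against a user-supplied compound table (identification levels 3/4).
- **io_config** — CSV readers/writers for spectra, long-format plates
  and feature tables, run configuration, and a tab-separated audit log.
- **synthetic_data** — generators for all of the above with known
  ground truth (Gaussian-band spectra, plates back-computed from true
  RSC / 4PL curves, planted feature overlaps), fully seeded.

## CLI

```sh
photoscreen synth panel --n 35 --n-pass 10 --seed 7 --out panel/
photoscreen uv-metrics --spectra panel/spectra/ --out uv.csv
photoscreen antioxidant --plates panel/plates.csv --out aox.csv
photoscreen cytotox --plate panel/plates.csv --out ct.csv
photoscreen screen --metrics uv.csv --antioxidant aox.csv \
    --cytotox ct.csv --reference-spfi 18 --out ranking.csv --audit-out audit.tsv
photoscreen msfeat mz --formula C28H38N4O6 --adduct "[M+H]+"
photoscreen msfeat match --tables a.csv,b.csv --out counts.csv
photoscreen msfeat annotate --features f.csv --compounds db.csv --out ann.csv
```

Spectra are two-column CSVs (`wavelength`, `absorbance`) covering
290–400 nm; plates are long-format CSVs with `assay`, `role`
(blank/sample or untreated/treated), `sample_id`, `concentration`,
`replicate`, `absorbance`; feature tables carry `feature_id`, `rt_min`,
`mz_observed` and optional `formula`/`adduct` columns.

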