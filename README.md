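# sdc-glioma

Diffusion-MRI metric mapping and IDH-genotype analysis for diffuse gliomas.

Adult diffuse gliomas are classified primarily by isocitrate dehydrogenase
(IDH) mutation status, which is normally determined from tissue. This
package implements a non-invasive, diffusion-weighted-imaging (DWI) based
analysis chain for that classification problem: from a single co-registered
multi-b-value DWI series it computes three pixelwise metrics, aggregates
them over a tumor region of interest, and combines them in a logistic
probability model of IDH-mutant genotype. It is written for imaging
scientists who want to apply, audit, or re-estimate this kind of model, and
ships synthetic phantom and cohort generators so the entire chain is
testable without patient data.

## The metrics and the model

Given signal volumes `S(b)` at diffusion weightings `b` (s/mm²):

- **SDC** (slow diffusion coefficient), default b = 500 and 750:

  `SDC = [S(b₁) − S(b₂)] / (b₂ − b₁)`  (au/s)

  a linear signal-difference index of tissue slow diffusion that avoids the
  log-ratio T2 sensitivity of ADC.

- **DDVD** (diffusion-derived vessel density), default b = 0 and 10:

  `DDVD = S_b0/ROI_area − S_b10/ROI_area`  (au/pixel)

  the mean per-pixel signal drop between b = 0 and a very low b — a
  microvascular-perfusion surrogate. The ROI scalar equals the ROI mean of
  the pixelwise `S_b0 − S_b10` map exactly.

- **ADC** (apparent diffusion coefficient), default b = 0 and 1000:

  `ADC = ln(S(b₁)/S(b₂)) / (b₂ − b₁)`  (mm²/s)

The shipped reference genotype model (SDC in au/s, DDVD in au/pixel, ADC in
10⁻⁴ mm²/s) is

```
p(IDH-mutant) = 1 / (1 + exp(−(8.941·SDC − 0.124·DDVD + 0.034·ADC − 1.229)))
```

and the same model form can be refit to any cohort by maximum likelihood.
Around these sit the supporting statistics a study of this design needs:
Mann-Whitney and Kruskal-Wallis group tests, Pearson correlations with
Fisher-z intervals, two-way random-effects ICC for inter-reader agreement,
empirical ROC/AUC, and diagnostic cutoff tables with Wilson-score 95%
confidence intervals and exact-fraction likelihood ratios.

## Worked example

Everything below is produced by the numbered drivers in `analysis/`
(each is a thin script over the library; run them in order):

```sh
python analysis/01_simulate_phantom.py
python analysis/02_metric_maps.py
```

```
       region  n_voxels  sdc_au_per_s  ddvd_au_per_pixel  adc_e4_mm2_per_s
wildtype_like      1056      0.367996          75.964896          8.962429
  mutant_like      1056      0.520169          32.804566         11.601845
direction check (wildtype-like: lower SDC, higher DDVD, lower ADC): PASS
```

The phantom's "wildtype-like" insert (hypervascular, densely cellular)
shows lower SDC, higher DDVD and lower ADC than the "mutant-like" insert —
the direction pattern the genotype model exploits. On the synthetic
63-subject cohort (33 wildtype, 30 mutant):

```sh
python analysis/03_simulate_cohort.py
python analysis/04_cohort_statistics.py
python analysis/06_genotype_model.py
```

```
sdc_au_per_s: wildtype vs mutant Mann-Whitney p = 3.34e-05
Pearson sdc_au_per_s ~ adc_e4_mm2_per_s: r = +0.803 (95% CI +0.692 to +0.876)
Pearson sdc_au_per_s ~ ki67_pct: r = -0.513 (95% CI -0.675 to -0.304)
refit: beta_sdc +9.304 (SE 6.744), ... in-sample AUC 0.875
  single-metric AUC sdc_au_per_s: 0.805
  single-metric AUC ddvd_au_per_pixel: 0.783
  single-metric AUC adc_e4_mm2_per_s: 0.770
```

SDC separates the genotypes on its own (AUC 0.805 here), and the fitted
three-metric combination improves on every single metric (AUC 0.875) — the
central claim the model encodes. `analysis/05_roc_cutoff_tables.py` writes
the full candidate-threshold table (sensitivity/specificity with 95% CIs
and likelihood ratios) to `results/cutoff_table_sdc.csv`.

The same steps are available as a CLI (`sdc-glioma run`,
`sdc-glioma compute-maps`, `sdc-glioma cutoff-table`, ... — see
`sdc-glioma --help`) for use on real NIfTI series and cohort CSVs.

## Layout

- `src/sdc_glioma/` — the library: `io` (NIfTI/bval/CSV), `synthetic`
  (phantom + cohort generators), `metrics` (SDC/DDVD/ADC + ROI
  aggregation), `stats` (rank tests, Pearson, ICC), `roc` (ROC/AUC, cutoff
  tables, Wilson intervals, DeLong), `model` (logistic genotype model),
  `pipeline`/`cli` (orchestration).
- `analysis/` — numbered narrative drivers writing `results/`.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
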