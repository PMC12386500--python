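# neuroftir

Chemometric analysis of ATR-FTIR spectra tracking rat cortical neuron
differentiation, built as a reusable, fully tested pipeline over a
synthetic spectrum generator.

During in-vitro differentiation (days in vitro, DIV 2–14) the infrared
fingerprint of whole neurons changes: protein content and α-helix /
intermolecular β-sheet structure rise, antiparallel β-sheet falls, lipids
accumulate with longer and more saturated acyl chains, and RNA signal
declines.  This package implements the full workflow used to quantify such
changes from absorbance spectra A(ν):

* **Preprocessing** per spectral region (lipid 3050–2800, protein
  1800–1500, fingerprint 1500–900 cm⁻¹): rubber-band baseline correction,
  area normalization (∫|A|dν = 1), Savitzky–Golay second derivative
  (7-point quadratic by default).
* **QC**: PCA outlier screening with Hotelling T² (F-distribution limit)
  and Q residual (Jackson–Mudholkar limit) at α = 0.01.
* **Regression**: kernel-algorithm PLS1 of second-derivative protein-region
  spectra on DIV, with grouped random-segment cross-validation
  (RMSEC/RMSECV, calibration/validation correlation) and factor-1
  β-coefficient band attribution.
* **Band metrics**: eleven metabolomic ratios/intensities, e.g. total
  protein = I_AmideI + I_AmideII, acyl chain length
  = (I₂₈₅₁+I₂₉₂₂)/(I₂₉₅₉+I₂₈₇₁), unsaturation = I₃₀₁₃/(I₂₈₅₁+I₂₉₂₂).
* **Statistics**: tie-corrected Kruskal–Wallis across the seven DIV groups
  with Dunn's post-hoc (Bonferroni over all 21 pairs) and mean ± SD
  summaries.

No measured spectra are publicly deposited, so the `synth` module generates
datasets with the study's structure — 7 DIV levels × 8 biological × 3
technical replicates, Gaussian bands at the assigned wavenumbers with
linear DIV amplitude trends, polynomial baselines, multiplicative and
additive noise, and a biological-replicate variance hierarchy.  See
`docs/methods.md` for the model and its limits.

## Worked example

```python
from neuroftir import pipeline

report = pipeline.run(pipeline.RunConfig(seed=1, outdir="results/run"))
print(report.correlation_cal, report.rmsecv, report.n_outliers_flagged)
# 0.9956692528831277 0.3911643808506435 0
```

The same analysis, step by step with printed narration, is in the numbered
drivers under `analysis/`:

```bash
python analysis/01_simulate.py        # datasets + band library table
python analysis/02_preprocess_qc.py   # PCA T2/Q screening
python analysis/03_pls_regression.py  # kernel PLS1 vs DIV
python analysis/04_band_metrics.py    # the 11 metabolomic metrics
python analysis/05_group_stats.py     # Kruskal-Wallis + Dunn
python analysis/06_calibration.py     # type-I error / power simulations
```

`03_pls_regression.py` prints, for the default synthetic conditions:

```
chosen factors: 1
factor 1: r_cal=0.996 r_val=0.995 RMSEC=0.372 RMSECV=0.391 DIV-days
factor-1 beta attribution (+1 late DIV, -1 early DIV):
   1740.0 cm^-1  +1  lipid_ester
   1692.0 cm^-1  -1  antiparallel_beta
   1652.0 cm^-1  +1  alpha_helix
   1628.0 cm^-1  +1  intermolecular_beta
   1544.0 cm^-1  +1  amide_II
   ...
```

i.e. one PLS factor orders the maturation stages to well under the 2-day
spacing between sampling points, and the β-coefficients attribute late
differentiation to the rising ester/α-helix/intermolecular-β/amide bands
and early differentiation to the declining antiparallel β-sheet band at
1693 cm⁻¹ — the construction encoded in the generator.  `05_group_stats.py`
shows every metric's DIV 2 vs DIV 14 Dunn comparison significant after
Bonferroni adjustment (`****`), and `06_calibration.py` confirms the
omnibus test holds its nominal 5 % false-positive rate (≈ 0.04) on
slope-zero null data.

## Layout

```
src/neuroftir/      synth, preprocess, qc, plsr, bands, stats, pipeline
analysis/           numbered narrative drivers writing to results/
tests/              unit, property and acceptance suites
scripts/            acceptance.py
docs/methods.md     model, parameters, numerical choices, limitations
```
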