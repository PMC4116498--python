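# qustex

Quantitative ultrasound (QUS) spectral-texture biomarkers for **early
prediction of chemotherapy response** in locally advanced breast cancer —
implemented as a tested, fully seeded pipeline from raw beamformed RF
ultrasound data to response classification and recurrence-free survival,
with a synthetic RF cohort simulator standing in for clinical data.

## The problem and the method

Tumour cell death changes the size, concentration and spatial arrangement of
sub-resolution acoustic scatterers, and with them the ultrasound backscatter
spectrum — weeks before any change in tumour size.  The pipeline quantifies
this:

1. **Spectral parametric maps.**  For each ~10-wavelength sliding window the
   per-line power spectra of the RF data are averaged and normalised by the
   spectrum of the *same window location* in a tissue-mimicking reference
   phantom acquired with identical scanner settings (cancelling the system
   transfer function, diffraction and first-order attenuation).  A line
   `S(f) = SS·f + I0` is fitted to the normalised spectrum (in dBr) over the
   transducer's −6 dB band, giving per-pixel
   * mid-band fit `MBF = SS·f_c + I0` (dBr) — backscatter power,
   * spectral slope `SS` (dBr/MHz) — effective scatterer size,
   * 0-MHz intercept `I0` (dBr) — scatterer concentration.
2. **Texture.**  Each map is quantised over the central-tumour ROI (~2/3 of
   the tumour cross-section at the focal depth) and symmetric gray-level
   co-occurrence matrices at 0°/45°/90°/135° yield contrast
   `Σ P(i,j)(i−j)²`, correlation `Σ P(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ)` and
   homogeneity `Σ P(i,j)/(1+|i−j|)`, averaged over angles (and distances).
3. **Longitudinal biomarkers.**  Mean and texture values are averaged over
   parallel scan planes (tumour volume) per visit, and expressed as the
   change from the pre-treatment baseline (percent of the baseline
   magnitude, with the absolute change carried alongside).
4. **Statistics.**  Responders vs non-responders are compared with a
   normality-gated t / two-sample-KS test; ultimate response is predicted
   from week-1 biomarkers with a pooled-covariance linear discriminant
   (leave-one-out sensitivity/specificity on the non-responder class, ROC
   AUC of the discriminant scores); recurrence-free survival is compared by
   Kaplan–Meier curves and a log-rank test.

The simulator generates point-scatterer tissue with a tumour whose response
is spatially heterogeneous (Poisson-placed patches with diffuse margins) for
responders and a homogeneous drift for non-responders, so the whole chain —
including the "texture moves before the mean becomes reliable" effect — is
exercised end-to-end with no data download.

## Worked example

```python
import qustex as qx
from qustex.pipeline import group_mean_shifts

patients = qx.simulate_cohort(15, 5, seed=42)     # responders / non-responders
result = qx.analyze_cohort(patients)

print(group_mean_shifts(result.visit_table, "mbf"))
print(result.classification[["feature_set", "sensitivity_pct",
                             "specificity_pct", "p_value", "auc"]])
```

prints (seed 42):

```
visit         label parameter  mean_shift_dbr  se_shift_dbr  n
  wk1 non-responder       mbf       -4.394321      1.373503  5
  wk1     responder       mbf        4.681727      1.403419 15
  wk4 non-responder       mbf        5.312767      8.311046  5
  wk4     responder       mbf        5.632466      1.712850 15

             feature_set  sensitivity_pct  specificity_pct      p_value      auc
                mbf_mean             60.0        86.666667 2.993502e-03 0.906667
            mbf_contrast             80.0       100.000000 5.223315e-05 0.973333
         mbf_homogeneity             60.0        86.666667 4.312911e-04 0.933333
         intercept0_mean             40.0        93.333333 4.698773e-02 0.720000
mbf+intercept0_combined8             80.0        93.333333 3.323368e-09 1.000000
```

The first table is the measured tumour-averaged MBF shift of each group at
weeks 1 and 4 (dBr, mean ± SE over patients): this cohort's responders
brightened by ~4.7 dBr at week 1 while non-responders darkened.  The second
table classifies each patient's *ultimate* response from week-1 biomarkers
alone: the texture biomarkers (contrast, homogeneity of the MBF map)
discriminate better than the plain mean shift, and the combined
spectral+textural profile separates the groups completely (AUC 1.0).  The
same run yields recurrence-free survival splits: log-rank p = 3.5e-06 by
true label and p = 3.0e-04 by the week-1 MBF-contrast prediction.

A command-line interface wraps the same steps
(`qustex simulate / maps / texture / biomarkers / classify / survival / all`);
`qustex all --seed 42 --out out/` reproduces the tables above as CSVs.

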