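# ventiqct

Integrated SPECT/qCT analysis of lung ventilation heterogeneity in COPD.

In chronic obstructive pulmonary disease, gas trapping from small-airway
disease and emphysematous tissue destruction reshape where inhaled air —
and with it an inhaled radioactive tracer — actually goes. This package
implements the quantitative machinery for studying that relationship in a
small longitudinal cohort imaged with both CT (at total lung capacity,
TLC, and at expiration) and SPECT ventilation scans:

* **qCT biomarkers** — the parametric response map (PRM) classifying each
  lung voxel of a registered inspiration/expiration pair as normal,
  gas-trapped (fSAD: inspiration HU ≥ −950 and expiration HU < −856) or
  emphysematous (below both thresholds); tissue fraction
  β = (HU + 1000)/1000; the Jacobian determinant J = det(I + ∇u) of the
  breathing deformation as a regional ventilation map; the anisotropic
  deformation index ADI = √(((λ₁−λ₂)/λ₂)² + ((λ₂−λ₃)/λ₃)²) from the
  principal stretches; lobar air-volume-change fractions ΔVairF and the
  upper-to-middle/lower ratio ΔVair,UML^F; airway metrics normalised
  against healthy-predicted values.
* **SPECT statistics** — lobar tracer share TC%, whole-lung heterogeneity
  CV_Total = SD/mean of voxel tracer concentration, and hot-spot magnitude
  TC_Max = max/mean, all computed after transporting the SPECT volume onto
  the TLC CT domain (affine mutual-information alignment to the expiration
  CT, then the expiration→inspiration displacement field).
* **Registration** — affine mutual-information alignment (SimpleITK
  backend) and a mass-preserving deformable registration minimising the
  sum of squared tissue-volume differences (SSTVD) over a multi-resolution
  free-form deformation.
* **Statistics for a small cohort** — Pearson correlation maps with
  conventional strength bands and |r| > 0.7 effect-size highlighting,
  exploratory factor analysis (principal-component extraction, Varimax
  rotation, parallel analysis for the factor count), and two-wave
  cross-lagged panel analysis whose cross-lagged terms are partial
  correlations with the outcome's prior wave partialled out.
* **A phantom generator** — paired CT volumes with seeded disease classes
  and a known smooth deformation (tissue mass conserved voxel-wise), plus
  misaligned, blurred, optionally Poisson-noisy SPECT volumes and a
  two-wave panel simulator, so every stage can be tested against ground
  truth.

The packaged data are the printed per-subject tables of an eight-subject,
three-visit COPD cohort (clinical/PFT values, CV_Total and TC_Max, and the
key qCT variables), which the `study` layer reproduces end to end.

## Worked example

```bash
python examples/reproduce_cohort.py
```

prints, among other things:

```
Pooled cross-sectional correlations (n = 22 subject-visits):
  r_cv_fsad: r = +0.905
  r_cv_emph: r = +0.710
  r_tcmax_fsad: r = +0.860
  r_tcmax_emph: r = +0.775
  r_cv_fev1pp: r = -0.738
  r_cv_fev1fvc: r = -0.797

Cross-lagged panel (fSAD% vs CV_Total at V1/V2, n = 8):
  fSAD1 -> CV2 partial r = +0.786 (significant: True)
  CV1 -> fSAD2 partial r = +0.141 (significant: False)
  inferred direction: x->y  (gas trapping drives ventilation heterogeneity, not the reverse)
```

Ventilation heterogeneity rises with gas trapping (r ≈ 0.90 with fSAD%)
and emphysema (r ≈ 0.71), falls with lung function (r ≈ −0.74 with
FEV1%pred), and the cross-lagged verdict pattern points from small-airway
disease to heterogeneity rather than the reverse. `examples/phantom_pipeline.py`
runs the full imaging chain on a synthetic lung and prints recovery
diagnostics (seeded 15% fSAD / 10% emphysema recovered within half a
point; 6 mm deformation recovered with ~0.7 mm mean endpoint error);
`examples/factor_analysis.py` and `examples/cross_lagged_calibration.py`
demonstrate the statistical layer on simulated data.

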