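# intrinsic-thickness

Folding-compensated cortical thickness from surface meshes.

Cortical thickness measured on a reconstructed surface covaries with
cortical folding: gyral crowns are consistently thicker and sulcal fundi
thinner. Since folds land in different places in different brains, this
folding signature inflates vertex-wise inter-individual variability,
obscures sharp thickness transitions at cortical area borders, and weakens
group statistics. This package estimates the *intrinsic* thickness — what
thickness would have been without folding — for researchers doing
surface-based morphometry (aging, development, cross-species and
parcellation studies).

## Method

At every vertex of a (regularized) mid-thickness mesh, five discrete
folding measures are computed: the principal curvatures k₁ ≥ k₂ (from mean
curvature H = ¼ Σᵢ‖lᵢ‖βᵢ/A and Gaussian curvature K = (2π − θₚ)/A),
the shape index SI = −(2/π)·arctan((k₁+k₂)/(k₂−k₁)) and the curvedness
C = √((k₁²+k₂²)/2). Thickness T is then fit, independently at each vertex,
over a geodesic patch with Gaussian weights (default 6 mm FWHM):

    T = β₀ + β₁X₁ + … + β₅X₅ + β₆X₁² + … + β₁₀X₅²

with X = (k₁, k₂, K, SI, C) demeaned within the patch, and compensated as

    Tcorr = T − β₁:₅·F − β₆:₁₀·F²

where F are the vertex's curvature values. A global single-regression
baseline (tcorr = t − H·k) is included, as are golden-section optimization
of the three smoothing/patch FWHM parameters against a target map, and the
evaluation statistics (spatial gradients, coefficient of variation, parcel
statistics, per-parcel age effect sizes f² = R²/(1−R²), and shape × depth
tables). A synthetic-cohort generator with exact analytic curvature ground
truth makes everything testable without restricted data.

## Worked example

```python
import numpy as np
import intrinsic_thickness as it

cohort = it.make_cohort(n_subjects=1, seed=0)      # synthetic folded sheet
s = cohort.subjects[0]
tcorr, fit, curv = it.compensate_pipeline(s.mesh, s.thickness,
                                          it.CompensationParams())
m = tcorr.mask
print(f"uncompensated: SD {s.thickness.values[m].std():.3f} mm")
print(f"compensated:   SD {tcorr.values[m].std():.3f} mm")
print("corr with k1: %.3f -> %.3f" % (
    np.corrcoef(s.thickness.values[m], curv.k1.values[m])[0, 1],
    np.corrcoef(tcorr.values[m], curv.k1.values[m])[0, 1]))
```

prints

```
uncompensated: SD 0.350 mm
compensated:   SD 0.061 mm
corr with k1: 0.855 -> 0.026
```

The generated subject's thickness carries a folding effect of ±0.35 mm that
tracks the maximum principal curvature (r = 0.86); after local compensation
the folding correlation is gone (r = 0.03) and the residual spread is the
measurement noise plus the intrinsic map. On real data the pipeline is the
same with GIFTI/FreeSurfer inputs:

```
intrinsic-thickness compensate \
    --surface mid.surf.gii --thickness thick.shape.gii \
    --mask roi.shape.gii --out MRcorrThickness.shape.gii
```

Subcommands: `curvature`, `regularize`, `compensate`, `optimize`,
`gradient`, `cov`, `parcel-stats`, `age-effect`, `shape-depth`, `synth`.

## Documentation

`docs/methods.md` describes the model, the numerical choices (ridge,
kernel truncation, fallbacks), the synthetic-data design and its
limitations.
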