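# Methods

## The problem

Measured cortical thickness covaries strongly with cortical folding: gyral
crowns are systematically thicker and sulcal fundi thinner than the
surrounding cortex. Because folding patterns differ across individuals, this
covariation inflates inter-individual thickness variability at every vertex
and blurs the sharp areal structure of the underlying ("intrinsic")
thickness map. This package estimates, at every vertex of a triangulated
cortical surface, what thickness would have been in the absence of folding,
by regressing folding geometry out of the measured thickness.

## Folding measures

At each vertex p of the (mid-thickness) mesh we compute discrete estimates
of:

- mean curvature `H_p = (1/4) * Σ_i ||l_i|| β_i / A_p`, summing over the
  edges incident to p (`l_i` edge length, `β_i` signed dihedral angle);
- Gaussian curvature `K_p = (2π − θ_p) / A_p` (angle deficit), with `θ_p`
  the sum of interior triangle angles at p.

`A_p` is the **vertex area**: one third of the summed areas of the
triangles meeting at p. The thirds partition the surface, which is what
makes both estimators consistent — on an icosphere of radius 50 mm the
masked median H is within 0.03% of 1/50 and K within 0.06% of 1/2500 at
subdivision 4, and the angle deficits sum to exactly 4π on any closed
genus-0 mesh (discrete Gauss–Bonnet). Dividing by the *full* one-ring area
instead biases both low by exactly 3×.

Dihedral angles are signed positive where the surface is convex with
respect to the outward normal, so gyri have H > 0 and sulci H < 0.

From H and K: principal curvatures `k1 = H + √(H²−K)`, `k2 = H − √(H²−K)`
(discriminant clamped to zero where discretization makes it negative; the
clamped fraction is reported), shape index
`SI = −(2/π)·arctan((k1+k2)/(k2−k1)) ∈ [−1, 1]` (cup −1, saddle 0, dome
+1; planar points set to 0 and flagged), and curvedness
`C = √((k1²+k2²)/2) ≥ 0`.

The regression uses the five measures (k1, k2, K, SI, C), in that fixed
order; H is excluded because it is exactly (k1+k2)/2.

## Regularization

Curvature estimates are sensitive to mesh quality, so before curvature
computation a native mesh can be (1) resampled onto a regular standard mesh
by barycentric interpolation through a matched sphere pair (no registration
— existing vertex correspondence is used), and (2) slightly smoothed with a
geodesic Gaussian kernel. Curvature maps are then smoothed the same way.
All kernels are specified as FWHM (σ = FWHM / 2√(2 ln 2)), truncated at 3σ
(<1.2% of Gaussian mass) and renormalized, with each neighbor weighted by
its one-third ring area so the average is robust to vertex-density
inhomogeneity. Smoothing respects the analysis mask: masked-out vertices
(medial wall, sheet borders) never contribute.

Geodesic distances are single-source Dijkstra shortest paths on the edge
graph with Euclidean edge lengths — an upper bound on the true polyhedral
geodesic, adequate at the ≤10 mm radii used here; an exact-geodesic
backend is a possible extension.

Surface smoothing is plain geodesic-Gaussian coordinate averaging. At the
default 2.14 mm FWHM the measured radius shrinkage on a 50 mm sphere is
below 0.1%, so no shrinkage-compensating (λ|μ) scheme is applied.

## Compensation models

**Global linear (single regression, SR).** One OLS fit `t = H·k + b` over
the whole analysis region; `tcorr = t − H·k`. The intercept stays in the
map. This underfits whenever the folding→thickness relationship varies
regionally.

**Local multiple regression (MR).** At each vertex, thickness over a
geodesic patch (Gaussian weights of a given FWHM, truncated at 3σ,
area-weighted) is regressed on the five predictors and their squares:

    T = β0 + β1 X1 + … + β5 X5 + β6 X1² + … + β10 X5²

Predictors and squared predictors are demeaned with the patch weights
(weighted demeaning *within each patch*, so β0 is the local weighted-mean
thickness and the fit is strictly local). The squares are squares of the
raw predictor values, demeaned afterwards. The compensated value subtracts
the folding-predicted part evaluated at the center's **raw** predictor
values:

    Tcorr = T − Σ βi·Fi − Σ β(5+i)·Fi²

Subtracting the raw-value prediction (rather than the patch-demeaned
deviation) removes both the within-patch and the patch-mean folding
contribution; on a noiseless sheet whose thickness is exactly linear in the
true curvatures, Tcorr recovers the constant intrinsic map to machine
precision when the same curvatures are supplied.

### Numerical safeguards

- **Ridge.** The normal equations get `ε · max_j(Σ w x_j²)` added to every
  diagonal entry, ε = 1e−4. The scaling by the *largest* column is
  deliberate: a locally near-constant predictor (e.g. SI ≈ +1 across a
  gyral crown) has almost no usable variance but a raw value of order one,
  so an unshrunk noise-driven coefficient would inject large errors into
  the raw-value subtraction. With this ridge the compensation is
  approximately idempotent (a second pass changes the map by <8% of the
  first-pass change on the default synthetic sheet) and exact-model
  recovery improves. Per-column-scaled ridges do not bound this mode.
- **Fallback ladder.** Patches with fewer than 33 in-mask vertices (3× the
  11 parameters) expand their radius 1.5× once; if a fit is rank-deficient
  after the ridge the quadratic columns are dropped; as a last resort
  `Tcorr = T` (the correct limit where folding explains nothing) and the
  vertex is flagged.
- Vertices are fit independently; outputs are bit-identical regardless of
  execution order.

### Free parameters

| parameter | default | role |
| --- | --- | --- |
| surface FWHM | 2.14 mm | geometry denoising before curvature |
| curvature FWHM | 2.52 mm | predictor denoising |
| patch FWHM | 6 mm | locality of the regression |

The defaults are the reference optimized configuration. `optimize_params`
re-derives them against a target ("silver standard") map — typically the
group average of globally compensated thickness, in which inconsistent
individual folding has largely averaged out — by maximizing the mean
across-subject R² of individual compensated maps on the target, with a
sequential golden-section search (patch, then surface, then curvature
FWHM; intervals [3, 10], [0, 3], [0, 3] mm; bracket tolerance 0.1 mm;
not-yet-optimized parameters held at interval midpoints; returned value is
the final bracket midpoint, with the best evaluated point in the trace).

## Evaluation statistics

- **Spatial gradient**: one-ring tangent-plane least-squares plane fit;
  the gradient magnitude marks candidate areal borders.
- **CoV**: across-subject SD / mean per vertex.
- **Parcel statistics**: group mean of per-subject parcel means and of
  per-subject within-parcel SDs (sample SDs, n−1).
- **Age effects**: per-parcel OLS of parcel-mean thickness on age; Cohen's
  `f² = R²/(1−R²)`; comparisons report the per-parcel percent change of f²
  and its area-weighted mean.
- **Shape × depth table**: mean thickness in shape-index × sulc bins
  (half-open bins, last bin closed); a subject with an empty cell is
  excluded from that cell's group mean.

## Synthetic data: what it emulates, and what it does not

Real cohorts of this kind are access-controlled, so all tests run on
generated sheets `z = A sin(2πx/λx + φx) sin(2πy/λy + φy)` with exact
Monge-patch curvatures as ground truth. Default conditions: 60×60 mm sheet,
1 mm spacing, λ = 20 mm, A = 2.5 mm (±10% per-subject jitter), per-subject
uniform random phases (inter-individual folding variability), 3 masked
border rings, 4×4 parcel tiling. Thickness is generated as

    T = T0(x) + g(x)·[1.5·k1 + 1.0·k2 + 0.15·SI] + age term + N(0, 0.05 mm)

with T0 = 2.5 mm plus optional sharp steps (areal borders), and a smooth
gain g(x) ∈ (0.25, 1.75) across the sheet. The gain makes the
folding→thickness coupling *regionally varying*, which is the regime the
local model exists for: with a spatially uniform coupling, a single global
regression is already the correct model and local regression can only add
noise. Aging cohorts add a −0.01 mm/year slope over ages uniform in
36–90. A `tanh` model-mismatch mode saturates the folding term to test
robustness when the data do not obey the fitted family.

Problem sizes in the test-suite and acceptance runs: 10,201-vertex sheets
for exact-model recovery, 20-subject cohorts (3,721 vertices each) for the
variability statistics, 40 subjects for the aging analysis.

What passing these tests does and does not show: the generator has perfect
geometry (no surface-placement error), periodic single-wavelength folds,
and a thickness model inside (or near) the fitted family. Real cortex has
aperiodic multi-scale folds, spatially correlated measurement error, and an
unknown folding→thickness law; results here demonstrate correctness of the
machinery and the direction of its effects, not real-data effect
magnitudes. Two synthetic regimes are worth knowing about:

- Because the generator couples thickness to the *analytic* curvatures
  while the full pipeline regresses on smoothed discrete estimates,
  predictor smoothing introduces a small systematic leak (~10% of the
  folding amplitude at these wavelengths). On real, noisy data the same
  smoothing is what makes the predictors usable.
- In regions where the coupling gain is near zero, compensation can only
  inject fit noise, and the per-parcel aging effect size does not improve
  there — mirroring the real-data observation that areas with little
  folding variability benefit least.

## Known limitations

- Dijkstra edge-graph distances overestimate true geodesics on coarse
  meshes; all kernels inherit this (consistently, so FWHM calibration
  absorbs most of it).
- The H estimator's 1/4 prefactor with vertex-area normalization has a
  known small bias at finite resolution (≈1.5% median on the default
  sheet); tests use tolerances that cover it.
- CIFTI dense files are out of scope; GIFTI and FreeSurfer binary formats
  are the interchange formats.
- No exact polyhedral geodesics, mesh repair, or surface registration.
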