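# Methods

## Problem setting and assumptions

`fidmatch` corresponds fiducial-marker coordinate sets across
electron-tomography tilt series. Its data model makes three assumptions:

1. Between two tilted views, marker positions are related by a global
   in-plane affine transform (projection rescaling by the tilt-angle
   cosines, plus stage rotation/translation and magnification changes)
   **up to** a smooth residual displacement field from beam-induced
   motion and sample deformation.
2. Markers are sparse: the typical nearest-neighbour spacing is large
   compared to both the localization error and the congruence threshold.
3. Detection is imperfect — markers are missed (increasingly at high
   tilt, where shadows and overlap obscure beads) and spurious detections
   appear (increasingly at high tilt, where the projected field of view
   widens).

Matching is purely geometric; no image intensities are used.

## Stage one: feature-driven RANSAC affine

The invariant used for hypothesis generation is the 4-point feature:
points `a, b, c, d` with intersecting diagonals `ab`, `cd` define ratios
`r1, r2` of the intersection along each diagonal, preserved by every
invertible affine map. The search for a congruent feature reduces to
generating, for each retained scene pair and both of its orientations,
the hypothetical intersection positions under `r1` and under `r2`, and
finding `r1`/`r2` hypothesis conflicts within the inquiry accuracy `δ`
with a k-d tree. Candidates whose quadrilateral area violates the
tilt-consistent band
`(1±ξ)·cos β_query / cos β_scene` are discarded before any transform is
estimated; on flat specimens the projected area of a shape scales exactly
with the cosine of the tilt angle, and the test is rotation- and
translation-invariant.

Pair retention (the min&max length window) serves two purposes: locality
(feature diagonals stay short, so the hypothesis pool is near-linear in
the marker count rather than quadratic) and stability (a diagonal of
length `l` with localization error `ε` carries a ratio error of about
`ε/l`, so short diagonals are excluded).

Numerical and design choices that the problem left open:

* **Feature sampling.** The first diagonal is drawn uniformly from the
  pruned pair set; the second is drawn uniformly among pairs whose
  midpoint lies within `l_max` of the first pair's midpoint. Only
  spatially overlapping pairs can intersect, so this raises the per-draw
  success rate by orders of magnitude on realistic fields without
  restricting which local features are reachable.
* **Quick check before full counting.** A transform hypothesis is first
  tested on 20 random model points and must place at least 10% of them
  within `d` of a scene point. The bar is deliberately low: a *correct*
  hypothesis estimated from one local feature initially covers only the
  neighbourhood of that feature, because px-scale localization noise on
  a ~10²-px feature leverages to tens of pixels across a 4k-px field.
* **Coarse-to-fine local optimization.** Every candidate whose congruent
  count reaches 4 is refined by iterated least-squares refit and recount
  with an annealed threshold schedule `8d, 4d, 2d, d`. Plain refitting at
  `d` demonstrably stalls on one drift-coherent region of the field;
  annealing lets each refit capture points the previous transform placed
  almost right and reliably reaches the global fit. The returned
  consensus is always counted at `d`.
* **Counting rule.** `Count(X, Y, d)` is a deterministic greedy
  one-to-one matching: all cross-pairs within `d` sorted by distance
  (ties broken by scene then model index) and accepted while both
  endpoints are free. On sparse marker sets this attains the optimal
  bipartite cardinality (asserted against an exhaustive matcher in the
  tests); reusing points would overcount congruence.
* **Iteration budget.** `I = log(1−p_s)/log(1−p_g⁴)` with `p_s = 0.99`,
  `p_g` initialized to 0.2 and updated to `c_max/min(N, M)` after every
  improvement, capped at 10 000.

### Stage-one parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `marker_diameter` (D) | 20 | px | 10 nm beads at ~0.5 nm/px |
| `lambda_d` | 0.65 | — | midpoint of the useful 0.5–0.8 band |
| `d` | `λ·D` = 13 | px | congruence threshold; above noise+drift, well below marker spacing |
| `delta` | `d/2` | px | inquiry accuracy for intersection conflicts |
| `l_min` | `4·D` = 80 | px | ratio error `ε/l_min ≈ 1–2%` for px-scale `ε` |
| `xi` | 0.15 | — | area-ratio relaxation; covers ±4% nuisance scale plus drift |
| `ratio_margin` | 0.05 | — | reject intersections within 5% of an endpoint |

## Stage two: weighted-GMM drift refinement

After applying the stage-one affine and pre-excluding points whose
nearest cross-set neighbour exceeds `κ·d` (κ = 5), the model points are
treated as Gaussian mixture centres with isotropic variance `σ²` and a
fixed outlier mass `w` spread uniformly. The displacement field is
`v(z) = Σ_m w_m g(z, y_m)` with Gaussian kernel bandwidth `β`, and the
EM alternates:

* E-step: `p_mn ∝ exp(−‖x_n − T(y_m)‖²/2σ²)`, normalized per scene point
  with the constant outlier term `2πσ²·w/(1−w)·M/N` in the denominator;
* M-step: solve `(G + λσ²·d(P1)⁻¹) W = d(P1)⁻¹ P X − Y`, set
  `T = Y + G W`, update `σ²` from the three weighted trace terms, floored
  at `σ²_min`.

The quantity EM descends monotonically is the **penalized** negative
log-likelihood (mixture likelihood plus the smoothness penalty
`(λ/2)·tr(WᵀGW)`); the bare likelihood may fluctuate by small amounts
when the regularizer trades fit for smoothness, which is expected and is
what the tests assert.

Numerical choices: coordinates are jointly shifted to zero mean and
scaled by the RMS radius before EM (so bandwidth and regularization
defaults are dataset-independent), `σ²` is initialized to the mean
squared cross-distance `Σ‖x_n − y_m‖²/(2MN)`, posterior row sums are
floored at 1e−12 before inversion, the E-step uses a per-column shift so
small `σ²` cannot underflow, and a divergence guard returns the
best-objective state if `σ²` grows five iterations in a row.

### Stage-two parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `w` | 0.1 | — | residual outlier mass after pre-exclusion; held fixed |
| `beta_kernel` | 0.5 | normalized | resolves fields with wavelength ≳ 1/3 of the field; measured on planted fields: recovers to the noise floor, while 2.0 underfits (4.6 px RMS) and 0.4 occasionally diverges |
| `lambda_reg` | 2.0 | — | smoothness/fit trade-off, stable across seeds |
| `kappa_exclude` | 5 | ×`d` | pre-exclusion radius |
| `tol` | 1e−8 | relative σ² | convergence criterion |
| `max_em_iterations` | 150 | — | typical convergence is 25–80 iterations |

## Track composition

Pairwise matches over a 2-neighbour window are merged by union-find over
`(image, marker)` nodes. Edges are processed in order of increasing match
residual (the only available confidence proxy); a merge that would place
two different markers of one image in the same component is rejected.
Components shorter than `min_track_length` (default 70% of the series
for reporting; 2 for raw output) are discarded. The procedure is fully
deterministic: ties break on image and marker indices.

## The simulator: what it does and does not emulate

`fidmatch.simulate` generates beads in a slab with `surface_bias`
(default 0.97) of them on the support-film face — beads are applied to
the film before freezing, so a near-monolayer is the physical norm, and
only markers that are approximately coplanar can satisfy the
affine-plus-smooth-drift model across large tilt intervals at all. The
remaining in-slab beads act as depth outliers whose tilt parallax
(`Δu = z·sin β`) no smooth field can absorb; they are the main reason
simulated detection ratios saturate around 0.96–0.98 rather than 1.0 on
0°/45° pairs.

Each image gets: single-axis projection `u = x·cos β + z·sin β, v = y`;
an independent in-plane nuisance (rotation ±2°, isotropic scale ±2%,
translation ±20 px); a smooth drift field (per axis, the sum of two
orthogonal sinusoids with random phases, amplitude 5 px, wavelength one
third of the field) applied in image coordinates; isotropic Gaussian
localization noise (1 px); tilt-dependent missed detections (probability
`miss_rate·(1−cos β)/(1−cos 45°)`, capped at 0.95); and
`outlier_rate·K` spurious detections uniform over the detected bounding
box extended by 10%.

Not emulated: image formation (contrast, defocus, dose), bead-bead
occlusion as a geometric process (missing is random given tilt),
correlated localization errors, stage jitter between window pairs beyond
the per-image nuisance, and markers leaving the field of view. Passing
tests on this generator therefore demonstrate the geometric estimator
under the stated statistical structure, not detector robustness on real
micrographs.

## Problem sizes used in the tests and acceptance script

The verification suite uses desk-scale analogues chosen to exercise every
regime: 400-marker 0°/45° pairs with 1 px noise, 15% outliers, 20%
high-tilt misses and 5 px drift (20 seeds; mean detection ratio asserted
≥ 0.95); a 21-image, 150-marker series over ±20° with the 2-neighbour
window; 100 planted 8-point instances compared against the exhaustive
3-point enumeration baseline; and 50 random EM instances for the
objective-descent property. The acceptance script repeats these at
slightly reduced repetition counts and finishes in well under a minute.

## Known limitations

* Thick specimens with beads on *both* faces produce two interleaved
  affine populations separated by `thickness·|sin β1 − sin β2|`; neither
  the affine stage nor a smooth drift field can represent this, and the
  method will track the dominant face only.
* The outlier weight `w` is fixed, not re-estimated within EM.
* Stage one assumes at least a handful of valid 4-point features exist
  inside the length window; extremely small sets (< ~8 usable markers)
  need the window overrides (`l_min=0`, `l_max=inf`).
* Track composition is greedy on residuals; it does not globally
  optimize conflicting evidence across the series.
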