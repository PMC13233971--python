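# Methods notes

## Pipeline model and assumptions

The package treats a subcortical ROI's functional organization as a small
number of overlapping spatial modes ("gradients") of connectivity
variation. The estimation chain assumes: (i) voxel time series are long
enough for stable Pearson correlations (≥ ~100 timepoints in practice);
(ii) the η² affinity over connectivity fingerprints yields a connected
graph over ROI voxels (always verified; a disconnected graph is an error
naming component sizes, never silently patched); (iii) eigenvector sign
and order per subject are arbitrary, so all cross-subject statistics go
through explicit matching, flipping and QC rather than raw mode indices.

Gradient extraction solves the generalized eigenproblem L v = λ D v
(random-walk Laplacian; the unnormalized variant is an option) with a
dense symmetric solver — ROI sizes in the hundreds of voxels make sparse
iterative methods unnecessary. The trivial λ = 0 eigenvector is dropped;
modes are returned in ascending eigenvalue order and rescaled to [0, 1]
for display and alignment, which leaves every correlation-based statistic
unchanged.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| k_gradients | 6 | modes | matches the retention plateau observed in practice for this ROI family |
| retention threshold | 0.50 | |r| | QC bar for individual-to-group spatial correlation |
| sharp-decline rule | min_retention 0.50, drop 0.20 | proportion | operationalizes "sharp decline"; both configurable |
| order_k | 9 (6, 12 allowed) | coefficients | three per-axis monomial degrees per axis; no cross terms |
| n_perm | 10,000 | draws | permutation null resolution; p floor 1/(n+1) ≈ 1e-4 |
| rotation | 37° about X, off by default | degrees | long-axis visualization convention for hippocampus-amygdala ROIs; synthetic data needs none |
| α / FDR | 0.05, BH over all gradient×template pairs per run | | family is configurable; the family choice is genuinely open |

Trend-surface fits z-score the input field and standardize coordinates
per axis before basis expansion (controls monomial collinearity; the
standardization record is stored with each fit so it is reproducible).
The intercept is fitted but excluded from the similarity vector — "the
coefficients" of a k-order model are its k slopes. Note that slope-vector
correlations are *not* invariant to changing the coordinate
standardization, because a shared restandardization acts on both slope
vectors through a common non-orthogonal linear map; similarity is
invariant to affine rescaling of the maps themselves, and all comparisons
in one analysis use one fixed standardization per mask.

## Permutation scheme

"Permuting template coefficients separately for each coefficient" is read
as shuffling each coefficient position independently **across** the
template set: this breaks template-specific coefficient patterns while
preserving each position's marginal distribution. A within-vector
shuffle is available (`perm_scheme="within"`) and is the automatic
fallback when only one template exists. The p-value uses the
(1 + exceedances)/(1 + n_perm) estimator, so it is never zero; permutation
streams are seeded. An `exhaustive=True` mode enumerates all distinct
per-coefficient shuffles for small template sets and is tested against an
independent enumeration oracle.

## Synthetic data: what it emulates, what it does not

The generator plants everything downstream stages are supposed to find:

* **ROI geometry** — two fused ellipsoids (elongated body + anterior
  bulb, ~330 voxels on a 24³ 2 mm grid) emulating the hippocampus–amygdala
  long-axis shape. The bulb sits so the ROI's long-axis extent is
  symmetric about a voxel plane, giving the planted mode an exact
  midpoint voxel.
* **Modes** — low-order polynomial fields over ROI world coordinates
  (long-axis first), demeaned, Gram–Schmidt orthogonalized, mapped to
  [−1, 1]. Orthogonality after demeaning is exact by construction.
* **BOLD** — ROI voxel v mixes unit-variance network signals with
  softmax weights over affine functions of its mode values
  (inverse temperature 1.5, per-mode gain decay 0.85); each out-of-ROI
  parcel carries one network signal. Gaussian noise (σ = 0.5 by default)
  is added everywhere. The softmax keeps loadings smooth and monotone in
  each mode; the temperature is low enough that loadings are near-linear
  across the ROI yet extremes still couple > 0.99 to their network in the
  noiseless case.
* **Templates** — degree ≤ 3 polynomial surfaces whose generating
  coefficient vectors hit a requested Pearson correlation with a planted
  mode's fitted trend-surface coefficients exactly (rotation-in-
  coefficient-space construction); remaining templates are random. The
  demo links are 0.95/0.92 — with nine coefficients and a 54-test BH
  family, weaker links are mathematically incapable of FDR significance,
  and the demo is meant to exercise the detection path.
* **Behavior** — symptom sum scores follow
  effect · rank(similarity) + √(1−effect²) · noise mapped onto integer
  questionnaire ranges (IDS-SR 0–84, ASI 0–64); trauma, comorbidity
  (0–5 disorder clusters) and covariates are independent. At effect = 1
  and default cohort size the rank map is strictly monotone, so Spearman
  recovery is exact.

Not emulated: hemodynamic convolution, physiological noise, spatial
autocorrelation of the noise field, registration error, or realistic
receptor-map covariance across templates. Passing tests therefore
demonstrate correctness of the estimation and inference machinery under a
known generative model — not robustness to fMRI artifacts.

A structural finding worth knowing: in a minimal one-mode/two-network
configuration the dense-affinity Fiedler vector is a *sigmoidal* function
of the planted mode and its Pearson correlation with the mode plateaus
near 0.90 even without noise. Recovery quality in the default two-mode
scenario (0.96+ group-level) is the meaningful benchmark; the solver
itself matches a dense eigendecomposition oracle to 1e-8.

## Numerical choices

* Voxel order is a C-order raster scan of the mask grid everywhere.
* Zero-variance voxels enter fingerprints as zero-correlation rows with a
  warning instead of NaNs.
* η² denominators ≤ 0 (identical, possibly constant rows) define
  similarity 1; the matrix is symmetrized and clipped to [0, 1].
* Eigenvector sign: correlation with the raster index ≥ 0, ties broken by
  the first non-zero entry.
* Assignment uses the Hungarian algorithm on −|r| (ties favor the lowest
  group index); a literal greedy pairwise-swap variant is available and
  agrees on well-separated modes.
* Spearman p-values: exact enumeration (chunked, mid-ranks kept) for
  n ≤ 10, t-approximation above; rank correlations within 1e-12 of ±1 are
  snapped to ±1.
* Fisher z of |r| = 1 is reported as +inf with a warning rather than an
  error, and such pairs are flagged near-singular.
* Rotation resamples about the world-space centroid of the grid
  (trilinear for data, nearest for masks so they stay binary).

## Problem sizes used by tests and the acceptance script

Default scenario 24³/329 ROI voxels/20 subjects/200 timepoints;
permutation calibration 200 datasets × 1,000 permutations × 18 templates;
behavior-link power 50 cohorts of n = 300 (false positives: 200 cohorts
of n = 120); exhaustive permutation check (3!)⁶ = 46,656 enumerated
shuffles; oracle sweeps 50–1,000 random instances each. These sizes give
stable Monte-Carlo estimates while keeping the full suite in tens of
seconds.

## Known limitations

* The across-template permutation null conditions on the observed
  template set; with very few templates it is coarse (the exhaustive mode
  exists for exactly that regime).
* No spatial-autocorrelation-preserving nulls (spin tests, variogram
  surrogates): the trend-surface representation is the mitigation, by
  design.
* Group aggregation averages subject affinity matrices by default;
  temporal concatenation is available, and the two can differ on small
  cohorts.
* `files` mode expects NIfTI volumes already in a common space; no
  registration or preprocessing is performed.
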