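# Methods

## Connectivity model

`safconn` works on region-by-region association-fiber connectivity
matrices `W`. A streamline contributes its weight to `w[i, j]` (and, by
symmetric storage, `w[j, i]`) only when both endpoints resolve to regions
of the same hemisphere and `i ≠ j`; cross-hemisphere ("commissural-like")
and intra-regional streamlines are excluded and tallied in a drop report.
With unit weights the entries are streamline counts; with per-streamline
weights (e.g. SIFT2 output, consumed as a one-value-per-line text file)
they are weight sums.

Short-range (U-fiber) connectivity is defined through a binary adjacency
matrix `A` over the parcellation: `A(i, j) = 1` when regions i and j share
voxel faces. Adjacency is computed with 6-connectivity (shared faces, not
edges/corners), which gives a meaningful contact-area threshold
(`min_shared_faces`, default 1). Cross-hemisphere borders are excluded by
default because the connectivity rule zeroes those entries anyway; a flag
exposes the permissive variant.

The Short-range Connectivity Fraction is the ratio of short-range to total
association strength, globally (GSCF) and per region row (RSCF). The
double sums are evaluated exactly as written over the full symmetric
matrix — each unordered pair appears twice in numerator and denominator,
leaving the ratio unchanged. Ratios make the metric invariant to global
streamline-count rescaling, which is the property that lets within-subject
cross-condition differences be read as reconstruction bias rather than
yield differences.

Zero denominators (a region with no strength, an empty matrix) produce
*undefined* values — NaN, excluded from statistics and atlases and
reported — never silent zeros: a zero-strength region is a data defect,
not evidence of zero short-range connectivity. Rounding in the two sums is
clamped so defined fractions always lie in [0, 1].

### SAF-definition variants

Two alternative definitions are supported and can be combined:

* **intra-regional**: diagonal strength (both endpoints in one region)
  counts as short-range, entering numerator and denominator alike. The
  diagonal is accumulated once per streamline (not doubled), so under the
  double-sum convention it enters the global sums once.
* **length threshold** (default 50 mm when enabled): a connection counts
  as short-range only if the streamline is adjacent *and* at or below the
  threshold. The restriction applies to the numerator only — long
  streamlines stay in the denominator; whether they should also leave the
  denominator is genuinely ambiguous, so both behaviours are reachable
  (threshold the numerator via `length_threshold_mm`, or pre-filter the
  tractogram).

## Resolution manipulation

Down-sampling emulates a lower acquisition resolution in the Fourier
domain: the centered DFT of the volume is cropped to the target matrix and
the retained coefficients are multiplied by a separable symmetric taper
with unit gain over the central `1 − taper_fraction` band per axis and a
raised-cosine roll-off to the band edge (a Tukey window; default
`taper_fraction = 0.2`, a mild apodization against Gibbs ringing). The
normalization preserves the DC coefficient exactly, so the image mean is
invariant — a hard, testable property. When a truncated axis has even
length the unpaired Nyquist coefficient is zeroed to keep the spectrum
conjugate-symmetric and the output real (asserted to 1e-10 relative).
Truncation plus a gain-≤1 taper can only remove spectral energy, so the
sum of squared deviations from the mean never increases (Parseval).

Up-sampling interpolates with a polynomial spline (order 0–5, default
cubic) at the new voxel centers under a voxel-center alignment convention
(`world = origin + index × voxel_size`, shared origin; no oblique
affines — synthetic grids are axis-aligned and registration is out of
scope). Boundary handling is mirror reflection by default; mirror
perturbations decay geometrically into the interior (factor ≈ 0.27 per
voxel for cubic splines), so polynomial reproduction holds away from the
edges. A `boundary="wrap"` option provides periodic handling, which is
the consistent choice after Fourier-domain down-sampling (whose implied
signal is periodic) and is what the band-limited round-trip test uses.

Temporal SNR of a repeated b=0 series is the per-voxel temporal mean over
temporal standard deviation (sample sd, n−1), averaged over mask voxels
with nonzero sd; zero-sd voxels are excluded and counted.

## Synthetic data: what it emulates, and what it does not

The generators replace the MRI side of the study with constructions whose
ground truth is analytic:

* **Ribbon parcellation** — an annulus ("cortical ribbon") in a central
  axial slab, split into `n` angular wedges per hemisphere with a midline
  gap that guarantees no left–right face contact. Consecutive wedges share
  a radial boundary, so the true adjacency is a chain per hemisphere,
  known without computing anything. Default geometry: 40³ grid, 1 mm
  voxels, inner/outer radii 8/14 mm, 2 mm gap, 5-voxel slab — large
  enough that every wedge is nonempty and only angular neighbours touch.
* **Tractograms** — short streamlines are quadratic Bézier arcs between
  interior points of adjacent wedges with the control point displaced
  radially inward so the arc's deepest point dips ~3 mm beneath the ribbon
  inner surface (the simplest smooth U-arch that stays sub-ribbon); long
  streamlines route through the deep annulus interior. Points are spaced
  at ~1 mm, keeping polyline lengths accurate to <0.1%. Endpoints lie
  strictly inside their voxels, so endpoint assignment recovers the
  ground-truth labels exactly — by design, because the pipeline tests
  need a noiseless reference.
* **Connectome ensembles** — the paired multi-resolution cohort design:
  subject `s` carries a multiplicative lognormal effect
  `m_s = exp(N(0, σ_s²))` shared across all conditions (default σ_s = 0.1),
  and condition `r` attenuates the expected adjacent-pair count by a
  factor `α_r ≤ 1` (reference 1). Adjacent pairs draw
  Poisson(α_r·μS·m_s), each non-adjacent same-hemisphere pair
  Poisson(μL·m_s); `noise_model="none"` uses the means. Defaults
  n = 20 subjects, 5 regions/hemisphere, μS = 200, μL = 100, α = {1.0, 0.8}
  — a cohort size matching the study design this emulates, counts large
  enough that Poisson noise is realistic but not dominant. The expected
  GSCF at condition r is `α_r·S0 / (α_r·S0 + L0)` with S0, L0 the total
  expected short/long strengths; subject effects cancel in the ratio.
* **Phantoms / b=0 series** — finite sums of real cosines (spectral
  support known exactly) and constant-plus-Gaussian-noise series inside an
  ellipsoidal mask.

All generators are pure functions of their seed; child streams are spawned
deterministically per subject/condition so partial re-runs reproduce.

What the synthetic data does *not* contain: realistic diffusion contrast,
fiber-orientation modeling, tracking errors, gyral geometry, spatially
varying SNR, or the empirical long-/short-count distributions of real
cohorts (the Poisson/lognormal choice is a modeling stand-in, not a claim
about acquired data). Passing tests therefore demonstrate the correctness
of the *quantification* — matrix construction, fraction metrics,
statistics, degradation operators — not the fidelity of any tractography
algorithm.

## Statistics

For each paired comparison the subject-wise differences `d = x − y` are
gated by Shapiro–Wilk at 0.05: normal-looking differences use the
two-sided paired *t*-test, otherwise the two-sided Wilcoxon signed-rank
test. Conventions the gate needs but that are genuinely underdetermined:

* all-zero differences short-circuit to a "degenerate" result (p = 1);
* constant nonzero differences route to Wilcoxon (Shapiro–Wilk is
  undefined on constant input, and a constant shift is a legitimate paired
  effect);
* Wilcoxon drops zero differences (classic signed-rank convention; the
  Pratt variant is available via `zero_method`), uses the exact null
  distribution for n ≤ 25 without tied |d|, and otherwise the normal
  approximation with continuity correction.

Benjamini–Hochberg step-up FDR adjustment is applied per family: all
cross-condition pairs within one method for GSCF, all tested regions for
RSCF (regions with <3 complete pairs are excluded and reported).
Significance is FDR-adjusted p < 0.05. The Top-10 summary ranks regions by
ascending RSCF difference per method (most negative first), includes all
regions tied with the 10th value (deterministic and order-independent),
keeps regions appearing in ≥50% of methods, and pairs homologous regions
by identical name across hemispheres.

Relative differences follow the lower-vs-higher-resolution convention,
`100 × (low − high) / high`, so negative values mean the lower resolution
underestimates the fraction.

## Numerical and design notes

* Endpoint assignment: containing voxel label, else nearest labeled voxel
  center within 2 mm (Euclidean; ties to the lowest region id). The radius
  is a logged configuration knob mirroring standard connectome tooling.
* The parameter-recovery check in `scripts/acceptance.py` estimates the
  cross-condition relative difference as the relative difference of the
  condition means (a consistent estimator of the analytic value); the
  per-subject-ratio mean that the comparison tables report carries a
  small Jensen bias of order var(GSCF)/GSCF², visible only when averaging
  many replicates.
* Problem sizes: simulation-heavy checks use 5 regions/hemisphere, 20
  subjects, 100 replicates for power and 400 for null calibration —
  enough for ±1% Monte-Carlo resolution on rejection rates while keeping
  the whole suite fast.
* Reproducibility is a tested contract: one seed, byte-identical output
  tables (`%.12g` formatting everywhere), config echoed and hashed into
  the run manifest.

## Known limitations

* Volumetric adjacency only; surface-mesh parcellations (annot files) are
  not supported, and whether a surface-derived adjacency would differ at
  midline regions is untested.
* No affine/oblique grid support; all volumes are axis-aligned.
* The resolution operators model truncation and interpolation, not
  acquisition physics (no noise amplification, no gradient
  nonlinearities, no slab reconstruction).
* TCK is the only tractogram dialect (TRK/TRX are not read).
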