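# Methods

This note documents the statistical model, the evaluation protocol, the
synthetic cohorts, and the numerical decisions behind `vesselvpop`, in the
spirit of a model-documentation page: what is computed, under which
assumptions, with which defaults, and what the package's own tests do and
do not establish.

## Shape representation

A centerline is an ordered polyline `v_1 … v_n` with inner radii
`r_1 … r_n`, all in millimetres, in a fixed laboratory frame. Registration
of the source images to a common atlas is assumed to have happened
upstream; the package never re-registers. Landmarking resamples a
centerline to `k` points at equal *arc length* along the piecewise-linear
polyline, both endpoints included, with all four channels (x, y, z, r)
interpolated linearly in arc length. Equal arc length — rather than an
equal index stride — makes landmark geometry independent of acquisition
density, which varies from artery to artery. The landmark set flattens
block-wise into the shape vector `p = [x-block, y-block, z-block, r-block]`
of length 4k.

Default landmark counts per label are 30 (BA) and 60 (L_ICA, R_ICA), the
upper ends of the sweep ranges studied below.

Two caveats discovered while validating the landmarking:

* resampling is *exactly* idempotent only on equal-chord polylines
  (straight lines, uniformly sampled constant-curvature arcs). On a general
  curve the landmark polyline's chords differ, so a second resampling
  shifts interior points by the chord-length variation. Tests assert exact
  idempotence where it genuinely holds and spacing uniformity elsewhere;
* the landmark polyline is always shorter than its source (chord
  shortening) and converges to it as k grows; this is asserted as a
  property test.

## The Gaussian shape model

The model is the full joint normal N(μ, Σ) over the 4k landmark variables:
μ is the column mean of the population matrix and Σ the sample covariance
with the N−1 denominator. Nothing is truncated or regularized: the point of
the method is that the complete position–radius covariance encodes both
centerline continuity and the anatomical corridor each segment occupies, so
sampled arteries inherit them without tuning.

With N arteries and 4k variables, rank(Σ) ≤ N−1 < 4k at any realistic
cohort size, so Σ is singular and is handled through its SVD `Σ = U S Uᵀ`:

* **pseudoinverse** — reciprocal of singular values above the rank
  tolerance, zero elsewhere; satisfies the four Moore–Penrose identities.
* **log-density** — the Gaussian log-density restricted to the rank-r
  support: `−(r/2)·log 2π − ½·Σ log s_i − ½ (p−μ)ᵀ Σ⁺ (p−μ)`, using the
  pseudo-determinant; a probe whose component orthogonal to the support
  exceeds `tol·|p−μ|` has zero density (−∞ returned). This is the standard
  density of a degenerate multivariate normal.
* **sampling** — `p = μ + U_r diag(√s_r) z`, `z ~ N(0, I_r)`: draws live
  exactly on the affine support `μ + span(U_r)`, the only well-defined
  sampling rule for a singular covariance.

Rank tolerance: `tol = max(4k, N) · ε · s_max`, floored at
`max(4k, N) · (ε · max|X|)²`. The floor matters for the degenerate case of
an identical-row population: mean-centering round-off produces singular
values of order `(ε·scale)²` which a purely `s_max`-relative tolerance
would classify as rank 1; with the floor the model is rank 0 and every
sample equals μ bitwise, as the degenerate Gaussian demands. For identical
rows μ is taken as the common row itself rather than the floating-point
column mean, for the same reason.

Sampled radius entries can be negative — the model is a Gaussian over an
unconstrained vector. They are counted, reported, and written with a flag
column, never silently altered; an explicit post-filter
(`filter_negative_radii`, reject or clamp) exists but is off by default.
At the default cohort statistics negative radii essentially never occur
(the radius mean sits ≈5 SD above zero).

## Reconstruction

A landmark set (real or sampled) becomes a dense centerline via a clamped
B-spline of degree 2 through all four channels, parameterized by the chord
length of the landmark positions and evaluated at `m` parameter values
equally spaced in the spline parameter. Defaults for `m` follow the average
acquisition point counts of the reference cohorts: 124 (L_ICA), 127
(R_ICA), 53 (BA), so real and virtual curves are always compared at
identical sampling.

Choices the data did not dictate, made once and exposed in
`ReconstructionConfig`:

* **interpolating vs smoothing** — default is interpolation; a smoothing
  mode (penalized least squares on the spline coefficients with both end
  coefficients pinned, penalty = squared second differences ×
  `smoothing_weight`) is available for noisy landmark sets. The endpoint
  pinning keeps the clamped-ends contract in both modes.
* **chord-length parameterization** over uniform: robust to uneven
  landmark spacing.
* the radius channel is splined together with the coordinates.

Degree 1 reduces exactly to linear resampling of the landmark polyline,
which is cross-checked against the landmarking module in the tests.

## Geometric features

On the reconstructed m-point curve (never on the sparse landmarks):

| feature | definition | units |
|---|---|---|
| length | `Σ |v_{i+1} − v_i|` | mm (reported in cm in summaries) |
| distance metric (DM) | length / endpoint chord | — (≥ 1) |
| local curvature κ_i | `|V_i × A_i| / |V_i|³`, `V_i = v_{i+1}−v_i`, `A_i = V_{i+1}−V_i` | 1/mm |
| maximum local curvature | max over the n−2 interior κ_i | 1/mm |
| mean diameter | 2 × mean radius | mm |

No endpoint padding: κ exists only where the finite differences define it.
Duplicate consecutive points are merged at load time (radii averaged)
precisely because κ divides by `|V_i|³`. Coincident curve endpoints leave
DM undefined and raise an error.

## Distribution comparison

For each feature, both samples are binned into 30 equal-width bins spanning
the pooled min/max of the two samples in that trial (rightmost bin closed),
normalized to relative frequencies, and compared with the bin-wise KL
divergence in nats, weighted by the *virtual* histogram:
`KL = Σ f_v log(f_v / f_r)`. This orientation follows the reference
formulation literally; the conventional orientation (weights `f_r`) is one
keyword away. Zero bins are regularized by adding `epsilon = 1e-6`
(absolute, pre-normalization) to every bin of both histograms and
renormalizing; the epsilon used is always reported with the value, and
`epsilon=0` returns ∞ (with a warning) when the reference bin is empty
under virtual mass. A pooled range of zero width — or one below
floating-point resolution — degenerates to a single shared unit-width bin,
which makes the KL of two identical degenerate distributions exactly 0.

Two KL caveats worth knowing when reading numbers: the value depends on the
real-sample size (30 bins filled by 17–46 real arteries leave many empty
bins, giving a substantial positive floor even for well-matched
distributions), and the pooled range is per-trial, so KL values are most
meaningful compared across landmark counts within one protocol, not as
absolute divergences.

## Evaluation protocol

One trial at landmark count k: landmark the real population at k → fit the
Gaussian → sample `n_vp` virtual shape vectors (seeded) → spline virtual
landmark sets to m points, and spline the real arteries *from their
full-resolution centerlines* to the same m → compute the three features on
both → histograms, KL per feature, and mean ± SD summaries per population.

Reconstructing the real arteries from their full point sets (not from the
k landmarks) is deliberate: the real arteries are re-interpolated only
because their point counts differ, and doing so from full resolution makes
the real feature distribution independent of k. The landmark count then
affects *only* the virtual population, whose fidelity improves as k grows —
which is the phenomenon the sweep measures. The alternative, pushing the
real arteries through the same k-landmark decimation
(`real_from="landmarks"`), processes both populations identically and is
the right mode for self-consistency checks (a population of identical
arteries must give exactly-zero KL at every k); it is used by those tests
and available in the API.

The landmark sweep repeats `trials` independent trials per k. Defaults
follow the reference protocol: 30 trials × 100 virtual arteries = 3000 per
sweep cell, k from 3 up to 60 (ICA) or 30 (BA). Trial t uses seed
`base_seed + t` *at every k*, so k is the only factor varying along the
sweep; only model sampling is randomized — the real population and its
landmarking are deterministic. Per-k mean and SD of KL (N−1) are reported.
A trial with infinite KL (possible under `epsilon=0`) records ∞ rather
than aborting the sweep. Requesting k beyond the sparsest real artery's
acquisition point count is refused, naming the artery.

The scaled-down sweep exercised by the tests and the acceptance script uses
an ICA-like cohort of n = 30, k ∈ {3, 10, 40}, 10 trials × 100 virtual
arteries — sizes chosen so the whole suite runs in seconds while the
mean-KL ordering across k remains far outside trial noise (the k = 3 vs
k = 40 gap is ~8–10 nats against a trial SD well under 1).

## Synthetic cohorts

`synthdata` generates stand-in "real" populations with the statistical
structure of the reference cohorts, since no patient centerlines are
distributable. Each family has a fixed template course built by integrating
a smooth curvature profile:

* **BA_like** — a constant-curvature arc (total turning ≈ 0.9 rad) with a
  mild out-of-plane bow;
* **ICA_like** — two opposite-signed curvature lobes (turning ≈ 2.8 and
  2.2 rad, smoothly joined) over a gentle base curvature: the S-shaped
  siphon, plus an out-of-plane bow.

A sampled artery is the template with: per-artery length
(BA 31.3 ± 8.3 mm, ICA 79.2 ± 7.2 mm), modest random variation of the
curvature-profile parameters, a smooth low-order random deviation field
(cos(jπs), j ≤ 4, ~2–2.5 mm rms) bounded along the whole course, a
narrowband fine-tortuosity field, per-point jitter (0.015 mm), a small
rigid pose perturbation, and a beaded radius profile
`r(s) = r_base (1 + a sin(2π f s + φ))` with r_base drawn from the cohort
diameter statistics (BA 3.33 ± 0.675 mm, ICA 5.42 ± 1.02 mm diameter),
a = 0.08, f = 5 (BA) / 8 (ICA) cycles. Point counts are rounded truncated
normals matching the cohort tables (BA 53.4 ± 12.9 in [31, 100], ICA
123.6 ± 12.9 in [101, 151]). The polyline length is renormalized to the
drawn length after all perturbations, so the length marginal is exact.

Three structural choices deserve justification:

* **bounded deviation field rather than accumulated random heading**: in
  atlas-registered cohorts every arterial segment stays within a few
  millimetres of its location in other subjects (the vessels are anchored
  by skull base and surrounding anatomy). Integrating independent random
  bend parameters instead lets heading errors accumulate to >10 mm distal
  scatter, which no registered cohort shows and which also breaks the
  approximate joint normality the whole method assumes.
* **fine-scale tortuosity**: real centerlines extracted from ~0.5 mm
  voxels carry structured undulation at few-millimetre wavelengths, which
  is exactly why the maximum-local-curvature distribution keeps improving
  with landmark count up to k ≈ 60 — sparse landmarks cannot resolve it.
  The generator adds modes j = 10–36 (wavelength 2L/j) with amplitudes set
  analytically so the aggregate curvature perturbation has rms 0.15/mm
  (ICA) / 0.20/mm (BA) while the tangent perturbation stays small
  (curvature of mode j scales as a·(jπ/L)², slope as a·jπ/L).
* **jitter bounded by curvature consistency**: a tube of radius r cannot
  bend tighter than 1/r. Point jitter σ at spacing d produces discrete
  curvature of order 4σ/d²; keeping that below the inscribed-sphere bound
  at the cohort point spacings gives σ ≈ 0.015 mm, consistent with
  sub-voxel centroid averaging in centerline extraction.

What the generator does **not** emulate: atlas coordinates, bifurcations,
named segment boundaries, vessel-wall geometry, left/right asymmetries, or
any non-Gaussian population structure beyond the smooth nonlinearities of
the construction. Consequently, passing tests show that the pipeline
recovers populations *of this smooth, near-Gaussian kind* and reproduces
the qualitative resolution effect of landmark count; they cannot certify
behaviour on real anatomies whose variability is less Gaussian (e.g.
bimodal course variants).

## Degenerate inputs and tie-breaks

* fewer than 2 distinct centerline points, non-finite values, zero-length
  segments, negative radii on non-sampled records → errors at load;
* N < 2 arteries → covariance undefined, fit refuses;
* rank-0 model → every sample is exactly μ; log-density is 0 at μ and −∞
  elsewhere;
* coincident curve endpoints → DM undefined, error;
* single-artery population summaries report SD = 0 with a degenerate flag;
* histogram ties: the rightmost bin is closed so the pooled maximum is
  counted; equal-width bins always span the pooled range.

## Known limitations

KL values depend on sample size and binning and are not comparable across
protocols. The full covariance makes the model dimension 4k with rank
capped at N−1: with very small N the virtual population lives in a thin
subspace and underrepresents tail shapes. Negative radii, while not
observed at the default statistics, are possible in principle and left to
the caller's policy. Multivariate-normality testing of real cohorts is out
of scope (it requires N > 4k).
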