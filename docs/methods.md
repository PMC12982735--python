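# Methods

## The model

Specific DNA-PAINT signal arises from reversible hybridization of freely
diffusing imager strands to docking strands fixed on the target. For a
cluster containing k docking strands with single-strand association rate
1/τ_d, binding events form (to an excellent approximation at DNA-PAINT
occupancies) a Poisson process of rate k/τ_d, so the waiting times between
consecutive binding events — the *dark times* — are i.i.d. exponential.
Non-specific adsorption has no such renewal structure. The denoising method
therefore keeps a cluster when its dark-time sample is consistent with an
exponential law and rejects it otherwise, with a minimum-events threshold
covering the regime where the test has no power.

The exponential mean is estimated from the same sample that is tested, so
the null is composite. The Anderson–Darling statistic is computed on the
probability-integral transform with the estimated rate, and its null
distribution is obtained by parametric bootstrap: B samples of size n are
drawn from the unit exponential, the rate is re-estimated in each, and
p = (1 + #{A²_b ≥ A²_obs}) / (B + 1). Because this null distribution
depends only on n, the bootstrap sample is drawn once per (n, B, seed) and
cached; all clusters with the same number of dark times share it. This is
statistically identical to per-cluster resimulation and makes whole-image
runs (thousands of clusters) cheap and reproducible from one global seed.
A table-based alternative (Stephens-type critical values for the composite
exponential case, small-sample correction 1 + 0.6/n, log-linear
interpolation, p clipped to the tabulated range 0.005–0.25) is provided and
agrees with the bootstrap on accept/reject decisions at the 1% level in
≥ 95% of mixed test cases.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| clustering.eps_nm | auto (= median precision) | DBSCAN search radius ε |
| clustering.min_pts | 5 | DBSCAN minimum neighbours n |
| clustering.render_pixel_frac | 0.5 | render pixel = frac × median precision |
| clustering.peak_rel_threshold | 0.3 | correlation peak acceptance vs global max |
| clustering.peak_min_sep_frac | 1.0 | minimum peak separation, × median precision |
| kinetics.max_gap_s | 1.0 s (2.0 s for HaloTag targets) | blink-link gap: dark spans strictly shorter than this merge |
| test.alpha | 0.01 | significance level |
| test.bootstrap_B | 10 000 | bootstrap replicates (±0.003 accuracy near p = 0.01) |
| test.min_times | 4 | minimum dark times to run the test (= 5 binding events) |
| denoise.min_events | 8 | minimum-events threshold N |
| denoise.cutoff | 1.0 | normalized-rate crossing level |

The ε and n defaults follow the standard protocol for
localization-precision-sized clusters; α = 0.01 keeps the false-rejection
rate of real clusters at 1% while the power against non-exponential
background rises above 90% once a cluster has ≥ 12 events. A 1 s link gap
at 5 Hz translates to 4 allowed dark frames (strict "< 1 s"); generally the
gap in frames is the largest whole number of dark frames spanning strictly
less than `max_gap_s`.

## Numerical choices

* **Median convention.** Lower-of-two-middles for even counts, so ε is an
  observed precision value. Documented and tested.
* **Rendering.** Plain 2D histogram (pixel = precision/2, padding 3× the
  members' median precision so template peaks near edges are not clipped);
  the Gaussian-template correlation itself supplies the smoothing. Gaussian
  rendering is available behind a flag.
* **Peak acceptance.** Local maxima of the correlation map above 0.3× its
  global maximum, thinned strongest-first to a minimum separation of one
  median precision. A cluster is precision-sized (radius ≈ 2σ), so modes
  closer than σ are not separable; both knobs are exposed in config.
* **k-means.** Plain Lloyd iterations, initialized exactly at the template
  seeds, no restarts, nearest-centroid ties to the lowest seed index,
  convergence when the largest centroid shift is < 0.01 nm (or 300
  iterations). Deterministic given seeds. Empty sub-clusters are dropped;
  if a DBSCAN cluster has fewer members than seeds, k is reduced.
* **DBSCAN ties.** Border points reachable from two clusters go to the
  cluster discovered first in record-scan order (the behaviour of the
  underlying scikit-learn implementation, matched exactly by the O(n²)
  reference used in the tests).
* **Dark times.** Counted as dark frames between events × frame duration
  (floored at one frame), so every measured dark time exceeds the link gap
  by construction. A start-to-start alternative is config-exposed. Numeric
  probability-integral values are clamped to [ε_mach, 1 − ε_mach] before
  logs.
* **Empirical CDF.** i/n at the order statistics for the RMSE diagnostic;
  other plotting positions change the RMSE only at O(1/n).
* **Normalized rate.** Rates are first differences of the rejected fraction
  on the integer threshold grid, F(T) − F(T−1), with F taken flat at the
  grid's lower edge. Smoothing uses truncated (shrinking) centred windows at
  the series ends — median-of-5 for the rates, mean-of-3 for the normalized
  series — so no data is invented beyond the grid. Where the background
  rate is exactly zero the normalized series is undefined (NaN), except
  that a zero background rate with a positive signal rate is the limit
  case "all background gone, signal being lost" and counts as a crossing
  (+inf).

## The simulator

Specific binding is an alternating renewal process per docking strand —
dark ~ Exp(τ_d), bright ~ Exp(τ_b) — run in continuous time and truncated
at min(acquisition, depletion time), with depletion ~ Exp(strand lifetime)
cutting a strand mid-event (photodamage does not wait for unbinding; the
alternative is config-visible in the code). Optional photophysical blinking
chops each bright interval into Exp(on)/Exp(off) fragments. Bright
intervals from different strands are unioned, and a camera frame is active
when its exposure window overlaps any on-interval — the physical camera
behaviour. Discretization to frames happens only at emission.

For the depletion experiments (5000 clusters × 10 strands, τ_b = 1 s,
τ_d = 1000 s, acquisition 10 000 s, lifetimes 80 000 s / 10 000 s, 5 Hz,
1 s link gap, α = 0.01) the per-cluster dark-time sample *includes the two
acquisition-edge intervals* (start → first event, last event → end).
Depletion shows up as a systematically long trailing interval; a
sensitivity analysis showed the test is roughly half as sensitive to the
extreme scenario without the edge intervals, and including them reproduces
the expected ~1% / ~6% rejection pair. The per-cluster measurement used in
the denoising pipeline itself excludes both edges by default (n − 1 dark
times from n events), with the edge modes available as options.

The non-specific background model is explicitly synthetic: apparent event
counts geometric with mean 3 (support ≥ 1), inter-event times lognormal
with log-σ 1.5 on an arbitrary scale (the test is scale invariant; the
table-emitting generator uses a 60 s median so that frame discretization
and blink linking cannot distort the drawn distribution), single-frame
blinks, tight Gaussian spots. It reproduces the qualitative character of
negative controls — most clusters have too few events to test, and the
event-rich ones are strongly non-exponential — but it is *not* fitted to
any measured background, so test results on it demonstrate the filter's
behaviour under this stated model, not performance on real samples. Real
background additionally contains off-target docking strands whose kinetics
are genuinely exponential and which no kinetic filter can remove; the
simulator does not model these.

Nanoruler fields place 3-mark, 80 nm-spaced rulers on a jittered coarse
grid with random in-plane orientation (no overlap by construction); each
mark runs an independent trace and every active frame emits one
localization with isotropic Gaussian error σ_loc (default 10 nm, which is
also the stored precision). Default mark kinetics (single strand,
τ_d = 100 s, τ_b = 0.5 s, 4000 s at 5 Hz) give ≈ 40 events per mark.

## Problem sizes

The validation experiments run at the study sizes: 5000 clusters for the
depletion and retention experiments, 10 000 for the noise-rejection
experiment. The test suite uses smaller replicate counts (hundreds to a
few thousand) wherever the binomial error at that size already leaves the
asserted bound a comfortable margin; each test notes its size inline. The
80-ruler nanoruler field (≈ 34 000 localizations) exercises the full
clustering path end to end.

## Known limitations

* The pipeline is 2D; axial structure is ignored.
* Blink linking assumes a single known binding-time scale; heterogeneous
  imager chemistries in one image would need per-target gaps.
* The minimum-events threshold interacts with acquisition length: short
  acquisitions starve real clusters of events and push them below N.
* Bootstrapped p-values have granularity 1/(B+1); decisions at exactly
  p = α are resolution limited.
* The geometric/lognormal background is a stand-in. Conclusions about real
  non-specific signal require region-based or negative-control curves from
  real data, which is what the `threshold` workflow is for.
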