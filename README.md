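# paintdenoise

Kinetics-based denoising of DNA-PAINT single-molecule localization data.

DNA-PAINT produces super-resolved images from the transient hybridization of
dye-labelled *imager* oligonucleotides to *docking* strands attached to the
target. Every binding event appears as a localizable blink — but so does
every non-specific sticking event of an imager to the sample, and this
background is often dense enough to obscure real structure. Morphological
filters cannot tell the two apart. Their kinetics can: for specific
hybridization the waiting times between binding events at one docking site
are exponentially distributed, while non-specific adsorption is not.

`paintdenoise` implements this kinetic filter:

1. **Two-step clustering** — DBSCAN (search radius ε = median localization
   precision, minimum n = 5 localizations) merges blinks into density
   clusters; each DBSCAN cluster is then rendered, cross-correlated with a
   2D Gaussian template of width σ = the localization precision, and split
   by k-means seeded at the correlation peaks into
   localization-precision-sized clusters.
2. **Time-trace construction** — each cluster's frames form a binary trace;
   blinks separated by less than the expected binding time (default < 1 s)
   are linked into single binding events, compensating for photophysical
   blinking of the dye within one hybridization episode.
3. **Exponentiality test** — the inter-event dark times x₁…xₙ of each
   cluster are tested against Exp(λ̂), λ̂ = 1/x̄, with the Anderson–Darling
   statistic

   A² = −n − (1/n) Σᵢ (2i−1)[ln u₍ᵢ₎ + ln(1 − u₍ₙ₊₁₋ᵢ₎)],  u₍ᵢ₎ = 1 − e^(−λ̂ x₍ᵢ₎),

   with composite-null p-values from a parametric bootstrap (or Stephens-type
   tables). Clusters with p < α (default 0.01) are rejected as noise, and
   clusters with fewer than a minimum number of binding events N (default 8)
   are rejected outright, since the test has little power there.
4. **Threshold selection** — the optimal N is read off the data by comparing
   cluster rejection rates between a signal region (r_s) and a
   background-dominated region or negative control (r_b): N is the smallest
   threshold where the smoothed normalized rate (r_s − r_b)/r_b exceeds 1.

The package also contains the binding-kinetics simulator used to validate
the method: per-strand alternating renewal processes (exponential dark and
bright intervals), optional photophysical blinking, docking-strand depletion
by photodamage, nanoruler geometries (3 marks, 80 nm apart) and a synthetic
non-specific background model. qPAINT molecule counting (mean dark time,
relative error 1/√(N−1)) is included.

## Worked example

Simulate a two-zone scene (specific clusters with exponential kinetics on
the right half, synthetic non-specific clusters everywhere) and denoise it:

```bash
paintdenoise simulate scene --n-specific 100 --n-noise 1000 --seed 7 --out scene.h5
paintdenoise denoise --input scene.h5 --out filtered.h5 --summary clusters.csv
```

```
wrote 14189 localizations
denoise: read 14189 localizations
denoise: 110/144 clusters kept, 10983 localizations written
```

Of the 1000 simulated noise clusters, most are too sparse to survive DBSCAN
at all; of the 144 clusters that are found, 26 fall below the 8-event
threshold and 8 fail the exponentiality test, leaving 110 — the 100 specific
clusters plus a small noise remainder. `clusters.csv` holds one row per
cluster:

```
cluster_id  n_localizations  n_events  centroid_x_nm  centroid_y_nm  mean_dark_s  ad_statistic  p_value   decision
         0               90        28        7157.49         676.69       122.16          0.35     0.73   specific
         1              124        31        7840.52         713.36       128.49          0.58     0.39   specific
```

`n_events` is the number of binding events after blink linking,
`mean_dark_s` the fitted exponential mean of the inter-event times (the
qPAINT observable), and `p_value` the composite-null Anderson–Darling
p-value the decision is based on.

The same pipeline is available as scikit-learn-style estimators:

```python
from paintdenoise import PaintDenoiser, read_localizations

table = read_localizations("scene.h5", frame_duration_s=0.2)
den = PaintDenoiser(min_events=8, alpha=0.01, random_state=0).fit(table)
filtered = den.transform(table)
```

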