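# Methods

This note records the models behind `filoquant`, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Gel calibration

The standard curve is a zero-intercept least-squares fit, slope
a = Σxy/Σx², because the blank lane carries no signal by construction. The
slope standard error uses the through-origin estimator
SE = √(SS_res/((n−1)·Σx²)) with df = n − 1, and R² is the uncentered
convention appropriate to an intercept-free model. Confidence intervals on
molecule estimates treat the slope as the **sole** error source and are
multiplicative, estimate · a/(a ± t₀.₉₇₅(df)·SE): a molecule count scales as
1/a, so symmetric error in the slope produces an asymmetric interval in
molecules. Lysate-lane densitometry noise is deliberately ignored — the
standard curve dominates the error budget — and quantiles are Student t with
df = n_lanes − 1 (with five standard lanes, t ≈ 2.78; a normal quantile
would understate the interval by ~10%). Aggregated material retained in the
well top is the caller's responsibility to sum into the lane signal.

Constants: standard MW 61,000 g/mol (HaloTag-GST fusion), labeling
efficiency 0.90, Avogadro from `scipy.constants`.

## Image pipeline

* **Background.** Fixed-cell images subtract the mean of a 56×56 px square
  placed over a signal-free region (placement is a required input — on real
  data it is a judgment call); live snapshots use a 50 px rolling-ball
  estimate. Negative pixels are clipped to zero after subtraction: punctum
  and cell quantities are *sums* over masks, and unclipped negatives would
  bias totals downward in low-signal regions.
* **Total-cell mask.** Otsu thresholding by default; a `sigma` mode
  (k × read-noise SD, k = 3, with the SD estimated from the background
  square) is provided for flat-background images where the bimodality
  assumption behind Otsu is weak. Components under 500 px are discarded as
  non-cell objects; touching cells are split by watershed seeded at
  distance-transform maxima (min peak separation 40 px, peaks below 30% of
  the component's maximum distance suppressed — only multi-peak components
  are ever split).
* **Body and filopodia masks.** The phalloidin channel is thresholded,
  eroded (r = 1) and opened (r = 2): the opening removes protrusions up to
  ~2 px wide while leaving the convex body essentially intact. The
  filopodia mask is the set difference total ∧ ¬body. In the bundled
  pipeline the body mask is first dilated by 3 px; without this margin,
  boundary pixels shaved from the body by erosion/opening reappear in the
  filopodia mask as bright ring fragments and masquerade as puncta. The
  margin costs a few shaft-base pixels per filopodium (~2% of a typical
  filopodium's molecules).
* **Puncta.** Connected components with 8-connectivity ("two orthogonal
  hops"), grouped into filopodia by single linkage on closest-pixel
  distance with a 0.5 µm gap; the most distal punctum of each group
  (distance transform from the body) is flagged as the tip. Punctum length
  is the maximum pairwise pixel distance plus one pixel, times the pixel
  size — an algorithmic stand-in for a manual line measurement, floored at
  one pixel.

## Tip geometry

A filopodium is modeled as a cylinder of radius 0.1 µm. Accessible actin:
16 surface filaments × (4/13 accessible monomers per helical turn) ×
(1/2.7 nm monomer rise) monomers per unit length, divided by the
cross-section volume per unit length — length cancels, giving 96.4 µM with
the defaults. The 2.7 nm axial rise is the standard F-actin half-pitch
value per subunit. The membrane budget counts a hemispherical cap (2πr²)
plus the cylindrical wall along the punctum (2πrL) divided by a per-motor
footprint; the footprint has **no privileged default** — tests use
100 nm² — and whether the wall should use the full punctum length or length
minus the cap is left to the caller via the length argument. Saturation
classification gives membrane excess precedence over actin excess.

## Rose profiles

20 half-open angular sections, counterclockwise from the image +x axis.
Within a cell, each punctum's molecules are assigned once, by centroid
angle; punctum *counts* credit every section the pixel set touches, so
counts may sum to more than the number of puncta. Per-section totals per
cell are averaged across cells (a config switch away from per-section
means), molecules-per-punctum is NaN where a section has no puncta and is
excluded from averaging. Alignment puts the argmax (or argmin; a seeded
random choice among multiple empty sections) at 0°, ties broken by lowest
index. Bootstrap SEM resamples cells with replacement (default 500 draws)
and takes the SD of the per-section bootstrap means.

## Trajectories

The linker is greedy nearest-neighbor: candidate frame-to-frame pairs
within 0.5 µm accepted in ascending distance order, then segment ends
rejoined to segment starts across 2 ≤ Δframe ≤ 2 within 1 µm, again
greedily. This replaces the reference LAP optimizer; at filopodial punctum
densities (nearest neighbors many times the step length) the two make
identical assignments, which is why the test suite can require exact track
recovery from the generator. Instantaneous speeds are gap-aware
(displacement over *actual* elapsed time); each speed is paired with the
molecule count at the step's start for the Spearman pooling. Trend curves
use a GCV-penalized cubic smoothing spline (`scipy.interpolate.
make_smoothing_spline`) on points within 100 s, with duplicate abscissae
averaged; the displayed band is fit ± 1.96·residual SD, a dispersion band.
Phase labels (initiation / second-phase / retraction) are supplied by the
caller or the generator; automatic event detection is out of scope.

## Synthetic data

The generator is the package's test bed and defines its study conditions:

* **Gel**: standard lanes at 1.25–15 ng with slope 24.32 signal/ng;
  the lysate signal is the exact inverse of the calibration chain, so the
  zero-noise round trip is an identity. Noise is multiplicative Gaussian
  with a chosen CV.
* **Scenes**: an elliptical body (smooth, center-weighted interior field)
  with filopodia radiating at jittered equally spaced angles (or a two-lobe
  angular bias). Tip punctum molecule counts are i.i.d. log-normal,
  µ_log = ln 730, σ_log = 1.3 — median 730 with a realistic four-decade
  range; 5.35% of each cell's molecules sit in filopodia; 30 filopodia per
  cell by default (observed range is roughly 12–116, median 55; 30 keeps
  protrusions resolvable on a 384² render). Shafts are drawn as crisp
  one-pixel Bresenham chains rather than anti-aliased strokes: anti-aliasing
  spreads mass into sub-threshold tails and makes the ground-truth pixel
  support ill-defined, which matters when tests assert mask coverage.
  Pixel size defaults to 0.108 µm (60×-class objective). The camera is
  gain × molecules + background (+ optional gradient) + **Gaussian** read
  noise — not Poisson shot noise, no PSF, no photobleaching, no 3D optics.
  Consequently, passing recovery tests demonstrates correctness of the
  mask algebra, conversion arithmetic, and error propagation — not
  robustness to optical blur, shot-noise-limited detection, or focus drift
  in real micrographs.
* **Trajectories**: start sizes log-normal around phase medians 160 / 290 /
  240 molecules (σ_log 0.6); accretion 1.5 molecules/s for growth phases
  (≈ +90 molecules over a 60 s track) and 0 for retraction; speed law
  v(m) = v_max/(1 + m/m_half) with v_max = 320 nm/s, m_half = 160 so that
  the median-sized cluster moves at the observed 160 nm/s median. The frame
  interval defaults to 1 s (the source movies are minutes long but their
  interval is not stated; 1 s keeps per-frame steps safely inside the
  0.5 µm linking radius). Trajectories start on an 8 µm grid so linking
  errors cannot contaminate statistics tests. Measurement noise: 5%
  multiplicative on molecules, 20 nm localization SD.

Problem sizes in the test suite (50 synthetic cells for parameter recovery,
237/60-frame trajectory sets, 1,000 oracle masks, 8,733 log-normal draws,
500 bootstrap draws over 50–200 cells) were chosen as the smallest sets at
which the asserted statistical properties are stable.

## Known limitations

* The Gaussian camera under-disperses relative to shot noise at high
  signal; recovery error bounds would loosen on Poisson data.
* The greedy linker is not guaranteed optimal in dense fields or for
  crossing trajectories; merging/splitting events are not modeled and are
  excluded from speed analysis by construction.
* Percent-filopodial estimates inherit any body-mask bias: the 3 px margin
  slightly truncates shaft bases.
* The membrane footprint of a Myo10 monomer is a free parameter; membrane
  saturation classifications are only as good as that number.
* CIs reflect calibration-slope error only; segmentation and photon noise
  are not in the interval.
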