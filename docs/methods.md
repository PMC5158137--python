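# Methods

This note documents the models, parameter choices and numerical decisions
behind `mtnet`, and what the synthetic-data tests do and do not establish.

## Microtubule-network morphometry

**Pipeline.** Cell-area selection → white top-hat → fixed-threshold
binarization → thinning → spur pruning → branch-point detection → densities.

- *Cell area*: Gaussian smoothing (σ = 10 px, configurable) → Otsu threshold →
  hole filling → largest connected component.  A flat bright field maps to the
  whole frame; an all-zero field raises an "empty field" error.  This is the
  simplest robust reading of "automated selection of the imaged cell area";
  every step is configurable.
- *Top-hat*: disk structuring element, default radius 5 px.  The radius must
  exceed the filament band half-width (bands are ~5–7 px wide after rendering)
  and stay below the inter-filament spacing; 5 px satisfies both for the
  synthetic defaults and for ~20 nm/px dSTORM reconstructions of 25 nm
  microtubules.
- *Threshold*: a single manual threshold per run, applied to every image
  identically.  The default (200 intensity units) was chosen once by
  inspecting the top-hat output of the default synthetic regime: centerline
  pixels sit at ≳ 300, the pure-noise top-hat background below ~150.  Real
  data need their own manually chosen value — that is the point of a manual
  threshold.
- *Skeleton*: Zhang–Suen thinning (scikit-image) followed by removal of
  8-redundant pixels (a non-endpoint pixel whose neighbours remain
  8-connected without it).  Thinning alone leaves staircase-corner pixels on
  anti-aliased band edges that masquerade as 3-way junctions; the cleanup
  makes the skeleton minimal and the operation idempotent.  The original
  analysis used a skeletonize-and-prune-ends variant of the same family of
  algorithms; standard topology-preserving thinning is the established
  equivalent, and tests cross-check against Guo–Hall thinning as an
  independent oracle (the two may differ by one endpoint pixel on tiny
  shapes).
- *Spur pruning*: skeleton segments shorter than 10 px that dangle off exactly
  one junction cluster are removed (two passes).  Bridges between junctions
  and isolated short filaments are never touched, so true crossings and true
  filament tips survive.  Without pruning, boundary noise contributes a few
  spurious branch points per cell.
- *Branch points*: skeleton pixels with ≥ 3 skeleton neighbours
  (8-connectivity); 8-connected clusters of such pixels count as one junction,
  because thinning can emit 2-px junction clusters.
- *Skeleton length*: pixel count by default (the convention in which the
  densities are defined); geodesic weighting (diagonal steps √2, edge-based)
  is available behind a flag.  Whether the original measure was pixel count or
  geodesic length is not decidable from its description; pixel count is the
  default here and the densities are in px⁻¹ either way.

## Orientation and local order

- *Rotating filter*: for each angle in {0°, 10°, …, 170°} a Bresenham line of
  11 px centred in its footprint is used as structuring element; the response
  image is the morphological opening (binary opening of the MT mask by
  default; grayscale opening of the image optionally).  The best angle per
  pixel is the argmax, ties to the smallest angle.
- *Consequences of the binary route*: on a band several pixels wide, every
  element within roughly ±20° of the band axis fits, so the recorded angle is
  the low edge of the tying set, not the axis itself.  This bias is constant
  across a cell and cancels in the angle-doubled statistic; it also means
  per-pixel angles follow an image rotation only up to the filter's angular
  resolution (±2 grid steps), and near 180° the smallest-angle rule wraps the
  recorded angle to 0°.  The acceptance tests assert exactly this behaviour:
  the order statistic S is rotation-invariant to < 0.05 while the modal angle
  tracks the rotation within 20°.
- *Local order statistic*: S = |mean of exp(2iθ)| over MT pixels inside a
  circular window of diameter 51 px (truncated at borders, no padding),
  computed by direct convolution of cos 2θ, sin 2θ and the validity mask.
  S is the mean resultant length of the doubled angles: 1 for locally parallel
  filaments, → 0 for isotropic disorder.  The quantity reported elsewhere
  under the name "circular variance, 1 when parallel" is this S (the textbook
  circular variance would be 1 − S); the implementation keeps the
  1-when-parallel semantics and the honest name.
- *Per-cell value*: arithmetic mean of S over MT pixels.

## AFM elasticity

- *Contact model*: Sneddon's rigid-sphere solution, parametrized by contact
  radius a (equations in the README).  δ(a) is strictly increasing on
  (0, R_s), so F(δ) is well defined; inversion uses a safeguarded, vectorized
  Newton iteration started from the Hertz guess a₀ = √(δR_s) and clipped into
  (0, R_s), accurate to ~1e-13·R_s.  For δ/R_s ≤ 0.005 the model agrees with
  the Hertz closed form (4/3)·E/(1−ν²)·√R_s·δ^{3/2} to < 1%.
- *Units*: nm, Pa, N/m and nN at every interface; Pa·nm² → nN is a fixed
  1e-9 factor, so no runtime unit conversion can go wrong.  Callers recording
  z in µm convert at input.
- *Force–indentation conversion*: F = k·d_corr, δ = (z − z₀) − d_corr, with
  d_corr the deflection minus a straight-line baseline fitted to pre-contact
  samples (photodiode offset and drift).
- *Fitting*: bounded least squares over (E, z₀), E ∈ [1, 10⁶] Pa, z₀ inside
  the recorded z range, residuals over all samples with δ ≤ fit depth
  (pre-contact samples contribute with model force 0).  Because the window
  depends on z₀, it is re-selected from the current estimate for up to three
  outer iterations.  z₀ is initialized where the smoothed corrected
  deflection last sits below 3× the baseline noise SD — scanning for the
  *last* sub-threshold sample makes the guess immune to isolated pre-contact
  noise spikes, which single-crossing detection is not.  Joint fitting of z₀
  is the default; a fixed pre-estimated z₀ is available via `FitConfig`.
- *Aggregation*: per-cell modulus = median over that cell's curves (robust to
  occasional bad contacts); mean available by flag.  Depths 200/400/600 nm
  are fitted per curve; on model-consistent data the three estimates agree to
  < 1%.
- *Group comparison*: Mann–Whitney U, exact distribution when both groups
  have ≤ 10 observations and no ties, normal approximation with tie
  correction otherwise; all-identical data returns p = 1 (the asymptotic
  variance is zero there).

## Synthetic data: what it emulates and what it does not

Filaments are infinite straight lines clipped to the frame — long, gently
curved microtubules at the scale of one cell are well approximated by
straight segments, and straight segments make angles and pairwise crossing
counts exact.  Ground truth (angles, Bresenham centerline pixels, crossing
count via exact segment-intersection geometry, axial resultant length) is
computed before rendering; a separate noise stream guarantees that changing
the noise realisation cannot change the truth.  Per-filament random
substreams keyed by filament index make same-seed networks nested, which is
what lets a test assert that adding one crossing filament never decreases the
detected crossing count.  "Total centerline length" is the count of distinct
centerline pixels, matching the skeleton-length pixel-count convention.

Defaults (512×512 px at 20 nm/px, 60 filaments, 3 px width, 2 px blur σ,
background 100 / amplitude 600 / noise SD 20 on a 16-bit scale) describe a
plausible reconstructed-dSTORM regime; no published noise or density
statistics exist for the images this emulates, so these are free parameters
chosen once, not calibrated to any figure.  The generator does not simulate
the localization process itself (blinking, drift, reconstruction artifacts),
filament curvature, depth structure, or intensity variation along filaments —
so a green morphometry test establishes correctness of the measurement
pipeline on networks of known geometry, not robustness to every dSTORM
artifact.

Approach curves follow the forward Sneddon model: past the contact point the
deflection solves k·d = F((z − z₀) − d) by bracketed root finding (Brent, to
1e-10 relative), giving exact generator↔fitter round trips; pre-contact
deflection is a linear baseline.  Defaults mirror the instrument
configuration this emulates: R_s = 2250 nm (4.5 µm silica bead),
k = 0.08 N/m, ν = 0.5, 1 nm deflection noise, 2500 nm sweep.  Cantilever
dynamics, hydrodynamic drag, adhesion and viscoelasticity are not modelled;
recovery tests therefore validate the estimator under the contact model's own
assumptions.

## Known limitations

- The morphometry threshold is manual by design; there is no auto-threshold
  fallback, and results are only comparable within a run sharing one value.
- Branch-point counts saturate on dense networks (crossings closer than the
  band width merge), so detected counts are a lower bound at high density;
  the monotonicity property, not equality to truth, is the guarantee.
- The binary orientation filter quantizes angles to the 10° grid with the
  smallest-angle tie bias described above; sub-degree orientation estimation
  (structure tensors, steerable filters) is out of scope.
- 2-D analysis only; depth-coded stacks are not handled.
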