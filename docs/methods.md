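# Methods

This note documents the models implemented in `bsitrack`, the parameters they
expose, the design of the synthetic phantom used for validation, the numerical
choices, and the known limitations. Every tunable value named here lives in
`PipelineConfig` (printable with `bsitrack config show`) or is a module-level
constant; nothing is hidden.

## 1. Template atlas (`bsitrack.atlas`)

All cross-scan and cross-view reasoning happens in the coordinate frame of a
template: a pair of 1024×256 anterior/posterior images of a stylised adult
skeleton at 2.26 mm/pixel, with a region label map assigning every skeletal
pixel to one of 10 regions (skull, cervical/thoracic/lumbar spine,
ribs+sternum, scapulae+clavicles, pelvis+sacrum, humeri, femora,
tibiae+fibulae). Each region carries a `weight_fraction` — its share of
reference-man total skeletal mass (fractions sum to 0.933; the remainder is
hands/feet, which planar scans resolve poorly and the template omits). The
posterior view is the horizontal mirror of the anterior: planar imaging sees
the same anatomy from the back, so a template column `c` corresponds to
posterior column `W−1−c` (`TemplateAtlas.mirror_column`). Region uptake in the
template follows typical relative tracer avidity (spine > pelvis/skull >
femora > ribs, soft tissue ≈ 6% of bone), lightly smoothed (σ = 1.2 px) to
avoid unphysical step edges.

The bundled atlas is generated procedurally at import; `save_atlas`/`load_atlas`
round-trip it to PNG + CSV/JSON for users supplying their own template.

## 2. Phantom (`bsitrack.phantom`)

Real serial bone scans are not redistributable, so validation uses a generator
with exact ground truth.

- **Lesions** are multiplicative isotropic Gaussian foci on bone:
  `activity *= 1 + (amplitude_ratio − 1)·exp(−r²/2σ²)` inside the skeleton.
  The user-facing `radius` is the **half-maximum radius**, i.e.
  `σ = radius/√(2 ln 2)`. This convention makes the ground-truth mask (the
  disk `r ≤ radius`) coincide with the full-width-at-half-maximum support that
  an intensity-based detector measures, independent of lesion contrast — the
  truth definition and the measurement definition agree by construction.
- **Anatomical deformation.** Each (time point, view) gets its own smooth
  random displacement field: white noise filtered with a Gaussian of
  σ = 40 px, rescaled so the peak displacement equals `deform_magnitude`
  (default 6 mm ≈ 2.7 px). The scan is formed by sampling,
  `scan(y) = activity(y + u(y))`; the same `u` warps the truth masks.
- **Noise.** Counts are Poisson with the deformed activity as mean, scaled so
  that median normal bone receives `counts_scale` counts/pixel (default 100,
  representative of planar acquisitions). `counts_scale=None` gives the
  noise-free deterministic image.
- **Determinism.** All randomness flows from one integer seed through
  `numpy.random.SeedSequence` with per-(time point, view) spawn keys;
  identical seeds give bit-identical images.
- **Cohorts.** `simulate_cohort` draws progressors (2–5 new lesions at
  follow-up) and non-progressors (0–1), each with 1–3 stable lesions, at
  random well-separated sites (≥ 26 px apart, `radius+2` px inside a region)
  with radius 3.2–5 px (≥ ~30 px disk area) and contrast 1.8–2.4×. Survival
  times follow `h(t) = h₀·exp(β·ΔBSI%)` with defaults h₀ = 0.04/month,
  β = 0.005, administrative censoring at 60 months. `imaging=False` skips
  image synthesis and yields only the truth covariates and outcomes.

Realism and its limits: Poisson counting statistics, smooth positioning/
anatomy differences between acquisitions, multiplicative focal uptake and
anterior/posterior mirroring are all physically motivated. Not modelled:
attenuation differences between views, scatter, bladder/injection-site
activity, superscan patterns, degenerative uptake, or patient-specific
skeleton shape. Conclusions about absolute clinical performance therefore do
not transfer; the phantom validates the *machinery* (correspondence, counting,
area measurement), not reader-level realism.

## 3. Registration (`bsitrack.registration`)

Each scan view is registered to the matching template view with a
multi-resolution B-spline free-form deformation (SimpleITK):

- Intensities are **rank-normalised** (each pixel replaced by its rank / N)
  before matching. Bone scans vary by injected dose and uptake time; ranks
  make the mean-squares criterion invariant to any monotone intensity
  transform.
- Fixed image = template, moving = scan, so the estimated transform maps
  **template → scan** points directly.
- Schedule: control-point mesh 3×12 (coarse across the narrow width, finer
  along the body axis), two pyramid levels (shrink 8 and 4, smoothing σ 2 and
  1 px), L-BFGS-B with 30 iterations per level, fully sampled metric. The
  full sampling and fixed schedule make registration deterministic. Two
  levels (rather than a deeper pyramid) were chosen after benchmarking: a
  third fine level tripled runtime (~10 s/view) for no accuracy gain at this
  resolution; the chosen schedule runs ~2 s/view with sub-pixel accuracy on
  the phantom (identity exact, 5/3 px translation recovered to ≤ 0.2 px,
  median landmark error ≈ 0.6 px at 6 mm deformation).
- The resulting `WarpField` stores a dense displacement `d` with
  `forward(x) = x + d(x)` (template → scan). The **inverse** (scan → template)
  is computed on demand by fixed-point iteration `x ← y − d(x)` (≤ 20
  iterations, 0.1 px tolerance); points in folded, non-invertible zones are
  reported with a warning. `transfer(a→b) = forward_b ∘ inverse_a` maps
  pixels between two scans through the template.

## 4. Hotspot detection (`bsitrack.detection`)

1. **Normalisation.** The scan is divided by the median count over the femora
   (reference region 9): healthy femoral shaft uptake is a stable internal
   reference, and the ratio image is invariant to global intensity scale.
2. **Seed segmentation.** The ratio image is smoothed (Gaussian σ = 1 px) and
   thresholded **per region** at `tau` (default 1.4) times the region's median
   ratio — regional thresholds absorb the normal uptake differences between,
   say, spine and ribs. 8-connected components with ≥ `min_area` (default 4)
   pixels become hotspot seeds.
3. **Extent.** Each seed grows to the full-width-at-half-maximum support of
   its peak above the regional baseline, confined to the seed's majority
   region (preventing leakage along the skeleton into neighbouring regions
   with different baselines). Because detection runs on the σ = 1 px smoothed
   image, the measured Gaussian is wider than the underlying lesion; the
   half-level is raised to `2^(−σ_l²/σ_e²)` (σ_e² the measured second moment,
   σ_l² = σ_e² − σ_smooth² the deconvolved one), which analytically removes
   the smoothing-induced area inflation for Gaussian-shaped foci.
4. **Classification.** Each hotspot (or linked group, see §5) gets features —
   area, peak ratio, mean ratio, eccentricity, boundary sharpness — and a
   logistic score `σ(−4 + 2·(mean_ratio−1) + 0.5·(peak_ratio−1) + ln area +
   region offset)`; score ≥ 0.5 labels it `metastasis`. The weights are fixed,
   interpretable coefficients (intensity and size increase suspicion;
   region offsets encode that e.g. isolated rib foci are more often benign);
   they are exposed in `DetectionConfig` and can be refit on labelled data.

Hotspot pixels are recorded in scan space; their template-space footprint
(via the warp's inverse) is attached for linking and reporting.

## 5. Linking and new-lesion counting (`bsitrack.linking`)

Hotspots from all scans and both views of a patient are mapped to template
space and joined into **lesion groups** by union-find. Two hotspots connect
when (same view) their template centroids lie within `d_max` = 8 px or their
template footprints overlap by ≥ `o_min` = 0.2 of the smaller area, or (across
views) the mirrored centroids lie within `d_pair` = 12 px (the cross-view
tolerance is looser because anterior and posterior see the lesion at slightly
different depths/projections). Union-find over canonically sorted hotspots
makes the partition independent of input order; the suite verifies equality
with a brute-force transitive closure on random fixtures.

Each group is classified once from area-weighted pooled features (area itself
averaged per acquisition), so a lesion faint in one view can be rescued by the
other. A **new lesion** is a metastatic group present at follow-up and absent
at baseline; `n_new ≥ 2` triggers the progression call. This counts
*lesions*, not hotspots: the same lesion seen in two views or persisting from
baseline is never double-counted, which is the entire point of linking.

## 6. Bone Scan Index (`bsitrack.bsi`)

For each metastatic hotspot, contribution = `(a / A_r) × w_r` with `a` the
hotspot area and `A_r` the region's area **in that view**. Contributions are
accumulated per (region, view); the two views of a region are then combined by
the **mean** rule (default; `max` and `sum` are available), reflecting that
each view is an independent estimate of the same regional involvement.
`BSI = 100 ×` the sum over regions. Serial change reports the ratio,
percent change and direction, with explicit conventions for zero baselines
(0→0 unchanged; 0→positive is an increase with undefined ratio).

## 7. Cohort evaluation (`bsitrack.cohort`)

Three-reader panels with majority consensus (undecidable patients excluded),
confusion matrices of automated vs consensus calls, and
sensitivity/specificity/PPV/NPV as whole percentages (half-up rounding, the
convention used when comparing against published counts). A zero denominator
yields `None` rather than a silent 0. `simulate_reader_panel` produces
synthetic panels that flip the true call with a given probability.

## 8. Survival (`bsitrack.survival`)

Kaplan–Meier and the two-group log-rank test are implemented directly (a few
dozen lines each) so that the test suite can check them against hand-computed
product-limit and O−E tables; the log-rank is also cross-checked against
`lifelines`. The Cox proportional-hazards fit delegates to
`lifelines.CoxPHFitter` (Efron tie handling) — a standard, well-tested
optimisation there is no value in re-implementing — behind a thin interface
returning coefficient, SE, hazard ratio and 95% CI. Two-year survival is the
KM estimate at 24 months per group, as a percentage.

## 9. Numerical choices

- All image warps use bilinear (`order=1`) interpolation: hotspot masks and
  count images must not acquire negative/overshooting values, which cubic
  interpolation produces at edges.
- Truth masks are warped as floats and re-thresholded at 0.5.
- Rank normalisation uses average ranks for ties, so flat background regions
  stay flat.
- Percentages reported against published-count fixtures use half-up rounding
  (`round_half_up`), not banker's rounding.
- Every stochastic component takes an explicit seed; sub-streams are derived
  with `SeedSequence` spawn keys, never by incrementing seeds.

## 10. Limitations

- The template is stylised; with real scans a population-derived template and
  refit classifier weights would be needed (both are injection points:
  `load_atlas`, `DetectionConfig`).
- The hotspot classifier's coefficients are fixed and interpretable, not
  trained; reported phantom sensitivity/specificity characterise the pipeline
  on the phantom's lesion model only.
- FWHM area measurement assumes roughly Gaussian focal uptake; confluent
  ("superscan") disease violates this and is out of scope.
- The inverse warp is approximate near folds; folded points are flagged, not
  silently accepted.
- The survival simulation uses exponential baselines and administrative
  censoring only; no competing risks.
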