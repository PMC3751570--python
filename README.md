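# bsitrack

Automated analysis of serial whole-body bone scans (planar scintigraphy):
hotspot detection, temporal lesion linking, new-lesion counting, and the Bone
Scan Index (BSI) — plus the statistics used to evaluate these imaging
biomarkers against reader panels and survival outcomes.

## Why

In metastatic prostate cancer, treatment response on bone scans is commonly
judged by two quantities:

- **New-lesion count.** Disease progression is called when a follow-up scan
  shows **two or more new lesions** relative to baseline (the PCWG2 criterion).
  Doing this automatically requires solving a correspondence problem: the
  patient is positioned differently at each acquisition, so hotspots must be
  compared in a shared anatomical coordinate frame, not in raw pixel
  coordinates.
- **Bone Scan Index.** The BSI expresses tumour burden as the percentage of
  total skeletal mass involved by metastases. Each metastatic hotspot
  contributes its area `a` relative to the area `A_r` of the skeletal region
  it lies in, weighted by that region's fraction `w_r` of reference-man
  skeletal mass:

  ```
  BSI = 100 × Σ_hotspots (a / A_r) × w_r
  ```

  Anterior and posterior views each see the full skeleton, so per-region
  contributions from the two views are averaged.

`bsitrack` implements the full pipeline: non-rigid registration of each scan
view to an anatomical template, region segmentation via the template's region
label map, intensity-based hotspot detection with a metastasis/benign
classifier, linking of hotspots across views and time points into lesion
groups, new-lesion counting and the progression call, and BSI with serial
change. Because real serial bone scans cannot be redistributed, the package
also ships a **phantom**: a synthetic scan generator with planted lesions,
smooth random anatomical deformation and Poisson counting noise, providing
pixel-level ground truth against which every stage is validated.

## Worked example

Simulate a progressing patient (one stable lesion, two new lesions at
follow-up, 6 mm anatomical deformation between acquisitions) and compare the
two scans:

```python
from bsitrack import LesionSpec, compare_pair, default_atlas, simulate_patient

atlas = default_atlas()
lesions = [
    LesionSpec(3, (250, 128), radius=4.4, amplitude_ratio=2.0,
               present_at=frozenset({0, 1})),   # stable (thoracic spine)
    LesionSpec(7, (490, 100), radius=4.0, amplitude_ratio=1.9,
               present_at=frozenset({1})),      # new at follow-up (pelvis)
    LesionSpec(9, (650, 95), radius=3.6, amplitude_ratio=2.2,
               present_at=frozenset({1})),      # new at follow-up (femur)
]
series, truth = simulate_patient(atlas, lesions, deform_magnitude=6.0,
                                 counts_scale=100.0, seed=11)
comparison, base, follow = compare_pair(series.baseline, series.followup, atlas)
```

Output of `python examples/02_serial_comparison.py`, which runs exactly this:

```
true new lesions:     2
detected new lesions: 2
progression (>= 2 new lesions): True
BSI baseline -> follow-up: 0.131% -> 0.265% (+102%, increase)

lesion groups (hotspots linked across views and time points):
  group 0: 4 hotspots, time points [0, 1], label metastasis (stable)
  group 1: 2 hotspots, time points [1], label metastasis (NEW)
  group 2: 2 hotspots, time points [1], label metastasis (NEW)
```

The stable lesion appears as one group with hotspots at both time points in
both views; each new lesion forms a group present only at follow-up. Two new
metastatic groups trigger the progression call.

The survival side (`python examples/04_survival_analysis.py`) simulates a
200-patient cohort whose hazard depends on the true BSI change
(`h = 0.04 × exp(0.005 × pct_change)` per month) and recovers the generating
coefficient with the package's Cox fit:

```
two-year survival: increase 15%, decrease 48%
log-rank: chi2 = 20.11, p = 7.3e-06

Cox, BSI % change as covariate:
  hazard ratio per % point: 1.0055 (95% CI 1.0046-1.0064), p = 7e-32
  generating value exp(0.005) = 1.0050 inside the CI
```

## Command line

Everything is also available as a CLI:

```bash
bsitrack simulate --out cohort/ --patients 10 --seed 1   # synthetic cohort
bsitrack analyze cohort/patient_000 --time-point 0       # hotspots + BSI
bsitrack compare cohort/patient_000 cohort/patient_000 --out report/
bsitrack cohort cohort/ --out report/                    # metrics + survival
bsitrack config show                                     # all thresholds
```

Scans are 16-bit grayscale PNGs with JSON sidecars; reports are JSON/CSV;
`compare` also writes overlay PNGs (new lesions red, old lesions yellow).
Exit codes: 0 success, 2 usage/validation error. Every command is
deterministic for a fixed seed and configuration.

## Package layout

| module | contents |
|---|---|
| `bsitrack.atlas` | template images, region label maps, skeletal mass fractions |
| `bsitrack.phantom` | synthetic patient/cohort generator with ground truth |
| `bsitrack.registration` | B-spline scan↔template registration, warp transfer |
| `bsitrack.detection` | hotspot segmentation and metastasis classification |
| `bsitrack.linking` | cross-view/cross-time lesion grouping, new-lesion count |
| `bsitrack.bsi` | BSI formula and serial change |
| `bsitrack.cohort` | reader panels, confusion matrices, diagnostic metrics |
| `bsitrack.survival` | Kaplan–Meier, log-rank, Cox (via lifelines) |
| `bsitrack.pipeline` | end-to-end composition of the above |
| `bsitrack.cli` | `bsitrack` command |

`docs/methods.md` describes the models, every tunable parameter, the phantom's
realism and its limits, and the numerical choices. `examples/` contains the
narrative scripts quoted above.
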