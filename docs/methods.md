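# Methods

This note documents the generative model, the measurement pipeline, the
default parameters (and why they were chosen), the numerical conventions
and the limitations of the `hodasym` package.

## 1. Geometry and grids

All volumes use RAS axis order `[x, y, z]` (`+x` right, `+y` anterior,
`+z` superior). The physical centre of voxel `i` along an axis with
spacing `s` is `(i + 0.5) · s` mm, so differently sampled grids share one
physical frame exactly.

| grid           | shape        | spacing (mm)          | used by |
|----------------|--------------|-----------------------|---------|
| fine           | 96 × 96 × 24 | 0.625 × 0.625 × 2.0   | PD, T2  |
| thick-slice    | 96 × 96 × 12 | 0.625 × 0.625 × 4.0   | FLAIR   |
| diffusion      | 30 × 30 × 24 | 2.0 × 2.0 × 2.0       | FA, MD  |

The in-plane field of view is 60 mm with the medulla axis at its centre.
The FLAIR volume is produced by averaging pairs of adjacent 2-mm slices
of a noiseless fine-grid image and adding noise afterwards, emulating a
thicker-slice acquisition rather than resampling a noisy image.

## 2. Phantom model

The medulla cross-section is a cylinder of radius 9 mm. The two inferior
olives are ellipsoids with semi-axes (3.0, 2.0, 3.5) mm, centred 3.2 mm
lateral and 3.5 mm anterior of the medulla axis at slice height 24 mm.
These dimensions keep each olive inside the anterior quadrant of the
medulla and inside the 8-mm measurement slab, and give an olive-to-ROI
voxel ratio (~110 of ~928 fine-grid voxels per side) such that realistic
olivary signal changes produce quadrant-level asymmetries in the
low-percent range actually observed for this measurement — the olive
signal is heavily *diluted* by surrounding quadrant tissue.

Structural intensities: background 100 in the medulla; the healthy olive
is visible only on PD (contrast factor 1.15; 1.0 on T2/FLAIR). A
degeneration-positive side applies

- a multiplicative intensity effect `1 + e` over the (possibly enlarged)
  olive on every structural modality, and
- an enlargement of the olive semi-axes by a factor `1 + g`
  (default `g = 0.1`), reflecting that hypertrophy is part of the
  pathology.

A signed per-modality percentage scales the whole left half of the
image, emulating residual left/right imbalance in healthy anatomy
(acquisition bias, coil profile, true anatomical asymmetry).
Zero-mean Gaussian voxel noise is added last (SD as a fraction of the
base intensity: 2 % for PD/T2/FA/MD, 3 % for FLAIR).

Diffusion maps: FA baseline 0.45 and MD baseline 8 × 10⁻⁴ mm²/s inside
the medulla. A degeneration-positive subject has FA reduced and MD
increased over the *affected anterior-quadrant olivary territory*
(medulla ∩ affected half ∩ anterior of the sulcus line ∩ 8-mm slab) on
the diffusion grid, because at 2-mm isotropic resolution the olive spans
only a handful of voxels and the degenerative diffusion change is not
confined to the visible nucleus. Nominal effects: FA × (1 − 0.35),
MD × (1 + 0.10).

### Analytic expectations

Because every region is defined by explicit voxel masks, the noiseless
anterior-quadrant means are exact finite sums. `expected_quadrant_means`
evaluates them from voxel counts alone (never from the generated image),
and `expected_diluted_effect` turns them into the predicted asymmetry
index. The test suite verifies the generated images against these
formulas to ~1e-10 relative precision, and noisy replicate means against
them within 3-SEM bands.

## 3. Cohort model

- **Controls** carry no degeneration. Their signed imbalance per modality
  is drawn `N(0, σ)`, making the *unsigned* asymmetry index follow a
  folded normal with mean `σ √(2/π)`. The default σ values
  (PD 1.517, T2 1.717, FLAIR 2.682 percent) place the expected control
  means at 1.21 / 1.37 / 2.14 % — the low-percent regime this measurement
  exhibits on real control anatomy.
- **Patients** carry a unilateral lesion (side uniform) and develop the
  degeneration with probability `hod_prevalence_in_patients`
  (default 0.8; recruitment by lesion precedes the imaging finding, so
  not every patient converts). Positive patients draw the intensity
  effect `e` from a truncated log-normal (median 0.25, log-SD 0.6,
  support (0, 0.5]) — right-skewed severities with a realistic spread of
  sub- and supra-threshold cases.
- **DTI severity coupling:** FA/MD effects scale with
  `min((e / 0.25)², 1)`, i.e. quadratically up to the reference effect.
  Mild (often threshold-negative) cases therefore carry only faint
  diffusion changes while clearly positive cases carry the nominal
  effects, which reproduces the qualitative pattern of a strongly
  negative FA / positive MD threshold-positive subgroup versus a
  near-zero threshold-negative subgroup.
- Controls receive no DTI volumes (the emulated design did not scan
  controls with DTI); optionally the first `n_flair_missing_patients`
  patients lack FLAIR.

Simulated reviewers call a degeneration-positive subject positive with
probability `sensitivity` (default 0.85), flip the reported side with
probability `laterality_error_rate` (0.05), and call a negative subject
positive with probability `1 − specificity` (0.07) with a random side.

## 4. Measurement pipeline

1. **Slab selection:** `n = round(8 mm / dz)` consecutive slices,
   centred on the olive with inferior bias for even `n`
   (start = centre − n//2): 4 slices at 2 mm, 2 at 4 mm.
2. **Quadrant segmentation** per slice from three landmarks: the
   anterior/posterior divide is the chord joining the posterolateral
   sulci; the left/right divide is its perpendicular through the
   anterior median fissure (robust to in-plane rotation; distances in
   mm, so anisotropic voxels are handled). On-line voxels count as
   anterior; on-axis voxels go to the left quadrant. Landmark validation
   enforces the RAS convention (fissure anterior of the sulcus chord).
3. **Index:** structural modalities use the unsigned index
   `100 (higher − lower)/lower`; FA/MD use the signed expected-side
   index `100 (expected − contralateral)/expected`.
4. **Calibration/classification:** threshold = control mean + 2.576 ×
   control SD (sample SD, ddof 1); a subject is positive when its index
   is *strictly* greater; for positives with a known lesion the side of
   the higher quadrant is checked against the expected side.
5. **Statistics:** Lilliefors normality screening routes comparisons to
   t-tests (normal) or Wilcoxon–Mann–Whitney (otherwise); the FA/MD
   subgroup contrast uses Welch's t between PD-threshold-positive and
   -negative patients.

## 5. Numerical and statistical choices

- `z = 2.576` is used verbatim for the "99 %" threshold (the upper
  99.5th normal percentile; one-sided coverage of the rule is ≈ 99.5 %,
  which the coverage simulation reflects).
- Lilliefors p-values come from a seeded 10,000-replicate Monte-Carlo
  null (statistic via statsmodels), `p = (1 + #{D* ≥ D}) / (n + 1)`.
- The Wilcoxon–Mann–Whitney p is exact (full enumeration) when
  `min(n₁, n₂) ≤ 8` and there are no ties, asymptotic with tie
  correction otherwise. All tests are two-sided.
- Welch's t with both variances zero is reported as a flagged degenerate
  result (`t = 0, p = 1` for equal constants, `±∞, p = 0` otherwise)
  rather than an exception.
- Fleiss' kappa is computed from the category count table; when chance
  agreement is 1 (a single used category) kappa is reported as
  undefined, not 0 or 1.
- All random draws flow from `numpy.random.SeedSequence`; per-subject
  seeds are derived from the cohort seed, so cohorts are reproducible
  bit-for-bit and subjects can be regenerated independently.

## 6. What the generator does and does not emulate

Emulated: multi-resolution acquisition of one anatomy; dilution of a
focal olivary change inside a quadrant ROI; residual control asymmetry;
degeneration prevalence below 1 in lesion-selected patients; coupled
structural/diffusion effects; missing modalities; imperfect blinded
reviewers.

Not emulated: realistic brainstem anatomy beyond a cylinder/ellipsoid
idealization; partial-volume and susceptibility artefacts; registration
or landmark-placement error (landmarks are exact by construction);
scanner- or sequence-specific contrast beyond a single contrast factor;
longitudinal evolution of the degeneration; bilateral degeneration.

## 7. Limitations

- Quadrant ROI sizes and the exact dilution factor depend on the
  idealized geometry; absolute thresholds from synthetic cohorts should
  not be transferred to clinical data.
- The DTI effect territory is a geometric surrogate; real degenerative
  diffusion changes are not sharply bounded by quadrant lines.
- Reviewer simulation treats ratings as conditionally independent given
  ground truth; real raters share systematic biases, which inflates
  real-world kappa relative to this model at equal accuracy.
- The folded-normal control model assumes a single imbalance scale per
  modality; real control asymmetry may be heavier-tailed.
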