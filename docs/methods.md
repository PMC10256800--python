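# Methods

This note documents the models, conventions and design choices behind
`lungfx`, and what the synthetic validation does and does not demonstrate.

## Volumes and geometry

All volumes are 3D scalar grids with per-axis spacing and an origin in mm;
voxel indices are 0-based, physical position = origin + index × spacing,
array order is `data[x, y, z]` with x fastest, and every inter-volume
operation works in physical space. NIfTI and MetaImage are read and written
through SimpleITK; direction cosines are assumed axis-aligned. Out-of-domain
resampling fills with −1000 HU (air), the neutral value in a lung context;
non-CT maps should pass `fill_value=0`. All tables are comma-separated
UTF-8 text with a header row.

## Ventilation model

The ventilation surrogate is the local expansion ratio over N breathing
phases. Displacement fields map end-exhale coordinates to each phase; the
Jacobian determinant J = det(I + ∇u) is evaluated with central differences
in physical units (one-sided at the grid boundary). Per voxel, LER-N is
max/min over {1} ∪ {J_k}: the exhale reference participates as J = 1, which
makes the map ≥ 1 by construction, permutation-invariant in phase order,
and monotone under added phases. Voxels with any non-positive J are
non-physical; they are flagged invalid and excluded from ROI statistics
rather than propagated as NaN.

Thresholds follow the operative study rules exactly as printed: High uses
LER-N ≥ 1.2 (inclusive), Low uses ≤ 1.1 (inclusive), decline uses
post/pre < 0.94 (strict) and increase > 1.06 (strict); ratios of exactly
0.94 or 1.06 are Stable.

Two open conventions were decided as follows and are switchable:

- **Per-contour change ratio** defaults to the ratio of ROI means
  (`ratio_of_means`), which is robust to voxel-level registration noise;
  `mean_of_ratios` is available for comparison.
- **Effort correction** is a single global scaling of the excess expansion,
  (LER-N − 1) × reference_TV / measured_TV, clipped below at 1. The source
  method is only cited, not specified, in the validation study; a global
  first-order scaling is the simplest rule consistent with a tidal-volume
  based correction, and is flagged here as a stand-in.

**Registration.** The B-spline deformable registration uses SimpleITK:
mean-squared-error metric, a 3-level image pyramid, control-point spacing
of 8 voxels, an L-BFGS-B optimizer, and either full metric sampling or
regular sparse sampling with a fixed seed — both deterministic.
Registration is pluggable: ground-truth displacement fields can be supplied
directly (bypass mode), which is how most of the synthetic validation
isolates the analysis stages from registration error.

## Perfusion model

Time-attenuation curves are ROI means per frame (the ROI statistic is the
mean throughout). Baseline is the mean of the pre-injection frames; peak
enhancement is max − baseline; AUC defaults to the baseline-subtracted
trapezoidal integral from the first post-injection frame to the last frame,
making it contrast-specific rather than anatomy-specific (raw-curve and
full-curve variants are keyword options, since the source analysis states
neither the subtraction nor the limits). The injection frame can be given
explicitly or detected as the first frame exceeding baseline + 3 baseline
standard deviations (1 HU floor).

Dose bins are half-open [lo, hi) 10-Gy bins over 0–60 Gy with the last bin
closed; an ROI's bin is set by its mean dose; empty bins are omitted with a
log notice. The vessel–parenchyma relation is a least-squares fit of
parenchyma Δbaseline against vessel Δpeak over bins whose lower edge is at
or above the dose threshold (default 25 Gy); zero-variance input returns
slope 0 and r 0 with a degenerate flag.

## Contours

Dose levels: MaxDose when the ROI intersects the PTV; otherwise by mean ROI
dose (< 5 Gy NoDose, 5–20 Gy inclusive LowDose; above 20 Gy outside the PTV
is flagged Unclassified and excluded). Mean dose, rather than max or a
point dose, is used because it is stable for small vessel ROIs; a config
switch is the natural extension if a max-dose criterion is wanted. Fed
status is strict descent in the vessel tree: a vessel is Fed iff it lies
downstream of the max-dose vessel (the max-dose vessel itself is not Fed).

The contralateral control mirrors the max-dose ROI centroid across the
mid-sagittal plane of the combined lung bounding box, snaps to the nearest
contralateral lung voxel (logging a warning beyond 30 mm) and emits an
equal-volume sphere clipped to the lung.

Ventilation points are spheres of configurable radius (default 10 mm,
standing in for the study's ~1-inch histology sections). A candidate centre
must have ≥ 90% of in-sphere lung voxels matching its pre/post class pair
(the "region of similar ventilation" rule); the most pure candidate wins,
with ties broken most-superior, then most-anterior, then most-right, making
selection deterministic. A class pair with no candidate is reported
unavailable, not an error, mirroring its subject-dependence.

## Pathology and concordance

Collagen grades live on the ordinal scale no significant = 0, minimal = 1,
mild = 2, moderate = 3, marked = 4, severe = 5, with hyphenated range
readings mapped to midpoints (e.g. minimal-mild = 1.5). Damage
classification: **Damaged** when collagen ≥ 2 (not artifact-suspect) or
fibrosis strength ≥ 2; **NotDamaged** when collagen ≤ 0.5 and no diagnosis
reaches strength 2; **Intermediate** otherwise. Collagen findings flagged
as suspected fixation artifacts are excluded from damage evidence. The
feasibility cohort's binary collagen is stored as grades {0, 2} so the same
rules apply.

The agreement policy — Decline↔Damaged and NoDecline↔{NotDamaged,
Intermediate} agree, everything else disagrees — is an *interpretation*:
the study never prints its operational rule. This table is the unique
reading that reproduces the printed tally (45 points, 41 agreements, 91%)
together with the printed identities of all four disagreements, and it is
exposed as a configurable policy argument.

One transcription decision deserves emphasis. The results narrative reports
that one of the five fully-characterised subjects had a max-dose LER-N
ratio of 0.95 (nominally Stable), while the concordance discussion counts
all five max-dose points as concordant with their uniformly damaged
pathology and lists no max-dose disagreement. The packaged ventilation
table follows the concordance arithmetic (Decline at all five MD rows); the
subject identity of the 0.95 animal is not printed, so no per-subject ratio
is stored for MD. Similarly, per-subject grades and strengths for cells the
text only constrains in aggregate were completed minimally and frozen; every
printed count and constraint in the narrative is honoured.

The paired t-test uses t = mean(d)/(sd(d)/√n) with the sample standard
deviation and a two-tailed p from the t distribution with n − 1 degrees of
freedom; zero-variance differences are degenerate (p = 1, flagged). Tests
cross-check it against numerical quadrature of the t density and an
independent library implementation.

## Synthetic study

The generator is a pure function of (spec, seed) end to end.

**Phantom.** A 192 mm cube, by default 96³ voxels at 2 mm: two disjoint
lung ellipsoids (semi-axes 32 × 42 × 62 mm), air −1000 HU, body 0 HU,
parenchyma −750 HU with smooth ±40 HU texture (so registration has
something to match), vessels 50 HU. The vessel tree is rooted at a shared
inlet and grown per lung by recursive spatial subdivision — each node owns
a box of its lung, split along the longest axis between its children — so
branches genuinely traverse the lung; radii decay by 0.78 per generation
with a 1.2 mm floor. Segment voxel sets are made disjoint (junction voxels
belong to the shallowest claimant), so per-vessel ROIs are unambiguous.

**Breathing series.** The displacement construction ships its own analytic
Jacobian: all displacement is along z, u_z(x, y, z) = ∫ (T − 1) dz from the
lung mid-plane, so det(I + ∇u) = T exactly in the continuum — the
cross-derivatives of a z-only displacement never enter the determinant.
Phase k scales u by a cosine waveform w_k ∈ [0, 1] (0 at exhale, 1 at peak
inhale), giving the analytic per-phase Jacobian 1 + w_k (T − 1). Phase
images are produced by fixed-point inversion of the forward map and linear
interpolation. Targets with |J − 1| > 0.6 trigger a small-deformation
warning.

**Expansion targets.** Background lung sits at LER-N 1.15; designed regions
(14 mm spheres, smoothly blended edges with exact interior plateaus) encode
the ventilation points: HHV 1.30 pre and post, LLV 1.06 pre and post, HLV
1.24 → 1.07. Treatment response is a voxel-wise post/pre ratio field: a
direct dose-coupled term falling linearly from 1 at 20 Gy to 0.90 at 45 Gy
and above, plus an indirect factor of 0.96 around fed low/no-dose vessel
segments with a per-subject standard deviation of 0.015 (the indirect
response is subject-dependent in kind). These values sit inside the
physiological ranges the validation study reports for each point class and
reproduce its qualitative outcome: decline at the max-dose and high-to-low
points in every subject, none at the control, high-high, low-low, or
not-fed points.

**Contrast kinetics.** The bolus is a peak-normalised gamma variate,
γ(t) = ((t − t0)/(αβ))^α exp(α − (t − t0)/β), so the amplitude parameter
(default 250 HU) *is* the peak enhancement; defaults t0 = 8 s, α = 2,
β = 3 s on a 24-frame, 2-s timeline with 4 pre-injection frames.
Parenchyma follows a 0.12-scaled, 3-s-delayed copy. Post-treatment, fed and
max-dose vessels lose amplitude by a factor 0.6 (AUC scales linearly with
amplitude), vessels above 25 Gy additionally lose 4 HU of peak per Gy, and
parenchyma baseline rises by 0.6 of the local vessel peak loss — the
designed vessel–parenchyma slope. Gaussian voxel noise (15 HU sd) is added
per frame. The realised per-vessel amplitude ratio is recorded as ground
truth for recovery checks.

**Contour construction.** The prescription (60 Gy Gaussian, σ = 16 mm)
centres on the second-generation ipsilateral vessel's segment midpoint;
per-node mean doses are annotated from segment voxels; the max-dose node,
its descendants (fed), and the dose ranges then yield the four indirect
contours — in each category the *largest measurable vessel* is contoured,
as tiny distal segments (a handful of voxels) are not a plausible
measurement region. Candidates intersecting the PTV are excluded. The
contralateral lung is capped below 5 Gy by masking, honouring the planning
constraint. Ventilation-point region centres are found by a deterministic
grid search maximising clearance from the contoured vessels, subject to
staying inside the lung, at most 10 Gy, and mutually separated.

**Pathology sampling.** Expected collagen grade = 0.3 + dose term (0 / 0.8 /
3.0 for no/low/max dose) + 0.7 if fed + 2.8 if ventilation declined, capped
at 4 (no severe grades, as observed), sampled with sd 0.3 and rounded to
half-steps; the control is forced clean. Diagnosis probabilities rise
linearly with the expected grade per condition. A scale of 0 gives the null
model (no findings anywhere).

**What the synthetic data does not emulate.** Realistic CT noise physics
and artifacts, porcine-specific anatomy beyond lung/vessel topology, the
3-month radiobiological time course, registration failure modes on real
texture, and inter-pathologist variability. Passing synthetic tests
therefore demonstrates the correctness of the computations and their
recovery of known ground truth, not clinical performance on real scans.

## Problem sizes and numerical notes

The generator default is 5 subjects, 10 phases, 96³ at 2 mm, and the
end-to-end cohort tests and the acceptance script run at exactly those
conditions (a full cohort takes ~20 s). Unit tests use 48³/64³ phantoms
with the same 192 mm physical geometry, and the registration-based recovery
check runs one 48³ two-phase study with a smooth 24 mm target region and
25% regular metric sampling — a deliberately smooth deformation, since the
check targets the registration-to-LER-N path, not registration robustness.
AUC effect-multiplier recovery at the default noise level is asserted at
cohort level (mean over the five subjects per contour); per-subject ratios
on the smallest vessel ROIs are noise-limited by ROI size. Numerical
tie-breaks (point selection, node choice) are lexicographic on voxel index
or node id; all randomness flows from explicit seeds through
`numpy.random.Generator`, and tables are written with fixed float
formatting so identical seeds give byte-identical files.

## Known limitations

The agreement policy and the MD-row transcription are interpretations of a
narrative that never states them operationally (both documented above); the
effort-correction rule is a stand-in for a method that is only cited; the
synthetic registration check exercises an easy deformation regime; and
group-level quantities that the study prints but does not decompose per
subject (e.g. 0.88 ± 0.03 at HLV) are represented in the fixtures only by
their class labels plus the few literal per-subject values that are printed.
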