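# Methods

This note records the models, conventions, and design choices behind
`pspdti`, in the order the pipeline runs.

## Scope and coordinate conventions

All analyses operate on scalar FA volumes on a 1-mm isotropic grid in a
shared space. Spatial normalization of real scans (nonlinear registration
to a stereotaxic template) is outside the package's scope: synthetic data
are generated pre-aligned, and real inputs are expected already normalized;
the identity affine carried by each volume stands in for that transform.
Voxel indices are 0-based; world coordinates follow the NIfTI affine.
Masks are stored as unsigned-integer label volumes on disk.

## Synthetic cohort generator

**What it emulates.** The generator produces the statistical structure the
staging analysis relies on, not anatomy. A toy atlas places 36 structures —
21 ROI cubes and 15 straight TOI corridors — on a slot lattice
(default grid 96×112×96 voxels) with enough spacing that an 8-mm smoothing
kernel does not mix neighbouring structures. The structures follow the
standard three-phase grouping of PSP-affected anatomy: 8 early-phase
(brainstem/basal-ganglia) structures including the putamen and globus
pallidus counted separately and the paired cerebral peduncles kept as
left/right, 19 intermediate-phase structures (basal ganglia, diencephalon,
frontal white matter, cerebellum, with the corpus callosum's frontal
segments I–III separate), and 9 late-phase structures (parietal, temporal,
occipital white matter and associated tracts, corpus callosum IV–V). All
other bilateral structures are pooled. The exact composition of published
36-parameter sets is not fully specified in the open literature, so this
enumeration is a documented reconstruction — the unique natural reading of
the three-phase table that sums to 36.

**Generative model.** Per subject and structure,

    FA = base + age_slope·(age − 70) + subject_effect + structure_effect
         + lesion_offset [+ retest_noise at follow-up],

with voxelwise Gaussian noise in fast mode. Defaults (FA units): baselines
0.45 (ROI), 0.55 (TOI corridor), 0.10 background; `subject_sd` 0.004 (a
global per-subject shift, shared across structures and therefore not
reduced by averaging); `structure_sd` 0.015 (independent per structure,
persisting across timepoints — the dominant component of control
between-subject spread); `voxel_noise_sd` 0.02; `retest_sd` 0.007 added to
follow-up scans at structure level, chosen so the control test–retest
floor (mean absolute FA change, ≈ σ·√(2/π) ≈ 0.006) matches the magnitude
reported for repeated clinical DTI; `age_slope` −0.001 FA/year applied
globally, with ages drawn uniformly on 50–90 years to match elderly cohort
ranges.

**Lesions.** A pattern-k structure is offset only for generated stages ≥ k:
pattern 1 −0.025/−0.028/−0.031 at stages 1/2/3, pattern 2 −0.025/−0.028 at
stages 2/3, pattern 3 −0.022 at stage 3. The mild deepening with stage
makes severity summaries monotone; the offsets are calibrated so pattern
score shifts land in the −1.2 to −1.9 z range — comfortably past the
0.47-z affectation threshold relative to the control spread
√(0.004² + 0.015²) ≈ 0.016, which is what makes ≥80% exact stage recovery
achievable while single structures still overlap between groups. The
putamen is the one structure whose FA *increases* in patients (+0.02 at
any stage), emulating the paradoxical putaminal FA elevation reported in
this disease; its positive z-values dilute the pattern-1 mean exactly as
in the analysis, since no sign flip is applied. Patients advance one
generated stage at follow-up; controls receive pure retest noise.

**Two generation modes.** Fast mode writes FA maps directly (Gaussian voxel
noise); full mode builds per-voxel axially symmetric tensors with
prescribed FA and mean diffusivity 0.7×10⁻³ mm²/s (lesions adjust
eigenvalues at constant trace), simulates the diffusion-weighted signal
S = S0·exp(−b·gᵀDg) under either the 70-volume two-shell scheme
(10 b=0, 30 b=700, 30 b=1000 s/mm²) or the 52-volume single-shell scheme
(4 b=0, 48 b=1000), adds Rician noise at a stated b0 SNR, and exercises
the tensor-fit path. Rician is the physically appropriate magnitude-MR
model; fast mode trades it for speed in statistical tests.

**What it does not emulate.** Brain geometry, crossing fibres, partial
volume with grey matter/CSF, scanner and site effects, motion and eddy
currents. Tests passing on this generator therefore certify the analysis
logic and its statistical calibration, not robustness to acquisition
artifacts.

## FA processing

The tensor fit is unweighted log-linear least squares with S0 estimated
from the mean b=0 signal; it inverts the noise-free forward model exactly.
Negative eigenvalues are clamped at 10⁻¹², voxels with non-positive b0 are
flagged invalid (FA 0). Smoothing uses σ = FWHM/(2√(2 ln 2)) with
zero padding at the volume boundary and clipping back to [0,1]; interior
constant regions are unchanged. Age correction fits a per-voxel OLS slope
of FA on age over controls and corrects every map to the control mean age;
both signs of slope are corrected, and the slope is accumulated without
stacking all control volumes in memory. The FA analysis floor of 0.2 is
inclusive (mask is FA ≥ 0.2), reading "below the floor is excluded"
literally; the same convention is used for the ROI/TFAS floor even though
a strictly-greater reading is also defensible there — the one-boundary-value
discrepancy is unified deliberately.

## WBSS

The analysis mask is defined at group level — voxels whose mean FA over
*all* subjects is ≥ 0.2 — so the multiple-testing family has a single
well-defined size. Tests are pooled-variance Student t, two-sided; at
zero-variance voxels t = 0 when means agree, and unequal means are capped
at the largest finite |t| in the map to avoid propagating infinities.
Benjamini–Hochberg runs over all in-mask voxels. Cluster pruning uses
6-connectivity (faces only — the conservative choice for eliminating
isolated voxels), labels positive-t and negative-t voxels separately, and
removes components below 512 voxels, the volume of the smoothing kernel's
8-mm cube on the 1-mm grid. The t-threshold profile re-applies this filter
at rising |t| thresholds; because surviving voxel sets nest, the reported
volume is monotonically non-increasing.

## Tractography and TFAS

TOIs are tracked once on an averaged control tensor field and reused for
all subjects; per-subject tractography is deliberately out of scope. When
cohorts are generated in fast mode (no per-subject tensors), the tracking
substrate is the noise-free control tensor field at the reference age —
the population limit of arithmetically averaging many control fields.
Tracking is deterministic streamline propagation: one seed per seed-voxel
centre, launched along ±e1; eigenvector lookup is nearest-voxel with sign
alignment to the previous direction (e1 is defined up to sign); a step of
0.5 mm (sub-voxel on the 1-mm grid) is accepted only if the new position
has FA ≥ 0.2 and the scalar product of consecutive sign-aligned
eigenvectors is ≥ 0.9; 2000 steps cap runaway paths. A streamline is kept
iff it enters the target; it then propagates through the target region and
stops on exit, so the collected substrate is identical when seed and
target are exchanged in a symmetric field. TFAS averages a subject's FA
over the substrate voxels at or above the floor; a tract whose voxels all
fall below the floor yields a missing value, which is distinct from the
structural error raised by an empty (untrackable) TOI.

Structure-level group comparisons select Student's t when Shapiro–Wilk
(α 0.05) accepts normality in both groups and Mann–Whitney U otherwise
(normality is not testable below n=3, where the t branch is used), with
BH-FDR across the 36 structures.

## Staging

Control reference: per-structure sample mean and SD (ddof 1) over control
baselines; zero control variance is a hard error naming the structure.
Scores are reported on a shifted scale, score = mean pattern z + 0.5, so
that the control average prints as 0.50 while the affectation threshold
μ − 0.47σ becomes 0.03; this reproduces both conventions simultaneously,
and a raw-z scale is a toggle. "Below the threshold" is strict: a subject
exactly at μ − 0.47σ is unaffected. The fixed 0.47 offset corresponds to a
nominal 68% control probability of remaining unaffected
(Φ(0.47) ≈ 0.6808); empirical specificities on finite cohorts will differ
— in particular, positively correlated structure z-values (here induced by
the global subject effect) shrink the spread of the pattern *mean* below 1
and push empirical specificity above the nominal value. The threshold is
fixed analytically and never re-tuned per cohort; an explicit calibration
mode was considered and rejected as under-specified. Missing structures
are dropped from a pattern mean (never imputed) with at least half of the
pattern's members required; the putamen's z enters pattern 1 unflipped.

The categorization rule is a pure function of the three affectation bits,
exhaustive and mutually exclusive over all 8 combinations: pattern 1
affectation is required for any step; CSα ignores pattern 3 (a subject with
patterns 1 and 3 affected but 2 spared is CSα); CSβ requires 1 and 2 but
not 3; CSχ requires all three. Severity (PSPRS-stage) summaries pool the
two most severe stages ("3+4"); longitudinal summaries report mean
baseline→follow-up pattern score changes for paired patients and the
control test–retest floor as mean ± SD over structures of the per-structure
mean |ΔFA|.

## Problem sizes and numerical tolerances

Default synthetic runs use the full 96×112×96 grid with 20 subjects per
group, which keeps a complete pipeline execution under a minute on one
CPU; Monte-Carlo calibration checks use 200 subjects per group and stage
recovery 50 per stage, computed on unsmoothed maps (smoothing rescales
structure-level signal and noise by the same local factor and leaves the
z-statistics essentially unchanged). Exact-inversion checks use 10⁻⁸
tolerances; Gaussian-peak and closed-form FA checks 10⁻³ relative or
better; determinism checks are bitwise.

## Known limitations

The atlas is geometric, not anatomical; TOI corridors are straight, so
tracking curvature behaviour is exercised only by synthetic bends. The
staging threshold's empirical specificity on synthetic controls
(≈ 80–90%) exceeds the nominal 68% because of the correlated subject
effect; both numbers are reported rather than reconciled. Real-data
ingestion accepts pre-normalized FA maps plus a manifest but has no
per-subject tensor input path yet, so the tract stage on real data
requires a precomputed structure table or synthetic substrate.
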