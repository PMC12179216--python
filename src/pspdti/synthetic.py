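"""Synthetic DTI cohorts with a staged white-matter lesion model.

The real imaging data behind the staging method (multi-site DTI of PSP
patients and controls) are not publicly deposited, so this module generates
everything downstream stages need: a toy atlas of 36 region/tract
structures grouped into three disease patterns, per-subject tensor fields
and diffusion-weighted volumes (or, in fast mode, FA maps directly), and
cohort tables with ground-truth stage, age, phenotype, severity stage, and
longitudinal pairs.

The generative model per subject and structure is

    FA = base + age_slope * (age - reference_age) + subject_effect
         + structure_effect + lesion_offset [+ retest_noise at follow-up]

with a voxelwise Gaussian noise term in fast mode and Rician noise on the
simulated diffusion signal in full mode. Lesion offsets are stage- and
pattern-dependent: a pattern-k structure is offset only for generated
stages >= k, deepening mildly with stage; the putamen is the one structure
whose FA *increases* in patients. Stage 0 denotes controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dti import DWIVolume, FAMap, TensorField
from .errors import ConfigurationError, ParameterError, ProtocolError, SizingError

DEFAULT_GRID = (96, 112, 96)

# Structure footprint, in voxels on the 1-mm grid. ROIs are cubes; TOIs are
# straight corridors along x with a seed slab at one end and a target slab at
# the other. Slots keep neighbouring structures far enough apart that an
# 8-mm-FWHM smoothing kernel does not mix their signals appreciably.
ROI_SIZE = 12
TOI_LENGTH = 24
TOI_CROSS = 7
TOI_END = 3
SLOT = (32, 18, 18)
MARGIN = 2


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


@dataclass
class StructureSpec:
    """One named region (ROI) or tract (TOI) of the staging atlas."""

    name: str
    kind: str  # "roi" | "toi"
    pattern: int  # 1 | 2 | 3
    expected_direction: str = "decrease"  # FA change in patients
    mask: np.ndarray | None = None  # ROI mask, or full TOI corridor
    seed_mask: np.ndarray | None = None
    target_mask: np.ndarray | None = None
    orientation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def validate(self, grid_shape: tuple[int, ...]) -> None:
        if self.kind not in ("roi", "toi"):
            raise ConfigurationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.pattern not in (1, 2, 3):
            raise ConfigurationError(f"{self.name}: pattern must be 1, 2, or 3")
        if self.mask is None or self.mask.shape != tuple(grid_shape):
            raise ConfigurationError(f"{self.name}: mask missing or off-grid")
        if not self.mask.any():
            raise ConfigurationError(f"{self.name}: empty mask")
        if self.kind == "toi":
            if self.seed_mask is None or self.target_mask is None:
                raise ConfigurationError(f"{self.name}: TOI needs seed and target masks")
            if (self.seed_mask & self.target_mask).any():
                raise ConfigurationError(f"{self.name}: seed and target masks overlap")
            if not (self.seed_mask.any() and self.target_mask.any()):
                raise ConfigurationError(f"{self.name}: empty seed or target mask")


@dataclass
class AtlasDefinition:
    """The full structure set with its pattern grouping."""

    grid_shape: tuple[int, ...]
    structures: list[StructureSpec]

    @property
    def pattern_assignment(self) -> dict[str, int]:
        return {s.name: s.pattern for s in self.structures}

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def pattern_members(self, pattern: int) -> list[str]:
        return [s.name for s in self.structures if s.pattern == pattern]

    def __getitem__(self, name: str) -> StructureSpec:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    def validate(self) -> None:
        for s in self.structures:
            s.validate(self.grid_shape)
        if len(set(self.names)) != len(self.structures):
            raise ConfigurationError("duplicate structure names in atlas")

    def label_volume(self) -> np.ndarray:
        """Integer label volume: structure i+1 over its mask/corridor;
        seed voxels of TOI i carry 1000+i+1, targets 2000+i+1."""
        labels = np.zeros(self.grid_shape, dtype=np.int32)
        for i, s in enumerate(self.structures):
            labels[s.mask] = i + 1
        for i, s in enumerate(self.structures):
            if s.kind == "toi":
                labels[s.seed_mask] = 1000 + i + 1
                labels[s.target_mask] = 2000 + i + 1
        return labels

    @property
    def structure_index(self) -> np.ndarray:
        """Flat int volume: 0 for background, i+1 over structure i.

        Cached; used to paint per-structure values with a single gather.
        """
        cached = getattr(self, "_structure_index", None)
        if cached is None:
            cached = np.zeros(self.grid_shape, dtype=np.int32)
            for i, s in enumerate(self.structures):
                cached[s.mask] = i + 1
            self._structure_index = cached
        return cached


# name, kind, pattern — order is the fixed column order of the structure
# table. The putamen is the single structure expected to show an FA increase
# in patients. Bilateral structures are pooled except the paired cerebral
# peduncles, which are kept as left/right to complete the eight early-phase
# parameters.
_STRUCTURES: list[tuple[str, str, int]] = [
    # pattern 1 — brainstem and basal ganglia (8)
    ("putamen", "roi", 1),
    ("globus_pallidus", "roi", 1),
    ("pontine_tegmentum", "roi", 1),
    ("medial_lemniscus", "toi", 1),
    ("nigrostriatal_tract", "toi", 1),
    ("cerebral_peduncle_left", "toi", 1),
    ("cerebral_peduncle_right", "toi", 1),
    ("subthalamopallidal_tract", "toi", 1),
    # pattern 2 — basal ganglia, diencephalon, frontal WM, cerebellum (19)
    ("caudate_nucleus", "roi", 2),
    ("thalamocortical_radiation_anterior", "toi", 2),
    ("thalamocortical_radiation_posterior", "toi", 2),
    ("fronto_orbital_wm", "roi", 2),
    ("prefrontal_wm", "roi", 2),
    ("premotor_wm", "roi", 2),
    ("precentral_wm", "roi", 2),
    ("fronto_occipital_fascicle", "toi", 2),
    ("uncinate_fascicle", "toi", 2),
    ("corpus_callosum_area_i", "roi", 2),
    ("corpus_callosum_area_ii", "roi", 2),
    ("corpus_callosum_area_iii", "roi", 2),
    ("internal_capsule_anterior_limb", "roi", 2),
    ("corticostriatal_tract", "toi", 2),
    ("cerebellar_wm", "roi", 2),
    ("dentate_nucleus", "roi", 2),
    ("superior_cerebellar_peduncle", "toi", 2),
    ("dentatorubrothalamic_tract", "toi", 2),
    ("corticospinal_tract", "toi", 2),
    # pattern 3 — cerebral cortex and cortical WM tracts (9)
    ("parietal_wm", "roi", 3),
    ("temporal_wm", "roi", 3),
    ("occipital_wm", "roi", 3),
    ("inferior_longitudinal_fascicle", "toi", 3),
    ("internal_capsule_posterior_limb", "roi", 3),
    ("corpus_callosum_area_iv", "roi", 3),
    ("corpus_callosum_area_v", "roi", 3),
    ("fornix", "toi", 3),
    ("cingulum_bundle", "toi", 3),
]


def make_default_atlas(grid_shape: Sequence[int] = DEFAULT_GRID) -> AtlasDefinition:
    """Build the 36-structure toy atlas on the given 1-mm grid.

    Structures are laid out on a slot lattice so no two structures overlap;
    each ROI is a cube, each TOI a straight corridor along x. Raises
    :class:`SizingError` naming the first structure that does not fit.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3:
        raise SizingError("grid must be three-dimensional")
    n_slots_axis = [max(0, (g - 2 * MARGIN) // s) for g, s in zip(grid_shape, SLOT)]
    capacity = int(np.prod(n_slots_axis))

    structures: list[StructureSpec] = []
    for idx, (name, kind, pattern) in enumerate(_STRUCTURES):
        if idx >= capacity:
            raise SizingError(
                f"grid {grid_shape} holds only {capacity} structure slots; "
                f"{name!r} does not fit"
            )
        iz = idx % n_slots_axis[2]
        iy = (idx // n_slots_axis[2]) % n_slots_axis[1]
        ix = idx // (n_slots_axis[2] * n_slots_axis[1])
        origin = [MARGIN + i * s for i, s in zip((ix, iy, iz), SLOT)]
        center = [o + s // 2 for o, s in zip(origin, SLOT)]
        direction = "increase" if name == "putamen" else "decrease"

        mask = np.zeros(grid_shape, dtype=bool)
        if kind == "roi":
            sl = tuple(slice(c - ROI_SIZE // 2, c - ROI_SIZE // 2 + ROI_SIZE) for c in center)
            mask[sl] = True
            spec = StructureSpec(
                name, kind, pattern, direction, mask,
                orientation=np.array([0.0, 0.0, 1.0]),
            )
        else:
            x0 = origin[0] + (SLOT[0] - TOI_LENGTH) // 2
            cross = tuple(
                slice(c - TOI_CROSS // 2, c - TOI_CROSS // 2 + TOI_CROSS) for c in center[1:]
            )
            mask[(slice(x0, x0 + TOI_LENGTH),) + cross] = True
            seed = np.zeros(grid_shape, dtype=bool)
            seed[(slice(x0, x0 + TOI_END),) + cross] = True
            target = np.zeros(grid_shape, dtype=bool)
            target[(slice(x0 + TOI_LENGTH - TOI_END, x0 + TOI_LENGTH),) + cross] = True
            spec = StructureSpec(
                name, kind, pattern, direction, mask, seed, target,
                orientation=np.array([1.0, 0.0, 0.0]),
            )
        structures.append(spec)

    atlas = AtlasDefinition(grid_shape=grid_shape, structures=structures)
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# Lesion model
# ---------------------------------------------------------------------------


@dataclass
class LesionModel:
    """Stage- and pattern-dependent FA alterations plus nuisance variation.

    ``stage_offsets[pattern]`` gives the signed FA offset applied to that
    pattern's structures at generated stages 1, 2, 3 (zero until the
    pattern's own stage is reached, then deepening mildly so severity
    summaries are monotone). Units are FA throughout; ``age_slope`` is FA
    per year and applies globally.
    """

    stage_offsets: Mapping[int, tuple[float, float, float]] = field(
        default_factory=lambda: {
            1: (-0.025, -0.028, -0.031),
            2: (0.0, -0.025, -0.028),
            3: (0.0, 0.0, -0.022),
        }
    )
    putamen_increase: float = 0.02
    subject_sd: float = 0.004
    structure_sd: float = 0.015
    voxel_noise_sd: float = 0.02
    retest_sd: float = 0.007
    age_slope: float = -0.001
    reference_age: float = 70.0
    background_fa: float = 0.10
    roi_fa: float = 0.45
    toi_fa: float = 0.55
    mean_diffusivity: float = 0.7e-3  # mm^2/s

    def offset(self, structure: StructureSpec, stage: int) -> float:
        """Lesion FA offset for one structure at a generated stage."""
        if stage == 0:
            return 0.0
        if stage not in (1, 2, 3):
            raise ParameterError(f"stage must be 0..3, got {stage}")
        if structure.expected_direction == "increase":
            return self.putamen_increase
        return self.stage_offsets[structure.pattern][stage - 1]

    def base_fa(self, structure: StructureSpec) -> float:
        return self.toi_fa if structure.kind == "toi" else self.roi_fa

    @property
    def control_structure_scale(self) -> float:
        """Between-subject SD of a structure's mean FA in controls."""
        return float(np.hypot(self.subject_sd, self.structure_sd))

    def expected_pattern_shift(self, atlas: AtlasDefinition, pattern: int, stage: int) -> float:
        """Analytic z-shift of a pattern score at a generated stage.

        Mean over the pattern's structures of offset / control SD; the
        putamen's positive offset enters as-is (no sign flip), diluting the
        pattern-1 shift exactly as in the analysis.
        """
        sigma = self.control_structure_scale
        offs = [self.offset(s, stage) for s in atlas.structures if s.pattern == pattern]
        return float(np.mean(offs) / sigma)


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """Ground-truth bookkeeping for one generated subject."""

    subject_id: str
    group: str  # "control" | "psp"
    phenotype: str  # "PSP-RS" | "PSP-P" | "none"
    true_stage: int  # 0 for controls
    age: float
    sex: str  # "m" | "f"
    psprs_stage: int | None = None
    has_followup: bool = False
    interval_months: float | None = None

    def __post_init__(self) -> None:
        if (self.true_stage == 0) != (self.group == "control"):
            raise ConfigurationError("true_stage 0 exactly for controls")


def _subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), subject_index, stream]))


def _structure_targets(
    atlas: AtlasDefinition,
    lesions: LesionModel,
    subject: SubjectRecord,
    seed: int,
    subject_index: int,
    timepoint: str,
) -> tuple[np.ndarray, float]:
    """Per-structure target mean FA for one scan, plus background level.

    Subject- and structure-level biological effects are drawn once per
    subject (shared across timepoints); test-retest noise is added to the
    follow-up scan only. Patients advance one generated stage at follow-up.
    """
    bio = _subject_rng(seed, subject_index, 0xB10)
    subject_effect = bio.normal(0.0, lesions.subject_sd) if lesions.subject_sd > 0 else 0.0
    structure_effects = (
        bio.normal(0.0, lesions.structure_sd, size=len(atlas.structures))
        if lesions.structure_sd > 0
        else np.zeros(len(atlas.structures))
    )
    age_term = lesions.age_slope * (subject.age - lesions.reference_age)

    stage = subject.true_stage
    retest = np.zeros(len(atlas.structures))
    if timepoint == "followup":
        if stage > 0:
            stage = min(stage + 1, 3)
        if lesions.retest_sd > 0:
            retest = _subject_rng(seed, subject_index, 0xFE7).normal(
                0.0, lesions.retest_sd, size=len(atlas.structures)
            )

    targets = np.array(
        [
            lesions.base_fa(s)
            + age_term
            + subject_effect
            + structure_effects[i]
            + lesions.offset(s, stage)
            + retest[i]
            for i, s in enumerate(atlas.structures)
        ]
    )
    background = lesions.background_fa + age_term
    return targets, background


def _paint_fa(atlas: AtlasDefinition, targets: np.ndarray, background: float) -> np.ndarray:
    values = np.concatenate([[background], targets])
    return values[atlas.structure_index]


def simulate_fa_map(
    atlas: AtlasDefinition,
    subject: SubjectRecord,
    lesions: LesionModel,
    seed: int,
    subject_index: int = 0,
    timepoint: str = "baseline",
) -> FAMap:
    """Fast-mode scan: write the FA map directly with Gaussian voxel noise."""
    targets, background = _structure_targets(
        atlas, lesions, subject, seed, subject_index, timepoint
    )
    fa = _paint_fa(atlas, targets, background)
    if lesions.voxel_noise_sd > 0:
        noise_rng = _subject_rng(
            seed, subject_index, 0x501 if timepoint == "baseline" else 0x502
        )
        fa = fa + noise_rng.normal(0.0, lesions.voxel_noise_sd, size=fa.shape)
    return FAMap(
        fa=np.clip(fa, 0.0, 1.0).astype(np.float32),
        subject_id=subject.subject_id,
        age=subject.age,
    )


def _axial_alpha(fa: np.ndarray) -> np.ndarray:
    """Shape parameter of an axially symmetric tensor with the given FA.

    With eigenvalues MD*(1+2a), MD*(1-a), MD*(1-a) the fractional
    anisotropy is 3a / sqrt(3 + 6a^2); this inverts that relation.
    """
    f = np.clip(np.asarray(fa, dtype=np.float64), 0.0, 0.999999)
    return f * np.sqrt(3.0 / (9.0 - 6.0 * f**2))


def tensors_from_fa(
    fa_target: np.ndarray, orientation: np.ndarray, mean_diffusivity: float
) -> np.ndarray:
    """Axially symmetric tensors with prescribed FA, MD, and axis field.

    ``orientation`` is (..., 3) unit vectors. Mean diffusivity is preserved
    for every FA, so lesion injection via FA change is an eigenvalue
    adjustment at constant trace.
    """
    alpha = _axial_alpha(fa_target)[..., None, None]
    n = np.asarray(orientation, dtype=np.float64)
    outer = n[..., :, None] * n[..., None, :]
    iso = np.eye(3)
    lam_perp = mean_diffusivity * (1.0 - alpha)
    lam_diff = mean_diffusivity * 3.0 * alpha  # lambda1 - lambda_perp
    return lam_perp * iso + lam_diff * outer


def simulate_tensor_field(
    atlas: AtlasDefinition,
    subject: SubjectRecord,
    lesions: LesionModel,
    seed: int,
    subject_index: int = 0,
    timepoint: str = "baseline",
) -> TensorField:
    """Noise-free (at voxel level) per-subject tensor field.

    Background voxels are near-isotropic; ROI voxels are anisotropic along
    z; TOI corridors are axially symmetric along the corridor axis. Lesions
    and biological variability perturb the eigenvalues at constant mean
    diffusivity. Voxel-level noise enters only via the simulated diffusion
    signal (:func:`simulate_dwi`), keeping this field exactly invertible.
    """
    targets, background = _structure_targets(
        atlas, lesions, subject, seed, subject_index, timepoint
    )
    fa_target = _paint_fa(atlas, targets, background)
    orientation = np.zeros(atlas.grid_shape + (3,))
    orientation[..., 2] = 1.0
    for s in atlas.structures:
        orientation[s.mask] = s.orientation / np.linalg.norm(s.orientation)
    tensor = tensors_from_fa(fa_target, orientation, lesions.mean_diffusivity)
    # spectral data are known analytically; avoid a full eigendecomposition
    alpha = _axial_alpha(fa_target)
    lam1 = lesions.mean_diffusivity * (1.0 + 2.0 * alpha)
    lam_perp = lesions.mean_diffusivity * (1.0 - alpha)
    evals = np.stack([lam1, lam_perp, lam_perp], axis=-1)
    return TensorField(
        tensor=tensor,
        evals=evals,
        e1=orientation,
        valid=np.ones(atlas.grid_shape, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Diffusion-weighted signal
# ---------------------------------------------------------------------------


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the hemisphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = i / n  # upper hemisphere only: antipodal directions are equivalent
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def protocol_two_shell() -> tuple[np.ndarray, np.ndarray]:
    """70-volume two-shell scheme: 10 b=0, 30 b=700, 30 b=1000 s/mm^2."""
    dirs = _fibonacci_directions(30)
    bvals = np.concatenate([np.zeros(10), np.full(30, 700.0), np.full(30, 1000.0)])
    bvecs = np.concatenate([np.zeros((10, 3)), dirs, dirs])
    return bvals, bvecs

def protocol_single_shell() -> tuple[np.ndarray, np.ndarray]:
    """52-volume single-shell scheme: 4 b=0, 48 b=1000 s/mm^2."""
    dirs = _fibonacci_directions(48)
    bvals = np.concatenate([np.zeros(4), np.full(48, 1000.0)])
    bvecs = np.concatenate([np.zeros((4, 3)), dirs])
    return bvals, bvecs


def simulate_dwi(
    tensors: TensorField,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    snr_b0: float = 0.0,
    seed: int = 0,
    s0: float = 1.0,
) -> DWIVolume:
    """Monoexponential diffusion signal S = S0 exp(-b g'Dg) with Rician noise.

    ``snr_b0`` is the b=0 signal-to-noise ratio; 0 (or negative) disables
    noise. Rician noise adds independent Gaussians of SD S0/snr to the real
    and an empty imaginary channel and takes the magnitude.
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    from .dti import _check_scheme  # shared validation

    if not np.any(bvals == 0):
        raise ProtocolError("scheme needs at least one b=0 volume")
    _check_scheme(bvals, bvecs)

    quad = np.einsum("...ij,ni,nj->...n", tensors.tensor, bvecs, bvecs)
    signal = s0 * np.exp(-bvals * quad)
    if snr_b0 and snr_b0 > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD11]))
        sigma = s0 / snr_b0
        real = signal + rng.normal(0.0, sigma, size=signal.shape)
        imag = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.hypot(real, imag)
    return DWIVolume(signal=signal, bvals=bvals, bvecs=bvecs, affine=tensors.affine)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """A generated cohort: atlas, ground-truth records, and scans."""

    atlas: AtlasDefinition
    lesions: LesionModel
    records: list[SubjectRecord]
    fa_maps: dict[tuple[str, str], FAMap]  # (subject_id, timepoint) -> map
    seed: int

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            timepoints = ["baseline"] + (["followup"] if r.has_followup else [])
            for tp in timepoints:
                rows.append(
                    {
                        "subject_id": r.subject_id,
                        "timepoint": tp,
                        "group": r.group,
                        "phenotype": r.phenotype,
                        "true_stage": r.true_stage,
                        "age": r.age,
                        "sex": r.sex,
                        "psprs_stage": r.psprs_stage,
                        "interval_months": r.interval_months if tp == "followup" else None,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def control_ids(self) -> list[str]:
        return [r.subject_id for r in self.records if r.group == "control"]

    @property
    def patient_ids(self) -> list[str]:
        return [r.subject_id for r in self.records if r.group == "psp"]

    def control_template_tensors(self) -> TensorField:
        """Noise-free control tensor field at the cohort's reference age.

        This is the population limit of arithmetically averaging many
        control tensor fields and serves as the tracking substrate when
        scans were generated in fast (FA-only) mode.
        """
        template = SubjectRecord(
            subject_id="__template__",
            group="control",
            phenotype="none",
            true_stage=0,
            age=self.lesions.reference_age,
            sex="f",
        )
        quiet = LesionModel(
            stage_offsets=self.lesions.stage_offsets,
            putamen_increase=self.lesions.putamen_increase,
            subject_sd=0.0,
            structure_sd=0.0,
            voxel_noise_sd=0.0,
            retest_sd=0.0,
            age_slope=self.lesions.age_slope,
            reference_age=self.lesions.reference_age,
            background_fa=self.lesions.background_fa,
            roi_fa=self.lesions.roi_fa,
            toi_fa=self.lesions.toi_fa,
            mean_diffusivity=self.lesions.mean_diffusivity,
        )
        return simulate_tensor_field(self.atlas, template, quiet, seed=self.seed)


def simulate_cohort(
    n_controls: int,
    stage_counts: Mapping[int, int],
    lesions: LesionModel | None = None,
    age_range: tuple[float, float] = (50.0, 90.0),
    followup: float = 0.0,
    seed: int = 0,
    atlas: AtlasDefinition | None = None,
    grid_shape: Sequence[int] = DEFAULT_GRID,
    rs_fraction: float = 0.7,
) -> SyntheticCohort:
    """Generate a control + patient cohort with fast-mode FA scans.

    ``stage_counts`` maps generated stage (1..3) to patient count. A
    ``followup`` fraction of each group receives a second scan: patients
    progress one stage, controls get pure test-retest noise. All randomness
    derives from ``seed``; re-running with the same arguments reproduces
    bit-identical maps and manifest.
    """
    if lesions is None:
        lesions = LesionModel()
    if atlas is None:
        atlas = make_default_atlas(grid_shape)
    if n_controls < 0 or any(c < 0 for c in stage_counts.values()):
        raise ConfigurationError("subject counts must be non-negative")
    n_patients = sum(stage_counts.values())
    if n_controls + n_patients == 0:
        raise ConfigurationError("cohort is empty: no controls and no patients")
    if not 0.0 <= followup <= 1.0:
        raise ParameterError("followup must be a fraction in [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    records: list[SubjectRecord] = []

    def draw_common() -> tuple[float, str]:
        age = float(rng.uniform(*age_range))
        sex = "m" if rng.random() < 0.5 else "f"
        return age, sex

    for i in range(n_controls):
        age, sex = draw_common()
        records.append(
            SubjectRecord(f"C{i:03d}", "control", "none", 0, age, sex)
        )
    pi = 0
    for stage in sorted(stage_counts):
        if stage not in (1, 2, 3):
            raise ConfigurationError(f"patient stages must be 1..3, got {stage}")
        for _ in range(stage_counts[stage]):
            age, sex = draw_common()
            phenotype = "PSP-RS" if rng.random() < rs_fraction else "PSP-P"
            # clinical severity tracks the generated stage; a fifth of
            # advanced patients carry the pooled top severity stage
            psprs = stage if not (stage == 3 and rng.random() < 0.2) else 4
            records.append(
                SubjectRecord(f"P{pi:03d}", "psp", phenotype, stage, age, sex, psprs_stage=psprs)
            )
            pi += 1

    for group in ("control", "psp"):
        members = [r for r in records if r.group == group]
        n_fu = int(round(followup * len(members)))
        if n_fu > 0:
            chosen = rng.choice(len(members), size=n_fu, replace=False)
            for j in sorted(chosen):
                members[j].has_followup = True
                members[j].interval_months = float(rng.uniform(11.0, 35.0))

    fa_maps: dict[tuple[str, str], FAMap] = {}
    for idx, r in enumerate(records):
        fa_maps[(r.subject_id, "baseline")] = simulate_fa_map(
            atlas, r, lesions, seed, subject_index=idx, timepoint="baseline"
        )
        if r.has_followup:
            fa_maps[(r.subject_id, "followup")] = simulate_fa_map(
                atlas, r, lesions, seed, subject_index=idx, timepoint="followup"
            )
    return SyntheticCohort(atlas=atlas, lesions=lesions, records=records, fa_maps=fa_maps, seed=seed)
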