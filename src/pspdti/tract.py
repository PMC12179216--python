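"""Deterministic streamline tractography and tract-wise FA statistics.

Tracts of interest (TOIs) are identified on a control-average tensor field
with a seed-to-target approach: streamlines are launched from every
seed-voxel center along both signs of the principal eigenvector and
propagated with sub-voxel steps along the (sign-aligned) eigenvector of the
current voxel. A step is accepted only while FA stays at or above the floor
and consecutive eigenvectors keep a scalar product of at least the
curvature threshold (default 0.9). Streamlines that enter the target region
define the TOI; the voxels they traverse are the substrate over which each
subject's FA is averaged (tract-wise FA statistics, TFAS).

Structure-level group statistics choose Student's t-test when both groups
pass a Shapiro-Wilk normality check and the Mann-Whitney U test otherwise,
with Benjamini-Hochberg correction across structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dti import FAMap, TensorField
from .errors import (
    ConfigurationError,
    SampleSizeError,
    StructuralError,
)
from .synthetic import AtlasDefinition
from .wbss import benjamini_hochberg

logger = logging.getLogger("pspdti")

DEFAULT_DOT_THRESHOLD = 0.9
DEFAULT_FA_FLOOR = 0.2
DEFAULT_STEP_MM = 0.5
DEFAULT_MAX_STEPS = 2000


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) voxel-space coordinates (1-mm grid)
    seed_point: np.ndarray
    terminated_reason: str  # target_reached | low_fa | angle | boundary | max_length


@dataclass
class TractOfInterest:
    structure_name: str
    streamlines: list[Streamline] = field(default_factory=list)
    underlying_voxels: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))

    @property
    def voxel_mask(self) -> np.ndarray | None:
        return None if self.underlying_voxels.size == 0 else self.underlying_voxels


def average_control_tensors(tensor_fields: Sequence[TensorField]) -> TensorField:
    """Component-wise arithmetic mean of control tensors, re-decomposed."""
    if len(tensor_fields) == 0:
        raise ConfigurationError("cannot average an empty list of tensor fields")
    shape = tensor_fields[0].tensor.shape
    if any(f.tensor.shape != shape for f in tensor_fields):
        raise ConfigurationError("tensor fields are not on a common grid")
    mean = np.mean([f.tensor for f in tensor_fields], axis=0)
    valid = np.all([f.valid for f in tensor_fields], axis=0)
    return TensorField.from_tensors(mean, valid=valid, affine=tensor_fields[0].affine)


def _inside(voxel: np.ndarray, shape: tuple[int, ...]) -> bool:
    return bool(np.all(voxel >= 0) and np.all(voxel < shape))


def _track_one(
    pos: np.ndarray,
    direction: np.ndarray,
    fa: np.ndarray,
    e1: np.ndarray,
    target: np.ndarray,
    dot_threshold: float,
    fa_floor: float,
    step: float,
    max_steps: int,
) -> Streamline:
    shape = fa.shape
    points = [pos.copy()]
    prev_dir = direction
    hit = False  # once inside the target, propagate through it and stop on exit
    reason = "max_length"
    for _ in range(max_steps):
        new_pos = points[-1] + step * prev_dir
        voxel = np.round(new_pos).astype(int)
        if not _inside(voxel, shape):
            reason = "target_reached" if hit else "boundary"
            break
        if fa[tuple(voxel)] < fa_floor:
            reason = "target_reached" if hit else "low_fa"
            break
        new_dir = e1[tuple(voxel)]
        if float(new_dir @ prev_dir) < 0:
            new_dir = -new_dir  # antipodal symmetry of the eigenvector
        if float(new_dir @ prev_dir) < dot_threshold:
            reason = "target_reached" if hit else "angle"
            break
        in_target = bool(target[tuple(voxel)])
        if hit and not in_target:
            reason = "target_reached"  # streamline ends in the target region
            break
        points.append(new_pos)
        hit = hit or in_target
        prev_dir = new_dir
    else:
        if hit:
            reason = "target_reached"
    return Streamline(points=np.array(points), seed_point=points[0], terminated_reason=reason)


def track_toi(
    tensors: TensorField,
    seed_mask: np.ndarray,
    target_mask: np.ndarray,
    dot_threshold: float = DEFAULT_DOT_THRESHOLD,
    fa_floor: float = DEFAULT_FA_FLOOR,
    step_mm: float = DEFAULT_STEP_MM,
    max_steps: int = DEFAULT_MAX_STEPS,
    structure_name: str = "",
) -> TractOfInterest:
    """Seed-to-target deterministic streamline tracking.

    One streamline pair (along +e1 and -e1) is launched from every
    seed-voxel center; eigenvector lookup is nearest-voxel with sign
    alignment to the previous direction. Only streamlines that enter the
    target region are kept; their traversed voxels form the TOI substrate.
    """
    if not seed_mask.any() or not target_mask.any():
        raise ConfigurationError(f"TOI {structure_name!r}: seed and target must be non-empty")
    if (seed_mask & target_mask).any():
        raise ConfigurationError(f"TOI {structure_name!r}: seed and target overlap")

    from .dti import fa_from_eigenvalues

    fa = fa_from_eigenvalues(tensors.evals)
    fa = np.where(tensors.valid, fa, 0.0)

    kept: list[Streamline] = []
    all_streamlines: list[Streamline] = []
    voxels: set[tuple[int, int, int]] = set()
    for voxel in np.argwhere(seed_mask):
        pos = voxel.astype(float)
        if fa[tuple(voxel)] < fa_floor:
            sl = Streamline(points=pos[None, :], seed_point=pos, terminated_reason="low_fa")
            all_streamlines.append(sl)
            continue
        e = tensors.e1[tuple(voxel)]
        for sign in (1.0, -1.0):
            sl = _track_one(
                pos, sign * e, fa, tensors.e1, target_mask,
                dot_threshold, fa_floor, step_mm, max_steps,
            )
            all_streamlines.append(sl)
            if sl.terminated_reason == "target_reached":
                kept.append(sl)
                for p in sl.points:
                    voxels.add(tuple(int(v) for v in np.round(p)))

    underlying = (
        np.array(sorted(voxels), dtype=int) if voxels else np.zeros((0, 3), dtype=int)
    )
    return TractOfInterest(
        structure_name=structure_name, streamlines=kept, underlying_voxels=underlying
    )


def _floored_mean(values: np.ndarray, fa_floor: float) -> float:
    passing = values[values >= fa_floor]
    return float(passing.mean()) if passing.size else float("nan")


def tfas(toi: TractOfInterest, subject_fa: FAMap, fa_floor: float = DEFAULT_FA_FLOOR) -> float:
    """Tract-wise FA: mean subject FA over the TOI's underlying voxels.

    Voxels below the FA floor are excluded; NaN marks a tract with no
    voxel passing the floor (a missing, not erroneous, value).
    """
    if toi.underlying_voxels.shape[0] == 0:
        raise StructuralError(f"TOI {toi.structure_name!r} has no underlying voxels")
    v = toi.underlying_voxels
    values = subject_fa.fa[v[:, 0], v[:, 1], v[:, 2]]
    return _floored_mean(np.asarray(values, dtype=float), fa_floor)


def roi_mean_fa(
    roi_mask: np.ndarray, subject_fa: FAMap, fa_floor: float = DEFAULT_FA_FLOOR
) -> float:
    """Mean subject FA over an ROI mask, excluding sub-floor voxels."""
    if not roi_mask.any():
        raise ConfigurationError("ROI mask is empty")
    return _floored_mean(subject_fa.fa[roi_mask].astype(float), fa_floor)


def build_structure_table(
    atlas: AtlasDefinition,
    tois: Mapping[str, TractOfInterest],
    subject_maps: Mapping[tuple[str, str], FAMap],
    fa_floor: float = DEFAULT_FA_FLOOR,
) -> pd.DataFrame:
    """Per-subject-timepoint mean FA for every atlas structure.

    Rows are indexed by (subject_id, timepoint); columns follow the fixed
    atlas order. ROI structures average over their mask, TOI structures
    over their tracked substrate. NaN cells mark structures fully below
    the FA floor for that scan.
    """
    for s in atlas.structures:
        if s.kind == "toi" and s.name not in tois:
            raise ConfigurationError(f"no tract of interest supplied for structure {s.name!r}")

    # flat substrate indices per structure, computed once for the whole table
    grid = atlas.grid_shape
    flat_idx = []
    for s in atlas.structures:
        if s.kind == "roi":
            if not s.mask.any():
                raise ConfigurationError(f"ROI mask for {s.name!r} is empty")
            flat_idx.append(np.flatnonzero(s.mask.ravel()))
        else:
            toi = tois[s.name]
            if toi.underlying_voxels.shape[0] == 0:
                raise StructuralError(f"TOI {s.name!r} has no underlying voxels")
            v = toi.underlying_voxels
            flat_idx.append(np.ravel_multi_index((v[:, 0], v[:, 1], v[:, 2]), grid))

    rows = {}
    for key, fa_map in subject_maps.items():
        flat = fa_map.fa.ravel()
        values = [_floored_mean(flat[idx].astype(float), fa_floor) for idx in flat_idx]
        rows[key] = values
        n_missing = int(np.sum(np.isnan(values)))
        if n_missing:
            logger.warning("scan %s: %d structure(s) fully below FA floor", key, n_missing)

    index = pd.MultiIndex.from_tuples(rows.keys(), names=["subject_id", "timepoint"])
    return pd.DataFrame(list(rows.values()), index=index, columns=atlas.names)


def group_compare_structures(
    table: pd.DataFrame,
    group1_ids: Sequence[str],
    group2_ids: Sequence[str],
    alpha: float = 0.05,
    timepoint: str = "baseline",
) -> pd.DataFrame:
    """Structure-wise two-group comparison with test selection by normality.

    Shapiro-Wilk (alpha 0.05) on each group decides per structure: both
    normal -> pooled two-sample t-test; otherwise Mann-Whitney U. P-values
    are BH-FDR corrected across structures. Returns a frame with columns
    test, statistic, p, p_fdr, significant.
    """
    sub = table.xs(timepoint, level="timepoint")
    g1 = sub.loc[sub.index.intersection(group1_ids)]
    g2 = sub.loc[sub.index.intersection(group2_ids)]
    if len(g1) < 2 or len(g2) < 2:
        raise SampleSizeError(f"need >= 2 subjects per group, got {len(g1)} and {len(g2)}")

    results = []
    for col in table.columns:
        a = g1[col].dropna().to_numpy()
        b = g2[col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise SampleSizeError(f"structure {col!r}: fewer than 2 non-missing per group")
        normal = True
        if len(a) >= 3 and len(b) >= 3:
            normal = (
                stats.shapiro(a).pvalue >= 0.05 and stats.shapiro(b).pvalue >= 0.05
            )
        if normal:
            res = stats.ttest_ind(a, b, equal_var=True)
            test = "student_t"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann_whitney"
            logger.info("structure %s: non-normal distribution, Mann-Whitney branch", col)
        results.append({"structure": col, "test": test, "statistic": float(res.statistic), "p": float(res.pvalue)})

    frame = pd.DataFrame(results).set_index("structure")
    frame["p_fdr_pass"] = benjamini_hochberg(frame["p"].to_numpy(), alpha=alpha)
    frame["significant"] = frame["p_fdr_pass"]
    return frame


def track_atlas_tois(
    tensors: TensorField,
    atlas: AtlasDefinition,
    dot_threshold: float = DEFAULT_DOT_THRESHOLD,
    fa_floor: float = DEFAULT_FA_FLOOR,
    step_mm: float = DEFAULT_STEP_MM,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> dict[str, TractOfInterest]:
    """Track every TOI structure of the atlas on one tensor field."""
    tois = {}
    for s in atlas.structures:
        if s.kind != "toi":
            continue
        tois[s.name] = track_toi(
            tensors, s.seed_mask, s.target_mask,
            dot_threshold=dot_threshold, fa_floor=fa_floor,
            step_mm=step_mm, max_steps=max_steps, structure_name=s.name,
        )
    return tois
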