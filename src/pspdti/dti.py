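"""Diffusion tensor estimation and fractional anisotropy processing.

This module owns the voxelwise tensor model: log-linear least-squares
fitting of the diffusion tensor from diffusion-weighted volumes, fractional
anisotropy (FA) computation, Gaussian smoothing of FA maps, voxelwise age
correction against a control group, and the FA analysis mask.

All volumes live on a 1-mm isotropic grid in a shared (synthetic standard)
space; spatial normalization of real data is expected to happen upstream and
is represented here only by the identity transform carried in each map's
affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateDesignError, ParameterError, ProtocolError, SampleSizeError

#: Conversion between a Gaussian kernel's full width at half maximum and its
#: standard deviation: FWHM = 2 * sqrt(2 * ln 2) * sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Eigenvalues below this are clamped after fitting (units mm^2/s).
EIGENVALUE_FLOOR = 1e-12


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class DWIVolume:
    """A diffusion-weighted acquisition: 4-D signal plus gradient scheme.

    ``signal`` is indexed (x, y, z, volume); ``bvals`` (s/mm^2) and ``bvecs``
    (unit direction per volume) describe the scheme, one entry per volume.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: float = 1.0
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.signal.ndim != 4:
            raise ProtocolError("DWI signal must be a 4-D (x, y, z, volume) array")
        n_vol = self.signal.shape[-1]
        if self.bvals.shape != (n_vol,) or self.bvecs.shape != (n_vol, 3):
            raise ProtocolError(
                "need exactly one bval and one bvec per volume "
                f"(got {self.bvals.shape}, {self.bvecs.shape} for {n_vol} volumes)"
            )
        if not np.any(self.bvals == 0):
            raise ProtocolError("acquisition must include at least one b=0 volume")
        if self.voxel_size <= 0:
            raise ParameterError("voxel_size must be positive")


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors with their spectral data.

    ``evals`` are sorted descending (lambda1 >= lambda2 >= lambda3) and
    clamped to a small positive floor; ``e1`` is the unit principal
    eigenvector (defined up to sign). ``valid`` flags voxels with a usable
    fit (positive b0 signal).
    """

    tensor: np.ndarray  # (..., 3, 3)
    evals: np.ndarray  # (..., 3) descending
    e1: np.ndarray  # (..., 3)
    valid: np.ndarray  # (...,) bool
    affine: np.ndarray = field(default_factory=_default_affine)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.tensor.shape[:-2]

    @classmethod
    def from_tensors(
        cls, tensor: np.ndarray, valid: np.ndarray | None = None, affine: np.ndarray | None = None
    ) -> "TensorField":
        """Eigen-decompose a (..., 3, 3) symmetric tensor array."""
        tensor = np.asarray(tensor, dtype=np.float64)
        evals, evecs = np.linalg.eigh(tensor)  # ascending
        evals = evals[..., ::-1]
        e1 = evecs[..., :, -1]
        evals = np.clip(evals, EIGENVALUE_FLOOR, None)
        if valid is None:
            valid = np.ones(tensor.shape[:-2], dtype=bool)
        return cls(
            tensor=tensor,
            evals=evals,
            e1=e1,
            valid=np.asarray(valid, dtype=bool),
            affine=np.eye(4) if affine is None else affine,
        )


@dataclass
class FAMap:
    """A 3-D fractional anisotropy volume with subject metadata."""

    fa: np.ndarray
    subject_id: str = ""
    age: float | None = None
    smoothed: bool = False
    age_corrected: bool = False
    affine: np.ndarray = field(default_factory=_default_affine)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.fa.shape


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows of -b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz].

    With tensor components packed as d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) the
    model reads log(S/S0) = B @ d.
    """
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)
    cols = np.stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    return -b[:, None] * cols


def _check_scheme(bvals: np.ndarray, bvecs: np.ndarray) -> None:
    dwi = bvals > 0
    if int(dwi.sum()) < 6:
        raise ProtocolError("tensor fit needs at least 6 diffusion-weighted directions")
    rank = np.linalg.matrix_rank(design_matrix(bvals[dwi], bvecs[dwi]))
    if rank < 6:
        raise ProtocolError(
            "gradient directions are collinear/degenerate: design rank "
            f"{rank} < 6"
        )


def fit_tensor(dwi: DWIVolume) -> TensorField:
    """Unweighted log-linear least-squares tensor fit.

    S0 is taken as the mean of the b=0 volumes; the six unique tensor
    components solve log(S/S0) = -b g'Dg in the least-squares sense at every
    voxel. Voxels with non-positive b0 signal are flagged invalid and given
    an isotropic floor tensor. Negative eigenvalues are clamped.
    """
    _check_scheme(dwi.bvals, dwi.bvecs)
    b0 = dwi.signal[..., dwi.bvals == 0].mean(axis=-1)
    valid = b0 > 0
    safe_b0 = np.where(valid, b0, 1.0)

    B = design_matrix(dwi.bvals, dwi.bvecs)
    pinv = np.linalg.pinv(B)  # (6, n_vol)
    log_ratio = np.log(np.clip(dwi.signal, 1e-300, None) / safe_b0[..., None])
    d6 = log_ratio @ pinv.T  # (..., 6)

    tensor = np.empty(d6.shape[:-1] + (3, 3))
    tensor[..., 0, 0] = d6[..., 0]
    tensor[..., 1, 1] = d6[..., 1]
    tensor[..., 2, 2] = d6[..., 2]
    tensor[..., 0, 1] = tensor[..., 1, 0] = d6[..., 3]
    tensor[..., 0, 2] = tensor[..., 2, 0] = d6[..., 4]
    tensor[..., 1, 2] = tensor[..., 2, 1] = d6[..., 5]
    tensor[~valid] = np.eye(3) * EIGENVALUE_FLOOR
    return TensorField.from_tensors(tensor, valid=valid, affine=dwi.affine)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean||  / ||lambda||, 0 when degenerate."""
    lam = np.asarray(evals, dtype=np.float64)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa(tensors: TensorField, subject_id: str = "", age: float | None = None) -> FAMap:
    """Fractional anisotropy map from a tensor field (0 where invalid)."""
    fa = fa_from_eigenvalues(tensors.evals)
    fa = np.where(tensors.valid, fa, 0.0)
    return FAMap(fa=fa.astype(np.float32), subject_id=subject_id, age=age, affine=tensors.affine)


def smooth_fa(fa_map: FAMap, fwhm_mm: float = 8.0, voxel_mm: float = 1.0) -> FAMap:
    """Gaussian smoothing with the given full width at half maximum.

    Boundary handling is zero padding (the volume is embedded in empty
    space); the result is clipped back to [0, 1].
    """
    if fwhm_mm <= 0:
        raise ParameterError(f"fwhm must be positive, got {fwhm_mm}")
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    smoothed = ndimage.gaussian_filter(fa_map.fa.astype(np.float64), sigma=sigma, mode="constant")
    smoothed = np.clip(smoothed, 0.0, 1.0).astype(np.float32)
    return replace(fa_map, fa=smoothed, smoothed=True)


def age_correct(
    maps: Sequence[FAMap], control_ids: Sequence[str]
) -> tuple[list[FAMap], np.ndarray, float]:
    """Voxelwise linear age correction fitted on controls.

    An ordinary least-squares slope beta of FA against age is fitted at each
    voxel using the control maps only; every map is then corrected as
    FA' = FA - beta * (age - reference_age) with the controls' mean age as
    reference. Both signs of beta are corrected. Returns the corrected maps,
    the per-voxel slope volume, and the reference age.
    """
    control_set = set(control_ids)
    controls = [m for m in maps if m.subject_id in control_set]
    if len(controls) < 3:
        raise SampleSizeError(f"age correction needs >= 3 controls, got {len(controls)}")
    ages = np.array([m.age for m in controls], dtype=float)
    if np.any(np.isnan(ages)):
        raise DegenerateDesignError("every control map needs an age for age correction")
    if np.ptp(ages) == 0:
        raise DegenerateDesignError("all control ages are equal; age slope is unidentifiable")

    ref_age = float(ages.mean())
    centered = ages - ref_age
    # accumulate the per-voxel OLS slope without stacking all control maps:
    # slope = sum_i (a_i - abar) FA_i / sum_i (a_i - abar)^2  (the mean-FA
    # term cancels because the age weights sum to zero)
    slope = np.zeros(controls[0].fa.shape, dtype=np.float64)
    for c, m in zip(centered, controls):
        slope += c * m.fa.astype(np.float64)
    slope /= (centered**2).sum()

    corrected = []
    for m in maps:
        if m.age is None:
            raise DegenerateDesignError(f"map {m.subject_id!r} has no age; cannot correct")
        fa = m.fa.astype(np.float64) - slope * (m.age - ref_age)
        corrected.append(replace(m, fa=np.clip(fa, 0.0, 1.0).astype(np.float32), age_corrected=True))
    return corrected, slope, ref_age


def fa_mask(fa_map: FAMap, floor: float = 0.2) -> np.ndarray:
    """Analysis mask: voxels whose FA is at or above the floor.

    The boundary value is included (mask is FA >= floor), reading the
    exclusion rule "below the floor" literally.
    """
    return fa_map.fa >= floor
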