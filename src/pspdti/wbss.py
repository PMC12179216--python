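"""Whole brain-based spatial statistics on FA maps.

Voxelwise two-sample Student t-tests (pooled variance) between groups of FA
maps, Benjamini-Hochberg false-discovery-rate control over the in-mask
voxel family, and cluster-extent pruning that removes significant
components smaller than the smoothing-kernel scale (default 512 voxels =
8^3 on the 1-mm grid, matching the 8-mm FWHM kernel). Decrease and increase
clusters are labeled separately so both effect directions are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .dti import FAMap
from .errors import SampleSizeError

DEFAULT_MIN_CLUSTER = 512


@dataclass
class Cluster:
    label: int
    size: int
    sign: str  # "decrease" | "increase" (group1 minus group2)
    peak_t: float
    peak_voxel: tuple[int, int, int]


@dataclass
class WBSSResult:
    t_map: np.ndarray
    p_map: np.ndarray
    analysis_mask: np.ndarray
    fdr_alpha: float
    significant_mask: np.ndarray
    clusters: list[Cluster] = field(default_factory=list)


def _stack(maps: Sequence[FAMap] | np.ndarray) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return maps.astype(np.float64)
    return np.stack([m.fa.astype(np.float64) for m in maps], axis=0)


def voxelwise_ttest(
    group1: Sequence[FAMap] | np.ndarray,
    group2: Sequence[FAMap] | np.ndarray,
    fa_floor: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t-test at every voxel.

    The analysis mask is defined at group level: voxels whose mean FA
    across *all* subjects is at or above ``fa_floor``, giving a single
    well-defined multiple-testing family. Outside the mask t and p are 0
    and 1. Degenerate voxels follow the conventions: zero pooled variance
    with equal means gives t = 0; zero variance with unequal means is
    capped at the largest finite |t| in the map (sign preserved).

    Returns (t_map, p_map, analysis_mask); p is two-sided.
    """
    a, b = _stack(group1), _stack(group2)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise SampleSizeError(f"need >= 2 subjects per group, got {n1} and {n2}")

    mean_all = (a.sum(axis=0) + b.sum(axis=0)) / (n1 + n2)
    mask = mean_all >= fa_floor

    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))

    diff = m1 - m2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    zero_var = se == 0
    t[zero_var & (diff == 0)] = 0.0
    bad = zero_var & (diff != 0)
    if bad.any():
        finite = np.abs(t[np.isfinite(t)])
        cap = finite.max() if finite.size else 0.0
        t[bad] = np.sign(diff[bad]) * cap
    t = np.where(mask, t, 0.0)
    p = np.where(mask, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, p, mask


def benjamini_hochberg(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Boolean rejections of the Benjamini-Hochberg step-up procedure.

    Rejects the k smallest p-values where k is the largest index with
    p_(k) <= k/m * alpha.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passing = ranked <= (np.arange(1, m + 1) / m) * alpha
    reject = np.zeros(m, dtype=bool)
    if passing.any():
        k = int(np.max(np.nonzero(passing)[0]))
        reject[order[: k + 1]] = True
    return reject


def fdr_correct(p_map: np.ndarray, analysis_mask: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH-FDR over all in-mask voxels; returns the voxelwise significance mask."""
    sig = np.zeros(p_map.shape, dtype=bool)
    idx = np.nonzero(analysis_mask)
    if idx[0].size == 0:
        return sig
    sig[idx] = benjamini_hochberg(p_map[idx], alpha=alpha)
    return sig


def _connectivity(order: int) -> np.ndarray:
    # order 1 = 6-connectivity (faces); 2 adds edges; 3 adds corners
    return ndimage.generate_binary_structure(3, order)


def cluster_filter(
    sig_mask: np.ndarray,
    t_map: np.ndarray,
    min_size: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = 1,
) -> tuple[list[Cluster], np.ndarray]:
    """Remove significant components smaller than ``min_size`` voxels.

    Connected components are computed separately for positive-t and
    negative-t voxels (a decrease in group1 vs group2 has t < 0 when
    group1 is the patient group compared against controls as group2 minus;
    here sign "decrease" means t < 0, i.e. group1 below group2).
    """
    structure = _connectivity(connectivity)
    clusters: list[Cluster] = []
    filtered = np.zeros(sig_mask.shape, dtype=bool)
    next_label = 1
    for sign, sel in (("increase", sig_mask & (t_map > 0)), ("decrease", sig_mask & (t_map < 0))):
        labels, n = ndimage.label(sel, structure=structure)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        for comp, size in enumerate(sizes, start=1):
            if size < min_size:
                continue
            member = labels == comp
            filtered |= member
            abs_t = np.where(member, np.abs(t_map), -np.inf)
            peak = np.unravel_index(int(np.argmax(abs_t)), t_map.shape)
            clusters.append(
                Cluster(
                    label=next_label,
                    size=int(size),
                    sign=sign,
                    peak_t=float(t_map[peak]),
                    peak_voxel=tuple(int(i) for i in peak),
                )
            )
            next_label += 1
    return clusters, filtered


def t_threshold_profile(
    t_map: np.ndarray,
    analysis_mask: np.ndarray,
    thresholds: Sequence[float],
    min_size: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = 1,
) -> list[int]:
    """Total surviving-cluster voxels as the |t| threshold rises.

    For each threshold, voxels with |t| >= threshold inside the analysis
    mask are cluster-filtered at ``min_size``; the summed voxel count is
    monotonically non-increasing in the threshold.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    volumes = []
    for theta in thresholds:
        sel = analysis_mask & (np.abs(t_map) >= theta)
        _, filtered = cluster_filter(sel, t_map, min_size=min_size, connectivity=connectivity)
        volumes.append(int(filtered.sum()))
    return volumes


def run_wbss(
    group1: Sequence[FAMap] | np.ndarray,
    group2: Sequence[FAMap] | np.ndarray,
    fa_floor: float = 0.2,
    fdr_alpha: float = 0.05,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = 1,
) -> WBSSResult:
    """Full WBSS stage: t-test, FDR correction, cluster-extent filter."""
    t, p, mask = voxelwise_ttest(group1, group2, fa_floor=fa_floor)
    sig = fdr_correct(p, mask, alpha=fdr_alpha)
    clusters, filtered = cluster_filter(sig, t, min_size=min_cluster, connectivity=connectivity)
    return WBSSResult(
        t_map=t,
        p_map=p,
        analysis_mask=mask,
        fdr_alpha=fdr_alpha,
        significant_mask=filtered,
        clusters=clusters,
    )
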