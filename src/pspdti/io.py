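"""File formats: NIfTI volumes, CSV tables, JSON reports, atlas bundles.

Volumes are NIfTI-1 with the affine preserved round-trip; cohort manifests,
structure tables, scores, and categories are CSV; cluster reports are JSON.
Every writer stamps a schema version so downstream readers can detect
incompatible layouts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .dti import FAMap
from .errors import FormatError
from .synthetic import AtlasDefinition, StructureSpec
from .wbss import Cluster

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
        return np.asarray(img.get_fdata()), img.affine
    except Exception as exc:  # nibabel raises a zoo of format errors
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc


def save_fa_map(path: str | Path, fa_map: FAMap) -> None:
    save_volume(path, fa_map.fa.astype(np.float32), fa_map.affine)


def load_fa_map(
    path: str | Path, subject_id: str = "", age: float | None = None,
    smoothed: bool = False, age_corrected: bool = False,
) -> FAMap:
    data, affine = load_volume(path)
    return FAMap(
        fa=data.astype(np.float32), subject_id=subject_id, age=age,
        smoothed=smoothed, age_corrected=age_corrected, affine=affine,
    )


# ---------------------------------------------------------------------------
# Gradient scheme (FSL-style whitespace text)
# ---------------------------------------------------------------------------


def save_bvals_bvecs(prefix: str | Path, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), np.asarray(bvals)[None, :], fmt="%.1f")
    np.savetxt(prefix.with_suffix(".bvec"), np.asarray(bvecs).T, fmt="%.6f")


def load_bvals_bvecs(prefix: str | Path) -> tuple[np.ndarray, np.ndarray]:
    prefix = Path(prefix)
    try:
        bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
        bvecs = np.loadtxt(prefix.with_suffix(".bvec")).T
    except Exception as exc:
        raise FormatError(f"cannot read gradient scheme {prefix}: {exc}") from exc
    if bvecs.shape != (bvals.size, 3):
        raise FormatError(f"gradient scheme {prefix}: {bvals.size} bvals vs {bvecs.shape} bvecs")
    return bvals, bvecs


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


def save_atlas(directory: str | Path, atlas: AtlasDefinition) -> None:
    """Label NIfTI plus a YAML structure table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(directory / "atlas_labels.nii.gz", atlas.label_volume())
    entries = []
    for i, s in enumerate(atlas.structures):
        entries.append(
            {
                "name": s.name,
                "kind": s.kind,
                "label": i + 1,
                "seed_label": 1000 + i + 1 if s.kind == "toi" else None,
                "target_label": 2000 + i + 1 if s.kind == "toi" else None,
                "pattern": s.pattern,
                "expected_direction": s.expected_direction,
                "orientation": [float(v) for v in s.orientation],
            }
        )
    doc = {"schema_version": SCHEMA_VERSION, "grid_shape": list(atlas.grid_shape), "structures": entries}
    (directory / "atlas.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))


def load_atlas(directory: str | Path) -> AtlasDefinition:
    directory = Path(directory)
    try:
        doc = yaml.safe_load((directory / "atlas.yaml").read_text())
        labels, _ = load_volume(directory / "atlas_labels.nii.gz")
    except FileNotFoundError as exc:
        raise FormatError(f"atlas bundle incomplete in {directory}: {exc}") from exc
    labels = labels.astype(int)
    structures = []
    for e in doc["structures"]:
        # corridors/ROIs carry the base label; TOI end slabs are offset
        wanted = [e["label"]] + [e[k] for k in ("seed_label", "target_label") if e[k]]
        mask = np.isin(labels, wanted)
        seed = labels == e["seed_label"] if e["kind"] == "toi" else None
        target = labels == e["target_label"] if e["kind"] == "toi" else None
        structures.append(
            StructureSpec(
                name=e["name"], kind=e["kind"], pattern=e["pattern"],
                expected_direction=e["expected_direction"],
                mask=mask, seed_mask=seed, target_mask=target,
                orientation=np.array(e["orientation"], dtype=float),
            )
        )
    atlas = AtlasDefinition(grid_shape=tuple(doc["grid_shape"]), structures=structures)
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# Tables and reports
# ---------------------------------------------------------------------------


def save_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def load_manifest(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read manifest {path}: {exc}") from exc
    required = {"subject_id", "timepoint", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


def save_structure_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path)


def load_structure_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, index_col=["subject_id", "timepoint"])
    except Exception as exc:
        raise FormatError(f"cannot read structure table {path}: {exc}") from exc


def save_cluster_report(path: str | Path, clusters: Sequence[Cluster], fdr_alpha: float, min_size: int) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "fdr_alpha": fdr_alpha,
        "min_cluster_voxels": min_size,
        "clusters": [
            {
                "label": c.label,
                "size": c.size,
                "sign": c.sign,
                "peak_t": c.peak_t,
                "peak_voxel": list(c.peak_voxel),
            }
            for c in clusters
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_cluster_report(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except Exception as exc:
        raise FormatError(f"cannot read cluster report {path}: {exc}") from exc
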