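import numpy as np
import pytest

from pspdti.synthetic import (
    AtlasDefinition,
    LesionModel,
    StructureSpec,
    SubjectRecord,
    make_default_atlas,
)


@pytest.fixture(scope="session")
def default_atlas():
    return make_default_atlas()


@pytest.fixture(scope="session")
def quiet_lesions():
    """Lesion model with all variability switched off (population means)."""
    return LesionModel(subject_sd=0.0, structure_sd=0.0, voxel_noise_sd=0.0, retest_sd=0.0)


@pytest.fixture
def control_subject():
    return SubjectRecord("C000", "control", "none", 0, 70.0, "f")


@pytest.fixture
def stage3_subject():
    return SubjectRecord("P000", "psp", "PSP-RS", 3, 70.0, "m")


def make_tube_atlas(grid=(40, 13, 13), length=30, cross=5, end=3, name="tube"):
    """Single straight TOI corridor along x on a small grid."""
    grid = tuple(grid)
    mask = np.zeros(grid, dtype=bool)
    c = [g // 2 for g in grid[1:]]
    cross_sl = tuple(slice(ci - cross // 2, ci - cross // 2 + cross) for ci in c)
    x0 = (grid[0] - length) // 2
    mask[(slice(x0, x0 + length),) + cross_sl] = True
    seed = np.zeros(grid, dtype=bool)
    seed[(slice(x0, x0 + end),) + cross_sl] = True
    target = np.zeros(grid, dtype=bool)
    target[(slice(x0 + length - end, x0 + length),) + cross_sl] = True
    spec = StructureSpec(
        name, "toi", 1, "decrease", mask, seed, target, orientation=np.array([1.0, 0.0, 0.0])
    )
    atlas = AtlasDefinition(grid_shape=grid, structures=[spec])
    atlas.validate()
    return atlas


def age_corrected_maps(cohort):
    """Apply the voxelwise age correction to every scan of a cohort, as the
    processing chain does before any structure-level statistic."""
    from pspdti.dti import age_correct

    keys = list(cohort.fa_maps)
    corrected, _, _ = age_correct([cohort.fa_maps[k] for k in keys], cohort.control_ids)
    return dict(zip(keys, corrected))


def make_mini_atlas(grid=(34, 34, 12)):
    """Three tiny ROIs, one per pattern, for fast cohort-level tests."""
    grid = tuple(grid)
    structures = []
    for i, pattern in enumerate((1, 2, 3)):
        mask = np.zeros(grid, dtype=bool)
        mask[4 + 10 * (i % 3) : 10 + 10 * (i % 3), 4:10, 4:10] = True
        structures.append(
            StructureSpec(f"roi_p{pattern}", "roi", pattern, "decrease", mask)
        )
    atlas = AtlasDefinition(grid_shape=grid, structures=structures)
    atlas.validate()
    return atlas
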