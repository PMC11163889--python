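import numpy as np
import pytest

from discmorph import default_growth_table

#: incommensurate sub-voxel shift so analytic surfaces never coincide
#: with voxel-centre planes (a degenerate alignment)
DIGITIZE_SHIFT = 0.2137


@pytest.fixture(scope="session")
def table():
    return default_growth_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def digitize(predicate, spacing, half_extent_mm):
    """Voxelize an analytic solid: mask of voxel centres satisfying
    ``predicate(x, y, z)`` (coordinates centred on the solid, mm)."""
    spacing = np.asarray(spacing, dtype=float)
    shape = np.ceil(2 * half_extent_mm / spacing).astype(int) + 2
    center = (shape - 1) / 2.0 * spacing + spacing * DIGITIZE_SHIFT
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    x, y, z = (g - c for g, c in zip(grids, center))
    return predicate(x, y, z), center


@pytest.fixture(scope="session")
def table1_counts():
    """Exclusion counts of the reference 180-scan cohort."""
    return {"spine_not_fully_imaged": 13, "no_sagittal": 6, "poor_quality": 11,
            "spinal_pathology": 16, "malposition": 1, "brain_mri": 3,
            "improper_slice_thickness": 4}
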