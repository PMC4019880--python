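import numpy as np
import pytest

import stereobench as sb


@pytest.fixture
def small_profile():
    """The fine-spacing fluorescence condition on a small grid."""
    return sb.preset_profile("3A").scaled(128, 128, 20)


@pytest.fixture
def easy_profile():
    """Fine-spacing fluorescence geometry at recovery-test scale."""
    return sb.preset_profile("3A").scaled(256, 256, 30)


@pytest.fixture
def easy_population():
    """Well-separated interior cells: the regime the baseline detector handles."""
    return sb.CellPopulationSpec(
        n_cells=20, min_separation=6.0, allow_boundary_cut=False
    )


@pytest.fixture
def easy_detector():
    """Mid-contrast threshold separating the well-separated bright cells."""
    return sb.DetectorParams(threshold=140, connectivity=26, min_voxels=500)


@pytest.fixture
def default_noise():
    return sb.NoiseModel()


def random_markers(rng, n, box=(40.0, 40.0, 15.0), boundary_frac=0.0):
    xyz = rng.uniform(0, 1, size=(n, 3)) * np.asarray(box)
    boundary = rng.uniform(size=n) < boundary_frac
    return sb.MarkerSet.from_arrays(xyz, boundary=boundary)


def perturbed_detector(gt, rng, jitter_xy=1.0, jitter_z=0.5, miss_rate=0.2,
                       n_spurious=5, box=(40.0, 40.0, 15.0)):
    """Simulate a detector: jittered subset of the truth plus spurious hits."""
    keep = rng.uniform(size=len(gt)) >= miss_rate
    xyz = gt.xyz[keep] + rng.normal(0, [jitter_xy, jitter_xy, jitter_z], size=(int(keep.sum()), 3))
    spurious = rng.uniform(0, 1, size=(n_spurious, 3)) * np.asarray(box)
    return sb.MarkerSet.from_arrays(np.vstack([xyz, spurious]))
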