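import numpy as np
import pytest

from kineticrad import DCESeries, PhantomSpec, generate_patient


@pytest.fixture()
def hand_series() -> DCESeries:
    """The worked TIC example: pre 100, posts 300/250/240/230/220 at 60..300 s."""
    pre = np.full((3, 3, 3), 100.0)
    posts = [np.full((3, 3, 3), v) for v in (300.0, 250.0, 240.0, 230.0, 220.0)]
    return DCESeries(
        pre_contrast=pre,
        post_contrast=posts,
        phase_times=np.array([60.0, 120.0, 180.0, 240.0, 300.0]),
        voxel_spacing=(1.0, 1.0, 1.0),
        patient_id="hand",
    )


@pytest.fixture(scope="session")
def noise_free_spec() -> PhantomSpec:
    return PhantomSpec(grid_shape=(32, 32, 24), noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noise_free_patient(noise_free_spec):
    return generate_patient(noise_free_spec, "HER2+", seed=11)


@pytest.fixture()
def small_roi_levels():
    """Seeded random discretized ROIs up to 5x5x3 with a masked-out corner."""
    rng = np.random.default_rng(42)
    rois = []
    for shape, n_levels in [((3, 3, 1), 3), ((4, 4, 2), 4), ((5, 5, 3), 5)]:
        lv = rng.integers(1, n_levels + 1, size=shape)
        lv[0, 0, 0] = 0  # a hole, so the ROI is not a full box
        rois.append(lv.astype(np.int64))
    return rois
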