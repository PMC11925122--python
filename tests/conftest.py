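import numpy as np
import pytest
import trimesh

from sozdensity import geometry, synthetic


@pytest.fixture(scope="session")
def grid_8x8():
    return geometry.build_grid_array(8, 8, 4.0, array_id="G")


@pytest.fixture(scope="session")
def depth_10():
    return geometry.build_depth_array(
        10, 5.0, entry=(40.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0), array_id="D"
    )


@pytest.fixture(scope="session")
def small_mesh():
    """Synthetic spherical cortex stand-in, radius 40 mm."""
    tm = trimesh.creation.icosphere(subdivisions=2, radius=40.0)
    return geometry.SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def true_disc_mask():
    return synthetic.generate_true_soz_mask((120, 120), radius_px=25.0)


@pytest.fixture(scope="session")
def short_seizure(grid_8x8, depth_10):
    """One synthetic focal seizure on the grid+depth implant (seeded)."""
    cfg = synthetic.SeizureSimConfig(
        seed=7, duration_s=12.0, onset_s=8.0, focus=(12.5, 13.0, 0.0)
    )
    return synthetic.generate_seizure_recording([grid_8x8, depth_10], cfg), cfg
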