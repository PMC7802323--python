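import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellmech import simgen, tfm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def geom():
    return tfm.PillarGeometry()  # 0.9 um posts, 1.8 um pitch, 2 MPa PDMS


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free single-frame pillar scene (no drift, no deflection)."""
    spec = simgen.PillarSceneSpec(
        image_shape=(160, 160), pixel_size=0.2,
        shot_noise=False, read_noise_sd=0.0, seed=11,
    )
    return simgen.simulate_pillar_sequence(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    """Shot-noise scene at 500 peak counts."""
    spec = simgen.PillarSceneSpec(
        image_shape=(160, 160), pixel_size=0.2,
        photon_level=500.0, shot_noise=True, read_noise_sd=2.0, seed=12,
    )
    return simgen.simulate_pillar_sequence(spec)


@pytest.fixture()
def cell_scene_spec():
    """Multi-frame scene factory with a central cell and planted deflections."""

    def make(n_frames=6, drift=(0.03, 0.0), n_deflected=6, seed=21,
             shot_noise=True, mag_range=(0.1, 0.4)):
        h = w = 160
        mask = simgen.disk_mask((h, w), (w / 2, h / 2), 34)
        spec = simgen.PillarSceneSpec(
            image_shape=(h, w), pixel_size=0.2, n_frames=n_frames,
            photon_level=500.0, shot_noise=shot_noise,
            read_noise_sd=2.0 if shot_noise else 0.0,
            drift_per_frame=drift, cell_mask=mask, seed=seed,
        )
        if n_deflected:
            spec = simgen.add_random_deflections(spec, n_deflected, mag_range)
        return spec

    return make


def truth_deflection_lookup(scene):
    """Map each truth pillar rest position to its planted deflection magnitude."""
    t0 = scene.truth[scene.truth.frame == scene.truth.frame.max()]
    pos = t0[["rest_x_um", "rest_y_um"]].to_numpy()
    mag = np.hypot(t0["defl_x_um"].to_numpy(), t0["defl_y_um"].to_numpy())
    return pos, mag
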