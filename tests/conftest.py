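import numpy as np
import pytest

import tunnelmetrics as tm


def rotation_matrix(axis, angle_rad):
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


@pytest.fixture
def arbitrary_rotation():
    return rotation_matrix([0.3, -0.5, 0.81], 1.1)


@pytest.fixture
def cylinder_mesh():
    """Moderate-resolution analytic cylinder, r=4 mm, axis +z."""
    return tm.make_cylinder_mesh(4.0, 30.0, n_circumferential=64, n_axial=40)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, unblurred oblique phantom with a 6 mm tunnel."""
    spec = tm.PhantomSpec(drill_diameter_mm=6.0, blur_sigma_voxels=0.0, noise_sd=0.0, seed=11)
    vol, truth = tm.make_phantom_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default (blur + noise) oblique phantom with a 6 mm tunnel."""
    spec = tm.PhantomSpec(drill_diameter_mm=6.0, seed=11)
    vol, truth = tm.make_phantom_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def cohort_study(tmp_path_factory):
    """One seeded 24-tunnel simulated study, shared across agreement and
    accuracy tests."""
    out = tmp_path_factory.mktemp("study")
    cfg = tm.RunConfig(seed=0, save_volumes=False, save_meshes=False)
    return tm.run_simulated_study(cfg, out_dir=out)
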