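import numpy as np
import pytest

from wmlearn.io_formats import ScalarVolume
from wmlearn.synthetic import BundleSimConfig, simulate_bundle


def curved_control_points():
    """A gently curved centerline, ~90 mm long."""
    return np.array(
        [[0.0, 0.0, 0.0], [30.0, 4.0, 2.0], [60.0, -4.0, -2.0], [90.0, 0.0, 0.0]]
    )


@pytest.fixture
def control_points():
    return curved_control_points()


@pytest.fixture
def small_bundle(control_points):
    cfg = BundleSimConfig(
        centerline_control_points=control_points,
        n_streamlines=30,
        points_per_streamline=60,
        radial_jitter_sd=1.0,
        seed=7,
    )
    bundle, _ = simulate_bundle(cfg)
    return bundle


@pytest.fixture
def gradient_volume():
    """80x40x40 voxel grid at 2 mm, origin (-20,-30,-30): value 0.3 + 0.001*x."""
    shape = (80, 40, 40)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-20.0, -30.0, -30.0]
    ii = np.arange(shape[0]) * 2.0 - 20.0
    values = np.broadcast_to((0.3 + 0.001 * ii)[:, None, None], shape).copy()
    return ScalarVolume(values, affine)


@pytest.fixture
def constant_volume():
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-20.0, -30.0, -30.0]
    return ScalarVolume(np.full((80, 40, 40), 0.42), affine)


def brute_force_profile(bundle, volume, kernel="gaussian"):
    """Independent double-loop reference for the weighted tract profile."""
    from wmlearn.io_formats import sample_trilinear

    arr = np.stack(bundle.streamlines)  # (S, K, 3)
    n_stream, n_nodes, _ = arr.shape
    core = np.array(
        [arr[:, k, :].mean(axis=0) for k in range(n_nodes)]
    )
    out = np.zeros(n_nodes)
    for k in range(n_nodes):
        vals = np.zeros(n_stream)
        dists = np.zeros(n_stream)
        for s in range(n_stream):
            v, oob = sample_trilinear(volume, arr[s, k])
            assert not oob
            vals[s] = v
            dists[s] = np.sqrt(((arr[s, k] - core[k]) ** 2).sum())
        if n_stream == 1:
            weights = np.ones(1)
        elif kernel == "gaussian":
            sigma = dists.std(ddof=1)
            if sigma == 0:
                weights = np.ones(n_stream)
            else:
                weights = np.exp(-(dists**2) / (2 * sigma**2))
        else:
            weights = 1.0 / (dists + 1e-12)
        weights = weights / weights.sum()
        out[k] = (weights * vals).sum()
    return out
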