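import numpy as np
import pytest

from rodmorph import SceneSpec, sample_scene


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free scene of 12 well-separated cells (session-cached)."""
    spec = SceneSpec(
        image_height_px=512,
        image_width_px=512,
        n_cells=12,
        noise_sd=0.0,
        min_gap_px=5,
        seed=7,
    )
    image, truth = sample_scene(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_region(rng, max_px=200):
    """A random connected-ish pixel blob as an (n, 2) coordinate array."""
    n = int(rng.integers(1, max_px + 1))
    # random walk keeps coordinates in a compact, overlapping cloud
    steps = rng.integers(-2, 3, size=(n, 2))
    coords = np.cumsum(steps, axis=0) + 50
    return np.unique(coords, axis=0)


def brute_force_max_feret(coords):
    pts = np.asarray(coords, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def _caliper_width(pts, theta):
    proj = pts @ np.stack([np.cos(theta), np.sin(theta)], axis=-1).T
    return proj.max(axis=0) - proj.min(axis=0)


def brute_force_min_feret(coords, step_deg=0.01):
    """Minimum caliper width by a 0.01-degree projection-extent sweep.

    The grid minimum brackets the true minimizer; the width function is
    V-shaped there, so a ternary search inside the bracketing interval
    closes the remaining gap to well below 1e-6 px.  Works directly on the
    raw point set — independent of any convex-hull construction.
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 2:
        return 0.0
    step = np.deg2rad(step_deg)
    theta = np.arange(0.0, np.pi, step)
    widths = _caliper_width(pts, theta)
    k = int(np.argmin(widths))
    lo, hi = theta[k] - step, theta[k] + step
    for _ in range(80):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        if _caliper_width(pts, np.array([m1]))[0] <= _caliper_width(pts, np.array([m2]))[0]:
            hi = m2
        else:
            lo = m1
    return float(_caliper_width(pts, np.array([(lo + hi) / 2.0]))[0])
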