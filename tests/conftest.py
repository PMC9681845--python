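import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from voitex.io import VolumeWithMask

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_vwm(rng):
    """An 8x7x6 volume with a box-shaped VOI."""
    intensities = rng.normal(100.0, 25.0, size=(8, 7, 6))
    mask = np.zeros((8, 7, 6), dtype=bool)
    mask[2:6, 1:6, 1:5] = True
    return VolumeWithMask(
        intensities=intensities,
        spacing=(0.79, 1.15, 4.0),
        mask=mask,
        subject_id="S1",
    )


def brute_force_glcm(level_vol: np.ndarray, n_levels: int, distance: int):
    """Independent GLCM oracle: loop over every voxel pair and test whether
    their offset equals distance times one of the 13 direction generators.

    Level 0 marks voxels outside the VOI. Returns the unnormalized
    symmetric count matrix.
    """
    from voitex.glcm import direction_set

    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    coords = np.argwhere(level_vol > 0)
    offsets = {tuple(distance * c for c in u) for u in direction_set()}
    for x in coords:
        for y in coords:
            if tuple(y - x) in offsets:
                a = level_vol[tuple(x)] - 1
                b = level_vol[tuple(y)] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts


def naive_haralick(p: np.ndarray, log=np.log):
    """Independent Haralick oracle: plain double loops over (i, j)."""
    ng = p.shape[0]
    out = {}
    mu_x = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    mu_y = sum((j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    sig_x = (
        sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
        ** 0.5
    )
    sig_y = (
        sum((j + 1 - mu_y) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
        ** 0.5
    )
    out["uniformity"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["homogeneity"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["entropy"] = -sum(
        p[i, j] * log(p[i, j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0
    )
    out["variance"] = sum(
        (i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    if sig_x * sig_y > 0:
        out["correlation"] = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sig_x * sig_y)
    else:
        out["correlation"] = 0.0
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    out["sum_average"] = sum(k * v for k, v in p_sum.items())
    out["sum_entropy"] = -sum(v * log(v) for v in p_sum.values() if v > 0)
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * v for k, v in p_sum.items()
    )
    mu_d = sum(k * v for k, v in p_diff.items())
    out["entropy_of_difference"] = -sum(
        v * log(v) for v in p_diff.values() if v > 0
    )
    out["variance_of_difference"] = sum(
        (k - mu_d) ** 2 * v for k, v in p_diff.items()
    )
    return out


def random_normalized_matrix(rng, ng, symmetric=True):
    m = rng.random((ng, ng))
    if symmetric:
        m = m + m.T
    return m / m.sum()
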