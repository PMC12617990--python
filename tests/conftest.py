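import numpy as np
import pytest

from dwiqc.io_bridge import BTable, DiffusionSeries, MaskSeries, QCConfig
from dwiqc.phantom import ArtifactSpec, PhantomConfig, make_phantom

SMALL_GRID = (24, 24, 16)
SMALL_SEMIAXES = (30.0, 30.0, 20.0)


def small_phantom_config(seed, artifacts=(), noise_sigma=0.0, **kwargs):
    """Desk-scale phantom used throughout the suite (fits the FOV)."""
    params = dict(grid=SMALL_GRID, brain_semiaxes_mm=SMALL_SEMIAXES,
                  csf_rim_mm=6.0)
    params.update(kwargs)
    return PhantomConfig(seed=seed, artifacts=tuple(artifacts),
                         noise_sigma=noise_sigma, **params)


@pytest.fixture(scope="session")
def clean_phantom():
    return make_phantom(small_phantom_config(seed=11))


@pytest.fixture
def qc_config():
    return QCConfig()


def uniform_series(value=100.0, grid=(8, 8, 6), n_volumes=1, bvals=None,
                   voxel_size=1.0):
    """A constant-intensity series with an all-ones mask (for rule tests)."""
    if bvals is None:
        bvals = [0.0] * n_volumes
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.zeros((bvals.size, 3))
    bvecs[bvals > 0] = (1.0, 0.0, 0.0)
    data = np.full(grid + (bvals.size,), float(value))
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    series = DiffusionSeries(data=data, affine=affine,
                             btable=BTable(bvals, bvecs))
    masks = MaskSeries(data=np.ones_like(data, dtype=np.uint8))
    return series, masks


def random_small_series(rng, max_grid=16, max_t=10):
    """Random series + masks for oracle-equivalence tests.

    Volume 0 always has a usable mask; later volumes may be empty.
    """
    grid = tuple(int(rng.integers(5, max_grid + 1)) for _ in range(3))
    t = int(rng.integers(2, max_t + 1))
    bvals = rng.choice([0.0, 10.0, 50.0, 200.0, 600.0, 1000.0], size=t)
    bvals[0] = 0.0
    bvecs = np.zeros((t, 3))
    bvecs[bvals > 0] = (0.0, 1.0, 0.0)
    data = rng.uniform(0.05, 1.0, size=grid + (t,))
    masks = np.zeros(grid + (t,), dtype=np.uint8)
    for i in range(t):
        if i > 0 and rng.random() < 0.1:
            continue  # empty mask path
        p = rng.uniform(0.2, 0.8)
        m = rng.random(grid) < p
        if i == 0 and not m.any():
            m[grid[0] // 2, grid[1] // 2, grid[2] // 2] = True
        masks[..., i] = m
    # occasionally scrub a slice to provoke the dropout rule
    for i in range(t):
        if rng.random() < 0.3:
            s = int(rng.integers(0, grid[2]))
            data[:, :, s, i] *= rng.uniform(0.0, 1.0)
    vox = float(rng.uniform(0.5, 4.0))
    affine = np.diag([vox, vox, vox, 1.0])
    series = DiffusionSeries(data=data, affine=affine,
                             btable=BTable(bvals, bvecs))
    return series, MaskSeries(data=masks)
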