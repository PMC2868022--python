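"""Shared fixtures and the independent full-lattice energy oracle.

The oracle recomputes the total adhesion + volume effective energy from
scratch by brute force (nested loops over all voxel bonds), deliberately
sharing no code with the incremental kernel it checks.
"""

import numpy as np
import pytest

from streaksim.core import AdhesionTable, SimParams, TissueState

MOORE = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)]


def brute_force_energy(owner, ctype, J, alpha=0.6, tvol=None):
    """Total adhesion + volume energy, recomputed from scratch.

    Bonds are counted once per ordered pair then halved; out-of-lattice
    neighbors count as medium (type 0).
    """
    H, W = owner.shape
    E = 0.0
    for i in range(H):
        for j in range(W):
            a = owner[i, j]
            for di, dj in MOORE:
                ni, nj = i + di, j + dj
                if 0 <= ni < H and 0 <= nj < W:
                    if a != owner[ni, nj]:
                        E += 0.5 * J[ctype[a], ctype[owner[ni, nj]]]
                elif a != 0:
                    # bond with the off-lattice medium exists only once
                    E += J[ctype[a], 0]
    if tvol is not None:
        vols = np.bincount(owner.ravel(), minlength=len(tvol))
        for cid in range(1, len(tvol)):
            if ctype[cid] > 0:
                E += alpha * (vols[cid] - tvol[cid]) ** 2
    return E


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_state(rng):
    """Random two-cell (AP | AO) configuration on a 12x12 lattice."""
    owner = np.zeros((12, 12), dtype=np.int32)
    owner[3:9, 2:6] = 1
    owner[3:9, 6:10] = 2
    state = TissueState(owner, [0, 1, 2], tvol=[0, 24, 24], rng=rng)
    return state


@pytest.fixture
def single_cell_state(rng):
    """One round AP cell of ~target volume in medium."""
    owner = np.zeros((20, 20), dtype=np.int32)
    yy, xx = np.indices((20, 20))
    owner[(yy - 10) ** 2 + (xx - 10) ** 2 <= 16] = 1
    return TissueState(owner, [0, 1], tvol=[0, 49], rng=rng)


def random_tissue(rng, shape=(16, 16), n_cells=4):
    """Random blobby multi-cell tissue for property tests."""
    from scipy.spatial import cKDTree

    H, W = shape
    pts = rng.uniform([2, 2], [H - 2, W - 2], size=(n_cells, 2))
    yy, xx = np.indices(shape)
    vox = np.column_stack([yy.ravel(), xx.ravel()])
    _, assign = cKDTree(pts).query(vox)
    owner = (assign + 1).reshape(shape).astype(np.int32)
    # carve some medium margin
    rr = np.hypot(yy - (H - 1) / 2, xx - (W - 1) / 2)
    owner[rr > H / 2 - 1] = 0
    types = [0] + [int(rng.integers(1, 5)) for _ in range(n_cells)]
    vols = np.bincount(owner.ravel(), minlength=n_cells + 1)
    return TissueState(owner, types, tvol=vols[: n_cells + 1], rng=rng)
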