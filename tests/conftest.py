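"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from maxfit import FixtureSpec, make_chain, make_pair
from maxfit.geometry import Transform


@pytest.fixture
def helix30():
    return make_chain(FixtureSpec(n=30, kind="helix", rng_seed=101))


@pytest.fixture
def mixed40_pair():
    """Rigid noise-free copy pair with full overlap."""
    return make_pair(FixtureSpec(n=40, kind="mixed", rng_seed=202))


@pytest.fixture
def noisy_pair():
    """Full-overlap pair with 0.5 Å coordinate noise."""
    return make_pair(FixtureSpec(n=40, kind="mixed", noise_sigma=0.5, rng_seed=303))


@pytest.fixture
def decoy_pair():
    """Partial-overlap decoy pair (f = 0.7, sigma = 0.3 Å)."""
    return make_pair(
        FixtureSpec(n=50, kind="mixed", overlap_fraction=0.7,
                    noise_sigma=0.3, rng_seed=404)
    )


def rotation_about(center: np.ndarray, axis: np.ndarray, angle_deg: float) -> Transform:
    """Rigid rotation by angle_deg about an axis through ``center``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    return Transform(R, center - R @ center)


def grid_rmsd_oracle(
    left: np.ndarray,
    right: np.ndarray,
    coarse_deg: float = 6.0,
    levels: int = 7,
    top: int = 20,
) -> float:
    """Minimum cRMS over rotations x centroid translation by exhaustive
    coarse Euler-grid scan followed by nested local grid refinement of the
    ``top`` coarse basins (final resolution far below 1 degree).

    Independent of the SVD/quaternion solvers it is used to check: pure
    rotation-grid function evaluation.
    """
    lc, rc = left.mean(axis=0), right.mean(axis=0)
    L, R0 = left - lc, right - rc

    def cost(mats: np.ndarray) -> np.ndarray:
        rot = np.einsum("rab,nb->rna", mats, R0)
        return np.sqrt(np.mean(np.sum((rot - L) ** 2, axis=2), axis=1))

    step = np.radians(coarse_deg)
    axes = [
        np.arange(0.0, 2 * np.pi, step),
        np.arange(0.0, np.pi + 1e-9, step),
        np.arange(0.0, 2 * np.pi, step),
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    c = cost(Rotation.from_euler("ZYZ", grid).as_matrix())
    order = np.argsort(c)[:top]
    best = float(c[order[0]])
    for idx in order:
        center, s = grid[idx], step
        for _ in range(levels):
            ax = [np.linspace(center[k] - s, center[k] + s, 9) for k in range(3)]
            g = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
            cc = cost(Rotation.from_euler("ZYZ", g).as_matrix())
            k = int(np.argmin(cc))
            center = g[k]
            best = min(best, float(cc[k]))
            s = s / 3.0
    return best
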