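"""Synthetic protein-like fixtures with known ground truth.

Generates Cα chains with realistic consecutive spacing (3.8 Å) as ideal
α-helices, self-avoiding random walks, or mixtures, and decoy pairs built
by copying a chain, deleting residues, replacing a block with decoy
geometry, applying a known rigid transform and adding coordinate noise.
Every pair fixture carries a machine-checkable certificate: under the
planted transform, all ground-truth residue pairs lie within
max(3 sigma, 0.5) Å, so the true correspondence places at least
(overlap fraction) x (chain length) pairs under that cutoff.  Recovery
tests compare search results against this certificate, never against
unproven optima.

Noise displacements are isotropic Gaussian with the norm truncated at
2.5 sigma; the truncation is what makes the certificate deterministic
rather than merely highly probable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .align_engine import Alignment
from .geometry import Transform
from .structio import Structure

__all__ = [
    "FixtureSpec",
    "PairFixture",
    "make_chain",
    "make_pair",
    "certificate_cutoff",
    "CA_SPACING",
    "CLASH_DISTANCE",
]

CA_SPACING = 3.8  # Å between consecutive Cα
CLASH_DISTANCE = 3.5  # Å self-avoidance radius for random walks

# ideal α-helix Cα geometry
_HELIX_RISE = 1.5  # Å per residue along the axis
_HELIX_TURN = np.radians(100.0)  # per residue
_HELIX_RADIUS = 2.3  # Å


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic chain or chain pair.

    n: number of residues (>= 3).
    kind: "helix", "random_walk" or "mixed" (alternating segments).
    transform: a :class:`Transform` to plant, or "random".
    noise_sigma: per-coordinate Gaussian noise scale in Å (norm truncated
        at 2.5 sigma).
    overlap_fraction: fraction f of the copied chain kept as true
        correspondence; the rest is replaced by decoy geometry.
    indel_pattern: positions (0-based, in the source chain) deleted from
        the copy.
    rng_seed: reproducibility seed; every coordinate is a pure function of
        the spec.
    """

    n: int = 60
    kind: str = "helix"
    transform: Transform | str = "random"
    noise_sigma: float = 0.0
    overlap_fraction: float = 1.0
    indel_pattern: tuple[int, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("chains need at least 3 residues")
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.kind not in ("helix", "random_walk", "mixed"):
            raise ValueError(f"unknown chain kind: {self.kind!r}")


@dataclass(frozen=True)
class PairFixture:
    """A decoy pair with its planted ground truth.

    ``transform`` maps b onto a (the direction aligners estimate);
    ``truth`` is the strictly increasing index correspondence of the
    non-decoy, non-deleted residues.
    """

    a: Structure
    b: Structure
    truth: Alignment
    transform: Transform
    spec: FixtureSpec


def _helix_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    phase = rng.uniform(0.0, 2 * np.pi)
    k = np.arange(n)
    ang = phase + k * _HELIX_TURN
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(ang),
            _HELIX_RADIUS * np.sin(ang),
            _HELIX_RISE * k,
        ]
    )


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _walk_coords(
    n: int,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
    existing: list[np.ndarray] | None = None,
    clash: float = CLASH_DISTANCE,
    max_tries: int = 200,
) -> np.ndarray:
    """Fixed-step self-avoiding random walk (rejection sampling).

    Consecutive residues are exempt from the clash check (they sit at the
    3.8 Å bond distance, closer than the 3.5 Å clash radius only never).
    If a step cannot be placed, the clash radius is relaxed slightly — a
    collapsed dead end must not hang the generator.
    """
    pts: list[np.ndarray] = [np.zeros(3) if start is None else np.array(start)]
    others = list(existing) if existing else []
    while len(pts) < n:
        placed = False
        radius = clash
        for attempt in range(max_tries):
            step = _random_direction(rng) * CA_SPACING
            cand = pts[-1] + step
            obstacles = pts[:-1] + others
            if not obstacles or np.min(
                np.linalg.norm(np.asarray(obstacles) - cand, axis=1)
            ) >= radius:
                pts.append(cand)
                placed = True
                break
            if attempt and attempt % 50 == 0:
                radius *= 0.9
        if not placed:  # pragma: no cover - rejection virtually always succeeds
            pts.append(pts[-1] + _random_direction(rng) * CA_SPACING)
    return np.asarray(pts)


def make_chain(spec: FixtureSpec) -> Structure:
    """Generate one protein-like Cα chain, deterministic per seed."""
    rng = np.random.default_rng(spec.rng_seed)
    if spec.kind == "helix":
        coords = _helix_coords(spec.n, rng)
    elif spec.kind == "random_walk":
        coords = _walk_coords(spec.n, rng)
    else:  # mixed: a helix followed by a walk continuing from its end
        n1 = spec.n // 2
        h = _helix_coords(max(n1, 3), rng)[: max(n1, 3)]
        w = _walk_coords(
            spec.n - len(h) + 1, rng, start=h[-1], existing=list(h[:-1])
        )
        coords = np.vstack([h, w[1:]])
    aas = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, spec.n))
    return Structure(
        id=f"syn{spec.rng_seed}",
        chain_id="A",
        residue_numbers=tuple(range(1, spec.n + 1)),
        insertion_codes=(" ",) * spec.n,
        amino_acids=aas,
        coords=coords,
    )


def _truncated_noise(
    rng: np.random.Generator, n: int, sigma: float
) -> np.ndarray:
    """Isotropic Gaussian displacements with norm clipped to 2.5 sigma."""
    if sigma == 0.0:
        return np.zeros((n, 3))
    disp = rng.normal(scale=sigma, size=(n, 3))
    norms = np.linalg.norm(disp, axis=1, keepdims=True)
    cap = 2.5 * sigma
    scale = np.where(norms > cap, cap / norms, 1.0)
    return disp * scale


def certificate_cutoff(spec: FixtureSpec) -> float:
    """Distance within which the planted transform provably places every
    ground-truth pair: max(3 sigma, 0.5) Å."""
    return max(3.0 * spec.noise_sigma, 0.5)


def make_pair(spec: FixtureSpec) -> PairFixture:
    """Build a decoy pair with planted correspondence and transform.

    The copy drops ``indel_pattern`` positions, replaces a contiguous block
    of (1 - f) of the remaining residues (seeded random location) with
    decoy random-walk geometry, then is rigidly moved by the planted
    transform and perturbed by truncated Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1]))
    a = make_chain(spec)

    keep = [i for i in range(spec.n) if i not in set(spec.indel_pattern)]
    if len(keep) < 3:
        raise ValueError("indel pattern removes too many residues")
    coords_b = a.coords[keep].copy()
    n_b = len(keep)

    n_decoy = n_b - int(np.ceil(spec.overlap_fraction * n_b))
    truth_mask = np.ones(n_b, dtype=bool)
    if n_decoy > 0:
        start = int(rng.integers(0, n_b - n_decoy + 1))
        block = slice(start, start + n_decoy)
        truth_mask[block] = False
        # decoy geometry: a walk branching off the residue preceding the
        # block (or the block's first true successor), far-from-native
        anchor = coords_b[start - 1] if start > 0 else coords_b[block.stop]
        decoy = _walk_coords(
            n_decoy + 1,
            rng,
            start=anchor,
            existing=[c for i, c in enumerate(coords_b) if truth_mask[i]],
        )[1:]
        if start == 0:
            decoy = decoy[::-1]
        coords_b[block] = decoy

    if spec.transform == "random":
        R = Rotation.random(random_state=np.random.default_rng(
            np.random.SeedSequence([spec.rng_seed, 2])
        )).as_matrix()
        tvec = rng.uniform(-20.0, 20.0, size=3)
        planted = Transform(R, tvec)
    else:
        planted = spec.transform

    coords_b = planted.apply(coords_b) + _truncated_noise(rng, n_b, spec.noise_sigma)

    b = Structure(
        id=f"syn{spec.rng_seed}B",
        chain_id="B",
        residue_numbers=tuple(range(1, n_b + 1)),
        insertion_codes=(" ",) * n_b,
        amino_acids="".join(a.amino_acids[i] for i in keep),
        coords=coords_b,
    )
    truth_pairs = tuple(
        (keep[jb], jb) for jb in range(n_b) if truth_mask[jb]
    )
    truth = Alignment(truth_pairs, float(len(truth_pairs)), "ground_truth")

    fixture = PairFixture(a=a, b=b, truth=truth,
                          transform=planted.inverse(), spec=spec)
    # certificate: the planted transform places every true pair within
    # max(3 sigma, 0.5) Å (noise norms are truncated at 2.5 sigma)
    b_back = fixture.transform.apply(b.coords)
    dist = np.linalg.norm(
        a.coords[[i for i, _ in truth_pairs]]
        - b_back[[j for _, j in truth_pairs]],
        axis=1,
    )
    assert np.all(dist <= certificate_cutoff(spec) + 1e-9)
    return fixture
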