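"""Rigid-body transforms, least-squares superposition, and the cRMS score.

A superposition is a proper rotation plus a translation applied to one set of
Cα coordinates.  The coordinate root-mean-square deviation (cRMS) over k
aligned pairs is

    cRMS = sqrt( (1/k) * sum_r ||a_r - b_r||^2 )

and the least-squares superposition is the rigid motion of the second set
minimizing cRMS, computed either by the Kabsch SVD method (with reflection
correction so the determinant is +1) or by Horn's quaternion method.  Both
are exact minimizers; the two routes cross-check each other in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Transform",
    "SuperpositionResult",
    "crms",
    "superpose_lsq",
    "apply_transform",
]


@dataclass(frozen=True)
class Transform:
    """A proper rigid motion x -> rotation @ x + translation (Å)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map an (n, 3) coordinate array through the rigid motion."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -(self.rotation.T @ self.translation))

    def rotation_angle_deg(self, other: "Transform | None" = None) -> float:
        """Geodesic rotation distance to ``other`` (identity if omitted), degrees."""
        R = self.rotation if other is None else self.rotation @ other.rotation.T
        c = (np.trace(R) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class SuperpositionResult:
    """Output of a least-squares fit: the transform, the cRMS it achieves,
    and whether the geometry was too degenerate for a unique rotation."""

    transform: Transform
    crms: float
    degenerate: bool = False


def crms(left: np.ndarray, right: np.ndarray) -> float:
    """cRMS over paired coordinates: sqrt(mean squared pair distance).

    Raises ``ValueError`` on an empty pairing (the quantity is undefined).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 2 or left.shape[1] != 3:
        raise ValueError("paired coordinates must be matching (k, 3) arrays")
    if left.shape[0] == 0:
        raise ValueError("cRMS is undefined for an empty pairing")
    return float(np.sqrt(np.mean(np.sum((left - right) ** 2, axis=1))))


def _kabsch_rotation(left_c: np.ndarray, right_c: np.ndarray) -> np.ndarray:
    """Optimal rotation of centered ``right_c`` onto centered ``left_c``."""
    H = right_c.T @ left_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _horn_rotation(left_c: np.ndarray, right_c: np.ndarray) -> np.ndarray:
    """Optimal rotation via Horn's unit-quaternion eigenvalue method."""
    M = right_c.T @ left_c
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, V = np.linalg.eigh(K)
    q = V[:, -1]  # eigenvector of the largest eigenvalue
    a, b, c, d = q
    # quaternion (a, b, c, d) -> rotation matrix mapping right onto left
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
            [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
            [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
        ]
    )


def superpose_lsq(
    left: np.ndarray, right: np.ndarray, method: str = "kabsch"
) -> SuperpositionResult:
    """Least-squares superposition of ``right`` onto ``left``.

    Returns the proper rigid motion of ``right`` minimizing cRMS, the cRMS
    it achieves, and a degeneracy flag.  Fewer than 3 pairs, or (near-)
    collinear/coincident point sets, do not pin down a unique rotation; a
    best-effort transform is still returned, flagged degenerate, so that
    iterative aligners can survive transiently tiny pairings.

    method: "kabsch" (SVD with determinant correction) or "quaternion"
    (Horn).  The two agree to numerical precision.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 2 or left.shape[1] != 3:
        raise ValueError("paired coordinates must be matching (k, 3) arrays")
    k = left.shape[0]
    if k == 0:
        raise ValueError("cannot superpose an empty pairing")

    lc = left.mean(axis=0)
    rc = right.mean(axis=0)
    left_c = left - lc
    right_c = right - rc

    # Rank of the centered cloud decides whether the rotation is unique:
    # rank >= 2 (non-collinear) is needed for a unique proper rotation.
    sv = np.linalg.svd(right_c, compute_uv=False) if k >= 2 else np.zeros(1)
    degenerate = k < 3 or np.sum(sv > 1e-8) < 2

    if np.allclose(right_c, 0.0, atol=1e-12):
        R = np.eye(3)  # all points coincident: only the translation matters
    elif method == "kabsch":
        R = _kabsch_rotation(left_c, right_c)
    elif method == "quaternion":
        R = _horn_rotation(left_c, right_c)
    else:
        raise ValueError(f"unknown superposition method: {method!r}")

    # Guard against numerical drift off the rotation manifold.
    U, _, Vt = np.linalg.svd(R)
    R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt

    t = lc - R @ rc
    transform = Transform(R, t)
    return SuperpositionResult(transform, crms(left, transform.apply(right)), degenerate)


def apply_transform(t: Transform, coords: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`Transform.apply` on raw coordinates."""
    return t.apply(coords)
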