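"""Dynamic-programming cores for sequential structure alignment.

Given a fixed spatial superposition, every aligner here reduces to a global
dynamic program over the inter-structure Cα distance matrix
``d[i, j] = ||a_i - b_j||``:

* STRUCTAL scoring:  ``S(i, j) = 20 / (1 + d_ij^2 / 5)`` with a linear gap
  penalty of 10 per skipped position;
* TM-align scoring:  ``S(i, j) = 1 / (1 + (d_ij / d0)^2)`` with affine gap
  penalties (0.6 open, 0.0 extend) and the length-dependent scale
  ``d0 = 1.24 * (L - 15)^(1/3) - 1.8`` for the shorter length L;
* threshold matching: maximize the *number* of sequentially matched pairs
  with ``d_ij <= d`` (the building block of the deep superposition search).

Gap convention.  The recurrence uses a zero boundary, so a run of skipped
positions before the first matched pair is free on the cheaper side
(``min(i_1, j_1)`` positions are charged), while skips between matched pairs
and after the last pair are charged in full.  The affine program charges
``open + extend * (len - 1)`` per such run, with a fresh ``open`` when a run
switches sides.  The brute-force enumeration oracles in this module score
candidate alignments with exactly the same convention, closed-form, so DP
and oracle are comparable to machine precision.

Tracebacks break ties deterministically: diagonal > up (skip in a) > left
(skip in b); outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .structio import Structure

__all__ = [
    "Alignment",
    "ScoreParams",
    "distance_matrix",
    "structal_score_matrix",
    "tmalign_d0",
    "tmalign_score_matrix",
    "dp_linear",
    "dp_affine",
    "numpairs_dp",
    "structal_total_score",
    "count_gap_positions",
    "count_gap_runs",
    "enumerate_monotone_alignments",
    "brute_force_linear",
    "brute_force_affine",
    "brute_force_numpairs",
]

_NEG = -1e18  # "never reachable" sentinel; avoids inf - inf NaNs
_TIE_TOL = 1e-9  # traceback equality tolerance for float scores

STRUCTAL_GAP = 10.0
TMALIGN_GAP_OPEN = 0.6
TMALIGN_GAP_EXTEND = 0.0
D0_FLOOR = 0.5  # Å; keeps d0 positive for chains of <= 17 residues


@dataclass(frozen=True)
class Alignment:
    """A sequential residue correspondence with its scheme score.

    ``pairs`` is a tuple of (i, j) index pairs, strictly increasing in both
    coordinates.  ``scheme`` names the scoring scheme that produced it.
    """

    pairs: tuple[tuple[int, int], ...]
    score: float
    scheme: str

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
            if not (i1 > i0 and j1 > j0):
                raise ValueError(
                    f"alignment pairs must be strictly increasing; "
                    f"({i0},{j0}) precedes ({i1},{j1})"
                )
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def left_indices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.pairs)

    @property
    def right_indices(self) -> tuple[int, ...]:
        return tuple(j for _, j in self.pairs)


@dataclass(frozen=True)
class ScoreParams:
    """Constants of a scoring scheme.

    scheme: "structal", "tmalign" or "threshold".
    gap_open / gap_extend: penalties (linear schemes use gap_open per
    skipped position and ignore gap_extend).
    d0: TM-align distance scale in Å (None -> derive from the shorter
    length via :func:`tmalign_d0`).
    d: distance cutoff in Å for the threshold scheme.
    """

    scheme: str
    gap_open: float = 0.0
    gap_extend: float = 0.0
    d0: float | None = None
    d: float = 3.0

    @classmethod
    def structal(cls, gap: float = STRUCTAL_GAP) -> "ScoreParams":
        return cls(scheme="structal", gap_open=gap)

    @classmethod
    def tmalign(
        cls,
        gap_open: float = TMALIGN_GAP_OPEN,
        gap_extend: float = TMALIGN_GAP_EXTEND,
        d0: float | None = None,
    ) -> "ScoreParams":
        return cls(scheme="tmalign", gap_open=gap_open, gap_extend=gap_extend, d0=d0)

    @classmethod
    def threshold(cls, d: float = 3.0) -> "ScoreParams":
        return cls(scheme="threshold", d=d)


# ---------------------------------------------------------------------------
# score matrices
# ---------------------------------------------------------------------------

def _coords(x) -> np.ndarray:
    return x.coords if isinstance(x, Structure) else np.asarray(x, dtype=float)


def distance_matrix(a, b_hat) -> np.ndarray:
    """Euclidean Cα distance matrix d[i, j] between two (superposed) chains."""
    return cdist(_coords(a), _coords(b_hat))


def structal_score_matrix(a, b_hat) -> np.ndarray:
    """STRUCTAL similarity S(i,j) = 20 / (1 + d_ij^2 / 5); values in (0, 20]."""
    d = distance_matrix(a, b_hat)
    return 20.0 / (1.0 + d * d / 5.0)


def tmalign_d0(L: int) -> float:
    """Length-dependent TM distance scale: 1.24 (L-15)^(1/3) - 1.8 Å.

    L is the length of the shorter structure.  The cube root is real for
    L < 15 (negative radicand), and the result is floored at 0.5 Å, where
    the raw formula would be non-positive (L <= 17 or so): short chains
    must not yield a zero or negative scale.
    """
    if L < 1:
        raise ValueError("structure length must be >= 1")
    raw = 1.24 * float(np.cbrt(L - 15.0)) - 1.8
    return max(raw, D0_FLOOR)


def tmalign_score_matrix(a, b_hat, d0: float) -> np.ndarray:
    """TM-align similarity S(i,j) = 1 / (1 + (d_ij/d0)^2); values in (0, 1]."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    d = distance_matrix(a, b_hat)
    return 1.0 / (1.0 + (d / d0) ** 2)


# ---------------------------------------------------------------------------
# linear-gap DP
# ---------------------------------------------------------------------------

def dp_linear(S: np.ndarray, gap: float, scheme: str = "linear") -> Alignment:
    """Global DP with a linear penalty of ``gap`` per skipped position.

    Implements  D(i,j) = max(D(i-1,j-1) + S(i,j), D(i-1,j) - gap,
    D(i,j-1) - gap)  with zero boundary D(i,0) = D(0,j) = 0 and returns a
    traceback alignment achieving D(m, n).
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        return Alignment((), 0.0, scheme)
    m, n = S.shape
    gap = float(gap)

    D = np.zeros((m + 1, n + 1))
    js = np.arange(n)  # decay-scan helper: D_j = cummax(T_j + g*j) - g*j
    for i in range(1, m + 1):
        T = np.maximum(D[i - 1, :-1] + S[i - 1], D[i - 1, 1:] - gap)
        if gap == 0.0:
            D[i, 1:] = np.maximum.accumulate(T)
        else:
            D[i, 1:] = np.maximum.accumulate(T + gap * js) - gap * js
            np.maximum(D[i, 1:], T, out=D[i, 1:])  # avoid cummax round-off

    pairs: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 and j > 0:
        v = D[i, j]
        if v <= D[i - 1, j - 1] + S[i - 1, j - 1] + _TIE_TOL:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif v <= D[i - 1, j] - gap + _TIE_TOL:
            i -= 1
        elif v <= D[i, j - 1] - gap + _TIE_TOL:
            j -= 1
        else:  # pragma: no cover - would indicate a broken forward pass
            raise AssertionError("linear DP traceback lost the optimal path")
    pairs.reverse()
    return Alignment(tuple(pairs), float(D[m, n]), scheme)


# ---------------------------------------------------------------------------
# affine-gap DP (Gotoh three-state)
# ---------------------------------------------------------------------------

def dp_affine(
    S: np.ndarray, open_: float, extend: float, scheme: str = "affine"
) -> Alignment:
    """Global Gotoh DP: each gap run costs ``open_ + extend * (len - 1)``.

    States: M (i matched to j), Ix (skipping in a), Iy (skipping in b).
    Leading skips along either edge are free, matching the zero-boundary
    convention of the linear program; switching gap direction mid-run opens
    a new run.  The empty alignment (score 0) is always admissible.
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        return Alignment((), 0.0, scheme)
    m, n = S.shape
    open_ = float(open_)
    extend = float(extend)

    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)
    Iy = np.full((m + 1, n + 1), _NEG)
    M[0, 0] = 0.0
    Ix[:, 0] = 0.0  # free run down the left edge (leading skip in a)
    Iy[0, :] = 0.0  # free run along the top edge (leading skip in b)

    js = np.arange(n)
    for i in range(1, m + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1] + best_prev[:-1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) - open_,
            Ix[i - 1, 1:] - extend,
        )
        # horizontal state: scan within the row, runs decay by `extend`
        P = np.maximum(M[i, :-1], Ix[i, :-1])  # run start at column k
        Q = P + extend * js
        Iy[i, 1:] = np.maximum.accumulate(Q) - open_ - extend * js

    final = max(M[m, n], Ix[m, n], Iy[m, n], 0.0)
    if final <= _TIE_TOL and final >= -_TIE_TOL and final == 0.0 and max(
        M[m, n], Ix[m, n], Iy[m, n]
    ) < -_TIE_TOL:
        return Alignment((), 0.0, scheme)

    # state traceback; priority M (diagonal) > Ix (up) > Iy (left)
    i, j = m, n
    if M[i, j] >= final - _TIE_TOL:
        state = "M"
    elif Ix[i, j] >= final - _TIE_TOL:
        state = "X"
    else:
        state = "Y"
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            v = M[i, j] - S[i - 1, j - 1]
            i -= 1
            j -= 1
            if i == 0 or j == 0:
                break
            if M[i, j] >= v - _TIE_TOL:
                state = "M"
            elif Ix[i, j] >= v - _TIE_TOL:
                state = "X"
            elif Iy[i, j] >= v - _TIE_TOL:
                state = "Y"
            else:  # boundary-start match (leading free edge)
                break
        elif state == "X":
            v = Ix[i, j]
            if M[i - 1, j] - open_ >= v - _TIE_TOL:
                state = "M"
            elif Ix[i - 1, j] - extend >= v - _TIE_TOL:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # "Y"
            v = Iy[i, j]
            if M[i, j - 1] - open_ >= v - _TIE_TOL:
                state = "M"
            elif Iy[i, j - 1] - extend >= v - _TIE_TOL:
                state = "Y"
            else:
                state = "X"
            j -= 1
    pairs.reverse()
    return Alignment(tuple(pairs), float(final), scheme)


# ---------------------------------------------------------------------------
# threshold-pair DP (the CA <= d building block)
# ---------------------------------------------------------------------------

def numpairs_dp(a, b_hat, d: float) -> Alignment:
    """Maximum-cardinality sequential pairing with every pair within d Å.

    Pure counting DP: a cell (i, j) may only be matched when
    ``||a_i - b_j|| <= d`` ("never match" elsewhere — no -inf arithmetic),
    gaps are free, and the score is the integer pair count.
    """
    if d <= 0:
        raise ValueError("distance cutoff d must be positive")
    A = _coords(a)
    B = _coords(b_hat)
    if len(A) == 0 or len(B) == 0:
        return Alignment((), 0.0, "threshold")
    allowed = cdist(A, B) <= d
    m, n = allowed.shape

    D = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        T = np.where(allowed[i - 1], D[i - 1, :-1] + 1, -1)
        np.maximum(T, D[i - 1, 1:], out=T)
        D[i, 1:] = np.maximum.accumulate(T)

    pairs: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 and j > 0:
        v = D[i, j]
        if allowed[i - 1, j - 1] and v == D[i - 1, j - 1] + 1:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif v == D[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return Alignment(tuple(pairs), float(D[m, n]), "threshold")


# ---------------------------------------------------------------------------
# STRUCTAL total score (the reported objective)
# ---------------------------------------------------------------------------

def count_gap_positions(
    pairs: tuple[tuple[int, int], ...], m: int, n: int, convention: str = "recurrence"
) -> int:
    """Number of penalized skipped positions for an alignment of an m-vs-n pair.

    convention:
      "recurrence" (default) — exactly what the zero-boundary DP charges:
        min(i1, j1) leading skips, all interior skips, all trailing skips;
      "interior" — only skips strictly between matched pairs.
    """
    if not pairs:
        return 0
    interior = 0
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        interior += (i1 - i0 - 1) + (j1 - j0 - 1)
    if convention == "interior":
        return interior
    if convention != "recurrence":
        raise ValueError(f"unknown gap convention: {convention!r}")
    leading = min(pairs[0][0], pairs[0][1])
    trailing = (m - 1 - pairs[-1][0]) + (n - 1 - pairs[-1][1])
    return leading + interior + trailing


def count_gap_runs(
    pairs: tuple[tuple[int, int], ...], m: int, n: int
) -> tuple[int, int]:
    """(number of charged gap runs, total charged gapped positions) under the
    affine convention matching :func:`dp_affine`: a leading double-sided skip
    is one charged run on the cheaper side; interior/trailing skips charge
    one run per side that has skips."""
    if not pairs:
        return 0, 0
    runs = 0
    positions = 0
    lead = min(pairs[0][0], pairs[0][1])
    if lead > 0:
        runs += 1
        positions += lead
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        for dlen in (i1 - i0 - 1, j1 - j0 - 1):
            if dlen > 0:
                runs += 1
                positions += dlen
    for dlen in (m - 1 - pairs[-1][0], n - 1 - pairs[-1][1]):
        if dlen > 0:
            runs += 1
            positions += dlen
    return runs, positions


def structal_total_score(
    al: Alignment, a, b_hat, gap: float = STRUCTAL_GAP, convention: str = "recurrence"
) -> float:
    """STRUCTAL objective: sum of 20/(1 + d^2/5) over aligned pairs minus
    ``gap`` per penalized skipped position (convention as in
    :func:`count_gap_positions`)."""
    A = _coords(a)
    B = _coords(b_hat)
    if not al.pairs:
        return 0.0
    li = np.fromiter((i for i, _ in al.pairs), dtype=int)
    rj = np.fromiter((j for _, j in al.pairs), dtype=int)
    dsq = np.sum((A[li] - B[rj]) ** 2, axis=1)
    pair_sum = float(np.sum(20.0 / (1.0 + dsq / 5.0)))
    G = count_gap_positions(al.pairs, len(A), len(B), convention)
    return pair_sum - gap * G


# ---------------------------------------------------------------------------
# exhaustive small-instance oracles
# ---------------------------------------------------------------------------

def enumerate_monotone_alignments(m: int, n: int):
    """Yield every strictly monotone pairing of [0, m) x [0, n), including
    the empty one.  Intended for m, n <= ~7 (the count grows like C(m+n, m))."""
    rows = range(m)
    cols = range(n)
    yield ()
    for k in range(1, min(m, n) + 1):
        for ri in combinations(rows, k):
            for cj in combinations(cols, k):
                yield tuple(zip(ri, cj))


def _pair_sum(S: np.ndarray, pairs) -> float:
    return float(sum(S[i, j] for i, j in pairs))


def brute_force_linear(S: np.ndarray, gap: float) -> float:
    """Best achievable linear-gap score by exhaustive enumeration."""
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    best = 0.0
    for pairs in enumerate_monotone_alignments(m, n):
        sc = _pair_sum(S, pairs) - gap * count_gap_positions(pairs, m, n)
        if sc > best:
            best = sc
    return best


def brute_force_affine(S: np.ndarray, open_: float, extend: float) -> float:
    """Best achievable affine-gap score by exhaustive enumeration."""
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    best = 0.0
    for pairs in enumerate_monotone_alignments(m, n):
        runs, positions = count_gap_runs(pairs, m, n)
        sc = _pair_sum(S, pairs) - open_ * runs - extend * (positions - runs)
        if sc > best:
            best = sc
    return best


def brute_force_numpairs(a, b_hat, d: float) -> int:
    """Largest monotone pairing with all pair distances <= d, by enumeration."""
    allowed = cdist(_coords(a), _coords(b_hat)) <= d
    m, n = allowed.shape
    best = 0
    for pairs in enumerate_monotone_alignments(m, n):
        if len(pairs) > best and all(allowed[i, j] for i, j in pairs):
            best = len(pairs)
    return best
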