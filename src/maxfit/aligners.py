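"""The three heuristic aligners: STRUCTAL, TM-align-style, and LOCK2.

Each method is the composition of (i) a source of initial superpositions,
(ii) an alignment step that is exactly optimal for its scoring scheme given
the superposition (a DP from :mod:`maxfit.align_engine`), and (iii) a
least-squares superposition step on the aligned pairs, iterated to a fixed
point:

* STRUCTAL alternates the 20/(1 + d^2/5) score matrix + linear-gap DP
  (penalty 10) with cRMS-minimizing superposition;
* the TM-align-style aligner alternates the 1/(1 + (d/d0)^2) matrix +
  affine DP (open 0.6, extend 0.0) with superposition, d0 fixed from the
  shorter chain length;
* LOCK2 refines a superposition by alternating mutual-nearest-neighbor
  pairing within 3 Å with quaternion/SVD superposition, then emits as its
  final alignment the largest subset of mutual-NN pairs that is sequential
  ("colinear": both index sequences strictly increasing).

Published initial-superposition heuristics (e.g. LOCK2's secondary-structure
vector matching) are replaced by a shared, deterministic fragment-pair
seeding; the iteration itself is the published procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .align_engine import (
    Alignment,
    STRUCTAL_GAP,
    TMALIGN_GAP_EXTEND,
    TMALIGN_GAP_OPEN,
    dp_affine,
    dp_linear,
    structal_score_matrix,
    structal_total_score,
    tmalign_d0,
    tmalign_score_matrix,
)
from .geometry import Transform, crms, superpose_lsq
from .structio import Structure

__all__ = [
    "IterationTrace",
    "AlignerResult",
    "seed_superpositions",
    "structal_align",
    "tmscore_align",
    "tmalign_align",
    "lock2_refine",
    "lock2_final_alignment",
    "lock2_align",
    "MAX_ITERATIONS",
]

MAX_ITERATIONS = 100  # iteration cap for every alternating loop


@dataclass(frozen=True)
class IterationTrace:
    """Per-iteration record of an alternating alignment/superposition loop.

    ``records`` holds one (alignment length, scheme score, cRMS of the
    aligned pairs) triple per iteration; ``converged`` is True when the
    loop reached a fixed point (the pair set repeated) rather than the
    iteration cap; ``stopped_empty`` marks a loop abandoned because no
    pairs survived the pairing step.
    """

    records: tuple[tuple[int, float, float], ...]
    converged: bool
    stopped_empty: bool = False

    @property
    def iterations(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class AlignerResult:
    """Final alignment, the superposition it was computed on, and the trace."""

    alignment: Alignment
    transform: Transform
    trace: IterationTrace

    @property
    def no_alignment(self) -> bool:
        return len(self.alignment) == 0


# ---------------------------------------------------------------------------
# fragment-pair seeding
# ---------------------------------------------------------------------------

def seed_superpositions(
    a: Structure,
    b: Structure,
    k: int = 8,
    stride: int = 4,
    dedupe_angle_deg: float = 2.0,
    dedupe_translation: float = 1.0,
    include_identity: bool = True,
) -> list[Transform]:
    """Initial superpositions from superposing all length-k fragment pairs.

    Fragments start at multiples of ``stride`` in each chain (the final
    window is always included); each fragment pair yields the least-squares
    transform of b's fragment onto a's.  Near-duplicate transforms (within
    ``dedupe_angle_deg`` of rotation and ``dedupe_translation`` Å of
    translation of an earlier seed) are dropped.  Order is deterministic.
    """
    m, n = len(a), len(b)
    if m < k or n < k:
        raise ValueError(f"both structures must have at least k={k} residues")
    starts_a = sorted(set(range(0, m - k + 1, stride)) | {m - k})
    starts_b = sorted(set(range(0, n - k + 1, stride)) | {n - k})

    seeds: list[Transform] = []
    if include_identity:
        seeds.append(Transform.identity())
    for ia in starts_a:
        fa = a.coords[ia : ia + k]
        for jb in starts_b:
            fb = b.coords[jb : jb + k]
            t = superpose_lsq(fa, fb).transform
            dup = any(
                t.rotation_angle_deg(s) < dedupe_angle_deg
                and np.linalg.norm(t.translation - s.translation)
                < dedupe_translation
                for s in seeds
            )
            if not dup:
                seeds.append(t)
    return seeds


def _superpose_pairs(
    a: Structure, b: Structure, pairs: tuple[tuple[int, int], ...], method: str
):
    li = np.fromiter((i for i, _ in pairs), dtype=int)
    rj = np.fromiter((j for _, j in pairs), dtype=int)
    return superpose_lsq(a.coords[li], b.coords[rj], method=method)


# ---------------------------------------------------------------------------
# STRUCTAL
# ---------------------------------------------------------------------------

def _structal_one_seed(
    a: Structure, b: Structure, seed: Transform, gap: float, max_iter: int
) -> AlignerResult:
    t = seed
    records: list[tuple[int, float, float]] = []
    seen: set[tuple[tuple[int, int], ...]] = set()
    alignment = Alignment((), 0.0, "structal")
    converged = False
    stopped_empty = False
    for _ in range(max_iter):
        b_hat = b.transformed(t)
        S = structal_score_matrix(a, b_hat)
        alignment = dp_linear(S, gap, scheme="structal")
        if not alignment.pairs:
            stopped_empty = True
            break
        if alignment.pairs in seen:  # fixed point (or cycle) reached
            converged = True
            break
        seen.add(alignment.pairs)
        sup = _superpose_pairs(a, b, alignment.pairs, "kabsch")
        t = sup.transform
        records.append((len(alignment), alignment.score, sup.crms))
    final_score = structal_total_score(alignment, a, b.transformed(t), gap=gap)
    alignment = Alignment(alignment.pairs, final_score, "structal")
    return AlignerResult(
        alignment,
        t,
        IterationTrace(tuple(records) or ((0, 0.0, float("nan")),),
                       converged, stopped_empty),
    )


def structal_align(
    a: Structure,
    b: Structure,
    seeds: list[Transform] | None = None,
    gap: float = STRUCTAL_GAP,
    max_iter: int = MAX_ITERATIONS,
) -> AlignerResult:
    """STRUCTAL: iterative DP from every seed; best final total score wins.

    From each seed the loop alternates [score matrix on the current
    superposition -> linear-gap DP -> least-squares superposition of the
    aligned pairs] until the alignment repeats or ``max_iter`` is hit.  The
    reported score is the STRUCTAL objective (pair scores minus 10 per
    penalized skipped position) recomputed on the returned alignment and
    transform.  Ties between seeds go to the earlier seed.
    """
    if len(a) < 3 or len(b) < 3:
        raise ValueError("structures must have at least 3 residues")
    if seeds is None:
        seeds = seed_superpositions(a, b)
    if not seeds:
        raise ValueError("at least one seed superposition is required")
    best: AlignerResult | None = None
    for seed in seeds:
        res = _structal_one_seed(a, b, seed, gap, max_iter)
        if res.no_alignment:
            continue
        if best is None or res.alignment.score > best.alignment.score:
            best = res
    if best is None:  # no seed produced a single aligned pair
        return AlignerResult(
            Alignment((), 0.0, "structal"),
            seeds[0],
            IterationTrace(((0, 0.0, float("nan")),), False, True),
        )
    return best


# ---------------------------------------------------------------------------
# TM-align-style scoring alignment
# ---------------------------------------------------------------------------

def tmscore_align(
    a: Structure,
    b: Structure,
    t: Transform,
    gap_open: float = TMALIGN_GAP_OPEN,
    gap_extend: float = TMALIGN_GAP_EXTEND,
    refine: bool = False,
    max_iter: int = MAX_ITERATIONS,
) -> Alignment:
    """TM-align scoring alignment on a *given* superposition.

    Applies ``t`` to b, derives d0 from the shorter length, builds the
    1/(1+(d/d0)^2) matrix and runs the affine DP.  The superposition is not
    re-estimated (the deep-search protocol hands each method a fixed
    transform); pass ``refine=True`` to iterate alignment/superposition to a
    fixed point instead, emulating a stand-alone run.
    """
    d0 = tmalign_d0(min(len(a), len(b)))
    if not refine:
        S = tmalign_score_matrix(a, b.transformed(t), d0)
        return dp_affine(S, gap_open, gap_extend, scheme="tmalign")
    return _tmalign_one_seed(a, b, t, d0, gap_open, gap_extend, max_iter).alignment


def _tmalign_one_seed(
    a: Structure,
    b: Structure,
    seed: Transform,
    d0: float,
    gap_open: float,
    gap_extend: float,
    max_iter: int,
) -> AlignerResult:
    t = seed
    records: list[tuple[int, float, float]] = []
    seen: set[tuple[tuple[int, int], ...]] = set()
    alignment = Alignment((), 0.0, "tmalign")
    converged = False
    stopped_empty = False
    for _ in range(max_iter):
        S = tmalign_score_matrix(a, b.transformed(t), d0)
        alignment = dp_affine(S, gap_open, gap_extend, scheme="tmalign")
        if not alignment.pairs:
            stopped_empty = True
            break
        if alignment.pairs in seen:
            converged = True
            break
        seen.add(alignment.pairs)
        sup = _superpose_pairs(a, b, alignment.pairs, "kabsch")
        t = sup.transform
        records.append((len(alignment), alignment.score, sup.crms))
    # report the score on the final superposition
    S = tmalign_score_matrix(a, b.transformed(t), d0)
    alignment = dp_affine(S, gap_open, gap_extend, scheme="tmalign")
    return AlignerResult(
        alignment,
        t,
        IterationTrace(tuple(records) or ((0, 0.0, float("nan")),),
                       converged, stopped_empty),
    )


def tmalign_align(
    a: Structure,
    b: Structure,
    seeds: list[Transform] | None = None,
    gap_open: float = TMALIGN_GAP_OPEN,
    gap_extend: float = TMALIGN_GAP_EXTEND,
    max_iter: int = MAX_ITERATIONS,
) -> AlignerResult:
    """Stand-alone TM-align-style run: iterate from every seed, keep the
    seed whose final affine score is highest (ties to the earlier seed)."""
    if len(a) < 3 or len(b) < 3:
        raise ValueError("structures must have at least 3 residues")
    if seeds is None:
        seeds = seed_superpositions(a, b)
    d0 = tmalign_d0(min(len(a), len(b)))
    best: AlignerResult | None = None
    for seed in seeds:
        res = _tmalign_one_seed(a, b, seed, d0, gap_open, gap_extend, max_iter)
        if len(res.alignment) == 0:
            continue
        if best is None or res.alignment.score > best.alignment.score:
            best = res
    if best is None:
        return AlignerResult(
            Alignment((), 0.0, "tmalign"),
            seeds[0],
            IterationTrace(((0, 0.0, float("nan")),), False, True),
        )
    return best


# ---------------------------------------------------------------------------
# LOCK2
# ---------------------------------------------------------------------------

def mutual_nearest_pairs(
    a: Structure, b_hat: Structure, d: float
) -> tuple[tuple[int, int], ...]:
    """Pairs (i, j) with j the nearest b-residue to a_i within d Å and vice
    versa.  Equidistant neighbors resolve to the lower index."""
    D = cdist(a.coords, b_hat.coords)
    nn_of_a = np.argmin(D, axis=1)  # ties -> lower index
    nn_of_b = np.argmin(D, axis=0)
    out = [
        (int(i), int(j))
        for i, j in enumerate(nn_of_a)
        if nn_of_b[j] == i and D[i, j] <= d
    ]
    return tuple(out)


def lock2_refine(
    a: Structure,
    b: Structure,
    init: Transform,
    d: float = 3.0,
    max_iter: int = MAX_ITERATIONS,
    method: str = "quaternion",
) -> tuple[Transform, IterationTrace]:
    """LOCK2 RMSD refinement: alternate mutual-NN pairing within d with
    least-squares superposition until the pair set stabilizes.

    If some iteration finds no pairs within d, the loop stops and the last
    valid transform is returned with ``stopped_empty`` set.
    """
    t = init
    records: list[tuple[int, float, float]] = []
    seen: set[tuple[tuple[int, int], ...]] = set()
    converged = False
    stopped_empty = False
    for _ in range(max_iter):
        pairs = mutual_nearest_pairs(a, b.transformed(t), d)
        if not pairs:
            stopped_empty = True
            break
        if pairs in seen:
            converged = True
            break
        seen.add(pairs)
        sup = _superpose_pairs(a, b, pairs, method)
        t = sup.transform
        records.append((len(pairs), sup.crms, sup.crms))
    return t, IterationTrace(
        tuple(records) or ((0, float("nan"), float("nan")),),
        converged,
        stopped_empty,
    )


def lock2_final_alignment(
    a: Structure, b_hat: Structure, d: float = 3.0
) -> Alignment:
    """LOCK2's final alignment on a superposed pair.

    Step 1 collects mutual-nearest-neighbor pairs within d Å; step 2 keeps
    the maximum-cardinality subset that is sequential (both index sequences
    strictly increasing), i.e. removes pairs violating colinearity.  Among
    equal-cardinality subsets the one with the smaller total pair distance
    wins.  The score is the pair count.  May be empty.
    """
    cand = mutual_nearest_pairs(a, b_hat, d)
    if not cand:
        return Alignment((), 0.0, "lock2")
    D = cdist(a.coords, b_hat.coords)
    cand = tuple(sorted(cand))  # mutual-NN pairs have distinct i and j

    # longest "increasing subsequence" over pairs; value = (count, -distance)
    P = len(cand)
    count = [1] * P
    dist = [float(D[i, j]) for i, j in cand]
    prev = [-1] * P
    for p in range(P):
        ip, jp = cand[p]
        for q in range(p):
            iq, jq = cand[q]
            if iq < ip and jq < jp:
                c = count[q] + 1
                dd = dist[q] + float(D[ip, jp])
                if c > count[p] or (c == count[p] and dd < dist[p]):
                    count[p] = c
                    dist[p] = dd
                    prev[p] = q
    best_p = 0
    for p in range(1, P):
        if count[p] > count[best_p] or (
            count[p] == count[best_p] and dist[p] < dist[best_p]
        ):
            best_p = p
    chain: list[tuple[int, int]] = []
    p = best_p
    while p != -1:
        chain.append(cand[p])
        p = prev[p]
    chain.reverse()
    return Alignment(tuple(chain), float(len(chain)), "lock2")


def lock2_align(
    a: Structure,
    b: Structure,
    seeds: list[Transform] | None = None,
    d: float = 3.0,
    max_iter: int = MAX_ITERATIONS,
) -> AlignerResult:
    """Stand-alone LOCK2 run: refine every seed, keep the transform with the
    most final-alignment pairs (ties: lower cRMS of those pairs, then the
    earlier seed), and emit its colinearity-filtered alignment."""
    if len(a) < 3 or len(b) < 3:
        raise ValueError("structures must have at least 3 residues")
    if seeds is None:
        seeds = seed_superpositions(a, b)
    best: tuple[int, float] | None = None
    best_res: AlignerResult | None = None
    for seed in seeds:
        t, trace = lock2_refine(a, b, seed, d=d, max_iter=max_iter)
        al = lock2_final_alignment(a, b.transformed(t), d=d)
        if not al.pairs:
            continue
        li = np.fromiter((i for i, _ in al.pairs), dtype=int)
        rj = np.fromiter((j for _, j in al.pairs), dtype=int)
        c = crms(a.coords[li], b.transformed(t).coords[rj])
        key = (-len(al), c)
        if best is None or key < best:
            best = key
            best_res = AlignerResult(al, t, trace)
    if best_res is None:
        return AlignerResult(
            Alignment((), 0.0, "lock2"),
            seeds[0],
            IterationTrace(((0, float("nan"), float("nan")),), False, True),
        )
    return best_res
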