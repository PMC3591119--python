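"""Alignment-quality measures.

Given an alignment of chains a and b and the superposition it was computed
on, the standard quality measures are:

* NumPairs(d) — the number of *aligned* pairs at distance <= d Å (method-
  specific; bounded above by the alignment-independent CA <= d count for
  the same superposition);
* SI, the Similarity Index — cRMS x min(L(a), L(b)) / Nmat, where Nmat is
  the number of aligned pairs; lower is better;
* PSI(d) — NumPairs(d) / min(L(a), L(b)), the fraction of the shorter
  chain matched within d;
* shift agreement against a gold-standard reference alignment — for a
  tolerance s, I_s counts test pairs (i, j) whose a-residue the reference
  aligns to some j' with |j - j'| <= s; the curve reports I_s / L_ref, and
  s = 0 is exact agreement.  Test pairs whose a-residue the reference does
  not align never count, measured a -> b.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .align_engine import Alignment
from .geometry import crms
from .structio import ReferenceAlignment, Structure

__all__ = [
    "QualityReport",
    "AgreementCurve",
    "numpairs",
    "similarity_index",
    "psi",
    "shift_agreement",
    "quality_report",
]


@dataclass(frozen=True)
class QualityReport:
    """All per-alignment quality measures at one cutoff d."""

    numpairs_d: int
    si: float | None  # None when the alignment is empty (SI undefined)
    psi_d: float
    crms_aligned: float | None
    nmat: int
    length_a: int
    length_b: int
    d: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class AgreementCurve:
    """I_s / L_ref for s = 0 .. s_max; nondecreasing, values in [0, 1]."""

    shifts: tuple[int, ...]
    values: tuple[float, ...]
    l_ref: int

    def __post_init__(self) -> None:
        if len(self.shifts) != len(self.values):
            raise ValueError("shifts and values must have equal length")

    def at(self, s: int) -> float:
        return self.values[self.shifts.index(s)]

    def to_dict(self) -> dict:
        return {"shifts": list(self.shifts), "values": list(self.values),
                "l_ref": self.l_ref}


def _pair_distances(al: Alignment, a: Structure, b_hat: Structure) -> np.ndarray:
    li = np.fromiter((i for i, _ in al.pairs), dtype=int)
    rj = np.fromiter((j for _, j in al.pairs), dtype=int)
    return np.linalg.norm(a.coords[li] - b_hat.coords[rj], axis=1)


def numpairs(al: Alignment, a: Structure, b_hat: Structure, d: float) -> int:
    """Aligned pairs at distance <= d Å after superposition."""
    if not al.pairs:
        return 0
    return int(np.count_nonzero(_pair_distances(al, a, b_hat) <= d))


def similarity_index(
    al: Alignment, a: Structure, b_hat: Structure
) -> float | None:
    """SI = cRMS(aligned pairs) x min(L(a), L(b)) / Nmat; None if empty."""
    if not al.pairs:
        return None
    li = np.fromiter((i for i, _ in al.pairs), dtype=int)
    rj = np.fromiter((j for _, j in al.pairs), dtype=int)
    c = crms(a.coords[li], b_hat.coords[rj])
    return c * min(len(a), len(b_hat)) / len(al)


def psi(al: Alignment, a: Structure, b_hat: Structure, d: float) -> float:
    """PSI(d) = NumPairs(d) / min(L(a), L(b)), in [0, 1]."""
    return numpairs(al, a, b_hat, d) / min(len(a), len(b_hat))


def shift_agreement(
    test: Alignment, ref: ReferenceAlignment, s_max: int = 10
) -> AgreementCurve:
    """Agreement curve I_s / L_ref of a test alignment with a reference.

    Raises ``ValueError`` for an empty reference (the ratio is undefined;
    callers report the value as absent rather than 0).
    """
    if len(ref) == 0:
        raise ValueError("shift agreement is undefined for an empty reference")
    ref_map = {i: j for i, j in ref.pairs}
    shifts_hit = [
        abs(j - ref_map[i]) for i, j in test.pairs if i in ref_map
    ]
    shifts = tuple(range(s_max + 1))
    values = tuple(
        sum(1 for sh in shifts_hit if sh <= s) / len(ref) for s in shifts
    )
    return AgreementCurve(shifts, values, len(ref))


def quality_report(
    al: Alignment, a: Structure, b_hat: Structure, d: float = 3.0
) -> QualityReport:
    """Bundle NumPairs(d), SI, PSI(d) and aligned cRMS into one record."""
    if al.pairs:
        li = np.fromiter((i for i, _ in al.pairs), dtype=int)
        rj = np.fromiter((j for _, j in al.pairs), dtype=int)
        crms_aligned = crms(a.coords[li], b_hat.coords[rj])
    else:
        crms_aligned = None
    return QualityReport(
        numpairs_d=numpairs(al, a, b_hat, d),
        si=similarity_index(al, a, b_hat),
        psi_d=psi(al, a, b_hat, d),
        crms_aligned=crms_aligned,
        nmat=len(al),
        length_a=len(a),
        length_b=len(b_hat),
        d=d,
    )
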