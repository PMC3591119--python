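"""Alignment-quality measures: NumPairs, SI, PSI, shift agreement."""

import numpy as np
import pytest

from maxfit.align_engine import Alignment
from maxfit.metrics import (
    numpairs,
    psi,
    quality_report,
    shift_agreement,
    similarity_index,
)
from maxfit.structio import ReferenceAlignment, Structure


def line_structure(n, spacing=3.8, offset=(0.0, 0.0, 0.0), cid="L"):
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    coords += np.asarray(offset)
    return Structure(
        id=cid, chain_id="A",
        residue_numbers=tuple(range(1, n + 1)),
        insertion_codes=(" ",) * n,
        amino_acids="A" * n,
        coords=coords,
    )


def structure_with_pair_offsets(offsets):
    """(a, b) of equal length whose i-th aligned pair is |offsets[i]| apart."""
    n = len(offsets)
    a = line_structure(n, spacing=30.0)
    b_coords = a.coords.copy()
    b_coords[:, 1] += np.asarray(offsets, dtype=float)
    b = Structure(
        id="B", chain_id="B",
        residue_numbers=a.residue_numbers,
        insertion_codes=a.insertion_codes,
        amino_acids=a.amino_acids,
        coords=b_coords,
    )
    return a, b


def full_alignment(n):
    return Alignment(tuple((i, i) for i in range(n)), 0.0, "test")


class TestNumpairs:
    def test_all_pairs_at_zero_distance(self):
        a, b = structure_with_pair_offsets([0.0] * 5)
        assert numpairs(full_alignment(5), a, b, 3.0) == 5

    def test_cutoff_below_every_distance(self):
        a, b = structure_with_pair_offsets([2.0, 2.0, 2.0])
        assert numpairs(full_alignment(3), a, b, 1.0) == 0

    def test_mixed_distances_counted_directly(self):
        a, b = structure_with_pair_offsets([1.0, 2.5, 3.5])
        assert numpairs(full_alignment(3), a, b, 3.0) == 2


class TestSimilarityIndex:
    def test_worked_value(self):
        # cRMS 2 Å over 50 pairs, shorter length 100 -> SI = 2*100/50 = 4
        a, b = structure_with_pair_offsets([2.0] * 50)
        a100 = line_structure(100, spacing=30.0)
        b_hat = b  # only aligned pairs enter cRMS
        al = full_alignment(50)
        assert similarity_index(al, a100, b_hat) is not None
        # build explicitly: alignment of 50 pairs on 100-vs-50 structures
        si = similarity_index(al, a100, b_hat)
        assert si == pytest.approx(2.0 * 50 / 50)  # min(L)=50 here
        # with both lengths 100 the classic worked value appears
        b100_coords = a100.coords.copy()
        b100_coords[:50, 1] += 2.0
        b100_coords[50:, 1] += 500.0
        b100 = Structure(
            id="B", chain_id="B",
            residue_numbers=a100.residue_numbers,
            insertion_codes=a100.insertion_codes,
            amino_acids=a100.amino_acids,
            coords=b100_coords,
        )
        assert similarity_index(full_alignment(50), a100, b100) == pytest.approx(4.0)

    def test_perfect_self_alignment_is_zero(self):
        a, b = structure_with_pair_offsets([0.0] * 10)
        assert similarity_index(full_alignment(10), a, b) == 0.0

    def test_halves_when_nmat_doubles(self):
        a, b = structure_with_pair_offsets([2.0] * 40)
        si20 = similarity_index(full_alignment(20), a, b)
        si40 = similarity_index(full_alignment(40), a, b)
        assert si40 == pytest.approx(si20 / 2)

    def test_empty_alignment_reported_absent(self):
        a, b = structure_with_pair_offsets([0.0] * 5)
        assert similarity_index(Alignment((), 0.0, "t"), a, b) is None


class TestPsi:
    def test_ratio_of_numpairs_to_shorter_length(self):
        a, b = structure_with_pair_offsets([0.0] * 30 + [99.0] * 30)
        assert psi(full_alignment(60), a, b, 3.0) == pytest.approx(0.5)

    def test_full_length_perfect_alignment(self):
        a, b = structure_with_pair_offsets([0.0] * 12)
        assert psi(full_alignment(12), a, b, 3.0) == 1.0

    def test_empty_alignment(self):
        a, b = structure_with_pair_offsets([0.0] * 12)
        assert psi(Alignment((), 0.0, "t"), a, b, 3.0) == 0.0


class TestShiftAgreement:
    def test_reference_against_itself(self):
        ref = ReferenceAlignment(tuple((i, i) for i in range(10)))
        test = Alignment(ref.pairs, 0.0, "t")
        curve = shift_agreement(test, ref, s_max=3)
        assert curve.at(0) == 1.0

    def test_uniform_shift_by_one(self):
        ref = ReferenceAlignment(tuple((i, i) for i in range(10)))
        test = Alignment(tuple((i, i + 1) for i in range(9)), 0.0, "t")
        curve = shift_agreement(test, ref, s_max=2)
        assert curve.at(0) == 0.0
        assert curve.at(1) == pytest.approx(0.9)  # 9 of L_ref=10

    def test_pairs_absent_from_reference_never_count(self):
        ref = ReferenceAlignment(((0, 0), (2, 2)))
        test = Alignment(((0, 0), (1, 1), (2, 2)), 0.0, "t")
        curve = shift_agreement(test, ref, s_max=5)
        assert curve.at(0) == 1.0  # both reference rows reproduced
        assert curve.at(5) == 1.0  # (1,1) has no reference row; never counted

    def test_empty_reference_undefined(self):
        with pytest.raises(ValueError):
            shift_agreement(Alignment(((0, 0),), 0.0, "t"),
                            ReferenceAlignment(()))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_by_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)

        def random_monotone(n, m, k):
            li = sorted(rng.choice(n, size=k, replace=False))
            rj = sorted(rng.choice(m, size=k, replace=False))
            return tuple(zip(map(int, li), map(int, rj)))

        ref_pairs = random_monotone(10, 10, 6)
        test_pairs = random_monotone(10, 10, 7)
        ref = ReferenceAlignment(ref_pairs)
        test = Alignment(test_pairs, 0.0, "t")
        curve = shift_agreement(test, ref, s_max=4)
        ref_map = dict(ref_pairs)
        for s in range(5):
            expected = sum(
                1 for i, j in test_pairs
                if i in ref_map and abs(j - ref_map[i]) <= s
            ) / len(ref_pairs)
            assert curve.at(s) == pytest.approx(expected)

    def test_curve_nondecreasing(self):
        ref = ReferenceAlignment(tuple((i, i) for i in range(8)))
        test = Alignment(tuple((i, min(7, i + i % 3)) for i in range(0, 8, 2)),
                         0.0, "t")
        curve = shift_agreement(test, ref, s_max=6)
        assert list(curve.values) == sorted(curve.values)
        assert all(0.0 <= v <= 1.0 for v in curve.values)


class TestQualityReport:
    def test_bundles_consistent_values(self):
        a, b = structure_with_pair_offsets([1.0, 2.5, 3.5, 0.0])
        q = quality_report(full_alignment(4), a, b, d=3.0)
        assert q.numpairs_d == 3
        assert q.psi_d == pytest.approx(3 / 4)
        assert q.nmat == 4
        assert q.numpairs_d <= q.nmat
        assert q.to_dict()["d"] == 3.0

    def test_si_scales_with_uniform_coordinate_scaling(self):
        a, b = structure_with_pair_offsets([2.0] * 10)
        q1 = similarity_index(full_alignment(10), a, b)
        a2 = Structure(a.id, a.chain_id, a.residue_numbers, a.insertion_codes,
                       a.amino_acids, a.coords * 3.0)
        b2 = Structure(b.id, b.chain_id, b.residue_numbers, b.insertion_codes,
                       b.amino_acids, b.coords * 3.0)
        q2 = similarity_index(full_alignment(10), a2, b2)
        assert q2 == pytest.approx(3.0 * q1)
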