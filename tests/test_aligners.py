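"""STRUCTAL, TM-align-style and LOCK2 aligners."""

import numpy as np
import pytest

from maxfit.align_engine import (
    brute_force_affine,
    brute_force_linear,
    dp_linear,
    structal_score_matrix,
    structal_total_score,
    tmalign_d0,
    tmalign_score_matrix,
)
from maxfit.aligners import (
    lock2_align,
    lock2_final_alignment,
    lock2_refine,
    mutual_nearest_pairs,
    seed_superpositions,
    structal_align,
    tmalign_align,
    tmscore_align,
)
from maxfit.geometry import Transform, crms, superpose_lsq
from maxfit.structio import Structure
from maxfit.synthetic import FixtureSpec, make_chain, make_pair

from conftest import rotation_about


def as_structure(coords, cid="T"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Structure(
        id=cid, chain_id="A",
        residue_numbers=tuple(range(1, n + 1)),
        insertion_codes=(" ",) * n,
        amino_acids="A" * n,
        coords=coords,
    )


class TestSeeds:
    def test_identity_seed_for_identical_structures(self, helix30):
        seeds = seed_superpositions(helix30, helix30)
        best = min(s.rotation_angle_deg() + np.linalg.norm(s.translation)
                   for s in seeds)
        assert best < 1e-6

    def test_seed_count_bounded_by_fragment_grid(self, helix30):
        k, stride = 8, 4
        seeds = seed_superpositions(helix30, helix30, k=k, stride=stride,
                                    include_identity=False)
        m = len(helix30)
        n_starts = len(set(range(0, m - k + 1, stride)) | {m - k})
        assert len(seeds) <= n_starts * n_starts

    def test_some_seed_near_planted_transform(self, mixed40_pair):
        fx = mixed40_pair
        seeds = seed_superpositions(fx.a, fx.b)
        best = min(s.rotation_angle_deg(fx.transform) for s in seeds)
        assert best < 10.0


class TestStructal:
    def test_self_alignment_of_rigid_copy(self, mixed40_pair):
        fx = mixed40_pair
        res = structal_align(fx.a, fx.b)
        assert res.alignment.pairs == fx.truth.pairs
        li = [i for i, _ in res.alignment.pairs]
        rj = [j for _, j in res.alignment.pairs]
        assert crms(fx.a.coords[li],
                    res.transform.apply(fx.b.coords[rj])) <= 1e-6

    def test_noisy_copy_recovered_with_crms_near_noise(self, noisy_pair):
        fx = noisy_pair
        res = structal_align(fx.a, fx.b)
        assert len(res.alignment) == len(fx.a)
        li = [i for i, _ in res.alignment.pairs]
        rj = [j for _, j in res.alignment.pairs]
        c = crms(fx.a.coords[li], res.transform.apply(fx.b.coords[rj]))
        sigma3 = fx.spec.noise_sigma * np.sqrt(3.0)  # E||noise|| scale
        assert c == pytest.approx(sigma3, abs=0.2 + sigma3)

    def test_reported_score_is_total_score_of_output(self, noisy_pair):
        fx = noisy_pair
        res = structal_align(fx.a, fx.b)
        recomputed = structal_total_score(
            res.alignment, fx.a, fx.b.transformed(res.transform)
        )
        assert res.alignment.score == pytest.approx(recomputed, abs=1e-9)

    def test_best_seed_beats_any_single_seed(self, decoy_pair):
        fx = decoy_pair
        seeds = seed_superpositions(fx.a, fx.b)
        full = structal_align(fx.a, fx.b, seeds=seeds)
        for single in seeds[:5]:
            one = structal_align(fx.a, fx.b, seeds=[single])
            assert full.alignment.score >= one.alignment.score - 1e-9

    def test_alignment_step_is_dp_optimal_for_fixed_superposition(self):
        rng = np.random.default_rng(42)
        a = as_structure(rng.uniform(0, 12, (6, 3)))
        b = as_structure(rng.uniform(0, 12, (5, 3)))
        S = structal_score_matrix(a, b)
        al = dp_linear(S, 10.0)
        assert al.score == pytest.approx(brute_force_linear(S, 10.0), abs=1e-9)


class TestTmscore:
    def test_identity_transform_on_identical_structures(self, helix30):
        al = tmscore_align(helix30, helix30, Transform.identity())
        assert al.pairs == tuple((i, i) for i in range(30))

    def test_score_recomputed_from_matrix_and_gap_runs(self, noisy_pair):
        fx = noisy_pair
        t = superpose_lsq(fx.a.coords, fx.b.coords).transform
        al = tmscore_align(fx.a, fx.b, t)
        d0 = tmalign_d0(min(len(fx.a), len(fx.b)))
        S = tmalign_score_matrix(fx.a, fx.b.transformed(t), d0)
        from maxfit.align_engine import count_gap_runs
        runs, _ = count_gap_runs(al.pairs, len(fx.a), len(fx.b))
        recomputed = sum(S[i, j] for i, j in al.pairs) - 0.6 * runs
        assert al.score == pytest.approx(recomputed, abs=1e-9)

    def test_invariant_under_common_rigid_motion(self, decoy_pair):
        fx = decoy_pair
        t = fx.transform
        al0 = tmscore_align(fx.a, fx.b, t)
        extra = rotation_about(np.array([1.0, 2.0, 3.0]),
                               np.array([0.3, -0.5, 1.0]), 37.0)
        a2 = fx.a.transformed(extra)
        b2 = fx.b.transformed(extra)
        # same relative placement: conjugated transform
        t2 = extra.compose(t).compose(extra.inverse())
        al2 = tmscore_align(a2, b2, t2)
        assert al2.pairs == al0.pairs
        assert al2.score == pytest.approx(al0.score, abs=1e-9)

    def test_standalone_run_matches_truth_on_rigid_copy(self, mixed40_pair):
        fx = mixed40_pair
        res = tmalign_align(fx.a, fx.b)
        assert res.alignment.pairs == fx.truth.pairs


class TestLock2:
    def test_refine_converges_immediately_at_optimum(self, helix30):
        t, trace = lock2_refine(helix30, helix30, Transform.identity())
        assert trace.converged
        assert trace.records[0][0] == len(helix30)  # all pairs retained

    def test_refine_recovers_perturbed_transform(self, mixed40_pair):
        fx = mixed40_pair
        bump = rotation_about(fx.a.coords.mean(axis=0),
                              np.array([0.0, 0.0, 1.0]), 5.0)
        init = bump.compose(fx.transform)
        assert init.rotation_angle_deg(fx.transform) == pytest.approx(5.0, abs=1e-6)
        t, trace = lock2_refine(fx.a, fx.b, init)
        assert t.rotation_angle_deg(fx.transform) < 1.0

    def test_crms_nonincreasing_under_refinement(self, noisy_pair):
        fx = noisy_pair
        bump = rotation_about(fx.a.coords.mean(axis=0),
                              np.array([1.0, 1.0, 0.0]), 8.0)
        t, trace = lock2_refine(fx.a, fx.b, bump.compose(fx.transform))
        crms_series = [rec[2] for rec in trace.records]
        # cRMS of the matched set cannot rise while the pair set is unchanged;
        # allow small rises only when the pair set grew
        ks = [rec[0] for rec in trace.records]
        for (k0, c0), (k1, c1) in zip(zip(ks, crms_series),
                                      zip(ks[1:], crms_series[1:])):
            if k0 == k1:
                assert c1 <= c0 + 1e-9

    def test_empty_pairing_stops_with_flag(self, helix30):
        far = Transform(np.eye(3), np.array([500.0, 0.0, 0.0]))
        t, trace = lock2_refine(helix30, helix30, far)
        assert trace.stopped_empty
        assert np.allclose(t.translation, far.translation)

    def test_final_alignment_keeps_everything_when_identical(self, helix30):
        al = lock2_final_alignment(helix30, helix30)
        assert al.pairs == tuple((i, i) for i in range(30))

    def test_colinearity_filter_on_crossing_pairs(self):
        # construct mutual-NN pairs {(0,1),(1,0),(2,2)}: a crossing pair
        # plus one consistent pair -> keep 2
        a = as_structure([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        b = as_structure([[10, 1, 0], [0, 1, 0], [20, 1, 0]])
        assert set(mutual_nearest_pairs(a, b, 3.0)) == {(0, 1), (1, 0), (2, 2)}
        al = lock2_final_alignment(a, b, 3.0)
        assert len(al) == 2
        assert al.pairs in (((0, 1), (2, 2)), ((1, 0), (2, 2)))

    def test_all_distant_pairs_give_empty_alignment(self, helix30):
        moved = helix30.transformed(
            Transform(np.eye(3), np.array([100.0, 0.0, 0.0])))
        assert len(lock2_final_alignment(helix30, moved, 3.0)) == 0

    def test_output_is_monotone_and_mutual_nn(self, decoy_pair):
        fx = decoy_pair
        res = lock2_align(fx.a, fx.b)
        b_hat = fx.b.transformed(res.transform)
        nn = set(mutual_nearest_pairs(fx.a, b_hat, 3.0))
        assert all(p in nn for p in res.alignment.pairs)
        li = res.alignment.left_indices
        rj = res.alignment.right_indices
        assert list(li) == sorted(li) and list(rj) == sorted(rj)
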