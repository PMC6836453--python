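import itertools

import numpy as np
import pytest

import synergait as sg
from synergait import synergy
from synergait.synergy import (
    SynergyDecomposition,
    _multiplicative_fit,
    average_synergies,
    cosine_similarity,
    group_order,
    nnmf_extract,
    normalize_synergies,
    order_synergies,
    select_order,
    vaf,
    vaf_curve,
)


class TestVaf:
    def test_exact_reconstruction(self):
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[1.0], [2.0]])
        H = np.array([[1.0, 2.0]])
        assert vaf(W @ H, W, H) == pytest.approx(1.0)

    def test_zero_reconstruction(self):
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert vaf(M, np.zeros((2, 1)), np.zeros((1, 2))) == pytest.approx(0.0)

    def test_hand_computed_frobenius(self):
        # M=[[1,2],[3,4]], WH=[[1,2],[3,0]]: residual 16, total 30
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[1.0, 0.0], [0.0, 3.0]])
        H = np.array([[1.0, 2.0], [1.0, 0.0]])
        assert vaf(M, W, H) == pytest.approx(1 - 16 / 30)

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            vaf(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((1, 2)))


class TestNnmfExtract:
    def test_recovers_well_separated_synergies(self, template):
        cfg = sg.CohortConfig(
            n_subjects=1, snr_db=np.inf, subject_perturbation_sd=0.0,
            sampling_rate_hz=200.0, strides_per_subject=4, seed=5,
        )
        M = sg.generate_cohort(cfg, template).subjects[0].clean_envelope
        dec = nnmf_extract(M, 4, restarts=20, max_iter=2000, seed=11)
        assert dec.vaf > 0.999
        dec = normalize_synergies(dec)
        _, sims = order_synergies(dec.W, template.W_true)
        assert np.all(sims > 0.99)

    def test_negative_entries_error(self):
        with pytest.raises(ValueError):
            nnmf_extract(np.array([[1.0, -1.0]]), 1)

    def test_invalid_order_error(self):
        with pytest.raises(ValueError):
            nnmf_extract(np.ones((3, 5)), 0)
        with pytest.raises(ValueError):
            nnmf_extract(np.ones((3, 5)), 4)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            nnmf_extract(np.zeros((3, 5)), 1)

    def test_outputs_nonnegative(self, rng):
        M = rng.uniform(0, 1, size=(6, 40))
        dec = nnmf_extract(M, 3, restarts=3, seed=0)
        assert np.all(dec.W >= 0) and np.all(dec.H >= 0)

    def test_objective_monotone_and_nonnegative_per_iteration(self, rng):
        M = rng.uniform(0, 1, size=(5, 30))
        W = rng.uniform(0.1, 1, size=(5, 2))
        H = rng.uniform(0.1, 1, size=(2, 30))
        prev = np.linalg.norm(M - W @ H) ** 2
        for _ in range(50):
            _multiplicative_fit(M, W, H, max_iter=1, tol=-np.inf)
            err = np.linalg.norm(M - W @ H) ** 2
            assert err <= prev + 1e-10
            assert np.all(W >= 0) and np.all(H >= 0)
            prev = err


class TestOrderSelection:
    def test_vaf_monotone_in_order(self, rng):
        M = rng.uniform(0, 1, size=(12, 60))
        curve = vaf_curve(M, n_max=12, restarts=3, seed=1)
        vals = [curve[n].vaf for n in sorted(curve)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert curve[12].vaf >= curve[4].vaf

    def test_selects_generative_order(self, template):
        cfg = sg.CohortConfig(
            n_subjects=1, snr_db=20.0, sampling_rate_hz=200.0,
            strides_per_subject=6, seed=8,
        )
        M = sg.generate_cohort(cfg, template).subjects[0].recording.samples
        assert select_order(M, threshold=0.90, restarts=10, seed=2) == 4

    def test_noiseless_at_most_generative_order(self, template):
        cfg = sg.CohortConfig(
            n_subjects=1, snr_db=np.inf, sampling_rate_hz=200.0,
            strides_per_subject=4, seed=9,
        )
        M = sg.generate_cohort(cfg, template).subjects[0].clean_envelope
        assert select_order(M, threshold=0.90, restarts=10, seed=3) <= 4

    def test_threshold_zero_returns_one(self, rng):
        M = rng.uniform(0.1, 1, size=(4, 20))
        assert select_order(M, threshold=0.0, restarts=3, seed=0) == 1

    def test_rank_one_matrix_returns_one(self, rng):
        M = np.outer(rng.uniform(0.5, 1, 5), rng.uniform(0.5, 1, 30))
        assert select_order(M, threshold=0.98, restarts=3, seed=0) == 1

    def test_unreachable_threshold_errors(self, rng):
        M = rng.uniform(0.5, 1.5, size=(6, 50))
        with pytest.raises(ValueError, match="not reached"):
            select_order(M, threshold=0.999999, n_max=2, restarts=2, seed=0)


class TestGroupOrder:
    @pytest.mark.parametrize(
        "orders,expected",
        [([3, 4, 4, 3], 4), ([4, 4, 4], 4), ([3, 3, 5], 4), ([1], 1)],
    )
    def test_ceiling_of_mean(self, orders, expected):
        assert group_order(orders) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            group_order([])


class TestNormalizeSynergies:
    def test_three_four_five(self):
        W = np.zeros((12, 1))
        W[0, 0], W[1, 0] = 3.0, 4.0
        H = np.ones((1, 10))
        dec = normalize_synergies(SynergyDecomposition(W, H, 1.0, 1))
        assert dec.W[0, 0] == pytest.approx(0.6)
        assert dec.W[1, 0] == pytest.approx(0.8)
        assert np.allclose(dec.H, 5.0)

    def test_reconstruction_invariant(self, rng):
        W = rng.uniform(0.1, 2, size=(12, 4))
        H = rng.uniform(0, 1, size=(4, 50))
        dec = normalize_synergies(SynergyDecomposition(W, H, 1.0, 4))
        assert np.allclose(dec.W @ dec.H, W @ H, rtol=1e-12, atol=1e-12)
        assert np.allclose(np.linalg.norm(dec.W, axis=0), 1.0)

    def test_idempotent(self, rng):
        W = rng.uniform(0.1, 2, size=(12, 3))
        H = rng.uniform(0, 1, size=(3, 20))
        once = normalize_synergies(SynergyDecomposition(W, H, 1.0, 3))
        twice = normalize_synergies(once)
        assert np.allclose(once.W, twice.W, atol=1e-15)
        assert np.allclose(once.H, twice.H, atol=1e-12)

    def test_zero_column_errors(self):
        W = np.zeros((12, 2))
        W[0, 0] = 1.0
        with pytest.raises(ValueError, match="column 1"):
            normalize_synergies(SynergyDecomposition(W, np.ones((2, 5)), 1.0, 2))


class TestCosineSimilarity:
    def test_identical(self, rng):
        w = rng.uniform(0.1, 1, 12)
        assert cosine_similarity(w, w) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert cosine_similarity([1, 0, 0], [0, 1, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0, 0], [1, 0, 0])


class TestOrderSynergies:
    def test_identity(self, rng):
        W = rng.uniform(0.1, 1, size=(12, 4))
        perm, sims = order_synergies(W, W)
        assert np.array_equal(perm, np.arange(4))
        assert np.allclose(sims, 1.0)

    def test_inverts_column_swap(self, rng):
        W = rng.uniform(0.1, 1, size=(12, 4))
        swapped = W[:, [2, 1, 0, 3]]
        perm, _ = order_synergies(swapped, W)
        assert np.allclose(swapped[:, perm], W)

    def test_matches_exhaustive_search(self, rng):
        W_ref = rng.uniform(0, 1, size=(12, 4))
        W_sub = rng.uniform(0, 1, size=(12, 4))
        perm, sims = order_synergies(W_sub, W_ref)
        best = -np.inf
        for p in itertools.permutations(range(4)):
            total = sum(
                cosine_similarity(W_ref[:, i], W_sub[:, p[i]]) for i in range(4)
            )
            best = max(best, total)
        assert sims.sum() == pytest.approx(best, abs=1e-12)

    def test_mismatched_order_errors(self, rng):
        with pytest.raises(ValueError):
            order_synergies(rng.uniform(0, 1, (12, 3)), rng.uniform(0, 1, (12, 4)))


class TestAverageSynergies:
    def test_identical_sets(self, rng):
        W = rng.uniform(0.1, 1, size=(12, 4))
        W = W / np.linalg.norm(W, axis=0)
        out = average_synergies([W, W, W])
        assert np.allclose(out.W_mean, W, atol=1e-12)

    def test_arithmetic_mean_before_renormalization(self):
        W1 = np.zeros((3, 1)); W1[:, 0] = [0.2, 1.0, 0.0]
        W2 = np.zeros((3, 1)); W2[:, 0] = [0.4, 1.0, 0.0]
        out = average_synergies([W1, W2])
        raw_mean = np.array([0.3, 1.0, 0.0])
        assert np.allclose(out.W_mean[:, 0], raw_mean / np.linalg.norm(raw_mean))

    def test_mean_columns_unit_norm(self, rng):
        sets = [rng.uniform(0.1, 1, size=(12, 4)) for _ in range(5)]
        sets = [W / np.linalg.norm(W, axis=0) for W in sets]
        out = average_synergies(sets)
        assert np.allclose(np.linalg.norm(out.W_mean, axis=0), 1.0, atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            average_synergies([])


class TestParameterRecovery:
    def test_median_matched_similarity_at_20db(self, template):
        cfg = sg.CohortConfig(
            n_subjects=4, snr_db=20.0, sampling_rate_hz=200.0,
            strides_per_subject=4, seed=17,
        )
        bundle = sg.generate_cohort(cfg, template)
        sims = []
        for subj in bundle.subjects:
            dec = nnmf_extract(subj.recording.samples, 4, restarts=8, seed=1)
            dec = normalize_synergies(dec)
            _, s = order_synergies(dec.W, subj.W_subject)
            sims.extend(s)
        assert np.median(sims) >= 0.9
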