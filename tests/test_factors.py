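"""NMF runs, Hungarian matching, stability selection, consensus, R^2."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import normfactor as nf
from normfactor.factors import (
    multiplicative_update_trace,
    pairwise_agreement,
    _standardized_rows,
)


class TestSingleRun:
    def test_planted_rank2_reconstructed_to_machine_noise(self, planted_lowrank):
        _W0, _H0, D = planted_lowrank
        best = min(
            nf.nmf_single_run(D, 2, seed=s)[2] for s in range(10)
        )
        assert best**2 < 1e-6 * np.sum(D**2)

    def test_row_permutation_equivariance_of_updates(self, planted_lowrank):
        """Permuting D's rows (and the init alike) permutes W and leaves H
        and the objective trajectory bit-identical: the objective is
        row-exchangeable."""
        *_, D = planted_lowrank
        rng = np.random.default_rng(0)
        perm = rng.permutation(D.shape[0])
        W0 = rng.random((D.shape[0], 2)) + 1e-6
        H0 = rng.random((2, D.shape[1])) + 1e-6
        W1, H1, e1 = multiplicative_update_trace(D, 2, seed=0, n_iter=50, init=(W0, H0))
        W2, H2, e2 = multiplicative_update_trace(
            D[perm], 2, seed=0, n_iter=50, init=(W0[perm], H0)
        )
        # equality up to BLAS summation order
        assert np.allclose(e1, e2, rtol=1e-10)
        assert np.allclose(H1, H2, rtol=1e-8)
        assert np.allclose(W1[perm], W2, rtol=1e-8)

    def test_rank_one_matrix_recovers_direction(self):
        rng = np.random.default_rng(3)
        u, v = rng.random(30), rng.random(80)
        W, H, _ = nf.nmf_single_run(np.outer(u, v), 1, seed=0)
        cos = H[0] @ v / (np.linalg.norm(H[0]) * np.linalg.norm(v))
        assert cos > 0.999

    def test_h_rows_unit_norm_and_seed_determinism(self, planted_lowrank):
        *_, D = planted_lowrank
        W1, H1, _ = nf.nmf_single_run(D, 3, seed=9)
        W2, H2, _ = nf.nmf_single_run(D, 3, seed=9)
        assert np.allclose(np.linalg.norm(H1, axis=1), 1.0)
        assert np.array_equal(W1, W2) and np.array_equal(H1, H2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nf.nmf_single_run(np.zeros((5, 5)), 2, seed=0)
        with pytest.raises(ValueError):
            nf.nmf_single_run(np.ones((5, 8)), 5, seed=0)
        with pytest.raises(ValueError):
            nf.nmf_single_run(-np.ones((5, 8)), 2, seed=0)

    def test_multiplicative_updates_monotone_and_consistent(self, planted_lowrank):
        *_, D = planted_lowrank
        W, H, errs = multiplicative_update_trace(D, 2, seed=0, n_iter=200)
        assert np.all(np.diff(errs) <= 1e-9)  # objective never increases
        _, _, err_prod = nf.nmf_single_run(D, 2, seed=0)
        assert errs[-1] < 0.05 * np.linalg.norm(D)  # both solvers near-exact
        assert err_prod < 0.05 * np.linalg.norm(D)


class TestMatching:
    def test_row_permutation_recovered_exactly(self):
        rng = np.random.default_rng(0)
        H = rng.random((4, 50))
        applied = rng.permutation(4)
        perm, corr = nf.match_factors(H, H[applied])
        assert np.allclose(corr, 1.0)
        # H_b[perm[i]] must equal H_a[i]
        assert np.array_equal(H[applied][perm], H)

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            k = int(rng.integers(2, 6))
            A, B = rng.random((k, 40)), rng.random((k, 40))
            _, best = nf.match_factors(A, B)
            za, zb = _standardized_rows(A), _standardized_rows(B)
            corr = za @ zb.T
            brute = max(
                np.mean([corr[i, p[i]] for i in range(k)])
                for p in itertools.permutations(range(k))
            )
            assert np.isclose(best, brute, atol=1e-12)

    def test_symmetric_matching_gives_inverse_permutation(self):
        rng = np.random.default_rng(2)
        A, B = rng.random((4, 60)), rng.random((4, 60))
        p_ab, _ = nf.match_factors(A, B)
        p_ba, _ = nf.match_factors(B, A)
        assert np.array_equal(p_ba[p_ab], np.arange(4))

    def test_noise_row_does_not_disturb_other_pairs(self):
        rng = np.random.default_rng(3)
        A = rng.random((3, 200))
        B = A.copy()
        B[1] = rng.random(200)
        perm, corr = nf.match_factors(A, B)
        assert perm[0] == 0 and perm[2] == 2
        rho_noise = np.corrcoef(A[1], B[perm[1]])[0, 1]
        assert np.isclose(corr, (2.0 + rho_noise) / 3.0, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        A, B = rng.random((3, 30)), rng.random((3, 30))
        _, r1 = nf.match_factors(A, B)
        B2 = B.copy()
        B2[1] *= c
        _, r2 = nf.match_factors(A, B2)
        assert np.isclose(r1, r2, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nf.match_factors(np.ones((2, 5)), np.ones((3, 5)))


class TestStability:
    def test_identical_forced_seeds_give_unit_stability(self, planted_lowrank):
        *_, D = planted_lowrank
        entry, runs = nf.stability_value(D, 2, run_seeds=[5, 5])
        assert np.isclose(entry.stability, 1.0)
        assert len(runs) == 2

    def test_signal_more_stable_than_noise(self, planted_lowrank):
        _W0, _H0, D = planted_lowrank
        noisy = D + np.abs(np.random.default_rng(0).normal(0, 0.1, D.shape))
        e_sig, _ = nf.stability_value(noisy, 2, n_runs=8, seed=1)
        D_noise = np.abs(np.random.default_rng(1).normal(size=D.shape))
        e_nse, _ = nf.stability_value(D_noise, 5, n_runs=8, seed=1)
        assert e_sig.stability - e_nse.stability > 0.1

    def test_agreement_matrix_symmetric_unit_diagonal(self, planted_lowrank):
        *_, D = planted_lowrank
        entry, _ = nf.stability_value(D, 2, n_runs=4, seed=0)
        A = entry.agreement
        assert np.allclose(A, A.T) and np.allclose(np.diag(A), 1.0)

    def test_stability_invariant_to_run_order(self, planted_lowrank):
        *_, D = planted_lowrank
        e1, _ = nf.stability_value(D, 2, run_seeds=[1, 2, 3])
        e2, _ = nf.stability_value(D, 2, run_seeds=[3, 1, 2])
        assert np.isclose(e1.stability, e2.stability, atol=1e-12)

    def test_degenerate_k_range_returns_k_without_search(self, planted_lowrank):
        *_, D = planted_lowrank
        k_opt, profile, _ = nf.select_k(D, k_min=2, k_max=2, n_runs=3, seed=0)
        assert k_opt == 2 and list(profile.entries) == [2]


class TestConsensus:
    def test_identical_runs_average_to_single_run(self, planted_lowrank):
        *_, D = planted_lowrank
        W, H, _ = nf.nmf_single_run(D, 2, seed=1)
        Hc, Wc = nf.consensus_factors([(W, H)] * 4)
        assert np.allclose(Hc.H, H) and np.allclose(Wc.W, W)

    def test_permuted_runs_align_to_reference(self, planted_lowrank):
        *_, D = planted_lowrank
        W, H, _ = nf.nmf_single_run(D, 3, seed=1)
        runs = [(W, H)] + [
            (W[:, p], H[list(p)]) for p in ([2, 0, 1], [1, 2, 0], [0, 2, 1])
        ]
        Hc, Wc = nf.consensus_factors(runs)
        # all runs are equivalent, so the consensus equals the reference run
        # up to the (arbitrary) factor ordering of whichever run was chosen
        perm, corr = nf.match_factors(H, Hc.H)
        assert np.isclose(corr, 1.0)
        assert np.allclose(Hc.H[perm], H) and np.allclose(Wc.W[:, perm], W)

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            nf.consensus_factors([(np.ones((2, 2)), np.ones((2, 3)))])


class TestVarianceExplained:
    def test_exact_span_gives_unit_r2_and_coefficients(self):
        rng = np.random.default_rng(0)
        H = rng.random((3, 100))
        D = np.vstack([2.0 * H[0], H[1] + 3.0 * H[2]])
        ve = nf.variance_explained(D, H)
        assert np.allclose(ve.r_squared, 1.0)
        assert np.allclose(ve.coefficients[0], [2.0, 0.0, 0.0], atol=1e-8)

    def test_orthogonal_row_gives_zero_r2(self):
        H = np.array([[1.0, 0.0, 0.0, 0.0]])
        D = np.array([[0.0, 1.0, 1.0, 0.0]])
        ve = nf.variance_explained(D, H)
        assert np.isclose(ve.r_squared[0], 0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        H = rng.random((4, 3000))
        D = rng.random((6, 3000))
        ve = nf.variance_explained(D, H)
        G = H @ H.T
        for s in range(6):
            beta = np.linalg.solve(G, H @ D[s])
            resid = D[s] - beta @ H
            r2 = 1.0 - resid @ resid / (D[s] @ D[s])
            assert abs(ve.r_squared[s] - r2) < 1e-10
            assert np.allclose(ve.coefficients[s], beta, atol=1e-8)

    def test_zero_row_flagged_as_zero(self):
        H = np.ones((1, 4))
        ve = nf.variance_explained(np.zeros((2, 4)), H)
        assert np.allclose(ve.r_squared, 0.0) and ve.flagged.all()


def test_recovery_of_planted_factors(small_bundle, small_parts):
    """Consensus factors correlate with the planted truth after matching."""
    parts, _ = small_parts
    truth = small_bundle.truth
    for D, H_true, W_true in (
        (parts.D_pos, truth.true_H_pos, truth.true_W_pos),
        (parts.D_neg, truth.true_H_neg, truth.true_W_neg),
    ):
        _, runs = nf.stability_value(D, 2, n_runs=10, seed=2)
        H, W = nf.consensus_factors(runs)
        perm, corr = nf.match_factors(H_true, H.H)
        assert corr >= 0.8
        from scipy.stats import spearmanr

        for j in range(2):
            rho = spearmanr(W_true[:, j], W.W[:, perm[j]]).statistic
            assert rho >= 0.7  # small fixture; the full-size bound is checked at scale
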