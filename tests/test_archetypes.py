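import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from archepop.archetypes import (
    AAConfig,
    archetypes_in_snp_space,
    constrained_simplex_nnls,
    explained_variance,
    fit,
    furthest_sum_init,
    random_init,
    rss_of,
)
from archepop.genotype_io import GenotypeMatrix


def brute_force_furthest_sum(data, K, first):
    """Independent re-implementation: scan every candidate at every step."""
    selected = [first]
    while len(selected) < K:
        best, best_d = None, -np.inf
        for c in range(len(data)):
            if c in selected:
                continue
            d = sum(np.linalg.norm(data[c] - data[s]) for s in selected)
            if d > best_d:  # strict: ties stay at lower index
                best, best_d = c, d
        selected.append(best)
    return selected


class TestFurthestSum:
    def test_line_example(self):
        # points 0..10 on a line, first pick at value 3: the farthest-by-sum
        # candidate is 10 (aggregate distance 7)
        data = np.arange(11.0)[:, None]
        idx = furthest_sum_init(data, 2, first_index=3)
        assert list(idx) == [3, 10]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(15, 4))
        for first in (0, 7, 14):
            got = furthest_sum_init(data, 5, first_index=first)
            assert list(got) == brute_force_furthest_sum(data, 5, first)

    def test_k1_is_seeded_random_index(self):
        data = np.arange(8.0)[:, None]
        idx = furthest_sum_init(data, 1, seed=3)
        assert idx.shape == (1,) and 0 <= idx[0] < 8
        np.testing.assert_array_equal(idx, furthest_sum_init(data, 1, seed=3))

    def test_k_equals_n_is_a_permutation(self):
        data = np.random.default_rng(0).normal(size=(6, 2))
        idx = furthest_sum_init(data, 6, seed=1)
        assert sorted(idx) == list(range(6))

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            furthest_sum_init(np.zeros((3, 2)), 4)

    def test_reselect_first_flag_returns_distinct_indices(self):
        data = np.random.default_rng(2).normal(size=(12, 3))
        idx = furthest_sum_init(data, 4, seed=0, reselect_first=True)
        assert len(set(idx)) == 4


class TestRandomInit:
    def test_degenerate_dimension_pinned(self):
        data = np.column_stack([np.full(5, 2.0), np.arange(5.0)])
        arch = random_init(data, 3, mode="uniform", seed=0)
        np.testing.assert_allclose(arch[:, 0], 2.0)

    def test_sample_mode_deterministic(self):
        data = np.random.default_rng(1).normal(size=(9, 3))
        a = random_init(data, 4, mode="sample", seed=11)
        b = random_init(data, 4, mode="sample", seed=11)
        np.testing.assert_array_equal(a, b)

    def test_uniform_mode_stays_in_bounding_box(self):
        data = np.random.default_rng(3).normal(size=(20, 6))
        arch = random_init(data, 10, mode="uniform", seed=4)
        assert (arch >= data.min(axis=0) - 1e-12).all()
        assert (arch <= data.max(axis=0) + 1e-12).all()

    def test_sample_mode_k_too_large(self):
        with pytest.raises(ValueError):
            random_init(np.zeros((3, 2)), 4, mode="sample")


class TestConstrainedSimplexNNLS:
    def test_exact_membership_is_one_hot(self):
        A = np.diag([3.0, 5.0, 2.0])
        w = constrained_simplex_nnls(A, A[:, 1])
        np.testing.assert_allclose(w, [0, 1, 0], atol=1e-6)

    def test_midpoint_of_orthogonal_columns(self):
        A = np.array([[2.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        w = constrained_simplex_nnls(A, A[:, 0] / 2 + A[:, 1] / 2)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)

    def test_single_column_gives_weight_one(self):
        w = constrained_simplex_nnls(np.array([[5.0], [1.0]]), np.array([-3.0, 7.0]))
        np.testing.assert_array_equal(w, [1.0])

    def test_zero_design_warns_and_returns_uniform(self):
        with pytest.warns(UserWarning, match="all-zero"):
            w = constrained_simplex_nnls(np.zeros((3, 4)), np.ones(3))
        np.testing.assert_allclose(w, 0.25)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_always_simplex_valued(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 4))
        w = constrained_simplex_nnls(A, rng.normal(size=6))
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_smaller_c_enforces_sum_harder_pre_normalization(self):
        # measured on the raw augmented NNLS solution, before renormalization
        from scipy.optimize import nnls as scipy_nnls

        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 3)) * 10
        b = rng.normal(size=5) * 10
        gaps = []
        for C in (1.0, 1e-2, 1e-4):
            A_aug = np.vstack([A, np.full((1, 3), 1 / C)])
            w, _ = scipy_nnls(A_aug, np.append(b, 1 / C))
            gaps.append(abs(w.sum() - 1))
        assert gaps[0] > gaps[1] > gaps[2] or gaps[2] < 1e-10


class TestRSS:
    def test_perfect_reconstruction_is_zero(self):
        data = np.random.default_rng(0).normal(size=(5, 3))
        alpha = np.eye(5)[:, :5]
        assert rss_of(data, np.eye(5), data) == pytest.approx(0.0, abs=1e-20)

    def test_unit_frobenius_error_gives_one(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(4, 3))
        alpha = rng.dirichlet(np.ones(2), size=4)
        Z = rng.normal(size=(2, 3))
        E = rng.normal(size=(4, 3))
        E /= np.linalg.norm(E)
        assert rss_of(alpha @ Z + E, alpha, Z) == pytest.approx(1.0, rel=1e-10)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(6, 4))
        alpha = rng.dirichlet(np.ones(3), size=6)
        Z = rng.normal(size=(3, 4))
        manual = sum(
            np.sum((data[i] - sum(alpha[i, k] * Z[k] for k in range(3))) ** 2) for i in range(6)
        )
        assert rss_of(data, alpha, Z) == pytest.approx(manual, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            rss_of(np.zeros((3, 2)), np.zeros((3, 2)), np.zeros((3, 3)))


class TestExplainedVariance:
    def test_perfect_prediction(self):
        y = np.random.default_rng(0).normal(size=(4, 4))
        assert explained_variance(y, y) == pytest.approx(1.0)

    def test_constant_mean_prediction_is_zero(self):
        y = np.array([0.0, 1.0, 2.0, 5.0])
        assert explained_variance(y, np.full(4, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        # Var(y - yhat) = Var(0,0,0,2) = 0.75, Var(y) = 1.25 -> EV = 0.4
        y = np.array([0.0, 1.0, 2.0, 3.0])
        yhat = np.array([0.0, 1.0, 2.0, 1.0])
        assert explained_variance(y, yhat) == pytest.approx(0.4, abs=1e-15)

    def test_zero_variance_target_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            explained_variance(np.ones(5), np.zeros(5))


class TestFit:
    def test_k1_recovers_mean_and_total_ss(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(30, 8))
        res = fit(data, AAConfig(K=1, seed=0))
        mean = data.mean(axis=0)
        tss = ((data - mean) ** 2).sum()
        np.testing.assert_allclose(res.Z[0], mean, rtol=1e-6, atol=1e-8)
        assert res.rss == pytest.approx(tss, rel=1e-6)

    def test_planted_generators_recovered(self):
        rng = np.random.default_rng(4)
        gen = rng.uniform(0, 4, size=(3, 10))
        weights = rng.dirichlet(np.full(3, 0.5), size=27)
        data = np.vstack([gen, weights @ gen])
        res = fit(data, AAConfig(K=3, seed=0))
        tss = ((data - data.mean(axis=0)) ** 2).sum()
        assert res.rss < 1e-6 * tss
        errs = np.array([[np.abs(res.Z[a] - gen[b]).max() for b in range(3)] for a in range(3)])
        rows, cols = linear_sum_assignment(errs)
        assert errs[rows, cols].max() < 1e-3

    def test_k_equals_n_reaches_zero_rss(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(7, 5))
        res = fit(data, AAConfig(K=7, seed=0))
        tss = ((data - data.mean(axis=0)) ** 2).sum()
        assert res.rss <= 1e-8 * tss

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fit(np.zeros((3, 2)), AAConfig(K=4))
        with pytest.raises(ValueError, match="finite"):
            fit(np.array([[1.0, np.nan], [0.0, 1.0]]), AAConfig(K=1))

    def test_same_seed_same_fit(self):
        data = np.random.default_rng(9).normal(size=(25, 6))
        cfg = AAConfig(K=3, seed=123)
        a, b = fit(data, cfg), fit(data, cfg)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.beta, b.beta)

    @pytest.mark.parametrize("init", ["furthest_sum", "random_uniform", "random_sample"])
    def test_simplex_contracts_and_monotone_trace(self, init):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(35, 9))
        res = fit(data, AAConfig(K=4, seed=7, init=init))
        assert res.alpha.min() >= 0 and res.beta.min() >= 0
        np.testing.assert_allclose(res.alpha.sum(axis=1), 1.0, atol=1e-4)
        np.testing.assert_allclose(res.beta.sum(axis=0), 1.0, atol=1e-4)
        np.testing.assert_allclose(res.Z, (data.T @ res.beta).T, atol=1e-8)
        trace = np.asarray(res.rss_trace)
        assert (np.diff(trace) <= 1e-8).all()

    def test_restarts_never_worse(self):
        data = np.random.default_rng(13).normal(size=(30, 5))
        single = fit(data, AAConfig(K=3, seed=2, init="random_sample"))
        multi = fit(data, AAConfig(K=3, seed=2, init="random_sample", restarts=4))
        assert multi.rss <= single.rss + 1e-12

    def test_free_parameter_accounting(self):
        data = np.random.default_rng(3).normal(size=(12, 4))
        res = fit(data, AAConfig(K=3, seed=0))
        n, k = 12, 3
        assert res.n_free_parameters == 2 * n * k - n - k == n * (k - 1) + k * (n - 1)

    def test_projection_equivalence_with_shared_init(self, sim_panel):
        # same initial archetype indices: fit on full-rank scores and on
        # centered dosages must agree in RSS (rotation invariance)
        from archepop.projection import fit_projection

        g, _ = sim_panel
        pm = fit_projection(g)
        xc = g.dosages - g.dosages.mean(axis=0)
        idx = np.array([1, 25, 50])
        res_scores = fit(pm.scores, AAConfig(K=3, seed=0), init_indices=idx)
        res_snp = fit(xc, AAConfig(K=3, seed=0), init_indices=idx)
        assert res_scores.rss == pytest.approx(res_snp.rss, rel=1e-6)


class TestArchetypesInSNPSpace:
    def test_one_hot_beta_returns_sample_row(self, tiny_matrix):
        beta = np.zeros((4, 2))
        beta[2, 0] = 1.0
        beta[0, 1] = 1.0
        arch = archetypes_in_snp_space(tiny_matrix, beta)
        np.testing.assert_array_equal(arch[0], tiny_matrix.dosages[2])
        np.testing.assert_array_equal(arch[1], tiny_matrix.dosages[0])

    def test_uniform_beta_returns_column_means(self, tiny_matrix):
        beta = np.full((4, 1), 0.25)
        np.testing.assert_allclose(
            archetypes_in_snp_space(tiny_matrix, beta)[0], tiny_matrix.dosages.mean(axis=0)
        )

    def test_entries_within_observed_ranges(self, sim_panel):
        g, _ = sim_panel
        rng = np.random.default_rng(8)
        beta = rng.dirichlet(np.ones(g.n_samples), size=3).T
        arch = archetypes_in_snp_space(g, beta)
        lo, hi = g.dosages.min(axis=0), g.dosages.max(axis=0)
        assert (arch >= lo - 1e-9).all() and (arch <= hi + 1e-9).all()

    def test_negative_beta_rejected(self, tiny_matrix):
        beta = np.array([[1.2], [-0.2], [0.0], [0.0]])
        with pytest.raises(ValueError, match="negative"):
            archetypes_in_snp_space(tiny_matrix, beta)
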