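import numpy as np
import pytest

from phenowalk.rwr import (
    WalkConfig,
    assemble_system,
    initial_vector,
    rank_candidates,
    row_normalize,
    walk,
)


def random_system(seed, m=None, n=None, lambda_=0.7):
    rng = np.random.default_rng(seed)
    m = m or int(rng.integers(3, 51))
    n = n or int(rng.integers(3, 51))
    D = rng.random((m, m)) * (rng.random((m, m)) < 0.5)
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    G = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
    G = (G + G.T) / 2
    np.fill_diagonal(G, 0)
    A = (rng.random((m, n)) < 0.1).astype(float)
    return assemble_system(D, G, A, lambda_)


class TestRowNormalize:
    def test_basic_rows(self):
        out = row_normalize(np.array([[2.0, 2.0, 0.0], [0.0, 0.0, 0.0]]))
        assert np.allclose(out[0], [0.5, 0.5, 0.0])
        assert np.array_equal(out[1], [0.0, 0.0, 0.0])

    def test_identity_unchanged(self):
        assert np.array_equal(row_normalize(np.eye(4)), np.eye(4))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            row_normalize(np.array([[1.0, -1.0]]))


class TestAssembly:
    def test_rows_are_stochastic(self):
        for seed in range(5):
            system = random_system(seed)
            assert np.allclose(system.W.sum(axis=1), 1.0, atol=1e-12)

    def test_lambda_zero_is_block_diagonal(self):
        system = random_system(3, lambda_=0.0)
        m = system.m
        assert np.allclose(system.W[:m, m:], 0.0)
        assert np.allclose(system.W[m:, :m], 0.0)

    def test_disease_without_genes_stays_on_disease_side(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        G = np.array([[0.0, 1.0], [1.0, 0.0]])
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        system = assemble_system(D, G, A, 0.7)
        row = system.W[1]  # disease 1 has no gene
        assert row[:2].sum() == pytest.approx(1.0)
        assert np.allclose(row[2:], 0.0)

    def test_two_by_two_toy_matches_hand_arithmetic(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        G = np.array([[0.0, 1.0], [1.0, 0.0]])
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        W = assemble_system(D, G, A, 0.7).W
        expected = np.array(
            [
                [0.0, 0.3, 0.7, 0.0],   # disease 0: wander 0.3, jump to g0 0.7
                [1.0, 0.0, 0.0, 0.0],   # disease 1: no genes, renormalized
                [0.7, 0.0, 0.0, 0.3],   # gene 0: jump to d0 0.7, wander 0.3
                [0.0, 0.0, 1.0, 0.0],   # gene 1: no disease, renormalized
            ]
        )
        assert np.allclose(W, expected, atol=1e-12)

    def test_isolated_vertex_gets_self_loop(self):
        D = np.zeros((2, 2))
        G = np.array([[0.0, 1.0], [1.0, 0.0]])
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        system = assemble_system(D, G, A, 0.7)
        assert system.W[1, 1] == 1.0  # disease 1 is fully isolated

    def test_binary_association_enforced(self):
        with pytest.raises(ValueError):
            assemble_system(np.zeros((1, 1)), np.zeros((1, 1)), np.array([[0.5]]))


class TestInitialVector:
    def test_one_seed_splits_evenly(self):
        system = random_system(0, m=3, n=4)
        p0 = initial_vector(system, system.diseases[0], [system.genes[1]], eta=0.5)
        assert p0[0] == 0.5
        assert p0[system.m + 1] == 0.5
        assert p0.sum() == pytest.approx(1.0)

    def test_two_seeds_quarter_each(self):
        system = random_system(0, m=3, n=4)
        p0 = initial_vector(system, system.diseases[0], system.genes[:2], eta=0.5)
        assert np.allclose(p0[system.m : system.m + 2], 0.25)

    def test_no_seeds_all_mass_on_disease(self):
        system = random_system(0, m=3, n=4)
        p0 = initial_vector(system, system.diseases[2], [], eta=0.5)
        assert p0[2] == 1.0
        assert p0.sum() == 1.0


class TestWalk:
    def test_pure_restart_returns_p0(self):
        system = random_system(1, m=5, n=5)
        p0 = initial_vector(system, system.diseases[0], [system.genes[0]])
        result = walk(system, p0, WalkConfig(gamma=1.0))
        assert np.allclose(result.steady_state, p0)

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_point_matches_direct_solve(self, seed):
        system = random_system(seed)
        p0 = initial_vector(system, system.diseases[0], system.seed_genes(system.diseases[0]))
        config = WalkConfig(epsilon=1e-10, max_iter=5000)
        result = walk(system, p0, config)
        gamma = config.gamma
        size = system.m + system.n
        direct = np.linalg.solve(
            np.eye(size) - (1 - gamma) * system.W.T, gamma * p0
        )
        assert np.abs(result.steady_state - direct).max() <= 1e-6
        assert result.converged

    def test_symmetric_toy_preserves_symmetry(self):
        # two diseases and two genes relabeled by the same permutation
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        G = np.array([[0.0, 1.0], [1.0, 0.0]])
        A = np.array([[1.0, 1.0], [1.0, 1.0]])
        system = assemble_system(D, G, A, 0.7)
        result = walk(system, np.array([0.25, 0.25, 0.25, 0.25]), WalkConfig(epsilon=1e-12))
        p = result.steady_state
        assert p[0] == pytest.approx(p[1], abs=1e-9)
        assert p[2] == pytest.approx(p[3], abs=1e-9)

    def test_nonconvergence_flagged(self):
        system = random_system(2, m=5, n=5)
        p0 = initial_vector(system, system.diseases[0], [])
        result = walk(system, p0, WalkConfig(epsilon=1e-14, max_iter=3))
        assert not result.converged
        assert result.iterations == 3

    def test_monotone_influence_of_seed_edges(self):
        """Connecting a candidate to a seed never hurts the candidate."""
        rng = np.random.default_rng(9)
        worse = 0
        for _ in range(50):
            m, n = 6, 12
            D = rng.random((m, m)); D = (D + D.T) / 2; np.fill_diagonal(D, 0)
            G = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
            G = (G + G.T) / 2; np.fill_diagonal(G, 0)
            A = (rng.random((m, n)) < 0.15).astype(float)
            A[0, 0] = 1.0
            base = assemble_system(D, G, A, 0.7)
            seeds = base.seed_genes(base.diseases[0])
            p0 = initial_vector(base, base.diseases[0], seeds)
            cand = n - 1  # last gene as candidate
            before = walk(base, p0).gene_scores[base.genes[cand]]
            G2 = G.copy()
            G2[0, cand] = G2[cand, 0] = max(G2[0, cand], 0.9)
            system2 = assemble_system(D, G2, A, 0.7)
            after = walk(system2, p0).gene_scores[system2.genes[cand]]
            if after < before - 1e-12:
                worse += 1
        assert worse == 0


class TestRanking:
    def make_result(self, scores):
        system = random_system(0, m=2, n=len(scores))
        p0 = initial_vector(system, system.diseases[0], [])
        result = walk(system, p0)
        result.gene_scores = dict(zip(system.genes, scores))
        return system, result

    def test_distinct_scores_sort_descending(self):
        system, result = self.make_result([0.1, 0.5, 0.3, 0.2])
        ranking = rank_candidates(result, system.genes, 0)
        assert [g for g, _ in ranking] == [
            system.genes[1], system.genes[2], system.genes[3], system.genes[0]
        ]
        assert [r for _, r in ranking] == [1, 2, 3, 4]

    def test_uniform_tie_breaking(self):
        system, result = self.make_result([0.2] * 5)
        total = np.zeros(5)
        n_trials = 10_000
        for seed in range(n_trials):
            for g, r in rank_candidates(result, system.genes, seed):
                total[system.genes.index(g)] += r
        mean_ranks = total / n_trials
        assert np.allclose(mean_ranks, 3.0, rtol=0.02)

    def test_unknown_candidate_rejected(self):
        system, result = self.make_result([0.1, 0.2])
        with pytest.raises(KeyError):
            rank_candidates(result, ["nonexistent"], 0)

    def test_empty_candidates_rejected(self):
        system, result = self.make_result([0.1, 0.2])
        with pytest.raises(ValueError):
            rank_candidates(result, [], 0)
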