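import numpy as np
import pytest

from oracles import brute_force_loglik, brute_force_posteriors

from wgdresolve.likelihood import (block_segmentation, edge_transition_matrices,
                                   emission_matrix, expected_loss_counts,
                                   junction_transition, pillar_loglik,
                                   posterior_assignments, sequence_loglik,
                                   tip_likelihood)
from wgdresolve.model import F, S1, S2, U, LossParams, transition_probs
from wgdresolve.pillars import (JunctionModel, PillarSet, PosteriorTable,
                                complement_index)
from wgdresolve.simulate import SimConfig, simulate_dataset, _example_newick
from wgdresolve.trees import LossTree


class TestTipLikelihood:
    @pytest.mark.parametrize("v", [1, 2])
    def test_duplicated_is_u_or_f(self, v):
        assert np.allclose(tip_likelihood(0, v), [1, 1, 0, 0])

    def test_single_copy_tracks_map_through_assignment(self):
        assert np.allclose(tip_likelihood(1, 1), [0, 0, 1, 0])  # p1, v=1 -> S1
        assert np.allclose(tip_likelihood(1, 2), [0, 0, 0, 1])
        assert np.allclose(tip_likelihood(2, 1), [0, 0, 0, 1])  # p2, v=1 -> S2
        assert np.allclose(tip_likelihood(2, 2), [0, 0, 1, 0])

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            tip_likelihood(3, 1)
        with pytest.raises(ValueError):
            tip_likelihood(0, 0)


class TestSingleGenomeClosedForms:
    """One tip below a stem: pruning reduces to one transition matrix."""

    def setup_method(self):
        self.b = 0.37
        self.tree = LossTree.from_newick(f"(A:{self.b}):0.0;")
        self.params = LossParams(gamma=0.25, epsilon=0.55)
        self.P = transition_probs(0.25, 0.55, self.b)
        self.edge_P = edge_transition_matrices(self.tree, self.params)

    def _single(self, obs_code):
        obs = np.array([[obs_code]], dtype=np.int8)
        return PillarSet(("A",), ["a0"], obs, np.zeros((0, 1), dtype=bool))

    def test_duplicated(self):
        ll = pillar_loglik(self._single(0), 0, 0, self.tree, self.edge_P)
        assert ll == pytest.approx(np.log(self.P[U, U] + self.P[U, F]), abs=1e-12)

    def test_single_in_p1_assignment_1(self):
        ll = pillar_loglik(self._single(1), 0, 0, self.tree, self.edge_P)
        assert ll == pytest.approx(np.log(self.P[U, S1]), abs=1e-12)

    def test_single_in_p1_assignment_2(self):
        ll = pillar_loglik(self._single(1), 0, 1, self.tree, self.edge_P)
        assert ll == pytest.approx(np.log(self.P[U, S2]), abs=1e-12)


class TestJunctionKernel:
    def test_theta_zero_identity(self):
        jm = JunctionModel(0.0, np.zeros((1, 3), dtype=bool))
        assert np.allclose(junction_transition(jm, 0), np.eye(8))

    def test_double_break_forces_half(self):
        flags = np.array([[False, True]])
        jm = JunctionModel(0.01, flags)
        K = junction_transition(jm, 0)
        # genome 1 flips with probability 0.5 regardless of theta
        marg = K[0].reshape(2, 2).sum(axis=1)  # genome-1 marginal from v=(1,1)
        assert np.allclose(marg, [0.5, 0.5])
        assert np.allclose(K.sum(axis=1), 1.0)

    def test_stay_probability_factorizes(self):
        jm = JunctionModel(0.01, np.zeros((1, 2), dtype=bool))
        K = junction_transition(jm, 0)
        assert K[0, 0] == pytest.approx(0.9801)


class TestForwardAgainstBruteForce:
    def test_total_loglik(self, small_pillars, two_genome_tree, params,
                          small_junctions):
        edge_P = edge_transition_matrices(two_genome_tree, params)
        fast = sequence_loglik(small_pillars, two_genome_tree, params,
                               small_junctions)
        slow = brute_force_loglik(small_pillars, two_genome_tree, edge_P,
                                  small_junctions)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_posterior_marginals(self, small_pillars, two_genome_tree, params,
                                 small_junctions):
        edge_P = edge_transition_matrices(two_genome_tree, params)
        post = posterior_assignments(small_pillars, two_genome_tree, params,
                                     small_junctions)
        slow = brute_force_posteriors(small_pillars, two_genome_tree, edge_P,
                                      small_junctions)
        assert np.abs(post.vector_probs - slow).max() < 1e-9
        assert np.allclose(post.vector_probs.sum(axis=1), 1.0)

    def test_four_pillars(self, two_genome_tree, params):
        rng = np.random.default_rng(3)
        obs = rng.integers(0, 3, size=(4, 2)).astype(np.int8)
        breaks = rng.random((3, 2)) < 0.3
        ps = PillarSet(("A", "B"), [f"a{i}" for i in range(4)], obs, breaks)
        jm = JunctionModel(0.05, breaks)
        edge_P = edge_transition_matrices(two_genome_tree, params)
        fast = sequence_loglik(ps, two_genome_tree, params, jm)
        slow = brute_force_loglik(ps, two_genome_tree, edge_P, jm)
        assert fast == pytest.approx(slow, abs=1e-9)


class TestChainStructure:
    def test_single_pillar_is_uniform_mixture(self, two_genome_tree, params):
        obs = np.array([[1, 2]], dtype=np.int8)
        ps = PillarSet(("A", "B"), ["a0"], obs, np.zeros((0, 2), dtype=bool))
        jm = JunctionModel(0.01, ps.double_breaks)
        edge_P = edge_transition_matrices(two_genome_tree, params)
        E, ls = emission_matrix(ps, two_genome_tree, edge_P)
        expected = np.log(np.mean(E[0] * np.exp(ls[0])))
        assert sequence_loglik(ps, two_genome_tree, params, jm) == \
            pytest.approx(expected, abs=1e-12)

    def test_all_double_breaks_decouple_the_chain(self, two_genome_tree, params):
        rng = np.random.default_rng(5)
        obs = rng.integers(0, 3, size=(5, 2)).astype(np.int8)
        breaks = np.ones((4, 2), dtype=bool)
        ps = PillarSet(("A", "B"), [f"a{i}" for i in range(5)], obs, breaks)
        jm = JunctionModel(0.01, breaks)
        edge_P = edge_transition_matrices(two_genome_tree, params)
        E, ls = emission_matrix(ps, two_genome_tree, edge_P)
        expected = sum(np.log(np.mean(E[i])) + ls[i] for i in range(5))
        assert sequence_loglik(ps, two_genome_tree, params, jm) == \
            pytest.approx(expected, abs=1e-9)

    def test_reversal_invariance(self, two_genome_tree, params):
        """The chain is reversible (symmetric kernel, uniform start), so the
        forward pass on the reversed pillar order gives the same total -- the
        backward recursion agrees with the forward one."""
        rng = np.random.default_rng(8)
        obs = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        breaks = rng.random((29, 2)) < 0.1
        ps = PillarSet(("A", "B"), [f"a{i}" for i in range(30)], obs, breaks)
        jm = JunctionModel(0.02, breaks)
        rev = PillarSet(("A", "B"), ps.anchors[::-1], obs[::-1], breaks[::-1])
        jm_rev = JunctionModel(0.02, breaks[::-1])
        f = sequence_loglik(ps, two_genome_tree, params, jm)
        r = sequence_loglik(rev, two_genome_tree, params, jm_rev)
        assert f == pytest.approx(r, rel=1e-9)


class TestDegeneracy:
    """With eps=1 the two subgenomes are statistically interchangeable."""

    def test_posteriors_symmetric_under_relabeling(self, small_pillars,
                                                   two_genome_tree,
                                                   small_junctions):
        params = LossParams(gamma=0.2, epsilon=1.0)
        post = posterior_assignments(small_pillars, two_genome_tree, params,
                                     small_junctions)
        for v in range(4):
            c = complement_index(v, 2)
            assert np.allclose(post.vector_probs[:, v], post.vector_probs[:, c],
                               atol=1e-12)
        assert np.allclose(post.marginals, 0.5)

    def test_fixed_assignment_likelihood_symmetry_breaks_with_bias(
            self, small_pillars, two_genome_tree, small_junctions):
        edge_sym = edge_transition_matrices(two_genome_tree,
                                            LossParams(0.2, 1.0))
        edge_bias = edge_transition_matrices(two_genome_tree,
                                             LossParams(0.2, 0.6))
        # pillar 0 is asymmetric: one genome duplicated, one single in p1
        v, c = 0, complement_index(0, 2)
        ll_sym_v = pillar_loglik(small_pillars, 0, v, two_genome_tree, edge_sym)
        ll_sym_c = pillar_loglik(small_pillars, 0, c, two_genome_tree, edge_sym)
        assert ll_sym_v == pytest.approx(ll_sym_c, abs=1e-12)
        ll_b_v = pillar_loglik(small_pillars, 0, v, two_genome_tree, edge_bias)
        ll_b_c = pillar_loglik(small_pillars, 0, c, two_genome_tree, edge_bias)
        assert abs(ll_b_v - ll_b_c) > 1e-6

    def test_posterior_asymmetry_with_bias(self, small_pillars, two_genome_tree,
                                           small_junctions):
        post = posterior_assignments(small_pillars, two_genome_tree,
                                     LossParams(0.2, 0.6), small_junctions)
        diffs = [abs(post.vector_probs[i, v]
                     - post.vector_probs[i, complement_index(v, 2)])
                 for i in range(post.m) for v in range(4)]
        assert max(diffs) > 1e-3

    def test_uninformative_pillar_between_breaks_is_uniform(
            self, two_genome_tree):
        obs = np.array([[1, 2], [0, 0], [2, 1]], dtype=np.int8)
        breaks = np.ones((2, 2), dtype=bool)
        ps = PillarSet(("A", "B"), ["a0", "a1", "a2"], obs, breaks)
        jm = JunctionModel(0.01, breaks)
        post = posterior_assignments(ps, two_genome_tree,
                                     LossParams(0.2, 0.6), jm)
        assert np.allclose(post.vector_probs[1], 0.25, atol=1e-12)


class TestExpectedLossCounts:
    def test_certain_single_loss(self):
        tree = LossTree.from_newick("(A:0.5):0.0;")
        ps = PillarSet(("A",), ["a0"], np.array([[1]], dtype=np.int8),
                       np.zeros((0, 1), dtype=bool))
        jm = JunctionModel(0.01, ps.double_breaks)
        # eps=0: only S1 losses possible, so the observed single copy in p1
        # must be an S1 loss on the only branch under assignment v=1
        counts = expected_loss_counts(ps, tree, LossParams(0.0, 0.0), jm)
        row = counts[counts.branch == "A"].iloc[0]
        assert row.expected_S1 == pytest.approx(1.0, abs=1e-12)
        assert row.expected_S2 == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_data_balanced_losses(self, two_genome_tree):
        # track-swap-symmetric observations under eps=1
        obs = np.array([[1, 2], [2, 1], [0, 0]], dtype=np.int8)
        ps = PillarSet(("A", "B"), ["a0", "a1", "a2"], obs,
                       np.zeros((2, 2), dtype=bool))
        jm = JunctionModel(0.01, ps.double_breaks)
        counts = expected_loss_counts(ps, two_genome_tree,
                                      LossParams(0.2, 1.0), jm)
        assert counts.expected_S1.sum() == pytest.approx(
            counts.expected_S2.sum(), abs=1e-9)

    def test_two_tip_star_hand_enumeration(self):
        b1, b2 = 0.3, 0.6
        gamma, eps = 0.2, 0.7
        tree = LossTree.from_newick(f"(A:{b1},B:{b2}):0.0;")
        obs = np.array([[1, 1]], dtype=np.int8)
        ps = PillarSet(("A", "B"), ["a0"], obs, np.zeros((0, 2), dtype=bool))
        jm = JunctionModel(0.01, ps.double_breaks)
        counts = expected_loss_counts(ps, tree, LossParams(gamma, eps), jm)
        # hand enumeration: stem length 0 so both tips descend from state U;
        # under v=(1,1) both observations are S1 losses with certainty; under
        # v=(2,2) both are S2; mixed assignments give one of each.  Posterior
        # over the 4 assignments is proportional to the emission products.
        PA = transition_probs(gamma, eps, b1)
        PB = transition_probs(gamma, eps, b2)
        like = {}
        for va in (1, 2):
            for vb in (1, 2):
                sa = S1 if va == 1 else S2
                sb = S1 if vb == 1 else S2
                like[(va, vb)] = PA[U, sa] * PB[U, sb]
        Z = sum(like.values())
        expA_S1 = sum(p for (va, vb), p in like.items() if va == 1) / Z
        expB_S1 = sum(p for (va, vb), p in like.items() if vb == 1) / Z
        rowA = counts[counts.branch == "A"].iloc[0]
        rowB = counts[counts.branch == "B"].iloc[0]
        assert rowA.expected_S1 == pytest.approx(expA_S1, abs=1e-10)
        assert rowA.expected_S2 == pytest.approx(1 - expA_S1, abs=1e-10)
        assert rowB.expected_S1 == pytest.approx(expB_S1, abs=1e-10)

    def test_expectations_track_realized_counts(self):
        cfg = SimConfig(tree=_example_newick(4), m=2000, gamma=0.17,
                        epsilon=0.65, theta=0.005, seed=12)
        res = simulate_dataset(cfg)
        jm = JunctionModel(cfg.theta, res.pillar_set.double_breaks)
        counts = expected_loss_counts(res.pillar_set, res.tree,
                                      cfg.loss_params(), jm)
        merged = counts.merge(res.branch_events, on="branch")
        # expectations at the generating parameters stay within Monte-Carlo
        # range of the realized event counts on every branch
        for _, row in merged.iterrows():
            for exp_col, true_col in (("expected_S1", "losses_S1"),
                                      ("expected_S2", "losses_S2"),
                                      ("expected_F", "fixations")):
                sd = max(3.0, np.sqrt(row[true_col]))
                assert abs(row[exp_col] - row[true_col]) < 5 * sd


class TestBlockSegmentation:
    def _posterior(self, marginals):
        marginals = np.asarray(marginals, dtype=float)
        m, n = marginals.shape
        probs = np.zeros((m, 1 << n))
        return PosteriorTable(tuple("ABCD"[:n]), probs, marginals)

    def test_uniform_confident_run_is_one_block(self):
        post = self._posterior(np.full((6, 2), 0.95))
        jm = JunctionModel(0.01, np.zeros((5, 2), dtype=bool))
        assert block_segmentation(post, jm) == [(0, 6)]

    def test_flip_splits_into_two_blocks(self):
        marg = np.full((6, 2), 0.95)
        marg[3:] = 0.05  # assignment flips at pillar 3
        post = self._posterior(marg)
        jm = JunctionModel(0.01, np.zeros((5, 2), dtype=bool))
        assert block_segmentation(post, jm) == [(0, 3), (3, 6)]

    def test_confidence_dips_terminate_blocks(self):
        m, n, min_genomes = 10, 3, 2
        marg = np.full((m, n), 0.95)
        dip_positions = [2, 5, 8]
        for i in dip_positions:
            marg[i, :n - min_genomes + 2] = 0.6  # too many genomes below 0.85
        post = self._posterior(marg)
        jm = JunctionModel(0.01, np.zeros((m - 1, n), dtype=bool))
        blocks = block_segmentation(post, jm, confidence=0.85,
                                    min_genomes=min_genomes)
        boundaries = sorted({b for blk in blocks for b in blk})
        assert boundaries == [0, 2, 3, 5, 6, 8, 9, 10]

    def test_all_genome_double_break_always_terminates(self):
        post = self._posterior(np.full((4, 2), 0.99))
        flags = np.zeros((3, 2), dtype=bool)
        flags[1] = True
        jm = JunctionModel(0.01, flags)
        assert block_segmentation(post, jm) == [(0, 2), (2, 4)]

    def test_min_genomes_bounds(self):
        post = self._posterior(np.full((3, 2), 0.9))
        jm = JunctionModel(0.01, np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            block_segmentation(post, jm, min_genomes=3)


def test_posterior_concentrates_as_theta_decreases():
    """Longer correlated blocks carry more information: the mean posterior
    probability of the generating assignment vector rises as the switching
    rate falls."""
    means = []
    for theta in (0.2, 0.05, 0.005):
        cfg = SimConfig(tree=_example_newick(3), m=600, gamma=0.17,
                        epsilon=0.65, theta=theta, seed=99,
                        double_break_rate=0.0)
        res = simulate_dataset(cfg)
        jm = JunctionModel(theta, res.pillar_set.double_breaks)
        post = posterior_assignments(res.pillar_set, res.tree,
                                     cfg.loss_params(), jm)
        true_idx = ((res.assignments - 1)
                    << np.arange(res.pillar_set.n_genomes)[None, :]).sum(axis=1)
        means.append(post.vector_probs[np.arange(post.m), true_idx].mean())
    assert means[0] < means[1] < means[2]
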