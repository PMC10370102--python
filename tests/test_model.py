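import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluorofit.model as model
from fluorofit import (
    PeptideDesign,
    SequencingParams,
    build_state_space,
    forward_backward,
    initial_distribution,
    kappa_distribution,
    simulate_reads,
    transition_factors,
)
from ._oracles import path_sum_log_likelihood, unfactored_cycle_matrix
from .conftest import random_params


class TestStateSpace:
    def test_single_label_single_cycle_has_seven_states(self):
        space = build_state_space(PeptideDesign(((1,),), n_cycles=1))
        # three unblocked states, their blocked twins, plus detached
        assert space.n_states == 7

    def test_allowed_counts_shrink_with_edman_progress(self):
        space = build_state_space(PeptideDesign(((2, 4),), n_cycles=6))
        k_at = lambda n: sorted(  # noqa: E731
            k[0] for (ne, k, blk) in space.states if ne == n and not blk
        )
        assert k_at(0) == [0, 1, 2]
        assert k_at(3) == [0, 1]
        assert k_at(4) == [0]

    def test_blocked_doubling_and_count_formula(self, tiny_design, tiny_space):
        unblocked = [s for s in tiny_space.states if not s[2]]
        blocked = [s for s in tiny_space.states if s[2]]
        assert len(unblocked) == len(blocked)
        expected = 2 * sum(
            np.prod([r + 1 for r in tiny_design.remaining_labels(n)])
            for n in range(tiny_design.n_cycles + 1)
        )
        assert tiny_space.n_states == expected + 1

    def test_ordering_is_canonical(self, tiny_space):
        keys = [(n, k, b) for (n, k, b) in tiny_space.states]
        assert keys == sorted(keys)
        assert tiny_space.detached_index == tiny_space.n_states - 1


class TestInitialDistribution:
    def test_error_free_mass_on_full_counts(self, tiny_design, tiny_space):
        p = SequencingParams(0, 0, 0, 0, (0.0,), (0.0,), (6000.0,), (700.0,), 350.0)
        pi = initial_distribution(p, tiny_space)
        full = tiny_space.state_index(0, (2,), False)
        assert pi[full] == pytest.approx(1.0)

    def test_dud_counts_are_binomial(self, tiny_params, tiny_space):
        p = tiny_params.with_rates({"dud_rate[0]": 0.2, "initial_block_rate": 0.0})
        pi = initial_distribution(p, tiny_space)
        get = lambda k: pi[tiny_space.state_index(0, (k,), False)]  # noqa: E731
        assert get(2) == pytest.approx(0.64)
        assert get(1) == pytest.approx(0.32)
        assert get(0) == pytest.approx(0.04)

    def test_conditioning_drops_dark_states_and_renormalizes(
        self, tiny_params, tiny_space
    ):
        p = tiny_params.with_rates({"dud_rate[0]": 0.2, "initial_block_rate": 0.0})
        pi = initial_distribution(p, tiny_space, condition_on_visible=True)
        get = lambda k: pi[tiny_space.state_index(0, (k,), False)]  # noqa: E731
        assert get(0) == 0.0
        assert get(2) == pytest.approx(0.64 / 0.96)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_block_probability_splits_mass(self, tiny_params, tiny_space):
        pi = initial_distribution(tiny_params, tiny_space)
        b = tiny_params.initial_block_rate
        blocked_mass = pi[tiny_space.blocked[: tiny_space.n_states - 1].nonzero()[0]].sum()
        assert blocked_mass == pytest.approx(b, abs=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestTransitionFactors:
    def test_zero_rates_give_identity_factors_except_edman(
        self, tiny_design, tiny_space
    ):
        p = SequencingParams(0, 0, 0, 0, (0.0,), (0.0,), (6000.0,), (700.0,), 350.0)
        factors = transition_factors(p, tiny_space, 1)
        for f in factors:
            if f.name == "edman":
                continue
            assert np.allclose(f.matrix.toarray(), np.eye(tiny_space.n_states))
        edman = [f for f in factors if f.name == "edman"][0].matrix.toarray()
        i = tiny_space.state_index(0, (2,), False)
        j = tiny_space.state_index(1, (1,), False)
        assert edman[i, j] == pytest.approx(1.0)  # label at position 1 removed

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_factor_rows_are_stochastic(self, tiny_design, tiny_space, seed):
        p = random_params(np.random.default_rng(seed))
        for f in transition_factors(p, tiny_space, 1):
            f.check_row_stochastic(tol=1e-12)

    @pytest.mark.parametrize(
        "labels", [((1,),), ((2,),), ((1, 2),), ((2, 4),)]
    )
    @pytest.mark.parametrize("seed", [3, 4])
    def test_factor_product_equals_enumerated_cycle_matrix(self, labels, seed):
        design = PeptideDesign(labels, n_cycles=3)
        space = build_state_space(design)
        p = random_params(np.random.default_rng(seed))
        product = transition_factors(p, space, 1).product()
        oracle = unfactored_cycle_matrix(design, p, space)
        assert np.allclose(product, oracle, atol=1e-12, rtol=0.0)

    def test_cycle_index_out_of_range(self, tiny_params, tiny_space):
        with pytest.raises(ValueError):
            transition_factors(tiny_params, tiny_space, 0)
        with pytest.raises(ValueError):
            transition_factors(tiny_params, tiny_space, 99)


class TestForwardBackward:
    def test_deterministic_single_path_likelihood(self):
        """All rates zero: the only path is the staircase, so the likelihood
        is a product of normal densities at the observed intensities."""
        design = PeptideDesign(((1,),), n_cycles=1)
        p = SequencingParams(0, 0, 0, 0, (0.0,), (0.0,), (6000.0,), (700.0,), 350.0)
        read = np.array([[6000.0], [0.0]])
        fb = forward_backward(read, design, p, condition_on_visible=False)
        expected = -0.5 * np.log(2 * np.pi * 700.0**2 * 2 * np.pi * 350.0**2)
        # one-dye emission has sd sqrt(bg^2 + sigma^2)
        import math

        sd1 = math.sqrt(350.0**2 + 700.0**2)
        expected = (
            -math.log(sd1 * math.sqrt(2 * math.pi))
            - math.log(350.0 * math.sqrt(2 * math.pi))
        )
        # degenerate zero rates are clamped to 1e-9 inside the likelihood,
        # shifting the result by a few parts in 1e9
        assert fb.log_likelihood == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("condition", [False, True])
    def test_likelihood_matches_path_enumeration(self, tiny_design, seed, condition):
        space = build_state_space(tiny_design)
        p = random_params(np.random.default_rng(100 + seed))
        sim = simulate_reads(tiny_design, p, 1, seed=seed, keep_invisible=not condition)
        read = sim.reads.intensities[0]
        pi = initial_distribution(p, space, condition_on_visible=condition)
        oracle = path_sum_log_likelihood(read, tiny_design, p, space, pi)
        fb = forward_backward(read, tiny_design, p, condition_on_visible=condition)
        assert fb.log_likelihood == pytest.approx(oracle, abs=1e-10)

    def test_posteriors_and_subtransitions_normalized(self, tiny_design, tiny_params):
        sim = simulate_reads(tiny_design, tiny_params, 3, seed=9)
        for i in range(3):
            fb = forward_backward(sim.reads.intensities[i], tiny_design, tiny_params)
            for gamma in fb.gammas:
                assert gamma.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.all(gamma >= -1e-15)
            for _name, _cycle, xi in fb.xis:
                assert xi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_rejected(self, tiny_design, tiny_params):
        with pytest.raises(ValueError):
            forward_backward(np.zeros((2, 1)), tiny_design, tiny_params)

    def test_agrees_with_reference_hmm_library(self, tiny_design, tiny_params):
        """Cross-check the scaled factor-by-factor forward pass against a
        standard Gaussian-HMM implementation on the unfactored model."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        space = build_state_space(tiny_design)
        m = unfactored_cycle_matrix(tiny_design, tiny_params, space)
        pi = initial_distribution(tiny_params, space, condition_on_visible=False)
        means = tiny_params.bg_mu + space.counts * (
            tiny_params.mu[0] - tiny_params.bg_mu
        )
        variances = tiny_params.bg_sigma**2 + space.counts * tiny_params.sigma[0] ** 2
        hmm = hmmlearn.GaussianHMM(n_components=space.n_states, covariance_type="diag")
        hmm.startprob_ = pi
        hmm.transmat_ = m
        hmm.means_ = means.astype(float)
        hmm.covars_ = variances.astype(float)
        sim = simulate_reads(tiny_design, tiny_params, 5, seed=21, keep_invisible=True)
        for i in range(5):
            read = sim.reads.intensities[i]
            fb = forward_backward(
                read, tiny_design, tiny_params, condition_on_visible=False
            )
            assert fb.log_likelihood == pytest.approx(hmm.score(read), abs=1e-8)


class TestKappaDistribution:
    def test_perfect_edman_concentrates_on_first_cycle(self):
        k = kappa_distribution(3, 0.0, 0.0, 0.0, i_max=4)
        assert k.kappa[0] == pytest.approx(1.0)
        assert np.all(k.kappa[1:] == 0.0)

    def test_geometric_tail_for_position_one(self):
        k = kappa_distribution(1, 0.1, 0.0, 0.0, i_max=3)
        assert np.allclose(k.kappa[:3], [0.9, 0.09, 0.009])

    @given(
        r=st.integers(1, 6),
        e=st.floats(0.01, 0.8),
        b=st.floats(0.0, 0.9),
        c=st.floats(0.0, 0.8),
    )
    @settings(max_examples=60, deadline=None)
    def test_ratio_recurrence(self, r, e, b, c):
        """kappa_{i+1}/kappa_i == e*(1-c)*(i+r)/(i+1) identically."""
        k = kappa_distribution(r, e, b, c, i_max=6)
        i = np.arange(6)
        expected = e * (1.0 - c) * (i + r) / (i + 1)
        assert np.allclose(k.ratios(), expected, rtol=1e-12)

    def test_ratios_depend_only_on_e_times_one_minus_c(self):
        """Rescaling e so that e(1-c) is constant leaves every ratio
        unchanged: the two rates are not separately identifiable from the
        tail shape."""
        base = kappa_distribution(2, 0.10, 0.05, 0.0, i_max=8)
        c = 0.3
        rescaled = kappa_distribution(2, 0.10 / (1 - c), 0.05, c, i_max=8)
        assert np.allclose(base.ratios(), rescaled.ratios(), rtol=1e-12)

    def test_invalid_position_rejected(self):
        with pytest.raises(ValueError):
            kappa_distribution(0, 0.1, 0.0, 0.0)

    def test_probabilities_sum_below_one_with_blocking(self):
        k = kappa_distribution(2, 0.1, 0.3, 0.1, i_max=200)
        assert 0.0 < k.kappa.sum() < 1.0
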