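import numpy as np
import pytest

import fluorofit as ff
from fluorofit import (
    PeptideDesign,
    SequencingParams,
    WeightedCount,
    accumulate_sufficient_stats,
    build_state_space,
    dud_bias_correction,
    fit_baum_welch,
    forward_backward,
    m_step,
    simulate_reads,
)
from fluorofit.baum_welch import _EStepEngine
from fluorofit.params import rate_names_for


def _sum_stats(a, b):
    return {k: a[k] + b[k] for k in a}


class TestSufficientStats:
    def test_batch_engine_matches_per_read_posterior_accumulation(
        self, tiny_design, tiny_params, tiny_space
    ):
        """The vectorized E-step and the explicit per-read sub-transition
        posteriors must produce identical weighted counts."""
        sim = simulate_reads(tiny_design, tiny_params, 6, seed=11)
        engine = _EStepEngine(sim.reads.intensities, tiny_design, tiny_params)
        loglik, batch = engine.run(tiny_params)
        agg = None
        singles = []
        for i in range(6):
            fb = forward_backward(
                sim.reads.intensities[i], tiny_design, tiny_params, space=tiny_space
            )
            singles.append(fb.log_likelihood)
            s = accumulate_sufficient_stats(fb, tiny_space, tiny_design)
            agg = s if agg is None else _sum_stats(agg, s)
        assert np.allclose(loglik, singles, atol=1e-9)
        for name in agg:
            assert batch[name].n == pytest.approx(agg[name].n, abs=1e-8)
            assert batch[name].x == pytest.approx(agg[name].x, abs=1e-8)

    def test_stats_additive_across_reads(self, tiny_design, tiny_params, tiny_space):
        sim = simulate_reads(tiny_design, tiny_params, 4, seed=12)
        parts = []
        for i in range(4):
            fb = forward_backward(
                sim.reads.intensities[i], tiny_design, tiny_params, space=tiny_space
            )
            parts.append(accumulate_sufficient_stats(fb, tiny_space, tiny_design))
        total = parts[0]
        for p in parts[1:]:
            total = _sum_stats(total, p)
        engine = _EStepEngine(sim.reads.intensities, tiny_design, tiny_params)
        _, batch = engine.run(tiny_params)
        for name in total:
            assert batch[name].n == pytest.approx(total[name].n, abs=1e-8)

    def test_zero_error_reads_have_no_error_evidence(self, tiny_design):
        p = SequencingParams(0, 0, 0, 0, (0.0,), (0.0,), (6000.0,), (700.0,), 350.0)
        sim = simulate_reads(tiny_design, p, 30, seed=13)
        engine = _EStepEngine(sim.reads.intensities, tiny_design, p)
        _, stats = engine.run(p)
        for name, count in stats.items():
            assert count.x / max(count.n, 1.0) < 1e-6, name

    def test_dye_loss_rate_matches_hand_counted_events(self):
        """Complete-data oracle: with near-zero intensity noise the posterior
        is concentrated on the true path, so the weighted dye-loss estimate
        must equal the directly counted fraction of fluorophore-cycles ending
        in loss.  Labels sit beyond the Edman window so no removal interferes."""
        design = PeptideDesign(((9, 10),), n_cycles=3)
        p = SequencingParams(
            0.1, 0.0, 0.0, 0.0, (0.12,), (0.0,), (6000.0,), (1e-3,), 1e-3
        )
        sim = simulate_reads(design, p, 400, seed=14)
        counts = sim.truth_tracks[:, :, 0]
        trials = counts[:, :-1].sum()
        losses = (counts[:, :-1] - counts[:, 1:]).sum()
        engine = _EStepEngine(sim.reads.intensities, design, p)
        _, stats = engine.run(p)
        wc = stats["dye_loss_rate[0]"]
        assert wc.n == pytest.approx(trials, rel=1e-6)
        assert wc.x == pytest.approx(losses, rel=1e-6)


class TestMStep:
    def test_rate_is_success_fraction(self, tiny_params, tiny_design):
        stats = {n: WeightedCount(100.0, 5.0) for n in rate_names_for(tiny_design)}
        stats["edman_failure_rate"] = WeightedCount(200.0, 10.0)
        stats["detach_rate"] = WeightedCount(50.0, 0.0)
        out = m_step(stats, {}, tiny_params)
        assert out.edman_failure_rate == pytest.approx(0.05)
        assert out.detach_rate == 0.0

    def test_constraint_pins_dominate_stats(self, tiny_params, tiny_design):
        stats = {n: WeightedCount(100.0, 30.0) for n in rate_names_for(tiny_design)}
        out = m_step(stats, {"detach_rate": 0.0}, tiny_params)
        assert out.detach_rate == 0.0
        assert out.cyclic_block_rate == pytest.approx(0.3)

    def test_intensity_model_held_fixed(self, tiny_params, tiny_design):
        stats = {n: WeightedCount(10.0, 1.0) for n in rate_names_for(tiny_design)}
        out = m_step(stats, {}, tiny_params)
        assert out.mu == tiny_params.mu and out.sigma == tiny_params.sigma

    def test_zero_trials_signals_non_identifiability(self, tiny_params, tiny_design):
        stats = {n: WeightedCount(10.0, 1.0) for n in rate_names_for(tiny_design)}
        stats["detach_rate"] = WeightedCount(0.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            m_step(stats, {}, tiny_params)


class TestDudBiasCorrection:
    def test_no_duds_no_pseudo_reads(self, tiny_design, tiny_params):
        p = tiny_params.with_rates({"dud_rate[0]": 0.0})
        state, extra = dud_bias_correction(1000, p, tiny_design)
        assert state.missing_reads_estimate == 0.0
        assert extra["dud_rate[0]"].n == 0.0

    def test_missing_read_estimate_formula(self, tiny_design, tiny_params):
        # force the all-dud probability x to 0.2 via a single-label design
        design = PeptideDesign(((1,),), n_cycles=2)
        p = tiny_params.with_rates({"dud_rate[0]": 0.2})
        state, extra = dud_bias_correction(1000, p, design)
        assert state.all_dud_prob == pytest.approx(0.2)
        assert state.missing_reads_estimate == pytest.approx(250.0)
        assert extra["dud_rate[0]"].n == pytest.approx(250.0)
        assert extra["dud_rate[0]"].x == pytest.approx(250.0)

    def test_two_labels_square_the_dud_probability(self, tiny_design, tiny_params):
        p = tiny_params.with_rates({"dud_rate[0]": 0.3})
        state, extra = dud_bias_correction(500, p, tiny_design)
        assert state.all_dud_prob == pytest.approx(0.09)
        # each pseudo-read carries both labels as duds
        assert extra["dud_rate[0]"].n == pytest.approx(
            2 * 500 * 0.09 / 0.91
        )


@pytest.fixture(scope="module")
def small_fit(tiny_design, tiny_params):
    sim = simulate_reads(tiny_design, tiny_params, 3000, seed=15)
    init = tiny_params.with_rates({n: 0.05 for n in rate_names_for(tiny_design)})
    result = fit_baum_welch(
        sim.reads, tiny_design, init, n_starts=1, tol=1e-5, max_iter=200
    )
    return sim, result


class TestFitBaumWelch:
    def test_recovers_rates_at_moderate_sample_size(
        self, small_fit, tiny_design, tiny_params
    ):
        _, result = small_fit
        for name in rate_names_for(tiny_design):
            assert result.params_hat.get_rate(name) == pytest.approx(
                tiny_params.get_rate(name), abs=0.03
            )

    def test_log_likelihood_trace_non_decreasing(self, small_fit):
        _, result = small_fit
        diffs = np.diff(result.trace)
        assert np.all(diffs >= -1e-8 * np.abs(result.trace[:-1]))

    def test_exact_em_monotonicity_without_censoring(self, tiny_design, tiny_params):
        """In the regime where classical EM theory applies exactly (complete
        visibility, no censoring correction) the trace must be monotone to
        within accumulation error."""
        sim = simulate_reads(tiny_design, tiny_params, 1500, seed=16, keep_invisible=True)
        init = tiny_params.with_rates({n: 0.03 for n in rate_names_for(tiny_design)})
        result = fit_baum_welch(
            sim.reads,
            tiny_design,
            init,
            n_starts=1,
            condition_on_visible=False,
            dud_correction=False,
            tol=1e-7,
            max_iter=300,
        )
        diffs = np.diff(result.trace)
        assert np.all(diffs >= -1e-8 * np.maximum(np.abs(result.trace[:-1]), 1.0))

    def test_self_consistency_at_generating_values(self, tiny_design, tiny_params):
        """Starting EM at the true generating parameters, the first update
        moves each rate by no more than Monte-Carlo noise."""
        sim = simulate_reads(tiny_design, tiny_params, 8000, seed=17)
        result = fit_baum_welch(
            sim.reads, tiny_design, tiny_params, n_starts=1, max_iter=1, tol=0.0,
            accelerate=False,
        )
        for name in rate_names_for(tiny_design):
            assert abs(
                result.params_hat.get_rate(name) - tiny_params.get_rate(name)
            ) < 0.02

    def test_single_read_dataset_is_legal(self, tiny_design, tiny_params):
        sim = simulate_reads(tiny_design, tiny_params, 1, seed=18)
        result = fit_baum_welch(
            sim.reads, tiny_design, tiny_params, n_starts=1, max_iter=20, tol=1e-3
        )
        assert np.isfinite(result.objective)

    def test_constraints_applied_for_single_label_design(self):
        design = PeptideDesign(((2,),), n_cycles=4)
        p = SequencingParams(
            0.08, 0.0, 0.1, 0.0, (0.05,), (0.0,), (6000.0,), (700.0,), 350.0
        )
        sim = simulate_reads(design, p, 1500, seed=19)
        init = p.with_rates({"edman_failure_rate": 0.05})
        result = fit_baum_welch(sim.reads, design, init, n_starts=1, tol=1e-4)
        assert result.params_hat.detach_rate == 0.0
        assert result.params_hat.cyclic_block_rate == 0.0
        assert result.params_hat.dud_rate[0] == 0.0
        assert set(result.constraints) == {
            "detach_rate",
            "cyclic_block_rate",
            "dud_rate[0]",
        }

    def test_empty_dataset_rejected(self, tiny_design, tiny_params):
        from fluorofit.reads import ReadSet

        empty = ReadSet(np.zeros((0, tiny_design.n_timepoints, 1)))
        with pytest.raises(ValueError):
            fit_baum_welch(empty, tiny_design, tiny_params)

    def test_float32_engine_agrees_with_float64(self, tiny_design, tiny_params):
        sim = simulate_reads(tiny_design, tiny_params, 2000, seed=20)
        init = tiny_params.with_rates({n: 0.05 for n in rate_names_for(tiny_design)})
        r64 = fit_baum_welch(sim.reads, tiny_design, init, n_starts=1, tol=1e-5)
        r32 = fit_baum_welch(
            sim.reads, tiny_design, init, n_starts=1, tol=1e-5, dtype=np.float32
        )
        for name in rate_names_for(tiny_design):
            assert r32.params_hat.get_rate(name) == pytest.approx(
                r64.params_hat.get_rate(name), abs=5e-4
            )


class TestCensoringBias:
    def test_uncorrected_dud_estimate_is_biased_low(self, tiny_design):
        """Visible-only data without the correction underestimates the dud
        rate; the correction restores it (small-scale version of the
        censoring experiment)."""
        p = SequencingParams(
            0.06, 0.02, 0.05, 0.01, (0.04,), (0.25,), (6000.0,), (700.0,), 350.0
        )
        sim = simulate_reads(tiny_design, p, 6000, seed=21)
        init = p.with_rates({n: 0.05 for n in rate_names_for(tiny_design)})
        corrected = fit_baum_welch(
            sim.reads, tiny_design, init, n_starts=1, tol=1e-5
        )
        uncorrected = fit_baum_welch(
            sim.reads, tiny_design, init, n_starts=1, tol=1e-5, dud_correction=False
        )
        m_corr = corrected.params_hat.dud_rate[0]
        m_raw = uncorrected.params_hat.dud_rate[0]
        assert m_raw < m_corr
        assert m_corr == pytest.approx(0.25, abs=0.04)


class TestDetachDyeLossConfounding:
    def test_detachment_folds_into_dye_loss_when_pinned(self):
        """For a single fluorophore, losing the dye and losing the peptide
        are visibly identical: data generated with detachment, fitted with
        the detach rate pinned to zero, recover the combined per-cycle
        survival as dye loss."""
        design = PeptideDesign(((2,),), n_cycles=6)
        base = dict(
            edman_failure_rate=0.08,
            initial_block_rate=0.05,
            cyclic_block_rate=0.0,
            dud_rate=(0.0,),
            mu=(6000.0,),
            sigma=(700.0,),
            bg_sigma=350.0,
        )
        pure_loss = SequencingParams(detach_rate=0.0, dye_loss_rate=(0.06,), **base)
        # same per-cycle dye survival 0.94 split between the two mechanisms
        mixed = SequencingParams(
            detach_rate=1.0 - 0.94 / 0.97, dye_loss_rate=(0.03,), **base
        )
        fits = []
        for p in (pure_loss, mixed):
            sim = simulate_reads(design, p, 6000, seed=55)
            init = p.with_rates(
                {"dye_loss_rate[0]": 0.05, "detach_rate": 0.0}
            )
            fits.append(
                fit_baum_welch(sim.reads, design, init, n_starts=1, tol=1e-5)
            )
        l_pure = fits[0].params_hat.dye_loss_rate[0]
        l_mixed = fits[1].params_hat.dye_loss_rate[0]
        assert l_pure == pytest.approx(0.06, abs=0.01)
        assert l_mixed == pytest.approx(l_pure, abs=0.012)
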