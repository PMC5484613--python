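"""Kernel estimation, psychometric fits, conditioning and seriality."""

import numpy as np
import pytest
from scipy.special import expit

import hiertree as ht
from hiertree.accumulator_models import SimResult
from hiertree.psychophysics_analysis import (
    ConditionalPsychometrics,
    _irls_logit,
    estimate_kernel,
    fit_psychometric,
    kernel_seriality,
)


def _synthetic_results(trials, decide, rt=1500.0):
    """Wrap a per-trial choice rule into SimResult objects."""
    out = []
    for t in trials:
        l1, l2 = decide(t)
        out.append(
            SimResult(
                trial_id=t.trial_id,
                model_name="synthetic",
                choice_per_level=(l1, l2),
                correct_per_level=(l1 == t.target_path[0], l2 == t.target_path[1]),
                rt=rt,
                terminated_by_bound=False,
                seed=0,
            )
        )
    return out


@pytest.fixture(scope="module")
def flat_trials():
    """Zero-signal trials: choices can only reflect noise."""
    spec = ht.make_tree_task(difficulty_levels=((0.0,), (0.0,)))
    return ht.generate_trials(spec, 5000, seed=200)


class TestEstimateKernel:
    def test_stimulus_blind_choices_have_null_kernel(self, flat_trials):
        rng = np.random.default_rng(0)
        res = _synthetic_results(
            flat_trials,
            lambda t: (rng.choice(["left", "right"]), rng.choice(["up", "down"])),
        )
        k = estimate_kernel(flat_trials, res, level=1, n_boot=400, seed=1)
        covers = (k.ci_low <= 0) & (0 <= k.ci_high)
        assert covers.mean() >= 0.85  # pointwise 95% CIs

    def test_single_frame_observer_peaks_at_that_frame(self, flat_trials):
        def decide(t):
            d = t.noise("L1-left") - t.noise("L1-right")
            return ("left" if d[3] > 0 else "right", "up")

        res = _synthetic_results(flat_trials, decide)
        k = estimate_kernel(flat_trials, res, level=1, n_boot=400, seed=2)
        assert int(np.argmax(k.weights)) == 3
        others = np.arange(len(k.weights)) != 3
        covers = (k.ci_low <= 0) & (0 <= k.ci_high)
        assert covers[others].mean() >= 0.85

    def test_linear_observer_kernel_proportional_to_weights(self, flat_trials):
        w = np.linspace(1.0, 0.25, flat_trials[0].n_frames)

        def decide(t):
            d = t.noise("L1-left") - t.noise("L1-right")
            return ("left" if w @ d > 0 else "right", "up")

        res = _synthetic_results(flat_trials, decide)
        k = estimate_kernel(flat_trials, res, level=1, n_boot=500, seed=3)
        scale = (k.weights @ w) / (w @ w)
        covered = (k.ci_low <= scale * w) & (scale * w <= k.ci_high)
        assert covered.mean() >= 0.85

    def test_level2_kernel_uses_visited_bifurcation(self, flat_trials):
        # observer decides L2 from the distractor-side bifurcation when it
        # went to the distractor side; the L2 kernel must still recover it
        def decide(t):
            side = "right" if t.target_path[0] == "left" else "left"  # always wrong at L1
            d = t.noise("DT") - t.noise("DD")
            local_t = d.sum() > 0
            l2 = t.target_path[1] if local_t else ht.flip(t.target_path[1])
            return (side, l2)

        res = _synthetic_results(flat_trials, decide)
        k = estimate_kernel(flat_trials, res, level=2, n_boot=100, seed=4)
        assert np.all(k.weights > 0)  # every frame entered the sum rule

    def test_response_alignment_reindexes_backward(self, flat_trials):
        # decision from the last frame before a 700 ms report: response-
        # aligned bin 0 (the frame just before the report) carries the peak
        def decide(t):
            d = t.noise("L1-left") - t.noise("L1-right")
            return ("left" if d[6] > 0 else "right", "up")

        res = _synthetic_results(flat_trials, decide, rt=700.0)
        k = estimate_kernel(flat_trials, res, level=1, alignment="response",
                            n_boot=100, seed=5)
        assert int(np.argmax(np.nan_to_num(k.weights))) == 0
        assert k.frame_times[0] == -flat_trials[0].sample_period
        assert np.isnan(k.weights[8])  # only 7 complete frames before report

    def test_errors(self, flat_trials):
        res = _synthetic_results(flat_trials, lambda t: ("left", "up"))
        with pytest.raises(ValueError, match="level"):
            estimate_kernel(flat_trials, res, level=3)
        with pytest.raises(ValueError, match="no trials"):
            estimate_kernel([], [], level=1)


class TestFitPsychometric:
    def test_coin_flip_slope_ci_covers_zero(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 4, 4000)
        y = rng.integers(0, 2, 4000)
        fit = fit_psychometric(x, y)
        assert abs(fit.slope) < 3 * fit.slope_se

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 5, 10_000)
        p = expit(0.3 * (x - 0.0))
        y = (rng.random(10_000) < p).astype(float)
        fit = fit_psychometric(x, y)
        assert abs(fit.slope - 0.3) < 3 * fit.slope_se
        assert abs(fit.bias - 0.0) < 3 * fit.bias_se

    def test_antisymmetric_data_has_zero_bias(self):
        x = np.array([-3.0, -1.0, 1.0, 3.0] * 50)
        y = np.array([0.0, 0.0, 1.0, 1.0] * 50)
        x_full = np.concatenate([x, -x])
        y_full = np.concatenate([y, 1 - y])
        # break perfect separation symmetrically
        x_full = np.concatenate([x_full, [0.5, -0.5]])
        y_full = np.concatenate([y_full, [0.0, 1.0]])
        fit = fit_psychometric(x_full, y_full)
        assert fit.bias == pytest.approx(0.0, abs=1e-6)

    def test_complete_separation_flagged_degenerate(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0] * 10)
        y = (x > 0).astype(float)
        fit = fit_psychometric(x, y)
        assert fit.degenerate
        assert np.isinf(fit.slope)

    def test_single_valued_evidence_degenerate(self):
        fit = fit_psychometric(np.ones(50), np.r_[np.zeros(25), np.ones(25)])
        assert fit.degenerate

    def test_free_lapse_recovers_lapse(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 6, 20_000)
        lapse = 0.08
        p = lapse + (1 - 2 * lapse) * expit(0.5 * x)
        y = (rng.random(20_000) < p).astype(float)
        fit = fit_psychometric(x, y, lapse_mode="free")
        assert fit.lapse == pytest.approx(lapse, abs=0.03)
        assert fit.slope == pytest.approx(0.5, rel=0.15)

    def test_irls_matches_statsmodels(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 3, 3000)
        y = (rng.random(3000) < expit(0.4 * x + 0.2)).astype(float)
        b0, b1 = _irls_logit(x, y)
        fit = fit_psychometric(x, y)
        assert b1 == pytest.approx(fit.slope, rel=1e-6)
        assert -b0 / b1 == pytest.approx(fit.bias, rel=1e-5, abs=1e-8)


class TestConditionalPsychometric:
    def test_duplicate_strata_give_unit_ratio(self, spec2):
        trials = ht.generate_trials(spec2, 400, seed=20)
        res = ht.batch_simulate(trials, "flat_race", ht.FlatRaceParams(), seed=21)
        # force both strata to be identical copies of the same behavior
        import dataclasses

        half = [dataclasses.replace(r, correct_per_level=(True, r.correct_per_level[1]))
                for r in res]
        other = [dataclasses.replace(r, trial_id=r.trial_id + 400,
                                     correct_per_level=(False, r.correct_per_level[1]))
                 for r in res]
        twin_trials = trials + [dataclasses.replace(t, trial_id=t.trial_id + 400)
                                for t in trials]
        cp = ht.conditional_psychometric(twin_trials, half + other, n_boot=50, seed=0)
        assert cp.slope_ratio == pytest.approx(1.0, abs=1e-6)

    def test_empty_stratum_raises(self, spec2):
        trials = ht.generate_trials(spec2, 50, seed=22)
        res = _synthetic_results(trials, lambda t: (t.target_path[0], t.target_path[1]))
        with pytest.raises(ValueError, match="L1-error"):
            ht.conditional_psychometric(trials, res)

    def test_flat_lca_flattens_l2_on_l1_correct(self, spec2):
        trials = ht.generate_trials(spec2, 8000, seed=23)
        res = ht.batch_simulate(trials, "flat_lca", ht.FlatLCAParams(), seed=24)
        cp = ht.conditional_psychometric(trials, res, n_boot=200, seed=0)
        assert cp.accuracy_given_l1_correct < cp.accuracy_given_l1_error
        assert cp.slope_ratio > 1.0


class TestRTByDifficulty:
    def test_equal_rts_zero_correlation(self, spec2):
        trials = ht.generate_trials(spec2, 60, seed=30)
        res = _synthetic_results(trials, lambda t: ("left", "up"), rt=800.0)
        labels = [i % 3 for i in range(60)]
        out = ht.rt_by_difficulty(res, labels)
        assert (out.table["mean_rt_ms"] == 800.0).all()
        assert out.rank_corr == pytest.approx(0.0) or np.isnan(out.rank_corr)

    def test_single_level_reports_nan_correlation(self, spec2):
        trials = ht.generate_trials(spec2, 20, seed=31)
        res = _synthetic_results(trials, lambda t: ("left", "up"))
        out = ht.rt_by_difficulty(res, [0] * 20)
        assert len(out.table) == 1
        assert np.isnan(out.rank_corr)

    def test_missing_labels_rejected(self, spec2):
        trials = ht.generate_trials(spec2, 5, seed=32)
        res = _synthetic_results(trials, lambda t: ("left", "up"))
        with pytest.raises(ValueError, match="missing"):
            ht.rt_by_difficulty(res, [0, 1, None, 0, 1])


class TestKernelSeriality:
    def _kernel(self, weights, times=None):
        w = np.asarray(weights, dtype=float)
        t = np.arange(len(w)) * 100.0 if times is None else times
        return ht.KernelEstimate(level=1, alignment="stimulus_onset", weights=w,
                                 ci_low=w, ci_high=w, frame_times=t,
                                 n_trials=1, n_boot=1)

    def test_identical_kernels(self):
        k = self._kernel([0.1, 0.5, 0.3, 0.1])
        s = kernel_seriality(k, k)
        assert s.overlap == pytest.approx(1.0)
        assert s.com_offset == pytest.approx(0.0)

    def test_disjoint_kernels(self):
        a = self._kernel([1.0, 1.0, 0.0, 0.0])
        b = self._kernel([0.0, 0.0, 1.0, 1.0])
        s = kernel_seriality(a, b)
        assert s.overlap == pytest.approx(0.0)
        assert s.com_offset == pytest.approx(200.0)

    def test_all_zero_kernel_rejected(self):
        a = self._kernel([1.0, 1.0])
        z = self._kernel([-1.0, 0.0])
        with pytest.raises(ValueError, match="all-zero"):
            kernel_seriality(a, z)

    def test_mismatched_alignment_rejected(self):
        a = self._kernel([1.0, 1.0])
        b = ht.KernelEstimate(level=2, alignment="response", weights=a.weights,
                              ci_low=a.weights, ci_high=a.weights,
                              frame_times=a.frame_times, n_trials=1, n_boot=1)
        with pytest.raises(ValueError, match="alignment"):
            kernel_seriality(a, b)

    def test_serial_tracer_l2_kernel_lags_l1(self, spec2):
        trials = ht.generate_trials(spec2, 3000, seed=33)
        res = ht.batch_simulate(trials, "serial", ht.SerialParams(), seed=34)
        k1 = estimate_kernel(trials, res, 1, n_boot=50, seed=0)
        k2 = estimate_kernel(trials, res, 2, n_boot=50, seed=0)
        assert kernel_seriality(k1, k2).com_offset > 0
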