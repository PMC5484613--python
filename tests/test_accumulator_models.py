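"""Model dynamics: races, LCA regimes, serial stages, hierarchy."""

import numpy as np
import pytest

import hiertree as ht
from hiertree.accumulator_models import LEAVES_2


def _constant_trial(spec, offsets=(8.0, 8.0), path=("left", "up"), trial_id=0):
    return ht.generate_trial_at_offsets(spec, offsets, path, seed=0, trial_id=trial_id)


class TestFlatRace:
    def test_constant_evidence_tt_always_wins(self, noiseless_spec):
        t = _constant_trial(noiseless_spec)
        r = ht.run_flat_race(t, ht.FlatRaceParams(bound=30.0), seed=1)
        assert r.choice_per_level == ("left", "up")
        assert r.correct_per_level == (True, True)
        assert r.terminated_by_bound

    def test_zero_evidence_each_leaf_wins_quarter(self):
        spec = ht.make_tree_task(difficulty_levels=((0.0,), (0.0,)))
        trials = ht.generate_trials(spec, 10_000, seed=2)
        res = ht.batch_simulate(trials, "flat_race", ht.FlatRaceParams(bound=30.0), seed=3)
        wins = {leaf: 0 for leaf in LEAVES_2}
        for t, r in zip(trials, res):
            leaf = ("T" if r.correct_l1 else "D") + ("T" if r.correct_l2 else "D")
            wins[leaf] += 1
        for leaf in LEAVES_2:
            # binomial 5-sigma band around 0.25 at n=1e4
            assert abs(wins[leaf] / 10_000 - 0.25) < 5 * np.sqrt(0.25 * 0.75 / 10_000)

    def test_frame1_crossing_matches_single_frame_oracle(self, spec2):
        # tiny bound: decision within frame 1 must equal argmax of frame-1 evidence
        trials = ht.generate_trials(spec2, 300, seed=4)
        res = ht.batch_simulate(trials, "flat_race", ht.FlatRaceParams(bound=1e-9), seed=5)
        for t, r in zip(trials, res):
            c1 = (t.samples[t.l1_target_branch][0] - t.samples[t.l1_distractor_branch][0]) / 2
            c2t = (t.samples["TT"][0] - t.samples["TD"][0]) / 2
            c2d = (t.samples["DT"][0] - t.samples["DD"][0]) / 2
            ev = [c1 + c2t, c1 - c2t, -c1 + c2d, -c1 - c2d]
            leaf = LEAVES_2[int(np.argmax(ev))]
            assert r.correct_per_level == (leaf[0] == "T", leaf[1] == "T")
            assert r.rt == t.sample_period

    def test_three_level_trial_rejected(self, spec3):
        t = ht.generate_trial(spec3, (0, 0, 0), ("left", "up", "up"), seed=0)
        with pytest.raises(ValueError, match="depth"):
            ht.run_flat_race(t, ht.FlatRaceParams(), seed=0)


class TestFlatLCA:
    def test_self_excitation_gives_exponential_growth(self, noiseless_spec):
        # closed form: one dominating unit with net rate (alpha - leak)
        t = _constant_trial(noiseless_spec)
        p = ht.FlatLCAParams(self_excitation=0.01, leak=0.002, global_inhibition=0.0,
                             noise_sd_model=0.0, bound=1e12)
        r = ht.run_flat_lca(t, p, seed=0, record_activity=True)
        from hiertree.activity_analysis import exponential_growth_test
        fit = exponential_growth_test(r.activity["TT"], r.activity_times, (600, 1400))
        assert fit.rate == pytest.approx(0.008, rel=0.05)
        assert fit.r_squared > 0.999

    def test_rectification_keeps_activity_nonnegative(self, spec2):
        trials = ht.generate_trials(spec2, 50, seed=6)
        res = ht.batch_simulate(trials, "flat_lca", ht.FlatLCAParams(rectify=True),
                                seed=7, record_activity=True)
        for r in res:
            assert min(tr.min() for tr in r.activity.values()) >= 0.0

    def test_collapsing_regime_decides_exactly_at_collapse(self, spec2):
        trials = ht.generate_trials(spec2, 40, seed=8)
        p = ht.FlatLCAParams(bound_regime="collapsing_500", nondecision_time=50.0)
        res = ht.batch_simulate(trials, "flat_lca", p, seed=9)
        assert all(r.rt == 550.0 for r in res)
        assert not any(r.terminated_by_bound for r in res)

    def test_stable_regime_flags_unreached_bound(self, spec2):
        trials = ht.generate_trials(spec2, 300, seed=10)
        res = ht.batch_simulate(trials, "flat_lca", ht.FlatLCAParams(), seed=11)
        frac_unreached = np.mean([not r.terminated_by_bound for r in res])
        assert 0.3 < frac_unreached < 1.0
        for r in res:
            if not r.terminated_by_bound:
                assert r.rt == 1500.0

    def test_invalid_regimes_rejected(self):
        with pytest.raises(ValueError, match="collapse_time"):
            ht.FlatLCAParams(bound_regime="collapsing_500", collapse_time=0.0)
        with pytest.raises(ValueError, match="dt"):
            ht.FlatLCAParams(dt=0.0)


class TestSerialTracer:
    def test_stage_times_strictly_ordered(self, spec2, spec3):
        trials = ht.generate_trials(spec2, 100, seed=12)
        res = ht.batch_simulate(trials, "serial", ht.SerialParams(), seed=13)
        for r in res:
            t1, t2 = r.stage_decision_times
            assert t1 < t2

        trials3 = ht.generate_trials(spec3, 50, seed=14)
        res3 = ht.batch_simulate(trials3, "serial", ht.SerialParams(), seed=15)
        for r in res3:
            t1, t2, t3 = r.stage_decision_times
            assert t1 < t2 < t3

    def test_weak_second_stage_takes_longer(self, spec2):
        # strong L1 evidence, weak L2: bounded accumulation is slower when harder
        spec = ht.make_tree_task(difficulty_levels=((8.0,), (2.0,)))
        trials = ht.generate_trials(spec, 2000, seed=16)
        res = ht.batch_simulate(trials, "serial", ht.SerialParams(), seed=17)
        d1 = np.mean([r.stage_decision_times[0] for r in res])
        d2 = np.mean([r.stage_decision_times[1] - r.stage_decision_times[0] for r in res])
        assert d2 > d1

    def test_rt_is_last_stage_plus_nondecision(self, spec2):
        trials = ht.generate_trials(spec2, 20, seed=18)
        p = ht.SerialParams(nondecision_time=120.0)
        res = ht.batch_simulate(trials, "serial", p, seed=19)
        for r in res:
            assert r.rt == pytest.approx(r.stage_decision_times[-1] + 120.0)


class TestHierarchical:
    def test_beta_zero_l1_choice_independent_of_l2_noise(self):
        spec = ht.make_tree_task(difficulty_levels=((0.0,), (0.0,)))
        trials = ht.generate_trials(spec, 10_000, seed=20)
        p = ht.HierarchicalParams(confidence_weight=0.0)
        res = ht.batch_simulate(trials, "hierarchical", p, seed=21)
        l1 = np.array([r.correct_l1 for r in res], dtype=float)
        l2noise = np.array([
            (t.samples["TT"] - t.samples["TD"]).sum() for t in trials
        ])
        rho = np.corrcoef(l1, l2noise)[0, 1]
        assert abs(rho) < 4 / np.sqrt(len(trials))

    def test_positive_beta_biases_l1_toward_easier_side(self):
        # one L2 bifurcation easy (offset 8), the other uninformative:
        # beta > 0 raises confidence on the easy (target) side, boosting
        # P(choose target side at L1) relative to beta = 0 at matched seeds
        import dataclasses

        spec = ht.make_tree_task(difficulty_levels=((0.0,), (8.0,)))
        trials = []
        for t in ht.generate_trials(spec, 4000, seed=22):
            s = dict(t.samples)
            m = dict(t.generative_means)
            s["DT"] = s["DT"] - 8.0
            m["DT"] = m["DT"] - 8.0
            trials.append(dataclasses.replace(t, samples=s, generative_means=m))
        base = ht.batch_simulate(trials, "hierarchical",
                                 ht.HierarchicalParams(confidence_weight=0.0), seed=23)
        biased = ht.batch_simulate(trials, "hierarchical",
                                   ht.HierarchicalParams(confidence_weight=50.0), seed=23)
        p0 = np.mean([r.correct_l1 for r in base])
        p1 = np.mean([r.correct_l1 for r in biased])
        assert p1 > p0 + 0.02

    def test_zero_deadline_gives_chance_choices(self, spec2):
        trials = ht.generate_trials(spec2, 2000, seed=24)
        p = ht.HierarchicalParams(deadline=0.0)
        res = ht.batch_simulate(trials, "hierarchical", p, seed=25)
        acc1 = np.mean([r.correct_l1 for r in res])
        acc2 = np.mean([r.correct_l2 for r in res])
        assert abs(acc1 - 0.5) < 5 * np.sqrt(0.25 / 2000)
        assert abs(acc2 - 0.5) < 5 * np.sqrt(0.25 / 2000)


class TestBatchSimulate:
    def test_empty_batch(self):
        assert ht.batch_simulate([], "flat_race", ht.FlatRaceParams(), seed=0) == []

    def test_unknown_model_rejected(self, small_batch):
        with pytest.raises(ValueError, match="unknown model"):
            ht.batch_simulate(small_batch, "bayes_net", None, seed=0)

    def test_same_seed_identical_results(self, small_batch):
        a = ht.batch_simulate(small_batch, "flat_lca", ht.FlatLCAParams(), seed=30)
        b = ht.batch_simulate(small_batch, "flat_lca", ht.FlatLCAParams(), seed=30)
        assert [(r.choice_per_level, r.rt) for r in a] == [(r.choice_per_level, r.rt) for r in b]

    @pytest.mark.parametrize("model,params", [
        ("flat_race", ht.FlatRaceParams()),
        ("flat_lca", ht.FlatLCAParams()),
        ("serial", ht.SerialParams()),
        ("hierarchical", ht.HierarchicalParams()),
    ])
    def test_results_invariant_under_trial_permutation(self, small_batch, model, params):
        rng = np.random.default_rng(31)
        perm = rng.permutation(len(small_batch))
        straight = ht.batch_simulate(small_batch, model, params, seed=32)
        shuffled = ht.batch_simulate([small_batch[i] for i in perm], model, params, seed=32)
        by_id = {r.trial_id: r for r in shuffled}
        for r in straight:
            assert by_id[r.trial_id].choice_per_level == r.choice_per_level
            assert by_id[r.trial_id].rt == r.rt

    def test_mixed_depth_batch_rejected(self, spec2, spec3):
        t2 = ht.generate_trial(spec2, (0, 0), ("left", "up"), seed=0)
        t3 = ht.generate_trial(spec3, (0, 0, 0), ("left", "up", "up"), seed=0, trial_id=1)
        with pytest.raises(ValueError, match="homogeneous"):
            ht.batch_simulate([t2, t3], "serial", ht.SerialParams(), seed=0)

    def test_rt_respects_nondecision_floor(self, small_batch):
        res = ht.batch_simulate(small_batch, "flat_race",
                                ht.FlatRaceParams(nondecision_time=200.0), seed=33)
        assert all(r.rt >= 200.0 for r in res)


class TestZeroNoiseOracle:
    def test_all_architectures_follow_cumulative_evidence(self, noiseless_spec):
        # with no stimulus and no model noise every architecture must pick
        # the alternative favored by the (constant) evidence: the target
        t = _constant_trial(noiseless_spec, offsets=(4.0, 4.0), path=("right", "down"))
        runs = [
            ht.run_flat_race(t, ht.FlatRaceParams(), seed=0),
            ht.run_flat_lca(t, ht.FlatLCAParams(noise_sd_model=0.0), seed=0),
            ht.run_serial_tracer(t, ht.SerialParams(
                stages=(ht.StageParams(noise_sd_model=0.0),) * 2), seed=0),
            ht.run_hierarchical(t, ht.HierarchicalParams(noise_sd_model=0.0), seed=0),
        ]
        for r in runs:
            assert r.choice_per_level == ("right", "down"), r.model_name
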