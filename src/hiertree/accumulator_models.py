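"""Candidate decision architectures for the luminance decision tree.

Four model families are implemented, all driven by the same per-frame
luminance evidence and all producing choices, reaction times and activity
traces:

* ``flat_race`` — a 3-parameter flat race: one perfect integrator per
  terminal alternative (leaf), no leak or self-excitation, first bound
  crossing wins all levels at once.
* ``flat_lca`` — a leaky competing accumulator over the four leaves with
  self-excitation, a single global inhibition pool, rectification at zero
  and additive diffusion noise that (by default) does not scale with the
  evidence.  Two bound regimes: infinite bounds that collapse at a fixed
  time (forcing an argmax choice), or stable high bounds with an argmax
  fallback at the deadline.
* ``serial`` — stage-wise tracing: a two-alternative bounded accumulation
  at each bifurcation, each stage starting only when the previous one has
  terminated.
* ``hierarchical`` — parallel sub-decision accumulators (one for L1, one
  per L2 bifurcation); the confidence in the two L2 decisions can bias
  the L1 report through a logistic confidence read-out.

Evidence convention: at each bifurcation the momentary input contrast is
(branch luminance - sibling luminance) / 2 at the current frame, signed
toward the local target, so the target-relative leaf ``TT`` receives
``+gain_l1*c1 + gain_l2*c2`` and so on.  Integration uses Euler-Maruyama
with a 1 ms step and frame-held inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .task_stimuli import (
    LuminanceTrial,
    flip,
    trial_rng,
    _MODEL_SALT,
)

LEAVES_2 = ("TT", "TD", "DT", "DD")
L3_PREFIXES = LEAVES_2  # the four level-3 bifurcations hang off these

MODEL_NAMES = ("flat_race", "flat_lca", "serial", "hierarchical")

_LCA_CHUNK = 2000  # trials integrated per vectorized chunk


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlatRaceParams:
    """Flat race with exactly three free parameters.

    ``gain`` scales luminance contrast (cd/m^2) into activity per frame,
    ``bound`` is the common decision threshold, ``nondecision_time`` an
    additive latency in ms.  No leak, self-excitation or model noise: all
    stochasticity comes from the stimulus.
    """

    gain: float = 1.0
    bound: float = 30.0
    nondecision_time: float = 0.0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.bound <= 0:
            raise ValueError(f"bound must be > 0, got {self.bound}")
        if self.nondecision_time < 0:
            raise ValueError("nondecision_time must be >= 0")


@dataclass(frozen=True)
class FlatLCAParams:
    """Leaky competing accumulator over the four leaves (8 core parameters).

    Units: gains in activity/ms per cd/m^2 of contrast; ``self_excitation``,
    ``leak`` and ``global_inhibition`` in 1/ms; ``noise_sd_model`` in
    activity/sqrt(ms) (constant diffusion, independent of the evidence
    unless ``scale_noise_with_evidence`` is set, in which case the
    per-step SD is ``noise_sd_model * |input|``).

    ``bound_regime``:

    * ``"collapsing_500"`` — bounds are infinite before ``collapse_time``
      and drop to zero there, forcing an argmax choice exactly then.
    * ``"stable_high"`` — constant ``bound``; if unreached by ``deadline``
      the choice is the argmax at the deadline and ``terminated_by_bound``
      is False.

    Defaults were calibrated once (scripts/calibrate_lca_defaults.py) so
    that in the stable regime the bound goes unreached on a large fraction
    of trials within the deadline while activity still grows
    super-linearly through net self-excitation.
    """

    gain_l1: float = 0.010
    gain_l2: float = 0.010
    self_excitation: float = 0.005
    global_inhibition: float = 0.0015
    leak: float = 0.001
    noise_sd_model: float = 0.30
    bound_regime: str = "stable_high"
    bound: float = 600.0
    collapse_time: float = 500.0
    deadline: float = 1500.0
    nondecision_time: float = 0.0
    rectify: bool = True
    scale_noise_with_evidence: bool = False
    dt: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.bound_regime not in ("collapsing_500", "stable_high"):
            raise ValueError(f"unknown bound_regime {self.bound_regime!r}")
        if self.bound_regime == "collapsing_500" and self.collapse_time <= 0:
            raise ValueError("collapse_time must be > 0 in the collapsing regime")
        if self.bound_regime == "stable_high" and self.bound <= 0:
            raise ValueError("bound must be > 0 in the stable_high regime")
        if self.noise_sd_model < 0:
            raise ValueError("noise_sd_model must be >= 0")


@dataclass(frozen=True)
class StageParams:
    """One serial stage: 2-alternative bounded accumulation."""

    gain: float = 0.020
    bound: float = 8.0
    noise_sd_model: float = 0.30


@dataclass(frozen=True)
class SerialParams:
    """Stage-wise tracer: bifurcations resolved strictly in sequence.

    ``stages[k]`` parametrizes the accumulation at level k+1; the total
    reaction time is the sum of stage times plus ``nondecision_time``.
    ``max_time_factor`` caps a stage at that multiple of the stimulus
    duration (sign read-out at the cap).
    """

    stages: tuple[StageParams, ...] = (StageParams(), StageParams(), StageParams())
    nondecision_time: float = 0.0
    dt: float = 1.0
    max_time_factor: float = 4.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")


@dataclass(frozen=True)
class HierarchicalParams:
    """Parallel sub-decision accumulators with confidence-coupled L1 report.

    Three accumulators run concurrently: a signed L1 integrator and one
    signed integrator per L2 bifurcation (target side and distractor
    side), each to its own bound or to ``deadline``.  Confidence in each
    L2 decision is ``expit(confidence_slope * |accumulated evidence|)``;
    the L1 report is the sign of the L1 decision variable plus
    ``confidence_weight`` (beta) times the confidence difference.  With
    beta = 0 the L1 choice is independent of the L2 streams by
    construction.
    """

    l1_gain: float = 0.010
    l2_gain: float = 0.010
    l1_bound: float = 1e9
    l2_bound: float = 1e9
    noise_sd_model: float = 0.50
    confidence_weight: float = 20.0
    confidence_slope: float = 0.02
    deadline: float = 1500.0
    nondecision_time: float = 0.0
    dt: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.l1_bound <= 0 or self.l2_bound <= 0:
            raise ValueError("bounds must be > 0")


# ---------------------------------------------------------------------------
# Simulation result
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """One simulated trial: choices, correctness, RT and activity traces."""

    trial_id: int
    model_name: str
    choice_per_level: tuple[str, ...]
    correct_per_level: tuple[bool, ...]
    rt: float
    terminated_by_bound: bool
    seed: int
    activity: dict[str, np.ndarray] | None = None
    activity_times: np.ndarray | None = None
    stage_decision_times: tuple[float, ...] | None = None

    @property
    def choice_l1(self) -> str:
        return self.choice_per_level[0]

    @property
    def choice_l2(self) -> str:
        return self.choice_per_level[1]

    @property
    def correct_l1(self) -> bool:
        return self.correct_per_level[0]

    @property
    def correct_l2(self) -> bool:
        return self.correct_per_level[1]


def _require_depth(trials: Sequence[LuminanceTrial], depths: tuple[int, ...], model: str):
    bad = {t.n_levels for t in trials} - set(depths)
    if bad:
        raise ValueError(
            f"{model}: unsupported tree depth {sorted(bad)}; supported: {depths}"
        )


def _leaf_choice(trial: LuminanceTrial, leaf: str) -> tuple[tuple[str, str], tuple[bool, bool]]:
    """Map a target-relative leaf label to spatial choices and correctness."""
    l1 = trial.target_path[0] if leaf[0] == "T" else flip(trial.target_path[0])
    l2 = trial.target_path[1] if leaf[1] == "T" else flip(trial.target_path[1])
    return (l1, l2), (leaf[0] == "T", leaf[1] == "T")


def _contrasts_2level(trials: Sequence[LuminanceTrial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed contrasts (n, F): L1, target-side L2, distractor-side L2."""
    n, f = len(trials), trials[0].n_frames
    c1 = np.empty((n, f))
    c2t = np.empty((n, f))
    c2d = np.empty((n, f))
    for i, t in enumerate(trials):
        c1[i] = (t.samples[t.l1_target_branch] - t.samples[t.l1_distractor_branch]) / 2.0
        c2t[i] = (t.samples["TT"] - t.samples["TD"]) / 2.0
        c2d[i] = (t.samples["DT"] - t.samples["DD"]) / 2.0
    return c1, c2t, c2d


def _leaf_inputs(c1, c2t, c2d, gain_l1, gain_l2) -> np.ndarray:
    """Per-frame input to the four leaves, order TT, TD, DT, DD: (n, F, 4)."""
    return np.stack(
        [
            gain_l1 * c1 + gain_l2 * c2t,
            gain_l1 * c1 - gain_l2 * c2t,
            -gain_l1 * c1 + gain_l2 * c2d,
            -gain_l1 * c1 - gain_l2 * c2d,
        ],
        axis=2,
    )


def _argmax_tiebreak(values: np.ndarray, rng: np.random.Generator) -> int:
    """Index of the maximum; exact ties resolved uniformly at random."""
    top = np.flatnonzero(values == values.max())
    return int(top[0] if len(top) == 1 else rng.choice(top))


# ---------------------------------------------------------------------------
# Flat race
# ---------------------------------------------------------------------------


def _flat_race_batch(
    trials: Sequence[LuminanceTrial],
    params: FlatRaceParams,
    seed: int,
    record_activity: bool = False,
    record_dt: float | None = None,
) -> list[SimResult]:
    _require_depth(trials, (2,), "flat_race")
    c1, c2t, c2d = _contrasts_2level(trials)
    inputs = _leaf_inputs(c1, c2t, c2d, params.gain, params.gain)
    cum = np.cumsum(inputs, axis=1)  # (n, F, 4): one integration step per frame
    crossed = cum.max(axis=2) >= params.bound  # (n, F)
    results = []
    for i, trial in enumerate(trials):
        rng = trial_rng(seed, trial.trial_id, _MODEL_SALT)
        f = trial.n_frames
        hit = np.flatnonzero(crossed[i])
        if hit.size:
            k = int(hit[0])
            winner = _argmax_tiebreak(cum[i, k], rng)
            rt = (k + 1) * _frame_period(trial) + params.nondecision_time
            terminated = True
        else:
            k = f - 1
            winner = _argmax_tiebreak(cum[i, k], rng)
            rt = f * _frame_period(trial) + params.nondecision_time
            terminated = False
        leaf = LEAVES_2[winner]
        choices, correct = _leaf_choice(trial, leaf)
        activity = None
        times = None
        if record_activity:
            times = _frame_period(trial) * (np.arange(f) + 1)
            activity = {lab: cum[i, :, j].copy() for j, lab in enumerate(LEAVES_2)}
        results.append(
            SimResult(
                trial_id=trial.trial_id,
                model_name="flat_race",
                choice_per_level=choices,
                correct_per_level=correct,
                rt=float(rt),
                terminated_by_bound=terminated,
                seed=int(seed),
                activity=activity,
                activity_times=times,
            )
        )
    return results


def _frame_period(trial: LuminanceTrial) -> float:
    """Frame period in ms, carried by the trial."""
    return trial.sample_period


def run_flat_race(trial: LuminanceTrial, params: FlatRaceParams, seed: int) -> SimResult:
    """Simulate one trial of the 3-parameter flat race."""
    return _flat_race_batch([trial], params, seed)[0]


# ---------------------------------------------------------------------------
# Flat LCA
# ---------------------------------------------------------------------------


def _flat_lca_batch(
    trials: Sequence[LuminanceTrial],
    params: FlatLCAParams,
    seed: int,
    record_activity: bool = False,
    record_dt: float = 10.0,
) -> list[SimResult]:
    _require_depth(trials, (2,), "flat_lca")
    dt = params.dt
    period = _frame_period(trials[0])
    f = trials[0].n_frames
    stim_steps = int(round(f * period / dt))
    if params.bound_regime == "collapsing_500":
        horizon = params.collapse_time
    else:
        horizon = params.deadline
    steps = int(round(horizon / dt))
    # frame index per step; -1 once the stimulus has ended (zero input)
    frame_of_step = np.arange(steps) * dt // period
    frame_of_step = np.where(np.arange(steps) < stim_steps, frame_of_step, -1).astype(int)
    rec_every = max(int(round(record_dt / dt)), 1)
    sqdt = np.sqrt(dt)
    k_net = params.self_excitation - params.leak

    results: list[SimResult] = [None] * len(trials)  # type: ignore[list-item]
    for lo in range(0, len(trials), _LCA_CHUNK):
        chunk = trials[lo : lo + _LCA_CHUNK]
        m = len(chunk)
        c1, c2t, c2d = _contrasts_2level(chunk)
        inputs = _leaf_inputs(c1, c2t, c2d, params.gain_l1, params.gain_l2)  # (m,F,4)
        rngs = [trial_rng(seed, t.trial_id, _MODEL_SALT) for t in chunk]
        noise = np.stack([r.standard_normal((steps, 4)) for r in rngs])  # (m,steps,4)
        a = np.zeros((m, 4))
        active = np.ones(m, dtype=bool)
        dec_step = np.full(m, -1)
        dec_leaf = np.full(m, -1)
        rec_traces = np.empty((m, steps // rec_every, 4)) if record_activity else None
        rec_times = []
        rec_k = 0
        zero_inp = np.zeros((m, 4))
        for t in range(steps):
            fr = frame_of_step[t]
            inp = inputs[:, fr, :] if fr >= 0 else zero_inp
            drift = inp + k_net * a - params.global_inhibition * a.sum(axis=1, keepdims=True)
            if params.scale_noise_with_evidence:
                sd = params.noise_sd_model * np.abs(inp)
            else:
                sd = params.noise_sd_model
            a_new = a + drift * dt + sd * sqdt * noise[:, t, :]
            if params.rectify:
                np.maximum(a_new, 0.0, out=a_new)
            a = np.where(active[:, None], a_new, a)
            if params.bound_regime == "stable_high":
                hit = active & (a.max(axis=1) >= params.bound)
                if hit.any():
                    for i in np.flatnonzero(hit):
                        dec_leaf[i] = _argmax_tiebreak(a[i], rngs[i])
                        dec_step[i] = t
                    active[hit] = False
            if record_activity and (t + 1) % rec_every == 0:
                rec_traces[:, rec_k, :] = a
                rec_times.append((t + 1) * dt)
                rec_k += 1
        # unresolved trials: forced argmax (collapse or deadline)
        for i in np.flatnonzero(active):
            dec_leaf[i] = _argmax_tiebreak(a[i], rngs[i])
            dec_step[i] = steps - 1
        times_arr = np.asarray(rec_times) if record_activity else None
        for j, trial in enumerate(chunk):
            terminated = params.bound_regime == "stable_high" and not active[j]
            decision_time = horizon if active[j] or params.bound_regime == "collapsing_500" else (dec_step[j] + 1) * dt
            leaf = LEAVES_2[dec_leaf[j]]
            choices, correct = _leaf_choice(trial, leaf)
            act = None
            if record_activity:
                act = {lab: rec_traces[j, :rec_k, q].copy() for q, lab in enumerate(LEAVES_2)}
            results[lo + j] = SimResult(
                trial_id=trial.trial_id,
                model_name="flat_lca",
                choice_per_level=choices,
                correct_per_level=correct,
                rt=float(decision_time + params.nondecision_time),
                terminated_by_bound=bool(terminated),
                seed=int(seed),
                activity=act,
                activity_times=times_arr[:rec_k] if record_activity else None,
            )
    return results


def run_flat_lca(trial: LuminanceTrial, params: FlatLCAParams, seed: int,
                 record_activity: bool = False, record_dt: float = 10.0) -> SimResult:
    """Simulate one trial of the flat leaky competing accumulator."""
    return _flat_lca_batch([trial], params, seed, record_activity, record_dt)[0]


# ---------------------------------------------------------------------------
# Serial stage-wise tracer
# ---------------------------------------------------------------------------


def _stage_rng(seed: int, trial_id: int, stage: int) -> np.random.Generator:
    # separate stream per (trial, stage) so a trial's draws never depend on
    # how long other trials' stages ran (permutation invariance)
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(trial_id), _MODEL_SALT, int(stage)])
    )


def _serial_chunk(
    trials: Sequence[LuminanceTrial],
    params: SerialParams,
    seed: int,
) -> list[SimResult]:
    depth = trials[0].n_levels
    dt = params.dt
    period = _frame_period(trials[0])
    f = trials[0].n_frames
    stim_steps = int(round(f * period / dt))
    cap_steps = int(round(params.max_time_factor * f * period / dt))
    sqdt = np.sqrt(dt)
    n = len(trials)

    # per-level signed contrasts toward the local target, per candidate prefix
    c1, c2t, c2d = _contrasts_2level(trials)
    c2 = {"T": c2t, "D": c2d}
    c3: dict[str, np.ndarray] = {}
    if depth == 3:
        for p in L3_PREFIXES:
            arr = np.empty((n, f))
            for i, t in enumerate(trials):
                arr[i] = (t.samples[p + "T"] - t.samples[p + "D"]) / 2.0
            c3[p] = arr

    start = np.zeros(n, dtype=int)  # global step at which the current stage starts
    letters = [[] for _ in range(n)]
    stage_end_ms = np.zeros((n, depth))

    for k in range(depth):
        sp = params.stages[k]
        if k == 0:
            drift_src = c1
        elif k == 1:
            drift_src = np.stack([c2[letters[i][0]][i] for i in range(n)])
        else:
            drift_src = np.stack([c3[letters[i][0] + letters[i][1]][i] for i in range(n)])
        rngs = [_stage_rng(seed, t.trial_id, k) for t in trials]
        max_local = int((cap_steps - start).max())
        noise = (
            np.stack([r.standard_normal(max_local) for r in rngs])
            if max_local > 0
            else np.zeros((n, 0))
        )
        v = np.zeros(n)
        done = np.zeros(n, dtype=bool)
        end_step = np.array(cap_steps - start)  # local step count at cap
        sign_at_end = np.zeros(n)
        for t in range(max_local):
            glob = start + t
            live = ~done & (glob < cap_steps)
            if not live.any():
                break
            fr = (glob * dt // period).astype(int)
            in_stim = glob < stim_steps
            drift = np.zeros(n)
            idx = np.flatnonzero(live & in_stim)
            if idx.size:
                drift[idx] = sp.gain * drift_src[idx, np.minimum(fr[idx], f - 1)]
            v = np.where(live, v + drift * dt + sp.noise_sd_model * sqdt * noise[:, t], v)
            hit = live & (np.abs(v) >= sp.bound)
            if hit.any():
                end_step[hit] = t + 1
                sign_at_end[hit] = np.sign(v[hit])
                done[hit] = True
        capped = ~done
        if capped.any():
            sign_at_end[capped] = np.sign(v[capped])
        for i in range(n):
            s = sign_at_end[i]
            if s == 0:
                # exact tie: fresh derived stream, independent of noise use
                tie = np.random.default_rng(
                    np.random.SeedSequence([int(seed), int(trials[i].trial_id), _MODEL_SALT, 900 + k])
                )
                s = 1.0 if tie.random() < 0.5 else -1.0
            letters[i].append("T" if s > 0 else "D")
            stage_end_ms[i, k] = (start[i] + end_step[i]) * dt
        start = start + end_step

    results = []
    for i, trial in enumerate(trials):
        choices = []
        correct = []
        for k, letter in enumerate(letters[i]):
            base = trial.target_path[k]
            choices.append(base if letter == "T" else flip(base))
            correct.append(letter == "T")
        results.append(
            SimResult(
                trial_id=trial.trial_id,
                model_name="serial",
                choice_per_level=tuple(choices),
                correct_per_level=tuple(correct),
                rt=float(stage_end_ms[i, -1] + params.nondecision_time),
                terminated_by_bound=True,
                seed=int(seed),
                stage_decision_times=tuple(stage_end_ms[i]),
            )
        )
    return results


def _serial_batch(
    trials: Sequence[LuminanceTrial],
    params: SerialParams,
    seed: int,
    record_activity: bool = False,
    record_dt: float = 10.0,
) -> list[SimResult]:
    _require_depth(trials, (2, 3), "serial")
    depth = trials[0].n_levels
    if len(params.stages) < depth:
        raise ValueError(f"serial: {depth} levels but only {len(params.stages)} stages")
    out: list[SimResult] = []
    for lo in range(0, len(trials), _LCA_CHUNK):
        out.extend(_serial_chunk(trials[lo : lo + _LCA_CHUNK], params, seed))
    return out


def run_serial_tracer(trial: LuminanceTrial, params: SerialParams, seed: int) -> SimResult:
    """Simulate one trial of the serial stage-wise tracer."""
    return _serial_batch([trial], params, seed)[0]


# ---------------------------------------------------------------------------
# Hierarchical parallel accumulators
# ---------------------------------------------------------------------------

HIER_LABELS = ("L1", "L2T", "L2D")


def _hierarchical_batch(
    trials: Sequence[LuminanceTrial],
    params: HierarchicalParams,
    seed: int,
    record_activity: bool = False,
    record_dt: float = 10.0,
) -> list[SimResult]:
    _require_depth(trials, (2,), "hierarchical")
    dt = params.dt
    period = _frame_period(trials[0])
    f = trials[0].n_frames
    stim_steps = int(round(f * period / dt))
    steps = int(round(params.deadline / dt))
    sqdt = np.sqrt(dt)
    n = len(trials)
    c1, c2t, c2d = _contrasts_2level(trials)
    gains = np.array([params.l1_gain, params.l2_gain, params.l2_gain])
    bounds = np.array([params.l1_bound, params.l2_bound, params.l2_bound])
    rngs = [trial_rng(seed, t.trial_id, _MODEL_SALT) for t in trials]
    rec_every = max(int(round(record_dt / dt)), 1)

    results = []
    for lo in range(0, n, _LCA_CHUNK):
        sl = slice(lo, min(lo + _LCA_CHUNK, n))
        m = sl.stop - sl.start
        src = np.stack([c1[sl], c2t[sl], c2d[sl]], axis=2)  # (m, F, 3)
        noise = np.stack([rngs[i].standard_normal((steps, 3)) for i in range(sl.start, sl.stop)])
        v = np.zeros((m, 3))
        frozen = np.zeros((m, 3), dtype=bool)
        t_dec = np.full((m, 3), params.deadline)
        rec = np.empty((m, steps // rec_every, 3)) if record_activity else None
        rec_times = []
        rec_k = 0
        for t in range(steps):
            fr = int(t * dt // period)
            inp = gains * src[:, fr, :] if t < stim_steps else 0.0
            v_new = v + inp * dt + params.noise_sd_model * sqdt * noise[:, t, :]
            v = np.where(frozen, v, v_new)
            hit = ~frozen & (np.abs(v) >= bounds)
            if hit.any():
                v = np.where(hit, np.clip(v, -bounds, bounds), v)
                t_dec[hit] = (t + 1) * dt
                frozen |= hit
            if record_activity and (t + 1) % rec_every == 0:
                rec[:, rec_k, :] = v
                rec_times.append((t + 1) * dt)
                rec_k += 1
        conf_t = _expit(params.confidence_slope * np.abs(v[:, 1]))
        conf_d = _expit(params.confidence_slope * np.abs(v[:, 2]))
        dv1 = v[:, 0] + params.confidence_weight * (conf_t - conf_d)
        for j in range(m):
            trial = trials[lo + j]
            rng = rngs[lo + j]
            s1 = dv1[j]
            if s1 == 0:
                s1 = 1.0 if rng.random() < 0.5 else -1.0
            on_target_side = s1 > 0
            l1 = trial.target_path[0] if on_target_side else flip(trial.target_path[0])
            v2 = v[j, 1] if on_target_side else v[j, 2]
            if v2 == 0:
                v2 = 1.0 if rng.random() < 0.5 else -1.0
            local_t = v2 > 0
            l2 = trial.target_path[1] if local_t else flip(trial.target_path[1])
            terminated = bool(frozen[j].all())
            rt = float(t_dec[j].max() + params.nondecision_time) if steps > 0 else params.nondecision_time
            act = None
            times = None
            if record_activity:
                act = {lab: rec[j, :rec_k, q].copy() for q, lab in enumerate(HIER_LABELS)}
                times = np.asarray(rec_times)
            results.append(
                SimResult(
                    trial_id=trial.trial_id,
                    model_name="hierarchical",
                    choice_per_level=(l1, l2),
                    correct_per_level=(on_target_side, local_t),
                    rt=rt,
                    terminated_by_bound=terminated,
                    seed=int(seed),
                    activity=act,
                    activity_times=times,
                )
            )
    return results


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def run_hierarchical(trial: LuminanceTrial, params: HierarchicalParams, seed: int) -> SimResult:
    """Simulate one trial of the hierarchical parallel-accumulator model."""
    return _hierarchical_batch([trial], params, seed)[0]


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------

_ENGINES = {
    "flat_race": _flat_race_batch,
    "flat_lca": _flat_lca_batch,
    "serial": _serial_batch,
    "hierarchical": _hierarchical_batch,
}

PARAM_CLASSES = {
    "flat_race": FlatRaceParams,
    "flat_lca": FlatLCAParams,
    "serial": SerialParams,
    "hierarchical": HierarchicalParams,
}


def batch_simulate(
    trials: Sequence[LuminanceTrial],
    model_name: str,
    params,
    seed: int,
    record_activity: bool = False,
    record_dt: float = 10.0,
) -> list[SimResult]:
    """Simulate a homogeneous batch of trials under one model.

    Per-trial randomness is keyed on ``(seed, trial_id)``, so results are
    reproducible and invariant under permutation of the trial list.
    """
    if model_name not in _ENGINES:
        raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    if len(trials) == 0:
        return []
    depths = {t.n_levels for t in trials}
    if len(depths) > 1:
        raise ValueError(f"batch_simulate requires homogeneous tree depth, got {sorted(depths)}")
    return _ENGINES[model_name](trials, params, seed, record_activity, record_dt)
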