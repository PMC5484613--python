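"""Decision-tree task generation with stochastic luminance evidence.

The task is a binary tree traced outward from a fixation point.  At each
bifurcation two branches carry luminance samples drawn per frame with
additive Gaussian noise; the subject (or model) must pick the branch with
the higher mean luminance.  A two-level tree has a left/right decision at
L1 and an up/down decision at L2; a three-level tree adds an up/down L3.

Branch labels follow the field's target-relative convention: level-1
branches are spatial (``L1-left``, ``L1-right``); deeper branches are
letter codes where each letter is ``T`` if the branch is the local target
(higher mean) of its bifurcation and the preceding letters give the same
status for its ancestors.  ``TT`` is the final target of a two-level tree,
and the ``DT``/``DD`` bifurcation on the distractor side is the one often
called L2'.

This module also implements the Quest adaptive staircase used to hold a
simulated observer near a criterion proportion correct, mirroring the
human sessions in which the target-minus-distractor mean luminance was
adjusted online.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, logit

# ---------------------------------------------------------------------------
# Constants and label algebra
# ---------------------------------------------------------------------------

L1_BRANCHES = ("L1-left", "L1-right")
L2_BRANCHES = ("TT", "TD", "DT", "DD")
L3_BRANCHES = tuple(p + s for p in L2_BRANCHES for s in "TD")

#: spatial choice vocabulary per level (1-based level index)
LEVEL_CHOICES = {1: ("left", "right"), 2: ("up", "down"), 3: ("up", "down")}

_FLIP = {"left": "right", "right": "left", "up": "down", "down": "up"}

# salts separating the per-trial RNG streams of stimulus generation and
# model simulation (both key on (session_seed, trial_id))
_STIM_SALT = 0
_MODEL_SALT = 1


def flip(direction: str) -> str:
    """Opposite spatial direction (left<->right, up<->down)."""
    return _FLIP[direction]


def branch_labels(n_levels: int) -> tuple[str, ...]:
    """All branch labels of an ``n_levels`` tree, shallow to deep."""
    if n_levels == 2:
        return L1_BRANCHES + L2_BRANCHES
    if n_levels == 3:
        return L1_BRANCHES + L2_BRANCHES + L3_BRANCHES
    raise ValueError(f"n_levels must be 2 or 3, got {n_levels}")


def trial_rng(session_seed: int, trial_id: int, salt: int = _STIM_SALT) -> np.random.Generator:
    """Per-trial generator keyed on (session seed, trial id).

    Trials are reproducible independently of execution order because the
    stream depends only on the key, never on how many trials were drawn
    before.
    """
    return np.random.default_rng(np.random.SeedSequence([int(session_seed), int(trial_id), int(salt)]))


# ---------------------------------------------------------------------------
# TreeTaskSpec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeTaskSpec:
    """Static definition of a decision-tree luminance task.

    All luminances are in cd/m^2, durations in ms.  ``difficulty_levels``
    holds one tuple of target-minus-distractor offsets per level; a trial's
    per-level ``difficulty_label`` indexes into these tuples.
    """

    n_levels: int = 2
    samples_per_trial: int = 15
    sample_period: float = 100.0
    background_lum: float = 50.0
    target_mean_lum: float = 58.0
    distractor_mean_lum: float = 50.0
    noise_sd: float = 10.0
    difficulty_levels: tuple[tuple[float, ...], ...] = ((2.0, 4.0, 8.0), (2.0, 4.0, 8.0))
    min_view_time: float = 500.0

    @property
    def trial_duration(self) -> float:
        """Stimulus duration in ms."""
        return self.samples_per_trial * self.sample_period

    @property
    def n_leaves(self) -> int:
        return 2 ** self.n_levels

    @property
    def branch_labels(self) -> tuple[str, ...]:
        return branch_labels(self.n_levels)


def make_tree_task(
    n_levels: int = 2,
    samples_per_trial: int = 15,
    sample_period: float = 100.0,
    noise_sd: float = 10.0,
    background_lum: float = 50.0,
    difficulty_levels: Sequence[Sequence[float]] | None = None,
    min_view_time: float = 500.0,
    distractor_mean_lum: float | None = None,
    target_mean_lum: float | None = None,
) -> TreeTaskSpec:
    """Validate arguments and build a :class:`TreeTaskSpec`.

    Defaults reproduce the human-task statistics: sigma = 10 cd/m^2 of
    additive per-frame noise on a 50 cd/m^2 background, with a 500 ms
    minimum viewing time.  Raises ``ValueError`` listing every offending
    field at once.
    """
    problems: list[str] = []
    if n_levels not in (2, 3):
        problems.append(f"n_levels: must be 2 or 3, got {n_levels}")
    if samples_per_trial < 1:
        problems.append(f"samples_per_trial: must be >= 1, got {samples_per_trial}")
    if sample_period <= 0:
        problems.append(f"sample_period: must be > 0, got {sample_period}")
    if noise_sd < 0:
        problems.append(f"noise_sd: must be >= 0, got {noise_sd}")

    if distractor_mean_lum is None:
        distractor_mean_lum = background_lum
    if difficulty_levels is None:
        difficulty_levels = tuple((2.0, 4.0, 8.0) for _ in range(max(n_levels, 2)))
    difficulty_levels = tuple(tuple(float(o) for o in lvl) for lvl in difficulty_levels)
    if n_levels in (2, 3) and len(difficulty_levels) != n_levels:
        problems.append(
            f"difficulty_levels: need one offset tuple per level "
            f"({n_levels}), got {len(difficulty_levels)}"
        )
    for k, lvl in enumerate(difficulty_levels):
        if len(lvl) == 0:
            problems.append(f"difficulty_levels[{k}]: empty")
        if any(o < 0 for o in lvl):
            problems.append(
                f"difficulty_levels[{k}]: offsets must be >= 0 "
                f"(target mean >= distractor mean), got {lvl}"
            )
    if target_mean_lum is None:
        max_off = max((max(lvl) for lvl in difficulty_levels if lvl), default=0.0)
        target_mean_lum = distractor_mean_lum + max_off
    if target_mean_lum < distractor_mean_lum:
        problems.append(
            f"target_mean_lum: must be >= distractor_mean_lum "
            f"({target_mean_lum} < {distractor_mean_lum})"
        )
    if min_view_time < 0:
        problems.append(f"min_view_time: must be >= 0, got {min_view_time}")
    if sample_period > 0 and samples_per_trial >= 1 and min_view_time > samples_per_trial * sample_period:
        problems.append(
            f"min_view_time: exceeds stimulus duration "
            f"({min_view_time} > {samples_per_trial * sample_period})"
        )
    if problems:
        raise ValueError("invalid TreeTaskSpec: " + "; ".join(problems))
    return TreeTaskSpec(
        n_levels=n_levels,
        samples_per_trial=samples_per_trial,
        sample_period=float(sample_period),
        background_lum=float(background_lum),
        target_mean_lum=float(target_mean_lum),
        distractor_mean_lum=float(distractor_mean_lum),
        noise_sd=float(noise_sd),
        difficulty_levels=difficulty_levels,
        min_view_time=float(min_view_time),
    )


# ---------------------------------------------------------------------------
# LuminanceTrial
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LuminanceTrial:
    """One trial's luminance streams plus generative ground truth.

    ``samples[b]`` is the per-frame luminance of branch ``b`` (cd/m^2);
    ``generative_means[b]`` the mean it was drawn around, so
    ``samples[b] - generative_means[b]`` recovers the injected noise
    exactly.  ``target_path`` is the per-level correct spatial choice and
    ``offsets`` the per-level target-minus-distractor mean difference.
    """

    trial_id: int
    samples: dict[str, np.ndarray]
    target_path: tuple[str, ...]
    difficulty_label: tuple[int, ...] | None
    offsets: tuple[float, ...]
    generative_means: dict[str, float]
    sample_period: float = 100.0

    @property
    def n_levels(self) -> int:
        return len(self.target_path)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.samples.values())))

    def noise(self, branch: str) -> np.ndarray:
        """Injected Gaussian noise on ``branch`` (sample minus mean)."""
        return self.samples[branch] - self.generative_means[branch]

    def l1_branch(self, side: str) -> str:
        """Spatial level-1 branch label for ``side`` in {left, right}."""
        return f"L1-{side}"

    @property
    def l1_target_branch(self) -> str:
        return self.l1_branch(self.target_path[0])

    @property
    def l1_distractor_branch(self) -> str:
        return self.l1_branch(flip(self.target_path[0]))

    def direction_of(self, label: str) -> str:
        """Spatial direction of a deep branch's last letter.

        The local target of every level-k bifurcation points in the
        direction ``target_path[k-1]``, so a label ending in T points that
        way and one ending in D the opposite way.
        """
        level = len(label) + 1  # letter codes start at level 2
        base = self.target_path[level - 1]
        return base if label.endswith("T") else flip(base)


def _generative_means(spec: TreeTaskSpec, offsets: Sequence[float], target_path: Sequence[str]) -> dict[str, float]:
    means: dict[str, float] = {}
    d = spec.distractor_mean_lum
    means[f"L1-{target_path[0]}"] = d + offsets[0]
    means[f"L1-{flip(target_path[0])}"] = d
    for label in L2_BRANCHES:
        means[label] = d + (offsets[1] if label.endswith("T") else 0.0)
    if spec.n_levels == 3:
        for label in L3_BRANCHES:
            means[label] = d + (offsets[2] if label.endswith("T") else 0.0)
    return means


def _draw_trial(
    spec: TreeTaskSpec,
    offsets: tuple[float, ...],
    target_path: tuple[str, ...],
    difficulty_label: tuple[int, ...] | None,
    trial_id: int,
    rng: np.random.Generator,
) -> LuminanceTrial:
    means = _generative_means(spec, offsets, target_path)
    samples = {
        b: means[b] + spec.noise_sd * rng.standard_normal(spec.samples_per_trial)
        for b in spec.branch_labels
    }
    return LuminanceTrial(
        trial_id=trial_id,
        samples=samples,
        target_path=target_path,
        difficulty_label=difficulty_label,
        offsets=offsets,
        generative_means=means,
        sample_period=spec.sample_period,
    )


def _validate_target_path(spec: TreeTaskSpec, target_path: Sequence[str]) -> tuple[str, ...]:
    target_path = tuple(target_path)
    if len(target_path) != spec.n_levels:
        raise ValueError(
            f"target_path: expected {spec.n_levels} levels, got {len(target_path)}"
        )
    for k, choice in enumerate(target_path, start=1):
        if choice not in LEVEL_CHOICES[k]:
            raise ValueError(
                f"target_path: level {k} choice {choice!r} not in {LEVEL_CHOICES[k]}"
            )
    return target_path


def generate_trial(
    spec: TreeTaskSpec,
    difficulty_label: Sequence[int],
    target_path: Sequence[str],
    seed: int,
    trial_id: int = 0,
) -> LuminanceTrial:
    """Draw one trial with per-frame Gaussian luminance noise.

    ``difficulty_label`` indexes ``spec.difficulty_levels`` per level.  The
    random stream is keyed on ``(seed, trial_id)``.
    """
    target_path = _validate_target_path(spec, target_path)
    difficulty_label = tuple(int(i) for i in difficulty_label)
    if len(difficulty_label) != spec.n_levels:
        raise ValueError(
            f"difficulty_label: expected {spec.n_levels} indices, got {len(difficulty_label)}"
        )
    offsets = []
    for k, idx in enumerate(difficulty_label):
        lvl = spec.difficulty_levels[k]
        if not 0 <= idx < len(lvl):
            raise ValueError(f"difficulty_label[{k}]={idx} out of range for {lvl}")
        offsets.append(lvl[idx])
    rng = trial_rng(seed, trial_id, _STIM_SALT)
    return _draw_trial(spec, tuple(offsets), target_path, difficulty_label, trial_id, rng)


def generate_trial_at_offsets(
    spec: TreeTaskSpec,
    offsets: Sequence[float],
    target_path: Sequence[str],
    seed: int,
    trial_id: int = 0,
) -> LuminanceTrial:
    """Like :func:`generate_trial` but with explicit per-level offsets.

    Used by adaptive (Quest) sessions where the offset is continuous
    rather than an index into ``difficulty_levels``.
    """
    target_path = _validate_target_path(spec, target_path)
    offsets = tuple(float(o) for o in offsets)
    if len(offsets) != spec.n_levels:
        raise ValueError(f"offsets: expected {spec.n_levels} values, got {len(offsets)}")
    if any(o < 0 for o in offsets):
        raise ValueError(f"offsets: must be >= 0, got {offsets}")
    rng = trial_rng(seed, trial_id, _STIM_SALT)
    return _draw_trial(spec, offsets, target_path, None, trial_id, rng)


def generate_trials(
    spec: TreeTaskSpec,
    n_trials: int,
    seed: int,
    difficulty_labels: Sequence[Sequence[int]] | None = None,
    target_paths: Sequence[Sequence[str]] | None = None,
    start_id: int = 0,
) -> list[LuminanceTrial]:
    """Draw a batch of trials.

    When ``difficulty_labels`` / ``target_paths`` are omitted they are
    drawn uniformly per trial from the trial's own stream, so the batch is
    reproducible trial-by-trial.
    """
    trials = []
    for i in range(n_trials):
        tid = start_id + i
        rng = trial_rng(seed, tid, _STIM_SALT)
        if difficulty_labels is None:
            label = tuple(int(rng.integers(len(spec.difficulty_levels[k]))) for k in range(spec.n_levels))
        else:
            label = tuple(int(x) for x in difficulty_labels[i])
        if target_paths is None:
            path = tuple(LEVEL_CHOICES[k + 1][int(rng.integers(2))] for k in range(spec.n_levels))
        else:
            path = _validate_target_path(spec, target_paths[i])
        offsets = tuple(spec.difficulty_levels[k][label[k]] for k in range(spec.n_levels))
        trials.append(_draw_trial(spec, offsets, path, label, tid, rng))
    return trials


# ---------------------------------------------------------------------------
# Observers
# ---------------------------------------------------------------------------

#: an observer maps a trial to (per-level spatial choices, per-level correct flags)
ObserverSpec = Callable[[LuminanceTrial], tuple[tuple[str, ...], tuple[bool, ...]]]


@dataclass(frozen=True)
class IdealObserver:
    """Observer that picks, at each bifurcation along its believed path,
    the branch with the larger sum of luminance samples.

    This matches the task instruction (choose the branch with the higher
    luminance) and is the calibration observer for Quest sessions.
    """

    def __call__(self, trial: LuminanceTrial) -> tuple[tuple[str, ...], tuple[bool, ...]]:
        # level 1: spatial comparison
        s_left = float(np.sum(trial.samples["L1-left"]))
        s_right = float(np.sum(trial.samples["L1-right"]))
        side = "left" if s_left >= s_right else "right"
        choices = [side]
        prefix = "T" if side == trial.target_path[0] else "D"
        # deeper levels: walk the believed path through letter-coded branches
        for k in range(2, trial.n_levels + 1):
            b_t, b_d = prefix + "T", prefix + "D"
            letter = "T" if np.sum(trial.samples[b_t]) >= np.sum(trial.samples[b_d]) else "D"
            base = trial.target_path[k - 1]
            choices.append(base if letter == "T" else flip(base))
            prefix = prefix + letter
        choices_t = tuple(choices)
        correct = tuple(c == t for c, t in zip(choices_t, trial.target_path))
        return choices_t, correct


@dataclass(frozen=True)
class RandomObserver:
    """Stimulus-blind observer choosing uniformly at each level (null model)."""

    seed: int = 0

    def __call__(self, trial: LuminanceTrial) -> tuple[tuple[str, ...], tuple[bool, ...]]:
        rng = trial_rng(self.seed, trial.trial_id, _MODEL_SALT)
        choices = tuple(
            LEVEL_CHOICES[k + 1][int(rng.integers(2))] for k in range(trial.n_levels)
        )
        correct = tuple(c == t for c, t in zip(choices, trial.target_path))
        return choices, correct


# ---------------------------------------------------------------------------
# Quest adaptive staircase
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuestState:
    """Grid-based Bayesian staircase over the luminance-offset threshold.

    The assumed psychometric link is a logistic in the offset x with slope
    ``beta``, guess rate ``guess_rate`` and lapse rate ``lapse_rate``:

        p(correct | x, T) = g + (1 - g - l) * expit(beta * (x - T) + c)

    with the lateral constant c solved so that p(correct | T, T) equals
    ``target_p`` — i.e. the threshold parameter T is by construction the
    offset at which performance sits at the criterion.  After each outcome
    the posterior over T is updated and the next offset is placed at the
    posterior mode (ties resolve to the smaller offset).
    """

    grid: np.ndarray
    log_posterior: np.ndarray
    current_offset: float
    target_p: float = 0.75
    beta: float = 0.6
    guess_rate: float = 0.25
    lapse_rate: float = 0.02
    trial_count: int = 0
    outcome_history: tuple[bool, ...] = ()

    @property
    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_posterior - np.max(self.log_posterior))
        return p / p.sum()

    @property
    def threshold_estimate(self) -> float:
        return float(self.grid[int(np.argmax(self.log_posterior))])

    def p_correct(self, x: float) -> np.ndarray:
        """Assumed p(correct) at offset ``x`` for every grid threshold."""
        g, l = self.guess_rate, self.lapse_rate
        c = logit((self.target_p - g) / (1.0 - g - l))
        f = expit(self.beta * (x - self.grid) + c)
        return g + (1.0 - g - l) * f


def make_quest(
    grid: np.ndarray | None = None,
    target_p: float = 0.75,
    beta: float = 0.6,
    guess_rate: float = 0.25,
    lapse_rate: float = 0.02,
    prior_mean: float = 8.0,
    prior_sd: float = 6.0,
) -> QuestState:
    """Initial Quest state; first placement at the prior mode."""
    if not 0.5 < target_p < 1.0:
        raise ValueError(f"target_p must lie in (0.5, 1), got {target_p}")
    if grid is None:
        grid = np.linspace(0.1, 16.0, 160)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("offset grid must be non-negative")
    log_prior = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    offset = float(grid[int(np.argmax(log_prior))])
    return QuestState(
        grid=grid,
        log_posterior=log_prior,
        current_offset=offset,
        target_p=target_p,
        beta=beta,
        guess_rate=guess_rate,
        lapse_rate=lapse_rate,
    )


def quest_update(state: QuestState, outcome: bool) -> QuestState:
    """Fold one correct/error outcome into the staircase.

    Returns a new state with the posterior updated at the offset that was
    actually shown and the next offset placed at the posterior mode.
    """
    p = state.p_correct(state.current_offset)
    log_lik = np.log(p if outcome else 1.0 - p)
    log_post = state.log_posterior + log_lik
    log_post = log_post - np.max(log_post)  # keep finite over long sessions
    new_offset = float(state.grid[int(np.argmax(log_post))])
    return replace(
        state,
        log_posterior=log_post,
        current_offset=new_offset,
        trial_count=state.trial_count + 1,
        outcome_history=state.outcome_history + (bool(outcome),),
    )


def run_quest_session(
    spec: TreeTaskSpec,
    observer: ObserverSpec,
    n_trials: int,
    seed: int,
    quest: QuestState | None = None,
) -> tuple[list[LuminanceTrial], list[bool], QuestState]:
    """Run an adaptive session: generate -> observe -> update, per trial.

    A trial counts as correct only when the observer is correct at every
    level (it reaches the final target), matching the staircase's 25%
    guess rate for a two-level tree.  Target paths are drawn uniformly
    from each trial's own stream.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    q = quest if quest is not None else make_quest()
    trials: list[LuminanceTrial] = []
    outcomes: list[bool] = []
    for tid in range(n_trials):
        rng = trial_rng(seed, tid, _STIM_SALT)
        path = tuple(LEVEL_CHOICES[k + 1][int(rng.integers(2))] for k in range(spec.n_levels))
        trial = _draw_trial(spec, (q.current_offset,) * spec.n_levels, path, None, tid, rng)
        _, correct = observer(trial)
        outcome = all(correct)
        q = quest_update(q, outcome)
        trials.append(trial)
        outcomes.append(outcome)
    return trials, outcomes, q
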