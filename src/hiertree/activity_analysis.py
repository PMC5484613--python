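"""Diagnostics on simulated accumulator activity traces.

Two analyses mirror the neural diagnostics used to adjudicate between
flat and hierarchical architectures:

* quartile conditioning — trials are split into quartiles of L1 evidence
  strength (computed within each difficulty level, correct trials only by
  default) and per-branch mean activity traces are compared across
  quartiles.  A flat accumulator with a single global inhibition source
  must move the TT and TD branches together (both driven by the same L1
  evidence) while suppressing DT and DD; it cannot produce the
  {TT up, TD flat, DT down, DD down} pattern.
* exponential-growth test — a log-linear fit of activity against time;
  net self-excitation (self-excitation minus leak) appears as a positive
  exponential rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

from .accumulator_models import SimResult
from .task_stimuli import LuminanceTrial

LOG_FLOOR = 1e-6  # activity floor added before taking logs


@dataclass(frozen=True)
class QuartileTraces:
    """Mean activity per (branch, L1-evidence quartile) plus window stats.

    ``quartile_means[(branch, q)]`` (q in 1..4) is the mean activity time
    series over the pooled quartile cell; ``window_stat[branch]`` is the
    OLS slope (with SE) of the per-trial windowed mean activity on the
    quartile rank; ``n_per_cell[(difficulty, q)]`` gives cell sizes.
    """

    quartile_means: dict[tuple[str, int], np.ndarray]
    times: np.ndarray
    window_stat: dict[str, tuple[float, float]]
    n_per_cell: dict[tuple[Hashable, int], int]
    window: tuple[float, float]


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth rate from a log-linear fit over a time window."""

    rate: float
    rate_se: float
    r_squared: float
    window: tuple[float, float]


def l1_evidence_strength(trial: LuminanceTrial) -> float:
    """Signed L1 evidence: target minus distractor luminance, averaged
    over the first two frames."""
    if trial.n_frames < 2:
        raise ValueError("l1_evidence_strength needs at least 2 frames")
    t = trial.samples[trial.l1_target_branch][:2].mean()
    d = trial.samples[trial.l1_distractor_branch][:2].mean()
    return float(t - d)


def quartile_condition(
    trials: Sequence[LuminanceTrial],
    results: Sequence[SimResult],
    correct_only: bool = True,
    window: tuple[float, float] = (200.0, 500.0),
    seed: int = 0,
) -> QuartileTraces:
    """Group trials into quartiles of L1 evidence strength and average
    per-branch activity.

    Quartile boundaries are computed within each difficulty level over
    the included trials (ties broken by a seeded shuffle), then cells are
    pooled across difficulty per quartile rank.  ``correct_only``
    restricts to trials correct at every level.  The windowed mean
    activity of each branch is regressed on quartile rank (1-4).
    """
    if len(trials) != len(results) or len(trials) == 0:
        raise ValueError("need equal, non-zero numbers of trials and results")
    pairs = list(zip(trials, results))
    if correct_only:
        pairs = [(t, r) for t, r in pairs if all(r.correct_per_level)]
    if not pairs:
        raise ValueError("no trials left after the correct-only filter")
    for _, r in pairs:
        if r.activity is None or r.activity_times is None:
            raise ValueError("results lack activity traces; simulate with record_activity=True")

    times = pairs[0][1].activity_times
    branches = sorted(pairs[0][1].activity.keys())
    # partition within difficulty level
    by_diff: dict[Hashable, list[int]] = {}
    for i, (t, _) in enumerate(pairs):
        by_diff.setdefault(t.difficulty_label, []).append(i)
    strength = np.array([l1_evidence_strength(t) for t, _ in pairs])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))

    quartile_of = np.empty(len(pairs), dtype=int)
    n_per_cell: dict[tuple[Hashable, int], int] = {}
    for dlab, idx in by_diff.items():
        if len(idx) < 4:
            raise ValueError(
                f"difficulty level {dlab!r}: only {len(idx)} included trials (< 4)"
            )
        idx = np.asarray(idx)
        shuffled = rng.permutation(idx)  # seeded shuffle breaks exact ties
        order = shuffled[np.argsort(strength[shuffled], kind="stable")]
        for q, cell in enumerate(np.array_split(order, 4), start=1):
            quartile_of[cell] = q
            n_per_cell[(dlab, q)] = len(cell)

    in_win = (times >= window[0]) & (times <= window[1])
    if not in_win.any():
        raise ValueError(f"window {window} outside trace support {times[0]}-{times[-1]} ms")

    quartile_means: dict[tuple[str, int], np.ndarray] = {}
    window_stat: dict[str, tuple[float, float]] = {}
    for b in branches:
        traces = np.stack([r.activity[b] for _, r in pairs])
        for q in range(1, 5):
            sel = quartile_of == q
            quartile_means[(b, q)] = traces[sel].mean(axis=0)
        wmean = traces[:, in_win].mean(axis=1)
        fit = stats.linregress(quartile_of.astype(float), wmean)
        window_stat[b] = (float(fit.slope), float(fit.stderr))
    return QuartileTraces(
        quartile_means=quartile_means,
        times=times.copy(),
        window_stat=window_stat,
        n_per_cell=n_per_cell,
        window=window,
    )


def subtract_mean_trace(qt: QuartileTraces) -> QuartileTraces:
    """Remove the across-quartile mean trace per branch and time point.

    After centering, the four quartile traces of each branch sum to zero
    at every time; the quartile-rank regression slopes are unchanged
    (translation by a per-branch constant) and are copied through.
    """
    branches = {b for b, _ in qt.quartile_means}
    centered: dict[tuple[str, int], np.ndarray] = {}
    for b in branches:
        mean = np.mean([qt.quartile_means[(b, q)] for q in range(1, 5)], axis=0)
        for q in range(1, 5):
            centered[(b, q)] = qt.quartile_means[(b, q)] - mean
    return QuartileTraces(
        quartile_means=centered,
        times=qt.times,
        window_stat=dict(qt.window_stat),
        n_per_cell=dict(qt.n_per_cell),
        window=qt.window,
    )


def exponential_growth_test(
    values: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    floor: float = LOG_FLOOR,
) -> GrowthFit:
    """OLS of log(activity + floor) on time (ms) over a window.

    Returns the exponential rate in 1/ms with its SE and the fit r^2.
    Raises if the window misses the trace or the floored activity is not
    strictly positive there.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise ValueError("values and times must have the same shape")
    sel = (times >= window[0]) & (times <= window[1])
    if sel.sum() < 3:
        raise ValueError(f"window {window} holds fewer than 3 points of the trace")
    v = values[sel] + floor
    if np.any(v <= 0):
        raise ValueError("trace not strictly positive on the window (beyond the floor)")
    fit = stats.linregress(times[sel], np.log(v))
    return GrowthFit(
        rate=float(fit.slope),
        rate_se=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        window=(float(window[0]), float(window[1])),
    )
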