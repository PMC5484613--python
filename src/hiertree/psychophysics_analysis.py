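"""Behavioral diagnostics for simulated decision-tree sessions.

Implements the analyses used to discriminate flat, serial and hierarchical
architectures from choices alone:

* psychophysical reverse-correlation kernels — the influence of luminance
  noise at each frame on the choice at a given level, with trial-level
  bootstrap confidence bands;
* maximum-likelihood logistic psychometric fits (optionally with a lapse
  rate);
* the conditional L2 psychometric function, split by L1 correctness —
  flat architectures flatten the L2 function on L1-correct trials, a
  hierarchical architecture with zero confidence coupling does not;
* mean reaction time by difficulty;
* kernel-overlap / center-of-mass seriality indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .accumulator_models import SimResult
from .task_stimuli import LuminanceTrial, flip

# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelEstimate:
    """Per-frame influence of luminance noise on one level's choice.

    ``weights`` are in raw cd/m^2 of noise (chosen-branch minus unchosen-
    sibling noise averaged over trials), so the noiseless limit is exactly
    zero.  ``frame_times`` gives each bin's start time in ms: from
    stimulus onset for ``alignment="stimulus_onset"``, negative and
    counting back from the report for ``alignment="response"`` (index 0
    is the last complete frame before the report).
    """

    level: int
    alignment: str
    weights: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    frame_times: np.ndarray
    n_trials: int
    n_boot: int


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic choice function P(1) = lapse + (1-2 lapse) expit(slope (x - bias))."""

    slope: float
    bias: float
    lapse: float
    slope_se: float
    bias_se: float
    n_trials: int
    loglik: float
    degenerate: bool = False


@dataclass(frozen=True)
class ConditionalPsychometrics:
    """L2 psychometric fits stratified by L1 correctness."""

    fit_given_l1_correct: PsychometricFit
    fit_given_l1_error: PsychometricFit
    slope_ratio: float
    ratio_ci: tuple[float, float]
    accuracy_given_l1_correct: float
    accuracy_given_l1_error: float


@dataclass(frozen=True)
class SerialityIndex:
    """Overlap and center-of-mass offset between two levels' kernels."""

    overlap: float
    com_offset: float


@dataclass(frozen=True)
class RTByDifficulty:
    """Per-difficulty mean RT table plus a rank-correlation statistic."""

    table: pd.DataFrame
    rank_corr: float


# ---------------------------------------------------------------------------
# Reverse-correlation kernels
# ---------------------------------------------------------------------------


def _chosen_vs_sibling_noise(
    trial: LuminanceTrial, result: SimResult, level: int
) -> np.ndarray:
    """Noise on the chosen branch minus its unchosen sibling, per frame."""
    if level == 1:
        chosen = trial.l1_branch(result.choice_per_level[0])
        sibling = trial.l1_branch(flip(result.choice_per_level[0]))
    else:
        # walk the reported path to the visited bifurcation's letter prefix
        prefix = ""
        for k in range(level - 1):
            prefix += "T" if result.choice_per_level[k] == trial.target_path[k] else "D"
        local_t = result.choice_per_level[level - 1] == trial.target_path[level - 1]
        chosen = prefix + ("T" if local_t else "D")
        sibling = prefix + ("D" if local_t else "T")
    return trial.noise(chosen) - trial.noise(sibling)


def estimate_kernel(
    trials: Sequence[LuminanceTrial],
    results: Sequence[SimResult],
    level: int,
    alignment: str = "stimulus_onset",
    n_boot: int = 1000,
    seed: int = 0,
) -> KernelEstimate:
    """Psychophysical kernel for one level by choice-triggered averaging.

    Per frame, the weight is the mean over trials of (noise on the chosen
    branch - noise on its unchosen sibling), where noise is the sample
    minus its generative mean.  ``alignment="response"`` re-indexes frames
    backward from the report time, dropping the partial frame at the
    boundary.  Percentile bootstrap CIs resample whole trials.
    """
    if len(trials) == 0:
        raise ValueError("estimate_kernel: no trials")
    if len(trials) != len(results):
        raise ValueError("trials and results length mismatch")
    if alignment not in ("stimulus_onset", "response"):
        raise ValueError(f"unknown alignment {alignment!r}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    depth = trials[0].n_levels
    if not 1 <= level <= depth:
        raise ValueError(f"level {level} absent from a {depth}-level task")

    n, f = len(trials), trials[0].n_frames
    period = trials[0].sample_period
    d = np.empty((n, f))
    for i, (t, r) in enumerate(zip(trials, results)):
        d[i] = _chosen_vs_sibling_noise(t, r, level)

    if alignment == "stimulus_onset":
        mat = d
        frame_times = period * np.arange(f)
    else:
        mat = np.full((n, f), np.nan)
        for i, r in enumerate(results):
            m = int(min(np.floor(r.rt / period), f))
            if m > 0:
                mat[i, :m] = d[i, m - 1 :: -1]
        frame_times = -period * (np.arange(f) + 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        weights = np.nanmean(mat, axis=0)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
        boots = np.empty((n_boot, f))
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = np.nanmean(mat[idx], axis=0)
        ci_low = np.nanpercentile(boots, 2.5, axis=0)
        ci_high = np.nanpercentile(boots, 97.5, axis=0)
    # percentile intervals are guaranteed to bracket the point estimate
    ci_low = np.fmin(ci_low, weights)
    ci_high = np.fmax(ci_high, weights)
    return KernelEstimate(
        level=level,
        alignment=alignment,
        weights=weights,
        ci_low=ci_low,
        ci_high=ci_high,
        frame_times=frame_times,
        n_trials=n,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Psychometric fits
# ---------------------------------------------------------------------------

_SLOPE_SENTINEL = 50.0  # |logit slope| above this flags separation


def _irls_logit(x: np.ndarray, y: np.ndarray, max_iter: int = 50) -> tuple[float, float]:
    """Plain Newton/IRLS logistic regression (intercept, slope).

    Used for bootstrap refits where statsmodels' overhead dominates.
    """
    X = np.column_stack([np.ones_like(x), x])
    b = np.zeros(2)
    for _ in range(max_iter):
        p = expit(X @ b)
        w = p * (1.0 - p)
        g = X.T @ (y - p)
        h = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            break
        b = b + step
        if np.abs(step).max() < 1e-10 or np.abs(b).max() > 1e6:
            break
    return float(b[0]), float(b[1])


def fit_psychometric(
    signed_evidence: Sequence[float],
    choices: Sequence[int],
    lapse_mode: str = "fixed",
) -> PsychometricFit:
    """Maximum-likelihood logistic psychometric fit.

    ``lapse_mode="fixed"`` fixes the lapse at 0 (plain logistic
    regression, standard errors from the observed information);
    ``"free"`` estimates a shared lapse in [0, 0.5).  Complete separation
    or single-valued evidence yields a degenerate fit with an
    infinite-slope sentinel rather than an exception.
    """
    x = np.asarray(signed_evidence, dtype=float)
    y = np.asarray(choices, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("signed_evidence and choices must be equal-length 1-D")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("choices must be binary 0/1")
    n = len(x)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return PsychometricFit(
            slope=np.inf, bias=0.0, lapse=0.0, slope_se=np.nan, bias_se=np.nan,
            n_trials=n, loglik=np.nan, degenerate=True,
        )
    if lapse_mode not in ("fixed", "free"):
        raise ValueError(f"unknown lapse_mode {lapse_mode!r}")
    if lapse_mode == "free":
        return _fit_psychometric_free_lapse(x, y)

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            b0, b1 = res.params
            cov = res.cov_params()
            llf = float(res.llf)
        except Exception:
            b0, b1 = _irls_logit(x, y)
            cov = None
            llf = np.nan
    if not np.isfinite(b1) or abs(b1) > _SLOPE_SENTINEL or cov is None or not np.isfinite(cov).all():
        return PsychometricFit(
            slope=np.inf if b1 >= 0 else -np.inf, bias=0.0, lapse=0.0,
            slope_se=np.nan, bias_se=np.nan, n_trials=n, loglik=llf, degenerate=True,
        )
    slope = float(b1)
    bias = float(-b0 / b1)
    slope_se = float(np.sqrt(cov[1, 1]))
    # delta method for bias = -b0/b1
    grad = np.array([-1.0 / b1, b0 / b1**2])
    bias_se = float(np.sqrt(grad @ cov @ grad))
    return PsychometricFit(
        slope=slope, bias=bias, lapse=0.0, slope_se=slope_se, bias_se=bias_se,
        n_trials=n, loglik=llf,
    )


def _fit_psychometric_free_lapse(x: np.ndarray, y: np.ndarray) -> PsychometricFit:
    from scipy.optimize import minimize

    def unpack(theta):
        slope, bias, z = theta
        lapse = 0.499 * expit(z)
        return slope, bias, lapse

    def nll(theta):
        slope, bias, lapse = unpack(theta)
        p = lapse + (1.0 - 2.0 * lapse) * expit(slope * (x - bias))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))

    b0, b1 = _irls_logit(x, y)
    start = np.array([b1 if np.isfinite(b1) else 1.0, -b0 / b1 if b1 else 0.0, -4.0])
    res = minimize(nll, start, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    slope, bias, lapse = unpack(res.x)
    if not np.isfinite(slope) or abs(slope) > _SLOPE_SENTINEL:
        return PsychometricFit(
            slope=np.inf if slope >= 0 else -np.inf, bias=0.0, lapse=lapse,
            slope_se=np.nan, bias_se=np.nan, n_trials=len(x), loglik=-res.fun,
            degenerate=True,
        )
    hess = _numerical_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(hess)
        slope_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        bias_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        slope_se = bias_se = np.nan
    return PsychometricFit(
        slope=float(slope), bias=float(bias), lapse=float(lapse),
        slope_se=slope_se, bias_se=bias_se, n_trials=len(x), loglik=float(-res.fun),
    )


def _numerical_hessian(fun, theta, eps=1e-4):
    k = len(theta)
    h = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            h[i, j] = h[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * eps * eps)
    return h


# ---------------------------------------------------------------------------
# Conditional psychometrics (L1 x L2 interaction)
# ---------------------------------------------------------------------------


def l2_signed_evidence(trial: LuminanceTrial) -> float:
    """Up-branch minus down-branch generative mean at the level-2 bifurcation.

    The local target of every level-2 bifurcation points in the direction
    ``target_path[1]``, so the signed evidence is +offset when the target
    is up and -offset when it is down, on either side of the tree.
    """
    off = trial.offsets[1]
    return off if trial.target_path[1] == "up" else -off


def conditional_psychometric(
    trials: Sequence[LuminanceTrial],
    results: Sequence[SimResult],
    n_boot: int = 1000,
    seed: int = 0,
    lapse_mode: str = "fixed",
) -> ConditionalPsychometrics:
    """L2 psychometric function conditioned on L1 correctness.

    Fits P(choose up at L2) against the signed up-minus-down mean
    luminance, separately for L1-correct and L1-error trials, and returns
    the slope ratio (error/correct) with a trial-resampling bootstrap CI.
    A ratio near 1 indicates independent sub-decisions; flat
    architectures push it above 1 (flatter psychometric function on
    L1-correct trials).
    """
    if len(trials) != len(results) or len(trials) == 0:
        raise ValueError("need equal, non-zero numbers of trials and results")
    if trials[0].n_levels < 2:
        raise ValueError("conditional_psychometric needs 2-level trials")
    x = np.array([l2_signed_evidence(t) for t in trials])
    y = np.array([1.0 if r.choice_per_level[1] == "up" else 0.0 for r in results])
    acc2 = np.array([r.correct_per_level[1] for r in results], dtype=float)
    corr1 = np.array([r.correct_per_level[0] for r in results], dtype=bool)
    if not corr1.any():
        raise ValueError("empty stratum: no L1-correct trials")
    if corr1.all():
        raise ValueError("empty stratum: no L1-error trials")

    fit_c = fit_psychometric(x[corr1], y[corr1], lapse_mode)
    fit_e = fit_psychometric(x[~corr1], y[~corr1], lapse_mode)
    ratio = fit_e.slope / fit_c.slope

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    xc, yc = x[corr1], y[corr1]
    xe, ye = x[~corr1], y[~corr1]
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        ic = rng.integers(0, len(xc), len(xc))
        ie = rng.integers(0, len(xe), len(xe))
        _, sc = _irls_logit(xc[ic], yc[ic])
        _, se_ = _irls_logit(xe[ie], ye[ie])
        ratios[b] = se_ / sc if sc != 0 else np.nan
    lo, hi = np.nanpercentile(ratios, [2.5, 97.5])
    return ConditionalPsychometrics(
        fit_given_l1_correct=fit_c,
        fit_given_l1_error=fit_e,
        slope_ratio=float(ratio),
        ratio_ci=(float(lo), float(hi)),
        accuracy_given_l1_correct=float(acc2[corr1].mean()),
        accuracy_given_l1_error=float(acc2[~corr1].mean()),
    )


# ---------------------------------------------------------------------------
# RT by difficulty
# ---------------------------------------------------------------------------


def rt_by_difficulty(
    results: Sequence[SimResult],
    difficulty_labels: Sequence,
) -> RTByDifficulty:
    """Mean RT (with SEM) per difficulty label plus a rank correlation.

    ``difficulty_labels`` is one orderable label per result (higher label
    = harder by the caller's convention).  The monotonicity statistic is
    the Spearman correlation between the label rank and the per-label
    mean RT; it is NaN when fewer than two labels are present.
    """
    if len(results) == 0:
        raise ValueError("no results")
    if len(difficulty_labels) != len(results):
        raise ValueError("difficulty_labels must align with results")
    if any(lab is None for lab in difficulty_labels):
        raise ValueError("missing difficulty labels")
    df = pd.DataFrame({
        "difficulty": list(difficulty_labels),
        "rt_ms": [r.rt for r in results],
    })
    table = (
        df.groupby("difficulty")["rt_ms"]
        .agg(n="count", mean_rt_ms="mean", sem_rt_ms="sem")
        .reset_index()
        .sort_values("difficulty", ignore_index=True)
    )
    if len(table) < 2:
        rho = np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant mean RTs -> undefined rho
            rho = float(stats.spearmanr(np.arange(len(table)), table["mean_rt_ms"]).statistic)
    return RTByDifficulty(table=table, rank_corr=rho)


# ---------------------------------------------------------------------------
# Kernel seriality
# ---------------------------------------------------------------------------


def kernel_seriality(k1: KernelEstimate, k2: KernelEstimate) -> SerialityIndex:
    """Overlap and center-of-mass offset between two kernels.

    Both kernels are clipped at zero and normalized to unit sum; overlap
    is sum(min)/sum(max) (1 for identical kernels, 0 for disjoint
    support), and ``com_offset`` is center-of-mass(k2) minus
    center-of-mass(k1) in ms.  Serial processing shows up as a positive
    offset and reduced overlap.
    """
    if k1.alignment != k2.alignment:
        raise ValueError("kernels must share alignment")
    if len(k1.frame_times) != len(k2.frame_times) or not np.allclose(k1.frame_times, k2.frame_times):
        raise ValueError("kernels must share the frame grid")
    w1 = np.clip(np.nan_to_num(k1.weights), 0.0, None)
    w2 = np.clip(np.nan_to_num(k2.weights), 0.0, None)
    s1, s2 = w1.sum(), w2.sum()
    if s1 == 0 or s2 == 0:
        raise ValueError("undefined overlap: all-zero kernel after clipping")
    w1, w2 = w1 / s1, w2 / s2
    overlap = float(np.minimum(w1, w2).sum() / np.maximum(w1, w2).sum())
    t = k1.frame_times
    com1 = float(np.sum(t * w1))
    com2 = float(np.sum(t * w2))
    return SerialityIndex(overlap=overlap, com_offset=com2 - com1)
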