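# Methods

## Task model

A trial of the decision-tree task presents, at each bifurcation, two
branches whose luminance is sampled once per frame:

    x_b[k] = mu_b + eps_b[k],   eps_b[k] ~ N(0, sigma^2) i.i.d.

with sigma = 10 cd/m² and a 50 cd/m² background by default. The local
target branch of each bifurcation carries mean `background + offset`,
the distractor carries `background`; the offset (cd/m², per level) is
the difficulty. Defaults: 15 frames of 100 ms (1.5 s of stimulus), a
500 ms minimum viewing time, and three per-level offsets (2, 4, 8).
The frame rate is a package choice — the source task specifies only
the 500 ms minimum wait — picked so that at least five frames fall
inside the enforced viewing window, giving the kernels usable temporal
resolution.

Branch labels are target-relative: level-1 branches are spatial
(`L1-left`, `L1-right`); deeper branches are letter codes (`TT`, `TD`,
`DT`, `DD`, and three-letter codes at level 3) in which each letter says
whether the branch is the local target (`T`) of its bifurcation and the
prefix gives the same status for its ancestors. A 2-level tree has 6
branches and 4 leaves; a 3-level tree has 14 branches and 8 leaves.

The local target *direction* at every level-k bifurcation equals the
k-th entry of the trial's target path (e.g. if the L2 answer is "up",
the brighter branch points up on both sides of the tree). The task
does not parameterize per-side difficulty asymmetries; analyses that
need them construct modified trials directly.

Randomness is keyed per trial: the stream for trial *i* of a session
with seed *s* is `SeedSequence([s, i, salt])`, with separate salts for
stimulus generation and model simulation (and one per serial stage), so
any trial can be regenerated in isolation and results are invariant
under permutation of a batch.

## Quest staircase

The adaptive sessions use a grid-based Bayesian staircase over the
offset threshold T. The assumed link is logistic in the offset x,

    p(correct | x, T) = g + (1 - g - l) * expit(beta (x - T) + c),

with guess rate g = 0.25 (a two-level trial is correct only when the
observer reaches the final target, so chance is 1/4), lapse l = 0.02,
slope beta = 0.6 per cd/m², and the lateral constant c solved so that
p(correct | T, T) = target_p = 0.75 — T is by construction the offset
holding performance at the criterion. The posterior is updated on a
160-point grid over [0.1, 16] cd/m² under a broad Gaussian prior
(mean 8, SD 6) and the next trial is placed at the posterior mode (ties
to the smaller offset). The exact staircase variant used with the human
data is not on record; this realization is a declared package choice.
The calibration observer sums the samples of the two branches at each
bifurcation along its believed path and picks the larger sum, matching
the task instruction. With it, a 2000-trial session converges to ~75%
correct over the final 500 trials (the acceptance script recomputes
this).

## Accumulator models

All models receive, per bifurcation and frame, the signed contrast
`c = (branch - sibling)/2` toward the local target, held constant within
the frame, and integrate with Euler–Maruyama at Δt = 1 ms.

**Flat race** (3 parameters: gain, bound, non-decision time). Four
perfect integrators, one per leaf, each driven by
`gain * (c_L1 +/- c_L2)`; the first to cross the common bound decides
both levels; no model noise (all stochasticity is stimulus noise). If
the bound is never crossed, the choice is the argmax at stimulus end and
`terminated_by_bound` is False. Within-step ties go to the largest
overshoot; exact ties are broken uniformly with the trial's stream.

**Flat LCA** (8 core parameters). Per leaf,

    da_i = (I_i + (alpha - lambda) a_i - w * sum_j a_j) dt + sigma_m dW_i,

rectified at zero each step; `I_i = g1*c_L1 +/- g2*c_L2`. Diffusion is
constant by default (independent of the evidence); the
`scale_noise_with_evidence` variant uses a per-step SD of
`sigma_m * |I_i|`. Two bound regimes: *collapsing* (bounds infinite
before `collapse_time` = 500 ms, then a forced argmax, so every decision
lands exactly at 500 ms plus non-decision time) and *stable high*
(constant bound; argmax fallback at the 1.5 s deadline with
`terminated_by_bound = False`). Defaults
(g1 = g2 = 0.01/ms per cd/m², alpha = 0.005/ms, lambda = 0.001/ms,
w = 0.0015/ms, sigma_m = 0.3, bound = 600) were fixed once by
`scripts/calibrate_lca_defaults.py` to realize the two regimes this
family is meant to exhibit: the stable bound goes unreached on ~35-40%
of trials within the deadline, and mean activity grows super-linearly
(net self-excitation alpha - lambda = 0.004/ms). The companion fitted
values are not on record; the defaults are configuration, not estimates.

**Serial tracer.** Stage k is a signed two-alternative accumulation of
the level-k contrast of the currently believed path to +/-bound
(defaults per stage: gain 0.02, bound 8, diffusion 0.3); stage k+1
starts at stage k's termination. After the stimulus ends the drift is
zero; a stage still undecided at four stimulus durations is read out by
sign. Per-stage decision times are recorded; total RT is the last
stage's termination plus non-decision time.

**Hierarchical.** Three concurrent signed accumulators — L1, and one
per L2 bifurcation — each to its own bound or the deadline. Confidence
in each L2 decision is `expit(kappa |v|)` of the accumulated evidence;
the L1 report is `sign(v_L1 + beta (conf_target_side - conf_other))`.
At beta = 0 the L1 choice depends only on the L1 stream. Defaults
kappa = 0.02, beta = 20: at the evidence scale the task produces
(|v| of order tens of activity units) this keeps the confidence
read-out graded rather than saturated, which is what lets the
confidence difference carry useful signal; with a much steeper kappa
both confidences saturate near 1 and the coupling becomes inert. How
the original hierarchical account computed its reward-maximizing
confidence is not specified; the logistic read-out is a declared
stand-in.

## Analyses

**Reverse-correlation kernels.** Per frame, the weight is the mean over
trials of (noise on the chosen branch - noise on its unchosen sibling)
at the level's visited bifurcation, in raw cd/m² (so the no-influence
limit is exactly zero). Response alignment re-indexes complete frames
backward from the report time, dropping the partial boundary frame;
both alignments are provided. CIs are percentile bootstrap over trials
(default 1000 resamples, seeded); they are pointwise and descriptive —
no familywise correction — which matters when comparing extremes across
frames (see Limitations).

**Psychometric fits.** Maximum-likelihood logistic
`P(1) = lapse + (1 - 2 lapse) expit(slope (x - bias))`, lapse fixed at 0
by default (statsmodels Logit; SEs from the observed information, bias
SE by the delta method) or freed (Nelder–Mead with a numerical
Hessian). Complete separation or single-valued evidence returns a
degenerate fit flagged with an infinite-slope sentinel rather than
raising.

**Conditional psychometrics.** The L2 signed evidence is the up-minus-
down generative-mean difference at the reported side's bifurcation;
fits are stratified by L1 correctness and compared by the slope ratio
(error/correct), with a within-stratum trial bootstrap for the ratio CI
(robust when the L1-error stratum is small). Bootstrap refits use an
internal IRLS logistic solver, cross-checked against statsmodels in the
tests.

**RT by difficulty** reports per-label mean RT with SEM and the
Spearman correlation between label rank and mean RT (NaN with fewer
than two labels).

**Kernel seriality.** Kernels are clipped at zero and normalized to
unit sum; overlap is sum(min)/sum(max) and the center-of-mass offset is
in ms. Serial processing yields a positive L2-minus-L1 offset and
reduced overlap.

**Quartile conditioning.** L1 evidence strength is the target-minus-
distractor L1 luminance averaged over the first two frames. Within each
difficulty level (correct trials only by default) trials are split into
quartiles — ties broken by a seeded shuffle — then pooled by quartile
rank across difficulty. Per branch, the mean activity in a window
(default 200-500 ms post-onset; the neural analysis window is not on
record, so this is a config knob) is regressed on quartile rank. For a
flat accumulator with one global inhibition source, TT and TD slopes
share their sign (both leaves ride the same L1 input) while DT and DD
are suppressed, and rectification pins DD near zero, making its slope
the weakest — the pattern such a model cannot escape, and the one the
package's acceptance test asserts. Model traces are analyzed raw; no
neural-style normalization is applied.

**Exponential growth.** OLS of log(activity + 1e-6) on time over a
stated window; with no noise and no inhibition the fitted rate matches
the linear-system rate alpha - lambda (late-window bias from the
`(e^{kt} - 1)` transient is below 1% for windows starting after ~5/k).

## I/O and determinism

All tables are CSV with a header row, floats at 9 significant digits,
0-based frame indices, ms and cd/m² units. Trials serialize to a long
samples file plus a metadata file (target path, difficulty indices,
offsets, frame period); results and activity have their own schemas.
A pipeline run writes a manifest with a config hash and per-file SHA-256
checksums; identical configs reproduce identical checksums. Analysis
failures on degenerate inputs (e.g. zero trials) are recorded in the
run log and manifest without aborting the run; generation or simulation
failures abort with the stage name.

## Problem sizes

The test suite runs the discriminating analyses at the sizes that make
the qualitative contrasts statistically unambiguous while keeping a
single-CPU run short: 5×10⁴ trials for the crosstalk and independence
contrasts and the linear-observer recovery, 2×10⁴ for kernels and
quartile conditioning, 10⁴ per cell elsewhere. The synthetic generator
emulates the luminance statistics, tree structure and adaptive
difficulty of the behavioral experiments; it does not emulate
eye movements, display calibration, temporal blurring across frames, or
sequential dependencies between trials, so passing tests certify the
estimators and the models' qualitative signatures, not any fit to a
particular subject's data.

## Limitations

* No parameter fitting to empirical choices is included, and the
  original neural recordings are not consumed; activity analyses apply
  to model traces only.
* Kernel CIs are pointwise; comparisons that select extreme frames
  (max vs min) inherit an extreme-order-statistics bias that pointwise
  intervals do not control, so the flatness of a kernel is better judged
  against the cross-frame dispersion expected under flatness
  (~3.5 standard errors between max and min of 15 frames) than by
  mutual CI containment of the extremes.
* The Quest criterion applies to whole-trial correctness (chance 25%);
  holding a per-bifurcation criterion instead would need a different
  guess rate.
* The collapsing-bound regime forces every decision at exactly
  `collapse_time`; RT distributions in that regime are degenerate by
  design.
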