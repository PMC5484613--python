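"""Diagnostics behind the default FlatLCAParams.

Prints, at the packaged defaults, the quantities the defaults were chosen
to satisfy:

* stable-high regime: fraction of trials on which the bound goes
  unreached within the deadline (target: a large fraction, > 0.3);
* super-linear (exponential) growth of the winning accumulator's mean
  activity, from the log-linear rate over the late trial;
* direction of the L1-correct vs L1-error crosstalk in L2 accuracy;
* quartile-of-L1-evidence regression slopes per branch.

Run: python scripts/calibrate_lca_defaults.py [seed]
"""

import sys

import numpy as np

import hiertree as ht
from hiertree.activity_analysis import exponential_growth_test


def main(seed: int = 0) -> None:
    spec = ht.make_tree_task()
    params = ht.FlatLCAParams()
    print(f"defaults: {params}")

    n = 6000
    labels = [(i % 3,) * 2 for i in range(n)]
    trials = ht.generate_trials(spec, n, seed=seed, difficulty_labels=labels)
    results = ht.batch_simulate(trials, "flat_lca", params, seed=seed + 1, record_activity=True)

    unreached = np.mean([not r.terminated_by_bound for r in results])
    print(f"stable-high bound unreached on {unreached:.1%} of trials (want > 30%)")

    mean_tt = np.mean([r.activity["TT"] for r in results], axis=0)
    fit = exponential_growth_test(mean_tt, results[0].activity_times, window=(600.0, 1400.0))
    print(f"mean TT activity growth rate {fit.rate:.5f}/ms (r^2={fit.r_squared:.3f}; "
          f"positive rate = super-linear growth)")

    c1 = np.array([r.correct_l1 for r in results])
    c2 = np.array([r.correct_l2 for r in results])
    print(f"L2 accuracy given L1 correct {c2[c1].mean():.3f}, given L1 error {c2[~c1].mean():.3f} "
          f"(flat-model crosstalk: first should be lower)")

    qt = ht.quartile_condition(trials, results, correct_only=True, window=(200.0, 500.0), seed=seed)
    for b, (s, se) in sorted(qt.window_stat.items()):
        print(f"quartile slope {b}: {s:+.3f} +- {se:.3f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
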