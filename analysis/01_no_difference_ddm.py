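#!/usr/bin/env python
"""No-difference DDM study: the spurious a-diff/t0-diff correlation.

Every participant uses identical parameters in both conditions (drawn from
uniform ranges v [0,4], a [0.5,2], t0 [0.2,0.5]), so every true difference
score is zero.  Fitting each condition separately by ML nevertheless yields
a large negative correlation between the boundary-separation and
non-decision-time difference scores (full-scale reference r = -.743); an EZ
closed-form refit of the same data shows the same artefact (r = -.683), and
|z| > 2.5 outlier removal does not abolish it (r = -.661).

Writes the generating/fitted tables, correlation matrices and heatmaps
under results/01_no_difference/.
"""

import argparse

from diffscore import (
    StudyConfig,
    compute_diff_scores,
    outlier_filtered_correlation,
    run_study,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-participants", type=int, default=200)
    ap.add_argument("--n-trials", type=int, default=500)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/01_no_difference")
    args = ap.parse_args()

    for fitter in ("ml", "ez"):
        cfg = StudyConfig(
            study="sim1", fitter=fitter, n_participants=args.n_participants,
            n_trials=args.n_trials, seed=args.seed,
            out_dir=f"{args.out}/{fitter}",
        )
        report = run_study(cfg)
        corr = report.corr
        print(f"\n[{fitter.upper()}] {args.n_participants} participants x "
              f"{args.n_trials} trials/condition (seed {args.seed})")
        print(f"  corr(a diff, t0 diff)     = {corr.loc['a diff', 't0 diff']:+.3f}")
        print(f"  corr(a diff, v diff)      = {corr.loc['a diff', 'v diff']:+.3f}")
        print(f"  corr(v diff, t0 diff)     = {corr.loc['v diff', 't0 diff']:+.3f}")
        print(f"  corr(a, t0) within easy   = {corr.loc['a (easy)', 't0 (easy)']:+.3f}")
        if fitter == "ml":
            diffs = compute_diff_scores(report.fitted)
            r, n_removed, n_used = outlier_filtered_correlation(
                diffs["a_diff"], diffs["t0_diff"]
            )
            print(f"  after |z|>2.5 filtering   = {r:+.3f} "
                  f"({n_removed} removed, {n_used} kept)")


if __name__ == "__main__":
    main()
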