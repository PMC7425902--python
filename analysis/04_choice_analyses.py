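#!/usr/bin/env python
"""Run the study's inferential chain on the simulated experiments.

For the natural- and learned-default trial tables from 03_simulate_hypotheses:
priming one-sample t-tests against 50%, backward GLMM selection on choices,
and the RT manipulation check.  Writes results/choice_analysis_<hyp>.json.
The learned-default run should end with a positive ToT x CP interaction; the
natural-default run with a positive TP main effect; both RT checks with a
negative TP slope.
"""

import json
import sys
from pathlib import Path

from risky_defaults import choice_analysis as ca
from risky_defaults.pipeline import _jsonable
from risky_defaults.trialtable import read_trials

OUT = Path("results")


def analyze(hyp: str) -> None:
    path = OUT / f"trials_{hyp}.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing: run analysis/03_simulate_hypotheses.py first")
    trials = read_trials(path)
    report = {"hypothesis": hyp, "priming": {}}
    pr = trials[trials.session == "priming"]
    for group, side in (("safe_default", "greater"), ("risky_default", "less")):
        props = pr[pr.group == group].groupby("subject")["choice"].mean()
        t, df, p, mean, se = ca.priming_proportion_test(props, side=side)
        report["priming"][group] = dict(t=t, df=df, p=p, mean=mean, se=se)
        print(f"{hyp}/{group}: priming safe proportion {mean:.2f} +/- {se:.2f}, "
              f"t({df}) = {t:.2f}, one-sided p = {p:.4g}")
    trace = ca.backward_select(trials)
    report["final_formula"] = trace.final_spec.formula()
    report["final_coefficients"] = {
        n: dict(coef=c, se=s, p=p)
        for n, c, s, p in zip(trace.final_fit.fe_names, trace.final_fit.coef,
                              trace.final_fit.se, trace.final_fit.pvalues)
    }
    print(f"{hyp}: final model {trace.final_spec.formula()}")
    rt = ca.rt_manipulation_check(trials)
    report["rt_check"] = rt.to_dict(orient="index")
    print(f"{hyp}: RT TP slope {rt.loc['TP', 'coef']:.1f} ms "
          f"(p = {rt.loc['TP', 'p']:.3g})\n")
    with open(OUT / f"choice_analysis_{hyp}.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)


def main() -> None:
    for hyp in sys.argv[1:] or ("natural", "learned"):
        analyze(hyp)


if __name__ == "__main__":
    main()
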