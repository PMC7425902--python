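"""End-to-end pipeline: simulate (or load) -> choice analyses -> fixed point.

Configuration is a flat dict (typically loaded from YAML); every stage logs
its name, the master seed and a hash of the configuration, and all outputs
are written as JSON/CSV so a fixed seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import choice_analysis as ca
from . import fixedpoint as fp
from .experiment_simulator import DesignSpec, ScenarioSpec, simulate_experiment
from .trialtable import read_trials, write_trials

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

log = logging.getLogger("risky_defaults")

DEFAULT_CONFIG = {
    "seed": 0,
    "trials": None,  # path to an existing trial table; None -> simulate
    "hypothesis": "learned",
    "frame": "gain",
    "n_subjects": 18,
    "alpha": 0.05,
    "fixed_point_factors": ["tp_code", "tot_code"],
    "out_dir": "pipeline_out",
}


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full analysis chain; returns the report bundle.

    Any stage failure raises with the stage name in the message and leaves no
    partial JSON reports behind (reports are written at the end).
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    tag = _config_hash(cfg)
    out_dir = Path(cfg["out_dir"])

    def _log(stage: str, msg: str) -> None:
        log.info("stage=%s seed=%d config=%s %s", stage, seed, tag, msg)

    stage = "simulate"
    try:
        if cfg["trials"] is not None:
            stage = "load"
            trials = read_trials(cfg["trials"])
            _log(stage, f"loaded {len(trials)} trials from {cfg['trials']}")
        else:
            design = DesignSpec(n_subjects=int(cfg["n_subjects"]), frame=cfg["frame"])
            scenario = ScenarioSpec(hypothesis=cfg["hypothesis"])
            trials = simulate_experiment(design, scenario, seed=seed)
            _log(stage, f"simulated {len(trials)} trials ({cfg['hypothesis']})")

        stage = "analyze-choices"
        priming = {}
        pr = trials[trials["session"] == "priming"]
        for group, side in (("safe_default", "greater"), ("risky_default", "less")):
            props = pr[pr["group"] == group].groupby("subject")["choice"].mean()
            t, df_, p, mean, se = ca.priming_proportion_test(props, side=side)
            priming[group] = {"t": t, "df": df_, "p": p, "mean": mean, "se": se}
        trace = ca.backward_select(trials, alpha=float(cfg["alpha"]))
        rt_table = ca.rt_manipulation_check(trials)
        _log(stage, f"final model: {trace.final_spec.formula()}")

        stage = "fixed-point"
        fp_reports = {}
        for factor in cfg["fixed_point_factors"]:
            result, crossings = fp.run_fixed_point(trials, factor)
            fp_reports[factor] = {
                "bf01": result.bf01,
                "n_participants": result.n_participants,
                "excluded": result.excluded,
                "pair_means": result.pair_means,
                "pair_ses": result.pair_ses,
            }
            _log(stage, f"factor={factor} BF01={result.bf01:.3g}")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    bundle = {
        "config": cfg,
        "config_hash": tag,
        "priming": priming,
        "selection": {
            "final_formula": trace.final_spec.formula(),
            "final_coefficients": {
                n: {"coef": c, "se": s, "p": p}
                for n, c, s, p in zip(
                    trace.final_fit.fe_names,
                    trace.final_fit.coef,
                    trace.final_fit.se,
                    trace.final_fit.pvalues,
                )
            },
            "steps": [
                {
                    "removed": ":".join(st.removed),
                    "formula": st.formula,
                    "loglik": st.loglik,
                    "lrt_stat": st.lrt_stat,
                    "df": st.df,
                    "p": st.p,
                    "accepted": st.accepted,
                }
                for st in trace.steps
            ],
        },
        "rt_check": {
            name: {"coef": row["coef"], "se": row["se"], "p": row["p"]}
            for name, row in rt_table.iterrows()
        },
        "fixed_point": fp_reports,
    }

    out_dir.mkdir(parents=True, exist_ok=True)
    write_trials(trials, out_dir / "trials.csv")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2, sort_keys=True)
    _log("done", f"report bundle written to {out_dir}")
    return bundle
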