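"""Inferential chain on choice data.

* Priming manipulation check: one-sample t-tests of per-subject safe-choice
  proportions against 50%, one-sided in each group's designed direction.
* Mixed-effects logistic regression of choice (1 = safe) on time pressure
  (TP), time on task (ToT) and choice-proportion group (CP), with random
  intercepts and TP/ToT slopes per subject; TP/ToT coded -1/0/+1 (cardinal),
  CP coded +1 (safe-default) / -1 (risky-default).
* Backward iterative model comparison: start from the full TP*ToT*CP
  factorial and repeatedly remove the least significant removable term,
  accepting each removal only if the likelihood-ratio test against the
  richer model is non-significant; interactions go before the main effects
  they contain.
* RT manipulation check: linear mixed model (ML) of RT on TP (+ ToT + CP),
  delegated to statsmodels MixedLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_logit import ConvergenceError, MixedLogitResult, fit_mixed_logit

__all__ = [
    "FACTORS",
    "FULL_TERMS",
    "RegressionSpec",
    "SelectionStep",
    "SelectionTrace",
    "priming_proportion_test",
    "add_analysis_codes",
    "fit_mixed_logistic",
    "lr_test",
    "backward_select",
    "rt_manipulation_check",
]

FACTORS = ("TP", "ToT", "CP")

#: full factorial fixed-effects structure, as ordered term tuples
FULL_TERMS: tuple[tuple[str, ...], ...] = tuple(
    tuple(c)
    for k in (1, 2, 3)
    for c in combinations(FACTORS, k)
)

RANDOM_TERMS = ("1", "TP", "ToT")


@dataclass(frozen=True)
class RegressionSpec:
    """Which fixed-effect terms enter; the random-effects structure is fixed
    (intercept + TP + ToT per subject) so backward selection only varies the
    fixed part."""

    response: str = "choice"
    terms: tuple[tuple[str, ...], ...] = FULL_TERMS

    def formula(self) -> str:
        fixed = " + ".join(":".join(t) for t in self.terms) or "1"
        return f"{self.response} ~ {fixed} + (1 + TP + ToT | subject)"

    def drop(self, term: tuple[str, ...]) -> "RegressionSpec":
        return RegressionSpec(
            response=self.response,
            terms=tuple(t for t in self.terms if t != term),
        )


@dataclass
class SelectionStep:
    removed: tuple[str, ...]
    formula: str  # formula of the candidate (reduced) model
    loglik: float  # its maximised marginal log-likelihood
    lrt_stat: float
    df: int
    p: float
    accepted: bool


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_spec: RegressionSpec
    final_fit: MixedLogitResult


def priming_proportion_test(
    proportions: Sequence[float], null: float = 0.5, side: str = "greater"
):
    """One-sample t-test of subject-level safe-choice proportions vs 50%.

    ``side`` is the designed direction: 'greater' for the safe-default group,
    'less' for the risky-default group ('two-sided' also accepted).
    Returns (t, df, p, mean, se).
    """
    x = np.asarray(proportions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate sample: zero variance in proportions")
    res = stats.ttest_1samp(x, null, alternative=side)
    se = float(np.std(x, ddof=1) / np.sqrt(x.size))
    return float(res.statistic), int(x.size - 1), float(res.pvalue), float(x.mean()), se


def add_analysis_codes(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach TP/ToT/CP numeric codes used by all regressions."""
    df = trials.copy()
    df["TP"] = df["tp_code"].astype(float)
    df["ToT"] = df["tot_code"].astype(float)
    df["CP"] = np.where(df["group"] == "safe_default", 1.0, -1.0)
    return df


def _design_matrix(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for t in terms:
        v = np.ones(len(df))
        for f in t:
            v = v * df[f].to_numpy()
        cols.append(v)
        names.append(":".join(t))
    return np.column_stack(cols), names


def fit_mixed_logistic(
    trials: pd.DataFrame, spec: RegressionSpec = RegressionSpec(), start=None
) -> MixedLogitResult:
    """Mixed logistic regression of choice on the spec's fixed terms.

    Uses experimental-session rows only (the priming session has no TP/ToT
    manipulation).  Deterministic given data and spec.
    """
    df = add_analysis_codes(trials)
    if "session" in df.columns:
        df = df[df["session"] == "experimental"]
    X, names = _design_matrix(df, spec.terms)
    Z = np.column_stack(
        [np.ones(len(df)), df["TP"].to_numpy(), df["ToT"].to_numpy()]
    )
    return fit_mixed_logit(
        df["choice"].to_numpy(),
        X,
        Z,
        df["subject"].to_numpy(),
        fe_names=names,
        re_names=list(RANDOM_TERMS),
        start=start,
    )


def lr_test(ll_full: float, ll_reduced: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic (clipped at 0 for nested fits) and p."""
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return stat, float(stats.chi2.sf(stat, df))


def _removable(terms) -> list[tuple[str, ...]]:
    """Terms not contained in any retained higher-order interaction."""
    out = []
    for t in terms:
        if any(set(t) < set(o) for o in terms if o != t):
            continue
        out.append(t)
    return out


def backward_select(
    trials: pd.DataFrame,
    full_spec: RegressionSpec = RegressionSpec(),
    alpha: float = 0.05,
) -> SelectionTrace:
    """Backward iterative model comparison on the fixed effects.

    At each step, among removable terms (those not nested in a retained
    interaction) the one with the largest Wald p is dropped and the reduced
    model is compared to the current one by LRT; a significant LRT
    (p < alpha) vetoes the removal and stops the procedure.  Ties in Wald p
    are broken toward higher-order terms, then lexicographically.
    """
    spec = full_spec
    try:
        fit = fit_mixed_logistic(trials, spec)
    except ConvergenceError as err:
        raise ConvergenceError(f"full model failed to fit: {err}") from err
    steps: list[SelectionStep] = []
    while spec.terms:
        cand = _removable(spec.terms)
        pmap = dict(zip(fit.fe_names, fit.pvalues))
        # largest Wald p; ties -> higher order first, then lexicographic
        cand.sort(key=lambda t: (-np.nan_to_num(pmap[":".join(t)], nan=1.0),
                                 -len(t), t))
        term = cand[0]
        reduced = spec.drop(term)
        # warm-start the reduced fit from the parent solution
        keep = [n != ":".join(term) for n in fit.fe_names]
        start = np.concatenate([fit.coef[keep], fit.re_sd])
        try:
            red_fit = fit_mixed_logistic(trials, reduced, start=start)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"step {len(steps) + 1} (removing {':'.join(term)}): {err}"
            ) from err
        stat, p = lr_test(fit.loglik, red_fit.loglik, df=1)
        accepted = p >= alpha
        steps.append(
            SelectionStep(
                removed=term,
                formula=reduced.formula(),
                loglik=red_fit.loglik,
                lrt_stat=stat,
                df=1,
                p=p,
                accepted=accepted,
            )
        )
        if not accepted:
            break
        spec, fit = reduced, red_fit
    return SelectionTrace(steps=steps, final_spec=spec, final_fit=fit)


def rt_manipulation_check(
    trials: pd.DataFrame, terms: tuple[tuple[str, ...], ...] = (("TP",), ("ToT",), ("CP",))
) -> pd.DataFrame:
    """Linear mixed model (ML) of RT on TP (+ ToT, CP): the TP slope should
    be negative when the time-pressure manipulation works.

    Returns a coefficient table (coef, se, p) indexed by term name.
    """
    import statsmodels.formula.api as smf

    df = add_analysis_codes(trials)
    if "session" in df.columns:
        df = df[df["session"] == "experimental"]
    df = df.dropna(subset=["rt_ms"]).copy()
    # fit on seconds for optimizer conditioning; report on the ms scale
    df["rt_s"] = df["rt_ms"] / 1000.0
    fixed = " + ".join(":".join(t) for t in terms)
    model = smf.mixedlm(
        f"rt_s ~ {fixed}", df, groups=df["subject"], re_formula="~TP + ToT"
    )
    res = model.fit(reml=False, method=["lbfgs", "powell"])
    if not res.converged:
        raise ConvergenceError(
            "RT mixed model did not converge; try dropping random slopes"
        )
    keep = ["Intercept"] + [":".join(t) for t in terms]
    return pd.DataFrame(
        {
            "coef": res.params[keep] * 1000.0,
            "se": res.bse[keep] * 1000.0,
            "p": res.pvalues[keep],
        }
    )
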