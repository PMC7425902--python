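"""Fixed-point property test for binary RT mixtures.

If the RT distribution in every condition is a mixture, in different
proportions, of the same two base distributions, then all condition-wise
densities intersect at one common point (the density value where the two
base densities cross).  The test proceeds in three steps:

1. per participant and condition, a Gaussian kernel density estimate of the
   RT distribution, with the kernel SD set to the SD of that participant's
   RTs pooled across conditions;
2. for each pair of condition densities, the crossing-point RT (three
   conditions -> three crossings per participant);
3. across participants, a repeated-measures comparison of the crossing
   points across condition pairs; a Bayes factor (BIC approximation,
   unit-information prior) quantifies support for a single common crossing
   population (BF01 > 1: fixed point present) versus pair-dependent
   crossings (BF01 < 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DensityEstimate",
    "FixedPointResult",
    "pooled_bandwidth",
    "make_grid",
    "estimate_density",
    "crossing_point",
    "crossing_set",
    "fixed_point_bayes_test",
    "run_fixed_point",
]

GRID_POINTS = 512
MIN_RTS_PER_CONDITION = 5


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int


@dataclass
class FixedPointResult:
    bf01: float
    pair_means: "pd.Series"
    pair_ses: "pd.Series"
    n_participants: int
    excluded: list


def pooled_bandwidth(rts) -> float:
    """Kernel SD: the SD of the RT sample collapsed across conditions."""
    x = np.asarray(rts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 RTs to set a bandwidth")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("constant RT sample: bandwidth undefined")
    return sd


def make_grid(pooled_rts, bandwidth: float, n_points: int = GRID_POINTS) -> np.ndarray:
    """Common evaluation grid spanning [min - 3*bw, max + 3*bw]."""
    x = np.asarray(pooled_rts, dtype=float)
    return np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, n_points)


def estimate_density(rts, bandwidth: float, grid) -> DensityEstimate:
    """Gaussian KDE with fixed kernel SD, evaluated on ``grid``."""
    x = np.asarray(rts, dtype=float)
    if x.size < MIN_RTS_PER_CONDITION:
        raise ValueError(
            f"need at least {MIN_RTS_PER_CONDITION} RTs, got {x.size}"
        )
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (
        x.size * bandwidth * np.sqrt(2 * np.pi)
    )
    return DensityEstimate(grid=grid, density=dens, bandwidth=bandwidth, n=x.size)


def crossing_point(
    d1: DensityEstimate,
    d2: DensityEstimate,
    lo: float | None = None,
    hi: float | None = None,
) -> float | None:
    """RT at which the two densities cross, or None if they never do.

    Sign changes of d1 - d2 on the shared grid are refined by linear
    interpolation.  When ``lo``/``hi`` bound the search (the interval between
    the two conditions' medians), only crossings inside are kept; among
    several candidates the one with the highest density is returned — the
    theoretically meaningful crossing sits between the mixture-component
    modes, where density is still substantial, while KDE-wiggle crossings
    live in the tails.
    """
    if d1.grid.shape != d2.grid.shape or not np.allclose(d1.grid, d2.grid):
        raise ValueError("densities must share a common grid")
    g = d1.grid
    diff = d1.density - d2.density
    s = np.sign(diff)
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    crossings = []
    for i in idx:
        frac = diff[i] / (diff[i] - diff[i + 1])
        x = g[i] + frac * (g[i + 1] - g[i])
        dens = d1.density[i] + frac * (d1.density[i + 1] - d1.density[i])
        crossings.append((x, dens))
    # exact grid-node zeros
    for i in np.nonzero(s == 0)[0]:
        crossings.append((g[i], d1.density[i]))
    if not crossings:
        return None
    if lo is not None and hi is not None:
        lo_, hi_ = min(lo, hi), max(lo, hi)
        inside = [c for c in crossings if lo_ <= c[0] <= hi_]
        if inside:
            crossings = inside
        else:
            # estimation noise can push the real crossing just past a median;
            # take the crossing nearest the interval rather than losing the
            # participant (max density would favour tail wiggles when the
            # true crossing sits in a deep inter-mode valley)
            nearest = min(
                crossings, key=lambda c: max(lo_ - c[0], c[0] - hi_, 0.0)
            )
            return float(nearest[0])
    return float(max(crossings, key=lambda c: c[1])[0])


def crossing_set(
    trials: pd.DataFrame,
    factor: str,
    rt_col: str = "rt_ms",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Per-participant pairwise crossing points for one factor.

    ``factor`` names a condition column with 3 levels (e.g. ``tp_code`` or
    ``tot_code``); RTs are pooled within condition regardless of the choice
    made.  Participants with fewer than 5 RTs in any condition are excluded
    with a reason.  Returns a tidy frame (subject, pair, crossing, reason).
    """
    df = trials.dropna(subset=[rt_col])
    if "session" in df.columns:
        df = df[df["session"] == "experimental"]
    levels = np.sort(df[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    rows = []
    for subj, sdf in df.groupby(subject_col):
        samples = {lv: sdf.loc[sdf[factor] == lv, rt_col].to_numpy() for lv in levels}
        small = [lv for lv in levels if samples[lv].size < MIN_RTS_PER_CONDITION]
        if small:
            for la, lb in combinations(levels, 2):
                rows.append((subj, f"{la}|{lb}", np.nan,
                             f"fewer than {MIN_RTS_PER_CONDITION} RTs in {small}"))
            continue
        pooled = sdf[rt_col].to_numpy()
        bw = pooled_bandwidth(pooled)
        grid = make_grid(pooled, bw)
        dens = {lv: estimate_density(samples[lv], bw, grid) for lv in levels}
        for la, lb in combinations(levels, 2):
            x = crossing_point(
                dens[la], dens[lb],
                lo=float(np.median(samples[la])),
                hi=float(np.median(samples[lb])),
            )
            if x is None:
                rows.append((subj, f"{la}|{lb}", np.nan, "no crossing"))
            else:
                rows.append((subj, f"{la}|{lb}", x, ""))
    return pd.DataFrame(rows, columns=["subject", "pair", "crossing", "reason"])


def _ols_loglik_bic(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    k = int(np.linalg.matrix_rank(X)) + 1  # + error variance
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return ll, -2.0 * ll + k * np.log(n)


def fixed_point_bayes_test(crossings: pd.DataFrame) -> FixedPointResult:
    """Step 3: Bayes factor for one common crossing population.

    One-way repeated-measures comparison of crossing RT across condition
    pairs: OLS models `crossing ~ subject` (null) vs `crossing ~ subject +
    pair` (effect); BF01 = exp((BIC_effect - BIC_null) / 2).  Participants
    with an incomplete crossing triple are excluded (and reported).
    """
    ok = crossings[np.isfinite(crossings["crossing"])]
    counts = ok.groupby("subject")["pair"].nunique()
    n_pairs = crossings["pair"].nunique()
    complete = counts[counts == n_pairs].index
    excluded = sorted(set(crossings["subject"]) - set(complete))
    ok = ok[ok["subject"].isin(complete)]
    if ok["subject"].nunique() < 2:
        raise ValueError(
            "fewer than 2 participants with complete crossing sets "
            f"(excluded: {excluded})"
        )
    y = ok["crossing"].to_numpy(dtype=float)
    subj = pd.get_dummies(ok["subject"]).to_numpy(dtype=float)
    paird = pd.get_dummies(ok["pair"], drop_first=True).to_numpy(dtype=float)
    _, bic_null = _ols_loglik_bic(y, subj)
    _, bic_eff = _ols_loglik_bic(y, np.column_stack([subj, paird]))
    bf01 = float(np.exp((bic_eff - bic_null) / 2.0))
    means = ok.groupby("pair")["crossing"].mean()
    ses = ok.groupby("pair")["crossing"].sem()
    return FixedPointResult(
        bf01=bf01,
        pair_means=means,
        pair_ses=ses,
        n_participants=int(ok["subject"].nunique()),
        excluded=excluded,
    )


def run_fixed_point(trials: pd.DataFrame, factor: str) -> tuple[FixedPointResult, pd.DataFrame]:
    """Crossing extraction + Bayes test for one factor column."""
    cs = crossing_set(trials, factor)
    return fixed_point_bayes_test(cs), cs
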