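"""Model-inversion stimulus design.

Given softmax-EU parameters and a target safe-choice probability, the choice
model is inverted analytically: fixing the safe lottery (P, a) and the target
p_s, the risky amount A satisfying p_safe(P, a, A) = p_s is

    U(A) = (P * U(a) - logit(p_s) / beta) / (1 - P),

with the sign-preserving power utility U.  Drawing (P, a) from a design grid
and solving for A yields stimulus sets whose *expected* safe-choice
probability is controlled exactly (70% in the safe-default group, 30% in the
risky-default group), before currency rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logit

from .lottery_model import LotteryPair, ModelParams, p_safe_arrays, utility

__all__ = [
    "StimulusSpec",
    "InfeasibleTargetError",
    "StimulusGenerationError",
    "solve_risky_amount",
    "generate_stimulus_set",
    "model_p_safe",
]

#: generating parameters: mean individual estimates from the preliminary study
PRELIMINARY_PARAMS = ModelParams(beta=4.38, u=0.56)

DEFAULT_P_GRID = (0.55, 0.60, 0.65, 0.70, 0.75, 0.80)


class InfeasibleTargetError(ValueError):
    """The requested target probability cannot be met for this (P, a)."""


class StimulusGenerationError(RuntimeError):
    """Rejection sampling exceeded the oversampling budget."""


@dataclass(frozen=True)
class StimulusSpec:
    """Configuration of one stimulus set.

    ``target_ps`` is the model-implied safe-choice probability every emitted
    pair attains (before rounding); ``jitter_sd`` > 0 jitters the per-trial
    target (Gaussian, truncated to (0.05, 0.95)) around ``target_ps``.
    Amounts are rounded to the currency quantum ``rounding`` (pass None to
    keep exact amounts); pairs with |A| <= |a| or |A| > amount_cap are
    rejected and resampled.
    """

    target_ps: float
    n_trials: int
    frame: str = "gain"
    P_grid: Sequence[float] = DEFAULT_P_GRID
    a_range: tuple[float, float] = (2.0, 10.0)
    params: ModelParams = PRELIMINARY_PARAMS
    rounding: float | None = 0.05
    jitter_sd: float = 0.0
    amount_cap: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_ps < 1.0:
            raise ValueError(f"target_ps must lie in (0,1), got {self.target_ps}")
        if self.frame not in ("gain", "loss"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if any(not 0.5 < p <= 0.8 for p in self.P_grid):
            raise ValueError("P_grid values must lie in (0.5, 0.8]")
        if not 0 < self.a_range[0] < self.a_range[1]:
            raise ValueError("a_range must be positive magnitudes, lo < hi")
        if self.rounding is not None and not self.rounding > 0:
            raise ValueError("rounding quantum must be positive (or None)")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


def solve_risky_amount(
    P: float, a: float, target_ps: float, params: ModelParams
) -> float:
    """Invert the choice model for the risky amount A.

    ``a`` is signed (negative in the loss frame); the returned A carries the
    same sign.  Raises InfeasibleTargetError when the required utility flips
    sign (no amount of the right sign can reach the target).
    """
    if not 0.0 < P < 1.0:
        raise ValueError(f"P must lie in (0,1), got {P}")
    if not 0.0 < target_ps < 1.0:
        raise ValueError(f"target_ps must lie in (0,1), got {target_ps}")
    if a == 0:
        raise ValueError("safe amount a must be nonzero")
    need = float(logit(target_ps)) / params.beta  # required dEU
    uA = (P * utility(a, params.u) - need) / (1.0 - P)
    if uA == 0 or np.sign(uA) != np.sign(a):
        raise InfeasibleTargetError(
            f"target p_s={target_ps} infeasible for P={P}, a={a}: "
            f"required risky utility {uA:.4g} has the wrong sign"
        )
    return float(np.sign(uA) * np.abs(uA) ** (1.0 / params.u))


def _round_to(x: float, quantum: float | None) -> float:
    if quantum is None:
        return x
    return round(round(x / quantum) * quantum, 10)


def generate_stimulus_set(spec: StimulusSpec, seed) -> list[LotteryPair]:
    """Rejection-sample ``spec.n_trials`` lottery pairs hitting the target.

    Deterministic under ``seed``.  Every emitted pair's model-implied p_safe
    equals its (possibly jittered) per-trial target exactly before rounding;
    with jitter_sd = 0 the set mean equals ``spec.target_ps`` exactly.
    """
    rng = np.random.default_rng(seed)
    sign = 1.0 if spec.frame == "gain" else -1.0
    pairs: list[LotteryPair] = []
    attempts = 0
    budget = 10 * spec.n_trials
    while len(pairs) < spec.n_trials:
        if attempts >= budget and len(pairs) < spec.n_trials:
            raise StimulusGenerationError(
                f"rejected too many draws ({attempts} attempts for "
                f"{len(pairs)}/{spec.n_trials} accepted): target "
                f"{spec.target_ps} is largely infeasible on P_grid="
                f"{tuple(spec.P_grid)}, a_range={spec.a_range}"
            )
        attempts += 1
        P = float(rng.choice(np.asarray(spec.P_grid)))
        a_mag = _round_to(float(rng.uniform(*spec.a_range)), spec.rounding)
        target = spec.target_ps
        if spec.jitter_sd > 0:
            while True:  # truncated Gaussian jitter
                target = spec.target_ps + spec.jitter_sd * rng.standard_normal()
                if 0.05 < target < 0.95:
                    break
        a = sign * a_mag
        try:
            A = solve_risky_amount(P, a, target, spec.params)
        except InfeasibleTargetError:
            continue
        A = _round_to(A, spec.rounding)
        if abs(A) <= abs(a) or abs(A) > spec.amount_cap:
            continue
        pairs.append(LotteryPair(P=P, a=a, A=A, frame=spec.frame))
    return pairs


def model_p_safe(pairs: Sequence[LotteryPair], params: ModelParams) -> np.ndarray:
    """Model-implied safe-choice probability of each pair."""
    P = np.array([p.P for p in pairs])
    a = np.array([p.a for p in pairs])
    A = np.array([p.A for p in pairs])
    return p_safe_arrays(P, a, A, params)
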