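"""Expected-utility/softmax model of binary lottery choice.

Each trial offers a *safe* lottery (amount ``a`` with probability ``P``)
against a *risky* lottery (larger amount ``A`` with probability ``1 - P``).
The probability of choosing the safe option is a logistic (softmax) function
of the expected-utility difference,

    p_safe = 1 / (1 + exp(-beta * dEU)),   dEU = P * U(a) - (1 - P) * U(A),

with a sign-preserving power utility ``U(x) = sign(x) * |x|**u``.  ``beta``
(inverse temperature) controls choice stochasticity and ``u`` (utility
curvature) risk attitude: u < 1 is risk-averse for gains and risk-seeking for
losses.  Parameters are estimated per subject by MAP under independent
Gaussian priors, with a Laplace (Gaussian) approximation to the posterior.

Choices are coded 1 = safe, 0 = risky throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.special import expit, log_expit, logit

__all__ = [
    "LotteryPair",
    "ModelParams",
    "PriorSpec",
    "FitResult",
    "utility",
    "delta_eu",
    "delta_eu_arrays",
    "p_safe",
    "p_safe_arrays",
    "log_likelihood",
    "simulate_choices",
    "fit_map",
    "fit_map_arrays",
]

#: project-wide choice coding
SAFE, RISKY = 1, 0


@dataclass(frozen=True)
class LotteryPair:
    """One binary choice problem: safe (P, a) vs risky (1-P, A).

    Gain frame: both amounts positive; loss frame: both negative.  The risky
    amount always carries the larger magnitude and the safe probability lies
    in the middle range (0.5, 0.8].
    """

    P: float
    a: float
    A: float
    frame: str = "gain"

    def __post_init__(self) -> None:
        if not 0.5 < self.P <= 0.8:
            raise ValueError(
                f"invariant violated: safe probability P={self.P} outside (0.5, 0.8]"
            )
        if self.frame not in ("gain", "loss"):
            raise ValueError(f"invariant violated: unknown frame {self.frame!r}")
        if self.a == 0 or self.A == 0:
            raise ValueError("invariant violated: amounts must be nonzero")
        if np.sign(self.a) != np.sign(self.A):
            raise ValueError(
                f"invariant violated: sign(a)={np.sign(self.a)} != sign(A)={np.sign(self.A)}"
            )
        if self.frame == "gain" and self.a < 0:
            raise ValueError("invariant violated: gain frame requires positive amounts")
        if self.frame == "loss" and self.a > 0:
            raise ValueError("invariant violated: loss frame requires negative amounts")
        if abs(self.A) <= abs(self.a):
            raise ValueError(
                f"invariant violated: |A|={abs(self.A)} must exceed |a|={abs(self.a)}"
            )


@dataclass(frozen=True)
class ModelParams:
    """Softmax-EU parameters: inverse temperature and utility curvature."""

    beta: float
    u: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.u > 0:
            raise ValueError(f"u must be > 0, got {self.u}")


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors on (beta, u); defaults are wide/unbiased."""

    beta_mean: float = 3.0
    beta_sd: float = 10.0
    u_mean: float = 1.0
    u_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.beta_sd <= 0 or self.u_sd <= 0:
            raise ValueError("prior SDs must be positive")


@dataclass
class FitResult:
    """MAP fit with Laplace-approximate posterior covariance."""

    params: ModelParams
    laplace_cov: np.ndarray | None
    loglik: float
    n_trials: int


def utility(amount, u: float):
    """Sign-preserving power utility ``sign(x) * |x|**u``.

    Works elementwise on arrays.  Raises for non-positive curvature or zero
    amounts (utility of 'nothing' is never evaluated in this task).
    """
    if not u > 0:
        raise ValueError(f"utility curvature u must be > 0, got {u}")
    x = np.asarray(amount, dtype=float)
    if np.any(x == 0):
        raise ValueError("amount must be nonzero")
    out = np.sign(x) * np.abs(x) ** u
    return out if out.ndim else float(out)


def delta_eu_arrays(P, a, A, u: float):
    """dEU = P*U(a) - (1-P)*U(A), vectorised over trial attribute arrays."""
    P = np.asarray(P, dtype=float)
    return P * utility(a, u) - (1.0 - P) * utility(A, u)


def delta_eu(pair: LotteryPair, params: ModelParams) -> float:
    """Expected-utility difference (safe minus risky) for one lottery pair."""
    return float(delta_eu_arrays(pair.P, pair.a, pair.A, params.u))


def p_safe_arrays(P, a, A, params: ModelParams):
    """Softmax probability of the safe choice, vectorised and overflow-safe.

    Clipped into the open unit interval so downstream logs never see 0 or 1.
    """
    p = expit(params.beta * delta_eu_arrays(P, a, A, params.u))
    return np.clip(p, 1e-308, 1.0 - 1e-16)


def p_safe(pair: LotteryPair, params: ModelParams) -> float:
    """Probability of choosing the safe lottery (Eq. softmax on dEU)."""
    return float(p_safe_arrays(pair.P, pair.a, pair.A, params))


def _trials_to_arrays(
    trials: Sequence[Tuple[LotteryPair, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if len(trials) == 0:
        raise ValueError("empty trial sequence")
    P = np.array([t[0].P for t in trials])
    a = np.array([t[0].a for t in trials])
    A = np.array([t[0].A for t in trials])
    y = np.array([t[1] for t in trials], dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("choices must be coded 1 (safe) or 0 (risky)")
    return P, a, A, y


def _loglik_arrays(P, a, A, y, beta: float, u: float) -> float:
    z = beta * delta_eu_arrays(P, a, A, u)
    # log p_safe for safe choices, log(1 - p_safe) for risky; stable form
    return float(np.sum(y * log_expit(z) + (1.0 - y) * log_expit(-z)))


def log_likelihood(
    trials: Sequence[Tuple[LotteryPair, int]], params: ModelParams
) -> float:
    """Bernoulli log-likelihood of coded choices under the softmax-EU model."""
    P, a, A, y = _trials_to_arrays(trials)
    return _loglik_arrays(P, a, A, y, params.beta, params.u)


def simulate_choices(pairs: Iterable[LotteryPair], params: ModelParams, rng) -> np.ndarray:
    """Draw one coded choice (1 safe / 0 risky) per pair from the model."""
    pairs = list(pairs)
    P = np.array([p.P for p in pairs])
    a = np.array([p.a for p in pairs])
    A = np.array([p.A for p in pairs])
    ps = p_safe_arrays(P, a, A, params)
    return (rng.random(len(pairs)) < ps).astype(int)


# ---------------------------------------------------------------------------
# MAP estimation
# ---------------------------------------------------------------------------

# fixed multi-start grid (deterministic fits)
_BETA_STARTS = (0.5, 1.5, 3.0, 6.0, 12.0)
_U_STARTS = (0.2, 0.45, 0.7, 1.0, 1.5)
_BOUNDS = ((1e-3, 50.0), (0.05, 5.0))


class FitError(RuntimeError):
    """Raised when MAP optimisation fails on every restart; carries the best
    point found so far in ``best``."""

    def __init__(self, msg: str, best=None):
        super().__init__(msg)
        self.best = best


def _neg_log_joint_and_grad(x, P, a, A, y, prior: PriorSpec):
    beta, u = x
    ua = utility(a, u)
    uA = utility(A, u)
    deu = P * ua - (1.0 - P) * uA
    z = beta * deu
    ll = np.sum(y * log_expit(z) + (1.0 - y) * log_expit(-z))
    lp = -0.5 * ((beta - prior.beta_mean) / prior.beta_sd) ** 2
    lp += -0.5 * ((u - prior.u_mean) / prior.u_sd) ** 2
    resid = y - expit(z)  # d loglik / dz
    # d U(x)/du = sign(x)|x|^u log|x| = U(x) * log|x|
    ddeu_du = P * ua * np.log(np.abs(a)) - (1.0 - P) * uA * np.log(np.abs(A))
    g_beta = np.sum(resid * deu) - (beta - prior.beta_mean) / prior.beta_sd**2
    g_u = beta * np.sum(resid * ddeu_du) - (u - prior.u_mean) / prior.u_sd**2
    return -(ll + lp), -np.array([g_beta, g_u])


def fit_map_arrays(P, a, A, y, prior: PriorSpec = PriorSpec()) -> FitResult:
    """MAP fit of (beta, u) from trial attribute/choice arrays.

    Deterministic multi-start L-BFGS-B over a fixed 5x5 grid; the posterior
    covariance is the inverse Hessian (finite differences of the analytic
    gradient) at the mode, or None when the Hessian is not positive definite.
    """
    P, a, A, y = (np.asarray(v, dtype=float) for v in (P, a, A, y))
    if P.size == 0:
        raise ValueError("empty trial sequence")
    args = (P, a, A, y, prior)
    best = None
    for b0 in _BETA_STARTS:
        for u0 in _U_STARTS:
            res = optimize.minimize(
                _neg_log_joint_and_grad,
                x0=np.array([b0, u0]),
                args=args,
                jac=True,
                method="L-BFGS-B",
                bounds=_BOUNDS,
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
    if best is None:
        raise FitError("MAP optimisation failed on all 25 restarts", best=None)

    mode = best.x
    # numerical Hessian of the negative log joint via central differences of
    # the analytic gradient
    h = 1e-5 * np.maximum(np.abs(mode), 1.0)
    H = np.zeros((2, 2))
    for j in range(2):
        xp, xm = mode.copy(), mode.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        _, gp = _neg_log_joint_and_grad(xp, *args)
        _, gm = _neg_log_joint_and_grad(xm, *args)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    cov: np.ndarray | None
    try:
        eigs = np.linalg.eigvalsh(H)
        cov = np.linalg.inv(H) if np.all(eigs > 0) else None
    except np.linalg.LinAlgError:
        cov = None
    return FitResult(
        params=ModelParams(beta=float(mode[0]), u=float(mode[1])),
        laplace_cov=cov,
        loglik=float(-best.fun),
        n_trials=int(P.size),
    )


def fit_map(
    trials: Sequence[Tuple[LotteryPair, int]], prior: PriorSpec = PriorSpec()
) -> FitResult:
    """MAP fit of (beta, u) from a sequence of (LotteryPair, coded choice)."""
    P, a, A, y = _trials_to_arrays(trials)
    return fit_map_arrays(P, a, A, y, prior)
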