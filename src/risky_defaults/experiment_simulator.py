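"""Synthetic two-session lottery experiment under competing default hypotheses.

The design mirrors the study: a self-paced priming session (72 trials) that
establishes each group's dominant choice, followed by an experimental session
of 18 blocks x 18 trials in which time pressure (TP: low/medium/high, coded
-1/0/+1) is crossed orthogonally with time on task (ToT: beginning/middle/
end, coded -1/0/+1) — every ToT stage contains 2 blocks of every TP level,
with TP order counterbalanced across subjects by Latin-square rotation.
Choice proportion (CP) is manipulated between subjects by the stimulus sets
(safe-default group: 70% safe target; risky-default group: 30%).

Four generative hypotheses are implemented:

``none``
    pure softmax-EU choice; no default mechanism.
``natural``
    time pressure biases choice toward the frame's natural option (safe in
    gains, risky in losses): an additive term on the softmax input.
``dominant``
    time pressure amplifies repetition of the subject's own running-majority
    option, whatever it is.
``learned``
    a dual-process mixture: with probability m(ToT) = clip(m0 + m1*ToT, 0, 1)
    the trial is executed by a fast *default* process that emits the
    running-majority option; otherwise the *deliberative* softmax process
    decides.  TP never changes m.

RTs are drawn from shifted lognormals, one per process; the deliberative
meanlog decreases with TP (the manipulation check).  Under ``learned`` the
RT distribution at each ToT stage is, by construction, a binary mixture of
the two process distributions — ground truth for fixed-point tests.  Under
the single-process scenarios TP shifts the one distribution instead, so no
fixed point should arise across TP conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .lottery_model import LotteryPair, ModelParams, delta_eu_arrays
from .stimulus_generator import (
    PRELIMINARY_PARAMS,
    StimulusSpec,
    generate_stimulus_set,
)

__all__ = [
    "DesignSpec",
    "RTProcess",
    "ScenarioSpec",
    "DesignError",
    "build_design",
    "simulate_choice",
    "simulate_rt",
    "build_group_stimuli",
    "simulate_experiment",
]

GROUPS = ("safe_default", "risky_default")
GROUP_TARGETS = {"safe_default": 0.70, "risky_default": 0.30}

_LATIN_ROWS = ((-1, 0, 1), (0, 1, -1), (1, -1, 0))


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """Session structure; defaults reproduce the study's design."""

    n_subjects: int = 18  # per group
    frame: str = "gain"
    priming_trials: int = 72
    n_blocks: int = 18
    trials_per_block: int = 18
    tp_levels: tuple[int, ...] = (-1, 0, 1)
    tot_stages: tuple[int, ...] = (-1, 0, 1)

    def __post_init__(self) -> None:
        cells = len(self.tp_levels) * len(self.tot_stages)
        if self.n_blocks % cells != 0:
            raise DesignError(
                f"n_blocks={self.n_blocks} not divisible by "
                f"{len(self.tp_levels)} TP levels x {len(self.tot_stages)} stages"
            )
        if self.frame not in ("gain", "loss"):
            raise DesignError(f"unknown frame {self.frame!r}")
        if self.n_subjects < 1 or self.priming_trials < 0:
            raise DesignError("n_subjects must be >= 1 and priming_trials >= 0")

    @property
    def experimental_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def trials_per_subject(self) -> int:
        return self.priming_trials + self.experimental_trials


@dataclass(frozen=True)
class RTProcess:
    """Shifted-lognormal RT process: rt = shift + LogNormal(meanlog, sdlog),
    with meanlog reduced by tp_meanlog_slope per unit of TP code."""

    shift: float
    meanlog: float
    sdlog: float
    tp_meanlog_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("RT shift must be >= 0 ms")
        if self.sdlog <= 0:
            raise ValueError("sdlog must be > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative hypothesis and its effect/RT parameters."""

    hypothesis: str = "none"
    base_params: ModelParams = PRELIMINARY_PARAMS
    natural_bias: float = 0.5
    dominant_bias: float = 0.5
    m0: float = 0.2
    m1: float = 0.2
    rt_deliberative: RTProcess = RTProcess(
        shift=200.0, meanlog=6.6, sdlog=0.5, tp_meanlog_slope=0.25
    )
    rt_default: RTProcess = RTProcess(shift=150.0, meanlog=5.9, sdlog=0.35)

    def __post_init__(self) -> None:
        if self.hypothesis not in ("none", "natural", "dominant", "learned"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")

    def mixture_weight(self, tot_code: int) -> float:
        """Probability that the default process executes the trial."""
        return float(np.clip(self.m0 + self.m1 * tot_code, 0.0, 1.0))


class _History:
    """Running tally of a subject's own safe/risky choices."""

    __slots__ = ("n_safe", "n_total")

    def __init__(self) -> None:
        self.n_safe = 0
        self.n_total = 0

    def majority(self) -> int | None:
        """1 if safe is the running majority, 0 if risky, None if tied/empty."""
        if self.n_total == 0 or 2 * self.n_safe == self.n_total:
            return None
        return 1 if 2 * self.n_safe > self.n_total else 0

    def update(self, choice: int) -> None:
        self.n_safe += choice
        self.n_total += 1


def build_design(spec: DesignSpec, seed=None) -> pd.DataFrame:
    """Block schedule for every subject of one group.

    Returns a tidy frame (subject, block, tp_code, tot_code).  TP order is
    counterbalanced across subjects by rotating a Latin square within every
    stage; the 2-blocks-per-TP-per-stage balance holds for each subject.
    ``seed`` is accepted for interface symmetry (the schedule is
    deterministic).
    """
    n_stages = len(spec.tot_stages)
    bps = spec.n_blocks // n_stages  # blocks per stage
    reps = bps // len(spec.tp_levels)
    rows = []
    for s in range(spec.n_subjects):
        block = 0
        for g, tot in enumerate(spec.tot_stages):
            order = _LATIN_ROWS[(s + g) % 3]
            seq = [tp for tp in order for _ in range(reps)]
            for tp in seq:
                block += 1
                rows.append((s, block, tp, tot))
    return pd.DataFrame(rows, columns=["subject", "block", "tp_code", "tot_code"])


def _frame_sign(frame: str) -> float:
    # natural default: safe under gains, risky under losses
    return 1.0 if frame == "gain" else -1.0


def simulate_choice(
    pair: LotteryPair,
    tp_code: int,
    tot_code: int,
    history: _History,
    scenario: ScenarioSpec,
    rng,
) -> tuple[int, str]:
    """One trial's coded choice and the generating process label."""
    params = scenario.base_params
    z = params.beta * float(delta_eu_arrays(pair.P, pair.a, pair.A, params.u))
    hyp = scenario.hypothesis
    if hyp == "learned":
        maj = history.majority()
        if maj is not None and rng.random() < scenario.mixture_weight(tot_code):
            return maj, "default"
        return int(rng.random() < expit(z)), "deliberative"
    if hyp == "natural":
        z += scenario.natural_bias * tp_code * _frame_sign(pair.frame)
    elif hyp == "dominant":
        maj = history.majority()
        if maj is not None:
            direction = 1.0 if maj == 1 else -1.0
            z += scenario.dominant_bias * tp_code * direction
    return int(rng.random() < expit(z)), "deliberative"


def simulate_rt(generating_process: str, tp_code: int, scenario: ScenarioSpec, rng) -> float:
    """One trial's RT (ms) from the generating process's shifted lognormal."""
    proc = (
        scenario.rt_default
        if generating_process == "default"
        else scenario.rt_deliberative
    )
    meanlog = proc.meanlog - proc.tp_meanlog_slope * tp_code
    return float(proc.shift + rng.lognormal(meanlog, proc.sdlog))


def build_group_stimuli(
    design: DesignSpec,
    seed,
    params: ModelParams = PRELIMINARY_PARAMS,
    targets: dict[str, float] = GROUP_TARGETS,
) -> dict[str, list[LotteryPair]]:
    """One stimulus list per group, sized to priming + experimental trials."""
    out = {}
    for i, group in enumerate(GROUPS):
        spec = StimulusSpec(
            target_ps=targets[group],
            n_trials=design.trials_per_subject,
            frame=design.frame,
            params=params,
        )
        out[group] = generate_stimulus_set(spec, seed=[seed, i])
    return out


def simulate_experiment(
    design: DesignSpec,
    scenario: ScenarioSpec,
    stimuli: dict[str, Sequence[LotteryPair]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full synthetic experiment: both groups, both sessions, one trial table.

    Deterministic under ``seed`` (per-subject substreams).  Ground-truth
    ``generating_process`` is retained.  Stimulus lists must match the
    design's per-subject trial count.
    """
    if stimuli is None:
        stimuli = build_group_stimuli(design, seed=[seed, 10_007])
    for group in GROUPS:
        if len(stimuli[group]) != design.trials_per_subject:
            raise DesignError(
                f"stimulus set for {group} has {len(stimuli[group])} pairs, "
                f"design needs {design.trials_per_subject}"
            )
    schedule = build_design(design)
    by_subj = {s: g for s, g in schedule.groupby("subject")}
    frames = []
    subj_id = 0
    for gi, group in enumerate(GROUPS):
        pairs = list(stimuli[group])
        # per-trial (tp, tot) layout for the experimental session
        for s in range(design.n_subjects):
            rng = np.random.default_rng([seed, gi, s])
            rows = _simulate_subject(
                subj_id, group, design, scenario, pairs, by_subj[s], rng
            )
            frames.append(rows)
            subj_id += 1
    return pd.concat(frames, ignore_index=True)


def _simulate_subject(
    subj_id: int,
    group: str,
    design: DesignSpec,
    scenario: ScenarioSpec,
    pairs: Sequence[LotteryPair],
    schedule: pd.DataFrame,
    rng,
) -> pd.DataFrame:
    hist = _History()
    recs = []
    k = 0
    for t in range(design.priming_trials):
        pair = pairs[k]
        choice, proc = simulate_choice(pair, 0, -1, hist, scenario, rng)
        rt = simulate_rt(proc, 0, scenario, rng)
        hist.update(choice)
        recs.append(
            (subj_id, group, pair.frame, "priming", 0, t + 1, 0, -1,
             pair.P, pair.a, pair.A, choice, rt, proc)
        )
        k += 1
    for _, brow in schedule.iterrows():
        tp, tot, block = int(brow.tp_code), int(brow.tot_code), int(brow.block)
        for t in range(design.trials_per_block):
            pair = pairs[k]
            choice, proc = simulate_choice(pair, tp, tot, hist, scenario, rng)
            rt = simulate_rt(proc, tp, scenario, rng)
            hist.update(choice)
            recs.append(
                (subj_id, group, pair.frame, "experimental", block, t + 1,
                 tp, tot, pair.P, pair.a, pair.A, choice, rt, proc)
            )
            k += 1
    return pd.DataFrame(
        recs,
        columns=[
            "subject", "group", "frame", "session", "block", "trial",
            "tp_code", "tot_code", "P", "a", "A", "choice", "rt_ms",
            "generating_process",
        ],
    )
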