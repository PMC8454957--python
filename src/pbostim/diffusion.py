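"""EZ-diffusion estimation of two-choice behavioural performance.

The EZ-diffusion model inverts three summary statistics of a two-choice
task — proportion correct ``pc``, and the mean ``mrt`` and variance ``vrt``
of correct-response response times — into the three core parameters of a
Wiener diffusion process:

* drift rate ``v``      — rate of evidence accumulation (the ability measure),
* boundary separation ``a`` — response caution,
* non-decision time ``ter`` — encoding + motor time in seconds.

Drift rate is the performance currency of the whole package: a
stimulation block's drift rate divided by a held-out baseline drift rate
is the objective the optimizer maximizes.  A Monte-Carlo simulator of the
underlying Wiener first-passage process is provided as an independent
check of the closed-form estimator and as the noise engine of the
synthetic cohort generator.

Closed forms (scaling constant ``s``, conventionally 0.1)::

    L   = logit(pc)
    v   = sign(pc - 1/2) * s * [ L (pc^2 L - pc L + pc - 1/2) / vrt ]^(1/4)
    a   = s^2 L / v
    ter = mrt - (a / 2v) * (1 - e^(-va/s^2)) / (1 + e^(-va/s^2))

Edge cases: pc = 1 is replaced by 1 - 1/(2n) and pc = 0 by 1/(2n);
pc = 1/2 raises :class:`~pbostim.errors.DegenerateDriftError` because the
boundary separation is then undefined.  RT statistics use correct
responses only, the usual EZ convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDriftError,
    InvalidBaselineError,
    InvalidInputError,
    ProtocolError,
    ScoringError,
)

__all__ = [
    "TrialData",
    "SummaryStats",
    "DiffusionEstimates",
    "BaselineAbility",
    "summarize",
    "estimate_ez",
    "predicted_accuracy",
    "score_block",
    "fit_block",
    "split_baseline",
    "normalized_performance",
    "simulate_trials",
    "read_trials_csv",
    "write_trials_csv",
    "write_scores_csv",
]

#: Conventional EZ scaling constant for the within-trial noise.
DEFAULT_SCALING = 0.1

#: Number of trials in a full behavioural block.
BLOCK_TRIALS = 50

#: Number of trials in each half of the baseline split.
BASELINE_HALF = 25


@dataclass
class TrialData:
    """Trial-level log of one block: binary accuracy and RT in seconds."""

    subject_id: str
    block_id: str
    correct: np.ndarray
    rt: np.ndarray

    def __post_init__(self) -> None:
        self.correct = np.asarray(self.correct, dtype=int)
        self.rt = np.asarray(self.rt, dtype=float)
        if self.correct.shape != self.rt.shape or self.correct.ndim != 1:
            raise InvalidInputError("correct and rt must be 1-D and equal length")
        if not np.all((self.correct == 0) | (self.correct == 1)):
            raise InvalidInputError("correct must be binary 0/1")
        if not np.all(self.rt > 0):
            raise InvalidInputError("all response times must be positive")

    def __len__(self) -> int:
        return self.correct.size

    @property
    def n(self) -> int:
        return self.correct.size

    def subset(self, idx: Sequence[int], block_id: Optional[str] = None) -> "TrialData":
        idx = np.asarray(idx, dtype=int)
        return TrialData(
            subject_id=self.subject_id,
            block_id=block_id if block_id is not None else self.block_id,
            correct=self.correct[idx],
            rt=self.rt[idx],
        )


@dataclass(frozen=True)
class SummaryStats:
    """Edge-corrected EZ inputs: pc in (0, 1), vrt > 0 (s^2), mrt (s), n."""

    pc: float
    vrt: float
    mrt: float
    n: int


@dataclass(frozen=True)
class DiffusionEstimates:
    """EZ parameter estimates on the scale set by ``s``."""

    v: float
    a: float
    ter: float
    s: float = DEFAULT_SCALING


@dataclass
class BaselineAbility:
    """Per-subject personalization covariate derived from 25 baseline trials.

    ``p_raw`` is the drift rate of one random half of the 50-trial baseline
    block; the other half yields the normalization drift rate so the two are
    statistically independent given the subject.  ``p_unit`` is filled in by
    the design module's min-max normalization when the covariate enters the
    surrogate model.
    """

    p_raw: float
    split_seed: int
    p_unit: Optional[float] = None


def summarize(trials: TrialData) -> SummaryStats:
    """Compute edge-corrected EZ summary statistics for one block.

    RT mean and variance are taken over correct responses only.  A
    proportion correct of exactly 0 or 1 is pulled inside (0, 1) by half a
    trial: 1 -> 1 - 1/(2n), 0 -> 1/(2n).
    """
    n = trials.n
    if n < 2:
        raise InvalidInputError("need at least 2 trials to summarize a block")
    n_correct = int(trials.correct.sum())
    if n_correct < 2:
        raise ScoringError(
            f"block {trials.block_id!r}: {n_correct} correct responses; "
            "no RT distribution for correct responses"
        )
    pc = n_correct / n
    if pc >= 1.0:
        pc = 1.0 - 1.0 / (2 * n)
    elif pc <= 0.0:
        pc = 1.0 / (2 * n)
    rts = trials.rt[trials.correct == 1]
    mrt = float(np.mean(rts))
    vrt = float(np.var(rts, ddof=1))
    if vrt <= 0:
        raise InvalidInputError("variance of correct-response RTs must be positive")
    return SummaryStats(pc=float(pc), vrt=vrt, mrt=mrt, n=n)


def estimate_ez(stats: SummaryStats, s: float = DEFAULT_SCALING) -> DiffusionEstimates:
    """Invert the EZ closed forms for (v, a, ter).

    Raises
    ------
    DegenerateDriftError
        If ``pc`` equals 0.5: drift is forced to zero and the boundary
        separation is undefined.
    InvalidInputError
        For non-positive ``s`` or ``vrt``, or ``pc`` outside (0, 1).
    """
    if s <= 0:
        raise InvalidInputError("scaling constant s must be positive")
    if stats.vrt <= 0:
        raise InvalidInputError("vrt must be positive")
    pc = stats.pc
    if not 0.0 < pc < 1.0:
        raise InvalidInputError("pc must lie strictly inside (0, 1); apply edge correction")
    if pc == 0.5:
        raise DegenerateDriftError(
            "pc = 0.5 implies drift rate 0 and undefined boundary separation"
        )
    L = float(np.log(pc / (1.0 - pc)))
    inner = L * (L * pc**2 - L * pc + pc - 0.5) / stats.vrt
    v = float(np.sign(pc - 0.5)) * s * inner**0.25
    a = s**2 * L / v
    va = v * a / s**2
    y = np.exp(-va)
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    ter = stats.mrt - mdt
    return DiffusionEstimates(v=float(v), a=float(a), ter=float(ter), s=s)


def predicted_accuracy(v: float, a: float, s: float = DEFAULT_SCALING) -> float:
    """Proportion correct implied by (v, a) under the EZ model."""
    return float(1.0 / (1.0 + np.exp(-v * a / s**2)))


def fit_block(trials: TrialData, s: float = DEFAULT_SCALING) -> DiffusionEstimates:
    """Full EZ estimates for one block (summary + inversion)."""
    return estimate_ez(summarize(trials), s=s)


def score_block(trials: TrialData, s: float = DEFAULT_SCALING) -> float:
    """Drift rate of one block; the performance measure of the protocol."""
    return fit_block(trials, s=s).v


def split_baseline(trials: TrialData, seed: int) -> tuple[BaselineAbility, float]:
    """Randomly partition the 50 baseline trials into two 25-trial halves.

    One half yields the subject's baseline-ability drift rate (the
    personalization covariate ``p_raw``); the other yields the drift rate
    used to normalize stimulation-block scores.  Separate halves remove the
    dependency between the covariate and the objective.  The partition is a
    seeded uniform draw without replacement and is reproducible.
    """
    if trials.n != 2 * BASELINE_HALF:
        raise ProtocolError(
            f"baseline block must contain exactly {2 * BASELINE_HALF} trials, got {trials.n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(trials.n)
    half_a = trials.subset(np.sort(perm[:BASELINE_HALF]), block_id="baseline_p")
    half_b = trials.subset(np.sort(perm[BASELINE_HALF:]), block_id="baseline_norm")
    p_raw = score_block(half_a)
    v_base = score_block(half_b)
    return BaselineAbility(p_raw=p_raw, split_seed=int(seed)), v_base


def normalized_performance(v_stim: float, v_base: float) -> float:
    """Normalized performance score: stimulation drift over baseline drift.

    A score of 1 means no change from baseline; > 1 means improvement.
    """
    if v_base <= 0:
        raise InvalidBaselineError(f"baseline drift must be positive, got {v_base}")
    return float(v_stim) / float(v_base)


def simulate_trials(
    v: float,
    a: float,
    ter: float,
    s: float = DEFAULT_SCALING,
    n: int = BLOCK_TRIALS,
    seed: int = 0,
    dt: float = 1e-3,
    subject_id: str = "sim",
    block_id: str = "sim",
    max_time: float = 60.0,
) -> TrialData:
    """Simulate first-passage trials of a Wiener process with drift.

    Evidence starts at ``a / 2`` and diffuses with drift ``v`` and
    infinitesimal SD ``s`` between absorbing boundaries at 0 (error) and
    ``a`` (correct).  Euler steps of length ``dt`` (default 1 ms) are
    corrected for within-step boundary crossings with the standard
    Brownian-bridge crossing probability, which removes the leading
    O(sqrt(dt)) discretization bias, so observed accuracy and RT moments
    converge to the EZ closed forms as ``n`` grows.
    """
    if a <= 0:
        raise InvalidInputError("boundary separation a must be positive")
    if n < 1:
        raise InvalidInputError("need at least one trial")
    if dt <= 0:
        raise InvalidInputError("Euler step dt must be positive")
    if s <= 0:
        raise InvalidInputError("scaling constant s must be positive")
    rng = np.random.default_rng(seed)
    x = np.full(n, a / 2.0)
    alive = np.arange(n)
    correct = np.zeros(n, dtype=int)
    decision_t = np.full(n, np.nan)
    sig = s * np.sqrt(dt)
    inv = 1.0 / (s**2 * dt)
    t = 0.0
    while alive.size:
        t += dt
        x0 = x[alive]
        x1 = x0 + v * dt + sig * rng.standard_normal(alive.size)
        hit_up = x1 >= a
        hit_lo = x1 <= 0.0
        interior = ~(hit_up | hit_lo)
        if np.any(interior):
            # Brownian-bridge probability of an unseen excursion past either
            # boundary during the step.
            xi0, xi1 = x0[interior], x1[interior]
            p_up = np.exp(-2.0 * (a - xi0) * (a - xi1) * inv)
            p_lo = np.exp(-2.0 * xi0 * xi1 * inv)
            u = rng.random((2, xi0.size))
            bridge_up = u[0] < p_up
            bridge_lo = (~bridge_up) & (u[1] < p_lo)
            hit_up[interior] |= bridge_up
            hit_lo[interior] |= bridge_lo
        done = hit_up | hit_lo
        if t >= max_time:
            # vanishing-probability guard: force absorption by current side
            done = np.ones_like(done)
            hit_up = x1 >= a / 2.0
        if np.any(done):
            idx = alive[done]
            correct[idx] = hit_up[done].astype(int)
            decision_t[idx] = t
            alive = alive[~done]
            x1 = x1[~done]
        x[alive] = x1
    rt = ter + decision_t
    return TrialData(subject_id=subject_id, block_id=block_id, correct=correct, rt=rt)


# ---------------------------------------------------------------------------
# Trial CSV dialect: subject_id,block_id,trial,correct,rt_seconds

def read_trials_csv(path) -> list[TrialData]:
    """Read a trial-level CSV into one TrialData per (subject, block)."""
    df = pd.read_csv(path)
    required = {"subject_id", "block_id", "trial", "correct", "rt_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"trial CSV missing columns: {sorted(missing)}")
    blocks = []
    for (sid, bid), grp in df.groupby(["subject_id", "block_id"], sort=False):
        grp = grp.sort_values("trial")
        blocks.append(
            TrialData(
                subject_id=str(sid),
                block_id=str(bid),
                correct=grp["correct"].to_numpy(),
                rt=grp["rt_seconds"].to_numpy(),
            )
        )
    return blocks


def write_trials_csv(blocks: Sequence[TrialData], path) -> None:
    frames = []
    for b in blocks:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": b.subject_id,
                    "block_id": b.block_id,
                    "trial": np.arange(b.n),
                    "correct": b.correct,
                    "rt_seconds": np.round(b.rt, 6),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def write_scores_csv(rows: Sequence[dict], path) -> None:
    """Write per-block scores: subject_id,block_id,v,a,ter,score."""
    cols = ["subject_id", "block_id", "v", "a", "ter", "score"]
    pd.DataFrame(list(rows), columns=cols).to_csv(path, index=False)
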