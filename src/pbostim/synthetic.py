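"""Synthetic cohorts and ground-truth response surfaces.

Nothing in this package requires real participant data: this module
generates (a) baseline-dependent response surfaces with a known optimum
path, and (b) cohorts of simulated subjects whose behaviour is produced
by the same diffusion process the estimator assumes.  Both are first-class
study objects — the protocol, cross-validation and recovery analyses all
run against them.

The surface emulates the qualitative structure the personalized model is
designed to exploit: a smooth Gaussian bump in (frequency, current) whose
peak location moves monotonically from high frequency / high current at
low baseline ability toward low frequency / low current at high baseline
ability.  Expected scores sit in a plausible normalized-performance range
(roughly 0.85-1.85 before estimation noise, within the 0.5-3.8 span that
finite-trial drift-rate ratios produce).

Baseline abilities are drawn from a Beta(2, 5) distribution rescaled to
the configured drift-rate bounds (default [0, 0.2]), giving the
low-ability skew typical of such cohorts with a mean near 0.057.

Score noise can enter two ways: through finite-trial diffusion estimation
(the full pipeline; ``sample_subject``) or as additive Gaussian noise on
the surface value (a fast path for protocol-level analyses where the
behavioural layer is not under study).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import diffusion
from .design import (
    DEFAULT_BASELINE_BOUNDS,
    SearchSpace,
    StimulationParameters,
    normalize_p,
    normalize_params,
)
from .diffusion import BaselineAbility, TrialData
from .errors import InvalidInputError

__all__ = [
    "SurfaceConfig",
    "ResponseSurface",
    "CohortConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "make_surface",
    "sample_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class SurfaceConfig:
    """Shape of the ground-truth normalized-performance surface.

    The bump centre moves linearly in unit coordinates from
    ``center_low_ability`` at p = 0 to ``center_high_ability`` at p = 1.
    ``jitter`` is the half-width of the seeded uniform perturbation applied
    to the endpoints so distinct seeds give distinct but structurally
    identical surfaces.
    """

    base: float = 0.85
    amplitude: float = 1.0
    width: float = 0.3
    center_low_ability: tuple[float, float] = (0.8, 0.8)
    center_high_ability: tuple[float, float] = (0.2, 0.2)
    jitter: float = 0.05
    noise_sd: float = 0.15


@dataclass(frozen=True)
class ResponseSurface:
    """Deterministic map (x, p) -> expected normalized score, with known optimum."""

    base: float
    amplitude: float
    width: float
    center_low: np.ndarray
    center_high: np.ndarray
    noise_sd: float
    seed: int

    def center(self, p: float) -> np.ndarray:
        """Bump centre at unit baseline p; also the exact optimum path x*(p)."""
        return self.center_low + np.clip(p, 0.0, 1.0) * (self.center_high - self.center_low)

    def optimum_x(self, p: float) -> np.ndarray:
        return np.clip(self.center(p), 0.0, 1.0)

    def value(self, x, p) -> np.ndarray | float:
        """Expected normalized performance at unit coordinates (x, p)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        P = np.broadcast_to(np.asarray(p, dtype=float).ravel(), (X.shape[0],))
        C = self.center_low[None, :] + np.clip(P, 0, 1)[:, None] * (
            self.center_high - self.center_low
        )[None, :]
        d2 = np.sum((X - C) ** 2, axis=1)
        out = self.base + self.amplitude * np.exp(-d2 / (2.0 * self.width**2))
        return float(out[0]) if single and np.asarray(p).size == 1 else out


def make_surface(seed: int = 0, config: SurfaceConfig = SurfaceConfig()) -> ResponseSurface:
    """Build a seeded surface; the optimum path is recorded exactly."""
    rng = np.random.default_rng(seed)
    j = config.jitter
    lo = np.asarray(config.center_low_ability) + rng.uniform(-j, j, 2)
    hi = np.asarray(config.center_high_ability) + rng.uniform(-j, j, 2)
    width = config.width * (1.0 + rng.uniform(-0.1, 0.1))
    return ResponseSurface(
        base=config.base,
        amplitude=config.amplitude,
        width=float(width),
        center_low=np.clip(lo, 0.05, 0.95),
        center_high=np.clip(hi, 0.05, 0.95),
        noise_sd=config.noise_sd,
        seed=int(seed),
    )


# -- cohort -----------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for a synthetic cohort.

    Baseline abilities (true drift rates) follow Beta(beta_a, beta_b)
    rescaled to ``baseline_bounds``.  Subjects whose 25-trial baseline
    halves fail to yield positive drift estimates are regenerated with a
    fresh seed (bounded retries), mirroring the screening out of
    chance-level participants.
    """

    baseline_bounds: tuple[float, float] = DEFAULT_BASELINE_BOUNDS
    beta_a: float = 2.0
    beta_b: float = 5.0
    boundary_separation: float = 0.3
    non_decision_time: float = 0.35
    scaling: float = 0.1
    baseline_trials: int = 50
    max_retries: int = 30


@dataclass
class SyntheticSubject:
    subject_id: str
    p_true: float  # latent baseline drift rate
    baseline: TrialData
    ability: BaselineAbility  # estimated from one 25-trial half
    v_base: float  # estimated from the other half
    seed: int


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    config: CohortConfig
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def p_raw(self) -> np.ndarray:
        """Estimated baseline abilities across the cohort."""
        return np.array([s.ability.p_raw for s in self.subjects])


def sample_subject(
    surface: ResponseSurface,
    p_raw: float,
    params: StimulationParameters,
    n_trials: int = 50,
    seed: int = 0,
    v_base: Optional[float] = None,
    config: CohortConfig = CohortConfig(),
    space: SearchSpace = SearchSpace("optimization"),
) -> tuple[TrialData, float]:
    """Simulate one stimulation block and return its normalized score.

    The block's true drift rate is the surface value at (x, p) times the
    subject's baseline drift, so a surface value of 1 means no change from
    baseline.  Trials come from the diffusion simulator; the returned score
    is the estimated block drift divided by ``v_base`` (default: the true
    baseline drift), carrying realistic finite-trial estimation noise.
    """
    if not space.contains(params):
        raise InvalidInputError(f"{params} not on the {space.phase} grid")
    x = normalize_params(params)
    p_unit = normalize_p(p_raw, config.baseline_bounds)
    v_block = surface.value(np.asarray(x), p_unit) * p_raw
    trials = diffusion.simulate_trials(
        v=float(v_block),
        a=config.boundary_separation,
        ter=config.non_decision_time,
        s=config.scaling,
        n=n_trials,
        seed=seed,
        block_id="stim",
    )
    v_stim = diffusion.score_block(trials, s=config.scaling)
    score = diffusion.normalized_performance(v_stim, v_base if v_base is not None else p_raw)
    return trials, score


def _make_subject(
    subject_id: str, p_true: float, seed: int, config: CohortConfig
) -> SyntheticSubject:
    for attempt in range(config.max_retries):
        trial_seed = int(np.random.default_rng([seed, attempt]).integers(2**31 - 1))
        baseline = diffusion.simulate_trials(
            v=p_true,
            a=config.boundary_separation,
            ter=config.non_decision_time,
            s=config.scaling,
            n=config.baseline_trials,
            seed=trial_seed,
            subject_id=subject_id,
            block_id="baseline",
        )
        try:
            ability, v_base = diffusion.split_baseline(baseline, seed=trial_seed)
        except Exception:
            continue
        if ability.p_raw > 0 and v_base > 0:
            return SyntheticSubject(
                subject_id=subject_id,
                p_true=float(p_true),
                baseline=baseline,
                ability=ability,
                v_base=float(v_base),
                seed=trial_seed,
            )
    raise InvalidInputError(
        f"could not generate a positive-drift baseline for {subject_id} "
        f"(true drift {p_true:.4g}) in {config.max_retries} attempts"
    )


def generate_cohort(
    n: int = 50, seed: int = 0, config: CohortConfig = CohortConfig()
) -> SyntheticCohort:
    """Generate ``n`` subjects with low-skewed baseline abilities.

    Reproducible from the master seed; every subject carries 50 baseline
    trials, a split-derived ability estimate and a normalization drift.
    """
    if n < 1:
        raise InvalidInputError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = config.baseline_bounds
    p_true = lo + rng.beta(config.beta_a, config.beta_b, size=n) * (hi - lo)
    subjects = [
        _make_subject(f"S{i + 1:03d}", p_true[i], seed=int(rng.integers(2**31 - 1)), config=config)
        for i in range(n)
    ]
    return SyntheticCohort(subjects=subjects, config=config, seed=int(seed))
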