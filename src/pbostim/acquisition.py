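"""Acquisition functions and their exhaustive maximization over the grid.

Two closed-form criteria drive the selection of the next stimulation
setting from the Gaussian-process posterior (mu, sigma):

* expected improvement (EI) over the incumbent f+, the best included
  observation so far (standardized scale)::

      z  = (mu - f+) / sigma
      EI = (mu - f+) * Phi(z) + sigma * phi(z),     EI = 0 when sigma = 0

* GP upper confidence bound::

      UCB = mu + kappa * sigma

Because the deliverable is a discrete hardware setting, the acquisition
is maximized exhaustively over the (at most 782-point) stimulation grid
at the querying subject's fixed baseline value; ties are broken by a
seeded uniform choice among the maximizers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import design
from .design import SearchSpace, StimulationParameters
from .errors import ConfigurationError, InvalidInputError
from .pgp import PersonalizedGP

__all__ = [
    "AcquisitionSpec",
    "expected_improvement",
    "ucb",
    "srinivas_kappa",
    "argmax_over_grid",
    "argmax_candidates",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Which criterion to use: EI (default, no free parameter) or UCB."""

    kind: str = "ei"
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("ei", "ucb"):
            raise ConfigurationError(f"unknown acquisition kind {self.kind!r}")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be non-negative")


def expected_improvement(mu, sigma, f_plus: float) -> np.ndarray | float:
    """Closed-form EI; defined as 0 wherever sigma = 0."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise InvalidInputError("sigma must be non-negative")
    pos = sigma > 0
    # z may overflow to +/-inf for denormal sigma; Phi/phi handle the limit
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(pos, (mu - f_plus) / np.where(pos, sigma, 1.0), 0.0)
    ei = (mu - f_plus) * norm.cdf(z) + sigma * norm.pdf(z)
    out = np.where(pos, ei, 0.0)
    return out if out.ndim else float(out)


def ucb(mu, sigma, kappa: float) -> np.ndarray | float:
    """GP upper confidence bound mu + kappa * sigma."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise InvalidInputError("sigma must be non-negative")
    if kappa < 0:
        raise InvalidInputError("kappa must be non-negative")
    out = mu + kappa * sigma
    return out if out.ndim else float(out)


def srinivas_kappa(t: int, d: int = 3, delta: float = 0.1) -> float:
    """Theoretically-motivated UCB exploration weight sqrt(beta_t).

    beta_t = 2 log(d t^2 pi^2 / (6 delta)) for iteration t >= 1 over a
    finite candidate set of dimension d.
    """
    if t < 1:
        raise InvalidInputError("iteration index t must be >= 1")
    return float(np.sqrt(2.0 * np.log(d * t**2 * np.pi**2 / (6.0 * delta))))


def _acquisition_values(
    model: PersonalizedGP, Zq: np.ndarray, spec: AcquisitionSpec
) -> np.ndarray:
    mu, var = model.predict(Zq)
    sigma = np.sqrt(var)
    if spec.kind == "ei":
        return np.asarray(expected_improvement(mu, sigma, model.best_observed()))
    return np.asarray(ucb(mu, sigma, spec.kappa))


def argmax_candidates(values: np.ndarray, seed: int, rtol: float = 1e-12) -> tuple[int, np.ndarray]:
    """Index of a maximizer with seeded uniform tie-breaking.

    Candidates within ``rtol * max(1, |best|)`` of the best value count as
    tied.  Returns the chosen index and all tied indices.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ConfigurationError("empty candidate grid")
    best = np.max(values)
    ties = np.flatnonzero(values >= best - rtol * max(1.0, abs(best)))
    rng = np.random.default_rng(seed)
    return int(rng.choice(ties)), ties


def argmax_over_grid(
    model: PersonalizedGP,
    p: float,
    space: SearchSpace,
    spec: AcquisitionSpec = AcquisitionSpec(),
    seed: int = 0,
) -> StimulationParameters:
    """Exhaustive acquisition maximization at a fixed baseline value ``p``.

    Evaluates the acquisition at every grid member with the query's unit
    baseline coordinate held at ``p`` (ignored for a non-personalized
    model) and returns a maximizer, ties broken by a seeded uniform draw.
    """
    if not model.fitted:
        raise InvalidInputError("model is not fitted")
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError("p must lie in [0, 1]")
    grid = space.grid()
    X = design.grid_unit_coordinates(space)
    if model.personalized:
        Zq = np.column_stack([X, np.full(len(grid), p)])
    else:
        Zq = X
    values = _acquisition_values(model, Zq, spec)
    idx, _ = argmax_candidates(values, seed=seed)
    return grid[idx]
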