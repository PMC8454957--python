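"""Hartmann-3D simulation benchmark: pBO vs standard BO vs random search.

The three-dimensional Hartmann function stands in for the real experiment:
its first two coordinates play the role of the controllable stimulation
parameters and the third the uncontrollable per-iteration baseline value.
The function is negated so the task is maximization (global maximum
~3.8628 at ~(0.1146, 0.5556, 0.8525)); observations carry additive
Gaussian noise with variance sigma_n^2.

Per repeat, a fresh sequence of baseline values p_t ~ U[0,1] is drawn and
shared across algorithms (paired comparison).  pBO models (x1, x2, p) and
maximizes EI over x at the current p_t; standard BO models (x1, x2) only;
random search draws x uniformly.  Both model-based algorithms share a
random initial design inside the iteration budget and refit their
hyperparameters every iteration thereafter.

Two metrics are recorded each iteration:

* best-found value — the noise-free objective at the best point queried so
  far (true progress, not the noisy observation);
* distance to optimum — Euclidean distance in the unit 3-cube between the
  algorithm's identified optimum and the true maximizer.  For the GP
  algorithms the identified optimum is the posterior-mean argmax over a
  dense lattice ((x, p) for pBO; x for BO, paired with the true optimum's
  p-coordinate since BO cannot infer it).  Random search never narrows
  its query distribution and so has no estimator: its "identified
  optimum" is its current query, making its distance trace the accuracy
  of uninformed sampling itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd

from .acquisition import expected_improvement
from .errors import ConfigurationError, InvalidInputError
from .pgp import PersonalizedGP

__all__ = [
    "BenchmarkConfig",
    "BenchmarkResult",
    "hartmann3",
    "HARTMANN3_OPTIMUM",
    "HARTMANN3_MAX",
    "run_comparison",
    "summarize",
    "plot_traces",
]

_A = np.array(
    [[3.0, 10.0, 30.0], [0.1, 10.0, 35.0], [3.0, 10.0, 30.0], [0.1, 10.0, 35.0]]
)
_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_P = 1e-4 * np.array(
    [
        [3689.0, 1170.0, 2673.0],
        [4699.0, 4387.0, 7470.0],
        [1091.0, 8732.0, 5547.0],
        [381.0, 5743.0, 8828.0],
    ]
)

#: Maximizer of the negated Hartmann-3 function in the unit cube.
HARTMANN3_OPTIMUM = np.array([0.114590, 0.555649, 0.852547])
#: Maximum value of the negated Hartmann-3 function.
HARTMANN3_MAX = 3.8627798


def hartmann3(u) -> np.ndarray | float:
    """Negated Hartmann-3 function on the unit cube (maximization convention)."""
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    U = np.atleast_2d(u)
    if U.shape[1] != 3:
        raise InvalidInputError("hartmann3 expects points in [0,1]^3")
    if np.any(U < 0) or np.any(U > 1):
        raise InvalidInputError("hartmann3 input outside the unit cube")
    # sum_i alpha_i exp(-sum_j A_ij (u_j - P_ij)^2)
    D = (U[:, None, :] - _P[None, :, :]) ** 2
    vals = np.sum(_ALPHA[None, :] * np.exp(-np.sum(_A[None, :, :] * D, axis=2)), axis=1)
    return float(vals[0]) if single else vals


@dataclass(frozen=True)
class BenchmarkConfig:
    """Simulation-study settings.

    The six default noise variances span zero through the magnitude of the
    signal itself, covering the noise range a behavioural experiment
    plausibly produces on the standardized scale.
    """

    iterations: int = 60
    repeats: int = 30
    noise_levels: tuple[float, ...] = (0.0, 0.01, 0.1, 0.5, 1.0, 2.0)
    algorithms: tuple[str, ...] = ("pbo", "bo", "random")
    seed: int = 0
    n_init: int = 10
    restarts: int = 3
    candidate_resolution: int = 50  # per-axis lattice for the EI argmax over x
    optimum_resolution: int = 50  # per-axis lattice for the identified optimum

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.repeats < 1:
            raise ConfigurationError("iterations and repeats must be >= 1")
        if any(s < 0 for s in self.noise_levels):
            raise ConfigurationError("noise variances must be non-negative")
        unknown = set(self.algorithms) - {"pbo", "bo", "random"}
        if unknown:
            raise ConfigurationError(f"unknown algorithms {sorted(unknown)}")
        if self.n_init < 2 or self.n_init >= self.iterations:
            raise ConfigurationError("n_init must lie in [2, iterations)")


@dataclass
class BenchmarkResult:
    """Raw per-(algorithm, noise, repeat, iteration) traces."""

    best_value: dict  # (alg, noise) -> array (repeats, iterations)
    distance: dict  # (alg, noise) -> array (repeats, iterations)
    config: BenchmarkConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (alg, noise), bv in self.best_value.items():
            dist = self.distance[(alg, noise)]
            for r in range(bv.shape[0]):
                for t in range(bv.shape[1]):
                    rows.append(
                        {
                            "algorithm": alg,
                            "noise": noise,
                            "repeat": r,
                            "iteration": t,
                            "best_value": bv[r, t],
                            "distance": dist[r, t],
                        }
                    )
        return pd.DataFrame(rows)


def _x_lattice(res: int) -> np.ndarray:
    g = np.linspace(0.0, 1.0, res)
    return np.array(list(product(g, g)))


def _cube_lattice(res: int) -> np.ndarray:
    g = np.linspace(0.0, 1.0, res)
    return np.array(list(product(g, g, g)))


def _identified_optimum(
    model: Optional[PersonalizedGP],
    queried: np.ndarray,
    observed: np.ndarray,
    lattice: np.ndarray,
) -> np.ndarray:
    """3-D point the algorithm currently believes is best.

    Before a GP algorithm's initial design is complete, its belief is the
    queried point with the best noisy observation — the only information
    it has at that stage.
    """
    if model is None or not model.fitted:
        return queried[int(np.argmax(observed))]
    mu, _ = model.predict(lattice)
    u = lattice[int(np.argmax(mu))]
    if u.size == 2:  # standard BO: pair with the true optimum's p-coordinate
        return np.array([u[0], u[1], HARTMANN3_OPTIMUM[2]])
    return u


def _run_single(
    alg: str, noise: float, rep_rng: np.ndarray, config: BenchmarkConfig
) -> tuple[np.ndarray, np.ndarray]:
    """One repeat of one algorithm at one noise level; returns both traces."""
    T = config.iterations
    rng_p, rng_init, rng_noise, rng_alg = (
        np.random.default_rng([*rep_rng, k]) for k in range(4)
    )
    p_seq = rng_p.random(T)
    x_init = rng_init.random((config.n_init, 2))
    noise_seq = np.sqrt(noise) * rng_noise.standard_normal(T)
    x_cand = _x_lattice(config.candidate_resolution)
    lattice = (
        _cube_lattice(config.optimum_resolution)
        if alg == "pbo"
        else _x_lattice(config.optimum_resolution)
    )
    model = (
        None
        if alg == "random"
        else PersonalizedGP(personalized=(alg == "pbo"))
    )
    X = np.zeros((T, 3))
    y_obs = np.zeros(T)
    f_true = np.zeros(T)
    best_value = np.zeros(T)
    distance = np.zeros(T)
    for t in range(T):
        p_t = p_seq[t]
        if alg == "random":
            x_t = rng_alg.random(2)
        elif t < config.n_init:
            x_t = x_init[t]
        else:
            Z = X[:t, :3] if alg == "pbo" else X[:t, :2]
            model.fit(
                Z, y_obs[:t], restarts=config.restarts,
                seed=int(rng_alg.integers(2**31 - 1)), warm_start=True,
            )
            if alg == "pbo":
                Zq = np.column_stack([x_cand, np.full(x_cand.shape[0], p_t)])
            else:
                Zq = x_cand
            mu, var = model.predict(Zq)
            ei = expected_improvement(mu, np.sqrt(var), model.best_observed())
            x_t = x_cand[int(np.argmax(ei))]
        u_t = np.array([x_t[0], x_t[1], p_t])
        f_t = hartmann3(u_t)
        X[t] = u_t
        f_true[t] = f_t
        y_obs[t] = f_t + noise_seq[t]
        best_value[t] = np.max(f_true[: t + 1])
        if alg == "random":
            # uninformed sampling delivers whatever it is currently querying
            u_hat = u_t
        else:
            u_hat = _identified_optimum(
                model if t >= config.n_init else None,
                X[: t + 1],
                y_obs[: t + 1],
                lattice,
            )
        distance[t] = float(np.linalg.norm(u_hat - HARTMANN3_OPTIMUM))
    return best_value, distance


def run_comparison(config: BenchmarkConfig = BenchmarkConfig()) -> BenchmarkResult:
    """Run the full algorithm x noise x repeat factorial.

    Within a repeat, the baseline sequence, initial design and noise draws
    are shared across algorithms so comparisons are paired.
    """
    best_value, distance = {}, {}
    for ni, noise in enumerate(config.noise_levels):
        for alg in config.algorithms:
            bv = np.zeros((config.repeats, config.iterations))
            dist = np.zeros((config.repeats, config.iterations))
            for r in range(config.repeats):
                bv[r], dist[r] = _run_single(
                    alg, noise, np.array([config.seed, ni, r]), config
                )
            best_value[(alg, noise)] = bv
            distance[(alg, noise)] = dist
    return BenchmarkResult(best_value=best_value, distance=distance, config=config)


def summarize(result: BenchmarkResult) -> pd.DataFrame:
    """Mean and SD over repeats, per algorithm x noise x iteration."""
    rows = []
    for (alg, noise), bv in result.best_value.items():
        dist = result.distance[(alg, noise)]
        for t in range(bv.shape[1]):
            rows.append(
                {
                    "algorithm": alg,
                    "noise": noise,
                    "iteration": t,
                    "best_value_mean": float(np.mean(bv[:, t])),
                    "best_value_sd": float(np.std(bv[:, t], ddof=0)),
                    "distance_mean": float(np.mean(dist[:, t])),
                    "distance_sd": float(np.std(dist[:, t], ddof=0)),
                }
            )
    return pd.DataFrame(rows)


def plot_traces(summary: pd.DataFrame, path, metric: str = "best_value") -> None:
    """Mean +/- SD traces per algorithm, one panel per noise level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    noises = sorted(summary["noise"].unique())
    fig, axes = plt.subplots(1, len(noises), figsize=(3.2 * len(noises), 3.2), squeeze=False)
    for ax, noise in zip(axes[0], noises):
        sub = summary[summary["noise"] == noise]
        for alg, grp in sub.groupby("algorithm"):
            m = grp[f"{metric}_mean"].to_numpy()
            s = grp[f"{metric}_sd"].to_numpy()
            it = grp["iteration"].to_numpy()
            ax.plot(it, m, label=alg)
            ax.fill_between(it, m - s, m + s, alpha=0.2)
        ax.set_title(f"noise var {noise:g}")
        ax.set_xlabel("iteration")
    axes[0][0].set_ylabel(metric.replace("_", " "))
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
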