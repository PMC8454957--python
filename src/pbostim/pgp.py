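"""Personalized Gaussian-process surrogate.

The surrogate jointly models the stimulation coordinates x in [0,1]^2 and
the per-subject baseline-ability covariate p in [0,1] with a product of
exponentiated-quadratic kernels,

    k({x_i, p_i}, {x_j, p_j}) = exp(-||x_i - x_j||^2 / (2 sigma_l^2))
                              * exp(-(p_i - p_j)^2 / (2 sigma_p^2)),

plus independent observation noise sigma_n^2 on the diagonal (Kronecker
delta keyed on observation index, so repeated measurements at the same
grid point carry independent noise).  The noise variance is added once to
the product kernel — i.e. y ~ GP(0, k + sigma_n^2 delta_ij) — which is the
only reading compatible with i.i.d. measurement noise.

A large sigma_p makes the model insensitive to the covariate: the
personalized surrogate then degenerates to a standard two-input surrogate,
which is exactly the ``personalized=False`` configuration used for the
standard-BO comparator.

Outputs are standardized to zero mean and unit variance over the included
observations at every refit (so the zero prior mean is appropriate, and
the prior variance is 1); the transform is stored for raw-scale
predictions.  Hyperparameters (sigma_l, sigma_p, sigma_n2) are estimated
by multi-restart L-BFGS-B maximization of the log marginal likelihood
over log-parameters, with analytic gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .design import UnitCoordinates
from .errors import (
    DegenerateDataError,
    InvalidHyperparameterError,
    InvalidInputError,
    NumericalFailureError,
)

__all__ = [
    "GPHyperparameters",
    "PersonalizedGP",
    "kernel_value",
    "predict",
    "log_marginal_likelihood",
    "fit_hyperparameters",
    "DEFAULT_BOUNDS",
    "DEFAULT_JITTER",
]

#: (sigma_l, sigma_p, sigma_n2) box bounds, enclosing length scales of a few
#: percent of the cube up to effectively-flat, and noise variances from
#: numerically negligible up to several prior variances.
DEFAULT_BOUNDS = ((1e-2, 10.0), (1e-2, 10.0), (1e-4, 4.0))

DEFAULT_JITTER = 1e-8

_DEFAULT_START = (0.2, 0.3, 0.1)


@dataclass
class GPHyperparameters:
    """Kernel hyperparameters on the normalized/standardized scale.

    sigma_l : shared length scale of the two stimulation coordinates
    sigma_p : length scale of the baseline-ability coordinate
    sigma_n2 : observation-noise variance
    """

    sigma_l: float
    sigma_p: float
    sigma_n2: float
    bounds: tuple = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.sigma_l <= 0 or self.sigma_p <= 0 or self.sigma_n2 <= 0:
            raise InvalidHyperparameterError(
                f"hyperparameters must be strictly positive, got "
                f"({self.sigma_l}, {self.sigma_p}, {self.sigma_n2})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_l, self.sigma_p, self.sigma_n2])


def _as_z(c) -> np.ndarray:
    """Coerce UnitCoordinates or array-like to a flat coordinate vector."""
    if isinstance(c, UnitCoordinates):
        return np.array([c.x[0], c.x[1], c.p], dtype=float)
    return np.asarray(c, dtype=float).ravel()


def kernel_value(
    ci, cj, hyper: GPHyperparameters, same_index: bool = False, d_x: Optional[int] = None
) -> float:
    """Product-kernel covariance between two observations.

    The last coordinate is treated as the personalization covariate p; the
    leading ``d_x`` coordinates (default: all but the last) share sigma_l.
    ``same_index`` adds sigma_n2 per the index-keyed Kronecker delta.
    """
    zi, zj = _as_z(ci), _as_z(cj)
    if zi.shape != zj.shape:
        raise InvalidInputError("coordinate dimensions differ")
    if d_x is None:
        d_x = zi.size - 1
    dx2 = float(np.sum((zi[:d_x] - zj[:d_x]) ** 2))
    k = np.exp(-dx2 / (2.0 * hyper.sigma_l**2))
    if d_x < zi.size:
        dp2 = float(np.sum((zi[d_x:] - zj[d_x:]) ** 2))
        k *= np.exp(-dp2 / (2.0 * hyper.sigma_p**2))
    if same_index:
        k += hyper.sigma_n2
    return float(k)


def _kernel_matrix(
    Zi: np.ndarray, Zj: np.ndarray, hyper: GPHyperparameters, d_x: int
) -> np.ndarray:
    """Noise-free product kernel between two coordinate sets."""
    Dx = cdist(Zi[:, :d_x], Zj[:, :d_x], "sqeuclidean")
    K = np.exp(-Dx / (2.0 * hyper.sigma_l**2))
    if d_x < Zi.shape[1]:
        Dp = cdist(Zi[:, d_x:], Zj[:, d_x:], "sqeuclidean")
        K *= np.exp(-Dp / (2.0 * hyper.sigma_p**2))
    return K


def _lml_and_grad(
    log_theta: np.ndarray, Z: np.ndarray, y: np.ndarray, d_x: int, jitter: float
) -> tuple[float, np.ndarray]:
    """Log marginal likelihood and gradient w.r.t. log hyperparameters."""
    sl, sp, sn2 = np.exp(log_theta)
    n = Z.shape[0]
    Dx = cdist(Z[:, :d_x], Z[:, :d_x], "sqeuclidean")
    Ks = np.exp(-Dx / (2.0 * sl**2))
    personalized = d_x < Z.shape[1]
    if personalized:
        Dp = cdist(Z[:, d_x:], Z[:, d_x:], "sqeuclidean")
        Ks *= np.exp(-Dp / (2.0 * sp**2))
    K = Ks + (sn2 + jitter) * np.eye(n)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise NumericalFailureError("covariance factorization failed") from exc
    alpha = cho_solve((L, True), y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    grad = np.empty(3)
    grad[0] = 0.5 * float(np.sum(W * (Ks * Dx / sl**2)))
    grad[1] = 0.5 * float(np.sum(W * (Ks * Dp / sp**2))) if personalized else 0.0
    grad[2] = 0.5 * sn2 * float(np.trace(W))
    return lml, grad


def log_marginal_likelihood(
    Z: np.ndarray,
    y: np.ndarray,
    hyper: GPHyperparameters,
    d_x: Optional[int] = None,
    jitter: float = DEFAULT_JITTER,
) -> float:
    """GP log marginal likelihood of standardized outputs ``y`` at ``hyper``."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if Z.shape[0] != y.size or y.size < 1:
        raise InvalidInputError("Z and y sizes disagree or are empty")
    if d_x is None:
        d_x = Z.shape[1] - 1 if Z.shape[1] >= 3 else Z.shape[1]
    log_theta = np.log([hyper.sigma_l, hyper.sigma_p, hyper.sigma_n2])
    lml, _ = _lml_and_grad(log_theta, Z, y, d_x, jitter)
    return lml


def fit_hyperparameters(
    Z: np.ndarray,
    y: np.ndarray,
    bounds: tuple = DEFAULT_BOUNDS,
    restarts: int = 10,
    seed: int = 0,
    d_x: Optional[int] = None,
    jitter: float = DEFAULT_JITTER,
    start: Optional[Sequence[float]] = None,
) -> GPHyperparameters:
    """Multi-restart maximization of the log marginal likelihood.

    Optimization runs in log-parameter space with analytic gradients; the
    first restart starts from ``start`` (default a mid-range triple), the
    remainder from seeded log-uniform draws inside the bounds.  Deterministic
    under ``seed``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise DegenerateDataError("need at least 3 observations to fit hyperparameters")
    if np.var(y) == 0:
        raise DegenerateDataError("zero output variance; standardization undefined")
    if d_x is None:
        d_x = Z.shape[1] - 1 if Z.shape[1] >= 3 else Z.shape[1]
    lo = np.log([b[0] for b in bounds])
    hi = np.log([b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    starts = [np.clip(np.log(start if start is not None else _DEFAULT_START), lo, hi)]
    for _ in range(max(0, restarts - 1)):
        starts.append(lo + rng.random(3) * (hi - lo))

    def objective(log_theta):
        lml, grad = _lml_and_grad(log_theta, Z, y, d_x, jitter)
        return -lml, -grad

    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 100},
        )
        if best is None or res.fun < best.fun:
            best = res
    sl, sp, sn2 = np.exp(np.clip(best.x, lo, hi))
    return GPHyperparameters(sigma_l=float(sl), sigma_p=float(sp), sigma_n2=float(sn2), bounds=bounds)


class PersonalizedGP:
    """GP surrogate over [x1, x2, p] (personalized) or [x1, x2] (standard).

    The model stores the raw training outputs and the standardization
    transform; predictions are returned on the standardized scale by
    default, or on the raw score scale with ``raw=True``.
    """

    def __init__(
        self,
        personalized: bool = True,
        bounds: tuple = DEFAULT_BOUNDS,
        jitter: float = DEFAULT_JITTER,
    ) -> None:
        self.personalized = personalized
        self.bounds = bounds
        self.jitter = jitter
        self.hyper: Optional[GPHyperparameters] = None
        self.Z: Optional[np.ndarray] = None
        self.y_raw: Optional[np.ndarray] = None
        self.y_mean: float = 0.0
        self.y_std: float = 1.0
        self._L = None
        self._alpha = None

    # -- fitting -----------------------------------------------------------

    @property
    def d_x(self) -> int:
        assert self.Z is not None
        return self.Z.shape[1] - 1 if self.personalized else self.Z.shape[1]

    @property
    def n(self) -> int:
        return 0 if self.Z is None else self.Z.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Standardized training outputs."""
        return (self.y_raw - self.y_mean) / self.y_std

    def fit(
        self,
        Z: np.ndarray,
        y_raw: np.ndarray,
        hyper: Optional[GPHyperparameters] = None,
        optimize: bool = True,
        restarts: int = 10,
        seed: int = 0,
        warm_start: bool = False,
    ) -> "PersonalizedGP":
        """Standardize outputs, estimate hyperparameters, factorize.

        ``warm_start=True`` seeds the first restart of the hyperparameter
        search from the previous fit.
        """
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        y_raw = np.asarray(y_raw, dtype=float).ravel()
        if Z.shape[0] != y_raw.size or y_raw.size < 1:
            raise InvalidInputError("Z and y sizes disagree or are empty")
        expected = 3 if self.personalized else 2
        if Z.shape[1] != expected:
            raise InvalidInputError(
                f"expected {expected}-column inputs for personalized={self.personalized}"
            )
        self.Z = Z
        self.y_raw = y_raw
        sd = float(np.std(y_raw))
        if sd > 0:
            self.y_mean, self.y_std = float(np.mean(y_raw)), sd
        else:
            self.y_mean, self.y_std = float(np.mean(y_raw)), 1.0
        if hyper is not None:
            self.hyper = hyper
        elif optimize:
            start = self.hyper.as_array() if (warm_start and self.hyper is not None) else None
            self.hyper = fit_hyperparameters(
                Z, self.y, bounds=self.bounds, restarts=restarts, seed=seed,
                d_x=self.d_x, jitter=self.jitter, start=start,
            )
        elif self.hyper is None:
            self.hyper = GPHyperparameters(*_DEFAULT_START, bounds=self.bounds)
        self._factorize()
        return self

    def _factorize(self) -> None:
        n = self.n
        K = _kernel_matrix(self.Z, self.Z, self.hyper, self.d_x)
        K[np.diag_indices(n)] += self.hyper.sigma_n2 + self.jitter
        try:
            self._L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError as exc:
            raise NumericalFailureError("covariance factorization failed despite jitter") from exc
        self._alpha = cho_solve((self._L, True), self.y)

    @property
    def fitted(self) -> bool:
        return self._L is not None

    # -- prediction --------------------------------------------------------

    def predict(self, Zq: np.ndarray, raw: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance at query coordinates.

        The noise variance appears on the training diagonal only; the query
        term uses the noise-free kernel, so the posterior variance is the
        uncertainty about the latent function and never exceeds the prior
        variance of 1 (standardized scale).  Negative variances from
        round-off are clipped at 0.
        """
        if not self.fitted:
            raise InvalidInputError("model is not fitted")
        Zq = np.atleast_2d(np.asarray(Zq, dtype=float))
        Kq = _kernel_matrix(Zq, self.Z, self.hyper, self.d_x)
        mu = Kq @ self._alpha
        V = solve_triangular(self._L, Kq.T, lower=True)
        var = 1.0 - np.sum(V**2, axis=0)
        var = np.clip(var, 0.0, None)
        if raw:
            return mu * self.y_std + self.y_mean, var * self.y_std**2
        return mu, var

    def best_observed(self) -> float:
        """Best (standardized) training output: the EI incumbent f+."""
        if self.y_raw is None or self.y_raw.size == 0:
            raise InvalidInputError("no observations")
        return float(np.max(self.y))

    def log_marginal_likelihood(self, hyper: Optional[GPHyperparameters] = None) -> float:
        return log_marginal_likelihood(
            self.Z, self.y, hyper or self.hyper, d_x=self.d_x, jitter=self.jitter
        )

    # -- persistence -------------------------------------------------------

    def snapshot(self) -> dict:
        """JSON-serializable state sufficient to reproduce predictions."""
        return {
            "personalized": self.personalized,
            "Z": self.Z.tolist(),
            "y_raw": self.y_raw.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "jitter": self.jitter,
            "bounds": [list(b) for b in self.bounds],
            "hyper": {
                "sigma_l": self.hyper.sigma_l,
                "sigma_p": self.hyper.sigma_p,
                "sigma_n2": self.hyper.sigma_n2,
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.snapshot(), fh)

    @classmethod
    def from_snapshot(cls, payload: dict) -> "PersonalizedGP":
        bounds = tuple(tuple(b) for b in payload["bounds"])
        model = cls(personalized=payload["personalized"], bounds=bounds, jitter=payload["jitter"])
        hyper = GPHyperparameters(bounds=bounds, **payload["hyper"])
        model.fit(np.array(payload["Z"]), np.array(payload["y_raw"]), hyper=hyper)
        model.y_mean = payload["y_mean"]
        model.y_std = payload["y_std"]
        model._factorize()
        return model

    @classmethod
    def load(cls, path) -> "PersonalizedGP":
        with open(path) as fh:
            return cls.from_snapshot(json.load(fh))


def predict(model: PersonalizedGP, query) -> tuple[float, float]:
    """Posterior mean and variance at one query (UnitCoordinates or vector)."""
    z = _as_z(query)
    if not model.personalized:
        z = z[: model.d_x]
    mu, var = model.predict(z.reshape(1, -1))
    return float(mu[0]), float(var[0])
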