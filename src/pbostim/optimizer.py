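"""The sequential personalized-BO experimental protocol.

The protocol runs 50 subjects x 3 blocks = 150 assignments.  The first 60
assignments (20 subjects) form a burn-in of random draws from the 736-point
active grid (no sham); every later assignment is the acquisition argmax at
the subject's baseline value over the 782-point grid with the 0 mA sham
setting included.  After every observation the Gaussian process is refitted
to all included data; observations whose raw score reaches the exclusion
threshold (default 3.6) are logged but never enter the model.

Three modes share the loop:

* ``pbo``        — personalized GP over (frequency, current, baseline),
* ``standard_bo``— GP over (frequency, current) only,
* ``random``     — uniform draws throughout.

Every source of randomness is derived from the protocol seed and the
assignment index, so (config, seeds, log) replays to the identical
sequence of recommendations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import design
from .acquisition import (
    AcquisitionSpec,
    argmax_candidates,
    argmax_over_grid,
    expected_improvement,
    ucb,
)
from .design import (
    BURN_IN,
    DEFAULT_BASELINE_BOUNDS,
    OPTIMIZATION,
    BlindingCodebook,
    SearchSpace,
    StimulationParameters,
    grid_unit_coordinates,
    normalize_p,
    normalize_params,
)
from .diffusion import BaselineAbility
from .errors import (
    ConfigurationError,
    InvalidInputError,
    ProtocolComplete,
    ProtocolError,
    SplitError,
)
from .pgp import DEFAULT_BOUNDS, PersonalizedGP
from .synthetic import SyntheticCohort, ResponseSurface, sample_subject

__all__ = [
    "ProtocolConfig",
    "Recommendation",
    "OptimizerState",
    "ProtocolResult",
    "propose_next",
    "update",
    "run_synthetic_protocol",
    "best_inferred",
    "cross_validate",
]

MODES = ("pbo", "standard_bo", "random")


@dataclass
class ProtocolConfig:
    """All protocol-level settings; every run logs a resolved copy."""

    n_subjects: int = 50
    blocks_per_subject: int = 3
    burn_in_subjects: int = 20
    burn_in_assignments: int = 60
    exclusion_threshold: Optional[float] = 3.6
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    seed: int = 0
    baseline_bounds: tuple[float, float] = DEFAULT_BASELINE_BOUNDS
    restarts: int = 10
    hyper_refit_every: int = 1
    hyper_bounds: tuple = DEFAULT_BOUNDS
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.burn_in_assignments != self.burn_in_subjects * self.blocks_per_subject:
            raise ConfigurationError(
                "burn_in_assignments must equal burn_in_subjects * blocks_per_subject"
            )
        if self.n_subjects < self.burn_in_subjects:
            raise ConfigurationError("n_subjects must be >= burn_in_subjects")
        if self.hyper_refit_every < 1:
            raise ConfigurationError("hyper_refit_every must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")

    @property
    def total_assignments(self) -> int:
        return self.n_subjects * self.blocks_per_subject

    def to_dict(self) -> dict:
        d = asdict(self)
        d["acquisition"] = {"kind": self.acquisition.kind, "kappa": self.acquisition.kappa}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            d["acquisition"] = AcquisitionSpec(**d["acquisition"])
        if "baseline_bounds" in d:
            d["baseline_bounds"] = tuple(d["baseline_bounds"])
        if "hyper_bounds" in d:
            d["hyper_bounds"] = tuple(tuple(b) for b in d["hyper_bounds"])
        return cls(**d)


@dataclass(frozen=True)
class Recommendation:
    """One proposed stimulation setting, optionally blinded."""

    params: StimulationParameters
    phase: str  # burn_in | pbo | standard_bo | random
    iteration: int
    acquisition_value: Optional[float] = None
    f_plus: Optional[float] = None
    code: Optional[int] = None


class OptimizerState:
    """Ordered observation history plus the current surrogate model.

    Excluded observations stay in the log but never enter covariance
    matrices.  The surrogate is rebuilt from the log after every update, so
    the state is fully determined by (config, mode, history).
    """

    def __init__(
        self,
        config: ProtocolConfig,
        mode: str = "pbo",
        codebook: Optional[BlindingCodebook] = None,
    ) -> None:
        if mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        self.config = config
        self.mode = mode
        self.codebook = codebook
        self.history: list[dict] = []
        # per-subject baseline bookkeeping for interactive sessions:
        # subject_id -> {"p_raw": ..., "v_base": ..., "split_seed": ...}
        self.subjects: dict[str, dict] = {}
        self.model: Optional[PersonalizedGP] = None
        self._updates_since_hyper_fit = 0
        # burn-in assignments are pre-drawn without replacement so the phase
        # is reproducible regardless of when proposals are requested
        rng = np.random.default_rng([config.seed, 0])
        grid = BURN_IN.grid()
        k = min(config.burn_in_assignments, len(grid))
        self._burn_in_sequence = [grid[i] for i in rng.choice(len(grid), size=k, replace=False)]

    @property
    def n_assignments(self) -> int:
        return len(self.history)

    def included(self) -> list[dict]:
        return [h for h in self.history if not h["excluded"] and np.isfinite(h["y_raw"])]

    def history_frame(self) -> pd.DataFrame:
        cols = [
            "iter", "subject_id", "block_id", "phase", "code",
            "frequency", "current", "p_raw", "y_raw", "excluded",
        ]
        return pd.DataFrame(self.history, columns=cols)

    # -- persistence -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "mode": self.mode,
            "history": self.history,
            "subjects": self.subjects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path, codebook: Optional[BlindingCodebook] = None) -> "OptimizerState":
        with open(path) as fh:
            payload = json.load(fh)
        state = cls(ProtocolConfig.from_dict(payload["config"]), payload["mode"], codebook)
        for rec in payload["history"]:
            state.history.append(rec)
        state.subjects = dict(payload.get("subjects", {}))
        state._refit()
        return state

    # -- model maintenance -------------------------------------------------

    def _training_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        rows = self.included()
        Z, y = [], []
        for h in rows:
            x = normalize_params(StimulationParameters(h["frequency"], h["current"]))
            if self.mode == "standard_bo":
                Z.append(x)
            else:
                Z.append((*x, normalize_p(h["p_raw"], self.config.baseline_bounds)))
            y.append(h["y_raw"])
        return np.array(Z, dtype=float), np.array(y, dtype=float)

    def _refit(self) -> None:
        Z, y = self._training_arrays()
        if Z.shape[0] < 3 or np.var(y) == 0:
            self.model = None
            return
        refit_hyper = (
            self.model is None
            or self.model.hyper is None
            or self._updates_since_hyper_fit >= self.config.hyper_refit_every
        )
        if self.model is None:
            self.model = PersonalizedGP(
                personalized=(self.mode != "standard_bo"), bounds=self.config.hyper_bounds
            )
        if refit_hyper:
            self.model.fit(
                Z, y, optimize=True, restarts=self.config.restarts,
                seed=self.config.seed, warm_start=True,
            )
            self._updates_since_hyper_fit = 1
        else:
            self.model.fit(Z, y, hyper=self.model.hyper)
            self._updates_since_hyper_fit += 1


def propose_next(state: OptimizerState, p, mode: Optional[str] = None) -> Recommendation:
    """Select the next stimulation setting for a subject with baseline ``p``.

    ``p`` may be a BaselineAbility or a raw drift rate; it is min-max
    normalized with the configured bounds.  During the first 60 assignments
    (and always in random mode before burn-in ends) the proposal is a
    seeded uniform draw from the burn-in grid; afterwards it is the
    acquisition argmax at ``p`` over the optimization grid (random mode
    keeps drawing uniformly, from the sham-augmented grid).
    """
    mode = mode or state.mode
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}")
    cfg = state.config
    t = state.n_assignments
    if t >= cfg.total_assignments:
        raise ProtocolComplete(f"stopping criterion reached ({cfg.n_subjects} subjects)")
    p_raw = p.p_raw if isinstance(p, BaselineAbility) else float(p)
    p_unit = normalize_p(p_raw, cfg.baseline_bounds)
    in_burn_in = t < cfg.burn_in_assignments
    if in_burn_in:
        return Recommendation(
            params=state._burn_in_sequence[t],
            phase="burn_in",
            iteration=t,
            code=_maybe_code(state, state._burn_in_sequence[t]),
        )
    if mode == "random":
        rng = np.random.default_rng([cfg.seed, t])
        grid = OPTIMIZATION.grid()
        params = grid[int(rng.integers(len(grid)))]
        return Recommendation(
            params=params, phase="random", iteration=t, code=_maybe_code(state, params)
        )
    if state.model is None or not state.model.fitted:
        raise ProtocolError("surrogate model unavailable after burn-in; update with data first")
    tie_seed = int(np.random.default_rng([cfg.seed, t]).integers(2**31 - 1))
    params = argmax_over_grid(
        state.model, p_unit, OPTIMIZATION, cfg.acquisition, seed=tie_seed
    )
    z = np.array([*normalize_params(params), p_unit])
    if not state.model.personalized:
        z = z[:2]
    mu, var = state.model.predict(z.reshape(1, -1))
    f_plus = state.model.best_observed()
    if cfg.acquisition.kind == "ei":
        aval = float(expected_improvement(mu[0], np.sqrt(var[0]), f_plus))
    else:
        aval = float(ucb(mu[0], np.sqrt(var[0]), cfg.acquisition.kappa))
    return Recommendation(
        params=params,
        phase=mode,
        iteration=t,
        acquisition_value=aval,
        f_plus=f_plus,
        code=_maybe_code(state, params),
    )


def _maybe_code(state: OptimizerState, params: StimulationParameters) -> Optional[int]:
    return state.codebook.encode(params) if state.codebook is not None else None


def update(
    state: OptimizerState,
    subject_id: str,
    block_id: str,
    params: StimulationParameters,
    p_raw: float,
    y_raw: float,
    phase: Optional[str] = None,
) -> OptimizerState:
    """Append one scored observation and refit the surrogate.

    Raw scores at or above the exclusion threshold are flagged and kept out
    of the model; duplicate (subject, block) keys are a protocol error.
    """
    key = (subject_id, block_id)
    if any((h["subject_id"], h["block_id"]) == key for h in state.history):
        raise ProtocolError(f"duplicate observation for subject/block {key}")
    cfg = state.config
    excluded = bool(
        cfg.exclusion_threshold is not None
        and np.isfinite(y_raw)
        and y_raw >= cfg.exclusion_threshold
    ) or not np.isfinite(y_raw)
    t = state.n_assignments
    state.history.append(
        {
            "iter": t,
            "subject_id": subject_id,
            "block_id": block_id,
            "phase": phase or ("burn_in" if t < cfg.burn_in_assignments else state.mode),
            "code": _maybe_code(state, params),
            "frequency": params.frequency,
            "current": params.current,
            "p_raw": float(p_raw),
            "y_raw": float(y_raw),
            "excluded": excluded,
        }
    )
    state._refit()
    return state


def best_inferred(
    model: PersonalizedGP,
    p: float,
    space: SearchSpace = OPTIMIZATION,
    seed: int = 0,
) -> StimulationParameters:
    """Posterior-mean argmax over the grid at a fixed unit baseline ``p``."""
    if model is None or not model.fitted:
        raise InvalidInputError("model is not fitted")
    X = grid_unit_coordinates(space)
    Zq = np.column_stack([X, np.full(X.shape[0], p)]) if model.personalized else X
    mu, _ = model.predict(Zq)
    idx, _ = argmax_candidates(mu, seed=seed)
    return space.grid()[idx]


@dataclass
class ProtocolResult:
    history: pd.DataFrame
    model: Optional[PersonalizedGP]
    trace: pd.DataFrame  # per-iteration predicted best (raw scale) and its SD
    config: ProtocolConfig
    mode: str
    state: OptimizerState


def run_synthetic_protocol(
    config: ProtocolConfig,
    cohort: SyntheticCohort,
    surface: ResponseSurface,
    mode: str = "pbo",
    score_mode: str = "surface",
    codebook: Optional[BlindingCodebook] = None,
) -> ProtocolResult:
    """Run the full closed loop against a synthetic cohort.

    ``score_mode='surface'`` scores each block as the surface value plus
    additive Gaussian noise (SD = surface.noise_sd) at the subject's true
    baseline; ``score_mode='diffusion'`` generates 50 diffusion trials per
    block and scores them through the estimator, using the subject's
    estimated baseline ability and normalization drift.
    """
    if len(cohort) < config.n_subjects:
        raise ProtocolError(
            f"cohort of {len(cohort)} cannot supply {config.n_subjects} subjects"
        )
    if score_mode not in ("surface", "diffusion"):
        raise ConfigurationError(f"unknown score_mode {score_mode!r}")
    state = OptimizerState(config, mode=mode, codebook=codebook)
    trace_rows = []
    grid_X = grid_unit_coordinates(OPTIMIZATION)
    for si in range(config.n_subjects):
        subj = cohort.subjects[si]
        p_raw = subj.p_true if score_mode == "surface" else subj.ability.p_raw
        p_unit = normalize_p(p_raw, config.baseline_bounds)
        for bi in range(config.blocks_per_subject):
            rec = propose_next(state, p_raw, mode=mode)
            t = rec.iteration
            obs_rng = np.random.default_rng([config.seed, 1, t])
            if score_mode == "surface":
                x = np.asarray(normalize_params(rec.params))
                y = float(
                    surface.value(x, p_unit) + surface.noise_sd * obs_rng.standard_normal()
                )
            else:
                _, y = sample_subject(
                    surface,
                    p_raw=subj.p_true,
                    params=rec.params,
                    seed=int(obs_rng.integers(2**31 - 1)),
                    v_base=subj.v_base,
                    config=cohort.config,
                )
            if config.dropout > 0 and obs_rng.random() < config.dropout:
                y = float("nan")  # missing observation: logged, never modelled
            update(
                state, subj.subject_id, f"block{bi + 1}", rec.params, p_raw, y, phase=rec.phase
            )
            trace_rows.append(_trace_row(state, t, p_unit, grid_X))
    return ProtocolResult(
        history=state.history_frame(),
        model=state.model,
        trace=pd.DataFrame(trace_rows),
        config=config,
        mode=mode,
        state=state,
    )


def _trace_row(state: OptimizerState, t: int, p_unit: float, grid_X: np.ndarray) -> dict:
    """Best performance predicted by the GP at any parameter combination."""
    if state.model is None or not state.model.fitted:
        return {"iter": t, "predicted_best": np.nan, "predicted_sd": np.nan}
    if state.model.personalized:
        Zq = np.column_stack([grid_X, np.full(grid_X.shape[0], p_unit)])
    else:
        Zq = grid_X
    mu, var = state.model.predict(Zq, raw=True)
    i = int(np.argmax(mu))
    return {"iter": t, "predicted_best": float(mu[i]), "predicted_sd": float(np.sqrt(var[i]))}


def cross_validate(
    history: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    baseline_bounds: tuple[float, float] = DEFAULT_BASELINE_BOUNDS,
    restarts: int = 10,
) -> float:
    """Participant-level hold-out MSE of GP regression on the protocol log.

    Subjects are split (all blocks together) into train/test by a seeded
    permutation; a personalized GP regresses raw score on (frequency,
    current, baseline) and the mean squared error is computed on the test
    participants, on the raw score scale.
    """
    df = history[~history["excluded"].astype(bool) & np.isfinite(history["y_raw"])]
    subjects = df["subject_id"].unique()
    if subjects.size < 5:
        raise SplitError("need at least 5 distinct subjects for cross-validation")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    n_train = int(round(train_fraction * subjects.size))
    train_ids, test_ids = set(perm[:n_train]), set(perm[n_train:])
    if len(train_ids) < 2 or len(test_ids) < 2:
        raise SplitError("fewer than 2 subjects in a split")

    def arrays(ids):
        sub = df[df["subject_id"].isin(ids)]
        Z = np.column_stack(
            [
                (sub["frequency"].to_numpy() - design.FREQ_MIN)
                / (design.FREQ_MAX - design.FREQ_MIN),
                (sub["current"].to_numpy() - design.CURRENT_MIN)
                / (design.CURRENT_MAX - design.CURRENT_MIN),
                np.clip(
                    (sub["p_raw"].to_numpy() - baseline_bounds[0])
                    / (baseline_bounds[1] - baseline_bounds[0]),
                    0.0,
                    1.0,
                ),
            ]
        )
        return Z, sub["y_raw"].to_numpy()

    Z_tr, y_tr = arrays(train_ids)
    Z_te, y_te = arrays(test_ids)
    model = PersonalizedGP(personalized=True)
    model.fit(Z_tr, y_tr, restarts=restarts, seed=seed)
    pred, _ = model.predict(Z_te, raw=True)
    return float(np.mean((pred - y_te) ** 2))
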