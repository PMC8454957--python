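"""Stimulation search space, unit-cube normalization and double-blinding.

The decision variable is a (frequency, current) pair on a discrete
hardware lattice: frequency 5-50 Hz in 1 Hz steps, current 0.1-1.6 mA
peak-to-peak in 0.1 mA steps during burn-in, with a 0 mA sham setting
added for the model-driven optimization phase (46 x 16 = 736 and
46 x 17 = 782 combinations respectively).

All model-facing coordinates live in the unit cube: frequency and current
are min-max mapped over fixed physical bounds (5-50 Hz, 0-1.6 mA — the
same bounds in both phases so training points never move in kernel space
when the phase changes), and the baseline-ability covariate is min-max
mapped over configured bounds, default [0, 0.2] drift-rate units.
Coordinate convention: dimension 1 of x is frequency, dimension 2 is
current.

Double blinding is preserved by a seeded pseudo-random bijection between
grid combinations and opaque integer codes, persisted to JSON; session
logs can carry codes only.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
import numpy as np

from .errors import CodebookError, InvalidInputError

__all__ = [
    "StimulationParameters",
    "SearchSpace",
    "UnitCoordinates",
    "BlindingCodebook",
    "BURN_IN",
    "OPTIMIZATION",
    "DEFAULT_BASELINE_BOUNDS",
    "normalize",
    "denormalize",
    "normalize_params",
    "normalize_p",
    "grid_unit_coordinates",
]

FREQ_MIN, FREQ_MAX, FREQ_STEP = 5.0, 50.0, 1.0
CURRENT_MIN, CURRENT_MAX, CURRENT_STEP = 0.0, 1.6, 0.1

#: Bounds for min-max normalization of the baseline drift rate, bracketing
#: a typical mean baseline ability of about 0.055.
DEFAULT_BASELINE_BOUNDS = (0.0, 0.2)


@dataclass(frozen=True, order=True)
class StimulationParameters:
    """One lattice point: frequency in Hz, current in mA peak-to-peak."""

    frequency: float
    current: float


@dataclass(frozen=True)
class SearchSpace:
    """Discrete stimulation lattice for one protocol phase.

    ``burn_in`` excludes the 0 mA sham setting (736 points); ``optimization``
    includes it (782 points).  Normalization bounds are phase-independent.
    """

    phase: str = "optimization"

    def __post_init__(self) -> None:
        if self.phase not in ("burn_in", "optimization"):
            raise InvalidInputError(f"unknown phase {self.phase!r}")

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(FREQ_MIN, FREQ_MAX + FREQ_STEP / 2, FREQ_STEP)

    @property
    def currents(self) -> np.ndarray:
        active = np.round(np.arange(1, 17) * CURRENT_STEP, 1)  # 0.1 .. 1.6
        if self.phase == "optimization":
            return np.concatenate([[0.0], active])
        return active

    def grid(self) -> list[StimulationParameters]:
        """Exhaustive, duplicate-free lattice in (frequency, current) order."""
        return [
            StimulationParameters(frequency=float(f), current=float(c))
            for f in self.frequencies
            for c in self.currents
        ]

    def contains(self, params: StimulationParameters) -> bool:
        return (
            np.any(np.isclose(self.frequencies, params.frequency))
            and np.any(np.isclose(self.currents, params.current))
        )

    @property
    def size(self) -> int:
        return self.frequencies.size * self.currents.size

    def digest(self) -> str:
        payload = json.dumps(
            {"phase": self.phase, "freq": self.frequencies.tolist(), "curr": self.currents.tolist()}
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


BURN_IN = SearchSpace(phase="burn_in")
OPTIMIZATION = SearchSpace(phase="optimization")


@dataclass(frozen=True)
class UnitCoordinates:
    """Model-facing coordinates: x = (frequency, current) in [0,1]^2, p in [0,1]."""

    x: tuple[float, float]
    p: float


def normalize_params(params: StimulationParameters) -> tuple[float, float]:
    fx = (params.frequency - FREQ_MIN) / (FREQ_MAX - FREQ_MIN)
    cx = (params.current - CURRENT_MIN) / (CURRENT_MAX - CURRENT_MIN)
    return (float(fx), float(cx))


def normalize_p(
    p_raw: float, baseline_bounds: tuple[float, float] = DEFAULT_BASELINE_BOUNDS
) -> float:
    lo, hi = baseline_bounds
    if not lo <= p_raw <= hi:
        warnings.warn(
            f"baseline ability {p_raw:.4g} outside configured bounds [{lo}, {hi}]; clipping",
            stacklevel=2,
        )
    return float(np.clip((p_raw - lo) / (hi - lo), 0.0, 1.0))


def normalize(
    params: StimulationParameters,
    p_raw: float,
    space: SearchSpace = OPTIMIZATION,
    baseline_bounds: tuple[float, float] = DEFAULT_BASELINE_BOUNDS,
) -> UnitCoordinates:
    """Affine min-max map of a grid point and a baseline drift to the unit cube."""
    if not space.contains(params):
        raise InvalidInputError(f"{params} not on the {space.phase} grid")
    return UnitCoordinates(x=normalize_params(params), p=normalize_p(p_raw, baseline_bounds))


def denormalize(
    coords: UnitCoordinates,
    space: SearchSpace = OPTIMIZATION,
    baseline_bounds: tuple[float, float] = DEFAULT_BASELINE_BOUNDS,
) -> tuple[StimulationParameters, float]:
    """Invert :func:`normalize`, snapping (frequency, current) to the lattice."""
    f = coords.x[0] * (FREQ_MAX - FREQ_MIN) + FREQ_MIN
    c = coords.x[1] * (CURRENT_MAX - CURRENT_MIN) + CURRENT_MIN
    f = float(np.round(f / FREQ_STEP) * FREQ_STEP)
    c = float(np.round(c / CURRENT_STEP) * CURRENT_STEP)
    params = StimulationParameters(frequency=f, current=round(c, 1))
    lo, hi = baseline_bounds
    return params, float(coords.p * (hi - lo) + lo)


def grid_unit_coordinates(space: SearchSpace) -> np.ndarray:
    """(n, 2) array of the whole grid in unit coordinates, same order as grid()."""
    return np.array([normalize_params(g) for g in space.grid()])


class BlindingCodebook:
    """Seeded pseudo-random bijection between grid points and opaque codes.

    Codes are drawn without replacement from the 3-digit range 100-999 so
    they reveal no ordering of current or frequency; in particular the 0 mA
    sham setting is indistinguishable from active settings.
    """

    def __init__(
        self, mapping: dict[int, StimulationParameters], seed: int, space_digest: str
    ) -> None:
        self._code_to_params = dict(mapping)
        self._params_to_code = {p: c for c, p in mapping.items()}
        if len(self._params_to_code) != len(self._code_to_params):
            raise CodebookError("codebook mapping is not a bijection")
        self.seed = int(seed)
        self.space_digest = space_digest

    @classmethod
    def generate(cls, space: SearchSpace = OPTIMIZATION, seed: int = 0) -> "BlindingCodebook":
        grid = space.grid()
        rng = np.random.default_rng(seed)
        codes = rng.choice(np.arange(100, 1000), size=len(grid), replace=False)
        return cls(
            {int(c): g for c, g in zip(codes, grid)}, seed=seed, space_digest=space.digest()
        )

    def encode(self, params: StimulationParameters) -> int:
        try:
            return self._params_to_code[params]
        except KeyError:
            raise CodebookError(f"{params} is not in the codebook grid") from None

    def decode(self, code: int) -> StimulationParameters:
        try:
            return self._code_to_params[int(code)]
        except KeyError:
            raise CodebookError(f"unknown code {code}") from None

    def __len__(self) -> int:
        return len(self._code_to_params)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "space_digest": self.space_digest,
            "codes": {
                str(c): {"frequency": p.frequency, "current": p.current}
                for c, p in self._code_to_params.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BlindingCodebook":
        with open(path) as fh:
            payload = json.load(fh)
        mapping = {
            int(c): StimulationParameters(frequency=d["frequency"], current=d["current"])
            for c, d in payload["codes"].items()
        }
        return cls(mapping, seed=payload["seed"], space_digest=payload["space_digest"])
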