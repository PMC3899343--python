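"""Deterministic RGR response surface f(θ, s; φ).

The relative growth rate of a cereal-aphid population is modelled as a
separable response to ambient temperature θ (°C) and host-wheat phenology s
(Zadoks decimal stage):

    f(θ, s) = a · θ^b · (θ_max − θ)/θ_max
                · 1 / (1 + exp(−k (s − s_m)))
                · (1 − exp(−(s_max − s)/τ))

The temperature branch rises like a power law and is pulled down linearly
towards the lethal maximum θ_max, giving an interior thermal optimum at
θ* = b θ_max / (b + 1).  The phenology branch is sigmoidal on the left with
inflexion near s_m (aphid populations build up once stem extension is under
way) and collapses over the last few Zadoks units before s_max, the latest
stage still allowing aphid feeding.  Outside the viable domain (θ ≥ θ_max,
θ ≤ 0 or s ≥ s_max) the surface is defined as 0 rather than negative: a
population that cannot grow is flat, and the data never reach those corners.

An optional linear natural-enemy extension subtracts (or adds) per-count
effects of fungus-killed aphids E and parasitoid mummies M.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = ["RGRParams", "rgr_surface", "rgr_with_enemies", "prediction_grid"]

#: Fixed right-hand fall rate of the terminal-stage factor (Zadoks units).
#: Held constant, not fitted, to preserve the four-parameter count of the model.
TAU_STAGE_FALL = 2.0


@dataclass(frozen=True)
class RGRParams:
    """Parameter vector of the RGR surface.

    ``theta_max`` and ``s_max`` are fixed biological constants (lethal
    temperature 30 °C; latest feeding stage, Zadoks 92).  ``s_m``, ``a``,
    ``b`` and ``k`` are the free parameters estimated from data; ``c_E`` and
    ``c_M`` are the optional linear natural-enemy coefficients.
    """

    s_m: float
    a: float
    b: float
    k: float
    theta_max: float = 30.0
    s_max: float = 92.0
    tau: float = TAU_STAGE_FALL
    c_E: Optional[float] = None
    c_M: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.theta_max > 0:
            raise ValueError(f"theta_max must be positive, got {self.theta_max}")
        if not (0 < self.s_m < self.s_max <= 99):
            raise ValueError(
                f"require 0 < s_m < s_max <= 99, got s_m={self.s_m}, s_max={self.s_max}"
            )
        if self.a < 0:
            raise ValueError(f"scale parameter a must be >= 0, got {self.a}")
        if not self.k > 0:
            raise ValueError(f"stage steepness k must be > 0, got {self.k}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def has_enemy_terms(self) -> bool:
        return self.c_E is not None and self.c_M is not None

    def free_names(self, with_enemies: bool = False) -> list[str]:
        """Names of the free parameters, in the conventional reporting order."""
        names = ["s_m", "a", "b", "k"]
        if with_enemies:
            names += ["c_E", "c_M"]
        return names

    def free_values(self, with_enemies: bool = False) -> np.ndarray:
        d = asdict(self)
        return np.array([d[n] for n in self.free_names(with_enemies)], dtype=float)

    def replace_free(self, values, with_enemies: bool = False) -> "RGRParams":
        """New parameter set with the free entries replaced by ``values``."""
        d = asdict(self)
        for name, v in zip(self.free_names(with_enemies), values, strict=True):
            d[name] = float(v)
        return RGRParams(**d)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "RGRParams":
        return cls(**d)


def _check_stage(s: np.ndarray) -> None:
    if np.any((s < 0) | (s > 99)):
        bad = np.asarray(s)[(np.asarray(s) < 0) | (np.asarray(s) > 99)]
        raise ValueError(f"Zadoks stage outside [0, 99]: {bad[:5]}")


def rgr_surface(theta, s, params: RGRParams):
    """Evaluate the RGR surface f(θ, s; φ) in 1/day.

    Accepts scalars or broadcastable arrays; returns a float for scalar
    input.  Zero outside the viable domain (θ ≤ 0, θ ≥ θ_max, s ≥ s_max).
    """
    theta = np.asarray(theta, dtype=float)
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("temperature must be finite")
    _check_stage(s)

    theta_b, s_b = np.broadcast_arrays(theta, s)
    out = np.zeros(theta_b.shape, dtype=float)
    alive = (theta_b > 0) & (theta_b < params.theta_max) & (s_b < params.s_max)
    th = theta_b[alive]
    st = s_b[alive]
    temp = params.a * th**params.b * (params.theta_max - th) / params.theta_max
    sig = 1.0 / (1.0 + np.exp(-params.k * (st - params.s_m)))
    fall = 1.0 - np.exp(-(params.s_max - st) / params.tau)
    out[alive] = temp * sig * fall
    if out.ndim == 0:
        return float(out)
    return out


def rgr_with_enemies(theta, s, E, M, params: RGRParams):
    """RGR surface plus linear natural-enemy terms c_E·E + c_M·M.

    E is the count of aphids killed by entomophthoralean fungi, M the count
    of parasitoid mummies, both in the same sample as the aphid count.
    """
    if params.c_E is None or params.c_M is None:
        raise ValueError("params lack enemy coefficients c_E / c_M")
    E = np.asarray(E, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(E < 0) or np.any(M < 0):
        raise ValueError("enemy counts must be nonnegative")
    base = rgr_surface(theta, s, params)
    out = base + params.c_E * E + params.c_M * M
    if np.ndim(out) == 0:
        return float(out)
    return out


def prediction_grid(
    params: RGRParams,
    theta_range: tuple[float, float] = (0.0, 30.0),
    s_range: tuple[float, float] = (30.0, 92.0),
    resolution: int | tuple[int, int] = 50,
):
    """Rectangular evaluation of the surface for prediction maps.

    Returns ``(theta_values, s_values, grid)`` where ``grid[i, j]``
    corresponds to ``s_values[i]`` (rows) and ``theta_values[j]`` (columns).
    """
    if isinstance(resolution, int):
        res_theta = res_s = resolution
    else:
        res_theta, res_s = resolution
    if res_theta < 1 or res_s < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    t0, t1 = theta_range
    s0, s1 = s_range
    if (t1 < t0) or (s1 < s0):
        raise ValueError("degenerate range: upper bound below lower bound")
    theta_values = np.linspace(t0, t1, res_theta)
    s_values = np.linspace(s0, s1, res_s)
    grid = rgr_surface(theta_values[None, :], s_values[:, None], params)
    grid = np.atleast_2d(grid)
    return theta_values, s_values, grid
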