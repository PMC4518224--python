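"""Core contracts for autonomous ODE models over named parameter spaces.

An :class:`OdeModel` couples a vectorised right-hand side (and optionally an
analytic Jacobian) with named states, named parameters, per-state upper
bounds, default parameter values and documented default sampling ranges.
Concentrations are in nM and time in seconds by convention; units are
documentation only and never enforced numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "NumericsError",
    "OdeModel",
    "ParameterPoint",
    "ParameterSpec",
    "eval_jacobian",
    "eval_rhs",
    "finite_difference_jacobian",
]


class NumericsError(RuntimeError):
    """Raised when an evaluation produces non-finite values."""


@dataclass(frozen=True)
class ParameterSpec:
    """Sampling-range metadata for one parameter.

    Parameters
    ----------
    name
        Parameter identifier (must match a model parameter name).
    low, high
        Range bounds in model units; ``low <= high`` and, for log scale,
        ``low > 0``.
    scale
        ``"linear"`` for uniform sampling on [low, high], ``"log"`` for
        uniform sampling in log10 space.
    integer
        If true the parameter only takes integer values (e.g. Hill
        coefficients); bounds must then be integers.
    """

    name: str
    low: float
    high: float
    scale: str = "linear"
    integer: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.low > self.high:
            raise ValueError(f"{self.name}: low={self.low} > high={self.high}")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log scale requires low > 0")
        if self.integer and (self.low != int(self.low) or self.high != int(self.high)):
            raise ValueError(f"{self.name}: integer spec requires integer bounds")


@dataclass(frozen=True)
class ParameterPoint:
    """One concrete parameterisation: a mapping name -> value (model units)."""

    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def as_mapping(point: "ParameterPoint | Mapping[str, float]") -> Mapping[str, float]:
    if isinstance(point, ParameterPoint):
        return point.values
    return point


RhsFn = Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
JacFn = Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
BoundsFn = Callable[[Mapping[str, float]], np.ndarray]


@dataclass(frozen=True)
class OdeModel:
    """An autonomous ODE system with named states and parameters.

    ``rhs(state, params)`` maps a state vector (shape ``(..., n)``; the
    leading axes broadcast so batches of states evaluate in one call) and a
    parameter mapping to d(state)/dt (nM/s). ``jacobian``, when supplied,
    returns the analytic matrix d(rhs)/d(state) with shape ``(..., n, n)``.
    Conservation laws are substituted at model-definition time, so states
    are the free/phosphorylated forms only and totals appear as parameters.
    ``state_upper_bounds(params)`` gives strictly positive per-state bounds
    (conserved totals where they exist, otherwise a documented heuristic)
    that delimit the admissible box used for root-finder starts and random
    initial conditions.
    """

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    rhs: RhsFn
    state_upper_bounds: BoundsFn
    default_params: dict[str, float]
    jacobian: JacFn | None = None
    default_specs: tuple[ParameterSpec, ...] = ()

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def params_with(self, overrides: Mapping[str, float] | None = None) -> dict[str, float]:
        """Default parameters updated with ``overrides`` (names validated)."""
        p = dict(self.default_params)
        if overrides:
            unknown = set(as_mapping(overrides)) - set(self.param_names)
            if unknown:
                raise ValueError(f"unknown parameters for {self.name}: {sorted(unknown)}")
            p.update(as_mapping(overrides))
        return p

    def spec_for(self, name: str) -> ParameterSpec:
        for s in self.default_specs:
            if s.name == name:
                return s
        raise KeyError(f"{self.name} has no default sampling spec for {name!r}")


def _check_state(model: OdeModel, state: np.ndarray) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape[-1] != model.n_states:
        raise ValueError(
            f"state dimension {x.shape[-1]} != {model.n_states} for model {model.name}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite values")
    return x


def eval_rhs(
    model: OdeModel,
    state: np.ndarray,
    point: ParameterPoint | Mapping[str, float],
) -> np.ndarray:
    """Evaluate d(state)/dt. Pure; raises :class:`NumericsError` on NaN/inf."""
    x = _check_state(model, state)
    out = np.asarray(model.rhs(x, as_mapping(point)), dtype=float)
    if out.shape != x.shape:
        raise ValueError(f"rhs returned shape {out.shape}, expected {x.shape}")
    if not np.all(np.isfinite(out)):
        raise NumericsError(f"non-finite rhs for model {model.name}")
    return out


def finite_difference_jacobian(
    rhs: RhsFn, state: np.ndarray, params: Mapping[str, float]
) -> np.ndarray:
    """Central finite differences with per-coordinate step
    ``h_i = max(1e-7, 1e-7 * |state_i|)``."""
    x = np.asarray(state, dtype=float)
    n = x.shape[-1]
    h = np.maximum(1e-7, 1e-7 * np.abs(x))  # (..., n)
    # Perturbed states stacked on a new leading axis of size 2n: +h_j then -h_j.
    eye = np.eye(n)
    plus = x[..., None, :] + eye * h[..., None, :]
    minus = x[..., None, :] - eye * h[..., None, :]
    f_plus = np.asarray(rhs(plus, params), dtype=float)
    f_minus = np.asarray(rhs(minus, params), dtype=float)
    # d f_i / d x_j : (f_plus - f_minus)[..., j, i] / (2 h_j)
    jac = (f_plus - f_minus) / (2.0 * h[..., None])
    return np.swapaxes(jac, -1, -2)


def eval_jacobian(
    model: OdeModel,
    state: np.ndarray,
    point: ParameterPoint | Mapping[str, float],
) -> np.ndarray:
    """Evaluate d(rhs)/d(state), analytically when the model provides it,
    otherwise by central finite differences on :func:`eval_rhs`."""
    x = _check_state(model, state)
    p = as_mapping(point)
    if model.jacobian is not None:
        jac = np.asarray(model.jacobian(x, p), dtype=float)
    else:
        jac = finite_difference_jacobian(model.rhs, x, p)
    n = model.n_states
    if jac.shape[-2:] != (n, n):
        raise ValueError(f"jacobian shape {jac.shape} not square of dim {n}")
    if not np.all(np.isfinite(jac)):
        raise NumericsError(f"non-finite Jacobian for model {model.name}")
    return jac
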