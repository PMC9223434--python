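"""Core ODE machinery: model containers, simulation, and time-domain summaries.

A pathway model is an autonomous-or-driven ODE system

    dX/dt = F(X, P, u),    X(0) = X0,

with named states, named kinetic parameters P, an optional excitation u(t)
(e.g. an irradiation pulse or a cytokine stimulation), and one state
designated as the system output.  All sensitivity indices in this package
are built from areas under the curve (AUC) of simulated trajectories, so
this module also provides the shared quadrature helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ValidationError

__all__ = [
    "OdeModel",
    "SimulationConfig",
    "Trajectory",
    "PiecewiseConstant",
    "simulate",
    "auc",
]

#: RHS signature: (t, state_vector, parameter_map, excitation_value) -> derivatives
RhsFunc = Callable[[float, np.ndarray, Mapping[str, float], float], Sequence[float]]


class PiecewiseConstant:
    """Piecewise-constant excitation u(t).

    ``PiecewiseConstant([0, 10], [1.0, 0.0])`` is 1.0 on [0, 10) and 0.0
    afterwards — e.g. a stimulation pulse switched off at t = 10.
    """

    def __init__(self, breakpoints: Sequence[float], values: Sequence[float]):
        if len(breakpoints) != len(values):
            raise ValidationError("breakpoints and values must have equal length")
        bp = np.asarray(breakpoints, dtype=float)
        if bp.size == 0 or bp[0] != 0.0 or np.any(np.diff(bp) <= 0):
            raise ValidationError("breakpoints must start at 0 and increase strictly")
        self.breakpoints = bp
        self.values = np.asarray(values, dtype=float)

    def __call__(self, t: float) -> float:
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self.values[max(idx, 0)])


@dataclass
class OdeModel:
    """Named ODE pathway model.

    Parameters are kinetic rate constants in whatever units the model author
    chose; ``non_ranked_params`` lists parameters excluded from sensitivity
    analysis (Michaelis–Menten coefficients, saturation constants and other
    quantities that are not rates of targetable processes).
    """

    name: str
    state_names: list[str]
    param_names: list[str]
    nominal_params: dict[str, float]
    rhs: RhsFunc
    initial_state: np.ndarray
    output_variable: str
    excitation: Callable[[float], float] | None = None
    non_ranked_params: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        self.non_ranked_params = frozenset(self.non_ranked_params)
        if len(set(self.state_names)) != len(self.state_names):
            raise ValidationError(f"duplicate state names in model {self.name!r}")
        if len(set(self.param_names)) != len(self.param_names):
            raise ValidationError(f"duplicate parameter names in model {self.name!r}")
        if self.output_variable not in self.state_names:
            raise ValidationError(
                f"output_variable {self.output_variable!r} is not a state of {self.name!r}"
            )
        if not self.non_ranked_params <= set(self.param_names):
            unknown = self.non_ranked_params - set(self.param_names)
            raise ValidationError(f"non_ranked_params not in model: {sorted(unknown)}")
        missing = [p for p in self.param_names if p not in self.nominal_params]
        if missing:
            raise ValidationError(f"nominal value missing for parameters: {missing}")
        for p in self.param_names:
            v = self.nominal_params[p]
            if not np.isfinite(v):
                raise ValidationError(f"nominal value of {p!r} is not finite: {v}")
        if self.initial_state.shape != (len(self.state_names),):
            raise ValidationError(
                f"initial_state length {self.initial_state.shape} does not match "
                f"{len(self.state_names)} states"
            )

    @property
    def ranked_params(self) -> list[str]:
        """Parameters subject to sensitivity analysis, in declaration order."""
        return [p for p in self.param_names if p not in self.non_ranked_params]

    def output_index(self) -> int:
        return self.state_names.index(self.output_variable)


@dataclass
class SimulationConfig:
    """Solver settings shared across every simulation of one analysis.

    A single fixed output grid is used for the nominal and all perturbed
    runs, so response differences are computed pointwise without any
    interpolation.
    """

    horizon_T: float
    n_points: int = 1000
    time_grid: np.ndarray | None = None
    rtol: float = 1e-6
    atol: float = 1e-9
    stiff_solver: bool = True

    def __post_init__(self) -> None:
        if self.horizon_T <= 0:
            raise ValidationError(f"horizon_T must be > 0, got {self.horizon_T}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValidationError("solver tolerances must be > 0")
        if self.time_grid is not None:
            grid = np.asarray(self.time_grid, dtype=float)
            if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
                raise ValidationError("time_grid must be strictly increasing")
            if grid[0] != 0.0 or not np.isclose(grid[-1], self.horizon_T):
                raise ValidationError("time_grid must run from 0 to horizon_T")
            self.time_grid = grid
        elif self.n_points < 2:
            raise ValidationError("n_points must be >= 2")

    def grid(self) -> np.ndarray:
        if self.time_grid is not None:
            return self.time_grid
        return np.linspace(0.0, self.horizon_T, self.n_points)


@dataclass
class Trajectory:
    """One simulation result: a shared time grid and a (time x state) matrix."""

    times: np.ndarray
    states: np.ndarray
    state_names: list[str]
    model_name: str
    params_used: dict[str, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.state_names)):
            raise ValidationError(
                f"states shape {self.states.shape} inconsistent with "
                f"{self.times.size} times x {len(self.state_names)} states"
            )

    def variable(self, name: str) -> np.ndarray:
        """Time course of one named state."""
        try:
            idx = self.state_names.index(name)
        except ValueError:
            raise ValidationError(
                f"variable {name!r} not in trajectory states {self.state_names}"
            ) from None
        return self.states[:, idx]

    def to_frame(self):
        """Trajectory as a DataFrame with a time column (CSV export shape)."""
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{s: self.states[:, i] for i, s in enumerate(self.state_names)}}
        )


def simulate(
    model: OdeModel,
    params: Mapping[str, float],
    config: SimulationConfig,
) -> Trajectory:
    """Integrate the model on the configured output grid.

    ``params`` must cover every model parameter; it typically is the nominal
    map with a single entry multiplied by an alteration factor.  A stiff-
    capable solver is used by default because feedback pathway models
    routinely become stiff under strong parameter perturbations.

    Raises
    ------
    ValidationError
        if a parameter is missing.
    IntegrationError
        if the solver fails or produces non-finite states; the exception
        carries the offending parameter map.
    """
    missing = [p for p in model.param_names if p not in params]
    if missing:
        raise ValidationError(f"simulate: missing parameters {missing}")
    pmap = {p: float(params[p]) for p in model.param_names}
    u = model.excitation if model.excitation is not None else (lambda t: 0.0)

    def f(t, y):
        return np.asarray(model.rhs(t, y, pmap, u(t)), dtype=float)

    grid = config.grid()
    method = "LSODA" if config.stiff_solver else "RK45"
    sol = solve_ivp(
        f,
        (grid[0], grid[-1]),
        model.initial_state,
        method=method,
        t_eval=grid,
        rtol=config.rtol,
        atol=config.atol,
        dense_output=False,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"integration of model {model.name!r} failed: {sol.message}", params=pmap
        )
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        state_names=list(model.state_names),
        model_name=model.name,
        params_used=pmap,
    )


def auc(traj: Trajectory, variable: str, horizon_T: float | None = None) -> float:
    """Area under the curve of one state over [0, T], composite trapezoid.

    The grid is the trajectory's own output grid; ``horizon_T`` defaults to
    the trajectory end time and must not exceed it.
    """
    x = traj.variable(variable)
    t = traj.times
    if horizon_T is None:
        horizon_T = float(t[-1])
    if horizon_T > t[-1] + 1e-12:
        raise ValidationError(
            f"horizon_T={horizon_T} exceeds trajectory end time {t[-1]}"
        )
    mask = t <= horizon_T + 1e-12
    return float(np.trapezoid(x[mask], t[mask]))
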