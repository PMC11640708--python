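"""SIR and SCIR compartmental ODE models with bias-adjusted transmission.

Three deterministic models are provided:

* **SIR**: dS/dt = -beta*S*I, dI/dt = beta*S*I - gamma*I, dR/dt = gamma*I
  (optionally with the transmission term divided by N);
* **SCIR, confirmation variant**: an intermediate confirmed compartment C
  fed by transmission and drained at the confirmation rate alpha:
  dC/dt = beta*S*I - alpha*C, dI/dt = alpha*C - gamma*I;
* **SCIR, carrier variant**: identical structure with the carrier-to-
  infected rate named delta.  Transmission is driven by I (force
  -beta*S*I), which is the form that reproduces the reference state
  values for this model at 2-decimal precision.

Integration uses adaptive Runge-Kutta (Dormand-Prince 5(4)) with dense
output by default.  A ``"legacy-lsoda"`` method is provided that emulates
the classic default-tolerance LSODA setup ubiquitous in epidemiological
scripts; the two differ only in the exponentially small tail of S, where
values fall below any sensible absolute tolerance and become
solver-dependent (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

__all__ = [
    "EpiSummary",
    "SCIRCarrierParams",
    "SCIRConfirmParams",
    "SIRParams",
    "apply_bias_to_beta",
    "basic_reproduction_number",
    "integrate",
    "recovery_rate",
    "scir_carrier_derivs",
    "scir_confirm_derivs",
    "sensitivity_sweep",
    "sir_derivs",
    "summarize",
]


@dataclass(frozen=True)
class SIRParams:
    """SIR rates: beta (transmission), gamma (recovery), per unit time.

    ``normalised=True`` divides the transmission term by the total
    population N (frequency-dependent form); the default is the
    density-dependent form -beta*S*I.
    """

    beta: float
    gamma: float
    normalised: bool = False

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class SCIRConfirmParams:
    """SCIR confirmation-variant rates: beta, alpha (confirmation), gamma."""

    beta: float
    alpha: float
    gamma: float
    normalised: bool = False

    def __post_init__(self) -> None:
        if min(self.beta, self.alpha, self.gamma) < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class SCIRCarrierParams:
    """SCIR carrier-variant rates: beta (S->C), delta (C->I), gamma (I->R)."""

    beta: float
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.beta, self.delta, self.gamma) < 0:
            raise ValueError("rates must be >= 0")


def _check_state(state: Sequence[float], n: int) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (n,):
        raise ValueError(f"state must have {n} compartments, got shape {y.shape}")
    if np.any(y < 0):
        raise ValueError(f"state must be non-negative, got {y}")
    return y


def sir_derivs(state: Sequence[float], params: SIRParams) -> tuple[float, float, float]:
    """(dS/dt, dI/dt, dR/dt) for state (S, I, R)."""
    S, I, R = _check_state(state, 3)
    N = S + I + R if params.normalised else 1.0
    inf = params.beta * S * I / N
    rec = params.gamma * I
    return (-inf, inf - rec, rec)


def scir_confirm_derivs(
    state: Sequence[float], params: SCIRConfirmParams
) -> tuple[float, float, float, float]:
    """(dS, dC, dI, dR) for state (S, C, I, R), confirmation variant."""
    S, C, I, R = _check_state(state, 4)
    N = S + C + I + R if params.normalised else 1.0
    inf = params.beta * S * I / N
    conf = params.alpha * C
    rec = params.gamma * I
    return (-inf, inf - conf, conf - rec, rec)


def scir_carrier_derivs(
    state: Sequence[float], params: SCIRCarrierParams
) -> tuple[float, float, float, float]:
    """(dS, dC, dI, dR) for state (S, C, I, R), carrier variant."""
    S, C, I, R = _check_state(state, 4)
    inf = params.beta * S * I
    prog = params.delta * C
    rec = params.gamma * I
    return (-inf, inf - prog, prog - rec, rec)


def _rhs(params) -> tuple[Callable[[float, np.ndarray], list[float]], tuple[str, ...]]:
    """Unchecked right-hand side for the solver, plus compartment names."""
    if isinstance(params, SIRParams):
        def f(t, y):
            S, I, R = y
            N = S + I + R if params.normalised else 1.0
            inf = params.beta * S * I / N
            return [-inf, inf - params.gamma * I, params.gamma * I]
        return f, ("S", "I", "R")
    if isinstance(params, SCIRConfirmParams):
        def f(t, y):
            S, C, I, R = y
            N = S + C + I + R if params.normalised else 1.0
            inf = params.beta * S * I / N
            return [-inf, inf - params.alpha * C,
                    params.alpha * C - params.gamma * I, params.gamma * I]
        return f, ("S", "C", "I", "R")
    if isinstance(params, SCIRCarrierParams):
        def f(t, y):
            S, C, I, R = y
            inf = params.beta * S * I
            return [-inf, inf - params.delta * C,
                    params.delta * C - params.gamma * I, params.gamma * I]
        return f, ("S", "C", "I", "R")
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


#: Output-grid pitch of the legacy LSODA emulation (model time units).
LEGACY_GRID_STEP = 0.02


def integrate(
    params,
    init: Sequence[float],
    t_eval: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    t0: float = 0.0,
) -> pd.DataFrame:
    """Integrate a compartmental model and return states at ``t_eval``.

    Parameters
    ----------
    params:
        One of :class:`SIRParams`, :class:`SCIRConfirmParams`,
        :class:`SCIRCarrierParams`.
    init:
        Initial compartment values at ``t0`` (3 for SIR, 4 for SCIR).
    t_eval:
        Strictly increasing output times, all >= ``t0``.
    method:
        ``"RK45"`` (default; adaptive Dormand-Prince with dense output) or
        ``"legacy-lsoda"`` (classic default-tolerance LSODA on a uniform
        grid of pitch :data:`LEGACY_GRID_STEP`, emulating the historical
        odeint setup).

    Returns a DataFrame with columns ``t`` and the compartment names.
    Conservation of the total population is checked at every output time.
    """
    f, names = _rhs(params)
    y0 = _check_state(init, len(names))
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or len(t_eval) == 0:
        raise ValueError("t_eval must be a non-empty 1-D array")
    if np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    if t_eval[0] < t0:
        raise ValueError("t_eval must start at or after t0")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")

    if method == "legacy-lsoda":
        grid = np.round(
            np.arange(t0, t_eval[-1] + LEGACY_GRID_STEP / 2, LEGACY_GRID_STEP), 9
        )
        grid = np.union1d(grid, t_eval)
        ys = odeint(f, y0, grid, tfirst=True)
        sel = np.searchsorted(grid, t_eval)
        y_out = ys[sel].T
        cons_tol = 1e-6
    elif method in ("RK45", "DOP853", "LSODA", "Radau"):
        sol = solve_ivp(
            f, (t0, float(t_eval[-1])), y0, method=method,
            rtol=rtol, atol=atol, dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed at t={sol.t[-1]:.6g} with state {sol.y[:, -1]}: "
                f"{sol.message}"
            )
        y_out = sol.sol(t_eval)
        cons_tol = max(10.0 * atol, 1e-12)
    else:
        raise ValueError(f"unknown method {method!r}")

    n0 = float(y0.sum())
    drift = np.max(np.abs(y_out.sum(axis=0) - n0))
    if drift > cons_tol * max(1.0, n0):
        raise RuntimeError(f"conservation violated: max drift {drift:.3e}")

    data = {"t": t_eval}
    data.update({name: y_out[i] for i, name in enumerate(names)})
    return pd.DataFrame(data)


def apply_bias_to_beta(beta: float, bias_factor: float) -> float:
    """Effective transmission rate beta * (1 + b).

    A bias factor of -0.10 reduces transmission by 10%.
    """
    eff = beta * (1.0 + bias_factor)
    if eff < 0:
        raise ValueError(
            f"bias factor {bias_factor} drives beta={beta} negative"
        )
    return eff


def basic_reproduction_number(beta: float, gamma: float) -> float:
    """R0 = beta / gamma (average secondary infections)."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    return beta / gamma


def recovery_rate(total_recoveries: float, total_cases: float) -> float:
    """Total recoveries divided by total cases over a simulation.

    This is the trajectory-level summary ratio, not the per-capita rate
    gamma; it can exceed 1 when recoveries drain compartments (initial
    carriers) not counted as cases.
    """
    if total_cases == 0:
        raise ValueError("recovery rate undefined: total_cases is zero")
    return total_recoveries / total_cases


@dataclass(frozen=True)
class EpiSummary:
    """Trajectory-level totals for reporting."""

    total_cases: float
    total_recoveries: float
    recovery_rate: float
    bias_impact: float = 0.0


def _influx_into_I(traj: pd.DataFrame, params) -> np.ndarray:
    if isinstance(params, SIRParams):
        N = traj[["S", "I", "R"]].sum(axis=1).to_numpy() if params.normalised else 1.0
        return params.beta * traj["S"].to_numpy() * traj["I"].to_numpy() / N
    if isinstance(params, SCIRConfirmParams):
        return params.alpha * traj["C"].to_numpy()
    if isinstance(params, SCIRCarrierParams):
        return params.delta * traj["C"].to_numpy()
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def summarize(
    traj: pd.DataFrame,
    params,
    total_cases_def: str = "incidence",
    bias_impact: float = 0.0,
) -> EpiSummary:
    """Summarise a trajectory into totals and the recovery-rate ratio.

    ``total_cases_def="incidence"`` (default) counts the initial infected
    plus the integral of the flux into I (trapezoid over the trajectory);
    ``"cumulative_with_carrier"`` additionally counts the initial carrier
    pool.  Total recoveries are R(T) - R(0), the exact integral of
    gamma*I along the trajectory.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    t = traj["t"].to_numpy()
    total_recoveries = float(traj["R"].iloc[-1] - traj["R"].iloc[0])
    influx = np.broadcast_to(np.asarray(_influx_into_I(traj, params), dtype=float), t.shape)
    cases = float(traj["I"].iloc[0]) + float(np.trapezoid(influx, t))
    if total_cases_def == "cumulative_with_carrier":
        if "C" not in traj.columns:
            raise ValueError("no carrier compartment in this trajectory")
        cases += float(traj["C"].iloc[0])
    elif total_cases_def != "incidence":
        raise ValueError(f"unknown total_cases_def {total_cases_def!r}")
    return EpiSummary(
        total_cases=cases,
        total_recoveries=total_recoveries,
        recovery_rate=recovery_rate(total_recoveries, cases),
        bias_impact=bias_impact,
    )


def sensitivity_sweep(
    param_grid: Sequence,
    init: Sequence[float],
    t_eval: Sequence[float],
    **integrate_kwargs,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Integrate one trajectory per parameter configuration.

    Returns a summary table (one row per configuration, in grid order,
    with the endpoint state, summary totals and any recorded error) and a
    dict of trajectories keyed by row index.  A failing configuration is
    recorded in its row; the sweep continues.
    """
    if len(param_grid) == 0:
        raise ValueError("param_grid must be non-empty")
    rows = []
    trajectories: dict[int, pd.DataFrame] = {}
    for i, params in enumerate(param_grid):
        row: dict[str, object] = {"index": i}
        row.update(
            {k: v for k, v in vars(params).items() if not isinstance(v, bool)}
        )
        try:
            traj = integrate(params, init, t_eval, **integrate_kwargs)
            summ = summarize(traj, params)
            end = traj.iloc[-1]
            for col in traj.columns:
                if col != "t":
                    row[f"{col}_end"] = float(end[col])
            row["t_end"] = float(end["t"])
            row["total_cases"] = summ.total_cases
            row["total_recoveries"] = summ.total_recoveries
            row["recovery_rate"] = summ.recovery_rate
            row["error"] = None
            trajectories[i] = traj
        except (RuntimeError, ValueError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows), trajectories
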