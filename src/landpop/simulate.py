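"""Numerical integration of the model and trajectory summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    Derivatives,
    DomainError,
    ModelParameters,
    NumericalError,
    SystemState,
    agri_efficiency,
)

__all__ = [
    "Scenario",
    "Trajectory",
    "PeakSummary",
    "integrate",
    "integrate_rk4",
    "detect_peak",
    "relative_change",
]


@dataclass(frozen=True)
class Scenario:
    """A parameter set, initial state and time span to integrate."""

    params: ModelParameters
    initial: SystemState
    t_start: float
    t_end: float
    output_step: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise DomainError(f"t_end ({self.t_end}) must exceed t_start ({self.t_start})")
        if self.output_step <= 0:
            raise DomainError(f"output_step must be > 0, got {self.output_step}")
        self.initial.validate(L=self.params.L, tol=1e-6)

    def with_params(self, **changes: float) -> "Scenario":
        return Scenario(
            params=self.params.replace(**changes),
            initial=self.initial,
            t_start=self.t_start,
            t_end=self.t_end,
            output_step=self.output_step,
            label=self.label,
        )


@dataclass
class Trajectory:
    """States sampled on a uniform time grid, plus the scenario that made them."""

    t: np.ndarray
    N: np.ndarray
    A: np.ndarray
    D: np.ndarray
    H: np.ndarray
    scenario: Optional[Scenario] = field(default=None, repr=False)

    _VARS = ("N", "A", "D", "H")

    def __len__(self) -> int:
        return len(self.t)

    def variable(self, name: str) -> np.ndarray:
        if name not in self._VARS:
            raise KeyError(f"unknown variable {name!r}; expected one of {self._VARS}")
        return getattr(self, name)

    def state_at(self, index: int) -> SystemState:
        return SystemState(
            N=float(self.N[index]), A=float(self.A[index]), D=float(self.D[index]),
            H=float(self.H[index]), t=float(self.t[index]),
        )

    def value_at(self, name: str, time: float) -> float:
        """Linear interpolation of one variable at an arbitrary time."""
        if not (self.t[0] <= time <= self.t[-1]):
            raise DomainError(f"time {time} outside trajectory span [{self.t[0]}, {self.t[-1]}]")
        return float(np.interp(time, self.t, self.variable(name)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.t, "N": self.N, "A": self.A, "D": self.D, "H": self.H}
        )

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# columns: year, N, A, D, H\n")
            fh.write("# units: year CE; N, A, D in billion ha; H in billion individuals\n")
            self.to_frame().to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, comment="#")
        return cls(
            t=df["year"].to_numpy(float),
            N=df["N"].to_numpy(float),
            A=df["A"].to_numpy(float),
            D=df["D"].to_numpy(float),
            H=df["H"].to_numpy(float),
        )


@dataclass(frozen=True)
class PeakSummary:
    """Location and size of a trajectory peak, and the decline that follows it."""

    variable: str
    t_peak: float
    peak_value: float
    decline_fraction_50y: Optional[float]
    exists_interior_peak: bool


def _rhs(t: float, y: np.ndarray, p: ModelParameters, cap: bool) -> list[float]:
    # Pools are clipped at zero for evaluation: every sink is proportional to
    # its own pool, so the true solution never goes negative and tiny solver
    # undershoots must not inject mass.
    N = y[0] if y[0] > 0.0 else 0.0
    A = y[1] if y[1] > 0.0 else 0.0
    D = y[2] if y[2] > 0.0 else 0.0
    H = y[3] if y[3] > 0.0 else 0.0

    L = p.L
    u_na = p.eta_N * H - (1.0 - p.p_N) * N - p.eta_A * H + (1.0 - p.p_A) * A
    u_na = u_na / L if u_na > 0.0 else 0.0
    u_nd = p.eta_N * H - (1.0 - p.p_N) * N
    u_nd = u_nd / L if u_nd > 0.0 else 0.0
    u_a = p.eta_A * H - (1.0 - p.p_A) * A
    u_a = u_a / L if u_a > 0.0 else 0.0

    conv_AtoN = p.c_NA * u_na * H * A
    conv_DtoN = p.c_ND * u_nd * H * D
    conv_NtoA = p.c_AN * u_a * N * H
    conv_DtoA = p.c_AD * u_a * H * D

    dN = conv_AtoN + conv_DtoN - conv_NtoA - p.d_N * H * N - p.delta_N * N + p.r * D
    dA = (
        conv_NtoA + conv_DtoA - conv_AtoN
        - p.d_A * math.exp(-N / p.N_th) * H * A
        - p.delta_A * A
    )

    eps_A = p.E_A - p.phi * (p.N_th - N)
    if eps_A < 0.0:
        eps_A = 0.0
    if cap and eps_A > p.E_A:
        eps_A = p.E_A
    recruitment = p.b * math.exp(-p.beta * p.eta_N) * (
        1.0 - math.exp(-p.q_N * N - p.q_A * A)
    )
    mort_arg = p.q * (p.eta_N * H - p.E_N * N + p.eta_A * H - eps_A * A)
    if mort_arg > 700.0:
        raise NumericalError(
            f"mortality term m*exp(...) overflowed at t={t:.3f}: exponent {mort_arg:.6g}"
        )
    dH = (recruitment - p.m * math.exp(mort_arg)) * H

    return [dN, dA, -(dN + dA), dH]


def integrate(
    scenario: Scenario,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    cap_efficiency: bool = False,
) -> Trajectory:
    """Integrate the model with an adaptive Runge-Kutta 4(5) solver.

    Output is sampled every ``scenario.output_step`` years.  Land-pool
    conservation and non-negativity are verified on the output grid;
    small negative excursions (within solver tolerance) are clipped to
    zero, anything larger aborts with a diagnostic.
    """
    s0 = scenario.initial
    y0 = [s0.N, s0.A, s0.D, s0.H]
    n_steps = int(round((scenario.t_end - scenario.t_start) / scenario.output_step))
    t_eval = scenario.t_start + scenario.output_step * np.arange(n_steps + 1)
    if t_eval[-1] > scenario.t_end:  # guard against round-off past the span
        t_eval[-1] = scenario.t_end

    sol = solve_ivp(
        _rhs,
        (scenario.t_start, scenario.t_end),
        y0,
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        args=(scenario.params, cap_efficiency),
        dense_output=False,
    )
    if not sol.success:
        raise NumericalError(f"integration failed ({scenario.label or 'scenario'}): {sol.message}")

    y = sol.y
    neg_tol = 100.0 * (atol + rtol * scenario.params.L)
    worst = y.min()
    if worst < -neg_tol:
        idx = np.unravel_index(np.argmin(y), y.shape)
        raise NumericalError(
            f"state went negative beyond tolerance: variable {'NADH'[idx[0]]} = {worst:.3e} "
            f"at t = {sol.t[idx[1]]:.2f}"
        )
    y = np.clip(y, 0.0, None)

    cons = np.abs(y[0] + y[1] + y[2] - scenario.params.L)
    cons_tol = 10.0 * (atol + rtol * scenario.params.L)
    if cons.max() > cons_tol:
        i = int(np.argmax(cons))
        raise NumericalError(
            f"land conservation violated: |N+A+D-L| = {cons.max():.3e} at t = {sol.t[i]:.2f}"
        )

    return Trajectory(t=sol.t, N=y[0], A=y[1], D=y[2], H=y[3], scenario=scenario)


def integrate_rk4(
    scenario: Scenario, step: float = 0.01, cap_efficiency: bool = False
) -> Trajectory:
    """Fixed-step classical Runge-Kutta integration.

    Slow but simple; serves as an independent cross-check of
    :func:`integrate`.  Output is still sampled at ``output_step``, which
    must be an integer multiple of ``step``.
    """
    ratio = scenario.output_step / step
    if abs(ratio - round(ratio)) > 1e-9:
        raise DomainError("output_step must be an integer multiple of the RK4 step")
    per_output = int(round(ratio))

    s0 = scenario.initial
    y = np.array([s0.N, s0.A, s0.D, s0.H], dtype=float)
    p, cap = scenario.params, cap_efficiency

    n_out = int(round((scenario.t_end - scenario.t_start) / scenario.output_step))
    t_out = scenario.t_start + scenario.output_step * np.arange(n_out + 1)
    out = np.empty((4, n_out + 1))
    out[:, 0] = y

    t = scenario.t_start
    h = step
    for i in range(1, n_out + 1):
        for _ in range(per_output):
            k1 = np.asarray(_rhs(t, y, p, cap))
            k2 = np.asarray(_rhs(t + 0.5 * h, y + 0.5 * h * k1, p, cap))
            k3 = np.asarray(_rhs(t + 0.5 * h, y + 0.5 * h * k2, p, cap))
            k4 = np.asarray(_rhs(t + h, y + h * k3, p, cap))
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        out[:, i] = y

    out = np.clip(out, 0.0, None)
    return Trajectory(t=t_out, N=out[0], A=out[1], D=out[2], H=out[3], scenario=scenario)


def detect_peak(traj: Trajectory, variable: str) -> PeakSummary:
    """First interior local maximum of one variable, refined by a parabola.

    If the series is monotone (no interior maximum) the boundary maximum
    is reported with ``exists_interior_peak=False``.  The fractional
    decline over the 50 years after the peak is reported whenever the
    trajectory extends that far.
    """
    y = traj.variable(variable)
    t = traj.t
    if len(y) < 3:
        raise DomainError("peak detection needs at least 3 samples")

    i_peak = None
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            i_peak = i
            break

    if i_peak is None:
        i_best = int(np.argmax(y))
        t_peak, peak = float(t[i_best]), float(y[i_best])
        interior = False
    else:
        # Quadratic through the three bracketing samples; uniform grid.
        ym, y0, yp = y[i_peak - 1], y[i_peak], y[i_peak + 1]
        denom = ym - 2.0 * y0 + yp
        if denom < 0.0:
            offset = 0.5 * (ym - yp) / denom
            dt = t[i_peak] - t[i_peak - 1]
            t_peak = float(t[i_peak] + offset * dt)
            peak = float(y0 - 0.25 * (ym - yp) * offset)
        else:  # flat-topped: keep the grid point
            t_peak, peak = float(t[i_peak]), float(y0)
        interior = True

    decline = None
    if t_peak + 50.0 <= t[-1] and peak != 0.0:
        later = float(np.interp(t_peak + 50.0, t, y))
        decline = (peak - later) / peak

    return PeakSummary(
        variable=variable,
        t_peak=t_peak,
        peak_value=peak,
        decline_fraction_50y=decline,
        exists_interior_peak=interior,
    )


def relative_change(traj: Trajectory, variable: str, t0: float, t1: float) -> float:
    """Fractional change ``(x(t1) - x(t0)) / x(t0)`` with linear interpolation."""
    x0 = traj.value_at(variable, t0)
    x1 = traj.value_at(variable, t1)
    if x0 == 0.0:
        raise DomainError(f"relative change undefined: {variable}({t0}) = 0")
    return (x1 - x0) / x0
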