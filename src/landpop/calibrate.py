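"""Trajectory-matching calibration of model parameters to observed series.

The observed data are yearly global human population ``H`` (billions) and
intensive agricultural area ``A`` (Gha); optionally ``N`` and ``D``.  A
candidate parameter vector is scored by integrating the model over the
observation window, starting from the first observed ``H`` and ``A`` (the
natural-land share of the remaining area is a configuration input, since
it is not directly observed), and summing squared *relative* residuals —
relative, because ``H`` and ``A`` live on different scales.

Fitting is bounded local least squares from a deterministic Latin-
hypercube multi-start, so results are reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import DomainError, ModelParameters, SystemState
from .simulate import Scenario, Trajectory, integrate

__all__ = ["ObservedSeries", "CalibrationResult", "loss", "fit_parameters",
           "profile_loss"]

#: Residual magnitude substituted when integration fails or blows up.
PENALTY_RESIDUAL = 1e6

#: Names accepted in the free set besides model parameters.
INITIAL_CONDITION_NAMES = ("N0",)


@dataclass
class ObservedSeries:
    """Year-indexed observations used for calibration."""

    years: np.ndarray
    H_obs: np.ndarray
    A_obs: np.ndarray
    N_obs: Optional[np.ndarray] = None
    D_obs: Optional[np.ndarray] = None
    noise_sd: Optional[Mapping[str, float]] = None
    truth: Optional[dict] = field(default=None, repr=False)  # for synthetic data

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.H_obs = np.asarray(self.H_obs, dtype=float)
        self.A_obs = np.asarray(self.A_obs, dtype=float)
        if self.N_obs is not None:
            self.N_obs = np.asarray(self.N_obs, dtype=float)
        if self.D_obs is not None:
            self.D_obs = np.asarray(self.D_obs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.years) < 5:
            raise DomainError(f"need at least 5 observations, got {len(self.years)}")
        if not np.all(np.diff(self.years) > 0):
            raise DomainError("observation years must be strictly increasing")
        for name in ("H_obs", "A_obs", "N_obs", "D_obs"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if len(arr) != len(self.years):
                raise DomainError(f"{name} length {len(arr)} != number of years {len(self.years)}")
            if not np.all(arr > 0):
                raise DomainError(f"all {name} values must be > 0")

    def observed_variables(self) -> list[str]:
        out = ["H", "A"]
        if self.N_obs is not None:
            out.append("N")
        if self.D_obs is not None:
            out.append("D")
        return out

    def values(self, variable: str) -> np.ndarray:
        arr = getattr(self, f"{variable}_obs")
        if arr is None:
            raise KeyError(f"variable {variable!r} not observed")
        return arr

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "H": self.H_obs, "A": self.A_obs}
        if self.N_obs is not None:
            data["N"] = self.N_obs
        if self.D_obs is not None:
            data["D"] = self.D_obs
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# units: year CE; H in billion individuals; N, A, D in billion ha\n")
            self.to_frame().to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def read_csv(cls, path) -> "ObservedSeries":
        df = pd.read_csv(path, comment="#")
        return cls(
            years=df["year"].to_numpy(float),
            H_obs=df["H"].to_numpy(float),
            A_obs=df["A"].to_numpy(float),
            N_obs=df["N"].to_numpy(float) if "N" in df.columns else None,
            D_obs=df["D"].to_numpy(float) if "D" in df.columns else None,
        )


@dataclass
class CalibrationResult:
    """Outcome of a bounded multi-start least-squares fit."""

    params: ModelParameters
    free_names: tuple[str, ...]
    fitted: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    loss: float
    rms_residuals: dict[str, float]
    converged: bool
    n_evaluations: int
    N0: Optional[float] = None


def _initial_state(data: ObservedSeries, params: ModelParameters, N0: float) -> SystemState:
    """First-row initial state: observed H and A, configured N, D as the remainder."""
    A0, H0 = float(data.A_obs[0]), float(data.H_obs[0])
    D0 = params.L - N0 - A0
    if D0 < 0:
        raise DomainError(f"N0 + A(first year) = {N0 + A0} exceeds L = {params.L}")
    return SystemState(N=N0, A=A0, D=D0, H=H0, t=float(data.years[0]))


def _simulate_at_observations(
    params: ModelParameters, data: ObservedSeries, N0: float
) -> Trajectory:
    scen = Scenario(
        params=params,
        initial=_initial_state(data, params, N0),
        t_start=float(data.years[0]),
        t_end=float(data.years[-1]),
        output_step=1.0,
        label="calibration",
    )
    return integrate(scen)


def _residual_vector(
    params: ModelParameters,
    data: ObservedSeries,
    N0: float,
    weights: Optional[Mapping[str, float]],
) -> np.ndarray:
    """Weighted relative residuals, flattened over variables and years.

    Any integration failure maps to a constant penalty vector so that
    optimizers see a large but finite, well-defined objective.
    """
    variables = data.observed_variables()
    n = len(data.years) * len(variables)
    try:
        traj = _simulate_at_observations(params, data, N0)
    except (DomainError, ArithmeticError, ValueError):
        return np.full(n, PENALTY_RESIDUAL)

    res = []
    for v in variables:
        w = 1.0 if weights is None else float(weights.get(v, 1.0))
        model = np.interp(data.years, traj.t, traj.variable(v))
        res.append(math.sqrt(w) * (model - data.values(v)) / data.values(v))
    out = np.concatenate(res)
    if not np.all(np.isfinite(out)):
        return np.full(n, PENALTY_RESIDUAL)
    return out


def _apply_free(
    base: ModelParameters,
    free_names: Sequence[str],
    free_values: Sequence[float],
    N0_default: float,
) -> tuple[ModelParameters, float]:
    if len(free_names) != len(free_values):
        raise DomainError("free_names and free_values must have equal length")
    changes = {}
    N0 = N0_default
    for name, value in zip(free_names, free_values):
        if name in INITIAL_CONDITION_NAMES:
            N0 = float(value)
        else:
            changes[name] = float(value)
    params = base.replace(**changes) if changes else base
    return params, N0


def loss(
    params: ModelParameters,
    free_names: Sequence[str],
    free_values: Sequence[float],
    data: ObservedSeries,
    weights: Optional[Mapping[str, float]] = None,
    N0: Optional[float] = None,
) -> float:
    """Weighted sum of squared relative residuals for one candidate.

    ``free_values`` overrides the parameters named in ``free_names`` on
    top of ``params`` (the name ``"N0"`` targets the initial natural-land
    area).  A failed integration returns a large finite penalty.
    """
    if N0 is None:
        N0 = default_N0(params, data)
    p, n0 = _apply_free(params, free_names, free_values, N0)
    r = _residual_vector(p, data, n0, weights)
    return float(np.dot(r, r))


def default_N0(params: ModelParameters, data: ObservedSeries) -> float:
    """Initial natural land: observed if available, else 60% of the non-A remainder.

    N(start) is not directly observed in the historical record; when the
    series does not carry it, a documented convention is used and can be
    overridden by passing ``N0`` explicitly (or fitting it).
    """
    if data.N_obs is not None:
        return float(data.N_obs[0])
    return 0.6 * (params.L - float(data.A_obs[0]))


def fit_parameters(
    data: ObservedSeries,
    free: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    fixed: ModelParameters,
    seed: int,
    n_starts: int = 5,
    weights: Optional[Mapping[str, float]] = None,
    N0: Optional[float] = None,
) -> CalibrationResult:
    """Bounded least-squares fit of the named free parameters.

    Starts are a Latin-hypercube sample over the bounds (deterministic
    given ``seed``) plus the bound midpoint; each start is refined with a
    trust-region-reflective least-squares solve and the best local
    optimum is returned.  With an empty free set, the fixed parameters
    are evaluated and returned without optimization.
    """
    free = tuple(free)
    for name in free:
        if name not in bounds:
            raise DomainError(f"no bounds given for free parameter {name!r}")
    if len(free) > 8:
        raise DomainError("at most 8 free parameters are supported")
    if N0 is None:
        N0 = default_N0(fixed, data)

    def rms_by_variable(p: ModelParameters, n0: float) -> dict[str, float]:
        out = {}
        try:
            traj = _simulate_at_observations(p, data, n0)
        except (DomainError, ArithmeticError, ValueError):
            return {v: float("inf") for v in data.observed_variables()}
        for v in data.observed_variables():
            model = np.interp(data.years, traj.t, traj.variable(v))
            rel = (model - data.values(v)) / data.values(v)
            out[v] = float(np.sqrt(np.mean(rel**2)))
        return out

    if not free:
        r = _residual_vector(fixed, data, N0, weights)
        return CalibrationResult(
            params=fixed, free_names=(), fitted={}, bounds={},
            loss=float(np.dot(r, r)), rms_residuals=rms_by_variable(fixed, N0),
            converged=True, n_evaluations=1, N0=N0,
        )

    lo = np.array([bounds[name][0] for name in free], dtype=float)
    hi = np.array([bounds[name][1] for name in free], dtype=float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)) or np.any(lo >= hi):
        raise DomainError("bounds must be finite with lower < upper")

    n_eval = 0

    def objective(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        p, n0 = _apply_free(fixed, free, x, N0)
        return _residual_vector(p, data, n0, weights)

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = [lo + (hi - lo) * row for row in sampler.random(max(0, n_starts - 1))]
    starts.insert(0, 0.5 * (lo + hi))

    best = None
    any_converged = False
    for x0 in starts:
        try:
            sol = least_squares(
                objective, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300 * len(free),
            )
        except (DomainError, ArithmeticError, ValueError):
            continue
        cost = 2.0 * sol.cost  # least_squares cost is 0.5 * sum(res^2)
        if best is None or cost < best[0]:
            best = (cost, sol)
        any_converged = any_converged or bool(sol.success)

    if best is None:  # every start failed outright
        r = _residual_vector(fixed, data, N0, weights)
        return CalibrationResult(
            params=fixed, free_names=free, fitted={},
            bounds={name: tuple(bounds[name]) for name in free},
            loss=float(np.dot(r, r)), rms_residuals=rms_by_variable(fixed, N0),
            converged=False, n_evaluations=n_eval, N0=N0,
        )

    cost, sol = best
    params_fit, N0_fit = _apply_free(fixed, free, sol.x, N0)
    return CalibrationResult(
        params=params_fit,
        free_names=free,
        fitted={name: float(v) for name, v in zip(free, sol.x)},
        bounds={name: tuple(bounds[name]) for name in free},
        loss=float(cost),
        rms_residuals=rms_by_variable(params_fit, N0_fit),
        converged=any_converged,
        n_evaluations=n_eval,
        N0=N0_fit,
    )


def profile_loss(
    data: ObservedSeries,
    name: str,
    values: Sequence[float],
    fixed: ModelParameters,
    weights: Optional[Mapping[str, float]] = None,
    N0: Optional[float] = None,
) -> pd.DataFrame:
    """Loss along a 1-D slice of one parameter, all others held fixed.

    An identifiability diagnostic, not an inference: a flat profile means
    the data do not constrain the parameter along this slice.  Returns a
    frame with columns ``value`` and ``loss``.
    """
    rows = [
        {"value": float(v), "loss": loss(fixed, [name], [v], data,
                                         weights=weights, N0=N0)}
        for v in values
    ]
    return pd.DataFrame(rows)
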