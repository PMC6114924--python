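"""Scenario analyses: equilibria, tipping points, parameter planes and sweeps.

These are the headline analyses of the model: where does the coupled
system settle, at what natural-land area does the human population tip
into sustained decline, how do perception biases (p_N, p_A) shape the
long-run population, and how do proactive (d_N) versus reactive (c_ND)
land-use choices bound the range of outcomes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import DomainError, ModelParameters, SystemState, derivatives
from .simulate import Scenario, Trajectory, detect_peak, integrate

__all__ = [
    "EquilibriumPoint",
    "TippingResult",
    "SweepResult",
    "find_equilibria",
    "tipping_onset",
    "perception_plane",
    "proactive_reactive_grid",
    "key_factor_sweep",
]


@dataclass(frozen=True)
class EquilibriumPoint:
    """A root of the reduced (N, A, H) system, with a stability label."""

    state: SystemState
    residual_norm: float
    stability: str  # "stable" | "unstable" | "marginal"
    eigenvalues: tuple[complex, ...] = ()
    basin: Optional[str] = None


@dataclass(frozen=True)
class TippingResult:
    """Natural-land area at the onset of sustained human-population decline."""

    detected: bool
    t_onset: Optional[float] = None
    N_at_decline_onset: Optional[float] = None
    scenario_label: str = ""


@dataclass
class SweepResult:
    """Gridded scenario outcomes over one or two parameter axes."""

    axes: dict[str, np.ndarray]          # axis name -> grid values
    metrics: dict[str, np.ndarray]       # metric name -> array, shape = grid shape
    converged: np.ndarray                # bool array, grid shape
    tipping: np.ndarray                  # object array of TippingResult
    envelopes: Optional[dict] = field(default=None, repr=False)
    settings: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.axes.values())

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per grid cell."""
        names = list(self.axes)
        grids = np.meshgrid(*self.axes.values(), indexing="ij")
        data = {n: g.ravel() for n, g in zip(names, grids)}
        for mname, arr in self.metrics.items():
            data[mname] = np.asarray(arr, dtype=float).ravel()
        data["converged"] = self.converged.ravel()
        tip = self.tipping.ravel()
        data["tipping_detected"] = [t.detected if t else False for t in tip]
        data["tipping_year"] = [t.t_onset if t and t.detected else np.nan for t in tip]
        data["N_at_tipping"] = [
            t.N_at_decline_onset if t and t.detected else np.nan for t in tip
        ]
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        """Long-format CSV plus a JSON sidecar with grids and settings."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, lineterminator="\n")
        sidecar = {
            "axes": {k: list(map(float, v)) for k, v in self.axes.items()},
            "metrics": sorted(self.metrics),
            "settings": self.settings,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# equilibria

def _reduced_rhs(x: np.ndarray, params: ModelParameters) -> np.ndarray:
    """RHS of the reduced system in (N, A, H) with D = L - N - A eliminated.

    Outside the physical domain the state is clipped for evaluation and a
    continuous restoring term proportional to the violation is added, so
    boundary equilibria (pools exactly at zero) remain reachable roots.
    """
    N, A, H = x
    D = params.L - N - A
    Nc, Ac, Hc = max(N, 0.0), max(A, 0.0), max(H, 0.0)
    Dc = max(params.L - Nc - Ac, 0.0)
    d = derivatives(SystemState(N=Nc, A=Ac, D=Dc, H=Hc), params)
    v_D = max(0.0, -D)
    return np.array([
        d.dN - min(N, 0.0) + v_D,
        d.dA - min(A, 0.0) + v_D,
        d.dH - min(H, 0.0),
    ])


def _jacobian_fd(x: np.ndarray, params: ModelParameters, h: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the reduced system.

    Central differences, falling back to one-sided steps at the domain
    boundary so probes never leave the physical region.
    """
    n = len(x)
    L = params.L
    J = np.empty((n, n))
    for j in range(n):
        step = h * max(1.0, abs(x[j]))
        minus_ok = x[j] - step >= 0.0
        plus_ok = j == 2 or (x[0] + x[1] + step <= L)
        xp, xm = x.copy(), x.copy()
        if plus_ok or not minus_ok:
            xp[j] += step
        if minus_ok or not plus_ok:
            xm[j] -= step
        J[:, j] = (_reduced_rhs(xp, params) - _reduced_rhs(xm, params)) / (xp[j] - xm[j])
    return J


def find_equilibria(
    params: ModelParameters,
    starts: Sequence[SystemState],
    tol: float = 1e-9,
    dedupe_tol: float = 1e-6,
    eig_tol: float = 1e-8,
) -> list[EquilibriumPoint]:
    """Root-find the reduced 3-variable system from each start.

    Converged roots are deduplicated and labelled stable/unstable/marginal
    by the dominant eigenvalue of a finite-difference Jacobian.  Returns
    an empty list when no start converges.
    """
    if not starts:
        raise DomainError("at least one start state is required")
    scale = max(1.0, params.L)
    found: list[EquilibriumPoint] = []
    for s in starts:
        x0 = np.array([s.N, s.A, s.H], dtype=float)
        sol = root(_reduced_rhs, x0, args=(params,), method="hybr", tol=1e-12)
        x = sol.x
        res = np.linalg.norm(_reduced_rhs(x, params))
        if res > tol:
            continue
        # Clip solver-level negatives; reject genuinely negative roots.
        x = np.where(np.abs(x) < 10 * tol, np.abs(x) * 0.0, x)
        D = params.L - x[0] - x[1]
        if min(x[0], x[1], x[2], D) < -10 * tol:
            continue
        x = np.clip(x, 0.0, None)
        D = max(0.0, params.L - x[0] - x[1])
        if any(np.linalg.norm(x - np.array([e.state.N, e.state.A, e.state.H]))
               < dedupe_tol * scale for e in found):
            continue
        eig = np.linalg.eigvals(_jacobian_fd(x, params))
        lead = float(np.max(eig.real))
        if lead < -eig_tol:
            stability = "stable"
        elif lead > eig_tol:
            stability = "unstable"
        else:
            stability = "marginal"
        found.append(
            EquilibriumPoint(
                state=SystemState(N=float(x[0]), A=float(x[1]), D=float(D),
                                  H=float(x[2])),
                residual_norm=float(res),
                stability=stability,
                eigenvalues=tuple(complex(v) for v in eig),
            )
        )
    return found


# ---------------------------------------------------------------------------
# tipping

def tipping_onset(traj: Trajectory, sustain_years: float = 5.0) -> TippingResult:
    """Detect the onset of sustained human-population decline.

    Onset is the first interior maximum of H that is followed by strictly
    decreasing samples for at least ``sustain_years`` years.  The natural
    land area at that moment is the tipping-point diagnostic.
    """
    H, t = traj.H, traj.t
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    n_sustain = max(1, int(round(sustain_years / dt)))
    for i in range(1, len(H) - 1):
        if not (H[i] > H[i - 1] and H[i] >= H[i + 1]):
            continue
        j_end = i + n_sustain
        if j_end >= len(H):
            break
        window = H[i : j_end + 1]
        if np.all(np.diff(window) < 0):
            return TippingResult(
                detected=True,
                t_onset=float(t[i]),
                N_at_decline_onset=float(traj.N[i]),
                scenario_label=traj.scenario.label if traj.scenario else "",
            )
    return TippingResult(detected=False,
                         scenario_label=traj.scenario.label if traj.scenario else "")


# ---------------------------------------------------------------------------
# sweep helpers

def _extended(base: Scenario, params: ModelParameters, horizon: float) -> Scenario:
    return Scenario(
        params=params,
        initial=base.initial,
        t_start=base.t_start,
        t_end=base.t_start + horizon,
        output_step=base.output_step,
        label=base.label,
    )


def _cell_metrics(traj: Trajectory) -> tuple[dict[str, float], TippingResult]:
    peak = detect_peak(traj, "H")
    tip = tipping_onset(traj)
    return (
        {
            "late_H": float(traj.H[-1]),
            "peak_H": float(peak.peak_value),
            "final_N": float(traj.N[-1]),
            "final_A": float(traj.A[-1]),
        },
        tip,
    )


def _run_grid(
    axes: dict[str, np.ndarray], base: Scenario, horizon: float,
    keep_series: bool = False,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, dict]:
    names = list(axes)
    shape = tuple(len(v) for v in axes.values())
    metrics = {
        k: np.full(shape, np.nan)
        for k in ("late_H", "peak_H", "final_N", "final_A")
    }
    converged = np.zeros(shape, dtype=bool)
    tipping = np.empty(shape, dtype=object)
    series: dict[tuple, Trajectory] = {}
    for idx in itertools.product(*(range(n) for n in shape)):
        overrides = {name: float(axes[name][i]) for name, i in zip(names, idx)}
        try:
            traj = integrate(_extended(base, base.params.replace(**overrides), horizon))
        except (DomainError, ArithmeticError, ValueError):
            tipping[idx] = TippingResult(detected=False)
            continue
        cell, tip = _cell_metrics(traj)
        for k, v in cell.items():
            metrics[k][idx] = v
        tipping[idx] = tip
        converged[idx] = True
        if keep_series:
            series[idx] = traj
    return metrics, converged, tipping, series


# ---------------------------------------------------------------------------
# headline sweeps

def perception_plane(
    p_N_grid: Sequence[float],
    p_A_grid: Sequence[float],
    base: Scenario,
    horizon: float = 1000.0,
) -> SweepResult:
    """Long-horizon outcomes over the (p_N, p_A) perception-bias plane.

    ``late_H`` — the population at the end of the horizon — serves as the
    equilibrium proxy: some cells are still drifting at century scale, so
    a fixed long horizon is comparable across the plane where a root
    finder would not be.
    """
    axes = {"p_N": np.asarray(p_N_grid, float), "p_A": np.asarray(p_A_grid, float)}
    if any(len(v) == 0 for v in axes.values()):
        raise DomainError("grids must be non-empty")
    if any((v < 0).any() or (v > 1).any() for v in axes.values()):
        raise DomainError("perception weights must lie in [0, 1]")
    metrics, converged, tipping, _ = _run_grid(axes, base, horizon)
    return SweepResult(
        axes=axes, metrics=metrics, converged=converged, tipping=tipping,
        settings={"horizon": horizon, "base_label": base.label},
    )


def proactive_reactive_grid(
    d_N_values: Sequence[float],
    c_ND_values: Sequence[float],
    base: Scenario,
    horizon: float = 160.0,
) -> SweepResult:
    """Outcomes over proactive (d_N) x reactive (c_ND) choices, with envelopes.

    For each proactive level d_N the envelope is the pointwise min/max
    over the reactive axis of the H(t) and N(t) series — the range of
    futures still reachable once the proactive decision is made.
    """
    axes = {"d_N": np.asarray(d_N_values, float), "c_ND": np.asarray(c_ND_values, float)}
    if any(len(v) == 0 for v in axes.values()):
        raise DomainError("grids must be non-empty")
    metrics, converged, tipping, series = _run_grid(axes, base, horizon, keep_series=True)

    envelopes: dict[float, dict[str, np.ndarray]] = {}
    for i, dn in enumerate(axes["d_N"]):
        rows = [series[(i, j)] for j in range(len(axes["c_ND"])) if (i, j) in series]
        if not rows:
            continue
        t = rows[0].t
        Hs = np.vstack([r.H for r in rows])
        Ns = np.vstack([r.N for r in rows])
        envelopes[float(dn)] = {
            "t": t,
            "H_min": Hs.min(axis=0), "H_max": Hs.max(axis=0),
            "N_min": Ns.min(axis=0), "N_max": Ns.max(axis=0),
        }
    return SweepResult(
        axes=axes, metrics=metrics, converged=converged, tipping=tipping,
        envelopes=envelopes,
        settings={"horizon": horizon, "base_label": base.label},
    )


SWEEPABLE = ("N_th", "E_A", "q", "c_ND", "d_N", "eta_N", "eta_A")


def key_factor_sweep(
    param_name: str,
    values: Sequence[float],
    base: Scenario,
    horizon: float = 160.0,
    divergence_fraction: float = 0.05,
) -> SweepResult:
    """1D sweep of one of the high-impact parameters.

    Adds ``divergence_year`` per cell: the first output year at which the
    swept trajectory's H departs from the base trajectory's H by more
    than ``divergence_fraction`` (NaN if it never does) — the horizon at
    which the parameter choice starts to matter.
    """
    if param_name not in SWEEPABLE:
        raise DomainError(f"{param_name!r} is not a sweepable key factor {SWEEPABLE}")
    axes = {param_name: np.asarray(values, float)}
    if len(axes[param_name]) == 0:
        raise DomainError("values must be non-empty")
    metrics, converged, tipping, series = _run_grid(axes, base, horizon, keep_series=True)

    base_traj = integrate(_extended(base, base.params, horizon))
    divergence = np.full(len(axes[param_name]), np.nan)
    for (i,), traj in ((k, v) for k, v in series.items()):
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(traj.H - base_traj.H) / np.where(base_traj.H > 0, base_traj.H, np.nan)
        hits = np.nonzero(rel > divergence_fraction)[0]
        if hits.size:
            divergence[i] = float(base_traj.t[hits[0]])
    metrics["divergence_year"] = divergence
    return SweepResult(
        axes=axes, metrics=metrics, converged=converged, tipping=tipping,
        settings={
            "horizon": horizon,
            "divergence_fraction": divergence_fraction,
            "base_label": base.label,
        },
    )
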