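"""Synthetic observation series with known ground truth.

Generates what the calibration stage assumes the real world produced: a
model-true trajectory sampled at observation years, with independent
multiplicative lognormal noise per variable and year.  Multiplicative
noise keeps observations positive (a series invariant) and matches the
roughly constant *relative* accuracy of national statistics.  The true
parameters travel with the series so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calibrate import ObservedSeries
from .model import DomainError, ModelParameters, SystemState
from .simulate import Scenario, integrate

__all__ = ["NoiseSpec", "generate_observed", "make_default_fixture", "DEFAULT_FIXTURE_SEED"]

DEFAULT_FIXTURE_SEED = 20160731


@dataclass(frozen=True)
class NoiseSpec:
    """Per-variable relative noise level for lognormal multiplicative noise.

    ``sd`` is either one relative standard deviation applied to every
    observed variable, or a mapping variable -> sd.  Observations are
    ``x * exp(eps)`` with ``eps ~ Normal(0, sd^2)``.
    """

    sd: float | Mapping[str, float] = 0.0
    seed: int = 0

    def sd_for(self, variable: str) -> float:
        s = self.sd.get(variable, 0.0) if isinstance(self.sd, Mapping) else float(self.sd)
        if s < 0:
            raise DomainError(f"noise sd must be >= 0, got {s} for {variable}")
        return s


def generate_observed(
    scenario: Scenario,
    sample_years: Sequence[float],
    noise: NoiseSpec,
    include: Sequence[str] = ("H", "A"),
) -> ObservedSeries:
    """Integrate ``scenario``, sample it, and add observation noise.

    Deterministic given ``noise.seed``; the returned series carries the
    generating parameters, initial state and noise spec in ``.truth``.
    """
    years = np.asarray(sorted(sample_years), dtype=float)
    if years[0] < scenario.t_start or years[-1] > scenario.t_end:
        raise DomainError(
            f"sample years [{years[0]}, {years[-1]}] outside scenario span "
            f"[{scenario.t_start}, {scenario.t_end}]"
        )
    traj = integrate(scenario)
    rng = np.random.default_rng(noise.seed)

    columns: dict[str, np.ndarray] = {}
    for v in ("H", "A", "N", "D"):  # fixed draw order: reproducible per seed
        if v not in include:
            continue
        clean = np.interp(years, traj.t, traj.variable(v))
        sd = noise.sd_for(v)
        eps = rng.normal(0.0, sd, size=len(years)) if sd > 0 else np.zeros(len(years))
        columns[v] = clean * np.exp(eps)

    truth = {
        "params": scenario.params.as_dict(),
        "initial": {"N": scenario.initial.N, "A": scenario.initial.A,
                    "D": scenario.initial.D, "H": scenario.initial.H,
                    "t": scenario.initial.t},
        "noise_sd": {v: noise.sd_for(v) for v in include},
        "seed": noise.seed,
    }
    return ObservedSeries(
        years=years,
        H_obs=columns["H"],
        A_obs=columns["A"],
        N_obs=columns.get("N"),
        D_obs=columns.get("D"),
        noise_sd={v: noise.sd_for(v) for v in include},
        truth=truth,
    )


def default_scenario(params: ModelParameters | None = None,
                     t_end: float = 2016.0) -> Scenario:
    """The packaged baseline over the historical window (1960 onward)."""
    from .io import default_parameters, default_initial_state  # lazy: avoid cycle

    if params is None:
        params = default_parameters()
    return Scenario(
        params=params,
        initial=default_initial_state(params),
        t_start=1960.0,
        t_end=t_end,
        output_step=1.0,
        label="historical-window baseline",
    )


def make_default_fixture(out_path) -> ObservedSeries:
    """Write the standard test fixture: annual 1960-2016, 1% noise, fixed seed.

    The series is generated from the packaged default parameters and
    initial state; the generating truth is written next to the CSV as
    ``<name>.truth.json`` so recovery tests can score themselves.
    """
    out_path = Path(out_path)
    scen = default_scenario()
    series = generate_observed(
        scen,
        sample_years=np.arange(1960, 2017),
        noise=NoiseSpec(sd=0.01, seed=DEFAULT_FIXTURE_SEED),
    )
    series.write_csv(out_path)
    truth_path = out_path.with_suffix(out_path.suffix + ".truth.json")
    with open(truth_path, "w") as fh:
        json.dump(series.truth, fh, indent=2, sort_keys=True)
    return series
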