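"""Parameter files, unit handling, packaged defaults and run manifests.

Parameter files are flat YAML (JSON is a YAML subset, so both parse)
whose keys are the model parameter names.  Every file must declare the
units of its values in a ``units`` block; supported declarations are
converted to the package's internal units (billion ha, billion
individuals, years) on load.  An optional ``initial`` block carries the
initial state of the baseline scenario.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .model import DomainError, ModelParameters, PARAMETER_NAMES, SystemState

__all__ = [
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "default_initial_state",
    "load_initial_state",
    "write_manifest",
    "RunConfig",
    "run_pipeline",
]

CANONICAL_UNITS = {"land": "billion_ha", "population": "billion", "time": "year"}

#: multiplicative factor to billion hectares
_LAND_FACTORS = {"billion_ha": 1.0, "Gha": 1.0, "million_km2": 0.1, "million_ha": 1e-3}
#: multiplicative factor to billions of individuals
_POP_FACTORS = {"billion": 1.0, "million": 1e-3, "individual": 1e-9}

# How each parameter's value scales when land areas are multiplied by
# lam and populations by pi to reach internal units.
_AREA = ("L", "N_th")                                   # * lam
_PER_CAPITA_AREA = ("eta_N", "eta_A")                   # * lam / pi
_PER_POP_RATE = ("d_N", "d_A", "c_NA", "c_ND", "c_AN", "c_AD")  # / pi
_INV_AREA = ("q", "q_N", "q_A", "phi")                  # / lam
_INV_PER_CAPITA_AREA = ("beta",)                        # * pi / lam


def _conversion_factors(units: Mapping[str, str]) -> tuple[float, float]:
    land = units.get("land", CANONICAL_UNITS["land"])
    pop = units.get("population", CANONICAL_UNITS["population"])
    time = units.get("time", CANONICAL_UNITS["time"])
    if land not in _LAND_FACTORS:
        raise DomainError(
            f"unsupported land unit {land!r}; supported: {sorted(_LAND_FACTORS)}"
        )
    if pop not in _POP_FACTORS:
        raise DomainError(
            f"unsupported population unit {pop!r}; supported: {sorted(_POP_FACTORS)}"
        )
    if time != "year":
        raise DomainError(f"unsupported time unit {time!r}; only 'year' is supported")
    return _LAND_FACTORS[land], _POP_FACTORS[pop]


def _convert(values: dict[str, float], lam: float, pi: float) -> dict[str, float]:
    out = dict(values)
    for k in _AREA:
        out[k] = out[k] * lam
    for k in _PER_CAPITA_AREA:
        out[k] = out[k] * lam / pi
    for k in _PER_POP_RATE:
        out[k] = out[k] / pi
    for k in _INV_AREA:
        out[k] = out[k] / lam
    for k in _INV_PER_CAPITA_AREA:
        out[k] = out[k] * pi / lam
    return out


def _read_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DomainError(f"parameter file {path} must be a mapping")
    return doc


def load_parameters(
    path=None, overrides: Optional[Mapping[str, float]] = None
) -> ModelParameters:
    """Load a parameter file (packaged default if ``path`` is None).

    ``overrides`` (name -> value, in internal units) are applied after
    unit conversion.  Unknown keys, missing keys and out-of-range values
    raise :class:`DomainError`/:class:`KeyError` naming the offender.
    """
    if path is None:
        ref = resources.files("landpop").joinpath("params/default.yaml")
        with resources.as_file(ref) as p:
            doc = _read_yaml(p)
    else:
        doc = _read_yaml(path)

    units = doc.pop("units", {})
    doc.pop("initial", None)
    doc.pop("meta", None)
    unknown = set(doc) - set(PARAMETER_NAMES)
    if unknown:
        raise KeyError(f"unknown parameter key(s) in file: {sorted(unknown)}")
    missing = set(PARAMETER_NAMES) - set(doc)
    if missing:
        raise KeyError(f"missing parameter key(s) in file: {sorted(missing)}")

    lam, pi = _conversion_factors(units or {})
    values = _convert({k: float(v) for k, v in doc.items()}, lam, pi)

    if overrides:
        unknown = set(overrides) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown override parameter(s): {sorted(unknown)}")
        values.update({k: float(v) for k, v in overrides.items()})
    return ModelParameters.from_dict(values)


def save_parameters(params: ModelParameters, path, meta: Optional[dict] = None) -> None:
    doc: dict = {"units": dict(CANONICAL_UNITS)}
    if meta:
        doc["meta"] = meta
    doc.update(params.as_dict())
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_parameters(overrides: Optional[Mapping[str, float]] = None) -> ModelParameters:
    """The packaged baseline parameter set (calibrated to the historical window)."""
    return load_parameters(None, overrides)


def _default_doc() -> dict:
    ref = resources.files("landpop").joinpath("params/default.yaml")
    with resources.as_file(ref) as p:
        return _read_yaml(p)


def load_initial_state(path, params: ModelParameters) -> SystemState:
    """Read the ``initial`` block of a parameter/scenario file.

    ``D`` may be omitted, in which case it is the remainder ``L - N - A``.
    """
    doc = _read_yaml(path)
    block = doc.get("initial")
    if block is None:
        raise KeyError(f"file {path} has no 'initial' block")
    return _initial_from_block(block, params)


def _initial_from_block(block: Mapping, params: ModelParameters) -> SystemState:
    N = float(block["N"])
    A = float(block["A"])
    H = float(block["H"])
    t = float(block.get("t", 0.0))
    D = float(block["D"]) if "D" in block else params.L - N - A
    state = SystemState(N=N, A=A, D=D, H=H, t=t)
    state.validate(L=params.L, tol=1e-6)
    return state


def default_initial_state(params: Optional[ModelParameters] = None) -> SystemState:
    """Initial state of the packaged baseline (historical-window start)."""
    if params is None:
        params = default_parameters()
    return _initial_from_block(_default_doc()["initial"], params)


def write_manifest(path, **entries) -> None:
    """Machine-readable record of a run: inputs, resolved parameters, versions."""
    import numpy, scipy  # noqa: PLC0415

    from . import __version__

    manifest = {
        "landpop_version": __version__,
        "python": sys.version.split()[0],
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
    manifest.update(entries)

    def _default(o):
        if hasattr(o, "as_dict"):
            return o.as_dict()
        if hasattr(o, "tolist"):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_default)


# ---------------------------------------------------------------------------
# pipeline dispatch

@dataclass
class RunConfig:
    """One pipeline invocation: a subcommand plus its resolved settings."""

    subcommand: str
    out: Path
    params_file: Optional[Path] = None
    init_file: Optional[Path] = None
    data_file: Optional[Path] = None
    overrides: dict[str, float] = field(default_factory=dict)
    t_start: float = 1960.0
    t_end: float = 2120.0
    output_step: float = 1.0
    seed: int = 1
    options: dict = field(default_factory=dict)


def _resolve_scenario(config: RunConfig) -> "Scenario":
    from .simulate import Scenario

    params = load_parameters(config.params_file, config.overrides)
    if config.init_file is not None:
        initial = load_initial_state(config.init_file, params)
    elif config.params_file is not None:
        try:
            initial = load_initial_state(config.params_file, params)
        except KeyError:
            initial = default_initial_state(params)
    else:
        initial = default_initial_state(params)
    if initial.t != config.t_start:
        initial = SystemState(N=initial.N, A=initial.A, D=initial.D,
                              H=initial.H, t=config.t_start)
    return Scenario(params=params, initial=initial, t_start=config.t_start,
                    t_end=config.t_end, output_step=config.output_step,
                    label=config.subcommand)


def run_pipeline(config: RunConfig) -> int:
    """Dispatch one subcommand; returns 0 on success.

    On failure the partial output file is removed, a one-line diagnostic
    goes to stderr, and a nonzero status is returned.  Every successful
    run leaves a ``<out>.manifest.json`` beside its output.
    """
    out = Path(config.out)
    try:
        _dispatch(config, out)
    except Exception as exc:  # noqa: BLE001 - single-line diagnostic contract
        for p in (out, out.with_suffix(".json")):
            if p.exists() and p != Path(config.data_file or ""):
                p.unlink()
        print(f"landpop {config.subcommand}: error: {exc}", file=sys.stderr)
        return 1
    write_manifest(
        str(out) + ".manifest.json",
        subcommand=config.subcommand,
        out=str(out),
        params_file=str(config.params_file) if config.params_file else "packaged default",
        overrides=config.overrides,
        parameters=load_parameters(config.params_file, config.overrides).as_dict(),
        t_start=config.t_start,
        t_end=config.t_end,
        seed=config.seed,
        options=config.options,
    )
    return 0


def _dispatch(config: RunConfig, out: Path) -> None:
    from .calibrate import ObservedSeries, fit_parameters
    from .scenarios import (
        key_factor_sweep, perception_plane, proactive_reactive_grid, tipping_onset,
    )
    from .simulate import integrate
    from .synthetic import NoiseSpec, generate_observed

    import numpy as np

    sub = config.subcommand
    if sub == "simulate":
        integrate(_resolve_scenario(config)).write_csv(out)
    elif sub == "tipping":
        traj = integrate(_resolve_scenario(config))
        tip = tipping_onset(traj)
        with open(out, "w") as fh:
            json.dump(
                {"detected": tip.detected, "t_onset": tip.t_onset,
                 "N_at_decline_onset": tip.N_at_decline_onset},
                fh, indent=2,
            )
    elif sub == "plane":
        scen = _resolve_scenario(config)
        res = perception_plane(
            config.options["p_N_grid"], config.options["p_A_grid"], scen,
            horizon=config.options.get("horizon", 1000.0),
        )
        res.write_csv(out)
    elif sub == "grid":
        scen = _resolve_scenario(config)
        res = proactive_reactive_grid(
            config.options["d_N_values"], config.options["c_ND_values"], scen,
            horizon=config.options.get("horizon", 160.0),
        )
        res.write_csv(out)
    elif sub == "sweep":
        scen = _resolve_scenario(config)
        res = key_factor_sweep(
            config.options["param"], config.options["values"], scen,
            horizon=config.options.get("horizon", 160.0),
        )
        res.write_csv(out)
    elif sub == "calibrate":
        data = ObservedSeries.read_csv(config.data_file)
        fixed = load_parameters(config.params_file, config.overrides)
        result = fit_parameters(
            data,
            free=config.options["free"],
            bounds=config.options["bounds"],
            fixed=fixed,
            seed=config.seed,
            n_starts=config.options.get("n_starts", 5),
            N0=config.options.get("N0"),
        )
        with open(out, "w") as fh:
            json.dump(
                {
                    "fitted": result.fitted,
                    "loss": result.loss,
                    "rms_residuals": result.rms_residuals,
                    "converged": result.converged,
                    "n_evaluations": result.n_evaluations,
                    "free": list(result.free_names),
                    "bounds": {k: list(v) for k, v in result.bounds.items()},
                    "N0": result.N0,
                    "params": result.params.as_dict(),
                },
                fh, indent=2, sort_keys=True,
            )
    elif sub == "synth":
        scen = _resolve_scenario(config)
        years = np.arange(config.options["year_start"], config.options["year_end"] + 1)
        series = generate_observed(
            scen, years, NoiseSpec(sd=config.options.get("sd", 0.01), seed=config.seed)
        )
        series.write_csv(out)
    else:
        raise DomainError(f"unknown subcommand {sub!r}")
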