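"""Core equations of the coupled human-population / land-cover system.

The globe is split into three land pools that always sum to the fixed
terrestrial area ``L``: productive natural / 'semi-natural' land ``N``
(forests, meadows, mostly uncultivated pastures), intensive agriculture
``A`` (arable land, permanent crops, monocultures) and degraded /
unproductive land ``D`` (deserts, tundra, urban and over-exploited land).
The fourth state variable is the human population ``H``.

Humans convert land between pools at rates driven by *perceived* land
value, a blend of supply-demand imbalance and perception bias (weights
``p_N``, ``p_A``); they degrade land in proportion to population; and
their own birth and death rates feed back on the resources the land
provides.  Ecosystem services enter through a natural-land threshold
``N_th``: below it, agricultural degradation accelerates
(``exp(-N/N_th)``) and agricultural efficiency ``eps_A(N)`` drops.

All functions here are pure and operate on plain floats; integration
lives in :mod:`landpop.simulate`.

Units: land areas in billions of hectares (Gha), population in billions
of individuals, time in years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace as _dc_replace
from typing import Iterator, Mapping


class DomainError(ValueError):
    """An input lies outside the model's physical domain (e.g. negative area)."""


class NumericalError(ArithmeticError):
    """A model term evaluated to a non-finite value; the message names the term."""


#: Order in which parameters appear in files, vectors and reprs.
PARAMETER_NAMES = (
    "r", "delta_N", "delta_A", "d_N", "d_A",
    "c_NA", "c_ND", "c_AN", "c_AD",
    "p_N", "p_A", "eta_N", "eta_A",
    "b", "beta", "m", "q", "q_N", "q_A",
    "E_N", "E_A", "phi", "N_th", "L",
)


@dataclass(frozen=True)
class ModelParameters:
    """The full parameter table of the model.

    Rates are per year; population-driven rates (``d_N``, ``d_A`` and the
    four conversion coefficients ``c_*``) are per billion individuals per
    year; per-capita demands ``eta_N``, ``eta_A`` are Gha per billion
    individuals (numerically, hectares per person).
    """

    r: float        # natural regeneration D -> N (1/yr)
    delta_N: float  # natural disturbance of N (1/yr)
    delta_A: float  # natural degradation of A (1/yr)
    d_N: float      # human-driven degradation of N (1/(B indiv * yr))
    d_A: float      # human-driven degradation of A (1/(B indiv * yr))
    c_NA: float     # max conversion A -> N (1/(B indiv * yr))
    c_ND: float     # max conversion D -> N (1/(B indiv * yr))
    c_AN: float     # max conversion N -> A (1/(B indiv * yr))
    c_AD: float     # max conversion D -> A (1/(B indiv * yr))
    p_N: float      # perceived value weight of N, in [0, 1]
    p_A: float      # perceived value weight of A, in [0, 1]
    eta_N: float    # per-capita demand for natural resources (Gha / B indiv)
    eta_A: float    # per-capita demand for agricultural resources (Gha / B indiv)
    b: float        # average recruitment rate: births minus under-5 deaths (1/yr)
    beta: float     # demographic-transition coefficient (inverse of eta_N units)
    m: float        # average mortality rate above age five (1/yr)
    q: float        # resource-availability mortality coefficient (1/Gha)
    q_N: float      # labour coefficient for natural resources (1/Gha)
    q_A: float      # labour coefficient for agricultural resources (1/Gha)
    E_N: float      # efficiency of use/harvest/distribution of N (unitless)
    E_A: float      # baseline efficiency of agricultural land (unitless)
    phi: float      # influence of the N_th shortfall on agricultural benefit (1/Gha)
    N_th: float     # natural-land threshold for ES / biodiversity (Gha)
    L: float        # total terrestrial land area (Gha)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise DomainError(f"parameter {f.name} must be a finite number, got {v!r}")
            if v < 0:
                raise DomainError(f"parameter {f.name} must be >= 0, got {v}")
        for name in ("p_N", "p_A"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"parameter {name} must lie in [0, 1], got {v}")
        if self.L <= 0:
            raise DomainError(f"total land area L must be > 0, got {self.L}")
        if not 0.0 < self.N_th < self.L:
            raise DomainError(
                f"threshold N_th must lie in (0, L) = (0, {self.L}), got {self.N_th}"
            )

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the named parameters changed (validated)."""
        unknown = set(changes) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return _dc_replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ModelParameters":
        unknown = set(values) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(values)
        if missing:
            raise KeyError(f"missing parameter(s): {sorted(missing)}")
        return cls(**{k: float(values[k]) for k in PARAMETER_NAMES})


@dataclass(frozen=True)
class SystemState:
    """The four state variables at one instant.

    ``N``, ``A``, ``D`` in Gha, ``H`` in billions of individuals, ``t`` in
    calendar years CE.
    """

    N: float
    A: float
    D: float
    H: float
    t: float = 0.0

    def validate(self, L: float | None = None, tol: float = 1e-9) -> None:
        for name in ("N", "A", "D", "H"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"state variable {name} is not finite: {v!r}")
            if v < 0:
                raise DomainError(f"state variable {name} must be >= 0, got {v}")
        if L is not None and abs(self.N + self.A + self.D - L) > tol * max(1.0, L):
            raise DomainError(
                f"land pools must sum to L={L}: N+A+D = {self.N + self.A + self.D}"
            )

    def __iter__(self) -> Iterator[float]:
        return iter((self.N, self.A, self.D, self.H))


@dataclass(frozen=True)
class Derivatives:
    """Time derivatives: land pools in Gha/yr, population in B indiv/yr.

    Conservation ``dN + dA + dD = 0`` holds exactly by construction.
    """

    dN: float
    dA: float
    dD: float
    dH: float

    def __iter__(self) -> Iterator[float]:
        return iter((self.dN, self.dA, self.dD, self.dH))


def _check_nonneg(**values: float) -> None:
    for name, v in values.items():
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")


def perception_u_NA(N: float, A: float, H: float, params: ModelParameters) -> float:
    """Perceived value of converting agricultural to natural land.

    Positive only when the (perception-weighted) unmet demand for natural
    land exceeds the unmet demand for agricultural land:
    ``max(0, (eta_N*H - (1-p_N)*N - eta_A*H + (1-p_A)*A) / L)``.
    """
    _check_nonneg(N=N, A=A, H=H)
    num = (
        params.eta_N * H - (1.0 - params.p_N) * N
        - params.eta_A * H + (1.0 - params.p_A) * A
    )
    return max(0.0, num / params.L)


def perception_u_ND(N: float, H: float, params: ModelParameters) -> float:
    """Perceived value of restoring degraded land to natural land.

    ``max(0, (eta_N*H - (1-p_N)*N) / L)``: scarcity of natural land
    relative to demand, discounted by the perception weight ``p_N``.
    """
    _check_nonneg(N=N, H=H)
    return max(0.0, (params.eta_N * H - (1.0 - params.p_N) * N) / params.L)


def perception_u_A(A: float, H: float, params: ModelParameters) -> float:
    """Perceived value of converting land into agriculture.

    ``max(0, (eta_A*H - (1-p_A)*A) / L)``.
    """
    _check_nonneg(A=A, H=H)
    return max(0.0, (params.eta_A * H - (1.0 - params.p_A) * A) / params.L)


def agri_efficiency(N: float, params: ModelParameters, cap: bool = False) -> float:
    """Efficiency of agricultural land as a function of natural land.

    ``eps_A(N) = max(0, E_A - phi * (N_th - N))``: below the ecosystem-
    service threshold ``N_th`` the efficiency falls linearly with the
    shortfall.  As printed the expression exceeds ``E_A`` when
    ``N > N_th``; pass ``cap=True`` to saturate at ``E_A`` instead.
    """
    _check_nonneg(N=N)
    eps = max(0.0, params.E_A - params.phi * (params.N_th - N))
    if cap:
        eps = min(eps, params.E_A)
    return eps


def derivatives(
    state: SystemState, params: ModelParameters, cap_efficiency: bool = False
) -> Derivatives:
    """Evaluate the right-hand side of the four coupled equations.

    Natural land gains from regeneration of degraded land (``r*D``) and
    perception-driven conversion out of ``A`` and ``D``; it is lost to
    agricultural conversion, human-driven degradation (``d_N*H*N``) and
    natural disturbance (``delta_N*N``).  Agricultural land gains by
    conversion from ``N`` and ``D`` and is lost to restoration,
    human-driven degradation accelerated below the ES threshold
    (``d_A*exp(-N/N_th)*H*A``) and natural degradation.  Degraded land
    takes up the balance: ``dD = -(dN + dA)``, which keeps
    ``N + A + D`` exactly constant.  Population grows by recruitment,
    damped by the demographic transition (``exp(-beta*eta_N)``) and by
    resource collapse (``1 - exp(-q_N*N - q_A*A)``), and shrinks by
    mortality that rises exponentially with the gap between per-capita
    demand and what the land supplies.

    Raises :class:`NumericalError` if the exponential mortality term
    overflows, and :class:`DomainError` on negative state variables.
    """
    state.validate()
    N, A, D, H = state.N, state.A, state.D, state.H

    u_na = perception_u_NA(N, A, H, params)
    u_nd = perception_u_ND(N, H, params)
    u_a = perception_u_A(A, H, params)

    conv_AtoN = params.c_NA * u_na * H * A
    conv_DtoN = params.c_ND * u_nd * H * D
    conv_NtoA = params.c_AN * u_a * N * H
    conv_DtoA = params.c_AD * u_a * H * D

    dN = conv_AtoN + conv_DtoN - conv_NtoA - params.d_N * H * N - params.delta_N * N + params.r * D
    dA = (
        conv_NtoA + conv_DtoA - conv_AtoN
        - params.d_A * math.exp(-N / params.N_th) * H * A
        - params.delta_A * A
    )
    dD = -(dN + dA)

    eps_A = agri_efficiency(N, params, cap=cap_efficiency)
    recruitment = (
        params.b
        * math.exp(-params.beta * params.eta_N)
        * (1.0 - math.exp(-params.q_N * N - params.q_A * A))
    )
    mortality_arg = params.q * (
        params.eta_N * H - params.E_N * N + params.eta_A * H - eps_A * A
    )
    try:
        mortality = params.m * math.exp(mortality_arg)
    except OverflowError:
        mortality = math.inf
    if not math.isfinite(mortality):
        raise NumericalError(
            f"mortality term m*exp(q*(demand - supply)) overflowed: "
            f"exponent q*(...) = {mortality_arg:.6g} at state {state}"
        )
    dH = (recruitment - mortality) * H

    return Derivatives(dN=dN, dA=dA, dD=dD, dH=dH)
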