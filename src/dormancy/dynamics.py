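"""Right-hand sides of the tumor-immune ODE system.

Three model variants share the same immune equations and differ in the
tumor compartments they carry:

* ``proliferative`` - aggressive clone only (``Cp``),
* ``quiescent`` - immunogenic clone only (``Cq``),
* ``heterogeneous`` - both clones competing for the same Gompertz carrying
  capacity, with the proliferative-side coefficients replaced by
  population-weighted means (:func:`mixed_parameters`).

Tumor growth is Gompertzian, ``a * C * ln(Cmax / C)``; immune predation and
immune inactivation follow mass action; effector recruitment saturates with
Michaelis-Menten kinetics in the squared tumor burden, ``C^2 / (h + C^2)``.

These functions are pure and operate on scalar states; the production
integrator uses a JIT-compiled kernel (:mod:`dormancy._kernel`) whose
agreement with these definitions is asserted in the test suite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DomainError
from .parameters import ParameterSet

__all__ = [
    "ModelVariant",
    "SystemState",
    "MixedParameters",
    "gompertz_term",
    "mixed_parameters",
    "rhs_proliferative",
    "rhs_quiescent",
    "rhs_heterogeneous",
    "rhs",
]


class ModelVariant(str, enum.Enum):
    """Which tumor compartments the simulation carries."""

    PROLIFERATIVE = "proliferative"
    QUIESCENT = "quiescent"
    HETEROGENEOUS = "heterogeneous"

    @classmethod
    def coerce(cls, value) -> "ModelVariant":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class SystemState:
    """A time-stamped population state (all counts in cells)."""

    t: float
    Cp: float
    Cq: float
    N: float
    T: float

    @property
    def total_tumor(self) -> float:
        return self.Cp + self.Cq

    def as_array(self) -> np.ndarray:
        return np.array([self.Cp, self.Cq, self.N, self.T], dtype=float)


class MixedParameters(NamedTuple):
    """Population-weighted proliferative-side coefficients of the
    heterogeneous model (same units as the unmixed constants)."""

    a1h: float
    b1h: float
    eta1h: float
    r1h: float
    u1h: float


def gompertz_term(a: float, Ci: float, Ctot: float, Cmax: float) -> float:
    """Gompertzian net growth ``a * Ci * ln(Cmax / Ctot)`` in cells/day.

    ``Ci`` is the compartment the term feeds; ``Ctot`` is the total tumor
    burden occupying the shared carrying capacity ``Cmax``. The limit value
    0 is returned when the compartment or the tumor is empty.
    """
    if Ci < 0 or Ctot < 0 or Ci > Ctot:
        raise DomainError(
            f"need 0 <= Ci <= Ctot, got Ci={Ci!r}, Ctot={Ctot!r}"
        )
    if Ctot > Cmax:
        raise DomainError(
            f"tumor burden {Ctot!r} exceeds carrying capacity {Cmax!r}"
        )
    if Ci == 0.0 or Ctot == 0.0:
        return 0.0
    return a * Ci * math.log(Cmax / Ctot)


def mixed_parameters(Cp: float, Cq: float, params: ParameterSet) -> MixedParameters:
    """Population-weighted means of the five proliferative-side coefficients.

    Each mixed value is ``(x1 * Cp + x2 * Cq) / (Cp + Cq)``, a convex
    combination of the clone-specific constants; the weights are the current
    clonal composition, so a mostly-quiescent tumor renders its
    proliferative minority nearly as immunogenic as the quiescent bulk.
    """
    total = Cp + Cq
    if total <= 0.0:
        raise DomainError("parameter mixing is undefined for an extinct tumor")
    if Cp < 0 or Cq < 0:
        raise DomainError(f"negative population: Cp={Cp!r}, Cq={Cq!r}")
    w = Cp / total
    v = 1.0 - w
    return MixedParameters(
        a1h=params.a1 * w + params.a2 * v,
        b1h=params.b1 * w + params.b2 * v,
        eta1h=params.eta1 * w + params.eta2 * v,
        r1h=params.r1 * w + params.r2 * v,
        u1h=params.u1 * w + params.u2 * v,
    )


def _check_nonnegative(state: SystemState) -> None:
    for name in ("Cp", "Cq", "N", "T"):
        if getattr(state, name) < 0:
            raise DomainError(
                f"negative state component {name}={getattr(state, name)!r}"
            )


def _immune_derivatives(
    C: float, N: float, T: float, r: float, u: float, params: ParameterSet
) -> tuple:
    """dN/dt and dT/dt shared by all variants, for total tumor burden C."""
    csq = C * C
    dN = (
        params.s
        + N * params.g * csq / (params.h + csq)
        - params.p * C * N
        - params.f * N
    )
    dT = (
        r * N * C
        + T * params.j * csq / (params.k + csq)
        - u * C * T
        - params.m * T
    )
    return dN, dT


def rhs_proliferative(state: SystemState, params: ParameterSet) -> np.ndarray:
    """Derivative (dCp, dCq, dN, dT) of the proliferative-only model."""
    _check_nonnegative(state)
    if state.Cq != 0.0:
        raise DomainError("proliferative variant requires Cq = 0")
    C = state.Cp
    dCp = (
        gompertz_term(params.a1, C, C, params.Cmax)
        - params.b1 * state.N * C
        - params.eta1 * state.T * C
    )
    dN, dT = _immune_derivatives(C, state.N, state.T, params.r1, params.u1, params)
    return np.array([dCp, 0.0, dN, dT])


def rhs_quiescent(state: SystemState, params: ParameterSet) -> np.ndarray:
    """Derivative (dCp, dCq, dN, dT) of the quiescent-only model."""
    _check_nonnegative(state)
    if state.Cp != 0.0:
        raise DomainError("quiescent variant requires Cp = 0")
    C = state.Cq
    dCq = (
        gompertz_term(params.a2, C, C, params.Cmax)
        - params.b2 * state.N * C
        - params.eta2 * state.T * C
    )
    dN, dT = _immune_derivatives(C, state.N, state.T, params.r2, params.u2, params)
    return np.array([0.0, dCq, dN, dT])


def rhs_heterogeneous(state: SystemState, params: ParameterSet) -> np.ndarray:
    """Derivative of the two-clone competition model.

    Both clones share the carrying capacity through the total burden
    ``C = Cp + Cq``. The proliferative equation and the CTL stimulation /
    inactivation coefficients use the population-weighted mixed values; the
    quiescent equation keeps its own constants. With an extinct tumor the
    tumor-coupled terms vanish and mixing is skipped.
    """
    _check_nonnegative(state)
    C = state.Cp + state.Cq
    if C == 0.0:
        dN, dT = _immune_derivatives(0.0, state.N, state.T, 0.0, 0.0, params)
        return np.array([0.0, 0.0, dN, dT])
    mixed = mixed_parameters(state.Cp, state.Cq, params)
    dCp = (
        gompertz_term(mixed.a1h, state.Cp, C, params.Cmax)
        - mixed.b1h * state.N * state.Cp
        - mixed.eta1h * state.T * state.Cp
    )
    dCq = (
        gompertz_term(params.a2, state.Cq, C, params.Cmax)
        - params.b2 * state.N * state.Cq
        - params.eta2 * state.T * state.Cq
    )
    dN, dT = _immune_derivatives(
        C, state.N, state.T, mixed.r1h, mixed.u1h, params
    )
    return np.array([dCp, dCq, dN, dT])


_RHS_BY_VARIANT = {
    ModelVariant.PROLIFERATIVE: rhs_proliferative,
    ModelVariant.QUIESCENT: rhs_quiescent,
    ModelVariant.HETEROGENEOUS: rhs_heterogeneous,
}


def rhs(variant, state: SystemState, params: ParameterSet) -> np.ndarray:
    """Dispatch to the variant's right-hand side."""
    return _RHS_BY_VARIANT[ModelVariant.coerce(variant)](state, params)
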