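"""Model constants and initial conditions for the tumor-immune dormancy system.

The model tracks four cell populations: proliferative tumor cells (``Cp``,
the aggressive 4T1-like phenotype), quiescent tumor cells (``Cq``, the
immunogenic MR20-like phenotype with active type I IFN signaling), natural
killer cells (``N``) and cytotoxic CD8+ T lymphocytes (``T``). All rate
constants are expressed per day and cell counts are continuous non-negative
reals; integer semantics only enter at the sub-unity extinction threshold
applied by the integrator.

Two couplings are structural: the NK kill rate and the CTL stimulation
coefficient on the proliferative phenotype are proportional to their
quiescent counterparts through a single immunogenicity coefficient
``alpha`` (< 1), i.e. ``b1 = alpha * b2`` and ``r1 = alpha * r2``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Mapping, Union

import yaml

from .errors import ConfigError, ParameterValidationError

__all__ = [
    "ParameterSet",
    "InitialState",
    "load_parameters",
    "load_initial_state",
    "default_parameters",
    "default_initial_state",
    "PARAMETER_FIELDS",
    "INITIAL_STATE_FIELDS",
]

#: Relative tolerance for the consistency check b1 == alpha * b2 (and r1/r2)
#: when all three values are supplied explicitly.
COUPLING_RTOL = 1e-12

ConfigSource = Union[None, str, Path, IO[str], Mapping[str, float]]


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and coefficients of the four-population model.

    Defaults are the calibrated values for the 4T1/MR20 murine TNBC system.
    ``b1`` and ``r1`` default to ``alpha * b2`` and ``alpha * r2``; passing
    them explicitly is allowed but they must agree with the coupling to
    relative :data:`COUPLING_RTOL`.
    """

    a1: float = 0.038  # proliferative tumor growth rate, day^-1
    a2: float = 0.0174  # quiescent tumor growth rate, day^-1
    Cmax: float = 1.0e9  # maximum tumor size, cells
    alpha: float = 0.3  # NK-cytotoxicity proportion coefficient
    b1: float = None  # NK kill rate, proliferative, cell^-1 day^-1
    b2: float = 5.2e-8  # NK kill rate, quiescent, cell^-1 day^-1
    eta1: float = 2.1e-8  # CTL kill rate, proliferative, cell^-1 day^-1
    eta2: float = 2.8e-7  # CTL kill rate, quiescent, cell^-1 day^-1
    s: float = 1.3e4  # constant NK source, cells day^-1
    r1: float = None  # CTL stimulation, proliferative, cell^-1 day^-1
    r2: float = 1.2e-7  # CTL stimulation, quiescent, cell^-1 day^-1
    g: float = 2.5e-2  # max NK recruitment rate, day^-1
    h: float = 2.02e7  # NK recruitment steepness, cell^2
    f: float = 4.12e-2  # NK death rate, day^-1
    p: float = 1.8e-8  # NK inactivation by tumor, cell^-1 day^-1
    j: float = 0.1  # max CTL recruitment rate, day^-1
    k: float = 2.02e7  # CTL recruitment steepness, cell^2
    m: float = 2.0e-2  # CTL death rate, day^-1
    u1: float = 2.1e-8  # CTL inactivation by proliferative, cell^-1 day^-1
    u2: float = 1.7e-12  # CTL inactivation by quiescent, cell^-1 day^-1

    def __post_init__(self):
        if self.b1 is None:
            object.__setattr__(self, "b1", self.alpha * self.b2)
        if self.r1 is None:
            object.__setattr__(self, "r1", self.alpha * self.r2)
        for name in PARAMETER_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)):
                raise ParameterValidationError(
                    f"parameter {name!r} must be a number, got {value!r}"
                )
            if value < 0:
                raise ParameterValidationError(
                    f"parameter {name!r} must be >= 0, got {value!r}"
                )
        if self.Cmax < 1:
            raise ParameterValidationError(
                f"Cmax must be >= 1 cell, got {self.Cmax!r}"
            )
        for derived, base in (("b1", "b2"), ("r1", "r2")):
            got = getattr(self, derived)
            expected = self.alpha * getattr(self, base)
            scale = max(abs(expected), abs(got))
            if scale > 0 and abs(got - expected) > COUPLING_RTOL * scale:
                raise ParameterValidationError(
                    f"{derived} = {got!r} is inconsistent with "
                    f"alpha * {base} = {expected!r} (relative tolerance "
                    f"{COUPLING_RTOL})"
                )

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with ``changes`` applied and re-validated.

        The alpha-coupling is preserved in whichever direction it is not
        pinned explicitly: changing ``b2`` (or ``alpha``) re-derives ``b1``,
        and changing ``b1`` alone back-propagates ``b2 = b1 / alpha``
        (likewise for ``r1``/``r2``).
        """
        for derived, base in (("b1", "b2"), ("r1", "r2")):
            if (base in changes or "alpha" in changes) and derived not in changes:
                changes[derived] = None
            elif derived in changes and base not in changes:
                alpha = changes.get("alpha", self.alpha)
                if alpha > 0:
                    changes[base] = changes[derived] / alpha
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAMETER_FIELDS}

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class InitialState:
    """Initial population sizes, in cells."""

    Cp0: float = 0.0
    Cq0: float = 5.0e4
    N0: float = 2.5e5
    T0: float = 5.2e5

    def __post_init__(self):
        for name in INITIAL_STATE_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or value < 0:
                raise ParameterValidationError(
                    f"initial state field {name!r} must be >= 0, got {value!r}"
                )

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in INITIAL_STATE_FIELDS}


PARAMETER_FIELDS = tuple(f.name for f in dataclasses.fields(ParameterSet))
INITIAL_STATE_FIELDS = tuple(f.name for f in dataclasses.fields(InitialState))

#: Default total tumor inoculum (cells) shared by all standard scenarios.
DEFAULT_INOCULUM = 5.0e4


def _read_config(source: ConfigSource) -> dict:
    """Parse a config source into a flat {key: float} dict.

    Accepts a mapping, a path to a YAML/JSON file, an open text stream, or
    ``None`` for the packaged defaults. Values are coerced through
    ``float()`` so scientific notation survives YAML 1.1 parsing quirks.
    """
    if source is None:
        ref = resources.files("dormancy").joinpath("data/default_params.yaml")
        raw = yaml.safe_load(ref.read_text())
    elif isinstance(source, Mapping):
        raw = dict(source)
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        raise ConfigError(f"unsupported config source: {source!r}")
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a flat mapping of parameter names")
    out = {}
    for key, value in raw.items():
        if value is None:
            continue
        try:
            out[str(key)] = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r} is not numeric: {value!r}") from exc
    return out


def load_parameters(source: ConfigSource = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a config source.

    Keys not naming a model constant (e.g. initial-state keys) are ignored.
    Missing keys fall back to the packaged defaults; ``b1``/``r1`` are
    re-derived from ``alpha`` when omitted.
    """
    values = _read_config(source)
    kwargs = {k: v for k, v in values.items() if k in PARAMETER_FIELDS}
    return ParameterSet(**kwargs)


def load_initial_state(source: ConfigSource = None) -> InitialState:
    """Build an :class:`InitialState` from the initial-state keys of a config."""
    values = _read_config(source)
    kwargs = {k: v for k, v in values.items() if k in INITIAL_STATE_FIELDS}
    return InitialState(**kwargs)


def default_parameters() -> ParameterSet:
    """The packaged default constants (loaded from the bundled config file)."""
    return load_parameters(None)


def default_initial_state(
    scenario_kind: str, heterogeneous_proliferative: float = 800.0
) -> InitialState:
    """Standard initial conditions for the three model variants.

    All scenarios start from a 5 x 10^4 cell tumor inoculum with the
    estimated day-7 immune levels (2.5 x 10^5 NK, 5.2 x 10^5 CD8+ T).
    For ``"heterogeneous"``, ``heterogeneous_proliferative`` cells of the
    inoculum are proliferative (default 800) and the rest quiescent.
    """
    n0, t0 = 2.5e5, 5.2e5
    if scenario_kind == "proliferative":
        return InitialState(Cp0=DEFAULT_INOCULUM, Cq0=0.0, N0=n0, T0=t0)
    if scenario_kind == "quiescent":
        return InitialState(Cp0=0.0, Cq0=DEFAULT_INOCULUM, N0=n0, T0=t0)
    if scenario_kind == "heterogeneous":
        cp0 = float(heterogeneous_proliferative)
        if not 0.0 <= cp0 <= DEFAULT_INOCULUM:
            raise ConfigError(
                "heterogeneous_proliferative must lie within the "
                f"{DEFAULT_INOCULUM:g}-cell inoculum, got {cp0!r}"
            )
        return InitialState(Cp0=cp0, Cq0=DEFAULT_INOCULUM - cp0, N0=n0, T0=t0)
    raise ConfigError(f"unknown scenario kind: {scenario_kind!r}")
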