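"""Synthetic fixtures with the statistical structure the analysis assumes.

The original mouse growth-curve measurements behind the calibrated
constants are not published, so calibration correctness is established by
parameter recovery on data generated from the model itself: noisy
tumor-size time courses sampled on a sparse (twice-weekly, caliper-style)
observation grid, plus the four named vaccination protocols as protocol
files. Every fixture is regenerated from a seed at run time; nothing is
shipped as data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .dynamics import ModelVariant
from .errors import ConfigError
from .calibration import ObservationSeries
from .integrator import DEFAULT_STEP, InjectionEvent, InjectionSchedule, integrate
from .parameters import InitialState, ParameterSet, default_initial_state
from .scenarios import VaccinationProtocol

__all__ = [
    "FixtureSpec",
    "make_observations",
    "make_protocol_fixtures",
    "default_observation_days",
]


def default_observation_days(horizon: float = 100.0) -> np.ndarray:
    """Twice-weekly measurement days (3-4 day cadence) up to ``horizon``."""
    days = []
    day = 0.0
    toggle = True
    while True:
        day += 3.0 if toggle else 4.0
        toggle = not toggle
        if day > horizon:
            break
        days.append(day)
    return np.array(days)


@dataclass(frozen=True)
class FixtureSpec:
    """Everything needed to regenerate one noisy observation series."""

    variant: Union[str, ModelVariant] = "quiescent"
    params: ParameterSet = field(default_factory=ParameterSet)
    initial: Optional[InitialState] = None
    observation_days: Sequence[float] = field(
        default_factory=default_observation_days
    )
    noise_kind: str = "multiplicative"  # or "additive"
    noise_scale: float = 0.05
    seed: int = 0
    step: float = DEFAULT_STEP

    def __post_init__(self):
        if self.noise_kind not in ("multiplicative", "additive"):
            raise ConfigError(f"unknown noise kind {self.noise_kind!r}")
        if self.noise_scale < 0:
            raise ConfigError("noise scale must be >= 0")


def make_observations(spec: FixtureSpec) -> Tuple[ObservationSeries, ParameterSet]:
    """Integrate the generating model and sample noisy observations.

    Multiplicative noise is log-normal, ``size * exp(sigma * Z)`` with
    ``sigma = noise_scale`` (tumor sizes span decades, so relative error is
    the natural scale); additive noise is plain Gaussian with standard
    deviation ``noise_scale * size``. Returns the series together with the
    generating constants so recovery tests can compare against the truth.
    """
    variant = ModelVariant.coerce(spec.variant)
    initial = spec.initial or default_initial_state(variant.value)
    days = np.asarray(list(spec.observation_days), dtype=float)
    if days.size == 0:
        raise ConfigError("observation_days must be non-empty")
    traj = integrate(
        variant,
        initial,
        spec.params,
        horizon=float(days[-1]),
        step=spec.step,
    )
    clean = np.interp(days, traj.t, traj.total)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_scale == 0.0:
        noisy = clean
    elif spec.noise_kind == "multiplicative":
        noisy = clean * np.exp(rng.normal(0.0, spec.noise_scale, size=clean.shape))
    else:
        noisy = np.clip(
            clean + rng.normal(0.0, spec.noise_scale * clean), 0.0, None
        )
    return (
        ObservationSeries(days=days, sizes=noisy, noise_scale=spec.noise_scale),
        spec.params,
    )


#: The four named vaccination protocols studied by the model:
#: a 10-day preconditioning with an equal dose, a 20-day prophylactic
#: injection of the four-fold dose, and the single / split therapeutic
#: schedules after the challenge.
_NAMED_PROTOCOLS = {
    "preconditioning": [(-10.0, 5.0e4)],
    "prophylactic": [(-20.0, 2.0e5)],
    "therapeutic_single": [(7.0, 2.0e6)],
    "therapeutic_split": [(7.0, 1.0e6), (14.0, 1.0e6)],
}


def make_protocol_fixtures(
    directory: Union[str, Path]
) -> Dict[str, Path]:
    """Write the four named vaccination protocols as JSON protocol files.

    Every protocol challenges with 5 x 10^4 proliferative cells at day 0;
    vaccine injections seed the quiescent compartment at the listed
    relative days. Returns {name: path}.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, events in _NAMED_PROTOCOLS.items():
        protocol = VaccinationProtocol(
            events=InjectionSchedule(
                [
                    InjectionEvent(day=day, compartment="quiescent", count=count)
                    for day, count in events
                ]
            ),
            name=name,
        )
        path = directory / f"{name}.json"
        protocol.to_json(path)
        written[name] = path
    return written
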