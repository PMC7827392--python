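"""Time integration, scheduled cell injections, and trajectory fate calls.

The solver is classic fixed-step 4th-order Runge-Kutta (default step 0.01
day). After every accepted step a tumor compartment found strictly between
zero and one cell is set to zero and logged as eliminated - the model's
discrete reading of "less than one cell means the population is gone".
Immune compartments are floored at zero but never flagged eliminated, since
the constant NK source regenerates them. Scheduled injections are
instantaneous additions to a tumor compartment at grid-snapped event times.

A trajectory's fate over the horizon is three-valued per tumor clone:

* ``eliminated`` - the compartment was zeroed (or never seeded),
* ``escaped`` - the total burden reached the escape threshold
  (default 10^8 cells, a tenth of the carrying capacity),
* ``dormant`` - alive below threshold at the horizon.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._kernel import (
    STATUS_NONFINITE,
    VARIANT_CODES,
    pack_parameters,
    rk4_segment,
)
from .dynamics import ModelVariant
from .errors import ClassificationError, ConfigError, IntegrationError
from .parameters import InitialState, ParameterSet

__all__ = [
    "InjectionEvent",
    "InjectionSchedule",
    "Trajectory",
    "Fate",
    "FateLabel",
    "integrate",
    "classify_fate",
    "escape_onset_day",
    "DEFAULT_STEP",
    "DEFAULT_HORIZON",
    "DEFAULT_ESCAPE_THRESHOLD",
]

DEFAULT_STEP = 0.01  # days
DEFAULT_HORIZON = 365.0  # days ("one year of simulation")
DEFAULT_ESCAPE_THRESHOLD = 1.0e8  # cells, Cmax / 10

_COMPARTMENTS = ("proliferative", "quiescent")


@dataclass(frozen=True)
class InjectionEvent:
    """A timed instantaneous addition of tumor cells."""

    day: float
    compartment: str  # "proliferative" or "quiescent"
    count: float

    def __post_init__(self):
        if self.compartment not in _COMPARTMENTS:
            raise ConfigError(
                f"unknown injection compartment {self.compartment!r}"
            )
        if not self.count > 0:
            raise ConfigError(f"injection count must be > 0, got {self.count!r}")
        if not math.isfinite(self.day):
            raise ConfigError(f"injection day must be finite, got {self.day!r}")


class InjectionSchedule:
    """An ordered list of injection events (days non-decreasing)."""

    def __init__(self, events: Iterable[InjectionEvent] = ()):
        events = [
            e if isinstance(e, InjectionEvent) else InjectionEvent(**e)
            for e in events
        ]
        for prev, nxt in zip(events, events[1:]):
            if nxt.day < prev.day:
                raise ConfigError("injection days must be non-decreasing")
        self.events = events

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    def __repr__(self):
        return f"InjectionSchedule({self.events!r})"


class Fate(str, enum.Enum):
    DORMANT = "dormant"
    ELIMINATED = "eliminated"
    ESCAPED = "escaped"


@dataclass(frozen=True)
class FateLabel:
    """Per-clone and overall trajectory outcome."""

    proliferative: Fate
    quiescent: Fate
    overall: Fate

    def as_dict(self) -> dict:
        return {
            "proliferative": self.proliferative.value,
            "quiescent": self.quiescent.value,
            "overall": self.overall.value,
        }


@dataclass
class Trajectory:
    """Solution curves plus the event log of one simulation run.

    ``states`` has one row per recorded time point with columns
    (Cp, Cq, N, T); ``events`` is a list of dicts with keys
    ``day``, ``type`` (injection / extinction / escape), ``compartment``
    and ``count`` (None for non-injections). ``max_total`` is the exact
    per-step running maximum of the tumor burden, independent of the
    recording stride.
    """

    t: np.ndarray
    states: np.ndarray
    events: list = field(default_factory=list)
    variant: str = "heterogeneous"
    step: float = DEFAULT_STEP
    escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD
    max_total: float = 0.0
    escape_day: Optional[float] = None
    horizon: float = DEFAULT_HORIZON
    t0: float = 0.0

    @property
    def Cp(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def Cq(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def total(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "Cp": self.Cp,
                "Cq": self.Cq,
                "N": self.N,
                "T": self.T,
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    def events_to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.events, fh, indent=2)


def _snap_index(day: float, t0: float, step: float, n_total: int) -> int:
    idx = int(round((day - t0) / step))
    if idx < 0 or idx > n_total:
        raise ConfigError(
            f"event at day {day!r} lies outside the integration window"
        )
    return idx


def integrate(
    variant,
    initial: InitialState,
    params: Optional[ParameterSet] = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
    schedule: Optional[InjectionSchedule] = None,
    t0: float = 0.0,
    record_every: int = 1,
    escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD,
) -> Trajectory:
    """Integrate a model variant from ``t0`` to ``horizon``.

    Parameters
    ----------
    variant : str or ModelVariant
        proliferative, quiescent, or heterogeneous.
    initial : InitialState
        Populations at ``t0``.
    params : ParameterSet, optional
        Model constants (packaged defaults if omitted).
    horizon : float
        End time in days (must exceed ``t0``).
    step : float
        RK4 step in days, in (0, 0.1]. Event days are snapped to the grid.
    schedule : InjectionSchedule, optional
        Timed tumor-cell injections within ``[t0, horizon]``.
    t0 : float
        Start time in days; negative values support pre-challenge
        vaccination phases.
    record_every : int
        Recording stride in steps (1 = every step). The final state is
        always recorded.
    escape_threshold : float
        Tumor burden (cells) that defines immune escape.
    """
    if params is None:
        params = ParameterSet()
    variant = ModelVariant.coerce(variant)
    if not horizon > t0:
        raise ConfigError(f"horizon {horizon!r} must exceed start time {t0!r}")
    if not 0.0 < step <= 0.1:
        raise ConfigError(f"step must lie in (0, 0.1] day, got {step!r}")
    if record_every < 1:
        raise ConfigError("record_every must be >= 1")

    prm = pack_parameters(params)
    code = VARIANT_CODES[variant.value]
    n_total = int(round((horizon - t0) / step))
    stride = int(record_every)

    # Group events by grid index.
    events_by_index: dict = {}
    for event in schedule or ():
        idx = _snap_index(event.day, t0, step, n_total)
        events_by_index.setdefault(idx, []).append(event)
    boundaries = sorted(events_by_index)

    n_rows = n_total // stride + 1
    tail_row = n_total % stride != 0
    rec = np.full((n_rows + (1 if tail_row else 0), 5), np.nan)

    y = initial.as_array() if hasattr(initial, "as_array") else np.array(
        [initial.Cp0, initial.Cq0, initial.N0, initial.T0], dtype=float
    )
    rec[0] = (t0, *y)

    event_log: list = []
    max_total = 0.0
    escape_day = -1.0
    done = 0

    segment_bounds = boundaries + [n_total]
    for bound in segment_bounds:
        # Apply any events scheduled at the current grid index.
        for event in events_by_index.pop(done, ()):
            comp = 0 if event.compartment == "proliferative" else 1
            y[comp] += event.count
            event_log.append(
                {
                    "day": t0 + done * step,
                    "type": "injection",
                    "compartment": event.compartment,
                    "count": event.count,
                }
            )
            if done % stride == 0:
                rec[done // stride] = (t0 + done * step, *y)
        n_seg = bound - done
        if n_seg <= 0:
            continue
        status, steps_done, ext_p, ext_q, escape_day, max_total = rk4_segment(
            y,
            t0 + done * step,
            n_seg,
            step,
            prm,
            code,
            escape_threshold,
            stride,
            done,
            rec,
            max_total,
            escape_day,
        )
        for day, compartment in ((ext_p, "proliferative"), (ext_q, "quiescent")):
            if day >= 0.0:
                event_log.append(
                    {
                        "day": day,
                        "type": "extinction",
                        "compartment": compartment,
                        "count": None,
                    }
                )
        if status == STATUS_NONFINITE:
            last_valid = t0 + (done + steps_done) * step
            raise IntegrationError(
                f"non-finite state at t = {last_valid + step:g} d "
                f"(last valid time {last_valid:g} d)",
                last_valid_time=last_valid,
            )
        done = bound

    if tail_row:
        rec[-1] = (t0 + n_total * step, *y)

    final_total = y[0] + y[1]
    if final_total > max_total:
        max_total = final_total
    if escape_day < 0.0 and max_total >= escape_threshold:
        escape_day = t0 + n_total * step

    if escape_day >= 0.0:
        event_log.append(
            {
                "day": escape_day,
                "type": "escape",
                "compartment": "total",
                "count": None,
            }
        )

    event_log.sort(key=lambda e: e["day"])
    return Trajectory(
        t=rec[:, 0].copy(),
        states=rec[:, 1:].copy(),
        events=event_log,
        variant=variant.value,
        step=step,
        escape_threshold=escape_threshold,
        max_total=max_total,
        escape_day=None if escape_day < 0.0 else escape_day,
        horizon=horizon,
        t0=t0,
    )


def _clone_fate(trajectory: Trajectory, column: int, escaped: bool) -> Fate:
    final = trajectory.states[-1, column]
    if final == 0.0:
        return Fate.ELIMINATED
    return Fate.ESCAPED if escaped else Fate.DORMANT


def classify_fate(
    trajectory: Trajectory,
    escape_threshold: Optional[float] = None,
    horizon: Optional[float] = None,
) -> FateLabel:
    """Assign per-clone and overall fates to a finished trajectory.

    A clone is eliminated if it ends at zero (zeroed by the extinction rule
    and never re-seeded, or never present); escaped if the total burden
    reached the threshold while the clone survived; dormant otherwise.
    Overall: escaped if either clone escaped, eliminated if both were
    eliminated, dormant otherwise.
    """
    if escape_threshold is None:
        escape_threshold = trajectory.escape_threshold
    if horizon is None:
        horizon = trajectory.horizon
    escaped = trajectory.max_total >= escape_threshold
    if trajectory.t[-1] < horizon - 0.5 * trajectory.step and not escaped:
        raise ClassificationError(
            f"trajectory ends at {trajectory.t[-1]:g} d, before the "
            f"{horizon:g}-d horizon, without an escape event"
        )
    fate_p = _clone_fate(trajectory, 0, escaped)
    fate_q = _clone_fate(trajectory, 1, escaped)
    if Fate.ESCAPED in (fate_p, fate_q):
        overall = Fate.ESCAPED
    elif fate_p == fate_q == Fate.ELIMINATED:
        overall = Fate.ELIMINATED
    else:
        overall = Fate.DORMANT
    return FateLabel(proliferative=fate_p, quiescent=fate_q, overall=overall)


def escape_onset_day(
    trajectory: Trajectory,
    definition: str = "threshold",
    compartment: str = "total",
) -> Optional[float]:
    """Time at which an escaped trajectory's escape becomes manifest.

    ``definition="threshold"`` (default) returns the day the tumor burden
    first reached the escape threshold - the moment escape is observable on
    a growth curve. ``definition="regrowth_minimum"`` returns the time of
    the last local minimum of the chosen series (``total``,
    ``proliferative`` or ``quiescent``) before the final uninterrupted rise
    to the threshold; for a monotonically growing trajectory this is the
    start time. Returns None for non-escaped trajectories.
    """
    if trajectory.max_total < trajectory.escape_threshold:
        return None
    if definition == "threshold":
        return trajectory.escape_day
    if definition != "regrowth_minimum":
        raise ConfigError(f"unknown onset definition {definition!r}")

    series = {
        "total": trajectory.total,
        "proliferative": trajectory.Cp,
        "quiescent": trajectory.Cq,
    }[compartment]
    crossing = int(np.argmax(trajectory.total >= trajectory.escape_threshold))
    if trajectory.total[crossing] < trajectory.escape_threshold:
        # Threshold crossed between recorded points; use the last point.
        crossing = len(series) - 1
    drops = np.nonzero(np.diff(series[: crossing + 1]) < 0.0)[0]
    if len(drops) == 0:
        return float(trajectory.t[0])
    return float(trajectory.t[drops[-1] + 1])
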