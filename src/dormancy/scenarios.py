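"""The four standard simulation series of the dormancy study.

* Series 1 - aggressive growth: proliferative-only runs across initial
  inocula; every run escapes, and larger inocula escape sooner.
* Series 2 - sustained dormancy: the quiescent-only run oscillates around
  a few thousand cells for the full one-year horizon.
* Series 3 - heterogeneous fates: two-clone runs whose outcome (dormant /
  eliminated / escaped, per clone) depends on the initial proliferative
  count, summarized as a phase map over initial size and composition.
* Series 4 - vaccination: quiescent ("dormant-cell") injections before or
  after a proliferative challenge, including the minimal protective dose
  search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError
from .integrator import (
    DEFAULT_ESCAPE_THRESHOLD,
    DEFAULT_HORIZON,
    DEFAULT_STEP,
    Fate,
    FateLabel,
    InjectionEvent,
    InjectionSchedule,
    Trajectory,
    classify_fate,
    integrate,
)
from .parameters import (
    DEFAULT_INOCULUM,
    InitialState,
    ParameterSet,
    default_initial_state,
)

__all__ = [
    "run_series1",
    "run_series2",
    "run_series3",
    "PhaseMap",
    "compute_phase_map",
    "VaccinationProtocol",
    "run_vaccination",
    "minimal_protective_dose",
    "DEFAULT_SERIES1_COUNTS",
    "DEFAULT_SIZE_GRID",
    "DEFAULT_PERCENT_GRID",
]

#: Initial proliferative inocula for the aggressive-growth series (cells).
DEFAULT_SERIES1_COUNTS = (5.0e3, 1.0e4, 5.0e4, 1.0e5, 5.0e5)

#: Phase-map axes: 25 log-spaced initial sizes, 26 linear percentages.
DEFAULT_SIZE_GRID = tuple(np.logspace(np.log10(2.0e4), np.log10(2.0e6), 25))
DEFAULT_PERCENT_GRID = tuple(np.linspace(0.0, 25.0, 26))


def run_series1(
    initial_counts: Sequence[float] = DEFAULT_SERIES1_COUNTS,
    params: Optional[ParameterSet] = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
    record_every: int = 1,
) -> List[Trajectory]:
    """Proliferative-only growth for each initial inoculum."""
    base = default_initial_state("proliferative")
    runs = []
    for count in initial_counts:
        if not count > 0:
            raise ConfigError(f"initial count must be > 0, got {count!r}")
        init = InitialState(Cp0=float(count), Cq0=0.0, N0=base.N0, T0=base.T0)
        runs.append(
            integrate(
                "proliferative",
                init,
                params,
                horizon=horizon,
                step=step,
                record_every=record_every,
            )
        )
    return runs


def run_series2(
    params: Optional[ParameterSet] = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
    record_every: int = 1,
) -> Trajectory:
    """The quiescent-only dormancy run (5 x 10^4 MR20-like cells)."""
    return integrate(
        "quiescent",
        default_initial_state("quiescent"),
        params,
        horizon=horizon,
        step=step,
        record_every=record_every,
    )


def run_series3(
    initial_proliferative: float,
    total: float = DEFAULT_INOCULUM,
    params: Optional[ParameterSet] = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
    record_every: int = 1,
) -> Trajectory:
    """One heterogeneous run with the given initial clonal split."""
    if not 0.0 <= initial_proliferative <= total:
        raise ConfigError(
            f"initial proliferative count {initial_proliferative!r} must lie "
            f"within the total inoculum {total!r}"
        )
    base = default_initial_state("quiescent")
    init = InitialState(
        Cp0=float(initial_proliferative),
        Cq0=float(total - initial_proliferative),
        N0=base.N0,
        T0=base.T0,
    )
    return integrate(
        "heterogeneous",
        init,
        params,
        horizon=horizon,
        step=step,
        record_every=record_every,
    )


@dataclass
class PhaseMap:
    """Fate labels over a grid of initial size x proliferative percentage.

    ``table`` is tidy with one row per grid point: columns ``size``,
    ``percent``, ``fate_proliferative``, ``fate_quiescent``,
    ``fate_overall``. Contiguity of equal fate combinations defines the
    map's regions (4-connectivity on the grid).
    """

    sizes: np.ndarray
    percents: np.ndarray
    table: pd.DataFrame

    def label_grid(self) -> np.ndarray:
        """Integer-coded (quiescent, proliferative) fate combination,
        shaped (len(sizes), len(percents))."""
        codes = {f.value: i for i, f in enumerate(Fate)}
        fq = self.table["fate_quiescent"].map(codes).to_numpy()
        fp = self.table["fate_proliferative"].map(codes).to_numpy()
        return (fq * len(codes) + fp).reshape(len(self.sizes), len(self.percents))

    def region_count(self) -> int:
        """Number of contiguous regions of constant fate combination."""
        grid = self.label_grid()
        total = 0
        for combo in np.unique(grid):
            _, n = ndimage.label(grid == combo)
            total += int(n)
        return total

    def region_combinations(self) -> List[Tuple[str, str, str]]:
        """(quiescent, proliferative, overall) fate triple of each
        contiguous region, one entry per region."""
        grid = self.label_grid()
        fq = self.table["fate_quiescent"].to_numpy().reshape(grid.shape)
        fp = self.table["fate_proliferative"].to_numpy().reshape(grid.shape)
        fo = self.table["fate_overall"].to_numpy().reshape(grid.shape)
        combos = []
        for combo in np.unique(grid):
            labeled, n = ndimage.label(grid == combo)
            for region in range(1, n + 1):
                i, j = np.argwhere(labeled == region)[0]
                combos.append((str(fq[i, j]), str(fp[i, j]), str(fo[i, j])))
        return combos

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)


def compute_phase_map(
    size_grid: Sequence[float] = DEFAULT_SIZE_GRID,
    percent_grid: Sequence[float] = DEFAULT_PERCENT_GRID,
    params: Optional[ParameterSet] = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
    escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD,
) -> PhaseMap:
    """Classify every (initial size, proliferative %) grid point.

    Trajectories are recorded sparsely (the classification only needs the
    exact per-step extinction and escape tracking, which is independent of
    the recording stride).
    """
    sizes = np.asarray(list(size_grid), dtype=float)
    percents = np.asarray(list(percent_grid), dtype=float)
    if sizes.size == 0 or percents.size == 0:
        raise ConfigError("phase-map grids must be non-empty")
    base = default_initial_state("quiescent")
    rows = []
    for size in sizes:
        for percent in percents:
            cp0 = size * percent / 100.0
            init = InitialState(Cp0=cp0, Cq0=size - cp0, N0=base.N0, T0=base.T0)
            traj = integrate(
                "heterogeneous",
                init,
                params,
                horizon=horizon,
                step=step,
                record_every=200,
                escape_threshold=escape_threshold,
            )
            fate = classify_fate(traj)
            rows.append(
                {
                    "size": size,
                    "percent": percent,
                    "fate_proliferative": fate.proliferative.value,
                    "fate_quiescent": fate.quiescent.value,
                    "fate_overall": fate.overall.value,
                }
            )
    return PhaseMap(sizes=sizes, percents=percents, table=pd.DataFrame(rows))


@dataclass
class VaccinationProtocol:
    """A dormant-cell vaccination protocol around a proliferative challenge.

    Event days are relative to the challenge (day 0); negative days are
    pre-challenge ("protective") injections, positive days post-challenge
    ("therapeutic") injections. All vaccine injections seed the quiescent
    compartment of the heterogeneous model.
    """

    events: InjectionSchedule = field(default_factory=InjectionSchedule)
    challenge_day: float = 0.0
    challenge_count: float = DEFAULT_INOCULUM
    variant: str = "heterogeneous"
    name: str = ""

    def __post_init__(self):
        if not self.challenge_count > 0:
            raise ConfigError("challenge dose must be > 0")
        if isinstance(self.events, (list, tuple)):
            self.events = InjectionSchedule(self.events)

    def all_events(self) -> List[InjectionEvent]:
        events = list(self.events) + [
            InjectionEvent(
                day=self.challenge_day,
                compartment="proliferative",
                count=self.challenge_count,
            )
        ]
        return sorted(events, key=lambda e: e.day)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "name": self.name,
            "variant": self.variant,
            "challenge": {"day": self.challenge_day, "count": self.challenge_count},
            "events": [
                {"day": e.day, "compartment": e.compartment, "count": e.count}
                for e in self.events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "VaccinationProtocol":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            events=InjectionSchedule(
                [InjectionEvent(**e) for e in payload.get("events", [])]
            ),
            challenge_day=float(payload["challenge"]["day"]),
            challenge_count=float(payload["challenge"]["count"]),
            variant=payload.get("variant", "heterogeneous"),
            name=payload.get("name", ""),
        )


def run_vaccination(
    protocol: VaccinationProtocol,
    params: Optional[ParameterSet] = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
    record_every: int = 1,
    escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD,
) -> Tuple[Trajectory, FateLabel]:
    """Simulate a vaccination protocol and classify its outcome.

    Integration starts at the earliest event (possibly before day 0) from a
    tumor-free state with the standard immune initial conditions, applies
    every injection (including the challenge) at its scheduled day, and
    runs to ``horizon`` days after the challenge. The reported time axis is
    relative to the challenge.
    """
    events = protocol.all_events()
    t0 = min(0.0, min(e.day for e in events))
    base = default_initial_state("quiescent")
    init = InitialState(Cp0=0.0, Cq0=0.0, N0=base.N0, T0=base.T0)
    traj = integrate(
        protocol.variant,
        init,
        params,
        horizon=horizon,
        step=step,
        schedule=InjectionSchedule(events),
        t0=t0,
        record_every=record_every,
        escape_threshold=escape_threshold,
    )
    return traj, classify_fate(traj)


def minimal_protective_dose(
    dose_grid: Sequence[float],
    lead_time: float = 20.0,
    params: Optional[ParameterSet] = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
    challenge_count: float = DEFAULT_INOCULUM,
    escape_threshold: float = DEFAULT_ESCAPE_THRESHOLD,
) -> Optional[float]:
    """Smallest grid dose whose protective vaccination prevents escape.

    Each dose of quiescent cells is injected ``lead_time`` days before the
    proliferative challenge; a dose protects when the run never reaches the
    escape threshold within the horizon. Returns None when no grid dose
    protects.
    """
    doses = list(dose_grid)
    if not doses:
        raise ConfigError("dose grid must be non-empty")
    if sorted(doses) != doses:
        raise ConfigError("dose grid must be sorted ascending")
    for dose in doses:
        protocol = VaccinationProtocol(
            events=InjectionSchedule(
                [InjectionEvent(day=-float(lead_time), compartment="quiescent",
                                count=float(dose))]
            ),
            challenge_count=challenge_count,
        )
        _, fate = run_vaccination(
            protocol,
            params,
            horizon=horizon,
            step=step,
            record_every=100,
            escape_threshold=escape_threshold,
        )
        if fate.overall is not Fate.ESCAPED:
            return float(dose)
    return None
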