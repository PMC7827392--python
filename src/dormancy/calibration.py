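"""Least-squares parameter estimation and Monte-Carlo sensitivity analysis.

Fitting minimizes the sum of squared differences between simulated and
observed total tumor size at the observation days, using a derivative-free
Nelder-Mead simplex in log10 parameter space (the free constants are
positive and span decades) with multiple seeded restarts.

Sensitivity analysis perturbs the immunological constants and immune
initial conditions as independent normal random variables whose standard
deviation is a fixed fraction (default 25%) of the nominal value, truncated
at zero, and tabulates the resulting fate frequencies and the envelope of
the tumor-size trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .dynamics import ModelVariant
from .errors import ConfigError, FitError, IntegrationError
from .integrator import (
    DEFAULT_HORIZON,
    DEFAULT_STEP,
    Fate,
    classify_fate,
    integrate,
)
from .parameters import (
    INITIAL_STATE_FIELDS,
    PARAMETER_FIELDS,
    InitialState,
    ParameterSet,
    default_initial_state,
)

__all__ = [
    "ObservationSeries",
    "FitResult",
    "SensitivityResult",
    "least_squares_objective",
    "fit_parameters",
    "sensitivity_analysis",
]

#: Objective value returned when the simulation blows up mid-optimization.
_PENALTY = 1.0e300


@dataclass(frozen=True)
class ObservationSeries:
    """Sparse tumor-size measurements (days strictly increasing)."""

    days: np.ndarray
    sizes: np.ndarray
    noise_scale: Optional[float] = None

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        sizes = np.asarray(self.sizes, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "sizes", sizes)
        if days.ndim != 1 or days.shape != sizes.shape:
            raise ConfigError("days and sizes must be equal-length 1-d arrays")
        if np.any(np.diff(days) <= 0):
            raise ConfigError("observation days must be strictly increasing")
        if np.any(sizes < 0):
            raise ConfigError("observed sizes must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "size": self.sizes})

    @classmethod
    def from_csv(cls, path) -> "ObservationSeries":
        frame = pd.read_csv(path)
        return cls(days=frame["day"].to_numpy(), sizes=frame["size"].to_numpy())


@dataclass
class FitResult:
    """Outcome of a least-squares fit."""

    params: Dict[str, float]
    objective: float
    converged: bool
    n_iterations: int
    n_restarts: int = 1

    def as_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "objective": self.objective,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_restarts": self.n_restarts,
        }


def _apply_free_params(
    free: Mapping[str, float], fixed: ParameterSet, initial: InitialState
) -> Tuple[ParameterSet, InitialState]:
    """Overlay free values onto the fixed constants / initial state."""
    param_changes = {k: v for k, v in free.items() if k in PARAMETER_FIELDS}
    init_changes = {k: v for k, v in free.items() if k in INITIAL_STATE_FIELDS}
    unknown = set(free) - set(param_changes) - set(init_changes)
    if unknown:
        raise ConfigError(f"unknown free parameter names: {sorted(unknown)}")
    params = fixed.replace(**param_changes) if param_changes else fixed
    init = (
        InitialState(**{**initial.to_dict(), **init_changes})
        if init_changes
        else initial
    )
    return params, init


def least_squares_objective(
    free_params: Mapping[str, float],
    observations: ObservationSeries,
    fixed: ParameterSet,
    variant: Union[str, ModelVariant] = "quiescent",
    initial: Optional[InitialState] = None,
    step: float = DEFAULT_STEP,
) -> float:
    """Sum of squared residuals of total tumor size at the observation days.

    The model is integrated to the last observation day and linearly
    interpolated onto the observation grid. Integration failures return a
    large penalty (with a warning) so an optimizer can continue.
    """
    variant = ModelVariant.coerce(variant)
    if initial is None:
        initial = default_initial_state(variant.value)
    params, init = _apply_free_params(free_params, fixed, initial)
    try:
        traj = integrate(
            variant,
            init,
            params,
            horizon=float(observations.days[-1]),
            step=step,
        )
    except (IntegrationError, ConfigError, ValueError) as exc:
        warnings.warn(f"objective penalized: {exc}", stacklevel=2)
        return _PENALTY
    simulated = np.interp(observations.days, traj.t, traj.total)
    residuals = simulated - observations.sizes
    return float(np.dot(residuals, residuals))


def fit_parameters(
    free_param_names: Sequence[str],
    bounds: Mapping[str, Tuple[float, float]],
    observations: ObservationSeries,
    fixed: ParameterSet,
    variant: Union[str, ModelVariant] = "quiescent",
    restarts: int = 3,
    seed: int = 0,
    initial: Optional[InitialState] = None,
    step: float = DEFAULT_STEP,
    xtol: float = 1e-4,
) -> FitResult:
    """Multi-start Nelder-Mead estimation of the named constants.

    Bounds must be positive and finite; the search runs in log10 space,
    which both enforces positivity and evens out the decades-wide scales
    of the rate constants. Starts are drawn uniformly in log space from a
    seeded generator, so results are reproducible. Raises :class:`FitError`
    carrying the best incumbent when no start converges.
    """
    names = list(free_param_names)
    if not names:
        raise ConfigError("free_param_names must be non-empty")
    if restarts < 1:
        raise ConfigError("restarts must be >= 1")
    log_bounds = []
    for name in names:
        if name not in bounds:
            raise ConfigError(f"missing bounds for free parameter {name!r}")
        lo, hi = bounds[name]
        if not (0 < lo < hi < np.inf):
            raise ConfigError(
                f"bounds for {name!r} must satisfy 0 < lo < hi < inf"
            )
        log_bounds.append((np.log10(lo), np.log10(hi)))
    log_bounds = np.array(log_bounds)

    def objective(log_values: np.ndarray) -> float:
        free = {n: 10.0 ** v for n, v in zip(names, log_values)}
        return least_squares_objective(
            free, observations, fixed, variant, initial=initial, step=step
        )

    # Nelder-Mead is comparison-based, so minimizing log1p(SSR) follows the
    # same path while making the function tolerance scale-free (SSR spans
    # many orders of magnitude across datasets).
    def compressed(log_values: np.ndarray) -> float:
        return float(np.log1p(objective(log_values)))

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    total_iterations = 0
    for start_index in range(restarts):
        if start_index == 0:
            x0 = log_bounds.mean(axis=1)  # center of the log-box
        else:
            x0 = rng.uniform(log_bounds[:, 0], log_bounds[:, 1])
        result = optimize.minimize(
            compressed,
            x0,
            method="Nelder-Mead",
            bounds=log_bounds,
            options={"xatol": xtol, "fatol": 1e-10, "maxiter": 2000},
        )
        total_iterations += int(result.nit)
        any_converged = any_converged or bool(result.success)
        if best is None or result.fun < best.fun:
            best = result

    fit = FitResult(
        params={n: float(10.0 ** v) for n, v in zip(names, best.x)},
        objective=float(np.expm1(best.fun)),
        converged=any_converged,
        n_iterations=total_iterations,
        n_restarts=restarts,
    )
    if not any_converged:
        raise FitError("no Nelder-Mead start converged", best=fit)
    return fit


# Grouped names: "b", "eta", "u" perturb the variant-relevant member and
# keep the alpha-coupling of the untouched partner.
_GROUPED = {
    "b": {"proliferative": "b1", "quiescent": "b2", "heterogeneous": "b2"},
    "eta": {"proliferative": "eta1", "quiescent": "eta2", "heterogeneous": "eta2"},
    "u": {"proliferative": "u1", "quiescent": "u2", "heterogeneous": "u2"},
}

DEFAULT_SENSITIVITY_PARAMS = ("N0", "T0", "b", "eta", "p", "u")


@dataclass
class SensitivityResult:
    """Replicate table, fate frequencies and trajectory envelope."""

    replicates: pd.DataFrame  # sampled values + fate per replicate
    fate_frequencies: Dict[str, float]
    envelope: pd.DataFrame  # columns t, total_min, total_median, total_max
    n_truncated: int  # negative draws truncated to zero
    scenario: str
    cv: float
    seed: int


def sensitivity_analysis(
    param_names: Sequence[str] = DEFAULT_SENSITIVITY_PARAMS,
    cv: float = 0.25,
    n_reps: int = 500,
    seed: int = 0,
    scenario: Union[str, ModelVariant] = "quiescent",
    params: Optional[ParameterSet] = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
) -> SensitivityResult:
    """Monte-Carlo perturbation of immunological constants.

    Each named quantity is drawn per replicate from
    ``Normal(mean = nominal, sd = cv * nominal)``, truncated at zero
    (negative rates and counts are biologically meaningless; the number of
    truncations is reported). Grouped names ``b``, ``eta``, ``u`` perturb
    the member relevant to the scenario (e.g. ``b2`` for quiescent runs)
    while the alpha-coupled partner follows automatically.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if not cv > 0:
        raise ConfigError("cv must be > 0")
    variant = ModelVariant.coerce(scenario)
    if params is None:
        params = ParameterSet()
    base_init = default_initial_state(variant.value)

    resolved = []
    for name in param_names:
        if name in _GROUPED:
            resolved.append(_GROUPED[name][variant.value])
        elif name in PARAMETER_FIELDS or name in INITIAL_STATE_FIELDS:
            resolved.append(name)
        else:
            raise ConfigError(f"unknown sensitivity parameter {name!r}")

    nominal = {
        name: (
            getattr(params, name)
            if name in PARAMETER_FIELDS
            else getattr(base_init, name)
        )
        for name in resolved
    }

    rng = np.random.default_rng(seed)
    rows = []
    totals = []
    n_truncated = 0
    t_grid = None
    for rep in range(n_reps):
        draws = {}
        for name in resolved:
            mean = nominal[name]
            value = rng.normal(mean, cv * mean)
            if value < 0.0:
                value = 0.0
                n_truncated += 1
            draws[name] = value
        rep_params, rep_init = _apply_free_params(draws, params, base_init)
        traj = integrate(
            variant,
            rep_init,
            rep_params,
            horizon=horizon,
            step=step,
            record_every=100,
        )
        fate = classify_fate(traj)
        rows.append({"replicate": rep, **draws, "fate": fate.overall.value})
        totals.append(traj.total)
        t_grid = traj.t

    totals = np.vstack(totals)
    replicates = pd.DataFrame(rows)
    freq = (
        replicates["fate"].value_counts(normalize=True).to_dict()
    )
    envelope = pd.DataFrame(
        {
            "t": t_grid,
            "total_min": totals.min(axis=0),
            "total_median": np.median(totals, axis=0),
            "total_max": totals.max(axis=0),
        }
    )
    return SensitivityResult(
        replicates=replicates,
        fate_frequencies={
            fate.value: float(freq.get(fate.value, 0.0)) for fate in Fate
        },
        envelope=envelope,
        n_truncated=n_truncated,
        scenario=variant.value,
        cv=cv,
        seed=seed,
    )
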