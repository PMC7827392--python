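"""Fixed-step RK4 integration kernel.

The kernel advances the four-population state between injection events with
classic 4th-order Runge-Kutta at a fixed step, applies the sub-unity
extinction rule to the tumor compartments after every accepted step, floors
the immune compartments at zero, and tracks the running maximum tumor
burden and the first crossing of the escape threshold.

The hot loop is JIT-compiled with numba when available; the identical
function runs as pure Python otherwise. It mirrors the pure right-hand
sides in :mod:`dormancy.dynamics` (agreement is asserted in the tests) and
is deliberately free of Python objects so a year-long trajectory costs
milliseconds rather than seconds.

Parameter vector layout (see :func:`pack_parameters`):
``[a1, a2, Cmax, b1, b2, eta1, eta2, s, r1, r2, g, h, f, p, j, k, m, u1, u2]``.
Variant codes: 0 proliferative, 1 quiescent, 2 heterogeneous.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly by every integration
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda func: func


VARIANT_CODES = {"proliferative": 0, "quiescent": 1, "heterogeneous": 2}

# Indices into the packed parameter vector.
_ORDER = (
    "a1", "a2", "Cmax", "b1", "b2", "eta1", "eta2", "s", "r1", "r2",
    "g", "h", "f", "p", "j", "k", "m", "u1", "u2",
)

# Kernel exit status codes.
STATUS_OK = 0
STATUS_NONFINITE = 1


def pack_parameters(params) -> np.ndarray:
    """Flatten a ParameterSet into the kernel's parameter vector."""
    return np.array([getattr(params, name) for name in _ORDER], dtype=np.float64)


@njit(cache=True)
def _rhs(y0, y1, y2, y3, prm, variant):
    """Model derivative at state (Cp, Cq, N, T) for the coded variant."""
    a1 = prm[0]; a2 = prm[1]; cmax = prm[2]; b1 = prm[3]; b2 = prm[4]
    e1 = prm[5]; e2 = prm[6]; s = prm[7]; r1 = prm[8]; r2 = prm[9]
    g = prm[10]; h = prm[11]; f = prm[12]; p = prm[13]; jj = prm[14]
    k = prm[15]; m = prm[16]; u1 = prm[17]; u2 = prm[18]

    C = y0 + y1
    if C <= 0.0:
        return 0.0, 0.0, s - f * y2, -m * y3

    lg = math.log(cmax / C)
    csq = C * C
    rec_n = csq / (h + csq)
    rec_t = csq / (k + csq)

    if variant == 0:  # proliferative only
        dCp = a1 * y0 * lg - b1 * y2 * y0 - e1 * y3 * y0
        dCq = 0.0
        rr = r1
        uu = u1
    elif variant == 1:  # quiescent only
        dCp = 0.0
        dCq = a2 * y1 * lg - b2 * y2 * y1 - e2 * y3 * y1
        rr = r2
        uu = u2
    else:  # heterogeneous: population-weighted proliferative-side constants
        w = y0 / C
        v = 1.0 - w
        a1h = a1 * w + a2 * v
        b1h = b1 * w + b2 * v
        e1h = e1 * w + e2 * v
        rr = r1 * w + r2 * v
        uu = u1 * w + u2 * v
        dCp = a1h * y0 * lg - b1h * y2 * y0 - e1h * y3 * y0
        dCq = a2 * y1 * lg - b2 * y2 * y1 - e2 * y3 * y1

    dN = s + y2 * g * rec_n - p * C * y2 - f * y2
    dT = rr * y2 * C + y3 * jj * rec_t - uu * C * y3 - m * y3
    return dCp, dCq, dN, dT


@njit(cache=True)
def rk4_segment(y, t0, n_steps, dt, prm, variant, threshold, stride,
                global_offset, rec, max_total_in, escape_day_in):
    """Integrate ``n_steps`` RK4 steps from ``t0``, recording into ``rec``.

    ``y`` (length 4) is updated in place. Rows of ``rec`` are filled for
    every global step index divisible by ``stride`` (global index =
    ``global_offset`` + local step). Returns
    ``(status, steps_done, extinct_p_day, extinct_q_day, escape_day, max_total)``
    where the extinction days are -1.0 if the compartment was not zeroed in
    this segment and ``escape_day`` carries through the first threshold
    crossing (-1.0 if never crossed yet).
    """
    half = 0.5 * dt
    sixth = dt / 6.0
    max_total = max_total_in
    escape_day = escape_day_in
    ext_p = -1.0
    ext_q = -1.0

    tot0 = y[0] + y[1]
    if tot0 > max_total:
        max_total = tot0
    if escape_day < 0.0 and max_total >= threshold:
        escape_day = t0

    for i in range(n_steps):
        y0 = y[0]; y1 = y[1]; y2 = y[2]; y3 = y[3]
        k1 = _rhs(y0, y1, y2, y3, prm, variant)
        k2 = _rhs(y0 + half * k1[0], y1 + half * k1[1],
                  y2 + half * k1[2], y3 + half * k1[3], prm, variant)
        k3 = _rhs(y0 + half * k2[0], y1 + half * k2[1],
                  y2 + half * k2[2], y3 + half * k2[3], prm, variant)
        k4 = _rhs(y0 + dt * k3[0], y1 + dt * k3[1],
                  y2 + dt * k3[2], y3 + dt * k3[3], prm, variant)
        y0 = y0 + sixth * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        y1 = y1 + sixth * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        y2 = y2 + sixth * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        y3 = y3 + sixth * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])

        t = t0 + (i + 1) * dt

        if not (math.isfinite(y0) and math.isfinite(y1)
                and math.isfinite(y2) and math.isfinite(y3)):
            return STATUS_NONFINITE, i, ext_p, ext_q, escape_day, max_total

        # Sub-unity extinction rule (tumor compartments only).
        if 0.0 < y0 < 1.0:
            y0 = 0.0
            if ext_p < 0.0:
                ext_p = t
        if 0.0 < y1 < 1.0:
            y1 = 0.0
            if ext_q < 0.0:
                ext_q = t
        # Immune compartments are floored at zero, never flagged extinct.
        if y2 < 0.0:
            y2 = 0.0
        if y3 < 0.0:
            y3 = 0.0

        y[0] = y0; y[1] = y1; y[2] = y2; y[3] = y3

        tot = y0 + y1
        if tot > max_total:
            max_total = tot
        if escape_day < 0.0 and max_total >= threshold:
            escape_day = t

        gidx = global_offset + i + 1
        if gidx % stride == 0:
            row = gidx // stride
            rec[row, 0] = t
            rec[row, 1] = y0
            rec[row, 2] = y1
            rec[row, 3] = y2
            rec[row, 4] = y3

    return STATUS_OK, n_steps, ext_p, ext_q, escape_day, max_total
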