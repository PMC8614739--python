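"""Adaptive Dormand-Prince 4(5) integrator for the scalar component balance.

The interval rate fit solves, for a candidate constant rate ``q``, one of

    biomass   : dc/dt = (q - D(t)) * c
    strict    : dc/dt = q * X(t) + feed(t) - D(t) * X(t)
    standard  : dc/dt = q * X(t) + feed(t) - D(t) * c

where X(t) (biomass), D(t) (dilution) and feed(t) (volumetric feed source
term) are piecewise-linear profiles sampled on a shared grid.  The ``strict``
variant keeps the dilution term proportional to biomass in every balance;
``standard`` dilutes the balanced component itself.  The solver is compiled
with numba because the Monte Carlo chain calls it hundreds of thousands of
times; accuracy is controlled by ``rtol`` (typically 1e-8) and cross-checked
against scipy's solve_ivp in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


KIND_BIOMASS = 0
KIND_STRICT = 1
KIND_STANDARD = 2


@njit(cache=False)
def _rhs(t, c, q, kind, tg, xg, dg, fg):
    d = np.interp(t, tg, dg)
    if kind == KIND_BIOMASS:
        return (q - d) * c
    x = np.interp(t, tg, xg)
    base = q * x + np.interp(t, tg, fg)
    if kind == KIND_STRICT:
        return base - d * x
    return base - d * c


@njit(cache=False)
def integrate_balance(c0, t0, t1, q, kind, tg, xg, dg, fg, rtol, atol):
    """Integrate the balance ODE from ``t0`` to ``t1``; returns c(t1).

    Dormand-Prince RK45 with standard step control (safety 0.9, factor
    clipped to [0.2, 5]).  Steps never straddle a knot of the interpolation
    grid: the profiles are piecewise linear, so the RHS is smooth inside a
    knot interval but kinked at the knots, and the embedded error estimate
    cannot see a kink crossed mid-step.  Returns NaN if the step count
    explodes.
    """
    t = t0
    c = c0
    h = (t1 - t0) / 16.0
    if h <= 0.0:
        return c0
    # index of the first grid knot strictly ahead of t
    j = np.searchsorted(tg, t0 + 1e-12)
    k1 = _rhs(t, c, q, kind, tg, xg, dg, fg)
    for _ in range(1000000):
        if t >= t1:
            return c
        h_cap = t1 - t
        while j < tg.size and tg[j] <= t + 1e-12:
            j += 1
        if j < tg.size and tg[j] - t < h_cap:
            h_cap = tg[j] - t
        if h > h_cap:
            h = h_cap
        k2 = _rhs(t + h / 5.0, c + h * (k1 / 5.0), q, kind, tg, xg, dg, fg)
        k3 = _rhs(
            t + 3.0 * h / 10.0,
            c + h * (3.0 / 40.0 * k1 + 9.0 / 40.0 * k2),
            q, kind, tg, xg, dg, fg,
        )
        k4 = _rhs(
            t + 4.0 * h / 5.0,
            c + h * (44.0 / 45.0 * k1 - 56.0 / 15.0 * k2 + 32.0 / 9.0 * k3),
            q, kind, tg, xg, dg, fg,
        )
        k5 = _rhs(
            t + 8.0 * h / 9.0,
            c
            + h
            * (
                19372.0 / 6561.0 * k1
                - 25360.0 / 2187.0 * k2
                + 64448.0 / 6561.0 * k3
                - 212.0 / 729.0 * k4
            ),
            q, kind, tg, xg, dg, fg,
        )
        k6 = _rhs(
            t + h,
            c
            + h
            * (
                9017.0 / 3168.0 * k1
                - 355.0 / 33.0 * k2
                + 46732.0 / 5247.0 * k3
                + 49.0 / 176.0 * k4
                - 5103.0 / 18656.0 * k5
            ),
            q, kind, tg, xg, dg, fg,
        )
        c5 = c + h * (
            35.0 / 384.0 * k1
            + 500.0 / 1113.0 * k3
            + 125.0 / 192.0 * k4
            - 2187.0 / 6784.0 * k5
            + 11.0 / 84.0 * k6
        )
        k7 = _rhs(t + h, c5, q, kind, tg, xg, dg, fg)
        c4 = c + h * (
            5179.0 / 57600.0 * k1
            + 7571.0 / 16695.0 * k3
            + 393.0 / 640.0 * k4
            - 92097.0 / 339200.0 * k5
            + 187.0 / 2100.0 * k6
            + 1.0 / 40.0 * k7
        )
        err = abs(c5 - c4)
        scale = atol + rtol * max(abs(c), abs(c5))
        if scale <= 0.0:
            scale = atol if atol > 0.0 else 1e-300
        ratio = err / scale
        if ratio <= 1.0:
            t = t + h
            c = c5
            k1 = k7  # FSAL
            if ratio == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * ratio ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
        else:
            fac = 0.9 * ratio ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            k1 = _rhs(t, c, q, kind, tg, xg, dg, fg)
        h = h * fac
        if h <= 0.0 or not np.isfinite(c):
            return np.nan
    return np.nan
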