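"""Piecewise-constant specific rates from component mass balances.

Between two consecutive offline samples the biomass-specific rate is assumed
constant.  The component balance ODE is integrated from the measured start
concentration and the rate is found by a derivative-free scalar minimisation
of the squared mismatch at the interval end point (and any interior points
when intervals are grouped).  Solving the balance, rather than taking finite
differences, accounts for feed and dilution dynamics inside the interval and
closes the mass balance by construction.

Balance forms (``strict_dilution`` selects the first):

    biomass   : dcX/dt = (mu - D) cX
    production: dcP/dt = qP cX - D cX      (strict)   or  - D cP  (standard)
    uptake    : dcS/dt = qS cX + c_feed F/V - D cX    or  - D cS

Uptake rates are negative when consuming.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from ._ivp import KIND_BIOMASS, KIND_STANDARD, KIND_STRICT, integrate_balance
from .data_model import FeedSpec, MeasurementSeries, ProcessDataset, Profile, RateSeries

__all__ = [
    "BalanceKind",
    "BalanceSpec",
    "RateFitError",
    "fit_interval_rate",
    "estimate_mu",
    "estimate_q",
]

_RATE_BOUND = 10.0  # |q| bracket, 1/h or g/(g h); failures outside are diagnosable
_Q_XATOL = 1e-10
_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-14


class BalanceKind(str, enum.Enum):
    BIOMASS_GROWTH = "biomass_growth"
    PRODUCTION = "production"
    UPTAKE = "uptake"


@dataclass
class BalanceSpec:
    """Structural choice of the component balance for one signal."""

    component: str
    kind: BalanceKind
    feed: FeedSpec | None = None
    strict_dilution: bool = True

    def __post_init__(self) -> None:
        self.kind = BalanceKind(self.kind)


class RateFitError(RuntimeError):
    pass


def _as_profile(p, t0: float, t1: float) -> Profile:
    if p is None:
        return Profile.constant(0.0)
    if isinstance(p, Profile):
        return p
    if isinstance(p, MeasurementSeries):
        return Profile(p.times, p.values)
    if callable(p):
        return Profile.from_callable(p, t0, t1)
    return Profile.constant(float(p))


def _shared_grid(t0: float, t1: float, profiles: list[Profile]) -> np.ndarray:
    knots = [np.array([t0, t1])]
    for p in profiles:
        m = (p.times > t0) & (p.times < t1)
        knots.append(p.times[m])
    return np.unique(np.concatenate(knots))


def _finite_difference_guess(kind, c_start, c_end, t0, t1, tg, xg, dg, fg) -> float:
    """Crude rate estimate used to seed and bracket the scalar search."""
    dt = t1 - t0
    m = (tg >= t0) & (tg <= t1)
    ts = np.concatenate(([t0], tg[m], [t1]))
    ts = np.unique(ts)
    d_bar = np.trapezoid(np.interp(ts, tg, dg), ts) / dt
    if kind == KIND_BIOMASS:
        if c_start > 0 and c_end > 0:
            return float(np.log(c_end / c_start) / dt + d_bar)
        return 0.0
    x = np.interp(ts, tg, xg)
    f = np.interp(ts, tg, fg)
    int_x = np.trapezoid(x, ts)
    if int_x <= 0:
        return 0.0
    if kind == KIND_STRICT:
        sink = np.trapezoid(np.interp(ts, tg, dg) * x, ts)
    else:
        c_lin = np.interp(ts, [t0, t1], [c_start, c_end])
        sink = np.trapezoid(np.interp(ts, tg, dg) * c_lin, ts)
    return float((c_end - c_start - np.trapezoid(f, ts) + sink) / int_x)


def fit_interval_rate(
    balance: BalanceSpec,
    c_start: float,
    c_end: float,
    cX_profile=None,
    D=None,
    feed_term=None,
    t_start: float = 0.0,
    t_end: float = 1.0,
    interior: list[tuple[float, float]] | None = None,
    rtol: float = _ODE_RTOL,
) -> float:
    """Best constant rate q over [t_start, t_end] for one component balance.

    ``cX_profile``, ``D`` and ``feed_term`` may be :class:`Profile` objects,
    measurement series, callables or constants; ``feed_term`` is the already
    assembled volumetric source c_feed*F/V in g/L/h.  ``interior`` optionally
    lists additional ``(t, c_measured)`` points whose squared mismatches enter
    the objective (interval grouping).  The ODE is solved with an adaptive
    explicit Runge-Kutta pair (rtol 1e-8) and q by bounded scalar minimisation
    to 1e-10 within |q| <= 10.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    cx = _as_profile(cX_profile, t_start, t_end)
    d = _as_profile(D, t_start, t_end)
    f = _as_profile(feed_term, t_start, t_end)
    tg = _shared_grid(t_start, t_end, [cx, d, f])
    xg, dg, fg = cx(tg), d(tg), f(tg)

    if balance.kind is BalanceKind.BIOMASS_GROWTH:
        kind = KIND_BIOMASS
    elif balance.strict_dilution:
        kind = KIND_STRICT
    else:
        kind = KIND_STANDARD

    targets = sorted((interior or []) + [(t_end, c_end)])

    def endpoint(q: float) -> float:
        c = c_start
        t_prev = t_start
        for t_k, _ in targets:
            c = integrate_balance(
                c, t_prev, t_k, q, kind, tg, xg, dg, fg, rtol, _ODE_ATOL
            )
            if not np.isfinite(c):
                return np.nan
            t_prev = t_k
        return c

    def sse(q: float) -> float:
        c = c_start
        t_prev = t_start
        total = 0.0
        for t_k, c_meas in targets:
            c = integrate_balance(
                c, t_prev, t_k, q, kind, tg, xg, dg, fg, rtol, _ODE_ATOL
            )
            if not np.isfinite(c):
                return 1e300
            total += (c - c_meas) ** 2
            t_prev = t_k
        return total

    q0 = _finite_difference_guess(kind, c_start, c_end, t_start, t_end, tg, xg, dg, fg)
    # golden-section search needs the minimum inside its bracket; start from a
    # window around the finite-difference rate and widen until it is interior
    width = max(0.05, 2.0 * abs(q0))
    res = None
    while True:
        lo = max(-_RATE_BOUND, q0 - width)
        hi = min(_RATE_BOUND, q0 + width)
        res = minimize_scalar(
            sse,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _Q_XATOL, "maxiter": 500},
        )
        at_edge = min(res.x - lo, hi - res.x) < 1e-6 * max(1.0, width)
        if not at_edge or (lo == -_RATE_BOUND and hi == _RATE_BOUND):
            break
        width *= 4.0
    if not res.success or not np.isfinite(res.x):
        raise RateFitError(
            f"rate fit failed for {balance.component} on "
            f"[{t_start:g}, {t_end:g}] h: {res.message}"
        )
    q_best = float(res.x)
    if interior is None:
        # mass-balance closure: the fitted rate must reproduce the end point.
        # The modelled end point is monotone in q for these balances, so when
        # the scalar minimiser stalls short of closure, polish by a bracketed
        # root solve on the signed mismatch.
        scale = max(1.0, abs(c_end), abs(c_start))
        resid = np.sqrt(res.fun)
        if resid > 1e-8 * scale:
            g_best = endpoint(q_best) - c_end
            delta = max(1e-6, abs(q_best) * 1e-4)
            lo = hi = q_best
            g_lo = g_hi = g_best
            for _ in range(60):
                if np.isfinite(g_lo) and np.isfinite(g_hi) and g_lo * g_hi < 0:
                    break
                lo = max(-_RATE_BOUND, lo - delta)
                hi = min(_RATE_BOUND, hi + delta)
                g_lo = endpoint(lo) - c_end
                g_hi = endpoint(hi) - c_end
                delta *= 2.0
            if np.isfinite(g_lo) and np.isfinite(g_hi) and g_lo * g_hi < 0:
                q_best = float(
                    brentq(lambda q: endpoint(q) - c_end, lo, hi, xtol=_Q_XATOL)
                )
                resid = abs(endpoint(q_best) - c_end)
        if resid > 1e-5 * scale:
            raise RateFitError(
                f"mass balance for {balance.component} cannot close on "
                f"[{t_start:g}, {t_end:g}] h (residual {resid:.3g})"
            )
    return q_best


def _growth_trajectory(
    mu: float, c_start: float, t0: float, t1: float, d: Profile, n_min: int = 65
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of dc/dt = (mu - D(t)) c for piecewise-linear D.

    c(t) = c0 * exp(mu (t - t0) - int_t0^t D), with the integral evaluated by
    the trapezoid rule on the D knots (exact for a piecewise-linear D).
    """
    m = (d.times > t0) & (d.times < t1)
    ts = np.unique(np.concatenate((np.linspace(t0, t1, n_min), d.times[m])))
    dv = d(ts)
    int_d = np.concatenate(([0.0], np.cumsum(0.5 * (dv[1:] + dv[:-1]) * np.diff(ts))))
    return ts, c_start * np.exp(mu * (ts - t0) - int_d)


def _grouped(times: np.ndarray, values: np.ndarray, group: int):
    """Yield (t0, c0, t1, c1, interior) measurement groups of `group` intervals."""
    n = times.size
    i = 0
    while i < n - 1:
        j = min(i + group, n - 1)
        interior = [(float(times[k]), float(values[k])) for k in range(i + 1, j)]
        yield float(times[i]), float(values[i]), float(times[j]), float(values[j]), interior
        i = j


def estimate_mu(
    ds: ProcessDataset,
    D=None,
    biomass_signal: str = "biomass",
    group: int = 1,
) -> tuple[RateSeries, Profile]:
    """Specific growth rate per measurement interval plus the implied cX(t).

    Returns the rate series and the continuous piecewise-exponential biomass
    trajectory reconstructed from the fitted rates, which downstream uptake
    and production balances use as their cX input.
    """
    cx = ds.resolved(biomass_signal) if biomass_signal in ds.uncertainty else ds.series(biomass_signal)
    if len(cx) < 2:
        raise ValueError("need at least two biomass measurements")
    return mu_from_series(cx.times, cx.values, D=D, group=group)


def mu_from_series(
    times: np.ndarray,
    values: np.ndarray,
    D=None,
    group: int = 1,
    rtol: float = _ODE_RTOL,
    trajectory_knots: int = 65,
) -> tuple[RateSeries, Profile]:
    """Growth-rate fit on plain arrays (used by the Monte Carlo chain)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    spec = BalanceSpec("biomass", BalanceKind.BIOMASS_GROWTH)
    starts, ends, mus = [], [], []
    traj_t: list[np.ndarray] = []
    traj_c: list[np.ndarray] = []
    d = _as_profile(D, float(times[0]), float(times[-1]))
    for t0, c0, t1, c1, interior in _grouped(times, values, group):
        mu = fit_interval_rate(
            spec, c0, c1, None, d, None, t0, t1, interior or None, rtol=rtol
        )
        ts, cs = _growth_trajectory(mu, c0, t0, t1, d, n_min=trajectory_knots)
        starts.append(t0)
        ends.append(t1)
        mus.append(mu)
        traj_t.append(ts[:-1] if t1 < times[-1] else ts)
        traj_c.append(cs[:-1] if t1 < times[-1] else cs)
    rates = RateSeries(
        name="mu",
        interval_starts=np.repeat(starts, 1),
        interval_ends=np.array(ends),
        values=np.array(mus),
        units="1/h",
    )
    profile = Profile(np.concatenate(traj_t), np.concatenate(traj_c))
    return rates, profile


def estimate_q(
    ds: ProcessDataset,
    component: str,
    D=None,
    cX_profile: Profile | None = None,
    kind: BalanceKind | str = BalanceKind.PRODUCTION,
    feed_term=None,
    strict_dilution: bool = True,
    group: int = 1,
    rate_name: str | None = None,
) -> RateSeries:
    """Specific production/uptake rate of ``component`` per interval."""
    series = ds.series(component)
    return q_from_series(
        series.times,
        series.values,
        D=D,
        cX_profile=cX_profile,
        kind=kind,
        feed_term=feed_term,
        strict_dilution=strict_dilution,
        group=group,
        rate_name=rate_name or f"q_{component}",
        component=component,
    )


def q_from_series(
    times,
    values,
    D=None,
    cX_profile=None,
    kind: BalanceKind | str = BalanceKind.PRODUCTION,
    feed_term=None,
    strict_dilution: bool = True,
    group: int = 1,
    rate_name: str = "q",
    component: str = "component",
    rtol: float = _ODE_RTOL,
) -> RateSeries:
    """Uptake/production fit on plain arrays (used by the Monte Carlo chain)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two measurements")
    spec = BalanceSpec(component, BalanceKind(kind), strict_dilution=strict_dilution)
    if spec.kind is BalanceKind.BIOMASS_GROWTH:
        raise ValueError("use mu_from_series for the biomass balance")
    starts, ends, qs = [], [], []
    for t0, c0, t1, c1, interior in _grouped(times, values, group):
        q = fit_interval_rate(
            spec, c0, c1, cX_profile, D, feed_term, t0, t1, interior or None, rtol=rtol
        )
        starts.append(t0)
        ends.append(t1)
        qs.append(q)
    unit = "g/(g h)"
    return RateSeries(
        name=rate_name,
        interval_starts=np.array(starts),
        interval_ends=np.array(ends),
        values=np.array(qs),
        units=unit,
    )
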