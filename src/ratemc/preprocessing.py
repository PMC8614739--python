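"""Derived online inputs: feed rates, reactor volume, dilution rate.

Feed balances log cumulative weight at high frequency; their time derivative
(the volumetric feed rate) is obtained by Savitzky-Golay differentiation.
Volume bookkeeping integrates all inflows and applies sampling withdrawals as
step changes; the dilution rate is total inflow over current volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import savgol_filter

from .data_model import FeedSpec, MeasurementSeries, ProcessDataset

__all__ = ["FlowSeries", "savgol_flow", "reconstruct_volume", "dilution_series"]


@dataclass
class FlowSeries:
    """Volumetric flow (L/h) derived from one feed balance."""

    times: np.ndarray
    flow: np.ndarray
    sigma: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.times.shape == self.flow.shape == self.sigma.shape):
            raise ValueError("flow series fields must have equal length")

    def __call__(self, t):
        return np.interp(t, self.times, self.flow)


@lru_cache(maxsize=32)
def _savgol_deriv_noise_gain(window: int, order: int) -> tuple[float, ...]:
    """Per-position noise gain of the SG first-derivative filter (unit dt).

    Position ``window//2`` is the symmetric interior filter; the other
    positions correspond to the one-sided evaluations used for the edge
    points, whose variance is considerably larger.
    """
    half = window // 2
    x = np.arange(window, dtype=float) - half
    A = np.vander(x, order + 1, increasing=True)
    pinv = np.linalg.pinv(A)
    gains = []
    for p in range(window):
        row = np.zeros(window)
        for j in range(1, order + 1):
            row += j * x[p] ** (j - 1) * pinv[j]
        gains.append(float(np.linalg.norm(row)))
    return tuple(gains)


def savgol_flow(
    balance: MeasurementSeries,
    density: float,
    window: int = 51,
    order: int = 2,
    clip_negative: bool = True,
) -> FlowSeries:
    """Differentiate a cumulative balance weight into a volumetric flow.

    Savitzky-Golay first derivative (local polynomial of ``order`` over
    ``window`` points); an even ``window`` is bumped to the next odd number
    since symmetric windows require odd length.  Edge points come from a
    polynomial refit over the truncated one-sided windows (scipy's ``interp``
    mode).  Weight (g) is converted to volume via ``density`` (g/mL).

    If the balance carries a resolved sigma, negative smoothed flows smaller
    in magnitude than three propagated flow sigmas are clipped to zero (a
    cumulative balance cannot run backwards); larger negative excursions are
    reported as a data problem via a warning and left in place.
    """
    t, w = balance.times, balance.values
    if t.size < 2:
        raise ValueError("need at least two balance points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("Savitzky-Golay differentiation requires a uniform time grid")
    dt = float(dt[0])
    if window % 2 == 0:
        window += 1
    if order >= window:
        raise ValueError("polynomial order must be smaller than the window")
    if t.size < window:
        raise ValueError(
            f"{t.size} points < window {window}; use a smaller window"
        )
    dwdt = savgol_filter(w, window, order, deriv=1, delta=dt, mode="interp")
    grams_per_litre = density * 1000.0
    flow = dwdt / grams_per_litre

    if balance.sigma is not None and np.any(balance.sigma > 0):
        gains = np.asarray(_savgol_deriv_noise_gain(window, order))
        half = window // 2
        sig_w = float(np.median(balance.sigma))
        sigma = np.full_like(flow, gains[half])
        n = flow.size
        sigma[:half] = gains[:half]
        sigma[n - half:] = gains[window - half:]
        sigma *= sig_w / (dt * grams_per_litre)
    else:
        sigma = np.zeros_like(flow)

    if clip_negative:
        # numerically-zero negatives (float noise on flat/smooth signals) are
        # always clipped; beyond that the propagated sigma decides
        tiny = 1e-10 * (float(np.max(np.abs(w))) + 1.0) / grams_per_litre
        neg = flow < 0
        bad = neg & (np.abs(flow) >= np.maximum(3.0 * sigma, tiny))
        small = neg & ~bad
        if np.any(small):
            flow = np.where(small, 0.0, flow)
        if np.any(bad):
            warnings.warn(
                f"{balance.name}: {int(bad.sum())} strongly negative flow points "
                "exceed 3 sigma - check the balance log",
                stacklevel=2,
            )
    return FlowSeries(times=t, flow=flow, sigma=sigma, source=balance.name)


def _union_grid(ds: ProcessDataset, flows: list[FlowSeries]) -> np.ndarray:
    pieces = [f.times for f in flows]
    pieces.append(np.array([t for t, _ in ds.sample_events], dtype=float))
    grid = np.unique(np.concatenate(pieces)) if pieces else np.array([0.0])
    return grid


def reconstruct_volume(ds: ProcessDataset, flows: list[FlowSeries]) -> MeasurementSeries:
    """Reactor volume V(t) = V0 + sum of integrated inflows - withdrawals.

    Inflows are trapezoid-integrated on the union of all flow grids; each
    sampling withdrawal is applied as a step at its event time (the grid value
    at the event time is the post-withdrawal volume).
    """
    grid = _union_grid(ds, flows)
    total_in = np.zeros_like(grid)
    for f in flows:
        total_in += np.interp(grid, f.times, f.flow)
    added = np.concatenate(
        ([0.0], np.cumsum(0.5 * (total_in[1:] + total_in[:-1]) * np.diff(grid)))
    )
    withdrawn = np.zeros_like(grid)
    for t_ev, v_ev in ds.sample_events:
        withdrawn[grid >= t_ev - 1e-12] += v_ev
    volume = ds.initial_volume + added - withdrawn
    if np.any(volume <= 0):
        t_bad = grid[np.argmax(volume <= 0)]
        raise ValueError(f"reconstructed volume non-positive at t={t_bad:g} h")
    return MeasurementSeries(name="V", times=grid, values=volume, units="L")


def dilution_series(V: MeasurementSeries, flows: list[FlowSeries]) -> MeasurementSeries:
    """Dilution rate D(t) = (sum of all inflows) / V(t), in 1/h.

    All liquid additions (substrate feeds and acid/base) count towards the
    total inflow.
    """
    total_in = np.zeros_like(V.times)
    for f in flows:
        total_in += np.interp(V.times, f.times, f.flow)
    D = total_in / V.values
    return MeasurementSeries(name="D", times=V.times, values=D, units="1/h")


def feed_term_series(
    feed: FeedSpec, flow: FlowSeries, V: MeasurementSeries
) -> MeasurementSeries:
    """Volumetric source term c_feed * F(t) / V(t) of a substrate feed (g/L/h)."""
    F = np.interp(V.times, flow.times, flow.flow)
    return MeasurementSeries(
        name=f"feed_term_{feed.name}",
        times=V.times,
        values=feed.concentration * F / V.values,
        units="g/L/h",
    )
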