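"""Synthetic fed-batch cultivations with known ground truth.

The generator forward-integrates the same component mass balances the rate
estimator inverts, with prescribed piecewise-constant specific rates aligned
to the sampling grid, and then corrupts the truth with the measurement error
model of a typical analytical setup: balance weights logged every 30 s with
an absolute sigma of 0.1 g, withdrawn sample volumes with a graduated-syringe
sigma of 3 mL, offline concentrations with relative errors of a few percent
or as replicate sets (triplicate dry weights, duplicate cell counts).

Two presets emulate the study conditions the package is aimed at:

``ecoli_like``
    12 h induction phase of a glycerol-limited E. coli fed-batch, 2-hourly
    sampling, exponential feed, dry-weight biomass in g/L, product formation
    linearly tied to substrate uptake (slope ~0.15).
``cho_like``
    10-day CHO fed-batch, daily sampling, cell counts in 1e8 cells/L,
    lactate formation linearly tied to glutamine uptake (slope ~1.9 with a
    negative intercept, so lactate production turns into consumption as the
    glutamine supply is lowered), and a late-process viability decline for
    harvest-decision analyses.

Rates are prescribed, not emergent from kinetics; that is what makes exact
round-trip recovery tests possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    FeedSpec,
    MeasurementSeries,
    ProcessDataset,
    SigmaKind,
    UncertaintySpec,
)

__all__ = [
    "FeedSegment",
    "SyntheticFeed",
    "SimulationScenario",
    "Truth",
    "simulate_truth",
    "observe",
    "ecoli_like",
    "cho_like",
]


@dataclass(frozen=True)
class FeedSegment:
    """F(t) = rate0 * exp(k * (t - t0)) on [t0, t1); k = 0 gives a constant."""

    t0: float
    t1: float
    rate0: float
    k: float = 0.0

    def flow(self, t: float) -> float:
        return self.rate0 * math.exp(self.k * (t - self.t0))

    def added_volume(self, t: float) -> float:
        """Integral of the flow from t0 to min(t, t1)."""
        te = min(t, self.t1)
        if te <= self.t0:
            return 0.0
        if self.k == 0.0:
            return self.rate0 * (te - self.t0)
        return self.rate0 / self.k * (math.exp(self.k * (te - self.t0)) - 1.0)


@dataclass
class SyntheticFeed:
    """A feed pump with an analytic flow schedule.

    ``target`` names the component state this feed supplies (``None`` for
    acid/base, which only add volume); ``concentration`` in g/L of that
    component, ``density`` in g/mL for the balance weight.
    """

    name: str
    concentration: float
    density: float
    segments: list[FeedSegment]
    target: str | None = None

    def flow(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for seg in self.segments:
            m = (t >= seg.t0) & (t < seg.t1)
            out[m] = seg.rate0 * np.exp(seg.k * (t[m] - seg.t0))
        # closed right end of the last segment
        last = self.segments[-1]
        m = t >= last.t1
        out[m] = last.rate0 * math.exp(last.k * (last.t1 - last.t0))
        return out

    def cumulative_volume(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.array([sum(s.added_volume(ti) for s in self.segments) for ti in t])

    def cumulative_weight(self, t) -> np.ndarray:
        return self.cumulative_volume(t) * self.density * 1000.0


@dataclass
class SimulationScenario:
    """Full specification of one synthetic cultivation.

    ``rates`` holds one value per sampling interval for ``"mu"`` and each
    component rate; ``component_balances`` maps a component signal to its
    balance kind (``"uptake"``/``"production"``) and the name of the feed that
    supplies it (or ``None``).  ``extra_signals`` carries signals observed but
    not mass-balanced (e.g. viability, in percent).
    """

    preset: str
    horizon: float
    sampling_times: np.ndarray
    initial_state: dict[str, float]
    rates: dict[str, np.ndarray]
    component_balances: dict[str, tuple[str, str | None]]
    feeds: list[SyntheticFeed] = field(default_factory=list)
    strict_dilution: bool = True
    sample_volume: float = 0.02
    noise: dict[str, UncertaintySpec] = field(default_factory=dict)
    replicate_counts: dict[str, int] = field(default_factory=dict)
    balance_sigma: float = 0.1
    syringe_sigma: float = 0.003
    balance_dt: float = 1.0 / 120.0  # 30 s online logging grid
    aligned: bool = True
    extra_signals: dict[str, np.ndarray] = field(default_factory=dict)
    biomass_units: str = "g/L"
    rate_units: str = "g/(g h)"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        n_int = self.sampling_times.size - 1
        for name, vals in self.rates.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size != n_int:
                raise ValueError(f"rate {name!r} needs {n_int} interval values")
            self.rates[name] = vals

    @property
    def components(self) -> list[str]:
        return list(self.component_balances)


@dataclass
class Truth:
    """Dense noise-free trajectories of one simulated cultivation."""

    times: np.ndarray
    states: dict[str, np.ndarray]  # biomass + components, keyed by signal name
    volume: np.ndarray
    dilution: np.ndarray
    flows: dict[str, np.ndarray]
    sampling_times: np.ndarray
    at_samples: dict[str, np.ndarray]
    scenario: SimulationScenario

    def flow_of(self, name: str):
        t, f = self.times, self.flows[name]
        return lambda x: np.interp(x, t, f)


def _rhs(y, t, scn: SimulationScenario, idx: int, comps: list[str]) -> np.ndarray:
    X = y[0]
    V = y[-1]
    flows = {f.name: float(f.flow(t)[0]) for f in scn.feeds}
    F_tot = sum(flows.values())
    D = F_tot / V
    dy = np.empty_like(y)
    mu = scn.rates["mu"][idx]
    dy[0] = (mu - D) * X
    for j, c in enumerate(comps, start=1):
        kind, feed_name = scn.component_balances[c]
        q = scn.rates[c][idx]
        term = q * X
        if feed_name is not None:
            feed = next(f for f in scn.feeds if f.name == feed_name)
            term += feed.concentration * flows[feed_name] / V
        if scn.strict_dilution:
            term -= D * X
        else:
            term -= D * y[j]
        dy[j] = term
    dy[-1] = F_tot
    return dy


def simulate_truth(scn: SimulationScenario, max_step: float = 0.005) -> Truth:
    """Forward-integrate the scenario's balances on a fine grid.

    Classic RK4 with fixed steps no longer than ``max_step`` hours within each
    sampling interval; sampling withdrawals are applied to the volume as step
    changes at the sampling times (concentrations are unaffected by ideal
    sampling).  Raises if any concentration or the volume turns negative -
    that marks an infeasible scenario, not a numerical problem.
    """
    comps = scn.components
    ts = scn.sampling_times
    y = np.array(
        [scn.initial_state["biomass"]]
        + [scn.initial_state[c] for c in comps]
        + [scn.initial_state["V"]]
    )
    grid: list[np.ndarray] = []
    traj: list[np.ndarray] = []
    at_samples = {name: [] for name in ["biomass", *comps, "V"]}

    def record_sample(yv):
        at_samples["biomass"].append(yv[0])
        for j, c in enumerate(comps, start=1):
            at_samples[c].append(yv[j])
        at_samples["V"].append(yv[-1])

    for k in range(ts.size - 1):
        t0, t1 = float(ts[k]), float(ts[k + 1])
        record_sample(y)
        y = y.copy()
        y[-1] -= scn.sample_volume  # withdrawal right at the sampling instant
        if y[-1] <= 0:
            raise ValueError(f"volume non-positive after sampling at t={t0:g} h")
        n = max(1, int(math.ceil((t1 - t0) / max_step)))
        h = (t1 - t0) / n
        seg_t = np.empty(n + 1)
        seg_y = np.empty((n + 1, y.size))
        seg_t[0], seg_y[0] = t0, y
        t = t0
        for i in range(n):
            k1 = _rhs(y, t, scn, k, comps)
            k2 = _rhs(y + 0.5 * h * k1, t + 0.5 * h, scn, k, comps)
            k3 = _rhs(y + 0.5 * h * k2, t + 0.5 * h, scn, k, comps)
            k4 = _rhs(y + h * k3, t + h, scn, k, comps)
            y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = t + h
            seg_t[i + 1], seg_y[i + 1] = t, y
        if np.any(seg_y[:, :-1] < -1e-9) or np.any(seg_y[:, -1] <= 0):
            raise ValueError(
                f"infeasible scenario: negative state in [{t0:g}, {t1:g}] h"
            )
        if k < ts.size - 2:
            # keep the pre-withdrawal state at an epsilon-earlier time so the
            # interpolated volume/dilution reproduce the sampling step exactly
            seg_t[-1] -= 1e-9
        grid.append(seg_t)
        traj.append(seg_y)
    record_sample(y)

    tt = np.concatenate(grid)
    yy = np.vstack(traj)
    flows = {f.name: f.flow(tt) for f in scn.feeds}
    F_tot = np.sum(list(flows.values()), axis=0) if flows else np.zeros_like(tt)
    V = yy[:, -1]
    states = {"biomass": yy[:, 0]}
    for j, c in enumerate(comps, start=1):
        states[c] = yy[:, j]
    return Truth(
        times=tt,
        states=states,
        volume=V,
        dilution=F_tot / V,
        flows=flows,
        sampling_times=ts,
        at_samples={k: np.asarray(v) for k, v in at_samples.items()},
        scenario=scn,
    )


def _observe_signal(
    name: str,
    truth_values: np.ndarray,
    scn: SimulationScenario,
    rng: np.random.Generator,
) -> MeasurementSeries:
    spec = scn.noise.get(name)
    n_rep = scn.replicate_counts.get(name, 1)
    times = scn.sampling_times
    if spec is None or (spec.value == 0.0 and spec.kind is not SigmaKind.REPLICATE):
        sig = np.zeros_like(truth_values)
    elif spec.kind is SigmaKind.RELATIVE:
        sig = spec.value * np.abs(truth_values)
    else:
        sig = np.full_like(truth_values, spec.value)
    if n_rep >= 2:
        reps = [v + sig[i] * rng.standard_normal(n_rep) for i, v in enumerate(truth_values)]
        values = np.array([r.mean() for r in reps])
        return MeasurementSeries(name=name, times=times, values=values, replicates=reps)
    values = truth_values + sig * rng.standard_normal(truth_values.size)
    return MeasurementSeries(name=name, times=times, values=values)


def observe(truth: Truth, scn: SimulationScenario | None = None, seed: int | None = None) -> ProcessDataset:
    """Sample the truth through the measurement error model into a dataset.

    With a fixed seed the dataset is bit-reproducible; with all noise specs
    set to zero sigma (and no replicates) it equals the truth at the sampling
    times exactly.
    """
    scn = scn or truth.scenario
    rng = np.random.default_rng(scn.seed if seed is None else seed)

    offline = [
        _observe_signal("biomass", truth.at_samples["biomass"], scn, rng)
    ]
    uncertainty: dict[str, UncertaintySpec] = {}
    for name in [*scn.components, *scn.extra_signals]:
        tv = (
            truth.at_samples[name]
            if name in truth.at_samples
            else np.asarray(scn.extra_signals[name], dtype=float)
        )
        offline.append(_observe_signal(name, tv, scn, rng))
    for name in ["biomass", *scn.components, *scn.extra_signals]:
        spec = scn.noise.get(name, UncertaintySpec(SigmaKind.ABSOLUTE, 0.0))
        if scn.replicate_counts.get(name, 1) >= 2:
            uncertainty[name] = UncertaintySpec(SigmaKind.REPLICATE, floor=spec.floor)
        else:
            uncertainty[name] = spec

    feeds = []
    t_grid = np.arange(0.0, scn.horizon + 1e-9, scn.balance_dt)
    for f in scn.feeds:
        w = f.cumulative_weight(t_grid)
        if scn.balance_sigma > 0:
            w = w + scn.balance_sigma * rng.standard_normal(w.size)
        balance = MeasurementSeries(
            name=f"weight_{f.name}",
            times=t_grid,
            values=w,
            sigma=np.full_like(w, scn.balance_sigma),
            units="g",
        )
        feeds.append(
            FeedSpec(
                name=f.name,
                concentration=f.concentration,
                density=f.density,
                balance_series=balance,
            )
        )

    events = []
    for t in scn.sampling_times[:-1]:
        v = scn.sample_volume
        if scn.syringe_sigma > 0:
            v = v + scn.syringe_sigma * rng.standard_normal()
        events.append((float(t), max(float(v), 0.0)))

    return ProcessDataset(
        organism_label=scn.preset,
        initial_volume=scn.initial_state["V"],
        feeds=feeds,
        sample_events=events,
        offline=offline,
        uncertainty=uncertainty,
    )


def _piecewise_biomass(x0: float, mu: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Biomass at the sampling times for piecewise-constant mu, ignoring dilution."""
    x = [x0]
    for k in range(mu.size):
        x.append(x[-1] * math.exp(mu[k] * (ts[k + 1] - ts[k])))
    return np.asarray(x)


def ecoli_like(seed: int | None = None, noise_scale: float = 1.0) -> SimulationScenario:
    """Induction phase of a glycerol-limited E. coli fed-batch.

    12 h horizon, samples every 2 h, exponential 500 g/L glycerol feed sized
    to roughly match the declining substrate demand, plus a small constant
    base addition.  True growth slows from 0.12 to 0.04 1/h; qP follows
    |qS| with slope 0.15 and a small positive offset.  ``noise_scale``
    multiplies every measurement sigma (0 gives noise-free data).
    """
    ts = np.arange(0.0, 12.1, 2.0)
    mu = np.array([0.12, 0.10, 0.08, 0.06, 0.05, 0.04])
    qs = -np.array([0.30, 0.25, 0.20, 0.15, 0.125, 0.10])
    qp = 0.15 * np.abs(qs) + 0.0005

    # feed sized against the analytic biomass trajectory (no-dilution estimate)
    x_s = _piecewise_biomass(8.0, mu, ts)
    demand = float(np.sum(np.abs(qs) * 0.5 * (x_s[:-1] + x_s[1:]) * np.diff(ts)))
    k_feed = -0.03
    total = (math.exp(k_feed * 12.0) - 1.0) / k_feed
    f0 = 1.04 * demand / 500.0 / total
    feeds = [
        SyntheticFeed(
            "glycerol_feed", 500.0, 1.1, [FeedSegment(0.0, 12.0, f0, k_feed)],
            target="glycerol",
        ),
        SyntheticFeed("base", 0.0, 1.0, [FeedSegment(0.0, 12.0, 0.0012, 0.0)]),
    ]
    s = noise_scale
    return SimulationScenario(
        preset="ecoli_like",
        horizon=12.0,
        sampling_times=ts,
        initial_state={"biomass": 8.0, "glycerol": 3.0, "product": 0.05, "V": 1.0},
        rates={"mu": mu, "glycerol": qs, "product": qp},
        component_balances={
            "glycerol": ("uptake", "glycerol_feed"),
            "product": ("production", None),
        },
        feeds=feeds,
        strict_dilution=True,
        sample_volume=0.02,
        noise={
            "biomass": UncertaintySpec(SigmaKind.RELATIVE, 0.03 * s),
            "glycerol": UncertaintySpec(SigmaKind.RELATIVE, 0.03 * s),
            "product": UncertaintySpec(SigmaKind.RELATIVE, 0.025 * s),
        },
        replicate_counts={"biomass": 3, "glycerol": 3, "product": 4} if s > 0 else {},
        balance_sigma=0.1 * s,
        syringe_sigma=0.003 * s,
        seed=seed,
    )


def cho_like(seed: int | None = None, noise_scale: float = 1.0) -> SimulationScenario:
    """10-day CHO fed-batch with a lactate shift and late viability decline.

    Cell density in 1e8 cells/L (so specific rates are g/(1e8 cells h)),
    daily sampling, concentrated glutamine feed.  qlac = 1.9*|qgln| - 0.004,
    so lactate formation turns negative once the glutamine uptake drops below
    ~0.0021 g/(1e8 cells h).  The standard dilution form (-D*c per component)
    is used: with cell-count biomass a biomass-proportional dilution term
    would not be dimensionally meaningful.
    """
    ts = np.arange(0.0, 241.0, 24.0)
    mu = np.array([0.029, 0.027, 0.025, 0.020, 0.015, 0.010, 0.005, 0.0, -0.003, -0.006])
    qgln = -np.array(
        [0.0040, 0.0037, 0.0034, 0.0030, 0.0026, 0.0023, 0.0021, 0.00195, 0.0019, 0.00185]
    )
    qlac = 1.9 * np.abs(qgln) - 0.004

    # two-segment feed: exponential during growth, nearly flat at peak density
    f0, k1, k2 = 5.0e-4, 0.0196, 0.00152
    f_mid = f0 * math.exp(k1 * 120.0)
    feeds = [
        SyntheticFeed(
            "glutamine_feed",
            50.0,
            1.02,
            [FeedSegment(0.0, 120.0, f0, k1), FeedSegment(120.0, 240.0, f_mid, k2)],
            target="glutamine",
        ),
        SyntheticFeed("base", 0.0, 1.0, [FeedSegment(0.0, 240.0, 0.0008, 0.0)]),
    ]
    viability = np.array(
        [99.5, 99.2, 98.8, 98.3, 97.6, 96.8, 95.7, 94.3, 93.2, 91.8, 88.3]
    )
    s = noise_scale
    return SimulationScenario(
        preset="cho_like",
        horizon=240.0,
        sampling_times=ts,
        initial_state={"biomass": 3.0, "glutamine": 1.6, "lactate": 0.3, "V": 2.0},
        rates={"mu": mu, "glutamine": qgln, "lactate": qlac},
        component_balances={
            "glutamine": ("uptake", "glutamine_feed"),
            "lactate": ("production", None),
        },
        feeds=feeds,
        strict_dilution=False,
        sample_volume=0.015,
        noise={
            "biomass": UncertaintySpec(SigmaKind.RELATIVE, 0.04 * s),
            "glutamine": UncertaintySpec(SigmaKind.RELATIVE, 0.03 * s),
            "lactate": UncertaintySpec(SigmaKind.RELATIVE, 0.03 * s),
            "viability": UncertaintySpec(SigmaKind.ABSOLUTE, 1.4 * s),
        },
        replicate_counts={"biomass": 2, "viability": 2} if s > 0 else {},
        balance_sigma=0.1 * s,
        syringe_sigma=0.003 * s,
        balance_dt=1.0 / 12.0,  # 5-min logging is ample against daily sampling
        extra_signals={"viability": viability},
        biomass_units="1e8 cells/L",
        rate_units="g/(1e8 cells h)",
        seed=seed,
    )
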