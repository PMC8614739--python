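"""Shared domain types for fed-batch cultivation data and measurement uncertainty.

Conventions used throughout the package: time in hours since inoculation (or
induction), volumes in litres, flows in L/h, concentrations in g/L.  For cell
cultures the "biomass" variable is the catalyst amount per litre in whatever
unit the specific rates are normalised to (g/L for dry weight, 1e8 cells/L for
cell counts), so that ``dC/dt = q * X`` holds without hidden scale factors.
Unit conversion happens at ingestion, never downstream.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SigmaKind",
    "UncertaintySpec",
    "MeasurementSeries",
    "FeedSpec",
    "ProcessDataset",
    "RateSeries",
    "MCEnsemble",
    "Profile",
    "Finding",
    "resolve_sigma",
    "validate_dataset",
]


class SigmaKind(str, enum.Enum):
    """How the standard deviation of a raw signal is obtained."""

    ABSOLUTE = "absolute"  # constant sigma in signal units (device spec sheet)
    RELATIVE = "relative"  # sigma = fraction * |value|  (e.g. 0.03 for +/-3%)
    REPLICATE = "replicate"  # sample std of repeated measurements per time point


@dataclass(frozen=True)
class UncertaintySpec:
    """Uncertainty model of one raw signal.

    Parameters
    ----------
    kind:
        One of :class:`SigmaKind` (or its string value).
    value:
        Standard deviation in signal units (``absolute``) or as a fraction of
        the measured value (``relative``).  Ignored for ``replicate``.
    floor:
        Minimum absolute sigma in signal units.  Guards against spuriously
        zero replicate spreads; defaults to 0 (no floor).
    """

    kind: SigmaKind
    value: float = 0.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", SigmaKind(self.kind))
        if self.value < 0:
            raise ValueError("sigma value must be >= 0")
        if self.floor < 0:
            raise ValueError("sigma floor must be >= 0")
        if self.kind is SigmaKind.RELATIVE and self.value >= 1:
            warnings.warn(
                f"relative uncertainty of {self.value:.0%} is implausibly large",
                stacklevel=2,
            )


def _as_array(x: Sequence[float] | np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class MeasurementSeries:
    """One time-stamped signal of a cultivation.

    ``replicates`` is an optional list (one entry per time point) of arrays of
    repeated measurements; ``values`` then holds their means.  ``sigma`` is the
    per-time-point standard deviation in signal units, filled in by
    :func:`resolve_sigma`.
    """

    name: str
    times: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    replicates: list[np.ndarray] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.times = _as_array(self.times)
        self.values = _as_array(self.values)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError(f"{self.name}: times and values must be equal-length 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"{self.name}: times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = _as_array(self.sigma)
            if self.sigma.shape != self.times.shape:
                raise ValueError(f"{self.name}: sigma length mismatch")
            if np.any(self.sigma < 0):
                raise ValueError(f"{self.name}: sigma must be >= 0")
        if self.replicates is not None:
            if len(self.replicates) != self.times.size:
                raise ValueError(f"{self.name}: one replicate set per time point required")
            self.replicates = [_as_array(r) for r in self.replicates]

    def __len__(self) -> int:
        return self.times.size


@dataclass
class FeedSpec:
    """A liquid addition tracked by a balance.

    ``concentration`` is the concentration of the balanced component in the
    feed (g/L); acid/base additions carry 0.  ``density`` (g/mL) converts the
    cumulative balance weight into added volume.
    """

    name: str
    concentration: float
    density: float
    balance_series: MeasurementSeries | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("feed concentration must be >= 0")
        if self.density <= 0:
            raise ValueError("feed density must be > 0")


@dataclass
class ProcessDataset:
    """All raw data of one cultivation plus per-signal uncertainty specs.

    ``sample_events`` lists ``(time_h, withdrawn_volume_L)`` pairs; withdrawn
    volumes are converted from mL to L at ingestion.
    """

    organism_label: str
    initial_volume: float
    feeds: list[FeedSpec] = field(default_factory=list)
    sample_events: list[tuple[float, float]] = field(default_factory=list)
    offline: list[MeasurementSeries] = field(default_factory=list)
    uncertainty: dict[str, UncertaintySpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.initial_volume <= 0:
            raise ValueError("initial volume must be > 0")
        for t, v in self.sample_events:
            if v < 0:
                raise ValueError(f"withdrawn volume at t={t} must be >= 0")

    def series(self, name: str) -> MeasurementSeries:
        for s in self.offline:
            if s.name == name:
                return s
        raise KeyError(f"no offline series named {name!r}")

    def resolved(self, name: str) -> MeasurementSeries:
        """Return the named series with sigma resolved from its spec."""
        s = self.series(name)
        if s.sigma is not None:
            return s
        if name not in self.uncertainty:
            raise KeyError(f"no uncertainty spec for signal {name!r}")
        return resolve_sigma(s, self.uncertainty[name])


@dataclass
class RateSeries:
    """Piecewise-constant biomass-specific rates over measurement intervals.

    Units: 1/h for growth, g/(g h) or g/(1e8 cells h) for uptake/production.
    Uptake rates are negative when consuming; ``sigma`` holds the Monte Carlo
    standard deviation once propagated, ``relative_error`` the mean of
    ``sigma/|value|``.
    """

    name: str
    interval_starts: np.ndarray
    interval_ends: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    relative_error: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.interval_starts = _as_array(self.interval_starts)
        self.interval_ends = _as_array(self.interval_ends)
        self.values = _as_array(self.values)
        if not (self.interval_starts.shape == self.interval_ends.shape == self.values.shape):
            raise ValueError("rate series fields must have equal length")
        if np.any(self.interval_ends <= self.interval_starts):
            raise ValueError("intervals must have positive length")
        if self.interval_starts.size > 1 and not np.allclose(
            self.interval_starts[1:], self.interval_ends[:-1]
        ):
            raise ValueError("intervals must be contiguous and non-overlapping")
        if self.sigma is not None:
            self.sigma = _as_array(self.sigma)
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be >= 0")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.interval_starts + self.interval_ends)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class MCEnsemble:
    """N Monte Carlo realizations of an evaluated quantity with summaries.

    ``mean`` is the per-position arithmetic mean over realizations and
    ``sigma`` the per-position standard deviation with the N-1 denominator.
    Rows that failed during evaluation are stored as NaN and excluded from the
    summaries.
    """

    realizations: np.ndarray
    n: int
    seed: int | None = None
    mean: np.ndarray = field(init=False)
    sigma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        r = np.atleast_2d(np.asarray(self.realizations, dtype=float))
        self.realizations = r
        ok = ~np.any(np.isnan(r), axis=1)
        good = r[ok]
        if good.shape[0] == 0:
            raise ValueError("ensemble has no successful realizations")
        self.mean = good.mean(axis=0)
        if good.shape[0] > 1:
            self.sigma = good.std(axis=0, ddof=1)
        else:
            self.sigma = np.zeros_like(self.mean)

    @property
    def n_failed(self) -> int:
        return int(np.any(np.isnan(self.realizations), axis=1).sum())


class Profile:
    """Piecewise-linear function of time built from (times, values) knots.

    Used to hand continuous inputs (biomass trajectory, dilution rate, feed
    term) into the interval ODE solver.  Constant extrapolation outside the
    knot range.
    """

    __slots__ = ("times", "values")

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        self.times = _as_array(times)
        self.values = _as_array(values)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("profile times/values must be equal-length 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("profile times must be strictly increasing")

    @classmethod
    def constant(cls, value: float) -> "Profile":
        return cls([0.0], [value])

    @classmethod
    def from_callable(
        cls, f: Callable[[float], float], t0: float, t1: float, n: int = 512
    ) -> "Profile":
        t = np.linspace(t0, t1, n)
        return cls(t, np.array([f(ti) for ti in t], dtype=float))

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is ``"warning"`` or ``"error"``."""

    level: str
    message: str


def _replicate_sigma(reps: np.ndarray, name: str, t: float) -> float:
    if reps.size < 2:
        raise ValueError(
            f"{name}: replicate-derived sigma needs >=2 replicates at t={t:g} h"
        )
    return float(np.std(reps, ddof=1))


def resolve_sigma(series: MeasurementSeries, spec: UncertaintySpec) -> MeasurementSeries:
    """Fill per-time-point sigma of ``series`` according to ``spec``.

    absolute -> constant ``spec.value``; relative -> ``spec.value * |value|``;
    replicate -> sample standard deviation (n-1 denominator) of the replicates
    at each time point.  All kinds are floored at ``spec.floor``.  Idempotent.
    """
    if spec.kind is SigmaKind.ABSOLUTE:
        sigma = np.full_like(series.values, float(spec.value))
    elif spec.kind is SigmaKind.RELATIVE:
        sigma = spec.value * np.abs(series.values)
    else:
        if series.replicates is None:
            raise ValueError(f"{series.name}: replicate kind requires replicates")
        sigma = np.array(
            [
                _replicate_sigma(r, series.name, t)
                for r, t in zip(series.replicates, series.times)
            ]
        )
    sigma = np.maximum(sigma, spec.floor)
    return replace(series, sigma=sigma)


def sigma_of_mean(series: MeasurementSeries) -> np.ndarray:
    """Standard deviation of the stored values as estimates of the truth.

    For a series whose values are means of replicate measurements this is
    the standard error of the mean (resolved sigma divided by sqrt of the
    replicate count per time point); otherwise it is the resolved sigma
    itself.  This is the sigma a resampling procedure should perturb the
    stored values with.
    """
    if series.sigma is None:
        raise ValueError(f"{series.name}: resolve sigma first")
    if series.replicates is None:
        return series.sigma
    n_rep = np.array([r.size for r in series.replicates], dtype=float)
    return series.sigma / np.sqrt(n_rep)


def validate_dataset(ds: ProcessDataset) -> list[Finding]:
    """Report structural problems without raising.

    Checks: uncertainty specs present for every offline signal, replicate
    requirements, negative concentrations, and a coarse volume-balance check
    (initial volume plus added feed volume minus withdrawals must stay
    positive; feed additions are taken from the cumulative balance weights).
    """
    findings: list[Finding] = []
    for s in ds.offline:
        spec = ds.uncertainty.get(s.name)
        if spec is None and s.sigma is None:
            findings.append(
                Finding("warning", f"signal {s.name!r} has no uncertainty spec")
            )
        if spec is not None and spec.kind is SigmaKind.REPLICATE:
            if s.replicates is None:
                findings.append(
                    Finding("error", f"signal {s.name!r}: replicate spec without replicates")
                )
            else:
                for t, r in zip(s.times, s.replicates):
                    if r.size < 2:
                        findings.append(
                            Finding(
                                "error",
                                f"signal {s.name!r}: <2 replicates at t={t:g} h",
                            )
                        )
        if np.any(s.values < 0) and s.name not in ("qS", "qgln"):
            findings.append(
                Finding("warning", f"signal {s.name!r} has negative values")
            )

    # coarse volume bookkeeping on the event horizon
    events = sorted(ds.sample_events)
    for i, (t, _) in enumerate(events):
        added = 0.0
        for f in ds.feeds:
            b = f.balance_series
            if b is None or b.times.size == 0:
                continue
            w = np.interp(t, b.times, b.values)
            added += (w - b.values[0]) / (f.density * 1000.0)
        withdrawn = sum(v for tv, v in events[: i + 1])
        v_now = ds.initial_volume + added - withdrawn
        if v_now <= 0:
            findings.append(Finding("error", f"volume non-positive at t={t:g} h"))
    return findings
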