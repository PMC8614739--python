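"""Control limits, predicted outcomes and probabilistic decisions.

Propagated rate uncertainties and fitted rate-rate relations are turned into
operational quantities: k-sigma control bands around a set-point (default
k = 3, nominally labelled 99%, exact Gaussian coverage 99.73%), predicted
outcome intervals at a set-point, the critical input value whose prediction
bound touches a target output, and Gaussian threshold-crossing probabilities
for signals such as viability (harvest timing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .eiv_regression import EIVFit, MCRegressionResult

__all__ = [
    "ControlBand",
    "control_limits",
    "predicted_outcome",
    "critical_input",
    "threshold_probability",
    "decide_time_point",
]


@dataclass(frozen=True)
class ControlBand:
    """Set-point +/- k_sigma * sigma control limits."""

    setpoint: float
    k_sigma: float
    lower: float
    upper: float
    nominal_coverage: float  # the conventional label (0.99 for 3 sigma)
    exact_coverage: float  # 2 Phi(k) - 1


def control_limits(setpoint: float, sigma_rate: float, k_sigma: float = 3.0) -> ControlBand:
    """Control band around a rate set-point from its propagated sigma.

    Fluctuations inside the band are attributable to measurement uncertainty
    alone; excursions beyond it flag true process deviations.  The exact
    Gaussian coverage 2*Phi(k)-1 is reported alongside the conventional
    nominal label (99% for k = 3).
    """
    if sigma_rate < 0:
        raise ValueError("sigma must be >= 0")
    half = k_sigma * sigma_rate
    exact = float(2.0 * norm.cdf(k_sigma) - 1.0)
    nominal = 0.99 if k_sigma == 3.0 else exact
    return ControlBand(
        setpoint=setpoint,
        k_sigma=k_sigma,
        lower=setpoint - half,
        upper=setpoint + half,
        nominal_coverage=nominal,
        exact_coverage=exact,
    )


def predicted_outcome(
    fit: EIVFit,
    mc: MCRegressionResult,
    x_setpoint: float,
    k_sigma: float = 3.0,
) -> tuple[float, float]:
    """Interval on y expected when operating at ``x_setpoint``.

    yhat(x) +/- k * sigma_yhat(x) with sigma from the Monte Carlo parameter
    cloud.  Set-points outside the fitted x-range are allowed but flagged via
    a warning (extrapolation).
    """
    import warnings

    yhat = float(fit.predict(x_setpoint))
    s = float(mc.prediction_sigma_at(x_setpoint))
    lo, hi = yhat - k_sigma * s, yhat + k_sigma * s
    cloud_x = None
    if mc.x_grid is not None and mc.x_grid.size:
        cloud_x = (float(mc.x_grid.min()), float(mc.x_grid.max()))
        if not cloud_x[0] <= x_setpoint <= cloud_x[1]:
            warnings.warn(
                f"set-point {x_setpoint:g} outside fitted range {cloud_x}; "
                "prediction is an extrapolation",
                stacklevel=2,
            )
    return lo, hi


def critical_input(
    fit: EIVFit,
    mc: MCRegressionResult,
    y_target: float,
    k_sigma: float = 3.0,
    direction: str = "upper",
    x_range: tuple[float, float] | None = None,
    sign_consistency: float = 0.95,
) -> float:
    """The x at which the k-sigma prediction bound meets ``y_target``.

    ``direction`` selects the upper or lower bound of the prediction band.
    Requires the slope sign to be consistent in at least ``sign_consistency``
    of the Monte Carlo realizations - with a slope cloud straddling zero no
    feasible limit exists at the stated confidence (the situation in which a
    biased unweighted fit cannot support a control limit).  The crossing is
    located by bisection to 1e-10.
    """
    if direction not in ("upper", "lower"):
        raise ValueError("direction must be 'upper' or 'lower'")
    slopes = mc.param_cloud[:, 1]
    frac = max((slopes > 0).mean(), (slopes < 0).mean())
    if frac < sign_consistency:
        raise ValueError(
            "no feasible critical input at stated confidence: slope sign is "
            f"consistent in only {frac:.1%} of realizations"
        )
    sgn = 1.0 if direction == "upper" else -1.0

    def bound(x: float) -> float:
        return float(fit.predict(x)) + sgn * k_sigma * float(mc.prediction_sigma_at(x))

    if x_range is None:
        if mc.x_grid is not None and mc.x_grid.size:
            lo, hi = float(mc.x_grid.min()), float(mc.x_grid.max())
            span = max(hi - lo, 1e-6)
            x_range = (lo - 2 * span, hi + 2 * span)
        else:
            x_range = (-1e3, 1e3)
    f_lo = bound(x_range[0]) - y_target
    f_hi = bound(x_range[1]) - y_target
    if f_lo * f_hi > 0:
        raise ValueError(
            f"prediction bound does not cross y={y_target:g} within {x_range}"
        )
    return float(brentq(lambda x: bound(x) - y_target, *x_range, xtol=1e-10))


def threshold_probability(
    values, sigma, threshold: float, direction: str = "above"
) -> np.ndarray:
    """Per-time probability that the true value is beyond a threshold.

    Gaussian measurement model: P(above) = Phi((value - threshold) / sigma).
    With sigma = 0 the probability degenerates to 0, 1/2 or 1 by the sign of
    value - threshold.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    values = np.atleast_1d(np.asarray(values, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), values.shape)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    delta = values - threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, delta / np.where(sigma > 0, sigma, 1.0), np.nan)
    p = np.where(
        sigma > 0,
        norm.cdf(np.nan_to_num(z)),
        np.where(delta > 0, 1.0, np.where(delta < 0, 0.0, 0.5)),
    )
    if direction == "below":
        p = 1.0 - p
    return p


def decide_time_point(
    times, probabilities, certainty: float, policy: str = "latest"
) -> float | None:
    """Time point at which to act given per-time compliance probabilities.

    ``policy="latest"`` (harvest logic) returns the latest time whose
    probability still meets ``certainty`` - culture time is maximised subject
    to the stated certainty of remaining beyond the threshold.
    ``policy="earliest"`` returns the first compliant time (threshold-entry
    events).  Returns ``None`` when no time point qualifies.
    """
    if policy not in ("latest", "earliest"):
        raise ValueError("policy must be 'latest' or 'earliest'")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    probabilities = np.atleast_1d(np.asarray(probabilities, dtype=float))
    if times.shape != probabilities.shape:
        raise ValueError("times and probabilities must align")
    ok = probabilities >= certainty
    if not np.any(ok):
        return None
    idx = np.nonzero(ok)[0]
    return float(times[idx[-1] if policy == "latest" else idx[0]])
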