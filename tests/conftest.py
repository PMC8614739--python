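import warnings

import numpy as np
import pytest

from ratemc.pipeline import (
    evaluate_rates,
    evaluate_with_uncertainty,
    settings_for_scenario,
)
from ratemc.synthetic_data import cho_like, ecoli_like, observe, simulate_truth


@pytest.fixture(scope="session")
def ecoli_clean():
    """Noise-free E. coli-like scenario with its dense truth."""
    scn = ecoli_like(noise_scale=0.0)
    return scn, simulate_truth(scn)


@pytest.fixture(scope="session")
def cho_clean():
    scn = cho_like(noise_scale=0.0)
    return scn, simulate_truth(scn)


@pytest.fixture(scope="session")
def ecoli_noisy():
    """One observed noisy E. coli-like dataset (fixed seed)."""
    scn = ecoli_like(seed=0)
    truth = simulate_truth(scn)
    return scn, truth, observe(truth, seed=1000)


@pytest.fixture(scope="session")
def ecoli_mc(ecoli_noisy):
    """Full Monte Carlo evaluation of the noisy E. coli dataset (N=500)."""
    scn, truth, ds = ecoli_noisy
    st = settings_for_scenario(scn)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ev, prop = evaluate_with_uncertainty(ds, st, n=500, seed=77)
    return scn, truth, ds, st, ev, prop


@pytest.fixture(scope="session")
def cho_noisy():
    scn = cho_like(seed=0)
    truth = simulate_truth(scn)
    return scn, truth, observe(truth, seed=1000)


def max_relative_error(estimate: np.ndarray, truth: np.ndarray, floor: float = 1e-3):
    return float(np.max(np.abs(estimate - truth) / np.maximum(np.abs(truth), floor)))


def recover_rates(scn, truth, st=None):
    """Estimate all rates from the exact simulated flows (no observation noise)."""
    from ratemc.data_model import Profile
    from ratemc.rate_estimation import mu_from_series, q_from_series

    D = Profile(truth.times, truth.dilution)
    mu_hat, cx_prof = mu_from_series(truth.sampling_times, truth.at_samples["biomass"], D=D)
    out = {"mu": mu_hat}
    for comp, (kind, feed_name) in scn.component_balances.items():
        ft = None
        if feed_name:
            feed = next(f for f in scn.feeds if f.name == feed_name)
            ft = Profile(truth.times, feed.concentration * truth.flows[feed_name] / truth.volume)
        out[comp] = q_from_series(
            truth.sampling_times,
            truth.at_samples[comp],
            D=D,
            cX_profile=cx_prof,
            kind="uptake" if kind == "uptake" else "production",
            feed_term=ft,
            strict_dilution=scn.strict_dilution,
            component=comp,
        )
    return out
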