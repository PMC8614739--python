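"""Monte Carlo error propagation across a chain of evaluation steps.

Every raw signal is resampled N times from a Gaussian with its measurement
sigma; each evaluation step (a node in an acyclic graph) is re-evaluated per
realization, and its ensemble mean and N-1 standard deviation summarise the
propagated uncertainty.  Two chaining variants are offered:

``chained`` (default)
    A downstream node draws fresh Gaussian perturbations around the upstream
    node's ensemble mean with its ensemble sigma - the per-step resampling
    scheme in which only (mean, sigma) travel between steps.
``coupled``
    Each realization of the upstream output is passed through unchanged, so
    correlations between inputs survive.  The two modes agree for linear
    chains but not in general; the coupled mode is the statistically faithful
    one when steps share inputs.

Randomness is derived from one master seed; every node gets its own
deterministic substream keyed on its name, so adding a node never reshuffles
the draws of the others.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data_model import MCEnsemble

__all__ = [
    "EvaluationNode",
    "PropagationResult",
    "PropagationError",
    "sample_gaussian",
    "propagate_chain",
    "relative_error",
]

MAX_FAILURE_FRACTION = 0.05


class PropagationError(RuntimeError):
    pass


@dataclass
class EvaluationNode:
    """One evaluation step f(inputs, theta) in the propagation graph.

    ``inputs`` lists raw-signal names and/or upstream node names; ``function``
    receives a dict mapping each input name to one realization (1-D array)
    and must return a 1-D array of fixed length.  Non-random parameters go in
    ``static_params`` and are passed as keyword arguments.
    """

    name: str
    function: Callable[..., np.ndarray]
    inputs: list[str]
    static_params: dict = field(default_factory=dict)


@dataclass
class PropagationResult:
    """Per-node ensembles and averaged relative errors of one propagation run."""

    ensembles: dict[str, MCEnsemble]
    relative_errors: dict[str, float]
    n: int
    seed: int | None
    failures: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, name: str) -> MCEnsemble:
        return self.ensembles[name]


def _node_rng(seed: int | None, name: str) -> np.random.Generator:
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, key]))


def sample_gaussian(
    values: np.ndarray, sigma: np.ndarray | float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n independent Gaussian perturbations of a series: value + sigma * R.

    Draws are independent per position and per realization; no truncation or
    clipping at physical bounds is applied (plain Gaussian resampling keeps
    the summary statistics unbiased).
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), values.shape)
    if n < 2:
        raise ValueError("need at least 2 realizations")
    return values[None, :] + sigma[None, :] * rng.standard_normal((n, values.size))


def _toposort(nodes: list[EvaluationNode], raw: set[str]) -> list[EvaluationNode]:
    by_name = {n.name: n for n in nodes}
    order: list[EvaluationNode] = []
    state: dict[str, int] = {}

    def visit(name: str) -> None:
        if name in raw:
            return
        if name not in by_name:
            raise PropagationError(f"node input {name!r} resolves to nothing")
        s = state.get(name, 0)
        if s == 1:
            raise PropagationError(f"cycle through node {name!r}")
        if s == 2:
            return
        state[name] = 1
        for dep in by_name[name].inputs:
            visit(dep)
        state[name] = 2
        order.append(by_name[name])

    for n in nodes:
        visit(n.name)
    return order


def propagate_chain(
    graph: list[EvaluationNode],
    raw_inputs: dict[str, tuple[np.ndarray, np.ndarray]],
    n: int = 500,
    seed: int | None = None,
    mode: str = "chained",
) -> PropagationResult:
    """Run the Monte Carlo error-propagation chain over the node graph.

    ``raw_inputs`` maps signal names to ``(values, sigma)``.  Realizations on
    which a node raises are dropped (and counted); a node failing on more
    than 5% of realizations aborts the run.  Fixed seeds give bit-identical
    results.
    """
    if mode not in ("chained", "coupled"):
        raise ValueError("mode must be 'chained' or 'coupled'")
    order = _toposort(graph, set(raw_inputs))
    raw_samples = {
        name: sample_gaussian(vals, sig, n, _node_rng(seed, f"raw:{name}"))
        for name, (vals, sig) in raw_inputs.items()
    }
    ensembles: dict[str, MCEnsemble] = {}
    failures: dict[str, int] = {}
    for node in order:
        rng = _node_rng(seed, f"node:{node.name}")
        rows: list[np.ndarray] = []
        length: int | None = None
        n_fail = 0
        upstream_draws: dict[str, np.ndarray] = {}
        for name in node.inputs:
            if name in raw_samples:
                upstream_draws[name] = raw_samples[name]
            elif mode == "chained":
                ens = ensembles[name]
                upstream_draws[name] = sample_gaussian(ens.mean, ens.sigma, n, rng)
            else:
                upstream_draws[name] = ensembles[name].realizations
        for k in range(n):
            args = {name: upstream_draws[name][k] for name in node.inputs}
            try:
                out = np.atleast_1d(
                    np.asarray(node.function(args, **node.static_params), dtype=float)
                )
                if np.any(~np.isfinite(out)):
                    raise FloatingPointError("non-finite node output")
            except Exception:
                n_fail += 1
                out = None
            if out is not None and length is None:
                length = out.size
            rows.append(out)
        if length is None:
            raise PropagationError(f"node {node.name!r} failed on every realization")
        if n_fail > MAX_FAILURE_FRACTION * n:
            raise PropagationError(
                f"node {node.name!r} failed on {n_fail}/{n} realizations"
            )
        if n_fail:
            warnings.warn(
                f"node {node.name!r}: dropped {n_fail}/{n} failed realizations",
                stacklevel=2,
            )
        mat = np.vstack(
            [r if r is not None else np.full(length, np.nan) for r in rows]
        )
        ensembles[node.name] = MCEnsemble(realizations=mat, n=n, seed=seed)
        failures[node.name] = n_fail
    rel = {
        name: relative_error(ens, _default_mask_eps(ens))
        for name, ens in ensembles.items()
    }
    return PropagationResult(
        ensembles=ensembles, relative_errors=rel, n=n, seed=seed, failures=failures
    )


def _default_mask_eps(ens: MCEnsemble) -> float:
    scale = float(np.max(np.abs(ens.mean))) if ens.mean.size else 0.0
    return 1e-6 * scale if scale > 0 else 1e-12


def relative_error(ens: MCEnsemble, mask_epsilon: float = 1e-12) -> float:
    """Average standard deviation normalised by the corresponding mean value.

    Positions with |mean| <= mask_epsilon are excluded (the ratio diverges at
    zero crossings); raises if every position is masked.
    """
    mask = np.abs(ens.mean) > mask_epsilon
    if not np.any(mask):
        raise ValueError("all positions masked; relative error undefined")
    return float(np.mean(ens.sigma[mask] / np.abs(ens.mean[mask])))
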