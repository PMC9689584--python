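"""Structural inference of unifilar hidden semi-Markov models.

Model selection proceeds Bayesian-structural-inference style: enumerate
candidate topologies, fit each by maximum likelihood, and pick the topology
minimising

    BIC = (k_M / 2) * log n  -  max_theta log Pr(D | theta, M)

(natural log; a factor of two off the textbook form, which changes no
ranking).  Unifilarity does the heavy lifting in the fit: given a start state
the observed symbols determine the full hidden path, so dwell times partition
cleanly by state, emission probabilities have the closed-form count ratio
p*(x|s) = n(s, x) / n(s), and each state's dwell density is fitted
independently by the neural estimator.  The likelihood is maximised over
start states by trying each one that decodes.

``k_M`` counts every free parameter: all neural network weights and biases
plus the free emission probabilities.  The dominant network term means the
sample size at which a larger topology overtakes a smaller one scales with
the network size — compact density networks (see
``density.COMPACT_DENSITY_CONFIG``) resolve structure at much smaller n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .density import DensityFitConfig, NeuralDensity, fit_neural_density
from .model_core import (
    DecodeError,
    EventSequence,
    StatePath,
    Topology,
    UhsMm,
    decode_states,
)

__all__ = [
    "FitResult",
    "IncompatibleTopologyError",
    "bic_penalized_loglik",
    "bic_score",
    "enumerate_topologies",
    "fit_topology",
    "select_model",
]

_LOG_EPS = 1e-12


class IncompatibleTopologyError(ValueError):
    """No start state of the topology can decode the observed sequence."""


@dataclass
class FitResult:
    """A maximum-likelihood fit of one topology to one event sequence."""

    model: UhsMm
    start_state: str
    state_path: StatePath
    log_likelihood: float
    n_params: int
    bic: float
    per_state_dwell_samples: dict[str, np.ndarray]
    transition_counts: dict[str, dict[str, int]]
    n_events: int  # events entering the likelihood (censored final excluded)


def enumerate_topologies(alphabet, max_states: int) -> list[Topology]:
    """All recurrent unifilar binary topologies up to ``max_states`` states.

    For a binary alphabet with forced symbol alternation these are exactly
    the even-length single cycles: 2, 4, ..., ``max_states`` states, each
    state emitting one symbol and handing over to the next state around the
    cycle.  Returned smallest first.
    """
    symbols = sorted(alphabet)
    if len(symbols) != 2:
        raise NotImplementedError(
            "topology enumeration is implemented for binary alphabets only"
        )
    if max_states < 2 or max_states % 2 != 0:
        raise ValueError("max_states must be an even integer >= 2")
    out = []
    for m in range(2, max_states + 1, 2):
        states = tuple(f"s{i}" for i in range(m))
        allowed = {s: frozenset({symbols[i % 2]}) for i, s in enumerate(states)}
        succ = {s: {symbols[i % 2]: states[(i + 1) % m]} for i, s in enumerate(states)}
        out.append(Topology(states, allowed, succ))
    return out


def _fit_for_start(
    topology: Topology,
    seq: EventSequence,
    start: str,
    config: DensityFitConfig,
    min_dwells: int,
) -> FitResult | None:
    try:
        path = decode_states(topology, seq, start)
    except DecodeError:
        return None

    n = len(seq)
    n_lik = n - 1 if seq.final_censored else n

    # partition completed dwells by decoded state
    dwell_samples: dict[str, list[float]] = {g: [] for g in topology.states}
    for i in range(n_lik):
        dwell_samples[path.states[i]].append(float(seq.dwells[i]))
    if any(len(v) < min_dwells for v in dwell_samples.values()):
        return None

    # transition / emission counts over all observed emissions
    emit_counts: dict[str, dict[str, int]] = {g: {} for g in topology.states}
    trans_counts: dict[str, dict[str, int]] = {g: {} for g in topology.states}
    for i in range(n):
        g, x = path.states[i], seq.symbols[i]
        emit_counts[g][x] = emit_counts[g].get(x, 0) + 1
        s2 = topology.successor[g][x]
        trans_counts[g][s2] = trans_counts[g].get(s2, 0) + 1

    emission_prob = {
        g: {x: c / sum(cs.values()) for x, c in cs.items()}
        for g, cs in emit_counts.items()
    }

    dwell_models: dict[str, NeuralDensity] = {}
    loglik = 0.0
    for g in topology.states:
        samples = np.asarray(dwell_samples[g])
        fit = fit_neural_density(samples, config)
        dwell_models[g] = fit
        loglik += float(np.sum(fit.log_density(samples)))
    for g, cs in emit_counts.items():
        for x, c in cs.items():
            loglik += c * math.log(emission_prob[g][x])

    n_emission_free = sum(
        len(topology.allowed_emissions[g]) - 1 for g in topology.states
    )
    n_params = n_emission_free + sum(d.n_params() for d in dwell_models.values())

    model = UhsMm(topology, emission_prob, dwell_models)
    return FitResult(
        model=model,
        start_state=start,
        state_path=path,
        log_likelihood=loglik,
        n_params=n_params,
        bic=bic_penalized_loglik(n_params, loglik, n_lik),
        per_state_dwell_samples={g: np.asarray(v) for g, v in dwell_samples.items()},
        transition_counts=trans_counts,
        n_events=n_lik,
    )


def fit_topology(
    topology: Topology,
    seq: EventSequence,
    density_config: DensityFitConfig | None = None,
    min_dwells_per_state: int = 10,
) -> FitResult:
    """Maximum-likelihood fit of one topology.

    Tries every start state; for each one that decodes, partitions the
    completed dwells by decoded state (the censored final dwell enters
    neither the density fits nor the likelihood), fits a neural density per
    state, sets emissions to the count ratio, and evaluates the exact
    decoded-path log-likelihood.  Returns the best start state's fit (ties
    broken by state-label order).  Start states leaving any state with fewer
    than ``min_dwells_per_state`` dwells are rejected.
    """
    if len(seq) == 0:
        raise ValueError("sequence is empty")
    config = density_config or DensityFitConfig()
    best: FitResult | None = None
    for start in topology.states:  # states are label-sorted
        fit = _fit_for_start(topology, seq, start, config, min_dwells_per_state)
        if fit is None:
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise IncompatibleTopologyError(
            f"no start state of the {topology.n_states()}-state topology decodes "
            "the sequence (or too few dwells per state)"
        )
    return best


def bic_penalized_loglik(n_params: int, log_likelihood: float, n_events: int) -> float:
    """(k/2) * ln(n) - log-likelihood (natural log)."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    return 0.5 * n_params * math.log(n_events) - log_likelihood


def bic_score(fit: FitResult, n_events: int | None = None) -> float:
    """BIC of a fit; ``n_events`` defaults to the fit's own likelihood count."""
    n = fit.n_events if n_events is None else n_events
    return bic_penalized_loglik(fit.n_params, fit.log_likelihood, n)


def select_model(
    seq: EventSequence,
    candidates: list[Topology],
    density_config: DensityFitConfig | None = None,
    min_dwells_per_state: int = 10,
) -> tuple[FitResult, list[tuple[Topology, float]]]:
    """Fit every candidate topology and return the minimum-BIC fit.

    Candidates that cannot decode the sequence are dropped.  Also returns the
    full (topology, BIC) table in candidate order, with ``nan`` for dropped
    candidates.  Deterministic given the density config's seed list.
    """
    if not candidates:
        raise ValueError("need at least one candidate topology")
    table: list[tuple[Topology, float]] = []
    best: FitResult | None = None
    for topo in candidates:
        try:
            fit = fit_topology(topo, seq, density_config, min_dwells_per_state)
        except IncompatibleTopologyError:
            table.append((topo, float("nan")))
            continue
        table.append((topo, fit.bic))
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise IncompatibleTopologyError("every candidate topology failed to decode")
    return best, table
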