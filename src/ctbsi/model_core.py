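"""Unifilar hidden semi-Markov models (uhsMm).

A uhsMm is a finite-state generator for continuous-time, discrete-event
processes.  Each hidden state ``g`` carries a dwell-time density ``phi_g`` on
(0, inf), an emission distribution ``p(x | g)`` over a finite alphabet, and a
deterministic successor map ``eps(g, x)`` giving the next hidden state once
the emitted symbol is known.  Determinism of the successor map (*unifilarity*)
is what makes the hidden path recoverable from the observed symbols plus a
start state, and it is enforced structurally here together with the
alternation constraint: a state reached by emitting ``x`` may never emit ``x``
again, so consecutive observed symbols always differ.

The module provides the model/data containers, structural validation,
trajectory simulation, unifilar decoding, the event-weighted stationary state
distribution, and the exact (quadrature) differential entropy rate of a model
with known dwell densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DecodeError",
    "DwellModel",
    "EventSequence",
    "InverseGaussianDwell",
    "MixtureDwell",
    "StatePath",
    "Topology",
    "UhsMm",
    "decode_states",
    "entropy_rate_exact",
    "simulate",
    "stationary_distribution",
    "validate_model",
]

Symbol = str
State = str


# ---------------------------------------------------------------------------
# Dwell-time models
# ---------------------------------------------------------------------------


class DwellModel:
    """A probability density on (0, inf) for state dwell times.

    Concrete subclasses expose ``density(t)`` (vectorised), ``sample(n, rng)``,
    a ``mean`` property, and ``quantile(q)`` used to pick quadrature ranges.
    """

    kind: str = "abstract"

    def density(self, t):  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator):  # pragma: no cover
        raise NotImplementedError

    @property
    def mean(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def quantile(self, q: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class InverseGaussianDwell(DwellModel):
    """Inverse Gaussian dwell density, parameterised by (mean mu, shape lam).

    Density sqrt(lam / (2 pi t^3)) * exp(-lam (t - mu)^2 / (2 mu^2 t)).
    This is the Wald parameterisation; scipy's ``invgauss(mu/lam, scale=lam)``
    realises it exactly.
    """

    kind = "inverse_gaussian"

    def __init__(self, mean: float, scale: float):
        if mean <= 0 or scale <= 0:
            raise ValueError("inverse Gaussian requires mean > 0 and scale > 0")
        self.mu = float(mean)
        self.lam = float(scale)
        self._dist = stats.invgauss(self.mu / self.lam, scale=self.lam)

    def density(self, t):
        return self._dist.pdf(t)

    def sample(self, n, rng):
        return self._dist.rvs(size=n, random_state=rng)

    @property
    def mean(self):
        return self.mu

    def quantile(self, q):
        return float(self._dist.ppf(q))

    def cdf(self, t):
        return self._dist.cdf(t)

    def __repr__(self):
        return f"InverseGaussianDwell(mean={self.mu}, scale={self.lam})"


class MixtureDwell(DwellModel):
    """Finite mixture of dwell densities with nonnegative weights summing to 1."""

    kind = "mixture"

    def __init__(self, weights: Sequence[float], components: Sequence[DwellModel]):
        w = np.asarray(weights, dtype=float)
        if len(w) != len(components) or len(w) == 0:
            raise ValueError("need one weight per mixture component")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        self.weights = w
        self.components = list(components)

    def density(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for w, c in zip(self.weights, self.components):
            out = out + w * c.density(t)
        return out

    def sample(self, n, rng):
        idx = rng.choice(len(self.components), size=n, p=self.weights)
        out = np.empty(n)
        for j, c in enumerate(self.components):
            m = idx == j
            if m.any():
                out[m] = c.sample(int(m.sum()), rng)
        return out

    @property
    def mean(self):
        return float(sum(w * c.mean for w, c in zip(self.weights, self.components)))

    def quantile(self, q):
        # conservative envelope: max of component quantiles
        return max(c.quantile(q) for c in self.components)


class UniformDwell(DwellModel):
    """Uniform dwell on [lo, hi]; handy for analytic entropy checks."""

    kind = "uniform"

    def __init__(self, lo: float, hi: float):
        if not 0 <= lo < hi:
            raise ValueError("require 0 <= lo < hi")
        self.lo, self.hi = float(lo), float(hi)

    def density(self, t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.lo) & (t <= self.hi), 1.0 / (self.hi - self.lo), 0.0)

    def sample(self, n, rng):
        return rng.uniform(self.lo, self.hi, size=n)

    @property
    def mean(self):
        return 0.5 * (self.lo + self.hi)

    def quantile(self, q):
        return self.lo + q * (self.hi - self.lo)


class ExponentialDwell(DwellModel):
    """Exponential dwell with the given mean."""

    kind = "exponential"

    def __init__(self, mean: float):
        if mean <= 0:
            raise ValueError("mean must be positive")
        self._mean = float(mean)

    def density(self, t):
        t = np.asarray(t, dtype=float)
        return np.where(t >= 0, np.exp(-t / self._mean) / self._mean, 0.0)

    def sample(self, n, rng):
        return rng.exponential(self._mean, size=n)

    @property
    def mean(self):
        return self._mean

    def quantile(self, q):
        return float(-self._mean * np.log1p(-q))


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class EventSequence:
    """An observed continuous-time, discrete-event record.

    ``symbols[i]`` was emitted for ``dwells[i]`` seconds.  When
    ``final_censored`` is true the last dwell is the time observed *so far*
    (the observation window closed mid-dwell), not a completed dwell.
    """

    symbols: list[Symbol]
    dwells: np.ndarray
    final_censored: bool = False

    def __post_init__(self):
        self.dwells = np.asarray(self.dwells, dtype=float)
        if len(self.symbols) != len(self.dwells):
            raise ValueError("symbols and dwells must have equal length")
        if np.any(self.dwells <= 0):
            raise ValueError("all dwells must be positive")
        for a, b in zip(self.symbols, self.symbols[1:]):
            if a == b:
                raise ValueError("consecutive symbols must differ")

    def __len__(self):
        return len(self.symbols)

    @property
    def events(self) -> list[tuple[Symbol, float]]:
        return list(zip(self.symbols, self.dwells.tolist()))

    @property
    def duration(self) -> float:
        return float(self.dwells.sum())


@dataclass
class StatePath:
    """Hidden state active during each event of an :class:`EventSequence`."""

    states: list[State]

    def __len__(self):
        return len(self.states)

    def __eq__(self, other):
        return isinstance(other, StatePath) and self.states == other.states


@dataclass
class Topology:
    """State set, per-state allowed emissions, and the unifilar successor map.

    ``successor[g][x]`` is defined exactly for the allowed emissions ``x`` of
    state ``g``.
    """

    states: tuple[State, ...]
    allowed_emissions: dict[State, frozenset[Symbol]]
    successor: dict[State, dict[Symbol, State]]

    def __post_init__(self):
        self.states = tuple(sorted(self.states))
        self.allowed_emissions = {
            g: frozenset(v) for g, v in self.allowed_emissions.items()
        }

    @property
    def alphabet(self) -> frozenset[Symbol]:
        out: set[Symbol] = set()
        for v in self.allowed_emissions.values():
            out |= v
        return frozenset(out)

    def n_states(self) -> int:
        return len(self.states)


@dataclass
class UhsMm:
    """A full generator: topology + emission probabilities + dwell densities."""

    topology: Topology
    emission_prob: dict[State, dict[Symbol, float]]
    dwell: dict[State, DwellModel]

    @property
    def states(self):
        return self.topology.states


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _reachability(topology: Topology) -> dict[State, set[State]]:
    """states reachable from each state by following successor edges"""
    adj = {
        g: {topology.successor[g][x] for x in topology.allowed_emissions.get(g, ())}
        for g in topology.states
    }
    out = {}
    for g in topology.states:
        seen = {g}
        frontier = [g]
        while frontier:
            u = frontier.pop()
            for v in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        out[g] = seen
    return out

def validate_model(model: UhsMm) -> list[str]:
    """Check every structural invariant of a uhsMm; return violation messages.

    An empty list means the model is valid.  Diagnostics name the offending
    state/symbol; this function never raises.
    """
    v: list[str] = []
    topo = model.topology
    states = set(topo.states)

    if len(topo.alphabet) < 2:
        v.append("alphabet must contain at least 2 symbols")

    for g in topo.states:
        allowed = topo.allowed_emissions.get(g, frozenset())
        if not allowed:
            v.append(f"state {g} has no allowed emissions")
        succ = topo.successor.get(g, {})
        if set(succ) != set(allowed):
            v.append(f"state {g}: successor map domain differs from allowed emissions")
        for x, nxt in succ.items():
            if nxt not in states:
                v.append(f"state {g}, symbol {x}: successor {nxt} is not a state")
                continue
            if x in topo.allowed_emissions.get(nxt, frozenset()):
                v.append(
                    f"alternation violated: state {g} emits {x} into state {nxt} "
                    f"which may emit {x} again"
                )

    reach = _reachability(topo)
    for g in topo.states:
        if reach[g] != states:
            missing = sorted(states - reach[g])
            v.append(f"state {g} cannot reach states {missing} (topology not recurrent)")

    for g in topo.states:
        p = model.emission_prob.get(g, {})
        allowed = topo.allowed_emissions.get(g, frozenset())
        total = sum(p.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            v.append(f"state {g}: emission probabilities sum to {total:.6g}, not 1")
        for x, px in p.items():
            if px < 0:
                v.append(f"state {g}: p({x}|{g}) = {px} is negative")
            if px > 0 and x not in allowed:
                v.append(f"state {g}: positive probability on disallowed symbol {x}")
        if g not in model.dwell:
            v.append(f"state {g} has no dwell model")

    return v


# ---------------------------------------------------------------------------
# Simulation and decoding
# ---------------------------------------------------------------------------


def embedded_transition_matrix(model: UhsMm) -> np.ndarray:
    """Event-to-event hidden state transition matrix P[i, j] = Pr(next=j | cur=i)."""
    states = model.topology.states
    idx = {g: i for i, g in enumerate(states)}
    P = np.zeros((len(states), len(states)))
    for g in states:
        for x, px in model.emission_prob[g].items():
            if px > 0:
                P[idx[g], idx[model.topology.successor[g][x]]] += px
    return P


def embedded_stationary(model: UhsMm) -> np.ndarray:
    """Stationary distribution of the embedded (event-indexed) state chain."""
    P = embedded_transition_matrix(model)
    n = P.shape[0]
    # solve pi P = pi, sum(pi) = 1
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate(
    model: UhsMm,
    n_events: int | None = None,
    duration: float | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[EventSequence, StatePath]:
    """Generate a trajectory from a uhsMm.

    Exactly one of ``n_events`` / ``duration`` must be given.  Generation
    follows the model's defining loop: draw a dwell from the current state's
    density, draw a symbol from its emission distribution, emit, and move to
    the successor state.  The initial state is drawn from the stationary
    distribution of the embedded event chain so that event statistics are
    stationary from the first event (uniform on a deterministic cycle).

    Under a ``duration`` horizon the final dwell is truncated at the boundary
    and the sequence is marked ``final_censored``.  The returned
    :class:`StatePath` records the hidden state active during each event.
    Identical seeds give identical output.
    """
    if (n_events is None) == (duration is None):
        raise ValueError("specify exactly one of n_events or duration")
    if n_events is not None and n_events <= 0:
        raise ValueError("n_events must be positive")
    if duration is not None and duration <= 0:
        raise ValueError("duration must be positive")

    bad = validate_model(model)
    if bad:
        raise ValueError("invalid model: " + "; ".join(bad))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = model.topology.states
    pi = embedded_stationary(model)
    g = states[rng.choice(len(states), p=pi)]

    symbols: list[Symbol] = []
    dwells: list[float] = []
    path: list[State] = []
    censored = False
    t_total = 0.0
    while True:
        tau = float(model.dwell[g].sample(1, rng)[0])
        xs = sorted(model.emission_prob[g])
        probs = np.array([model.emission_prob[g][x] for x in xs])
        x = xs[rng.choice(len(xs), p=probs / probs.sum())]
        if duration is not None and t_total + tau >= duration:
            tau = duration - t_total
            censored = True
            if tau > 0:
                symbols.append(x)
                dwells.append(tau)
                path.append(g)
            elif not symbols:
                # zero-length residual window on an empty sequence: emit a
                # degenerate censored sliver so callers always get >= 1 event
                symbols.append(x)
                dwells.append(duration)
                path.append(g)
            break
        symbols.append(x)
        dwells.append(tau)
        path.append(g)
        t_total += tau
        g = model.topology.successor[g][x]
        if n_events is not None and len(symbols) >= n_events:
            break

    return EventSequence(symbols, np.array(dwells), final_censored=censored), StatePath(path)


class DecodeError(ValueError):
    """Raised when an observed symbol is not emittable from the decoded state."""

    def __init__(self, index: int, state: State, symbol: Symbol):
        self.index = index
        self.state = state
        self.symbol = symbol
        super().__init__(
            f"symbol {symbol!r} at event {index} is not an allowed emission of "
            f"state {state!r}"
        )


def decode_states(topology: Topology, seq: EventSequence, start_state: State) -> StatePath:
    """Recover the unique hidden path implied by unifilarity.

    Starting from ``start_state``, each observed symbol deterministically
    selects the next state through the successor map.  Raises
    :class:`DecodeError` (carrying the failing event index) if a symbol is not
    an allowed emission of the current state.
    """
    g = start_state
    if g not in topology.successor and g not in topology.allowed_emissions:
        raise KeyError(f"unknown start state {g!r}")
    path: list[State] = []
    for i, x in enumerate(seq.symbols):
        if x not in topology.allowed_emissions.get(g, frozenset()):
            raise DecodeError(i, g, x)
        path.append(g)
        g = topology.successor[g][x]
    return StatePath(path)


# ---------------------------------------------------------------------------
# Stationary distribution and exact entropy rate
# ---------------------------------------------------------------------------


def stationary_distribution(
    mu: Mapping[State, float],
    transitions: Mapping[State, Mapping[State, float]],
) -> dict[State, float]:
    """Solve the time-weighted stationary state distribution.

    ``mu[s]`` is the mean dwell in state ``s`` and ``transitions[s][s']`` the
    count (or probability) of observed moves ``s -> s'``.  The returned vector
    is the unique probability solution of

        p(s) = sum_{s'} (mu_{s'} / mu_s) * (n_{s'->s} / n_{s'}) * p(s')

    found as the eigenvector of the weighted transition operator at eigenvalue
    one.  Raises if the transition structure is reducible (naming the states
    unreachable from the first label).
    """
    states = sorted(mu)
    if any(mu[s] <= 0 for s in states):
        raise ValueError("all mean dwells must be positive")
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)

    # row-normalised transition probabilities
    P = np.zeros((n, n))
    for s, row in transitions.items():
        tot = sum(row.values())
        if tot <= 0:
            raise ValueError(f"state {s} has no outgoing transitions")
        for s2, c in row.items():
            P[idx[s], idx[s2]] = c / tot

    # reducibility check: every state reachable from every other
    reach = np.eye(n, dtype=bool) | (P > 0)
    for _ in range(n):
        reach = reach | (reach @ reach)
    if not reach.all():
        bad = sorted(
            {states[j] for i in range(n) for j in range(n) if not reach[i, j]}
        )
        raise ValueError(f"transition structure is reducible; unreachable states: {bad}")

    if n == 1:
        return {states[0]: 1.0}

    mu_vec = np.array([mu[s] for s in states])
    # operator A[s, s'] = (mu_{s'}/mu_s) P[s', s]; p = A p
    A = (P.T * mu_vec[None, :]) / mu_vec[:, None]
    w, V = np.linalg.eig(A)
    j = int(np.argmin(np.abs(w - 1.0)))
    p = np.real(V[:, j])
    p = np.abs(p)
    p = p / p.sum()
    return {s: float(p[idx[s]]) for s in states}


def stationary_from_model(model: UhsMm) -> dict[State, float]:
    """Time-weighted stationary distribution of a model with known densities."""
    P = embedded_transition_matrix(model)
    states = model.topology.states
    mu = {g: model.dwell[g].mean for g in states}
    trans = {
        g: {
            s2: P[i, j]
            for j, s2 in enumerate(states)
            if P[i, j] > 0
        }
        for i, g in enumerate(states)
    }
    return stationary_distribution(mu, trans)


def _dwell_quad_range(d: DwellModel) -> tuple[float, float]:
    lo = 1e-6
    hi = d.quantile(1.0 - 1e-8)
    if not np.isfinite(hi) or hi <= lo:
        raise ValueError("cannot determine a finite quadrature range for dwell model")
    return lo, hi


def differential_entropy(d: DwellModel, n_grid: int = 4096) -> float:
    """- int phi log phi by dense trapezoidal quadrature on the dwell support."""
    lo, hi = _dwell_quad_range(d)
    t = np.linspace(lo, hi, n_grid)
    f = np.clip(d.density(t), 1e-300, None)
    val = -np.trapezoid(f * np.log(f), t)
    # refine once; dwell tails decay fast enough that doubling must agree
    t2 = np.linspace(lo, hi, 2 * n_grid)
    f2 = np.clip(d.density(t2), 1e-300, None)
    val2 = -np.trapezoid(f2 * np.log(f2), t2)
    if not np.isfinite(val2) or abs(val2 - val) > 1e-3:
        raise ArithmeticError(
            f"entropy quadrature did not stabilise ({val} vs {val2}); "
            "density may be non-integrable on the range"
        )
    return float(val2)


def entropy_rate_exact(model: UhsMm, n_grid: int = 4096) -> float:
    """Differential entropy rate of a uhsMm with known dwell densities (nats).

    Computes  h = - sum_s p(s) * mu_s * int phi_s(t) log phi_s(t) dt  with the
    time-weighted stationary p(s) (for a deterministic cycle, p(s)
    proportional to 1/mu_s).  The mean factor and the stationary weights
    follow the plug-in convention used throughout this package; for the
    four-state benchmark generator the value is 1.85 nats.
    """
    bad = validate_model(model)
    if bad:
        raise ValueError("invalid model: " + "; ".join(bad))
    p = stationary_from_model(model)
    total = 0.0
    for g in model.topology.states:
        d = model.dwell[g]
        total += p[g] * d.mean * differential_entropy(d, n_grid=n_grid)
    return float(total)
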