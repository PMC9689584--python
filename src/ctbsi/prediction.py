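"""Causal-state prediction of future symbols.

The triple (g, x0, tau0) — decoded hidden state, currently emitted symbol,
and time since the last symbol change — is a (typically minimal) sufficient
statistic of the past for processes generated by unifilar hidden semi-Markov
models.  Prediction therefore reduces to regression on this
three-dimensional mixed space: to forecast the symbol a horizon T ahead, we
take the k training points with matching discrete coordinates (g, x0) whose
tau0 is closest to the query's and average their observed futures.  With
enough data and well-chosen k this converges to the optimal (conditional
mean) predictor.  The floor comparator is the persistence rule: predict that
the current symbol is still being emitted at t + T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult
from .model_core import DecodeError, EventSequence, UhsMm, decode_states, simulate

__all__ = [
    "CausalState",
    "PredictionDataset",
    "evaluate_predictor",
    "extract_causal_states",
    "knn_predict",
]


@dataclass(frozen=True)
class CausalState:
    """Predictor input: hidden state, current symbol, time since last change."""

    g: str
    x0: str
    tau0: float

    def __post_init__(self):
        if self.tau0 < 0:
            raise ValueError("tau0 must be nonnegative")


@dataclass
class PredictionDataset:
    """(causal state, value observed a fixed horizon later) pairs."""

    records: list[tuple[CausalState, float]]
    horizon: float

    def groups(self) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
        """tau0 and future arrays per (g, x0), tau0-sorted."""
        by_key: dict[tuple[str, str], list[tuple[float, float]]] = {}
        for cs, fut in self.records:
            by_key.setdefault((cs.g, cs.x0), []).append((cs.tau0, fut))
        out = {}
        for key, pairs in by_key.items():
            pairs.sort()
            taus = np.array([p[0] for p in pairs])
            futs = np.array([p[1] for p in pairs])
            out[key] = (taus, futs)
        return out

    @property
    def global_mean(self) -> float:
        return float(np.mean([fut for _, fut in self.records]))


def _decode_any_start(fit: FitResult, seq: EventSequence):
    """Decode seq under the fitted model, picking the most likely start state.

    Several start states of a cyclic topology can decode the same symbol
    sequence (offset by half a cycle), and they assign different state labels
    to the same events.  The fitted dwell densities disambiguate: the start
    state maximising the completed-dwell log-likelihood aligns the decoded
    labels with the fit's, so causal states extracted from independently
    decoded sequences are comparable.  Ties break by state-label order.
    """
    topo = fit.model.topology
    n_done = len(seq) - 1 if seq.final_censored else len(seq)
    best = None
    for start in topo.states:
        try:
            path = decode_states(topo, seq, start)
        except DecodeError:
            continue
        ll = sum(
            float(np.log(np.clip(
                fit.model.dwell[g].density(np.array([tau]))[0], 1e-12, None)))
            for g, tau in zip(path.states[:n_done], seq.dwells[:n_done])
        )
        if best is None or ll > best[0]:
            best = (ll, path)
    if best is None:
        raise DecodeError(0, topo.states[0], seq.symbols[0])
    return best[1]


def extract_causal_states(
    fit: FitResult, seq: EventSequence, sample_times
) -> list[CausalState]:
    """Causal state (g, x0, tau0) active at each requested time.

    Event boundaries are right-continuous: at the instant of a symbol change
    the *new* symbol is active with tau0 = 0.  Times outside [0, duration]
    are an error.  The sequence is decoded under the fitted topology, trying
    start states in label order.
    """
    times = np.atleast_1d(np.asarray(sample_times, dtype=float))
    dur = seq.duration
    if np.any(times < 0) or np.any(times > dur):
        raise ValueError("sample times must lie within [0, sequence duration]")
    path = _decode_any_start(fit, seq)

    starts = np.concatenate([[0.0], np.cumsum(seq.dwells)[:-1]])
    idx = np.searchsorted(starts, times, side="right") - 1
    idx = np.clip(idx, 0, len(seq) - 1)
    return [
        CausalState(path.states[i], seq.symbols[i], float(t - starts[i]))
        for i, t in zip(idx, times)
    ]


def knn_predict(train: PredictionDataset, query: CausalState, k: int) -> float:
    """Average future value of the k nearest matching training points.

    Neighbours must share the query's (g, x0); distance is |tau0 - tau0'|.
    Fewer than k matches: use all of them.  No matches at all: fall back to
    the global training mean, with a warning.
    """
    if not train.records:
        raise ValueError("empty training dataset")
    if k < 1:
        raise ValueError("k must be >= 1")
    groups = train.groups()
    key = (query.g, query.x0)
    if key not in groups:
        warnings.warn(
            f"no training points with (g, x0) = {key}; returning global mean"
        )
        return train.global_mean
    taus, futs = groups[key]
    return _predict_in_group(taus, futs, np.array([query.tau0]), k)[0]


def _predict_in_group(
    sorted_taus: np.ndarray, futs: np.ndarray, queries: np.ndarray, k: int
) -> np.ndarray:
    """Vectorised k-nearest-by-tau0 mean within one (g, x0) group."""
    n = len(sorted_taus)
    kk = min(k, n)
    pos = np.searchsorted(sorted_taus, queries)
    out = np.empty(len(queries))
    for i, (q, p) in enumerate(zip(queries, pos)):
        lo = max(0, p - kk)
        hi = min(n, p + kk)
        window = sorted_taus[lo:hi]
        d = np.abs(window - q)
        sel = np.argpartition(d, kk - 1)[:kk] if len(d) > kk else np.arange(len(d))
        out[i] = futs[lo:hi][sel].mean()
    return out


def _dataset_from_sequence(
    fit: FitResult,
    seq: EventSequence,
    sample_times: np.ndarray,
    horizon: float,
    coding: dict[str, float],
) -> PredictionDataset:
    states_now = extract_causal_states(fit, seq, sample_times)
    states_future = extract_causal_states(fit, seq, sample_times + horizon)
    records = [
        (cs, coding[fs.x0]) for cs, fs in zip(states_now, states_future)
    ]
    return PredictionDataset(records, horizon)


def _mse_knn(train: PredictionDataset, test: PredictionDataset, k: int) -> float:
    groups = train.groups()
    gmean = train.global_mean
    err2 = []
    # batch queries by group for speed
    by_key: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for cs, fut in test.records:
        by_key.setdefault((cs.g, cs.x0), []).append((cs.tau0, fut))
    for key, pairs in by_key.items():
        q = np.array([p[0] for p in pairs])
        actual = np.array([p[1] for p in pairs])
        if key not in groups:
            pred = np.full(len(q), gmean)
        else:
            taus, futs = groups[key]
            pred = _predict_in_group(taus, futs, q, k)
        err2.append((pred - actual) ** 2)
    return float(np.concatenate(err2).mean())


def _choose_k_cv(train: PredictionDataset, k_grid, n_folds: int = 3,
                 seed: int = 0) -> int:
    rng = np.random.default_rng(seed)
    recs = list(train.records)
    perm = rng.permutation(len(recs))
    folds = np.array_split(perm, n_folds)
    best_k, best_mse = None, np.inf
    for k in k_grid:
        errs = []
        for f in folds:
            mask = np.zeros(len(recs), dtype=bool)
            mask[f] = True
            tr = PredictionDataset([recs[i] for i in range(len(recs)) if not mask[i]],
                                   train.horizon)
            te = PredictionDataset([recs[i] for i in range(len(recs)) if mask[i]],
                                   train.horizon)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                errs.append(_mse_knn(tr, te, k))
        m = float(np.mean(errs))
        if m < best_mse:
            best_mse, best_k = m, k
    return best_k


def evaluate_predictor(
    model: UhsMm,
    fit: FitResult,
    horizons,
    n_train: int = 5000,
    n_test: int = 2000,
    k: int | str = "cv",
    seed: int = 0,
    k_grid=(1, 3, 5, 10, 30, 100),
) -> pd.DataFrame:
    """Per-horizon mean-squared error of the causal-state kNN predictor.

    Simulates independent train and test trajectories from ``model``, samples
    causal states on a uniform grid (spacing = smallest mean dwell / 10),
    codes binary symbols as 0/1 reals, and reports the MSE of the kNN
    predictor and of the persistence baseline at every horizon.  ``k="cv"``
    chooses k per horizon by 3-fold cross-validation on the training set.
    """
    horizons = [float(h) for h in horizons]
    if any(h <= 0 for h in horizons):
        raise ValueError("horizons must be positive")
    alphabet = sorted(model.topology.alphabet)
    coding = {x: float(i) for i, x in enumerate(alphabet)}
    spacing = min(model.dwell[g].mean for g in model.topology.states) / 10.0
    h_max = max(horizons)

    def build(n_points: int, sim_seed: int):
        dur = n_points * spacing + h_max + 1.0
        seq, _ = simulate(model, duration=dur, seed=sim_seed)
        times = np.arange(n_points) * spacing
        return seq, times

    train_seq, train_times = build(n_train, seed)
    test_seq, test_times = build(n_test, seed + 1)

    rows = []
    for h in horizons:
        train = _dataset_from_sequence(fit, train_seq, train_times, h, coding)
        test = _dataset_from_sequence(fit, test_seq, test_times, h, coding)
        k_h = _choose_k_cv(train, k_grid, seed=seed) if k == "cv" else int(k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mse_knn = _mse_knn(train, test, k_h)
        actual = np.array([fut for _, fut in test.records])
        current = np.array([coding[cs.x0] for cs, _ in test.records])
        mse_persist = float(np.mean((current - actual) ** 2))
        rows.append({"horizon": h, "method": "ctbsi", "mse": mse_knn, "k": k_h})
        rows.append({"horizon": h, "method": "persistence", "mse": mse_persist,
                     "k": np.nan})
    return pd.DataFrame(rows)
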