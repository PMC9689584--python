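import numpy as np
import pytest

from ctbsi.density import COMPACT_DENSITY_CONFIG
from ctbsi.entropy_rate import (
    TrajectoryEnsemble,
    kl_knn_entropy,
    model_free_entropy_rate,
    plugin_entropy_rate,
    trajectory_entropy,
)
from ctbsi.inference import enumerate_topologies, fit_topology
from ctbsi.model_core import EventSequence, entropy_rate_exact, simulate


# ---------------------------------------------------------------------------
# Kozachenko-Leonenko estimator
# ---------------------------------------------------------------------------


def test_kl_entropy_standard_normal():
    x = np.random.default_rng(0).normal(size=10_000)
    assert kl_knn_entropy(x, k=3) == pytest.approx(0.5 * np.log(2 * np.pi * np.e),
                                                   abs=0.05)


def test_kl_entropy_uniform():
    x = np.random.default_rng(1).uniform(size=10_000)
    assert kl_knn_entropy(x, k=3) == pytest.approx(0.0, abs=0.05)


def test_kl_entropy_scaling_law():
    x = np.random.default_rng(2).normal(size=5000)
    a = 10.0
    assert kl_knn_entropy(a * x) - kl_knn_entropy(x) == pytest.approx(np.log(a),
                                                                      abs=0.05)


def test_kl_entropy_translation_invariant():
    x = np.random.default_rng(3).normal(size=2000, scale=2.0)
    assert kl_knn_entropy(x + 123.456) == pytest.approx(kl_knn_entropy(x), abs=1e-9)


def test_kl_entropy_multivariate_gaussian():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(8000, 2))
    assert kl_knn_entropy(x, k=3) == pytest.approx(np.log(2 * np.pi * np.e), abs=0.1)


def test_kl_entropy_duplicates_jittered():
    x = np.concatenate([np.zeros(10), np.random.default_rng(5).normal(size=200)])
    with pytest.warns(UserWarning, match="duplicate"):
        v = kl_knn_entropy(x)
    assert np.isfinite(v)


# ---------------------------------------------------------------------------
# trajectory entropy
# ---------------------------------------------------------------------------


def _two_event_ensemble(n, T, rng):
    """Trajectories with fixed symbols ('0' then '1') and one completed dwell."""
    seqs = []
    for _ in range(n):
        u = rng.uniform(0.2, T - 0.2)
        seqs.append(EventSequence(["0", "1"], np.array([u, T - u]),
                                  final_censored=True))
    return TrajectoryEnsemble(seqs, T)


def test_trajectory_entropy_reduces_to_knn_term_when_discrete_is_constant():
    rng = np.random.default_rng(6)
    ens = _two_event_ensemble(300, 2.0, rng)
    dwells = np.array([s.dwells[0] for s in ens.sequences])
    assert trajectory_entropy(ens) == pytest.approx(kl_knn_entropy(dwells), abs=1e-12)


def test_trajectory_entropy_zero_for_deterministic_trajectories():
    seqs = [EventSequence(["0"], np.array([3.0]), final_censored=True)
            for _ in range(100)]
    assert trajectory_entropy(TrajectoryEnsemble(seqs, 3.0)) == 0.0


def test_trajectory_entropy_converges_to_closed_form(exp_two_cycle):
    """Alternating unit-exponential cycle: event times form a rate-1 Poisson
    process, so H(T) has a closed form — the completed dwells are spacings of
    uniform order statistics with entropy m ln T - ln m!, the word entropy is
    ln 2 (the word is determined by the first symbol), and the count entropy
    is that of Poisson(T).  The estimate approaches this from above (the
    stratified KL term has positive small-sample bias) as the ensemble grows."""
    import warnings

    from scipy.special import gammaln
    from scipy.stats import poisson

    T = 5.0
    m = np.arange(0, 200)
    pm = poisson(T).pmf(m)
    exact = (
        -np.sum(pm[pm > 0] * np.log(pm[pm > 0]))
        + np.log(2)
        + np.sum(pm * (m * np.log(T) - gammaln(m + 1)))
    )

    def estimate(n, seed):
        seqs = [simulate(exp_two_cycle, duration=T, seed=s)[0]
                for s in range(seed, seed + n)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return trajectory_entropy(TrajectoryEnsemble(seqs, T))

    small, big = estimate(300, 0), estimate(3000, 10_000)
    assert abs(big - exact) < abs(small - exact)  # shrinking bias
    assert big > exact  # positive small-sample bias
    assert abs(big - exact) / exact < 0.25


def test_ensemble_requires_common_duration():
    a = EventSequence(["0"], np.array([1.0]), final_censored=True)
    b = EventSequence(["0"], np.array([2.0]), final_censored=True)
    with pytest.raises(ValueError):
        TrajectoryEnsemble([a, b], 1.0)
    with pytest.raises(ValueError):
        TrajectoryEnsemble([], 1.0)


# ---------------------------------------------------------------------------
# model-free rate
# ---------------------------------------------------------------------------


def test_model_free_rate_on_exponential_cycle(exp_two_cycle):
    """Exact rate for unit-mean exponential dwells is 1.0 nat; the slope
    estimate carries the stratified KL term's positive bias (which grows with
    the dwell-vector dimension, i.e. with T) on top of it."""
    rate, curve = model_free_entropy_rate(
        exp_two_cycle, np.linspace(0.5, 4, 8), n_traj=1000, seed=0
    )
    assert len(curve) == 8
    assert np.all(np.diff(curve) > 0)  # trajectory entropy grows with T
    assert rate == pytest.approx(1.0, abs=0.5)


def test_model_free_rejects_bad_grid(exp_two_cycle):
    with pytest.raises(ValueError):
        model_free_entropy_rate(exp_two_cycle, [1.0, 2.0], n_traj=10)
    with pytest.raises(ValueError):
        model_free_entropy_rate(exp_two_cycle, [1.0, 1.0, 2.0], n_traj=10)


# ---------------------------------------------------------------------------
# model-based plug-in
# ---------------------------------------------------------------------------


def test_plugin_with_exact_densities_matches_exact_rate(fig4_model):
    seq, _ = simulate(fig4_model, n_events=400, seed=7)
    topo = enumerate_topologies({"0", "1"}, 4)[1]
    fit = fit_topology(topo, seq, COMPACT_DENSITY_CONFIG)
    # map decoded state labels onto the generator's states via dwell means
    decoded_means = {g: float(np.mean(s)) for g, s in
                     fit.per_state_dwell_samples.items()}
    truth = {"A": fig4_model.dwell["A"], "B": fig4_model.dwell["B"]}
    densities = {g: truth["A"] if m < 2.0 else truth["B"]
                 for g, m in decoded_means.items()}
    exact = entropy_rate_exact(fig4_model)
    assert plugin_entropy_rate(fit, densities=densities) == pytest.approx(
        exact, abs=1e-6
    )


def test_plugin_kde_estimate_near_truth(fig4_model):
    seq, _ = simulate(fig4_model, n_events=5000, seed=11)
    topo = enumerate_topologies({"0", "1"}, 4)[1]
    fit = fit_topology(topo, seq, COMPACT_DENSITY_CONFIG)
    est = plugin_entropy_rate(fit)
    # kernel smoothing biases the rate upward slightly at this sample size
    assert est == pytest.approx(1.85, abs=0.3)


def test_plugin_errors_on_underpopulated_state(fig4_model):
    seq, _ = simulate(fig4_model, n_events=60, seed=1)
    topo = enumerate_topologies({"0", "1"}, 4)[1]
    fit = fit_topology(topo, seq, COMPACT_DENSITY_CONFIG, min_dwells_per_state=2)
    fit.per_state_dwell_samples["s0"] = fit.per_state_dwell_samples["s0"][:1]
    with pytest.raises(ValueError, match="s0"):
        plugin_entropy_rate(fit)
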