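import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ctbsi.experiments import cycle_model
from ctbsi.model_core import (
    DecodeError,
    EventSequence,
    ExponentialDwell,
    InverseGaussianDwell,
    Topology,
    UhsMm,
    UniformDwell,
    decode_states,
    differential_entropy,
    entropy_rate_exact,
    simulate,
    stationary_distribution,
    validate_model,
)

from conftest import random_cycle_model


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def test_valid_cycle_has_no_violations(fig4_model):
    assert validate_model(fig4_model) == []


def test_alternation_violation_names_state_and_symbol():
    # A emits 0 into B, but B may emit 0 again — exactly one alternation break
    topo = Topology(
        ("A", "B", "C"),
        {"A": frozenset({"0"}), "B": frozenset({"0", "1"}), "C": frozenset({"2"})},
        {"A": {"0": "B"}, "B": {"0": "C", "1": "C"}, "C": {"2": "A"}},
    )
    model = UhsMm(
        topo,
        {"A": {"0": 1.0}, "B": {"0": 0.5, "1": 0.5}, "C": {"2": 1.0}},
        {g: ExponentialDwell(1) for g in "ABC"},
    )
    msgs = [m for m in validate_model(model) if "alternation" in m]
    assert len(msgs) == 1 and "A" in msgs[0] and "0" in msgs[0]


def test_unnormalized_emissions_flagged(two_state_model):
    model = UhsMm(
        two_state_model.topology,
        {"A": {"0": 0.9}, "B": {"1": 1.0}},
        two_state_model.dwell,
    )
    msgs = [m for m in validate_model(model) if "sum to" in m]
    assert len(msgs) == 1 and "A" in msgs[0]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def test_two_state_symbols_alternate(two_state_model):
    seq, _ = simulate(two_state_model, n_events=5, seed=3)
    assert seq.symbols in (["0", "1", "0", "1", "0"], ["1", "0", "1", "0", "1"])


def test_fig4_mean_dwell_matches_cycle_average(fig4_model):
    # cycle mean (1 + 3 + 3 + 1) / 4 = 2.0
    seq, _ = simulate(fig4_model, n_events=10_000, seed=0)
    m = seq.dwells.mean()
    se = seq.dwells.std() / np.sqrt(len(seq))
    assert abs(m - 2.0) < 3 * se


def test_duration_shorter_than_any_dwell_gives_single_censored_event():
    model = cycle_model([UniformDwell(20, 30), UniformDwell(20, 30)])
    seq, _ = simulate(model, duration=10.0, seed=1)
    assert len(seq) == 1 and seq.final_censored and seq.duration == 10.0


def test_same_seed_reproduces(fig4_model):
    a, pa = simulate(fig4_model, n_events=50, seed=42)
    b, pb = simulate(fig4_model, n_events=50, seed=42)
    assert a.symbols == b.symbols and np.array_equal(a.dwells, b.dwells)
    assert pa == pb


def test_bad_horizon_rejected(fig4_model):
    with pytest.raises(ValueError):
        simulate(fig4_model, n_events=0, seed=0)
    with pytest.raises(ValueError):
        simulate(fig4_model, n_events=5, duration=3.0, seed=0)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def test_decode_four_cycle_by_hand(fig4_model):
    seq = EventSequence(["0", "1", "0", "1"], np.ones(4))
    path = decode_states(fig4_model.topology, seq, "A")
    assert path.states == ["A", "B", "C", "D"]


def test_decode_failure_reports_index(fig4_model):
    seq = EventSequence(["1", "0"], np.ones(2))
    with pytest.raises(DecodeError) as exc:
        decode_states(fig4_model.topology, seq, "A")  # A emits only 0
    assert exc.value.index == 0


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_unifilar_roundtrip_and_alternation(seed):
    """Decoding a simulated sequence from its first state recovers the path,
    and no two consecutive symbols are ever equal."""
    rng = np.random.default_rng(seed)
    model = random_cycle_model(rng)
    seq, path = simulate(model, n_events=30, seed=rng)
    assert all(a != b for a, b in zip(seq.symbols, seq.symbols[1:]))
    assert decode_states(model.topology, seq, path.states[0]) == path


# ---------------------------------------------------------------------------
# stationary distribution
# ---------------------------------------------------------------------------


def test_symmetric_two_cycle_is_uniform():
    p = stationary_distribution(
        {"A": 1.0, "B": 1.0}, {"A": {"B": 7}, "B": {"A": 7}}
    )
    assert p == pytest.approx({"A": 0.5, "B": 0.5})


def test_four_cycle_weights_inverse_to_mean_dwell():
    # deterministic cycle: p(s) proportional to 1/mu_s, normaliser 8/3
    mu = {"A": 1.0, "B": 3.0, "C": 3.0, "D": 1.0}
    trans = {"A": {"B": 5}, "B": {"C": 5}, "C": {"D": 5}, "D": {"A": 5}}
    p = stationary_distribution(mu, trans)
    assert p == pytest.approx({"A": 0.375, "B": 0.125, "C": 0.125, "D": 0.375})


def test_single_state_self_loop_normalises():
    assert stationary_distribution({"A": 2.0}, {"A": {"A": 3}}) == {"A": 1.0}


def test_reducible_chain_rejected_with_state_names():
    with pytest.raises(ValueError, match="C"):
        stationary_distribution(
            {"A": 1.0, "B": 1.0, "C": 1.0},
            {"A": {"B": 1}, "B": {"A": 1}, "C": {"A": 1}},
        )


def test_stationary_is_fixed_point_of_recursion():
    rng = np.random.default_rng(7)
    mu = {s: float(rng.uniform(0.5, 4)) for s in "ABCD"}
    trans = {"A": {"B": 3, "C": 2}, "B": {"C": 4, "D": 1},
             "C": {"D": 2, "A": 2}, "D": {"A": 5}}
    p = stationary_distribution(mu, trans)
    assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(v >= 0 for v in p.values())
    # residual of p(s) = sum_{s'} (mu_{s'}/mu_s)(n_{s'->s}/n_{s'}) p(s')
    for s in mu:
        rhs = sum(
            (mu[s2] / mu[s]) * (trans[s2].get(s, 0) / sum(trans[s2].values())) * p[s2]
            for s2 in mu
        )
        assert abs(p[s] - rhs) < 1e-10


# ---------------------------------------------------------------------------
# exact entropy rate
# ---------------------------------------------------------------------------


def test_uniform_unit_dwells_give_zero_rate():
    model = cycle_model([UniformDwell(0, 1), UniformDwell(0, 1)])
    assert entropy_rate_exact(model) == pytest.approx(0.0, abs=1e-6)


def test_exponential_unit_dwells_give_one_nat(exp_two_cycle):
    assert entropy_rate_exact(exp_two_cycle) == pytest.approx(1.0, abs=1e-4)


def test_fig4_rate_is_1_85(fig4_model):
    assert entropy_rate_exact(fig4_model) == pytest.approx(1.85, abs=0.01)


def test_rate_stable_under_grid_refinement(fig4_model):
    a = entropy_rate_exact(fig4_model, n_grid=4096)
    b = entropy_rate_exact(fig4_model, n_grid=8192)
    assert abs(a - b) < 1e-3


def test_differential_entropy_closed_forms():
    assert differential_entropy(ExponentialDwell(1.0)) == pytest.approx(1.0, abs=1e-4)
    assert differential_entropy(UniformDwell(0, 2)) == pytest.approx(np.log(2), abs=1e-6)


# ---------------------------------------------------------------------------
# sampler correctness
# ---------------------------------------------------------------------------


def test_inverse_gaussian_sampler_ks():
    d = InverseGaussianDwell(1, 5)
    x = d.sample(10_000, np.random.default_rng(0))
    stat = stats.kstest(x, d.cdf).statistic
    assert stat < 1.63 / np.sqrt(len(x))  # 1% critical value
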