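"""Stochastic engine: waiting times, division, trajectory order."""

import math

import numpy as np
import pytest
from scipy import stats

from yeastbkmc.engine import Engine, run_population, simulate_lineage
from yeastbkmc.graph import TABLE2_HIGHWAY
from yeastbkmc.params import Parameters
from yeastbkmc.rules import WILD_TYPE
from yeastbkmc.state import G1_STATE, state_index, state_str


def _fresh_cell(engine, state, size=0.65, seed=0):
    cell = engine.new_cell(np.random.SeedSequence(seed), state=state, size=size)
    return cell


def test_one_variable_changes_per_flip_event():
    cell = simulate_lineage(horizon=400, seed=3)
    prev = None
    for ev in cell.log:
        if ev.kind in ("flip", "start", "division") and prev is not None:
            diff = prev ^ ev.state
            assert diff and not (diff & (diff - 1))
        prev = ev.state


def test_highway_order_is_followed_every_cycle():
    """Within each cycle the flip sequence visits the 14 recurring states
    in their canonical order (timing is stochastic, order is not)."""
    expected = list(TABLE2_HIGHWAY[1:]) + ["1000000"]
    for seed in range(5):
        cell = simulate_lineage(horizon=500, seed=seed)
        seq = [state_str(e.state) for e in cell.log
               if e.kind in ("flip", "start", "division")]
        # drop a trailing partial cycle
        n_full = len(seq) // 14 * 14
        for i, s in enumerate(seq[:n_full]):
            assert s == expected[i % 14]


def test_interevent_times_exponential_at_constant_p0():
    """From a state with a single enabled variable (rate 1/min), waiting
    times are exponential(1) (Kolmogorov-Smirnov at 1e4 samples)."""
    engine = Engine()
    start = state_index("0110000")  # only Clb5 is enabled, p = 1
    rng_seeds = np.random.SeedSequence(42).spawn(1)
    cell = engine.new_cell(rng_seeds[0], state=start)
    samples = np.empty(10_000)
    for i in range(len(samples)):
        cell.state = start
        t0 = cell.clock
        ev = engine.step(cell)
        assert ev.kind == "flip" and ev.variable == "Clb5"
        samples[i] = ev.time - t0
    assert stats.kstest(samples, "expon", args=(0, 1.0)).pvalue > 0.01


def test_fast_switch_rate_scales_waiting_time():
    engine = Engine()
    start = state_index("1100000")  # only Cln2, p = 10/min
    cell = engine.new_cell(np.random.SeedSequence(7), state=start)
    samples = np.empty(10_000)
    for i in range(len(samples)):
        cell.state = start
        t0 = cell.clock
        samples[i] = engine.step(cell).time - t0
    assert samples.mean() == pytest.approx(0.1, rel=0.05)


def test_mitotic_activation_delay_is_lognormal():
    """Clb2_M activation uses the lognormal multi-step delay: sample mean
    over many draws matches t_M_mean * exp(t_M_CV^2 / 2)."""
    p = Parameters()
    engine = Engine(params=p)
    start = state_index("0001100")  # single enabled: Clb2_M turns on
    cell = engine.new_cell(np.random.SeedSequence(11), state=start)
    n = 20_000
    samples = np.empty(n)
    for i in range(n):
        cell.state = start
        t0 = cell.clock
        ev = engine.step(cell)
        assert ev.variable == "Clb2_M"
        samples[i] = ev.time - t0
    expected_mean = p.t_M_mean * math.exp(p.t_M_CV ** 2 / 2)
    se = samples.std(ddof=1) / math.sqrt(n)
    assert abs(samples.mean() - expected_mean) < 3 * se
    # and log-samples look normal with the right parameters
    logs = np.log(samples)
    assert logs.mean() == pytest.approx(math.log(p.t_M_mean), abs=0.01)
    assert logs.std(ddof=1) == pytest.approx(p.t_M_CV, rel=0.03)


def test_g1_waiting_when_gate_shut():
    """Below the critical size nothing is enabled; the cell idles with
    exponential(p_G1) increments and, at mu = 0, never leaves G1."""
    p = Parameters(mu=0.0)
    engine = Engine(params=p)
    cell = _fresh_cell(engine, G1_STATE, size=0.3, seed=5)
    waits = []
    t_prev = 0.0
    for _ in range(3000):
        ev = engine.step(cell)
        assert ev.kind == "g1_wait" and ev.state == G1_STATE
        waits.append(ev.time - t_prev)
        t_prev = ev.time
    assert np.mean(waits) == pytest.approx(1 / p.p_G1, rel=0.1)
    assert cell.size == pytest.approx(0.3)


def test_size_grows_exponentially_between_events():
    p = Parameters()
    cell = simulate_lineage(params=p, horizon=200, seed=9)
    prev = None
    for ev in cell.log:
        if prev is not None and ev.kind != "division":
            expected = prev.size * math.exp(p.mu * (ev.time - prev.time))
            assert ev.size == pytest.approx(expected, rel=1e-9)
        prev = ev


class TestDivision:
    def test_mass_conservation_is_exact(self):
        engine = Engine()
        cell = _fresh_cell(engine, state_index("1000101"), size=1.2, seed=13)
        ev = engine.step(cell)
        assert ev.kind == "division"
        parent_size = cell.size
        daughter = engine.divide(cell, next_cell_id=1)
        assert cell.size + daughter.size == pytest.approx(parent_size, rel=1e-12)
        assert cell.state == daughter.state == state_index("1000001")
        assert daughter.spawned and daughter.generation == 0
        assert cell.generation == 1
        assert daughter.parent_id == cell.cell_id

    def test_zero_cv_gives_exact_mother_fraction(self):
        engine = Engine(params=Parameters(f_CV=1e-12))
        for seed in range(5):
            cell = _fresh_cell(engine, state_index("1000101"), size=1.0, seed=seed)
            engine.step(cell)
            total = cell.size
            engine.divide(cell, 1)
            assert cell.size / total == pytest.approx(0.58, abs=1e-6)

    def test_mean_mother_fraction_matches_lognormal_mean(self):
        p = Parameters()
        engine = Engine(params=p)
        n = 10_000
        fracs = np.empty(n)
        for i in range(n):
            cell = _fresh_cell(engine, state_index("1000101"), size=1.0, seed=i)
            engine.step(cell)
            total = cell.size
            engine.divide(cell, 1)
            fracs[i] = cell.size / total
        expected = p.f_mean * math.exp(p.f_CV ** 2 / 2)
        se = fracs.std(ddof=1) / math.sqrt(n)
        assert abs(fracs.mean() - expected) < 3 * se

    def test_progeny_get_fresh_critical_sizes(self):
        engine = Engine()
        cell = _fresh_cell(engine, state_index("1000101"), size=1.1, seed=21)
        s0_before = cell.s0
        engine.step(cell)
        daughter = engine.divide(cell, 1)
        assert cell.s0 != s0_before
        assert daughter.s0 != cell.s0
        assert cell.birth_time == daughter.birth_time == cell.clock


def test_mother_lineage_division_count_at_defaults():
    """A mother lineage over 300 min typically divides 3-4 times (checked
    loosely over seeds)."""
    counts = []
    for seed in range(6):
        cell = simulate_lineage(horizon=300, seed=seed)
        counts.append(sum(1 for e in cell.log if e.kind == "division"))
    assert all(2 <= c <= 6 for c in counts)
    assert 3 <= np.median(counts) <= 4


def test_run_population_reproducible_and_horizon_respected():
    a = run_population(n_founders=5, horizon=250, seed=99)
    b = run_population(n_founders=5, horizon=250, seed=99)
    assert len(a) == len(b)
    for ca, cb in zip(a, b):
        assert ca.log == cb.log
    assert all(ev.time <= 250 for c in a for ev in c.log)
    # founders unchanged when the horizon precedes any event
    tiny = run_population(n_founders=3, horizon=1e-6, seed=1)
    assert len(tiny) == 3
    assert all(len(c.log) == 1 for c in tiny)  # only the birth record
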