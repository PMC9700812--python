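"""Cycle extraction, summary statistics, slopes, synchrony, growth."""

import math

import numpy as np
import pandas as pd
import pytest

from yeastbkmc.engine import run_population
from yeastbkmc.params import Parameters
from yeastbkmc.population import (
    binned_slope,
    budded_fraction,
    cell_counts,
    extract_cycles,
    fit_doubling_time,
    population_timecourse,
    summarize,
    trajectory_network,
)
from yeastbkmc.rules import mutant_ruleset


@pytest.fixture(scope="module")
def small_population():
    return run_population(n_founders=15, horizon=450, seed=1)


class TestExtractCycles:
    def test_interval_identity_and_positivity(self, small_population):
        rec = extract_cycles(small_population)
        assert len(rec) > 50
        assert np.allclose(rec.T_c, rec.T_G1 + rec.T_bud)
        assert (rec[["T_c", "T_G1", "T_bud", "size_at_birth"]] > 0).all().all()
        assert set(rec.pedigree) == {"mother", "daughter"}

    def test_burn_in_drops_early_births(self, small_population):
        rec_all = extract_cycles(small_population)
        rec_late = extract_cycles(small_population, burn_in=200.0)
        assert len(rec_late) < len(rec_all)
        assert (rec_late.birth_time >= 200.0).all()

    def test_exact_bookkeeping_on_a_synthetic_log(self):
        """Durations from a hand-built event log are recovered exactly."""
        from yeastbkmc.engine import Cell, SimEvent
        from yeastbkmc.state import state_index

        cell = Cell(cell_id=7, seed_seq=np.random.SeedSequence(0), spawned=True)
        s = state_index
        cell.log = [
            SimEvent(10.0, "birth", None, s("1000001"), 0.5),
            SimEvent(12.0, "flip", "Cdc20", s("1000000"), 0.51),
            SimEvent(40.0, "start", "SBF", s("1100000"), 0.6),
            SimEvent(95.0, "division", "Clb2_G", s("1000001"), 0.55),
            SimEvent(97.0, "flip", "Cdc20", s("1000000"), 0.551),
            SimEvent(120.0, "start", "SBF", s("1100000"), 0.6),
            SimEvent(190.0, "division", "Clb2_G", s("1000001"), 0.58),
        ]
        rec = extract_cycles([cell])
        assert len(rec) == 2
        first, second = rec.iloc[0], rec.iloc[1]
        assert first.pedigree == "daughter"
        assert (first.T_G1, first.T_bud, first.T_c) == (30.0, 55.0, 85.0)
        assert first.size_at_birth == 0.5
        assert second.pedigree == "mother"
        assert (second.T_G1, second.T_bud, second.T_c) == (25.0, 70.0, 95.0)


class TestSummarize:
    def test_identical_records_have_zero_cv(self):
        rec = pd.DataFrame({
            "cell_id": [1, 2], "pedigree": ["mother"] * 2,
            "birth_time": [0.0, 0.0], "size_at_birth": [0.6, 0.6],
            "T_c": [90.0, 90.0], "T_G1": [20.0, 20.0], "T_bud": [70.0, 70.0],
        })
        out = summarize(rec)
        assert out.loc["mother", "T_c_cv"] == 0.0
        assert out.loc["mother", "T_c_mean"] == 90.0

    def test_pedigree_asymmetries_at_defaults(self, default_cycles):
        out = summarize(default_cycles)
        # the mother keeps the larger share at division (f = 0.58 > 0.5) ...
        assert (out.loc["mother", "size_at_birth_mean"]
                > out.loc["daughter", "size_at_birth_mean"])
        # ... so daughters need longer G1 and a longer cycle
        assert out.loc["daughter", "T_c_mean"] > out.loc["mother", "T_c_mean"]
        assert out.loc["daughter", "T_G1_mean"] > out.loc["mother", "T_G1_mean"]

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["pedigree", "T_c", "T_G1",
                                            "T_bud", "size_at_birth"]))


def _synthetic_records(rng, n, t_g1_fn, pedigree="daughter"):
    size = rng.lognormal(math.log(0.45), 0.25, n)
    mu = 0.007
    t_g1 = t_g1_fn(size, mu)
    return pd.DataFrame({
        "cell_id": np.arange(n), "pedigree": pedigree,
        "birth_time": 0.0, "size_at_birth": size,
        "T_G1": t_g1, "T_bud": 70.0, "T_c": t_g1 + 70.0,
    })


class TestBinnedSlope:
    def test_perfect_sizer_has_slope_minus_one(self):
        """If cells always start at a fixed target size, mu*T_G1 =
        ln(target) - ln(birth size): slope exactly -1 in every branch."""
        rng = np.random.default_rng(2)
        rec = _synthetic_records(
            rng, 4000, lambda s, mu: (math.log(0.9) - np.log(s)) / mu)
        res = binned_slope(rec, mu=0.007, pedigree="daughter")
        assert res.slope_small == pytest.approx(-1.0, abs=1e-9)
        assert res.slope_large == pytest.approx(-1.0, abs=1e-9)
        assert res.slope_all_bins == pytest.approx(-1.0, abs=1e-9)

    def test_no_sizer_has_slope_zero(self):
        rng = np.random.default_rng(3)
        rec = _synthetic_records(rng, 4000, lambda s, mu: np.full(len(s), 40.0))
        res = binned_slope(rec, mu=0.007, pedigree="daughter")
        assert res.slope_all_bins == pytest.approx(0.0, abs=1e-9)

    def test_mother_default_is_single_line(self, default_cycles):
        res = binned_slope(default_cycles, mu=0.007, pedigree="mother")
        assert res.slope_small is None and res.breakpoint is None
        assert res.slope == res.slope_all_bins

    def test_too_few_bins_is_an_error(self):
        rec = pd.DataFrame({
            "cell_id": [0] * 10, "pedigree": "mother", "birth_time": 0.0,
            "size_at_birth": 0.65, "T_G1": 20.0, "T_bud": 70.0, "T_c": 90.0,
        })
        with pytest.raises(ValueError, match="fewer than 2 usable bins"):
            binned_slope(rec, mu=0.007, pedigree="mother")


class TestTimecourseAndSynchrony:
    def test_population_averages_are_fractions(self, small_population):
        grid = np.arange(0.0, 400.0, 5.0)
        tc = population_timecourse(small_population, grid, mu=0.007)
        for var in ("Cdh1", "SBF", "Cln2", "Clb5", "Clb2_G", "Clb2_M", "Cdc20"):
            vals = tc[var].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
        assert tc["n_cells"].iloc[0] == 15
        assert (tc["Size"].dropna() > 0).all()

    def test_budded_fraction_bounds_and_start(self, small_population):
        grid = np.arange(0.0, 400.0, 2.0)
        bf = budded_fraction(small_population, grid, cohort="daughter")
        vals = bf["fraction_budded"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()
        # founders all start unbudded in early G1
        assert bf["fraction_budded"].iloc[0] == 0.0
        with pytest.raises(ValueError):
            budded_fraction(small_population, grid, cohort=25)


def test_number_doubling_tracks_mass_doubling(small_population):
    grid = np.arange(0.0, 451.0, 10.0)
    counts = cell_counts(small_population, grid)
    assert counts[0] == 15 and counts[-1] > counts[0]
    mdt = fit_doubling_time(small_population, 50.0, 450.0)
    assert mdt == pytest.approx(math.log(2) / 0.007, rel=0.15)


class TestTrajectoryNetwork:
    def test_single_clb_mutant_has_two_fates(self):
        """In the single-B-type-cyclin strain most cells run a full mitotic
        sequence (Clb2_M on) but a minority reset when Cdh1 degrades Clb2_G
        straight away; both fates must appear, mitosis dominating."""
        net = trajectory_network(mutant_ruleset("clns-clb2"), n_cells=200,
                                 seed=2)
        n_mitosis = net[net.variable.eq("Clb2_M")
                        & net.to_state.str[5].eq("1")]["count"].sum()
        assert 0.5 < n_mitosis / 200 < 0.98
        # reset fate: Clb2_G turned off by Cdh1 with Clb2_M still off
        resets = net[net.variable.eq("Clb2_G")
                     & net.from_state.str[0].eq("1")
                     & net.from_state.str[5].eq("0")
                     & net.to_state.str[4].eq("0")]["count"].sum()
        assert resets > 0

    def test_cln2_repressed_mutant_never_buds(self):
        net = trajectory_network(mutant_ruleset("met3pr-cln2-clb2"),
                                 n_cells=100, seed=3)
        assert not (net.variable == "Cln2").any()
        # trajectories leave G1 despite Cln2 repression (SBF -> Clb2_G route)
        assert (net.variable == "Clb2_G").any()
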