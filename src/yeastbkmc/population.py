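"""Population experiments and cell-cycle statistics.

Builds on :mod:`yeastbkmc.engine` to reproduce the model's population-level
observables: per-cycle durations split by pedigree, their means and CVs,
size-control slopes of the scaled G1 duration against log birth size,
synchrony (budded-fraction) curves, per-minute population averages, and
exponential population growth.

A completed cycle runs from birth (the division flip that created the
record, state 1000001) to the cell's own next division.  ``T_G1`` ends at
SBF activation (state 1100000, operationally "bud emergence") and ``T_bud``
covers the rest, so ``T_c = T_G1 + T_bud`` identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Cell, run_population
from .params import Parameters
from .rules import WILD_TYPE, RuleSet
from .state import G1_STATE, START_STATE, state_str

#: volume conversion used only for binning: 1 dimensionless size = 61.4 fL
FL_PER_SIZE_UNIT = 61.4


def extract_cycles(cells: list[Cell], burn_in: float = 0.0) -> pd.DataFrame:
    """One row per completed cell cycle.

    Columns: cell_id, pedigree, birth_time, size_at_birth, T_c, T_G1,
    T_bud.  A founder's first segment has no birth division and is skipped;
    cycles still open at the horizon are dropped; cycles born before
    ``burn_in`` are excluded.
    """
    records = []
    for cell in cells:
        birth = None  # (time, size, pedigree) of current open cycle
        sbf_on = None
        n_divisions = 0
        for ev in cell.log:
            if ev.kind == "birth" and cell.spawned:
                birth = (ev.time, ev.size, "daughter")
            elif ev.kind == "start" and birth is not None and sbf_on is None:
                sbf_on = ev.time
            elif ev.kind == "division":
                if birth is not None and sbf_on is not None:
                    t0, size0, pedigree = birth
                    if t0 >= burn_in:
                        records.append(
                            (cell.cell_id, pedigree, t0, size0,
                             ev.time - t0, sbf_on - t0, ev.time - sbf_on)
                        )
                n_divisions += 1
                # the division event's size is the mother's retained share
                birth = (ev.time, ev.size, "mother")
                sbf_on = None
    return pd.DataFrame(
        records,
        columns=["cell_id", "pedigree", "birth_time", "size_at_birth",
                 "T_c", "T_G1", "T_bud"],
    )


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Means and coefficients of variation by pedigree.

    Returns a frame indexed by pedigree with columns ``<quantity>_mean``,
    ``<quantity>_cv`` and ``n`` for T_c, T_G1, T_bud and size_at_birth.
    """
    if records.empty:
        raise ValueError("no completed cycles to summarize")
    quantities = ["T_c", "T_G1", "T_bud", "size_at_birth"]
    rows = {}
    for pedigree, group in records.groupby("pedigree"):
        if len(group) < 2:
            raise ValueError(f"need >= 2 records for pedigree {pedigree!r}")
        row = {}
        for q in quantities:
            mean = group[q].mean()
            row[f"{q}_mean"] = mean
            row[f"{q}_cv"] = group[q].std(ddof=1) / mean if mean else np.nan
        row["n"] = len(group)
        rows[pedigree] = row
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class BinnedSlopeResult:
    """Binned size-control regression of mu*T_G1 on ln(size-at-birth).

    ``slope`` is the headline slope: for a single-line fit the overall
    slope; for a two-piece fit the large-cell branch.  ``slope_small`` /
    ``slope_large`` are the two branches (equal to ``slope`` when no
    breakpoint is used), ``breakpoint`` the ln-size at the joint, ``bins``
    the per-bin means used in the fit.
    """

    pedigree: str
    slope: float
    slope_small: float | None
    slope_large: float | None
    breakpoint: float | None
    slope_all_bins: float
    bins: pd.DataFrame


def binned_slope(
    records: pd.DataFrame,
    mu: float,
    pedigree: str = "mother",
    conversion_fl: float = FL_PER_SIZE_UNIT,
    bin_width_fl: float = 2.0,
    min_per_bin: int = 3,
    two_piece: bool | None = None,
) -> BinnedSlopeResult:
    """Size-control slope from bin means, as in the classic experimental
    protocol: birth sizes are binned in ``bin_width_fl`` (fL) intervals and
    the per-bin mean of mu*T_G1 is regressed on the per-bin mean of
    ln(size-at-birth), with bins weighted by their occupancy.

    By default mothers are fitted with one straight line, while daughters —
    whose small cells sit below the Start threshold and behave as near-
    perfect sizers — are fitted with two straight lines joined at the
    breakpoint minimizing the weighted squared error.  Pass ``two_piece``
    to force either behaviour.
    """
    group = records[records["pedigree"] == pedigree]
    if group.empty:
        raise ValueError(f"no records with pedigree {pedigree!r}")
    fl = group["size_at_birth"].to_numpy() * conversion_fl
    lnsize = np.log(group["size_at_birth"].to_numpy())
    y = mu * group["T_G1"].to_numpy()
    bin_idx = np.floor(fl / bin_width_fl).astype(int)
    frame = pd.DataFrame({"bin": bin_idx, "lnsize": lnsize, "y": y})
    bins = (
        frame.groupby("bin")
        .agg(lnsize=("lnsize", "mean"), mu_TG1=("y", "mean"), n=("y", "size"))
        .reset_index()
    )
    bins = bins[bins["n"] >= min_per_bin].sort_values("lnsize").reset_index(drop=True)
    if len(bins) < 2:
        raise ValueError("fewer than 2 usable bins")
    x = bins["lnsize"].to_numpy()
    yb = bins["mu_TG1"].to_numpy()
    w = np.sqrt(bins["n"].to_numpy(dtype=float))
    slope_all = float(np.polyfit(x, yb, 1, w=w)[0])

    if two_piece is None:
        two_piece = pedigree == "daughter"
    best = None
    if two_piece and len(bins) >= 4:
        # continuous piecewise-linear (hinge) fit; breakpoint on bin edges
        for k in range(2, len(bins) - 1):  # >= 2 bins per branch
            brk = 0.5 * (x[k - 1] + x[k])
            design = np.column_stack(
                [np.ones_like(x), x, np.maximum(0.0, brk - x)]
            )
            beta, *_ = np.linalg.lstsq(design * w[:, None], yb * w, rcond=None)
            sse = float(((yb - design @ beta) * w) @ ((yb - design @ beta) * w))
            if best is None or sse < best[0]:
                # slope below the break is b - c, above it is b
                best = (sse, float(beta[1] - beta[2]), float(beta[1]), brk)
    if best is None:
        return BinnedSlopeResult(pedigree, slope_all, None, None, None,
                                 slope_all, bins)
    _, s_small, s_large, brk = best
    return BinnedSlopeResult(pedigree, s_large, s_small, s_large, brk,
                             slope_all, bins)


# -- time-resolved population observables ---------------------------------


def _segments(cell: Cell):
    """(t_start, t_end, state, size_at_start, n_prior_divisions, budded)
    intervals of one cell's life, ignoring wait events."""
    events = [e for e in cell.log if e.kind != "g1_wait"]
    out = []
    divisions = 0
    budded = False
    for ev, nxt in zip(events, events[1:] + [None]):
        if ev.kind == "division":
            divisions += 1
            budded = False
        elif ev.kind == "start":
            budded = True
        t_end = nxt.time if nxt is not None else math.inf
        out.append((ev.time, t_end, ev.state, ev.size, divisions, budded))
    return out


def population_timecourse(
    cells: list[Cell], grid: np.ndarray, mu: float
) -> pd.DataFrame:
    """Population averages of each Boolean variable and of Size on a grid.

    Averages run over all cells extant at each time point; size between
    events is reconstructed from exponential growth.
    """
    from .state import N_VARS, VARIABLES, bit_of

    grid = np.asarray(grid, dtype=float)
    sums = np.zeros((len(grid), N_VARS))
    size_sum = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=int)
    for cell in cells:
        for t0, t1, state, size0, _, _ in _segments(cell):
            lo = np.searchsorted(grid, t0, side="left")
            hi = np.searchsorted(grid, t1, side="left")
            if hi <= lo:
                continue
            ts = grid[lo:hi]
            counts[lo:hi] += 1
            size_sum[lo:hi] += size0 * np.exp(mu * (ts - t0))
            for v in range(N_VARS):
                if bit_of(state, v):
                    sums[lo:hi, v] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        data = {name: sums[:, v] / counts for v, name in enumerate(VARIABLES)}
        data["Size"] = size_sum / counts
    data["n_cells"] = counts
    return pd.DataFrame(data, index=pd.Index(grid, name="time_min"))


def budded_fraction(
    cells: list[Cell], grid: np.ndarray, cohort: int | str = "daughter"
) -> pd.DataFrame:
    """Percent budded cells over time for one bud-scar cohort.

    ``cohort`` is ``"daughter"`` (cells that have never divided, scar count
    0) or an integer k (cells having divided exactly k times).  A cell is
    budded from SBF activation until its next division.
    """
    k = 0 if cohort == "daughter" else int(cohort)
    grid = np.asarray(grid, dtype=float)
    budded = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    for cell in cells:
        for t0, t1, _, _, divisions, is_budded in _segments(cell):
            if divisions != k:
                continue
            lo = np.searchsorted(grid, t0, side="left")
            hi = np.searchsorted(grid, t1, side="left")
            if hi <= lo:
                continue
            counts[lo:hi] += 1
            if is_budded:
                budded[lo:hi] += 1
    if counts.max() == 0:
        raise ValueError(f"cohort {cohort!r} is empty on the whole grid")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, budded / counts, np.nan)
    return pd.DataFrame(
        {"fraction_budded": frac, "n_cells": counts},
        index=pd.Index(grid, name="time_min"),
    )


def cell_counts(cells: list[Cell], grid: np.ndarray) -> np.ndarray:
    """Number of cells extant at each grid time."""
    grid = np.asarray(grid, dtype=float)
    counts = np.zeros(len(grid), dtype=int)
    for cell in cells:
        t0 = cell.log[0].time
        counts += (grid >= t0)
    return counts


def fit_doubling_time(
    cells: list[Cell], t_start: float, t_end: float, n_points: int = 50
) -> float:
    """Number-doubling time from an exponential fit to the cell count."""
    grid = np.linspace(t_start, t_end, n_points)
    counts = cell_counts(cells, grid)
    if counts.min() < 1:
        raise ValueError("no cells in part of the fitting window")
    slope, _ = np.polyfit(grid, np.log(counts), 1)
    return float(math.log(2) / slope)


# -- asynchronous-population protocol -------------------------------------


def asynchronous_cycles(
    rules: RuleSet = WILD_TYPE,
    params: Parameters | None = None,
    n_founders: int = 40,
    horizon: float = 700.0,
    burn_in: float = 400.0,
    founder_size: float = 0.65,
    seed: int = 0,
) -> pd.DataFrame:
    """Default steady-state sampling protocol.

    Simulates ``n_founders`` founder lineages with all progeny to
    ``horizon`` minutes and pools every cycle born after ``burn_in``.  With
    the defaults this yields on the order of 1500-2000 completed cycles at
    the standard growth rate; at slower growth extend ``horizon``.
    """
    cells = run_population(
        rules=rules, params=params, n_founders=n_founders,
        founder_size=founder_size, horizon=horizon, seed=seed,
    )
    return extract_cycles(cells, burn_in=burn_in)


# -- mutant trajectory networks -------------------------------------------


def trajectory_network(
    rules: RuleSet,
    params: Parameters | None = None,
    n_cells: int = 500,
    start_size: float = 0.65,
    seed: int = 0,
    max_time: float = 10000.0,
) -> pd.DataFrame:
    """Union of state-to-state transitions over repeated G1-to-G1 runs.

    Each of ``n_cells`` cells starts in the newborn state and is followed
    (mother branch at divisions) until it first returns there; the edge
    counts of the union of trajectories form the mutant's trajectory
    network.  Returns a frame (from_state, to_state, variable, count).
    """
    from .engine import Engine

    engine = Engine(rules, params)
    root = np.random.SeedSequence(seed)
    edges: dict[tuple[str, str, str], int] = {}
    for i, sq in enumerate(root.spawn(n_cells)):
        cell = engine.new_cell(sq, cell_id=i, state=G1_STATE, size=start_size)
        prev = cell.state
        while cell.clock < max_time:
            ev = engine.step(cell, log_waits=False)
            if ev.kind == "g1_wait":
                continue
            if ev.kind == "division":
                engine.divide(cell, next_cell_id=-1)  # follow the mother
            key = (state_str(prev), state_str(ev.state), ev.variable)
            edges[key] = edges.get(key, 0) + 1
            prev = ev.state
            if ev.state == G1_STATE:
                break
    frame = pd.DataFrame(
        [(u, v, var, c) for (u, v, var), c in sorted(edges.items())],
        columns=["from_state", "to_state", "variable", "count"],
    )
    return frame
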