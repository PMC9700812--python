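"""Kinetic Monte-Carlo engine: asynchronous updates in continuous time.

Each iteration evaluates the candidate vector, races the enabled variables
(the winner is the smallest index j with cumulative propensity exceeding
``r1 * P0``), draws the waiting time ``dt = -log(r2)/P0``, and grows Size
exponentially over ``dt``.  Three departures from the bare Gillespie loop:

1. The activations (0 -> 1) of Clb2_M and of Cdc20 are multi-step processes
   in reality; once selected, their ``dt`` is drawn lognormal with
   meanlog = log(t_M_mean) and sdlog = t_M_CV instead of exponentially.
2. In the newborn state with the Start gate shut, no variable is enabled
   (P0 = 0); the cell idles for ``dt = -log(r2)/p_G1`` and retries the gate
   with a fresh uniform draw each iteration.
3. A Clb2_G 1 -> 0 flip is cell division: the mother keeps a lognormal
   fraction f of the post-growth size, the daughter gets 1 - f, and both
   progeny draw fresh critical sizes S0.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .params import Parameters
from .rules import WILD_TYPE, RuleSet, sbf_gate_open
from .state import (
    CLB2G,
    CLB2M,
    CDC20,
    EXIT_STATE,
    G1_STATE,
    N_STATES,
    N_VARS,
    SBF,
    VARIABLES,
    bit_of,
    flip_bit,
    state_str,
)


class SimEvent(NamedTuple):
    """One logged event of a single-cell trajectory."""

    time: float
    kind: str  # birth | flip | start | g1_wait | division
    variable: Optional[str]
    state: int  # integer state index after the event
    size: float  # cell size at the event (mother's retained size at division)


@dataclass
class Cell:
    """One simulated cell lineage record.

    A cell object persists through its own divisions (the mother continues;
    each division spawns a new daughter ``Cell``).  ``generation`` counts
    completed divisions (bud scars).  ``spawned`` is False only for founder
    cells created directly by the caller.
    """

    cell_id: int
    seed_seq: np.random.SeedSequence
    state: int = G1_STATE
    size: float = 0.65
    s0: float = 0.4
    clock: float = 0.0
    birth_time: float = 0.0
    generation: int = 0
    spawned: bool = False
    parent_id: Optional[int] = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rng = np.random.default_rng(self.seed_seq)

    @property
    def pedigree(self) -> str:
        """Pedigree of the cycle currently in progress."""
        return "daughter" if self.spawned and self.generation == 0 else "mother"

    @property
    def state_string(self) -> str:
        return state_str(self.state)


class Engine:
    """Compiled simulator for one (rule set, parameter) combination.

    The candidate table is evaluated once for all 128 states; the Start gate
    (the only state- and size-dependent part) is re-evaluated each iteration
    in the newborn state.
    """

    def __init__(self, rules: RuleSet = WILD_TYPE, params: Parameters | None = None):
        self.rules = rules
        self.params = rules.apply_parameters(params or Parameters())
        rates = self.params.propensity_vector
        # per state: (cumulative propensities, [(var, newbit, next_state)], P0)
        self._trans: list[tuple[tuple[float, ...], list, float]] = []
        for s, cand in enumerate(rules.candidate_table()):
            moves = [
                (v, cand[v], flip_bit(s, v))
                for v in range(N_VARS)
                if cand[v] != bit_of(s, v)
            ]
            cum, total = [], 0.0
            for v, _, _ in moves:
                total += rates[v]
                cum.append(total)
            self._trans.append((tuple(cum), moves, total))

    # -- single update ----------------------------------------------------

    def step(self, cell: Cell, log_waits: bool = True) -> SimEvent:
        """Advance one iteration, mutating the cell; returns the event.

        Division is detected by the caller from the returned event kind.
        """
        p = self.params
        rng = cell.rng
        cum, moves, p0 = self._trans[cell.state]
        gate_move = None
        if cell.state == G1_STATE:
            if sbf_gate_open(cell.size, cell.s0, rng.random()):
                gate_move = (SBF, 1, flip_bit(cell.state, SBF))
                cum = cum + (p0 + p.p_SBF,)
                moves = moves + [gate_move]
                p0 = p0 + p.p_SBF

        if p0 == 0.0:
            # G1 waiting: nothing enabled, size keeps growing
            dt = -math.log(rng.random()) / p.p_G1
            cell.clock += dt
            cell.size *= math.exp(p.mu * dt)
            event = SimEvent(cell.clock, "g1_wait", None, cell.state, cell.size)
            if log_waits:
                cell.log.append(event)
            return event

        r1 = rng.random()
        j = bisect_right(cum, r1 * p0)
        var, newbit, next_state = moves[j]

        activation_delay = newbit == 1 and var in (CLB2M, CDC20)
        if activation_delay:
            dt = rng.lognormal(mean=math.log(p.t_M_mean), sigma=p.t_M_CV)
        else:
            dt = -math.log(rng.random()) / p0

        cell.clock += dt
        cell.size *= math.exp(p.mu * dt)
        cell.state = next_state

        if var == CLB2G and newbit == 0:
            kind = "division"
        elif moves[j] is gate_move:
            kind = "start"
        else:
            kind = "flip"
        event = SimEvent(cell.clock, kind, VARIABLES[var], next_state, cell.size)
        cell.log.append(event)
        return event

    # -- division ---------------------------------------------------------

    def divide(self, cell: Cell, next_cell_id: int) -> Cell:
        """Split the cell at its current (post-growth) size.

        The mother retains fraction f (lognormal around f_mean, redrawn on
        the rare draw outside (0, 1)); the daughter receives the rest.  Both
        progeny draw fresh critical sizes and reset their birth clocks.
        Returns the new daughter cell; the mother record is mutated in
        place.
        """
        p = self.params
        rng = cell.rng
        parent_size = cell.size
        while True:
            f = rng.lognormal(mean=math.log(p.f_mean), sigma=p.f_CV)
            if 0.0 < f < 1.0:
                break
        daughter_seq = cell.seed_seq.spawn(1)[0]
        daughter = Cell(
            cell_id=next_cell_id,
            seed_seq=daughter_seq,
            state=cell.state,
            size=(1.0 - f) * parent_size,
            s0=0.0,
            clock=cell.clock,
            birth_time=cell.clock,
            generation=0,
            spawned=True,
            parent_id=cell.cell_id,
        )
        daughter.s0 = float(
            daughter.rng.lognormal(mean=math.log(p.S0_mean), sigma=p.S0_CV)
        )
        daughter.log.append(
            SimEvent(cell.clock, "birth", None, daughter.state, daughter.size)
        )
        cell.size = f * parent_size
        cell.s0 = float(rng.lognormal(mean=math.log(p.S0_mean), sigma=p.S0_CV))
        cell.generation += 1
        cell.birth_time = cell.clock
        # rewrite the division event's size to the mother's retained share
        ev = cell.log[-1]
        cell.log[-1] = ev._replace(size=cell.size)
        return daughter

    # -- whole trajectories -----------------------------------------------

    def new_cell(
        self,
        seed_seq: np.random.SeedSequence,
        cell_id: int = 0,
        state: int = G1_STATE,
        size: float = 0.65,
        clock: float = 0.0,
    ) -> Cell:
        """Create a founder cell with a birth-assigned critical size."""
        cell = Cell(cell_id=cell_id, seed_seq=seed_seq, state=state, size=size,
                    s0=0.0, clock=clock, birth_time=clock)
        p = self.params
        cell.s0 = float(cell.rng.lognormal(mean=math.log(p.S0_mean), sigma=p.S0_CV))
        cell.log.append(SimEvent(clock, "birth", None, state, size))
        return cell

    def simulate_cell(
        self,
        cell: Cell,
        horizon: float,
        keep_daughters: bool = True,
        log_waits: bool = True,
        max_divisions: int | None = None,
        next_cell_id: int | None = None,
    ) -> list[Cell]:
        """Run one cell to the horizon, spawning (but not running) daughters.

        Returns the list of daughters born along the way.  When
        ``keep_daughters`` is False the mother lineage is followed alone
        (daughters are discarded at birth, Fig.-1c style).  An event whose
        time would exceed the horizon is discarded: the cell is left at its
        pre-event state with its clock at the last accepted event.
        """
        if horizon <= cell.clock:
            raise ValueError("horizon must exceed the cell's current clock")
        daughters: list[Cell] = []
        divisions = 0
        cid = next_cell_id if next_cell_id is not None else cell.cell_id * 1000 + 1
        while True:
            saved = (cell.state, cell.size, cell.clock)
            event = self.step(cell, log_waits=log_waits)
            if event.time > horizon:
                cell.state, cell.size, cell.clock = saved
                if cell.log and cell.log[-1].time > horizon:
                    cell.log.pop()
                break
            if event.kind == "division":
                daughter = self.divide(cell, cid)
                cid += 1
                divisions += 1
                if keep_daughters:
                    daughters.append(daughter)
                if max_divisions is not None and divisions >= max_divisions:
                    break
        return daughters


def run_population(
    rules: RuleSet = WILD_TYPE,
    params: Parameters | None = None,
    n_founders: int = 20,
    founder_size: float = 0.65,
    founder_state: int = G1_STATE,
    horizon: float = 400.0,
    seed: int | np.random.SeedSequence = 0,
    log_waits: bool = False,
) -> list[Cell]:
    """Simulate founders and all their progeny to the horizon.

    Cells do not interact, so each lineage is simulated independently; every
    cell derives its own random substream from the root seed, making the
    result independent of scheduling order.  Returns all cells (founders
    first, then progeny in breadth order).
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    engine = Engine(rules, params)
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    founder_seqs = root.spawn(n_founders)
    cells: list[Cell] = [
        engine.new_cell(sq, cell_id=i, state=founder_state, size=founder_size)
        for i, sq in enumerate(founder_seqs)
    ]
    queue = list(cells)
    next_id = n_founders
    while queue:
        cell = queue.pop(0)
        daughters = engine.simulate_cell(
            cell, horizon, keep_daughters=True, log_waits=log_waits,
            next_cell_id=next_id,
        )
        next_id += len(daughters)
        cells.extend(daughters)
        queue.extend(daughters)
    return cells


def simulate_lineage(
    rules: RuleSet = WILD_TYPE,
    params: Parameters | None = None,
    horizon: float = 300.0,
    size: float = 0.65,
    state: int = G1_STATE,
    seed: int | np.random.SeedSequence = 0,
    log_waits: bool = True,
) -> Cell:
    """Follow a single mother cell (daughters discarded) to the horizon."""
    engine = Engine(rules, params)
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    cell = engine.new_cell(root, cell_id=0, state=state, size=size)
    engine.simulate_cell(cell, horizon, keep_daughters=False, log_waits=log_waits)
    return cell
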