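"""Robustness screen: single-state flips off the cell-cycle highway.

Each of the 14 highway states has five perturbable components (excluding
the variable just updated on entry and the variable due to update next),
giving 70 single-flip perturbations.  Each perturbed state is relaxed
growth-free (the Start gate never opens, so every trajectory ends at the
G1 sink) under the propensity-weighted jump chain, and the recovery is
classified as normal or as one of three lethal patterns:

* ``no_bud_exit`` — the cell completes mitotic exit (divides with Cdc20
  active) although no bud ever emerged before prophase;
* ``exit_without_Clb2M`` — the cell divides out of mitosis although Clb2_M
  (spindle assembly) was never active;
* ``exit_without_Cdc20`` — the cell divides without Cdc20 ever turning on
  (no anaphase) after DNA replication had taken place.

Events executed on the highway before the perturbed state count toward the
order bookkeeping; the perturbation flip itself is not an event, although a
flipped-on variable is credited as active (Clb2_M-on flips also force
Clb2_G on, since high mitotic cyclin implies the residual level).  A
trajectory that drains back to the sink without dividing is a harmless
reset and counts as normal.

Class probabilities can be computed two ways: Monte-Carlo simulation
(:func:`run_screen`) and an exact first-step linear analysis on the flag-
augmented jump chain (:func:`exact_class_probabilities`); the two must
agree within binomial error.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import Highway, TABLE2_HIGHWAY, build_graph, find_highway
from .params import Parameters
from .rules import WILD_TYPE, RuleSet
from .state import (
    CDC20,
    CLB2G,
    CLB2M,
    CLB5,
    CLN2,
    G1_STATE,
    N_VARS,
    VARIABLES,
    bit_of,
    flip_bit,
    state_str,
)

OUTCOME_CLASSES = (
    "normal",
    "no_bud_exit",
    "exit_without_Clb2M",
    "exit_without_Cdc20",
)


@dataclass(frozen=True)
class OrderFlags:
    """Progress bookkeeping carried along a classified trajectory."""

    bud: bool = False  # Cln2 or Clb5 active/turned on
    repl: bool = False  # spontaneous/history Clb5-on or Clb2_G-on
    prophase: bool = False  # spontaneous/history Clb2_G-on
    spindle: bool = False  # Clb2_M active/turned on
    seg: bool = False  # Cdc20 activated this cycle (history/flip/event)
    bud_late: bool = False  # mitotic entry happened while bud was absent


@dataclass(frozen=True)
class Perturbation:
    """One single-variable flip applied to a highway state."""

    highway_index: int  # 0-based position in the 14-state highway
    highway_state: int
    variable: int
    direction: int  # resulting bit of the flipped variable
    start_state: int  # state after the flip (incl. Clb2_M->Clb2_G coupling)
    initial_flags: OrderFlags

    @property
    def label(self) -> str:
        onoff = "on" if self.direction else "off"
        return f"{state_str(self.highway_state)} {VARIABLES[self.variable]} turns {onoff}"


def _history_flags(highway_index: int) -> OrderFlags:
    """Flags accrued on the highway before reaching the perturbed state.

    Position k has executed the events producing states 1..k: SBF on (1),
    Cln2 on (2, bud), Cdh1 off (3), Clb5 on (4, replication), Clb2_G on
    (5, prophase), ..., Clb2_M on (8, spindle).
    """
    k = highway_index
    return OrderFlags(
        bud=k >= 2,
        repl=k >= 4,
        prophase=k >= 5,
        spindle=k >= 8,
        seg=k >= 9,
        bud_late=False,
    )


def _flip_flags(flags: OrderFlags, variable: int, direction: int) -> OrderFlags:
    """Credit a perturbation flip.

    A flipped-on Cln2/Clb5 counts as a bud, a flipped-on Clb2_M as an
    assembled spindle, a flipped-on Cdc20 as chromosome segregation.  A
    flipped-on mitotic cyclin (Clb2_G directly, or Clb2_M via its Clb2_G
    coupling) is mitotic entry: if no bud has emerged by then, any later
    bud is too late.  Flips-off change nothing (history stands).
    """
    if direction == 0:
        return flags
    if variable in (CLN2, CLB5):
        flags = replace(flags, bud=True)
    if variable == CLB2M:
        flags = replace(flags, spindle=True)
    if variable == CDC20:
        flags = replace(flags, seg=True)
    if variable in (CLB2G, CLB2M) and not flags.bud:
        flags = replace(flags, bud_late=True)
    return flags


def enumerate_perturbations(highway: Highway | None = None) -> list[Perturbation]:
    """All 70 single-state perturbations of the wild-type highway.

    For each state the excluded components are the variable updated on
    entering the state and the variable updated next.  Flipping Clb2_M on
    also sets Clb2_G on.
    """
    if highway is None:
        states = tuple(int(s, 2) for s in TABLE2_HIGHWAY)
    else:
        states = highway.states
    n = len(states)
    out: list[Perturbation] = []
    for k, s in enumerate(states):
        prev_state = states[(k - 1) % n]
        next_state = states[(k + 1) % n]
        entered_var = _changed_variable(prev_state, s)
        next_var = _changed_variable(s, next_state)
        history = _history_flags(k)
        for v in range(N_VARS):
            if v in (entered_var, next_var):
                continue
            direction = 1 - bit_of(s, v)
            start = flip_bit(s, v)
            if v == CLB2M and direction == 1 and not bit_of(start, CLB2G):
                start = flip_bit(start, CLB2G)
            out.append(
                Perturbation(
                    highway_index=k,
                    highway_state=s,
                    variable=v,
                    direction=direction,
                    start_state=start,
                    initial_flags=_flip_flags(history, v, direction),
                )
            )
    return out


def _changed_variable(a: int, b: int) -> int:
    diff = a ^ b
    var = diff.bit_length()
    if diff == 0 or diff & (diff - 1):
        raise ValueError("states are not at Hamming distance 1")
    return N_VARS - var


# -- trajectory classification --------------------------------------------


def classify(
    trace: Sequence[tuple[int, int]],
    initial_flags: OrderFlags = OrderFlags(),
    start_state: int = G1_STATE,
) -> str:
    """Classify an ordered post-perturbation event list.

    ``trace`` is a sequence of (variable, new_bit) single-flip events
    starting from ``start_state`` and ending at the G1 sink; ``initial_flags``
    carries the pre-perturbation highway history plus flip credits.
    Returns one of :data:`OUTCOME_CLASSES`.
    """
    flags = initial_flags
    state = start_state
    for var, newbit in trace:
        if bit_of(state, var) == newbit:
            raise ValueError("trace event does not flip the state")
        if var == CLB2G and newbit == 0:
            return _classify_division(state, flags)
        state = flip_bit(state, var)
        flags = _advance_flags(flags, var, newbit)
    if state != G1_STATE:
        raise ValueError("trace does not end at the G1 sink")
    return "normal"


def _advance_flags(flags: OrderFlags, var: int, newbit: int) -> OrderFlags:
    if newbit == 1:
        if var in (CLN2, CLB5):
            flags = replace(flags, bud=True)
        if var in (CLB5, CLB2G):
            flags = replace(flags, repl=True)
        if var == CLB2G:
            if not flags.bud:
                flags = replace(flags, bud_late=True)
            flags = replace(flags, prophase=True)
        if var == CLB2M:
            flags = replace(flags, spindle=True)
        if var == CDC20:
            flags = replace(flags, seg=True)
    return flags


def _classify_division(state_before: int, flags: OrderFlags) -> str:
    """Apply the lethal-pattern rules at a spontaneous Clb2_G 1->0 flip."""
    if flags.seg:
        # genuine mitotic exit (anaphase machinery was activated)
        if not flags.bud or flags.bud_late:
            return "no_bud_exit"
        if not flags.spindle:
            return "exit_without_Clb2M"
        return "normal"
    # Clb2 degraded with Cdc20 never activated: lethal only if the cell had
    # actually replicated its DNA; otherwise it is a harmless reset
    if flags.repl:
        return "exit_without_Cdc20"
    return "normal"


# -- jump-chain machinery --------------------------------------------------


def _jump_table(rules: RuleSet, params: Parameters):
    """Growth-free jump chain: per state, (cumulative probs, moves)."""
    rates = params.propensity_vector
    table = []
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
        cum = tuple(c / total for c in cum) if total else ()
        table.append((cum, moves))
    return table


def sample_trace(
    start_state: int,
    jump_table,
    rng: np.random.Generator,
    max_steps: int = 10_000,
) -> list[tuple[int, int]]:
    """One growth-free trajectory from ``start_state`` to the sink, as a
    list of (variable, new_bit) events."""
    state = start_state
    trace: list[tuple[int, int]] = []
    for _ in range(max_steps):
        cum, moves = jump_table[state]
        if not moves:
            return trace
        j = bisect_right(cum, rng.random())
        var, newbit, nxt = moves[j]
        trace.append((var, newbit))
        state = nxt
    raise RuntimeError("trajectory did not reach the sink (rule bug?)")


# -- exact first-step analysis --------------------------------------------


def exact_class_probabilities(
    perturbation: Perturbation,
    rules: RuleSet = WILD_TYPE,
    params: Parameters | None = None,
) -> dict[str, float]:
    """Exact outcome probabilities by dynamic programming on the
    flag-augmented growth-free jump chain (a DAG onto the sink)."""
    params = rules.apply_parameters(params or Parameters())
    jump = _jump_table(rules, params)
    cache: dict[tuple, np.ndarray] = {}
    class_index = {c: i for i, c in enumerate(OUTCOME_CLASSES)}

    def probs(state: int, flags: OrderFlags) -> np.ndarray:
        if state == G1_STATE:
            out = np.zeros(len(OUTCOME_CLASSES))
            out[0] = 1.0
            return out
        key = (state, flags)
        if key in cache:
            return cache[key]
        cum, moves = jump[state]
        if not moves:
            raise ValueError(
                f"absorbing state {state_str(state)} off the sink (rule bug?)"
            )
        out = np.zeros(len(OUTCOME_CLASSES))
        prev = 0.0
        for p_cum, (var, newbit, nxt) in zip(cum, moves):
            w = p_cum - prev
            prev = p_cum
            if var == CLB2G and newbit == 0:
                out[class_index[_classify_division(state, flags)]] += w
            else:
                out += w * probs(nxt, _advance_flags(flags, var, newbit))
        cache[key] = out
        return out

    vec = probs(perturbation.start_state, perturbation.initial_flags)
    return {c: float(vec[i]) for i, c in enumerate(OUTCOME_CLASSES)}


# -- Monte-Carlo screen ----------------------------------------------------


def run_screen(
    n_reps: int = 5000,
    rules: RuleSet = WILD_TYPE,
    params: Parameters | None = None,
    seed: int = 0,
    perturbations: Iterable[Perturbation] | None = None,
    with_exact: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo robustness screen.

    Simulates ``n_reps`` growth-free recovery trajectories for every
    perturbation and tabulates outcome-class fractions.  Timing rules are
    irrelevant to the (order-only) classification, so only the embedded
    jump chain is simulated.  Columns mirror the published table: state,
    variable, percent normal/abnormal, per-class percentages, and (with
    ``with_exact``) the exact oracle probabilities.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    params = rules.apply_parameters(params or Parameters())
    jump = _jump_table(rules, params)
    perts = (list(perturbations) if perturbations is not None
             else enumerate_perturbations())
    rng = np.random.default_rng(seed)
    rows = []
    for pert in perts:
        counts = dict.fromkeys(OUTCOME_CLASSES, 0)
        for _ in range(n_reps):
            trace = sample_trace(pert.start_state, jump, rng)
            counts[classify(trace, pert.initial_flags, pert.start_state)] += 1
        row = {
            "state": state_str(pert.highway_state),
            "highway_index": pert.highway_index,
            "variable": VARIABLES[pert.variable],
            "direction": "on" if pert.direction else "off",
            "n_reps": n_reps,
            "pct_normal": 100.0 * counts["normal"] / n_reps,
            "pct_abnormal": 100.0 * (n_reps - counts["normal"]) / n_reps,
        }
        for c in OUTCOME_CLASSES[1:]:
            row[f"pct_{c}"] = 100.0 * counts[c] / n_reps
        if with_exact:
            exact = exact_class_probabilities(pert, rules, params)
            row["exact_pct_normal"] = 100.0 * exact["normal"]
            for c in OUTCOME_CLASSES[1:]:
                row[f"exact_pct_{c}"] = 100.0 * exact[c]
        rows.append(row)
    return pd.DataFrame(rows)


def overall_normal_fraction(screen: pd.DataFrame) -> float:
    """Pooled fraction of simulations resuming the normal sequence."""
    return float(screen["pct_normal"].mean() / 100.0)


#: Highway states whose premature-Cdc20 flips form the S/prophase group.
PREMATURE_CDC20_STATES = ("0111000", "0111100", "0011100", "0001100")
#: Highway states whose premature-Cdh1 flips form the prophase/metaphase group.
PREMATURE_CDH1_STATES = ("0111100", "0011100", "0001100", "0001110")


def aggregate_group(
    screen: pd.DataFrame,
    states: Sequence[str],
    variable: str,
    outcome_class: str,
) -> float:
    """Pooled percentage of one aberrance class over a perturbation group
    (e.g. premature Cdc20 activation in the four S/prophase states)."""
    sel = screen[(screen["state"].isin(states))
                 & (screen["variable"] == variable)
                 & (screen["direction"] == "on")]
    if len(sel) != len(states):
        raise ValueError("screen does not contain the requested group")
    return float(sel[f"pct_{outcome_class}"].mean())
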