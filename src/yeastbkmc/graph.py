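"""Asynchronous state-transition graph and its analysis.

Nodes are the 128 Boolean states; a directed edge ``s -> s'`` exists for
every enabled single-variable update (``s'`` flips exactly that bit) and is
weighted by the variable's propensity constant.  Without the size-gated
Start edge the wild-type graph is a directed acyclic graph with one root
(1101010) and one sink (1000000); adding the Start edge (1000000 -> 1100000)
closes the globally attracting 14-state cell-cycle highway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .params import Parameters
from .rules import WILD_TYPE, RuleSet
from .state import (
    G1_STATE,
    N_STATES,
    N_VARS,
    SBF,
    START_STATE,
    VARIABLES,
    bit_of,
    flip_bit,
    state_str,
)

#: Event label (the variable change producing each highway state) keyed by
#: position in the highway; position 0 is the newborn state itself.
HIGHWAY_EVENTS = (
    "Newborn cell (G1)",
    "SBF turns on (Start)",
    "Cln2 turns on (bud emergence)",
    "Cdh1 turns off",
    "Clb5 turns on (S phase)",
    "Clb2_G turns on (prophase)",
    "SBF turns off",
    "Cln2 turns off",
    "Clb2_M turns on (metaphase)",
    "Cdc20 turns on (anaphase)",
    "Clb5 turns off",
    "Clb2_M turns off (telophase)",
    "Cdh1 turns on",
    "Clb2_G turns off (Exit)",
)


@dataclass(frozen=True)
class Highway:
    """The recurrent cell-cycle sequence: ordered states plus event labels."""

    states: tuple[int, ...]
    events: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.states)

    @property
    def state_strings(self) -> tuple[str, ...]:
        return tuple(state_str(s) for s in self.states)

    def __contains__(self, state: int) -> bool:
        return state in set(self.states)


def build_graph(
    rules: RuleSet = WILD_TYPE,
    params: Parameters | None = None,
    include_start_edge: bool = False,
) -> nx.DiGraph:
    """Build the 128-node asynchronous transition graph.

    Edge attributes: ``variable`` (name), ``var`` (index), ``rate``
    (propensity constant), ``start`` (True on the size-gated Start edge).
    """
    params = rules.apply_parameters(params or Parameters())
    rates = params.propensity_vector
    table = rules.candidate_table()
    g = nx.DiGraph()
    for s in range(N_STATES):
        g.add_node(s, label=state_str(s))
    for s in range(N_STATES):
        cand = table[s]
        for v in range(N_VARS):
            if cand[v] != bit_of(s, v):
                g.add_edge(s, flip_bit(s, v), variable=VARIABLES[v], var=v,
                           rate=rates[v], start=False)
    if include_start_edge:
        g.add_edge(G1_STATE, flip_bit(G1_STATE, SBF), variable=VARIABLES[SBF],
                   var=SBF, rate=rates[SBF], start=True)
    return g


def kahn_topological_sort(graph: nx.DiGraph) -> tuple[bool, list[int] | None]:
    """Kahn's algorithm: (acyclic?, topological order or None).

    Ties are broken by node index so the order is deterministic.
    """
    indeg = {n: d for n, d in graph.in_degree()}
    ready = sorted(n for n, d in indeg.items() if d == 0)
    order: list[int] = []
    while ready:
        n = ready.pop(0)
        order.append(n)
        inserted = False
        for m in sorted(graph.successors(n)):
            indeg[m] -= 1
            if indeg[m] == 0:
                ready.append(m)
                inserted = True
        if inserted:
            ready.sort()
    if len(order) != graph.number_of_nodes():
        return False, None
    return True, order


def is_acyclic(graph: nx.DiGraph) -> tuple[bool, list[int] | None]:
    """Alias of :func:`kahn_topological_sort` (cycle detection is a result)."""
    return kahn_topological_sort(graph)


def find_highway(graph: nx.DiGraph) -> Highway:
    """Extract the unique recurrent cycle of a graph with the Start edge.

    Raises if the attracting structure is not a single cycle through the
    newborn state (which would indicate a rule bug).
    """
    attracting = list(nx.attracting_components(graph))
    if len(attracting) != 1:
        raise ValueError(
            f"expected a single recurrent class, found {len(attracting)}"
        )
    component = attracting[0]
    if G1_STATE not in component:
        raise ValueError("recurrent class does not contain the newborn state")
    # walk the cycle from the newborn state; each recurrent state must have
    # exactly one successor inside the component
    states = [G1_STATE]
    events = [HIGHWAY_EVENTS[0]]
    current = G1_STATE
    while True:
        succ = [s for s in graph.successors(current) if s in component]
        if len(succ) != 1:
            raise ValueError(
                f"recurrent state {state_str(current)} has {len(succ)} "
                "successors in the recurrent class; not a simple cycle"
            )
        nxt = succ[0]
        if nxt == G1_STATE:
            break
        edge = graph.edges[current, nxt]
        onoff = "on" if bit_of(nxt, edge["var"]) else "off"
        pos = len(states)
        label = (HIGHWAY_EVENTS[pos] if pos < len(HIGHWAY_EVENTS)
                 else f"{edge['variable']} turns {onoff}")
        states.append(nxt)
        events.append(label)
        current = nxt
    if len(states) != len(component):
        raise ValueError("recurrent class is larger than the traced cycle")
    return Highway(states=tuple(states), events=tuple(events))


#: The published 14-state highway, for convenience and cross-checks.
TABLE2_HIGHWAY = (
    "1000000", "1100000", "1110000", "0110000", "0111000", "0111100",
    "0011100", "0001100", "0001110", "0001111", "0000111", "0000101",
    "1000101", "1000001",
)


@dataclass(frozen=True)
class HittingSteps:
    """Expected number of Boolean updates to reach the highway.

    ``expected`` maps every off-highway state to its exact expected step
    count on the propensity-weighted jump chain.  ``mean_off_highway``
    averages uniformly over all off-highway states; ``mean_big_component``
    averages over the largest weakly connected component of the off-highway
    induced subgraph (the big circular component of the state-graph layout).
    ``distribution`` is the pooled probability of hitting the highway in
    exactly k steps (uniform mixture over the corresponding averaging set).
    """

    expected: dict[int, float]
    mean_off_highway: float
    mean_big_component: float
    big_component: tuple[int, ...]
    distribution: np.ndarray
    distribution_big_component: np.ndarray


def steps_to_highway(
    graph: nx.DiGraph,
    highway: Iterable[int] | Highway | None = None,
    horizon: int = 40,
) -> HittingSteps:
    """Solve the expected hitting-step counts to the highway exactly.

    ``graph`` must be the growth-free graph (no Start edge).  One step is a
    single Boolean update; from state ``s`` the next state is chosen with
    probability proportional to the edge rate (the embedded jump chain of
    the kinetic Monte-Carlo process).  Expected counts solve the first-step
    linear equations; the step-count distribution is iterated to
    ``horizon`` steps.
    """
    if highway is None:
        highway_states = set(int(s, 2) for s in TABLE2_HIGHWAY)
    elif isinstance(highway, Highway):
        highway_states = set(highway.states)
    else:
        highway_states = set(highway)
    off = sorted(set(graph.nodes) - highway_states)
    if not off:
        raise ValueError("no off-highway states")
    pos = {s: i for i, s in enumerate(off)}
    n = len(off)
    q = np.zeros((n, n))  # off -> off jump probabilities
    for s in off:
        out = list(graph.out_edges(s, data="rate"))
        if not out:
            raise ValueError(
                f"state {state_str(s)} cannot reach the highway (no exits)"
            )
        total = sum(r for _, _, r in out)
        for _, t, r in out:
            if t in pos:
                q[pos[s], pos[t]] += r / total
    a = np.eye(n) - q
    try:
        h = np.linalg.solve(a, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "some state cannot reach the highway (singular system)"
        ) from exc
    if not np.all(np.isfinite(h)):
        raise ValueError("some state cannot reach the highway")
    expected = {s: float(h[pos[s]]) for s in off}

    sub = graph.subgraph(off)
    big = max(nx.weakly_connected_components(sub), key=len)
    big = tuple(sorted(big))

    # exact step-count distribution: mass remaining off-highway after k steps
    def _distribution(start_states: Sequence_like) -> np.ndarray:
        p = np.zeros(n)
        for s in start_states:
            p[pos[s]] += 1.0 / len(start_states)
        probs = []
        for _ in range(horizon):
            p_next = p @ q
            probs.append(p.sum() - p_next.sum())  # absorbed at this step
            p = p_next
        return np.array(probs)

    dist_all = _distribution(off)
    dist_big = _distribution(big)
    return HittingSteps(
        expected=expected,
        mean_off_highway=float(np.mean(h)),
        mean_big_component=float(np.mean([expected[s] for s in big])),
        big_component=big,
        distribution=dist_all,
        distribution_big_component=dist_big,
    )


Sequence_like = Iterable  # narrow alias used above


def export_graph(graph: nx.DiGraph, path: str, fmt: str = "csv") -> None:
    """Write the graph deterministically as ``csv``, ``dot`` or ``json``."""
    edges = sorted(
        (state_str(u), state_str(v), d["variable"], d["rate"], bool(d.get("start")))
        for u, v, d in graph.edges(data=True)
    )
    if fmt == "csv":
        lines = ["from_state,to_state,variable,rate,start"]
        lines += [f"{u},{v},{var},{rate:g},{int(start)}"
                  for u, v, var, rate, start in edges]
        text = "\n".join(lines) + "\n"
    elif fmt == "dot":
        lines = ["digraph cell_cycle {"]
        for s in sorted(graph.nodes):
            lines.append(f'  "{state_str(s)}";')
        for u, v, var, rate, start in edges:
            style = ", style=dashed" if start else ""
            lines.append(f'  "{u}" -> "{v}" [label="{var}", weight={rate:g}{style}];')
        lines.append("}")
        text = "\n".join(lines) + "\n"
    elif fmt == "json":
        text = json.dumps(
            {
                "nodes": [state_str(s) for s in sorted(graph.nodes)],
                "edges": [
                    {"from": u, "to": v, "variable": var, "rate": rate,
                     "start": start}
                    for u, v, var, rate, start in edges
                ],
            },
            indent=2,
        ) + "\n"
    else:
        raise ValueError(f"unknown export format {fmt!r}; use csv, dot or json")
    with open(path, "w") as fh:
        fh.write(text)


def graph_report(rules: RuleSet = WILD_TYPE, params: Parameters | None = None) -> dict:
    """Structural summary used by the CLI: counts, roots/sinks, highway,
    acyclicity, and hitting-step statistics."""
    g0 = build_graph(rules, params, include_start_edge=False)
    g1 = build_graph(rules, params, include_start_edge=True)
    acyclic, order = kahn_topological_sort(g0)
    highway = find_highway(g1)
    hitting = steps_to_highway(g0, highway)
    return {
        "n_nodes": g0.number_of_nodes(),
        "n_edges": g0.number_of_edges(),
        "acyclic_without_start_edge": acyclic,
        "roots": [state_str(n) for n, d in g0.in_degree() if d == 0],
        "sinks": [state_str(n) for n, d in g0.out_degree() if d == 0],
        "highway": list(highway.state_strings),
        "highway_events": list(highway.events),
        "mean_steps_off_highway": hitting.mean_off_highway,
        "mean_steps_big_component": hitting.mean_big_component,
        "big_component_size": len(hitting.big_component),
    }
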