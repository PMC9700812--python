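"""Boolean target functions, propensities and mutant rule sets.

The seven regulators update asynchronously.  For each variable the *target*
(candidate) activity ``B*_i`` is a logical function of the current state:

* ``Cdh1* = ~(Cln2|Clb5|Clb2_G|Clb2_M) | (Cdc20 & ~(Cln2|Clb5|Clb2_M))``
* ``SBF*  = start_gate | (SBF & ~(Clb2_G|Clb2_M))`` where the Start gate can
  open only in the newborn state 1000000 once Size exceeds the cell's
  critical size S0 (probability ``min(1, (Size-S0)^2)`` per evaluation)
* ``Cln2* = SBF``
* ``Clb5* = (Clb5|SBF) & ~(Cdh1|Cdc20)``
* ``Clb2_G* = Clb2_M | ((Clb5|Clb2_G) & ~Cdh1)``
* ``Clb2_M* = (Clb2_G|Clb2_M) & ~Cdh1 & (~Cdc20|Clb5) & ~Cln2``
* ``Cdc20* = Clb2_M | (Clb2_G & Cdc20)``

A variable with ``B*_i != B_i`` is *enabled* and carries propensity
``P_i = p_i``; the total ``P0 = sum(P_i)`` drives the Gillespie update.

Mutant strains are expressed as rule-set overrides: a mutant replaces only
the named target functions and/or parameters and inherits everything else
from wild type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._expr import BitFunction, compile_expression
from .params import Parameters
from .state import (
    CLB2G,
    G1_STATE,
    N_STATES,
    N_VARS,
    SBF,
    VARIABLES,
    BooleanState,
    bit_of,
    state_index,
)

#: Wild-type target functions.  The SBF entry is only the self-maintenance
#: disjunct; the size-gated Start disjunct is handled by ``candidate_state``.
WILD_TYPE_EXPRESSIONS: dict[str, str] = {
    "Cdh1": "~(Cln2 | Clb5 | Clb2_G | Clb2_M) | (Cdc20 & ~(Cln2 | Clb5 | Clb2_M))",
    "SBF": "SBF & ~(Clb2_G | Clb2_M)",
    "Cln2": "SBF",
    "Clb5": "(Clb5 | SBF) & ~(Cdh1 | Cdc20)",
    "Clb2_G": "Clb2_M | ((Clb5 | Clb2_G) & ~Cdh1)",
    "Clb2_M": "(Clb2_G | Clb2_M) & ~Cdh1 & (~Cdc20 | Clb5) & ~Cln2",
    "Cdc20": "Clb2_M | (Clb2_G & Cdc20)",
}

MUTANT_LABELS = ("wild-type", "clns-clb2", "met3pr-cln2-clb2", "dcln3")


@dataclass(frozen=True)
class RuleSet:
    """A labelled set of Boolean target functions plus parameter overrides.

    ``expressions`` maps every variable name to its target expression (the
    SBF expression excludes the Start gate).  ``parameter_overrides`` are
    applied on top of caller-supplied :class:`Parameters`.
    """

    label: str = "wild-type"
    expressions: Mapping[str, str] = field(
        default_factory=lambda: dict(WILD_TYPE_EXPRESSIONS)
    )
    parameter_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(VARIABLES) - set(self.expressions)
        extra = set(self.expressions) - set(VARIABLES)
        if missing or extra:
            raise ValueError(
                f"rule set must define exactly the seven variables; "
                f"missing={sorted(missing)} unknown={sorted(extra)}"
            )
        # compile eagerly so malformed expressions fail at construction
        object.__setattr__(self, "_functions", tuple(
            compile_expression(self.expressions[name]) for name in VARIABLES
        ))

    @property
    def functions(self) -> tuple[BitFunction, ...]:
        return self._functions  # type: ignore[attr-defined]

    def override(
        self,
        label: str,
        rules: Mapping[str, str] | None = None,
        parameters: Mapping[str, float] | None = None,
    ) -> "RuleSet":
        """Derive a new rule set changing only the named rules/parameters."""
        expressions = dict(self.expressions)
        for name, expr in (rules or {}).items():
            if name not in VARIABLES:
                raise ValueError(f"unknown variable {name!r} in rule override")
            expressions[name] = expr
        overrides = dict(self.parameter_overrides)
        overrides.update(parameters or {})
        return RuleSet(label=label, expressions=expressions,
                       parameter_overrides=overrides)

    def apply_parameters(self, params: Parameters) -> Parameters:
        """Parameters with this rule set's overrides applied."""
        if not self.parameter_overrides:
            return params
        return params.replace(**dict(self.parameter_overrides))

    def candidate_table(self) -> list[tuple[int, ...]]:
        """Gate-closed candidate vectors ``B*`` for all 128 states.

        Row ``s`` is the 7-bit candidate vector for integer state ``s`` with
        the Start gate closed; only the SBF entry of state 1000000 can ever
        differ when the gate is open.
        """
        table = []
        for s in range(N_STATES):
            bits = tuple(bit_of(s, v) for v in range(N_VARS))
            table.append(tuple(f(bits) for f in self.functions))
        return table


WILD_TYPE = RuleSet()


def sbf_gate_open(size: float, s0: float, r0: float) -> bool:
    """Outcome of the size-gated Start trial.

    True iff ``size > s0`` and ``r0 < min(1, (size - s0)**2)`` — SBF can be
    activated only above the critical size, with probability growing as the
    square of the excess (capped at 1).
    """
    if size <= s0:
        return False
    return r0 < min(1.0, (size - s0) ** 2)


def candidate_state(
    state: BooleanState | str | int,
    rules: RuleSet = WILD_TYPE,
    sbf_gate: bool = False,
) -> BooleanState:
    """Candidate vector ``B*`` for one state.

    ``sbf_gate`` is the externally evaluated outcome of the size-gate trial;
    it contributes to SBF only in the newborn state 1000000.
    """
    idx = state_index(state)
    bits = tuple(bit_of(idx, v) for v in range(N_VARS))
    cand = [f(bits) for f in rules.functions]
    if sbf_gate and idx == G1_STATE:
        cand[SBF] = 1
    return BooleanState(*cand)


def propensities(
    state: BooleanState | str | int,
    candidates: BooleanState | Sequence[int],
    params: Parameters,
) -> tuple[tuple[float, ...], float]:
    """Per-variable switching propensities ``P_i = p_i * |B*_i - B_i|``.

    Returns the 7-vector and its sum ``P0``.
    """
    idx = state_index(state)
    rates = params.propensity_vector
    vec = tuple(
        rates[v] if candidates[v] != bit_of(idx, v) else 0.0
        for v in range(N_VARS)
    )
    return vec, sum(vec)


#: Published mutant strains, as overrides on wild type.
_MUTANT_DEFS: dict[str, tuple[dict[str, str], dict[str, float]]] = {
    # single-B-type-cyclin strain: no Clb5/6; CLB2 additionally expressed
    # from the CLB5 promoter, so SBF can switch Clb2_G on directly
    "clns-clb2": (
        {
            "Clb5": "0",
            "Clb2_G": "Clb2_M | ((Clb5 | Clb2_G) & ~Cdh1) | SBF",
        },
        {},
    ),
    # same strain additionally lacking Cln1/3 with MET3pr-CLN2 repressed by
    # methionine: Cln2 permanently off, and (because cln3 is deleted) the
    # Start size threshold doubles
    "met3pr-cln2-clb2": (
        {
            "Clb5": "0",
            "Clb2_G": "Clb2_M | ((Clb5 | Clb2_G) & ~Cdh1) | SBF",
            "Cln2": "0",
        },
        {"S0_mean": 0.8},
    ),
}

#: Default Start threshold for the cln3-deletion strain (~70% above wild type).
DCLN3_S0_MEAN = 0.68


def mutant_ruleset(label: str, dcln3_s0_mean: float = DCLN3_S0_MEAN) -> RuleSet:
    """Return the rule set for a published strain label.

    Labels: ``wild-type``, ``clns-clb2``, ``met3pr-cln2-clb2``, ``dcln3``.
    ``dcln3`` keeps wild-type logic but raises S0_mean (cells ~70% larger by
    default; configurable via ``dcln3_s0_mean``).
    """
    if label == "wild-type":
        return WILD_TYPE
    if label == "dcln3":
        return WILD_TYPE.override("dcln3", parameters={"S0_mean": dcln3_s0_mean})
    try:
        rule_over, param_over = _MUTANT_DEFS[label]
    except KeyError:
        raise ValueError(
            f"unknown rule-set label {label!r}; choose from {MUTANT_LABELS}"
        ) from None
    return WILD_TYPE.override(label, rules=rule_over, parameters=param_over)


def ruleset_from_config(spec: Mapping | str) -> RuleSet:
    """Build a rule set from a declarative config block.

    ``spec`` is either a strain label or a mapping with optional keys
    ``base`` (label, default wild-type), ``label``, ``rules`` (expression
    overrides) and ``parameters`` (parameter overrides).
    """
    if isinstance(spec, str):
        return mutant_ruleset(spec)
    unknown = set(spec) - {"base", "label", "rules", "parameters"}
    if unknown:
        raise ValueError(f"unknown rule-set config key(s): {sorted(unknown)}")
    base = mutant_ruleset(spec.get("base", "wild-type"))
    return base.override(
        label=spec.get("label", f"{base.label}+custom"),
        rules=spec.get("rules"),
        parameters=spec.get("parameters"),
    )
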