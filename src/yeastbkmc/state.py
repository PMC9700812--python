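"""Boolean cell-cycle states.

The state of the control network is a septuplet of Boolean activities in the
fixed order (Cdh1, SBF, Cln2, Clb5, Clb2_G, Clb2_M, Cdc20).  States are
written as 7-digit binary strings, e.g. ``"1000000"`` for a newborn G1 cell,
and are internally indexed as integers 0..127 with Cdh1 as the most
significant bit.
"""

from __future__ import annotations

from typing import Iterator, NamedTuple

#: Variable names in the canonical (printed-string) order.
VARIABLES: tuple[str, ...] = (
    "Cdh1",
    "SBF",
    "Cln2",
    "Clb5",
    "Clb2_G",
    "Clb2_M",
    "Cdc20",
)

N_VARS = len(VARIABLES)
N_STATES = 2 ** N_VARS

#: index of each variable in VARIABLES
VAR_INDEX: dict[str, int] = {name: i for i, name in enumerate(VARIABLES)}

CDH1, SBF, CLN2, CLB5, CLB2G, CLB2M, CDC20 = range(N_VARS)


def bit_of(index: int, var: int) -> int:
    """Activity of variable ``var`` (0..6) in integer state ``index``."""
    return (index >> (N_VARS - 1 - var)) & 1


def flip_bit(index: int, var: int) -> int:
    """State obtained by flipping variable ``var`` in state ``index``."""
    return index ^ (1 << (N_VARS - 1 - var))


class BooleanState(NamedTuple):
    """One of the 128 Boolean network states.

    Fields follow the canonical order, so ``str(state)`` round-trips with
    :meth:`from_string`.
    """

    cdh1: int
    sbf: int
    cln2: int
    clb5: int
    clb2g: int
    clb2m: int
    cdc20: int

    @classmethod
    def from_string(cls, s: str) -> "BooleanState":
        if len(s) != N_VARS or set(s) - {"0", "1"}:
            raise ValueError(f"state string must be 7 binary digits, got {s!r}")
        return cls(*(int(c) for c in s))

    @classmethod
    def from_index(cls, index: int) -> "BooleanState":
        if not 0 <= index < N_STATES:
            raise ValueError(f"state index out of range: {index}")
        return cls(*(bit_of(index, v) for v in range(N_VARS)))

    @property
    def index(self) -> int:
        out = 0
        for b in self:
            out = (out << 1) | b
        return out

    def __str__(self) -> str:
        return "".join(str(b) for b in self)

    def flipped(self, var: int | str) -> "BooleanState":
        """Return the state with a single variable flipped."""
        if isinstance(var, str):
            var = VAR_INDEX[var]
        return BooleanState.from_index(flip_bit(self.index, var))


def all_states() -> Iterator[BooleanState]:
    """Enumerate all 128 states in increasing index order."""
    for i in range(N_STATES):
        yield BooleanState.from_index(i)


def state_str(index: int) -> str:
    """7-digit string for an integer state index."""
    return format(index, f"0{N_VARS}b")


def state_index(s: str | BooleanState | int) -> int:
    """Coerce a state given as string, BooleanState, or int to its index."""
    if isinstance(s, int):
        if not 0 <= s < N_STATES:
            raise ValueError(f"state index out of range: {s}")
        return s
    if isinstance(s, BooleanState):
        return s.index
    return BooleanState.from_string(s).index


#: Newborn/early-G1 sink state 1000000.
G1_STATE = state_index("1000000")
#: Late-G1 state 1100000 entered at Start.
START_STATE = state_index("1100000")
#: Post-division state 1000001 (mitotic exit).
EXIT_STATE = state_index("1000001")
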