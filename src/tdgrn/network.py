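"""Step 3: edge decisions and network assembly.

An ordered pair becomes a predicted-present edge iff its influence strictly
exceeds the threshold epsilon (default 0.96); influence equal to epsilon is
a predicted-absent edge.  Because Step 2 forwards a single ordering per
unordered pair, the assembled network never contains reciprocal edges.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import Network
from .exceptions import ValidationError
from .influence import InfluenceRecord

DEFAULT_EPSILON = 0.96


@dataclass(frozen=True)
class EdgeDecision:
    source: str
    target: str
    influence: float
    present: bool
    epsilon: float

    def __post_init__(self):
        if self.present != (self.influence > self.epsilon):
            raise ValidationError("present must hold iff influence > epsilon")


def decide_edge(record: InfluenceRecord, epsilon: float = DEFAULT_EPSILON) -> EdgeDecision:
    """Strict threshold rule: present iff influence > epsilon."""
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    return EdgeDecision(
        record.source,
        record.target,
        record.influence,
        record.influence > epsilon,
        epsilon,
    )


def assemble_network(decisions, universe, params=None) -> Network:
    """Collect the present decisions into a Network over ``universe``.

    At most one decision per ordered pair is allowed; edge ordering in the
    result is deterministic (natural order on regulator, then target).
    """
    seen = set()
    edges = []
    for d in decisions:
        if (d.source, d.target) in seen:
            raise ValidationError(f"duplicate decision for {d.source}->{d.target}")
        seen.add((d.source, d.target))
        if d.present:
            edges.append((d.source, d.target, d.influence))
    return Network(tuple(edges), frozenset(universe), params or {})
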