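"""Consensus networks across conditions (cell types / experiments).

Edges supported by at least ``min_conditions`` condition-specific networks
are kept, annotated with their support count and the consistency of the
partial-correlation sign across supporting conditions. Sign conflicts are
kept and flagged rather than resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from spcn.data_io import Network
from spcn.sparsify import SPCN

logger = logging.getLogger(__name__)

SIGN_POS = "+"
SIGN_NEG = "-"
SIGN_CONFLICT = "conflict"


@dataclass
class ConsensusEdge:
    pair: tuple[str, str]
    support_count: int
    sign: str
    weights: list[float | None]  # one slot per condition, None where absent


@dataclass
class ConsensusNetwork:
    variables: list[str]
    edges: list[ConsensusEdge]
    n_conditions: int
    min_conditions: int

    def edge(self, a: str, b: str) -> ConsensusEdge | None:
        key = tuple(sorted((a, b)))
        for e in self.edges:
            if e.pair == key:
                return e
        return None

    def to_network(self) -> Network:
        net = Network(variables=list(self.variables), edges={})
        for e in self.edges:
            mean_w = sum(w for w in e.weights if w is not None) / e.support_count
            net.add_edge(
                *e.pair,
                weight=mean_w,
                support_count=e.support_count,
                provenance=f"sign={e.sign}",
            )
        return net


def _as_network(obj: Network | SPCN) -> Network:
    return obj.to_network() if isinstance(obj, SPCN) else obj


def consensus_network(
    networks: list[Network | SPCN], min_conditions: int = 2
) -> ConsensusNetwork:
    """Keep edges present in at least ``min_conditions`` of the networks.

    Variable universes are intersected first (dropped variables are logged);
    edges touching a dropped variable are ignored. The edge sign is ``+`` or
    ``-`` when all supporting conditions agree and ``conflict`` otherwise.
    """
    nets = [_as_network(n) for n in networks]
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    if min_conditions < 1:
        raise ValueError("min_conditions must be positive")
    shared = set(nets[0].variables)
    for net in nets[1:]:
        shared &= set(net.variables)
    dropped = set().union(*(net.variables for net in nets)) - shared
    if dropped:
        logger.info("dropping %d variables absent from some networks: %s",
                    len(dropped), sorted(dropped))
    variables = sorted(shared)

    weights_by_pair: dict[tuple[str, str], list[float | None]] = {}
    for ci, net in enumerate(nets):
        for pair, attrs in net.edges.items():
            if pair[0] not in shared or pair[1] not in shared:
                continue
            slots = weights_by_pair.setdefault(pair, [None] * len(nets))
            slots[ci] = float(attrs.get("weight", 0.0))

    edges = []
    for pair in sorted(weights_by_pair):
        slots = weights_by_pair[pair]
        present = [w for w in slots if w is not None]
        if len(present) < min_conditions:
            continue
        if all(w > 0 for w in present):
            sign = SIGN_POS
        elif all(w < 0 for w in present):
            sign = SIGN_NEG
        else:
            sign = SIGN_CONFLICT
        edges.append(ConsensusEdge(pair, len(present), sign, slots))
    return ConsensusNetwork(variables, edges, len(nets), min_conditions)
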