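"""Per-practice network construction, symmetrization and inclusion filtering.

Each practice yields three directed nomination networks (DM, CHD, CHF) whose
nodes are all practice members — respondents and non-respondents alike — and
whose ties are the respondents' weekly information-exchange nominations.
Because the roster is the node universe, a single non-respondent still appears
in the network and can receive nominations; union symmetrization then
reconstructs their undirected edges from those incoming nominations.

The analysis protocol is gated: undirected networks are only warranted when
the cohort-wide reciprocity of respondent-to-respondent ties exceeds a
threshold (0.6 by default), i.e. when reported exchanges are predominantly
mutual. Practices enter the network analysis only if they have at least three
members and at most one non-respondent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import networkx as nx

from .roster import Cohort, Condition, PracticeRoster, Role

__all__ = [
    "NetworkNode",
    "DirectedTieNetwork",
    "UndirectedNetwork",
    "InclusionReason",
    "InclusionDecision",
    "build_directed_network",
    "symmetrize",
    "symmetrize_union",
    "reciprocity_gate",
    "UndefinedReciprocityError",
    "apply_inclusion_filter",
    "to_networkx",
    "write_graphml",
]

#: Default reciprocity threshold above which undirected networks are warranted.
DEFAULT_GATE_THRESHOLD = 0.6


@dataclass(frozen=True)
class NetworkNode:
    member_id: str
    role: Role
    responded: bool


@dataclass(frozen=True)
class DirectedTieNetwork:
    """Directed nomination network of one practice for one condition."""

    practice_id: str
    condition: Condition
    nodes: tuple[NetworkNode, ...]
    ties: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = {n.member_id for n in self.nodes}
        responded = {n.member_id for n in self.nodes if n.responded}
        for s, t in self.ties:
            if s == t:
                raise ValueError(f"self-loop {s!r} in {self.practice_id}/{self.condition.value}")
            if s not in ids or t not in ids:
                raise ValueError(
                    f"tie endpoint outside node set in {self.practice_id}/{self.condition.value}"
                )
            if s not in responded:
                raise ValueError(
                    f"non-respondent {s!r} cannot send nominations "
                    f"({self.practice_id}/{self.condition.value})"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(n.member_id for n in self.nodes)


@dataclass(frozen=True)
class UndirectedNetwork:
    """Symmetrized (undirected) network; edges are sorted pairs (a, b), a < b."""

    practice_id: str
    condition: Condition
    nodes: tuple[NetworkNode, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = {n.member_id for n in self.nodes}
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge {a!r} in {self.practice_id}/{self.condition.value}")
            if a > b:
                raise ValueError("undirected edges must be stored as sorted pairs")
            if a not in ids or b not in ids:
                raise ValueError("edge endpoint outside node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(n.member_id for n in self.nodes)

    def degrees(self) -> dict[str, int]:
        deg = {n.member_id: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


class InclusionReason(str, Enum):
    OK = "ok"
    TOO_FEW_MEMBERS = "too_few_members"
    TOO_MANY_MISSING = "too_many_missing"


@dataclass(frozen=True)
class InclusionDecision:
    practice_id: str
    included: bool
    reason: InclusionReason
    n_members: int
    n_nonrespondents: int


class UndefinedReciprocityError(ValueError):
    """Reciprocity gate evaluated on a cohort with no assessable ties."""


def build_directed_network(roster: PracticeRoster, condition: Condition) -> DirectedTieNetwork:
    """Directed network for one practice and condition.

    Nodes are all practice members; a tie s->t exists iff respondent s
    nominated t for this condition. Non-respondents appear as potential tie
    targets only.
    """
    nodes = tuple(NetworkNode(m.member_id, m.role, m.responded) for m in roster.members)
    ties = frozenset(
        (m.member_id, target)
        for m in roster.members
        if m.responded
        for target in m.nominations[condition]
    )
    return DirectedTieNetwork(roster.practice_id, condition, nodes, ties)


def symmetrize(net: DirectedTieNetwork, rule: str = "union") -> UndirectedNetwork:
    """Convert a directed nomination network to an undirected one.

    ``rule="union"`` (the default, used for the main analysis) places an edge
    wherever at least one direction was reported; this doubles as the
    reconstruction of a single non-respondent's ties from incoming
    nominations. ``rule="intersection"`` keeps only mutual dyads and is
    offered for sensitivity analysis (it discards every tie involving a
    non-respondent, who cannot reciprocate by design).
    """
    if rule == "union":
        edges = frozenset(tuple(sorted((s, t))) for s, t in net.ties)
    elif rule == "intersection":
        edges = frozenset(
            tuple(sorted((s, t))) for s, t in net.ties if (t, s) in net.ties
        )
    else:
        raise ValueError(f"unknown symmetrization rule {rule!r}")
    return UndirectedNetwork(net.practice_id, net.condition, net.nodes, edges)


def symmetrize_union(net: DirectedTieNetwork) -> UndirectedNetwork:
    return symmetrize(net, rule="union")


def reciprocity_gate(
    cohort_reciprocity: float | None, threshold: float = DEFAULT_GATE_THRESHOLD
) -> bool:
    """Decide whether pooled reciprocity warrants undirected networks.

    Strict inequality: the pipeline proceeds only when reciprocity is
    *above* the threshold. An undefined reciprocity (no assessable ties in
    the whole cohort) is an error, never a silent pass.
    """
    if cohort_reciprocity is None:
        raise UndefinedReciprocityError(
            "cohort reciprocity is undefined (no assessable directed ties)"
        )
    if not 0.0 <= cohort_reciprocity <= 1.0:
        raise ValueError(f"reciprocity must be in [0, 1], got {cohort_reciprocity}")
    return cohort_reciprocity > threshold


def apply_inclusion_filter(cohort: Cohort) -> list[InclusionDecision]:
    """One inclusion decision per practice.

    A practice enters the network analysis iff it has at least three members
    and at most one non-respondent. Size is checked first: a too-small
    practice is reported as ``too_few_members`` even if it also has too many
    non-respondents.
    """
    decisions = []
    for p in cohort.practices:
        if p.n_members < 3:
            reason = InclusionReason.TOO_FEW_MEMBERS
        elif p.n_nonrespondents > 1:
            reason = InclusionReason.TOO_MANY_MISSING
        else:
            reason = InclusionReason.OK
        decisions.append(
            InclusionDecision(
                practice_id=p.practice_id,
                included=reason is InclusionReason.OK,
                reason=reason,
                n_members=p.n_members,
                n_nonrespondents=p.n_nonrespondents,
            )
        )
    return decisions


def to_networkx(net: DirectedTieNetwork | UndirectedNetwork) -> nx.Graph:
    """Export to a networkx graph with role/responded node attributes."""
    g: nx.Graph
    if isinstance(net, DirectedTieNetwork):
        g = nx.DiGraph()
        links = net.ties
    else:
        g = nx.Graph()
        links = net.edges
    g.graph["practice_id"] = net.practice_id
    g.graph["condition"] = net.condition.value
    for node in net.nodes:
        g.add_node(node.member_id, role=node.role.value, responded=node.responded)
    g.add_edges_from(links)
    return g


def write_graphml(net: DirectedTieNetwork | UndirectedNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(net), path)
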