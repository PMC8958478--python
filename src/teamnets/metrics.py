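"""Native implementations of the four network properties.

*Number of connections* — the count of undirected edges.
*Density* — existing connections divided by possible connections,
``|E| / (n(n-1)/2)``.
*Degree centralization* (Freeman) — how strongly the network is centred on a
single person: ``sum_i(d_max - d_i) / ((n-1)(n-2))``; 0 when all degrees are
equal (in particular for a complete network), 1 for a star.
*Reciprocity* — the fraction of directed ties that are returned. Only ties
between two respondents are assessable: a non-respondent cannot return a
nomination by design, so ties pointing at non-respondents are excluded from
both numerator and denominator rather than counted as unreciprocated.

Metrics on degenerate networks (density on n < 2, centralization on n < 3)
raise :class:`UndefinedMetricError` instead of returning silent zeros, so
excluded practices cannot leak into summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .builder import DirectedTieNetwork, UndirectedNetwork
from .roster import Condition

__all__ = [
    "NetworkMetrics",
    "UndefinedMetricError",
    "density",
    "degree_centralization",
    "reciprocity",
    "pooled_reciprocity",
    "metrics_bundle",
]


class UndefinedMetricError(ValueError):
    """A network metric is undefined for this network (degenerate size)."""


@dataclass(frozen=True)
class NetworkMetrics:
    """All four network properties of one practice for one condition."""

    practice_id: str
    condition: Condition
    n_nodes: int
    n_edges: int
    density: float
    centralization: float
    reciprocity: Optional[float]  # None when the directed network has no assessable ties


def density(net: UndirectedNetwork) -> float:
    """Existing / possible connections: ``|E| / (n(n-1)/2)``."""
    n = net.n_nodes
    if n < 2:
        raise UndefinedMetricError(
            f"density undefined for n={n} ({net.practice_id}/{net.condition.value})"
        )
    return net.n_edges / (n * (n - 1) / 2)


def degree_centralization(net: UndirectedNetwork) -> float:
    """Freeman degree centralization ``sum_i(d_max - d_i) / ((n-1)(n-2))``.

    The denominator is the maximum attainable sum of degree differences,
    achieved by a star; hence the index is 0 for any regular network
    (complete or empty) and exactly 1 for a star.
    """
    n = net.n_nodes
    if n < 3:
        raise UndefinedMetricError(
            f"centralization undefined for n={n} ({net.practice_id}/{net.condition.value})"
        )
    degs = list(net.degrees().values())
    d_max = max(degs)
    return sum(d_max - d for d in degs) / ((n - 1) * (n - 2))


def _assessable(net: DirectedTieNetwork) -> list[tuple[str, str]]:
    responded = {node.member_id for node in net.nodes if node.responded}
    return [(s, t) for s, t in net.ties if s in responded and t in responded]


def reciprocity(net: DirectedTieNetwork) -> Optional[float]:
    """Fraction of assessable directed ties whose reverse tie also exists.

    Assessable means both endpoints responded; returns None (undefined) when
    there are no assessable ties.
    """
    assessable = _assessable(net)
    if not assessable:
        return None
    returned = sum((t, s) in net.ties for s, t in assessable)
    return returned / len(assessable)


def pooled_reciprocity(nets: Iterable[DirectedTieNetwork]) -> Optional[float]:
    """Reciprocity pooled over many directed networks.

    Numerator and denominator are summed across networks (all practices and
    conditions), giving the overall reciprocity used by the gate. None when
    no network contributes an assessable tie.
    """
    returned = total = 0
    for net in nets:
        assessable = _assessable(net)
        total += len(assessable)
        returned += sum((t, s) in net.ties for s, t in assessable)
    if total == 0:
        return None
    return returned / total


def metrics_bundle(
    directed: DirectedTieNetwork, undirected: UndirectedNetwork
) -> NetworkMetrics:
    """Assemble all four properties for one practice/condition pair."""
    if (directed.practice_id, directed.condition) != (
        undirected.practice_id,
        undirected.condition,
    ):
        raise ValueError(
            "directed and undirected networks must describe the same practice and condition"
        )
    if directed.node_ids != undirected.node_ids:
        raise ValueError("directed and undirected networks must share a node set")
    try:
        dens = density(undirected)
        cent = degree_centralization(undirected)
    except UndefinedMetricError as exc:
        raise UndefinedMetricError(
            f"metrics undefined for practice {directed.practice_id!r} "
            f"condition {directed.condition.value}: {exc}"
        ) from exc
    return NetworkMetrics(
        practice_id=directed.practice_id,
        condition=directed.condition,
        n_nodes=undirected.n_nodes,
        n_edges=undirected.n_edges,
        density=dens,
        centralization=cent,
        reciprocity=reciprocity(directed),
    )
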