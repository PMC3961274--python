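"""Regulatory motif detection in heterogeneous miRNA/gene networks.

The motifs of interest are the ones a mixed transcriptional (TF -> miRNA)
and post-transcriptional (miRNA -> gene) network supports:

* **self-adaption feedback loops** -- 2-node cycles in which a gene
  transcriptionally activates a miRNA that in turn represses the gene
  (e.g., PTEN and hsa-miR-21), a homeostatic balance motif;
* longer directed cycles, bounded to keep enumeration tractable;
* **ordered control chains** -- simple directed paths whose edges carry
  regulatory semantics (hosts edges, a co-location rather than a control
  relation, are excluded by default);
* **hubs** -- high-total-degree factors;
* **upstream influence** -- all factors with a directed path into a query
  set, categorized by the role through which they act (host gene, TF,
  miRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import ContractError, EdgeKind, NodeRef, RegulatoryNetwork

__all__ = [
    "FeedbackLoop",
    "InfluenceReport",
    "find_two_node_feedback_loops",
    "find_cycles_upto",
    "upstream_influence",
    "regulatory_chains",
    "rank_hubs",
]

#: combinatorial guard on cycle length; override via ``max_len_cap``
DEFAULT_MAX_CYCLE_LEN = 4

# deterministic kind choice when parallel edges join the same ordered pair
_KIND_PREFERENCE = (EdgeKind.REGULATES, EdgeKind.TARGETS, EdgeKind.HOSTS)


@dataclass(frozen=True)
class FeedbackLoop:
    """A directed cycle, canonically rotated.

    ``members[i]`` is linked to ``members[(i+1) % len]`` by ``kinds[i]``;
    the closing edge is included. The rotation starts at the
    lexicographically smallest member name; direction is preserved.
    """

    members: tuple[NodeRef, ...]
    kinds: tuple[EdgeKind, ...]

    @property
    def length(self) -> int:
        return len(self.members)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.members)


@dataclass
class InfluenceReport:
    """Upstream factors of a query set, categorized by acting role."""

    targets: set[str]
    hosts: set[str] = field(default_factory=set)
    tfs: set[str] = field(default_factory=set)
    mirnas: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "targets": sorted(self.targets),
            "hosts": sorted(self.hosts),
            "tfs": sorted(self.tfs),
            "mirnas": sorted(self.mirnas),
        }


# ---------------------------------------------------------------------------
# Cycle detection
# ---------------------------------------------------------------------------

def _edge_kind(net: RegulatoryNetwork, u: str, v: str,
               include_hosts: bool) -> EdgeKind:
    kinds = {EdgeKind(k) for k in net.graph[u][v]}
    if not include_hosts:
        kinds.discard(EdgeKind.HOSTS)
    for kind in _KIND_PREFERENCE:
        if kind in kinds:
            return kind
    raise KeyError((u, v))


def _canonical_loop(net: RegulatoryNetwork, cycle: list[str],
                    include_hosts: bool) -> FeedbackLoop:
    pivot = min(range(len(cycle)), key=lambda i: cycle[i])
    rotated = cycle[pivot:] + cycle[:pivot]
    members = tuple(net.node_ref(n) for n in rotated)
    kinds = tuple(
        _edge_kind(net, rotated[i], rotated[(i + 1) % len(rotated)], include_hosts)
        for i in range(len(rotated))
    )
    return FeedbackLoop(members, kinds)


def _motif_graph(net: RegulatoryNetwork, include_hosts: bool) -> nx.MultiDiGraph:
    if include_hosts:
        return net.graph
    sub = nx.MultiDiGraph()
    sub.add_nodes_from(net.graph.nodes(data=True))
    for u, v, k, data in net.graph.edges(keys=True, data=True):
        if k != EdgeKind.HOSTS.value:
            sub.add_edge(u, v, key=k, **data)
    return sub


def find_two_node_feedback_loops(net: RegulatoryNetwork) -> list[FeedbackLoop]:
    """Every self-adaption pair: gene G regulates miRNA M, M targets G."""
    loops = []
    for u, kind, v, _ in net.edges():
        if kind is EdgeKind.REGULATES and net.has_edge(v, EdgeKind.TARGETS, u):
            loops.append(_canonical_loop(net, [u, v], include_hosts=False))
    return sorted(set(loops), key=lambda lp: lp.names)


def find_cycles_upto(
    net: RegulatoryNetwork,
    max_len: int = 2,
    include_hosts: bool = False,
    max_len_cap: int = DEFAULT_MAX_CYCLE_LEN,
) -> list[FeedbackLoop]:
    """All simple directed cycles of length <= ``max_len``, canonicalized.

    Hosting edges are excluded unless ``include_hosts``; cycle length is
    guarded by ``max_len_cap`` to keep enumeration bounded.
    """
    if max_len < 2:
        raise ContractError("max_len must be >= 2")
    if max_len > max_len_cap:
        raise ContractError(
            f"max_len={max_len} exceeds the combinatorial guard "
            f"(max_len_cap={max_len_cap})"
        )
    graph = _motif_graph(net, include_hosts)
    loops = set()
    for cycle in nx.simple_cycles(graph, length_bound=max_len):
        if len(cycle) >= 2:
            loops.add(_canonical_loop(net, cycle, include_hosts))
    return sorted(loops, key=lambda lp: (lp.length, lp.names))


# ---------------------------------------------------------------------------
# Upstream influence
# ---------------------------------------------------------------------------

def upstream_influence(
    net: RegulatoryNetwork,
    targets: set[str] | list[str],
    max_depth: int | None = None,
) -> InfluenceReport:
    """Categorize every factor with a directed path into ``targets``.

    Path depth is unlimited by default (``max_depth`` caps it), and every
    edge kind conducts influence — a host gene acting through its hosted
    miRNA, or a TF acting through an intermediate miRNA, both count. A gene
    ancestor is reported as a host contributor if some path-entering edge
    out of it is a hosts edge, as a TF if some is a regulates edge (a gene
    emitting both appears in both sets); miRNA ancestors form the third set.
    """
    target_set = set(targets)
    for t in target_set:
        if t not in net:
            raise ContractError(f"target node {t!r} is not in the network")

    if max_depth is None:
        ancestors: set[str] = set()
        for t in target_set:
            ancestors |= nx.ancestors(net.graph, t)
    else:
        ancestors = set()
        frontier = set(target_set)
        for _ in range(max_depth):
            frontier = {
                u for v in frontier for u in net.graph.predecessors(v)
            } - ancestors - target_set
            if not frontier:
                break
            ancestors |= frontier
    ancestors -= target_set

    reach = ancestors | target_set
    report = InfluenceReport(targets=target_set)
    for node in ancestors:
        if net.role(node).value == "mirna":
            report.mirnas.add(node)
            continue
        for _, succ, kind in net.graph.out_edges(node, keys=True):
            if succ not in reach:
                continue
            if kind == EdgeKind.HOSTS.value:
                report.hosts.add(node)
            elif kind == EdgeKind.REGULATES.value:
                report.tfs.add(node)
    return report


# ---------------------------------------------------------------------------
# Chains and hubs
# ---------------------------------------------------------------------------

def regulatory_chains(
    net: RegulatoryNetwork, length: int, include_hosts: bool = False
) -> list[list[NodeRef]]:
    """All simple directed control paths with exactly ``length`` nodes.

    The role constraints make any such path alternate between
    transcriptional (gene -> miRNA) and post-transcriptional
    (miRNA -> gene) control; hosting edges do not convey control and are
    excluded unless ``include_hosts``.
    """
    if length < 2:
        raise ContractError("chain length must be >= 2 nodes")
    graph = _motif_graph(net, include_hosts)
    chains: list[tuple[str, ...]] = []

    def extend(path: list[str]) -> None:
        if len(path) == length:
            chains.append(tuple(path))
            return
        for succ in sorted(graph.successors(path[-1])):
            if succ not in path:
                path.append(succ)
                extend(path)
                path.pop()

    for start in sorted(graph.nodes):
        extend([start])
    chains.sort()
    return [[net.node_ref(n) for n in chain] for chain in chains]


def rank_hubs(net: RegulatoryNetwork, k: int) -> list[tuple[NodeRef, int]]:
    """Top-``k`` nodes by total degree (in + out over all edge kinds).

    Ties break by name ascending; if ``k`` exceeds the node count all nodes
    are returned.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    ranked = sorted(
        ((name, deg) for name, deg in net.graph.degree()),
        key=lambda item: (-item[1], item[0]),
    )
    return [(net.node_ref(name), deg) for name, deg in ranked[:k]]
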