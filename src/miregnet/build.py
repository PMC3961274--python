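"""Assembly of the global network and extraction of its nested levels.

The interactome is studied at three nested levels of disease association:

* **global** -- every factor and association in the source tables;
* **related** -- associations involving disease-related (or differentially-
  expressed) genes and miRNAs, together with the host genes of the retained
  miRNAs;
* **differential** -- the innermost level, restricted to differentially-
  expressed factors and the host genes of their miRNAs.

A fourth, promoter-scan-derived level (**tf1000**) integrates transcription
factors predicted by scanning 1,000-nt promoter regions with the
differentially-expressed miRNAs and their host genes.
"""

from __future__ import annotations

from typing import Iterable

from .io import (
    AnnotationSet,
    ContractError,
    EdgeKind,
    InteractionRecord,
    NodeRef,
    RegulatoryNetwork,
    Role,
    dedupe_records,
    strip_arm,
)

__all__ = [
    "classify_node",
    "build_global_network",
    "extract_level_network",
    "integrate_predicted_tfs",
    "network_summary",
]

_STATUS_ORDER = {"differential": 2, "related": 1, "unannotated": 0}


def classify_node(node: NodeRef, annotations: AnnotationSet) -> str:
    """Assign the expression status of a node: DE beats related beats none."""
    if node.role is Role.MIRNA:
        de, related = annotations.de_mirnas, annotations.related_mirnas
    else:
        de, related = annotations.de_genes, annotations.related_genes
    if node.name in de:
        return "differential"
    if node.name in related:
        return "related"
    return "unannotated"


def build_global_network(
    records: Iterable[InteractionRecord], annotations: AnnotationSet
) -> RegulatoryNetwork:
    """Union the typed interaction records into the global network.

    Every record endpoint becomes a node with its expression status; the
    edge count equals the number of distinct (source, target, kind) triples.
    """
    net = RegulatoryNetwork(level="global")
    for rec in dedupe_records(records):
        net.add_record(
            rec,
            source_status=classify_node(rec.source, annotations),
            target_status=classify_node(rec.target, annotations),
        )
    return net


def _qualifies(status: str, level: str) -> bool:
    return _STATUS_ORDER[status] >= _STATUS_ORDER[level]


def _mirna_qualifies(
    net: RegulatoryNetwork,
    mirna: str,
    level: str,
    annotations: AnnotationSet | None,
) -> bool:
    """Level test for a miRNA with a precursor-level (arm-stripped) retry.

    Hosting is a genomic, precursor-level relation, so a hosts edge to
    hsa-miR-99-5p also qualifies when hsa-miR-99 is annotated.
    """
    if _qualifies(net.status(mirna), level):
        return True
    stripped = strip_arm(mirna)
    if stripped != mirna:
        if stripped in net and _qualifies(net.status(stripped), level):
            return True
        if annotations is not None:
            if stripped in annotations.de_mirnas:
                return True
            if level == "related" and stripped in annotations.related_mirnas:
                return True
    return False


def extract_level_network(
    net: RegulatoryNetwork,
    level: str,
    mode: str = "adjacent",
    annotations: AnnotationSet | None = None,
) -> RegulatoryNetwork:
    """Extract the differential- or related-level network from the global one.

    ``adjacent`` (default) keeps an edge when at least one endpoint has the
    requested status or better; ``strict`` requires both endpoints. Hosting
    edges ride along with their miRNA: they are kept exactly when the hosted
    miRNA qualifies (with an arm-stripped retry), regardless of the host
    gene's own annotation. Kept nodes are exactly the endpoints of kept
    edges, so no orphans arise.
    """
    if level not in ("differential", "related"):
        raise ContractError(
            f"level must be 'differential' or 'related', got {level!r}"
        )
    if mode not in ("adjacent", "strict"):
        raise ContractError(f"mode must be 'adjacent' or 'strict', got {mode!r}")
    out = RegulatoryNetwork(level=level)
    for u, kind, v, prov in net.edges():
        if kind is EdgeKind.HOSTS:
            keep = _mirna_qualifies(net, v, level, annotations)
        else:
            qu = _qualifies(net.status(u), level)
            qv = _qualifies(net.status(v), level)
            keep = (qu and qv) if mode == "strict" else (qu or qv)
        if keep:
            rec = InteractionRecord(net.node_ref(u), net.node_ref(v), kind, prov)
            out.add_record(rec, source_status=net.status(u),
                           target_status=net.status(v))
    return out


def integrate_predicted_tfs(
    net: RegulatoryNetwork,
    predicted_tfs: set[str],
    tf_regulations: Iterable[InteractionRecord],
    annotations: AnnotationSet,
) -> RegulatoryNetwork:
    """Build the 1,000-nt-TF network from promoter-scan-predicted TFs.

    The promoter-predicted TFs are integrated with the differentially-
    expressed miRNAs and their host genes: the result keeps (a) regulates
    edges whose TF is predicted and whose miRNA is DE, (b) hosts edges of
    those DE miRNAs, and (c) targets edges from those DE miRNAs to DE or
    related genes. Hosting and targeting edges are drawn from ``net`` (the
    global network).
    """

    def is_de_mirna(name: str) -> bool:
        return name in annotations.de_mirnas or strip_arm(name) in annotations.de_mirnas

    out = RegulatoryNetwork(level="tf1000")
    kept_mirnas: set[str] = set()
    for rec in dedupe_records(tf_regulations):
        if rec.kind is not EdgeKind.REGULATES:
            raise ContractError("tf_regulations must contain regulates records")
        if rec.source.name in predicted_tfs and is_de_mirna(rec.target.name):
            out.add_record(
                rec,
                source_status=classify_node(rec.source, annotations),
                target_status=classify_node(rec.target, annotations),
            )
            kept_mirnas.add(rec.target.name)
    for u, kind, v, prov in net.edges():
        if kind is EdgeKind.HOSTS and v in kept_mirnas:
            keep = True
        elif kind is EdgeKind.TARGETS and u in kept_mirnas:
            keep = net.status(v) in ("differential", "related")
        else:
            keep = False
        if keep:
            rec = InteractionRecord(net.node_ref(u), net.node_ref(v), kind, prov)
            out.add_record(rec, source_status=net.status(u),
                           target_status=net.status(v))
    return out


def network_summary(net: RegulatoryNetwork) -> dict:
    """Deterministic JSON-serializable counts of nodes and edges."""
    roles = {"gene": 0, "mirna": 0}
    statuses = {"differential": 0, "related": 0, "unannotated": 0}
    for node in net.nodes():
        roles[node.role.value] += 1
        statuses[net.status(node.name)] += 1
    kinds = {k.value: 0 for k in EdgeKind}
    for _, kind, _, _ in net.edges():
        kinds[kind.value] += 1
    return {
        "level": net.level,
        "nodes": {"total": net.n_nodes, **roles},
        "status": statuses,
        "edges": {"total": net.n_edges, **kinds},
    }
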