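"""Reading and writing of interaction tables, annotation lists and networks.

A heterogeneous miRNA/gene regulatory interactome is assembled from three
typed two-column tables, in the style of the public curated resources they
emulate:

* ``targets``    -- miRNA -> target gene  (TarBase / miRTarBase exports)
* ``regulates``  -- TF gene -> miRNA      (TransmiR exports)
* ``hosts``      -- host gene -> miRNA    (miRBase / NCBI genomic mapping)

All identifiers are normalized on entry (genes uppercased, mature miRNA
names rendered in canonical ``hsa-miR-…`` / ``hsa-let-…`` casing) so that
every downstream join is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger("miregnet")

__all__ = [
    "IdentifierError",
    "ParseError",
    "ContractError",
    "Role",
    "EdgeKind",
    "NodeRef",
    "InteractionRecord",
    "AnnotationSet",
    "RegulatoryNetwork",
    "normalize_gene_symbol",
    "normalize_mirna_name",
    "strip_arm",
    "read_interaction_table",
    "read_annotation_list",
    "load_annotations",
    "write_network",
    "read_edge_tsv_network",
]


class IdentifierError(ValueError):
    """An identifier could not be normalized to the canonical form."""


class ParseError(ValueError):
    """A file violated its expected tabular layout."""


class ContractError(ValueError):
    """An operation was called outside its contract."""


class Role(str, Enum):
    GENE = "gene"
    MIRNA = "mirna"


class EdgeKind(str, Enum):
    TARGETS = "targets"      # miRNA -> gene, post-transcriptional repression
    REGULATES = "regulates"  # TF gene -> miRNA, transcriptional control
    HOSTS = "hosts"          # host gene -> miRNA, genomic co-location

    @property
    def source_role(self) -> Role:
        return Role.MIRNA if self is EdgeKind.TARGETS else Role.GENE

    @property
    def target_role(self) -> Role:
        return Role.GENE if self is EdgeKind.TARGETS else Role.MIRNA


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node: a gene symbol or a mature miRNA name."""

    name: str
    role: Role

    def __post_init__(self) -> None:
        if not self.name or self.name != self.name.strip():
            raise IdentifierError(f"invalid node name {self.name!r}")


@dataclass(frozen=True)
class InteractionRecord:
    """One directed, typed interaction pair — the unit of the interactome."""

    source: NodeRef
    target: NodeRef
    kind: EdgeKind
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.source.role is not self.kind.source_role:
            raise ContractError(
                f"{self.kind.value} edge requires a {self.kind.source_role.value} "
                f"source, got {self.source.name!r} ({self.source.role.value})"
            )
        if self.target.role is not self.kind.target_role:
            raise ContractError(
                f"{self.kind.value} edge requires a {self.kind.target_role.value} "
                f"target, got {self.target.name!r} ({self.target.role.value})"
            )
        if self.source.name == self.target.name:
            raise ContractError(f"self-pair {self.source.name!r} is not allowed")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.source.name, self.kind.value, self.target.name)


@dataclass
class AnnotationSet:
    """Differentially-expressed (DE) and disease-related membership lists.

    DE sets are nested inside the related sets: a DE factor is by definition
    also related, so the related sets are unioned with the DE sets on
    construction.
    """

    de_genes: set[str] = field(default_factory=set)
    related_genes: set[str] = field(default_factory=set)
    de_mirnas: set[str] = field(default_factory=set)
    related_mirnas: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.related_genes |= self.de_genes
        self.related_mirnas |= self.de_mirnas


# ---------------------------------------------------------------------------
# Identifier normalization
# ---------------------------------------------------------------------------

def normalize_gene_symbol(raw: str) -> str:
    """Trim and uppercase a gene symbol."""
    name = raw.strip()
    if not name:
        raise IdentifierError("empty gene symbol")
    return name.upper()


def normalize_mirna_name(raw: str) -> str:
    """Render a mature miRNA name in canonical casing.

    The species prefix and everything else are lowercased; the ``mir``
    segment is rendered ``miR`` (``let`` families stay lowercase); arm
    suffixes (``-5p``/``-3p``) are preserved. A bare ``mir-21`` style name
    gains the ``hsa-`` prefix.
    """
    name = raw.strip().lower()
    if not name:
        raise IdentifierError("empty miRNA name")
    tokens = name.split("-")
    if "mir" not in tokens and "let" not in tokens:
        raise IdentifierError(f"{raw!r} has no recognizable miR/let token")
    if tokens[0] in ("mir", "let"):
        tokens = ["hsa"] + tokens
    tokens = ["miR" if t == "mir" else t for t in tokens]
    return "-".join(tokens)


def strip_arm(mirna: str) -> str:
    """Drop a trailing -5p/-3p arm suffix (precursor-level comparison)."""
    for suffix in ("-5p", "-3p"):
        if mirna.endswith(suffix):
            return mirna[: -len(suffix)]
    return mirna


def _normalize_for_role(raw: str, role: Role) -> str:
    if role is Role.MIRNA:
        return normalize_mirna_name(raw)
    return normalize_gene_symbol(raw)


def _looks_like_mirna(raw: str) -> bool:
    # Hyphenated names with a mir/let token are mature miRNA names; plain
    # symbols such as MIR21 (a host-gene symbol) are genes.
    tokens = raw.strip().lower().split("-")
    return len(tokens) > 1 and ("mir" in tokens or "let" in tokens)


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def _iter_rows(path: Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_interaction_table(
    path: str | Path, kind: EdgeKind | str, provenance: str | None = None
) -> list[InteractionRecord]:
    """Read a two-column tab-separated interaction table.

    Column orientation follows the edge kind: ``targets`` tables are
    (miRNA, gene); ``regulates`` and ``hosts`` tables are (gene, miRNA).
    A first row whose miRNA-role column fails validation is treated as a
    header and skipped. Exact duplicate (source, target, kind) triples are
    dropped with a logged count.
    """
    kind = EdgeKind(kind)
    path = Path(path)
    if provenance is None:
        provenance = path.name
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str, str]] = set()
    dropped = 0
    first_data_row = True
    for lineno, line in _iter_rows(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
            )
        try:
            source = NodeRef(_normalize_for_role(cols[0], kind.source_role),
                             kind.source_role)
            target = NodeRef(_normalize_for_role(cols[1], kind.target_role),
                             kind.target_role)
        except IdentifierError:
            mirna_col = cols[0] if kind.source_role is Role.MIRNA else cols[1]
            if first_data_row and not _looks_like_mirna(mirna_col):
                first_data_row = False  # header row, skip
                continue
            raise IdentifierError(
                f"{path}:{lineno}: cannot normalize row {cols!r} for kind "
                f"{kind.value!r}"
            )
        first_data_row = False
        record = InteractionRecord(source, target, kind, provenance)
        if record.triple in seen:
            dropped += 1
            continue
        seen.add(record.triple)
        records.append(record)
    logger.info(
        "read %d %s records from %s (%d duplicate rows dropped)",
        len(records), kind.value, path, dropped,
    )
    return records


def read_annotation_list(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line annotation list into a normalized set.

    Hyphenated names carrying a mir/let token are normalized as miRNAs,
    everything else as gene symbols ('#' comments allowed).
    """
    names: set[str] = set()
    for _, line in _iter_rows(Path(path)):
        raw = line.strip()
        if _looks_like_mirna(raw):
            names.add(normalize_mirna_name(raw))
        else:
            names.add(normalize_gene_symbol(raw))
    return names


def load_annotations(
    de_genes: str | Path,
    de_mirnas: str | Path,
    related_genes: str | Path | None = None,
    related_mirnas: str | Path | None = None,
) -> AnnotationSet:
    """Assemble an AnnotationSet from list files (DE ⊆ related enforced)."""
    return AnnotationSet(
        de_genes=read_annotation_list(de_genes),
        de_mirnas=read_annotation_list(de_mirnas),
        related_genes=read_annotation_list(related_genes) if related_genes else set(),
        related_mirnas=read_annotation_list(related_mirnas) if related_mirnas else set(),
    )


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

class RegulatoryNetwork:
    """A directed heterogeneous regulatory graph.

    Nodes carry ``role`` (gene | mirna) and ``status`` (differential |
    related | unannotated); parallel edges between the same ordered pair are
    keyed by edge kind. ``level`` is a metadata tag only (global, related,
    differential, tf1000).
    """

    def __init__(self, level: str = "global") -> None:
        self.graph = nx.MultiDiGraph()
        self.level = level

    # -- construction -------------------------------------------------------
    def add_node(self, node: NodeRef, status: str = "unannotated") -> None:
        self.graph.add_node(node.name, role=node.role.value, status=status)

    def add_record(self, record: InteractionRecord,
                   source_status: str = "unannotated",
                   target_status: str = "unannotated") -> None:
        if record.source.name not in self.graph:
            self.add_node(record.source, source_status)
        if record.target.name not in self.graph:
            self.add_node(record.target, target_status)
        self.graph.add_edge(
            record.source.name, record.target.name, key=record.kind.value,
            kind=record.kind.value, provenance=record.provenance,
        )

    # -- queries ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_ref(self, name: str) -> NodeRef:
        return NodeRef(name, Role(self.graph.nodes[name]["role"]))

    def status(self, name: str) -> str:
        return self.graph.nodes[name]["status"]

    def role(self, name: str) -> Role:
        return Role(self.graph.nodes[name]["role"])

    def nodes(self) -> Iterator[NodeRef]:
        for name in self.graph.nodes:
            yield self.node_ref(name)

    def edges(self) -> Iterator[tuple[str, EdgeKind, str, str]]:
        """Yield (source, kind, target, provenance) tuples."""
        for u, v, k, data in self.graph.edges(keys=True, data=True):
            yield u, EdgeKind(k), v, data.get("provenance", "")

    def edge_triples(self) -> set[tuple[str, str, str]]:
        return {(u, k, v) for u, v, k in self.graph.edges(keys=True)}

    def has_edge(self, source: str, kind: EdgeKind | str, target: str) -> bool:
        return self.graph.has_edge(source, target, key=EdgeKind(kind).value)

    def records(self) -> list[InteractionRecord]:
        out = []
        for u, kind, v, prov in self.edges():
            out.append(InteractionRecord(self.node_ref(u), self.node_ref(v),
                                         kind, prov))
        return out

    def __contains__(self, name: str) -> bool:
        return name in self.graph


# ---------------------------------------------------------------------------
# Network writers / readers
# ---------------------------------------------------------------------------

def _sorted_edges(net: RegulatoryNetwork) -> list[tuple[str, str, str, str]]:
    return sorted((u, k.value, v, p) for u, k, v, p in net.edges())


def write_network(net: RegulatoryNetwork, path: str | Path, dialect: str) -> None:
    """Write a network as SIF, GraphML or a 4-column edge TSV.

    SIF lines are ``source kind target``; GraphML carries node ``role`` and
    ``status`` attributes plus the edge ``kind``; edge TSV is
    source/kind/target/provenance and round-trips the edge multiset exactly.
    """
    path = Path(path)
    if dialect == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, k, v, _ in _sorted_edges(net):
                fh.write(f"{u} {k} {v}\n")
    elif dialect == "edge_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#source\tkind\ttarget\tprovenance\n")
            for u, k, v, p in _sorted_edges(net):
                fh.write(f"{u}\t{k}\t{v}\t{p}\n")
    elif dialect == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ContractError(f"unknown dialect {dialect!r}")


def read_edge_tsv_network(path: str | Path, level: str = "global") -> RegulatoryNetwork:
    """Re-read an edge TSV written by :func:`write_network`.

    Node roles are recovered from the edge-kind role constraints; statuses
    are not stored in this dialect and default to unannotated.
    """
    net = RegulatoryNetwork(level=level)
    path = Path(path)
    for lineno, line in _iter_rows(path):
        cols = line.split("\t")
        if len(cols) not in (3, 4):
            raise ParseError(f"{path}:{lineno}: expected 3-4 columns")
        source, kind_s, target = cols[0], cols[1], cols[2]
        prov = cols[3] if len(cols) == 4 else ""
        kind = EdgeKind(kind_s)
        net.add_record(InteractionRecord(
            NodeRef(source, kind.source_role),
            NodeRef(target, kind.target_role),
            kind, prov,
        ))
    return net


def dedupe_records(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Drop exact duplicate (source, target, kind) triples, keeping order."""
    seen: set[tuple[str, str, str]] = set()
    out = []
    for rec in records:
        if rec.triple not in seen:
            seen.add(rec.triple)
            out.append(rec)
    return out
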