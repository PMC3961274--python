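"""Synthetic inputs: the literature fixture, random interactomes, promoters.

Two kinds of input stand in for the curated database snapshots the pipeline
expects:

* :func:`paper_fixture` returns the small cervical-cancer network described
  edge-by-edge in the study this pipeline reproduces (the PTEN/hsa-miR-21
  self-adaption system, the TP53/TGFB1 -> hsa-miR-143 -> FHIT flow, the MYC
  feedbacks, and the promoter-predicted NFKB1 regulations);
* :func:`generate_interactome` draws random typed interaction tables whose
  default magnitudes are one tenth of the curated snapshots the study used
  (6,749 targeting entries over 426 miRNAs and 2,029 genes; 862 TF->miRNA
  regulations over 153 TFs; 1,419 hostings over 1,136 host genes), with
  plantable 2-node feedback loops and a guarantee that no accidental
  2-node loop arises.

:func:`generate_promoters` draws uniform-background 1,000-nt promoters with
optionally planted consensus binding sites and a truth table for recovery
tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .io import (
    AnnotationSet,
    ContractError,
    EdgeKind,
    InteractionRecord,
    NodeRef,
    Role,
)
from .pwm import BASES, PositionWeightMatrix, PromoterSequence, reverse_complement

__all__ = [
    "Fixture",
    "InteractomeSpec",
    "paper_fixture",
    "generate_interactome",
    "generate_promoters",
    "PMATCH_PROVENANCE",
]

#: provenance tag separating promoter-scan-predicted TF regulations from the
#: curated (TransmiR-style) base tables; base-level networks exclude it
PMATCH_PROVENANCE = "pmatch-1000nt"


@dataclass
class Fixture:
    """Interaction records plus annotations, ready for network assembly."""

    records: list[InteractionRecord]
    annotations: AnnotationSet

    @property
    def base_records(self) -> list[InteractionRecord]:
        """Records backing the global/related/differential levels (curated
        tables only; promoter-scan-predicted regulations excluded)."""
        return [r for r in self.records if r.provenance != PMATCH_PROVENANCE]

    @property
    def tf_regulations(self) -> list[InteractionRecord]:
        """Promoter-scan-predicted TF regulations (tf1000-level input)."""
        return [r for r in self.records if r.provenance == PMATCH_PROVENANCE]

    @property
    def predicted_tfs(self) -> set[str]:
        return {r.source.name for r in self.tf_regulations}


def _gene(name: str) -> NodeRef:
    return NodeRef(name, Role.GENE)


def _mirna(name: str) -> NodeRef:
    return NodeRef(name, Role.MIRNA)


def _rec(src: NodeRef, tgt: NodeRef, kind: EdgeKind, prov: str) -> InteractionRecord:
    return InteractionRecord(src, tgt, kind, prov)


def paper_fixture() -> Fixture:
    """The cervical-cancer network stated in the source study's results text.

    21 edges: 11 TF->miRNA regulations (three of them — NFKB1's — promoter-
    scan predictions rather than curated data), 8 miRNA->gene targetings and
    2 host-gene->miRNA hostings. Role assignments the prose leaves implicit
    (STAT3 as a TF of hsa-miR-21; MIR21 and DNM3 as host genes) follow the
    stated 2-hosts/2-TFs/1-miRNA upstream count of the PTEN/hsa-miR-21
    system. hsa-let-7b is carried as differentially expressed, which the
    NFKB1 integration (with DE miRNAs only) requires.
    """
    reg = [
        ("TWIST1", "hsa-miR-214", "transmir"),
        ("PTEN", "hsa-miR-21", "transmir"),
        ("STAT3", "hsa-miR-21", "transmir"),
        ("TP53", "hsa-miR-143", "transmir"),
        ("TGFB1", "hsa-miR-143", "transmir"),
        ("MYC", "hsa-let-7b", "transmir"),
        ("MYC", "hsa-let-7c", "transmir"),
        ("MYC", "hsa-miR-34", "transmir"),
        ("NFKB1", "hsa-miR-21", PMATCH_PROVENANCE),
        ("NFKB1", "hsa-miR-214", PMATCH_PROVENANCE),
        ("NFKB1", "hsa-let-7b", PMATCH_PROVENANCE),
    ]
    targ = [
        ("hsa-miR-214", "PTEN"),
        ("hsa-miR-21", "PTEN"),
        ("hsa-miR-143", "FHIT"),
        ("hsa-let-7b", "KRAS"),
        ("hsa-let-7c", "KRAS"),
        ("hsa-let-7c", "MYC"),
        ("hsa-miR-34", "MYC"),
        ("hsa-miR-21", "NFKB1"),
    ]
    host = [
        ("DNM3", "hsa-miR-214"),
        ("MIR21", "hsa-miR-21"),
    ]
    records = (
        [_rec(_gene(g), _mirna(m), EdgeKind.REGULATES, prov)
         for g, m, prov in reg]
        + [_rec(_mirna(m), _gene(g), EdgeKind.TARGETS, "tarbase")
           for m, g in targ]
        + [_rec(_gene(g), _mirna(m), EdgeKind.HOSTS, "mirbase")
           for g, m in host]
    )
    annotations = AnnotationSet(
        de_genes={"PTEN", "TWIST1", "TP53", "TGFB1", "FHIT"},
        de_mirnas={"hsa-miR-21", "hsa-miR-214", "hsa-miR-143", "hsa-let-7b"},
        related_genes={"MYC", "KRAS", "STAT3", "NFKB1"},
        related_mirnas={"hsa-let-7c", "hsa-miR-34"},
    )
    return Fixture(records=records, annotations=annotations)


# ---------------------------------------------------------------------------
# Random interactomes
# ---------------------------------------------------------------------------

@dataclass
class InteractomeSpec:
    """Shape of a random interactome.

    Default magnitudes are one tenth of the curated snapshots the source
    study assembled; annotation fractions approximate its DE/related ratios
    (11 DE of 426 miRNAs; 38 DE and 241 related of ~2,000 genes).
    """

    n_mirnas: int = 43
    n_genes: int = 203
    n_tfs: int = 15
    n_hosts: int = 114
    n_targets: int = 675
    n_regulations: int = 86
    n_hostings: int = 142
    k_planted_loops: int = 0
    de_fraction_genes: float = 0.02
    de_fraction_mirnas: float = 0.03
    related_fraction: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mirnas", "n_genes", "n_tfs", "n_hosts",
                     "n_targets", "n_regulations", "n_hostings",
                     "k_planted_loops"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be non-negative")
        for name in ("de_fraction_genes", "de_fraction_mirnas",
                     "related_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ContractError(f"{name} must lie in [0, 1]")
        if self.related_fraction < max(self.de_fraction_genes,
                                       self.de_fraction_mirnas):
            raise ContractError("related_fraction must be >= the DE fractions")
        if self.k_planted_loops > min(self.n_tfs, self.n_mirnas):
            raise ContractError("k_planted_loops exceeds min(n_tfs, n_mirnas)")
        if self.k_planted_loops > self.n_regulations:
            raise ContractError("planted loops need n_regulations >= k")
        if self.k_planted_loops > self.n_targets:
            raise ContractError("planted loops need n_targets >= k")
        if self.n_regulations > self.n_tfs * self.n_mirnas:
            raise ContractError("n_regulations exceeds possible TF-miRNA pairs")
        if self.n_hostings > self.n_hosts * self.n_mirnas:
            raise ContractError("n_hostings exceeds possible host-miRNA pairs")
        if self.n_targets > self.n_mirnas * (self.n_genes + self.n_tfs):
            raise ContractError("n_targets exceeds possible miRNA-gene pairs")


def generate_interactome(spec: InteractomeSpec) -> Fixture:
    """Draw a random typed interactome with planted 2-node feedback loops.

    Exactly ``k_planted_loops`` (TF, miRNA) pairs receive both a regulates
    and the reverse targets edge. The remaining targets edges are sampled
    from candidates excluding the reverses of the sampled regulations, so no
    accidental 2-node loop can arise (a constructive guarantee). All draws
    come from a single seeded generator; re-running with the same spec
    reproduces the output exactly.
    """
    spec.validate()
    rng = random.Random(spec.seed)

    mirnas = [_mirna(f"hsa-miR-{9000 + i}") for i in range(spec.n_mirnas)]
    genes = [_gene(f"GENE{i:04d}") for i in range(spec.n_genes)]
    tfs = [_gene(f"TFGENE{i:03d}") for i in range(spec.n_tfs)]
    hosts = [_gene(f"HOSTG{i:03d}") for i in range(spec.n_hosts)]

    # planted self-adaption pairs
    planted_tfs = rng.sample(tfs, spec.k_planted_loops) if spec.k_planted_loops else []
    planted_mirnas = rng.sample(mirnas, spec.k_planted_loops) if spec.k_planted_loops else []
    planted = list(zip(planted_tfs, planted_mirnas))

    records: list[InteractionRecord] = []
    for g, m in planted:
        records.append(_rec(g, m, EdgeKind.REGULATES, "synthetic-planted"))
        records.append(_rec(m, g, EdgeKind.TARGETS, "synthetic-planted"))

    planted_reg = {(g.name, m.name) for g, m in planted}
    reg_candidates = [
        (g, m) for g in tfs for m in mirnas if (g.name, m.name) not in planted_reg
    ]
    n_extra_reg = spec.n_regulations - spec.k_planted_loops
    sampled_reg = rng.sample(reg_candidates, n_extra_reg)
    for g, m in sampled_reg:
        records.append(_rec(g, m, EdgeKind.REGULATES, "synthetic-regulates"))

    regulated = planted_reg | {(g.name, m.name) for g, m in sampled_reg}
    # excluding reverses of every regulates edge makes accidental 2-node
    # loops impossible by construction
    targ_candidates = [
        (m, g) for m in mirnas for g in genes + tfs
        if (g.name, m.name) not in regulated
    ]
    n_extra_targ = spec.n_targets - spec.k_planted_loops
    if n_extra_targ > len(targ_candidates):
        raise ContractError("n_targets infeasible after loop-avoidance filtering")
    for m, g in rng.sample(targ_candidates, n_extra_targ):
        records.append(_rec(m, g, EdgeKind.TARGETS, "synthetic-targets"))

    host_candidates = [(h, m) for h in hosts for m in mirnas]
    for h, m in rng.sample(host_candidates, spec.n_hostings):
        records.append(_rec(h, m, EdgeKind.HOSTS, "synthetic-hosts"))

    all_gene_names = sorted(g.name for g in genes + tfs + hosts)
    all_mirna_names = sorted(m.name for m in mirnas)
    rel_genes = rng.sample(all_gene_names,
                           round(spec.related_fraction * len(all_gene_names)))
    de_genes = rng.sample(rel_genes,
                          min(len(rel_genes),
                              round(spec.de_fraction_genes * len(all_gene_names))))
    rel_mirnas = rng.sample(all_mirna_names,
                            round(spec.related_fraction * len(all_mirna_names)))
    de_mirnas = rng.sample(rel_mirnas,
                           min(len(rel_mirnas),
                               round(spec.de_fraction_mirnas * len(all_mirna_names))))
    annotations = AnnotationSet(
        de_genes=set(de_genes), related_genes=set(rel_genes),
        de_mirnas=set(de_mirnas), related_mirnas=set(rel_mirnas),
    )
    return Fixture(records=records, annotations=annotations)


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    gene: str
    tf: str
    offset: int
    strand: str


def generate_promoters(
    pwms: list[PositionWeightMatrix],
    n: int,
    plant_rate: float = 0.5,
    seed: int = 0,
    length: int = 1000,
) -> tuple[list[PromoterSequence], list[PlantedSite]]:
    """Uniform-background promoters with optionally planted consensus sites.

    Each of the ``n`` promoters is i.i.d. uniform over ACGT; with
    probability ``plant_rate`` the consensus of a random matrix is written
    at a uniform random offset on a random strand. The truth table lists
    (gene, tf, offset, strand) for every planted site.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    if not 0.0 <= plant_rate <= 1.0:
        raise ContractError("plant_rate must lie in [0, 1]")
    if not pwms:
        raise ContractError("at least one matrix is required")
    rng = random.Random(seed)
    promoters: list[PromoterSequence] = []
    truth: list[PlantedSite] = []
    for i in range(n):
        gene = f"PROM{i:04d}"
        seq = [rng.choice(BASES) for _ in range(length)]
        if rng.random() < plant_rate:
            pwm = rng.choice(pwms)
            site = pwm.consensus
            strand = rng.choice("+-")
            if strand == "-":
                site = reverse_complement(site)
            offset = rng.randrange(length - pwm.length + 1)
            seq[offset:offset + pwm.length] = site
            truth.append(PlantedSite(gene, pwm.name, offset, strand))
        promoters.append(PromoterSequence(gene, "".join(seq)))
    return promoters, truth
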