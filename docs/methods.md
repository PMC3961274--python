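# Methods

## Model

The regulatory system is a directed heterogeneous graph over two node roles
(gene, miRNA) and three edge kinds:

| kind      | direction     | meaning                                  |
|-----------|---------------|------------------------------------------|
| targets   | miRNA → gene  | post-transcriptional repression          |
| regulates | gene → miRNA  | transcriptional control by a TF          |
| hosts     | gene → miRNA  | genomic co-location (intronic miRNAs are |
|           |               | typically co-expressed with their host)  |

Edge kinds impose role constraints, which in turn force any directed path
that uses only `targets`/`regulates` edges to alternate between
transcriptional and post-transcriptional control — the "ordered control
chain" structure. `hosts` is treated as co-expression, not control: host
edges conduct *influence* (a host gene affects its miRNA's abundance) but
are excluded from chains and cycles by default (an `include_hosts` flag
reverses this).

Nodes carry an expression status — `differential` ⊂ `related` ⊂
`unannotated` complement — loaded from annotation lists with the nesting
DE ⊆ related enforced by union at load time.

## Level extraction

The global network is the union of all records. The related and
differential networks are extracted by an *adjacent* rule (default): an
edge is kept when at least one endpoint has the requested status or better.
This reproduces the published content of the innermost network, which
contains unannotated participants (the TF STAT3, the host genes DNM3 and
MIR21) drawn in through their differentially-expressed partners. A
*strict* mode (both endpoints must qualify) is available; its output edge
set is always a subset of the adjacent one.

Hosting edges ride along with their miRNA: a hosts edge is kept exactly
when the hosted miRNA qualifies, regardless of the host gene's own
annotation. Because hosting is a precursor-level relation, the miRNA test
retries with the arm suffix (-5p/-3p) stripped.

Extraction is pure (the input network is unchanged) and level tags are
metadata only. The deeper reach of the original "search procedure" is
realized by the adjacent rule plus the unlimited-depth ancestor traversal
of the influence analysis, since no explicit depth is defined anywhere; a
`max_depth` option caps it.

## 1,000-nt TF integration

TFs predicted from promoter scanning are integrated with the
differentially-expressed miRNAs and their host genes: the tf1000 network
keeps (a) regulates edges whose TF is predicted and whose miRNA is DE,
(b) hosts edges of those miRNAs, and (c) targets edges from those miRNAs
to DE or related genes. Promoter-predicted regulations are provenance-
tagged (`pmatch-1000nt` in the fixture) and excluded from the curated base
tables, so they appear only at this level — which is what makes the
NFKB1/hsa-miR-21 feedback a tf1000-level discovery rather than a base-level
one.

## Motif detection

* Two-node feedback loops are found by a direct scan: every regulates edge
  (G→M) with the reverse targets edge (M→G).
* General cycles use bounded simple-cycle enumeration
  (`networkx.simple_cycles` with a length bound); a guard rejects bounds
  above 4 by default (configurable) because cycle counts explode
  combinatorially. Loops are canonicalized by rotating to the
  lexicographically smallest member; direction is preserved (edges are
  directed, so no reflection).
* Upstream influence computes the full ancestor set of the query nodes and
  categorizes gene ancestors by the kind of their path-entering out-edges:
  hosts → host contributor, regulates → TF contributor (a gene emitting
  both kinds appears in both sets — categories are roles, not a
  partition); miRNA ancestors form the third set. Unlimited depth is the
  default because host genes and TFs acting through an intermediate miRNA
  (DNM3 → hsa-miR-214 → PTEN) must count for the published 2/2/1 example
  to hold.
* Hubs are ranked by total degree over all edge kinds, ties broken by name.

Determinism: all outputs are sorted canonically, so identical inputs give
identical serialized results.

## PWM scanning

The scanner implements the Match-family information-weighted scores:

    I(i)  = Σ_b f(i,b) ln(4 f(i,b)),   0·ln 0 := 0
    S(w)  = Σ_i I(i) f(i, w_i)
    MSS   = (S − S_min) / (S_max − S_min)

with S_min/S_max from the per-position minimum/maximum frequencies, so the
consensus scores exactly 1 and the anti-consensus 0. CSS applies the same
normalization to the 5 consecutive positions with the largest ΣI
(leftmost on ties); matrices shorter than 5 positions degenerate to
CSS := MSS, as does any all-uniform stretch (S_max = S_min ⇒ score 1).

Numerical choices: counts gain a pseudocount of 0.01 per cell and are
renormalized per position; windows containing N are skipped rather than
scored (promoter sequences contain hard-masked runs); both strands are
scanned, minus-strand windows being scored through the reverse-complemented
matrix with coordinates reported 0-based, half-open on the + strand; the
degenerate-normalization threshold is S_max − S_min < 1e-12. Default
cutoffs are css = 0.75 and mss = 0.85 — conventional "high-quality"
operating points for this score family, exposed as `--css/--mss`; no
published cutoff table is reproduced.

## Synthetic data

`paper_fixture()` encodes the 21 interactions stated in the source study's
results text plus the annotation sets needed to reproduce its counts. Role
assignments the prose leaves implicit (STAT3 as a TF of hsa-miR-21; DNM3
and MIR21 as host genes) follow the stated 2-hosts/2-TFs/1-miRNA count of
the PTEN/hsa-miR-21 system. hsa-let-7b is carried as differentially
expressed: the DE-miRNA-only integration rule together with NFKB1's three
stated regulations requires it, and only 3 of the 10 DE miRNAs of the
innermost network are named, so this is consistent with the source. The
fixture is a lower bound on the published figures — only text-described
edges are present.

`generate_interactome` draws random typed tables whose default magnitudes
are one tenth of the curated snapshots the study assembled (43 miRNAs ×
203 target genes with 675 targetings; 15 TFs with 86 regulations; 114 host
genes with 142 hostings) — small enough to analyze instantly while keeping
the empirical density of each relation. Annotation fractions default to
de_genes 2%, de_mirnas 3%, related 12%, approximating the study's DE/related
ratios. Exactly `k_planted_loops` TF–miRNA pairs receive both a regulates
and the reverse targets edge; remaining targets edges are sampled from
candidates excluding the reverses of all sampled regulations, so no
accidental two-node loop can arise — a constructive guarantee, stronger
than rejection sampling. A single integer seed governs every draw.

`generate_promoters` emits i.i.d.-uniform 1,000-nt sequences with a
consensus site planted at a uniform offset on a random strand with
probability `plant_rate`, plus a truth table. What this emulates — and
what it does not: real promoters have composition bias, CpG islands,
repeats and degenerate (non-consensus) sites, so perfect planted-site
recovery here demonstrates scanner correctness (coordinates, strands,
normalization), not expected sensitivity on genomic sequence. Likewise the
random interactomes validate structural guarantees (level nesting,
monotonicity, planted-motif recovery), not biological realism of degree
distributions.

## Problem sizes used in tests and the acceptance script

Nesting is checked on 200 (tests) / 50 (script) random interactomes of
~60 nodes; enumeration oracles on 100 random ≤15-node graphs against
exhaustive search; planted-loop recovery at k ∈ {0, 1, 3, 10}; scanner
recovery on 100 promoters with 3 random sharp matrices. These sizes give
exact, fast, reproducible checks of the properties involved.

## Known limitations

* No alias/synonym resolution for gene symbols; joins are exact after
  case normalization. Only `hsa` miRNA names are validated.
* Whether source names are precursor- or mature-level is not always
  decidable; names are kept as given, with arm-stripped retries only where
  hosting (a precursor-level relation) is joined.
* No statistical enrichment of motif counts against degree-preserving
  rewired networks, and no weighted centralities beyond degree.
* The PWM scanner is a Match-style reimplementation with conventional
  defaults, not a reproduction of any proprietary cutoff tables.
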