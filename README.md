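# miregnet

Construction and analysis of heterogeneous miRNA–gene regulatory networks,
built for studies of disease (here: cervical cancer) regulation in which a
gene can act in several identities at once — as a miRNA **target**, as a
**transcription factor** (TF) driving a miRNA, or as the genomic **host**
of a miRNA.

The interactome is modeled as three typed relations,

```
U1 = {(M, G_T)  : miRNA M targets gene G_T}          (miRNA -> gene)
U2 = {(G_TF, M) : TF G_TF regulates miRNA M}          (gene  -> miRNA)
U3 = {(G_H, M)  : G_H is the host gene of miRNA M}    (gene  -> miRNA)
```

unioned into one directed graph and examined at nested levels of disease
association: the **global** network (everything), the **related** network
(factors associated with the disease), and the **differentially-expressed**
network (factors with validated expression changes, the innermost and most
informative level). A fourth, promoter-derived level integrates TFs whose
binding sites are predicted by scanning 1,000-nt promoter regions with
position weight matrices (the *1,000-nt TF* network).

On these networks the package detects the characteristic regulatory motifs:

* **self-adaption feedback loops** — a gene drives a miRNA that represses
  that same gene (PTEN ⇄ hsa-miR-21 is the canonical example), a
  homeostatic two-node cycle;
* longer simple cycles (bounded enumeration);
* **ordered control chains** — alternating TF→miRNA→gene… control paths
  such as TWIST1 → hsa-miR-214 → PTEN → hsa-miR-21;
* **hubs** — top total-degree factors;
* **upstream influence** — every factor with a directed path into a query
  set, categorized by the role through which it acts (host gene / TF /
  miRNA).

PWM scanning uses the Match-family scores: per-position information
I(i) = Σ_b f(i,b) ln 4f(i,b), matrix similarity
MSS = (S − S_min)/(S_max − S_min) with S = Σ_i I(i) f(i, b_i), and core
similarity CSS computed on the 5 most informative consecutive positions.

## Worked example

```python
import miregnet as m

fx = m.paper_fixture()                       # the curated literature network
net = m.build_global_network(fx.base_records, fx.annotations)
diff = m.extract_level_network(net, "differential", annotations=fx.annotations)

report = m.upstream_influence(diff, {"PTEN", "hsa-miR-21"})
print(report.as_dict())
print([lp.names for lp in m.find_two_node_feedback_loops(diff)])
```

prints

```
{'targets': ['PTEN', 'hsa-miR-21'], 'hosts': ['DNM3', 'MIR21'],
 'tfs': ['STAT3', 'TWIST1'], 'mirnas': ['hsa-miR-214']}
[('PTEN', 'hsa-miR-21')]
```

i.e. exactly two host genes (DNM3, MIR21), two TFs (STAT3, TWIST1) and one
miRNA (hsa-miR-214) affect the PTEN/hsa-miR-21 core system, and the two
core factors control each other in a self-adaption feedback loop.

The same pipeline is available from the shell:

```bash
miregnet fixture --out-dir data/
miregnet build --targets data/targets.tsv --tf data/tf.tsv --host data/host.tsv \
    --de-genes data/de_genes.txt --de-mirnas data/de_mirnas.txt \
    --related-genes data/related_genes.txt --related-mirnas data/related_mirnas.txt \
    --level differential --out diff.tsv
miregnet loops --net diff.tsv --max-len 2
miregnet influence --net diff.tsv --targets PTEN,hsa-miR-21
```

## Layout

```
src/miregnet/io.py        identifiers, tables, annotation lists, SIF/GraphML/TSV
src/miregnet/build.py     global network, level extraction, 1,000-nt TF integration
src/miregnet/motifs.py    feedback loops, cycles, chains, hubs, upstream influence
src/miregnet/pwm.py       Match-style MSS/CSS promoter scanning, TRANSFAC I/O
src/miregnet/simulate.py  literature fixture, random interactomes, promoters
src/miregnet/cli.py       command-line interface
docs/methods.md           model, parameters, design choices, limitations
```
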