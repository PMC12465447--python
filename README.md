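# cohic

Analysis of cohesin-dependent 3D genome organization in neurons: Hi-C
contact maps, A/B compartments, promoter–enhancer interactions, ChIP-seq
interval rules, 3D DNA-FISH distances, and the nonparametric statistics
that tie them together.

Cohesin (with its core subunit RAD21) extrudes chromatin loops and shapes
genome folding at several length scales. When cohesin is removed from a
mature neuron, some genes lose the local contacts between their promoters
and enhancers and are downregulated; a subset of distal intergenic
enhancers additionally falls out of the active A compartment. `cohic`
implements the computational side of such a study as a tested, reusable
pipeline, together with a synthetic-data generator that plants known
compartment flips, loop depletions and expression changes so every stage
can be validated against ground truth without any external download.

## What it computes

- **Contact matrices** — 4DN pairs-format text is filtered (intra-chromosomal
  separation ≥ 1 kb, exact duplicates removed), binned per chromosome
  (5 kb / 25 kb / 500 kb), pooled across datasets, and balanced with
  Knight–Ruiz matrix scaling: a weight vector *w* > 0 such that
  *w<sub>i</sub> c<sub>ij</sub> w<sub>j</sub>* has unit row sums.
- **A/B compartments** — the first eigenvector of the per-chromosome
  correlation matrix of the distance-normalized (observed/expected)
  balanced map, oriented so bins rich in H3K27ac and poor in H3K9me3 score
  positive (A). Differential analysis ranks control-A bins by the signed
  change in score after perturbation, chunks them into consecutive groups
  (sets of 500 at full scale), and summarizes per group the nearest-gene
  expression change (protein-coding, log₂ CPM > 0), the genic-overlap
  fraction, and the distance to the nearest intergenic peak per mark.
- **Local gene-body interactions** — the mean balanced contact over all
  unordered pairs of 5 kb bins spanning a transcript, with
  condition fold changes and region-level fold-change maps.
- **Enhancer rules** — H3K27ac peaks > 2 kb from every H3K4me3-bound TSS
  are enhancers; intergenic enhancers are assigned to the genes they
  immediately flank (no intervening protein-coding gene); the most distal
  enhancer distance per gene feeds a correlation *t*-test against the
  enhancer's compartment-score change.
- **3D DNA-FISH** — Gaussian-blurred volumes (anisotropy-aware), 3D
  26-connected spot segmentation, intensity-weighted centroids in µm,
  Euclidean probe distances, and neighbor-normalized fluorescence.
- **Statistics** — exact two-sided sign test, Mood's median test with
  Benjamini–Hochberg correction, Student's *t*-tests, Kruskal–Wallis with
  Dunn's post hoc, and the correlation *t*-test
  *t = r√((n−2)/(1−r²))*, all implemented from their definitions.

## Worked example

Generate a synthetic two-condition fixture (a 20 Mb chromosome with an
A/B checkerboard, 20 enhancer-bearing target genes, 30 planted A→B
compartment flips, 2×10⁶ contact pairs per condition) and run the full
pipeline on it:

```sh
cohic simulate --outdir fixture --seed 1
cat > run.yaml <<EOF
chrom_sizes: fixture/chrom.sizes
genes: fixture/genes.tsv
expression: fixture/expression.tsv
pairs_control: fixture/pairs_control.pairs
pairs_cko: fixture/pairs_cko.pairs
peaks:
  H3K27ac: fixture/H3K27ac.bed
  H3K4me3: fixture/H3K4me3.bed
  RAD21: fixture/RAD21.bed
  CTCF: fixture/CTCF.bed
  H3K9me3: fixture/H3K9me3.bed
output_dir: bundle
group_size: 50
EOF
cohic run run.yaml
```

The run prints a JSON report; on the fixture above it ends with

```json
 "enhancer_distance_correlation": {
  "r": 0.1983586236457914,
  "t": 0.8586256802915945,
  "p": 0.40183676955695724,
  "n": 20
 },
 "gene_body_fold_change": {
  "median": 1.032979533526937,
  "sign_test_p": 0.035200200217704855,
  "n": 100
 },
 "n_enhancers": 40,
 "n_genes": 100
```

meaning: this fixture plants its 30 compartment flips uniformly across
enhancer distances, so the distance-vs-Δscore correlation over the 20
enhancer-bearing downregulated genes is rightly non-significant
(p = 0.40); the genome-wide median gene-body interaction fold change sits
near 1 because only 10 of the 100 genes are loop-depleted. `bundle/`
holds the per-bin score, Δscore and balancing-weight bedGraphs, the
ranked-group feature table, per-gene interaction scores and the enhancer
calls; the recovery experiments below plant targeted perturbations and
score them against the manifest.

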