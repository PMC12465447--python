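# Methods

This note documents the models, rules and numerical choices behind
`cohic`, what the synthetic fixtures do and do not emulate, and the design
decisions taken where more than one reasonable convention exists.

## Coordinates and intervals

All internal coordinates are 0-based half-open (BED convention); gene
tables are expected pre-converted. Distances between intervals are
unstranded nearest-edge distances: overlapping or abutting intervals are
at distance 0. Strand enters only through the TSS (the 5′ end of the gene
interval) and through the 500 bp promoter window used to exclude peaks
from "intergenic" status, which extends strand-aware upstream of the TSS.
Nearest-feature ties are broken by the smaller start coordinate. Unknown
chromosomes in BED inputs are skipped with a logged count rather than
aborting, so scaffold-containing annotations do not kill a run.

## Contact matrices and balancing

Valid pairs are canonically ordered, then filtered: intra-chromosomal
pairs closer than 1 kb are dropped (the boundary is inclusive — a
separation of exactly 1,000 bp is kept, reading "minimum distance" as the
smallest permitted value), and exact coordinate+strand duplicates are
collapsed. The filter order (short-range before duplicates) does not
affect the result for exact duplicates. Inter-chromosomal pairs are
parsed and counted but excluded from every downstream analysis, which is
intra-chromosomal throughout.

Binning increments `counts[bin1, bin2]` and its mirror; a pair with both
ends in one bin increments the diagonal once. Pooling datasets sums raw
counts; weights are always recomputed on the pooled matrix.

Balancing uses the Knight–Ruiz inner–outer Newton iteration (conjugate
gradient inner loop, adaptive inner tolerance) on the submatrix of
retained bins, pre-scaled so row sums start near 1. The target row sum is
1.0 — an arbitrary constant that simplifies observed/expected ratios. The
contract is functional, not implementation-specific: balanced row sums
within tolerance of 1, and agreement with an independent symmetric
Sinkhorn–Knopp iteration, which converges to the same unique scaling for
positive symmetric matrices. Non-convergence is flagged and logged, never
raised.

**Low-coverage mask.** Bins with zero marginal count, or a marginal below
the 2nd percentile of non-zero marginals, are masked before balancing —
but the percentile cutoff is capped at 20% of the median non-zero
marginal. A pure percentile rule removes a fixed 2% of bins whatever
their coverage; on fixtures with planted A→B flips it removed exactly the
flipped bins, which are genuinely low-contact B-like bins, not the
near-empty rows that break the Newton iteration. The cap keeps the rule's
purpose (numerical safety) without biasing biology. Both knobs are
configurable.

## Compartment scores

Raw matrices are dominated by distance decay, so compartment structure is
read from the correlation matrix of the distance-normalized map: expected
contact per diagonal offset is the mean balanced entry over unmasked
pairs at that offset; O/E divides by it; the correlation matrix is the
pairwise Pearson correlation between O/E rows over their shared
non-missing columns (pairs sharing fewer than 3 columns, and zero-variance
rows, are missing). The compartment score is the eigenvector of the
largest-magnitude eigenvalue of this matrix, computed per chromosome on
the defined submatrix, unit-normalized, and re-expanded with missing
values at masked bins.

Orientation is per chromosome: the sign is flipped when the correlation
between scores and the rank difference of H3K27ac minus H3K9me3 per-bin
coverage is negative, so A bins score positive. A flat evidence track
leaves the orientation unresolved and flagged — no silent fallback to a
second eigenvector is attempted.

Δscores subtract unit-normalized profiles (perturbed − control) over
jointly defined bins; eigenvectors are scale-free, so unit norm is the
cross-condition comparability convention. Differential ranking restricts
to control-A bins (score > 0), sorts by signed Δ ascending — the
strongest A-loss first, matching a signed sorted curve rather than |Δ| —
and chunks into consecutive groups with the remainder kept as a short
group. Ties break by (chromosome, bin index).

Per-group features: (1) mean log₂ fold change of the nearest eligible
gene — protein-coding with control log₂ CPM > 0, nearest by gene-body
edge distance (the TSS alternative would differ only for long genes);
(2) fraction of bins overlapping any gene body by ≥ 1 bp; (3) mean bin
distance to the nearest intergenic peak, where a peak survives only if it
overlaps no gene body and no strand-aware 500 bp upstream promoter
window. Interval scores (used for enhancers) are length-weighted means of
the overlapped bins' scores, excluding missing bins from the weighting.

## Local gene-body interactions

The score of a transcript is the mean balanced contact over all unordered
pairs of distinct 5 kb bins overlapping it; the diagonal is excluded by
default for multi-bin transcripts because self-bin signal dwarfs
between-bin contacts, but `include_diagonal=True` is available and
single-bin transcripts always use the diagonal. A gene's score is its
maximum-length transcript's score. Fold changes are
(cKO + ε)/(control + ε) with ε defaulting to 5% of the genome-wide median
score, stabilizing ratios at lowly covered genes. Region fold-change maps
rescale the two region submatrices to equal totals first, so a global
depth difference between conditions cancels exactly.

## Enhancer rules

An H3K4me3-bound TSS is a TSS whose ±1 kb window (a conventional promoter
half-width; configurable) overlaps an H3K4me3 peak. An enhancer is an
H3K27ac peak strictly more than 2 kb (edge distance) from every bound
TSS. Intergenic enhancers overlap no gene body. Gene assignment searches
the two intergenic regions immediately flanking the gene body, bounded by
the nearest protein-coding gene on each side; an enhancer flanked by two
genes is a candidate for both. The most-distal distance per gene is the
maximum edge-to-midpoint distance (gene body edge → enhancer midpoint),
robust to enhancer width. The distance-vs-Δscore analysis takes, per
downregulated gene, the most distal intergenic enhancer's distance and
its length-weighted Δscore, then applies the correlation t-test.
Promoter read density is coverage summed over merged H3K27ac regions that
overlap bound TSSs, per kilobase of region per million library reads.

## 3D FISH

Volumes are smoothed with a separable Gaussian whose per-axis sigma is
`sigma_um / spacing` (default 0.15 µm), so the kernel is isotropic in
physical space despite 0.3 µm optical sections against ~0.1 µm pixels.
Segmentation thresholds default to a robust background rule —
median + 5 × 1.4826 × MAD — because FISH spots occupy a vanishing voxel
fraction and a two-class threshold like Otsu then degenerates to the
background mean and merges the background into one component; Otsu and
quantile rules remain available (Otsu is sensible inside a nuclear mask,
where foreground is a meaningful fraction). Components are 26-connected;
those under 4 voxels are discarded; centroids are intensity-weighted and
reported in µm. When a channel holds more than the expected signal count
the brightest spot is used and the event logged. Probe distance is the
Euclidean centroid distance. Fluorescence normalization divides a target
cell's mean intensity by the mean of exactly three neighbor cells.

## Statistics

All tests are computed from their definitions; only the reference
distributions come from scipy. The sign test drops zero differences and
uses the exact two-sided binomial tail `min(1, 2·min(P(X≤k), P(X≥k)))`.
Mood's median test dichotomizes at the grand median ("above" vs
"not-above", ties to not-above) and uses the chi-square statistic on
(groups − 1) df; for two-group tables the Yates continuity correction is
applied by default because the uncorrected 2×2 statistic rejects at ~7%
under the null at n = 30 per group (measured at 10,000 replicates),
whereas the corrected version is conservative (~2%); multi-group tables
are uncorrected, and `continuity_correction=False` restores the raw
statistic. Expected cells below 5 are flagged. Benjamini–Hochberg is the
step-up `q_(i) = min_{j≥i} p_(j)·m/j` capped at 1 (note BH is not
idempotent — re-adjusting adjusted values inflates them — so the invariants
tested are monotonicity and domination of raw p). The t-tests use pooled
variance (unpaired) or differences (paired); Kruskal–Wallis applies the
tie correction; Dunn's z-statistics use the tie-corrected pooled-rank
variance with BH-adjusted two-sided p-values.

## Synthetic fixtures

Contact pairs are sampled from
`P(i,j) ∝ (1+|i−j|)^(−α) · (1 + κ·c_i·c_j) · L(i,j)` over 5 kb bin pairs,
with α = 1, compartment signs `c` from alternating 1 Mb A/B blocks
(κ = 0.6), and a loop factor `L` = 3 on bin pairs inside target-gene
bodies and on promoter–enhancer pairs; in the perturbed condition the
boost excess is multiplied by the depletion factor (0.5) at loop-depleted
genes. Positions are uniform within bins; 0.5% sub-1 kb pairs (and, on
multi-chromosome genomes, 0.2% inter-chromosomal pairs) are injected to
exercise the filters. Default depth is 2×10⁶ pairs over a 20 Mb
chromosome — enough for clean 25 kb compartment calls in minutes on one
core; everything scales by config.

Genes sit mostly in A blocks. Each target gene carries a downstream
intergenic enhancer cluster at edge-to-midpoint distances drawn from
20–400 kb, closed by a short *silent* protein-coding spacer gene so the
flanking-region rule assigns each cluster to exactly one target (without
the spacer, a cluster sits between two targets and the most-distal
assignment mixes neighboring clusters). Spacers have zero expression, so
the log₂ CPM > 0 eligibility rule excludes them from nearest-gene
features. H3K4me3 marks every TSS, H3K27ac marks promoters and enhancers,
RAD21 marks target promoters and ~70% of enhancers, CTCF marks block
boundaries, H3K9me3 tiles B blocks. Planted A→B flips go to 25 kb bins
containing intergenic enhancers (optionally only each gene's most distal
enhancer beyond 100 kb); flips are always control-A bins. Expression is
negative-binomial (dispersion 0.1, Poisson at 0) with means tied to the
compartment and true log₂ fold changes applied in the perturbed
condition. FISH volumes are two-channel Gaussian blobs with Poisson shot
noise at a set peak-over-noise SNR and 0.3 µm z-spacing.

What the fixtures do **not** emulate: restriction-fragment structure and
read-level Hi-C artifacts, TAD nesting and insulation boundaries beyond
the planted loops, peak-width and fragment-length structure in ChIP
tracks, expression covariates (length, GC), chromatic shift or
anisotropic PSFs in imaging. Passing the recovery experiments therefore
demonstrates correctness of the pipeline's computations and sensitivity
under the stated generative model, not performance on real sequencing
data.

## Recovery experiments and problem sizes

`cohic.experiments` (used by both `scripts/acceptance.py` and the
acceptance tests) fixes the study conditions:

- KR contract: 100 random dense positive symmetric matrices, n ≤ 50.
- Compartment/flip recovery: the default fixture above, written to disk
  and read back through the parsers end to end; recovery is the fraction
  of unmasked 25 kb bins whose oriented sign matches the manifest (both
  conditions), and the fraction of the 30 planted flips landing in the
  strongest-loss decile of the ranked A bins. Ranked groups use
  group_size 50 here — the fixture has ~400 A bins, so sets of 500 would
  collapse to one group; the 500/500/200 partition contract is tested
  separately on a 1,200-bin fixture.
- Loop depletion: 50 depleted targets (factor 0.5) among 160 genes;
  median fold change and sign-test p for depleted genes, median for the
  rest.
- Distance dependence: two chromosomes (60 target genes with one
  enhancer each need more A-compartment room than one 20 Mb chromosome
  offers), loop-free (`L ≡ 1`) so the promoter–enhancer boost cannot add
  a distance-dependent A-like signal at enhancer bins that would
  confound the pure compartment effect; flips planted at distal-only
  (> 100 kb) vs all enhancers.
- FISH: 200 random placements, separations 0.5–5 µm, SNR 5; success is a
  distance error within one voxel diagonal (≈ 0.33 µm).
- Null calibration: 10,000 replicates for the sign and Mood's tests.

## Known limitations

- The correlation-eigenvector caller assumes the leading eigenvector is
  the compartment axis; on real chromosomes with strong arm-level
  structure it can track arms instead. The orientation evidence is
  recorded so such cases are visible, but no automatic eigenvector
  selection is performed.
- Pairwise-complete correlation can produce a non-positive-semidefinite
  matrix when missingness is heavy; with the default mask this does not
  occur on the fixtures.
- The pair filter treats duplicates as exact coordinate matches; true
  PCR-duplicate detection operates at the restriction-fragment level,
  which is out of scope along with alignment and fragment assignment.
- `simulate_contacts` materializes one probability entry per intra-
  chromosomal 5 kb bin pair, so memory grows quadratically with
  chromosome length; ~100 Mb per chromosome is a practical ceiling at
  the default bin size.
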