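"""Per-transcript local gene-body interaction statistics at 5 Kb resolution.

The gene-body interaction score of a transcript is the mean balanced Hi-C
contact over all unordered pairs of distinct 5 Kb bins spanning the
transcript (single-bin transcripts fall back to the diagonal entry).
Condition fold changes and region-level fold-change maps support
promoter-enhancer views.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .contacts import ContactMatrix
from .genome import GenomicInterval


@dataclass
class GeneInteractionScore:
    transcript_id: str
    n_bins: int
    score: float  # NaN when all constituent bin pairs are masked
    condition: str = ""


def gene_body_interaction(
    matrix: ContactMatrix,
    transcript: GenomicInterval,
    transcript_id: str = "",
    condition: str = "",
    include_diagonal: bool = False,
) -> GeneInteractionScore:
    """Mean balanced interaction among the 5 Kb bins spanning a transcript.

    Bins spanning the transcript are all bins overlapping [start, end). The
    score averages balanced entries over unordered distinct bin pairs
    (i < j); with ``include_diagonal`` the diagonal entries join the mean.
    Single-bin transcripts always use the diagonal entry. Masked pairs are
    excluded; if every pair is masked the score is NaN.
    """
    if transcript.chrom != matrix.chrom:
        raise ValueError(f"transcript on {transcript.chrom}, matrix is {matrix.chrom}")
    bins = list(matrix.grid.bins_overlapping(transcript))
    sub = matrix.balanced_submatrix(bins[0], bins[-1] + 1)
    k = len(bins)
    if k == 1:
        vals = np.array([sub[0, 0]])
    else:
        pairs = [(i, j) for i, j in combinations(range(k), 2)]
        vals = np.array([sub[i, j] for i, j in pairs])
        if include_diagonal:
            vals = np.concatenate([vals, np.diagonal(sub)])
    vals = vals[np.isfinite(vals)]
    score = float(vals.mean()) if vals.size else np.nan
    return GeneInteractionScore(transcript_id, k, score, condition)


def interaction_fold_change(
    score_cko: GeneInteractionScore | float,
    score_ctrl: GeneInteractionScore | float,
    pseudocount: float = 0.0,
) -> float:
    """(cko + pseudocount) / (ctrl + pseudocount); NaN if either is missing."""
    a = score_cko.score if isinstance(score_cko, GeneInteractionScore) else score_cko
    b = score_ctrl.score if isinstance(score_ctrl, GeneInteractionScore) else score_ctrl
    if not (np.isfinite(a) and np.isfinite(b)):
        return np.nan
    denom = b + pseudocount
    if denom == 0:
        return np.nan
    return (a + pseudocount) / denom


def gene_level_score(matrix: ContactMatrix, gene, **kwargs) -> GeneInteractionScore:
    """A gene's score: its maximum-length transcript's score.

    Falls back to the gene body interval when no transcripts are annotated.
    """
    candidates = list(gene.transcripts) or [gene.interval]
    longest = max(candidates, key=len)
    return gene_body_interaction(matrix, longest, transcript_id=gene.id, **kwargs)


def default_pseudocount(scores: np.ndarray, fraction: float = 0.05) -> float:
    """5% of the genome-wide median gene score (ratio stabilizer)."""
    scores = np.asarray(scores, float)
    scores = scores[np.isfinite(scores)]
    if scores.size == 0:
        return 0.0
    return fraction * float(np.median(scores))


def submatrix_fold_change_map(
    matrix_a: ContactMatrix,
    matrix_b: ContactMatrix,
    region: GenomicInterval,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Entry-wise balanced fold-change map (b/a) over a region's bin range.

    Before the ratio, each matrix's region submatrix is scaled so their
    total signals match (removes residual depth differences between
    conditions). Masked entries are NaN.
    """
    if matrix_a.grid.bin_size != matrix_b.grid.bin_size:
        raise ValueError("matrices must share bin size")
    bins = list(matrix_a.grid.bins_overlapping(region))
    lo, hi = bins[0], bins[-1] + 1
    a = matrix_a.balanced_submatrix(lo, hi)
    b = matrix_b.balanced_submatrix(lo, hi)
    ok = np.isfinite(a) & np.isfinite(b)
    sa = a[ok].sum()
    sb = b[ok].sum()
    if sa > 0 and sb > 0:
        mean_total = 0.5 * (sa + sb)
        a = a * (mean_total / sa)
        b = b * (mean_total / sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (b + pseudocount) / (a + pseudocount)
    fc[~np.isfinite(fc)] = np.nan
    return fc
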