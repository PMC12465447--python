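"""A/B compartment scoring and differential-compartment feature analysis.

Compartment scores are the first eigenvector (largest-magnitude eigenvalue)
of the per-chromosome Hi-C correlation matrix, oriented so that bins
enriched for the active mark H3K27ac and depleted of the repressive mark
H3K9me3 score positive (A compartment); negative bins are B. Differential
analysis restricts to control A bins, ranks them by the signed change in
score after perturbation, chunks the ranking into consecutive groups, and
summarizes genomic features (nearest-gene expression change, genic overlap,
distance to intergenic peaks) per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .genome import BinGrid, Gene, GenomicInterval, PeakSet, interval_distance, nearest_feature

logger = logging.getLogger(__name__)


@dataclass
class CompartmentProfile:
    """Oriented per-bin eigenvector scores for one chromosome.

    Positive scores are A (active), negative B (repressive). NaN marks bins
    excluded by the balancing mask. ``orientation_evidence`` is the
    correlation between scores and the active-minus-repressive mark signal
    after orientation (non-negative unless orientation was unresolved).
    """

    grid: BinGrid
    chrom: str
    scores: np.ndarray
    orientation_evidence: float = np.nan
    orientation_resolved: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.scores)

    def a_bins(self) -> np.ndarray:
        return np.where(np.nan_to_num(self.scores) > 0)[0]


def compartment_eigenvector(corr: np.ndarray, min_bins: int = 3) -> np.ndarray:
    """Leading eigenvector of a correlation matrix with missing rows.

    The eigenvector of the largest-magnitude eigenvalue is computed on the
    submatrix of defined rows, unit-normalized, and re-expanded with NaN at
    missing bins. Overall sign is arbitrary here; see orient_eigenvector.
    Returns an all-NaN vector if fewer than ``min_bins`` rows are defined.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    ok = np.isfinite(np.diagonal(corr))
    out = np.full(n, np.nan)
    if ok.sum() < min_bins:
        logger.warning("correlation matrix has < %d defined bins; no eigenvector", min_bins)
        return out
    sub = corr[np.ix_(ok, ok)]
    # residual NaN inside defined rows (rare pairwise dropouts) -> neutral 0
    sub = np.where(np.isfinite(sub), sub, 0.0)
    sub = 0.5 * (sub + sub.T)
    evals, evecs = scipy.linalg.eigh(sub)
    lead = np.argmax(np.abs(evals))
    v = evecs[:, lead]
    out[ok] = v / np.linalg.norm(v)
    return out


def _track_evidence(active: np.ndarray, repressive: np.ndarray) -> np.ndarray:
    """Rank-difference evidence track: high where active mark dominates."""
    a = pd.Series(active).rank().to_numpy()
    r = pd.Series(repressive).rank().to_numpy()
    return a - r


def orient_eigenvector(
    scores: np.ndarray,
    grid: BinGrid,
    chrom: str,
    active_track: np.ndarray,
    repressive_track: np.ndarray,
) -> CompartmentProfile:
    """Fix the eigenvector sign so active-mark-rich bins are positive (A).

    The global per-chromosome sign is flipped when the correlation between
    scores and the rank difference (active - repressive density) is
    negative. Zero-variance evidence leaves the sign unresolved (flagged).
    """
    scores = np.asarray(scores, dtype=float).copy()
    evidence = _track_evidence(np.asarray(active_track, float), np.asarray(repressive_track, float))
    ok = np.isfinite(scores)
    resolved = True
    corr = np.nan
    if ok.sum() >= 3 and np.std(evidence[ok]) > 0 and np.std(scores[ok]) > 0:
        corr = float(np.corrcoef(scores[ok], evidence[ok])[0, 1])
        if corr < 0:
            scores = -scores
            corr = -corr
    else:
        resolved = False
        logger.warning("orientation unresolved for %s (flat evidence track)", chrom)
    return CompartmentProfile(grid, chrom, scores, orientation_evidence=corr,
                              orientation_resolved=resolved)


def delta_scores(control: CompartmentProfile, perturbed: CompartmentProfile) -> np.ndarray:
    """Per-bin score change (perturbed - control) between oriented profiles.

    Each profile is unit-normalized over the bins defined in both before
    subtraction, making the difference scale-free. NaN where either is NaN.
    """
    if control.chrom != perturbed.chrom or control.grid.bin_size != perturbed.grid.bin_size:
        raise ValueError("profiles must share chromosome and grid")
    a = np.asarray(control.scores, float)
    b = np.asarray(perturbed.scores, float)
    ok = np.isfinite(a) & np.isfinite(b)
    out = np.full(len(a), np.nan)
    if not ok.any():
        return out
    na = np.linalg.norm(a[ok])
    nb = np.linalg.norm(b[ok])
    if na == 0 or nb == 0:
        return out
    out[ok] = b[ok] / nb - a[ok] / na
    return out


@dataclass
class RankedBinGroups:
    """Control-A bins ranked by signed score change, chunked into groups.

    ``bins`` is a DataFrame with columns (chrom, bin, delta) sorted most
    negative first; ``group_of`` assigns each row to a consecutive group of
    ``group_size`` (final remainder kept as a short group).
    """

    bins: pd.DataFrame
    group_size: int

    @property
    def n_groups(self) -> int:
        if len(self.bins) == 0:
            return 0
        return int(np.ceil(len(self.bins) / self.group_size))

    @property
    def group_of(self) -> np.ndarray:
        return np.arange(len(self.bins)) // self.group_size

    def group_sizes(self) -> list[int]:
        return [int(c) for c in np.bincount(self.group_of, minlength=self.n_groups)] \
            if len(self.bins) else []

    def bin_intervals(self, grid_lookup) -> list[GenomicInterval]:
        return [grid_lookup(row.chrom).bin_interval(row.chrom, row.bin)
                for row in self.bins.itertuples(index=False)]


def rank_and_group(
    deltas: dict[str, np.ndarray],
    control_profiles: dict[str, CompartmentProfile],
    group_size: int = 500,
) -> RankedBinGroups:
    """Rank control-A bins by signed delta-score, most negative first.

    ``deltas`` and ``control_profiles`` are keyed by chromosome. Bins with a
    missing score in either condition are excluded. Ties in delta are broken
    by (chrom, bin index).
    """
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    records = []
    for chrom in control_profiles:
        prof = control_profiles[chrom]
        delta = deltas[chrom]
        for i in prof.a_bins():
            if np.isfinite(delta[i]):
                records.append((chrom, int(i), float(delta[i])))
    df = pd.DataFrame(records, columns=["chrom", "bin", "delta"])
    df = df.sort_values(["delta", "chrom", "bin"], kind="mergesort").reset_index(drop=True)
    return RankedBinGroups(df, group_size)


def _bin_interval(grid: BinGrid, chrom: str, i: int) -> GenomicInterval:
    return grid.bin_interval(chrom, i)


def group_feature_expression(
    groups: RankedBinGroups,
    grid: BinGrid,
    genes: Sequence[Gene],
    log2fc: dict[str, float],
    control_log2cpm: dict[str, float],
) -> np.ndarray:
    """Per-group mean log2 fold change of the nearest eligible gene.

    Eligible genes are protein-coding with control log2 CPM > 0. Bins with
    no eligible gene on their chromosome are excluded from the group mean.
    """
    eligible = [g for g in genes
                if g.biotype == "protein_coding" and control_log2cpm.get(g.id, -np.inf) > 0]
    by_chrom: dict[str, list[Gene]] = {}
    for g in eligible:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.interval.start)
    values = np.full(len(groups.bins), np.nan)
    for idx, row in enumerate(groups.bins.itertuples(index=False)):
        feats = by_chrom.get(row.chrom, [])
        if not feats:
            continue
        q = _bin_interval(grid, row.chrom, row.bin)
        gene, _ = nearest_feature(q, feats, interval_of=lambda g: g.interval)
        if gene is not None:
            values[idx] = log2fc.get(gene.id, np.nan)
    return _group_means(values, groups)


def group_feature_genic_fraction(
    groups: RankedBinGroups, grid: BinGrid, genes: Sequence[Gene]
) -> np.ndarray:
    """Per-group fraction of bins overlapping any gene body (>= 1 bp)."""
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    overlap = np.zeros(len(groups.bins))
    for idx, row in enumerate(groups.bins.itertuples(index=False)):
        q = _bin_interval(grid, row.chrom, row.bin)
        overlap[idx] = float(any(q.overlaps(g.interval) for g in by_chrom.get(row.chrom, [])))
    return _group_means(overlap, groups)


def intergenic_peak_filter(
    peaks: PeakSet, genes: Sequence[Gene], promoter_upstream_bp: int = 500
) -> PeakSet:
    """Peaks overlapping no gene body and no strand-aware 500 bp upstream promoter window."""
    windows: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        windows.setdefault(g.chrom, []).append(g.interval)
        windows.setdefault(g.chrom, []).append(g.promoter_upstream(promoter_upstream_bp))

    def survives(p: GenomicInterval) -> bool:
        return not any(p.overlaps(w) for w in windows.get(p.chrom, []))

    return peaks.filter(survives)


def group_feature_peak_distance(
    groups: RankedBinGroups,
    grid: BinGrid,
    peaks: PeakSet,
    genes: Sequence[Gene],
    promoter_upstream_bp: int = 500,
) -> np.ndarray:
    """Per-group mean bin-edge distance to the nearest surviving intergenic peak.

    Peaks overlapping gene bodies or promoter windows are removed first; bins
    on chromosomes with no surviving peak are excluded from the group mean.
    """
    surviving = intergenic_peak_filter(peaks, genes, promoter_upstream_bp)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in surviving:
        by_chrom.setdefault(p.chrom, []).append(p)
    values = np.full(len(groups.bins), np.nan)
    for idx, row in enumerate(groups.bins.itertuples(index=False)):
        feats = by_chrom.get(row.chrom, [])
        if not feats:
            continue
        q = _bin_interval(grid, row.chrom, row.bin)
        _, d = nearest_feature(q, feats)
        values[idx] = d
    return _group_means(values, groups)


def _group_means(values: np.ndarray, groups: RankedBinGroups) -> np.ndarray:
    out = np.full(groups.n_groups, np.nan)
    gof = groups.group_of
    for g in range(groups.n_groups):
        v = values[gof == g]
        v = v[np.isfinite(v)]
        if v.size:
            out[g] = v.mean()
    return out


def score_at_intervals(
    profile: CompartmentProfile, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Length-weighted mean compartment score over the bins each interval overlaps.

    Missing bins are excluded from the weighting; an interval covered only
    by missing bins scores NaN. Works for score or delta-score vectors alike.
    """
    grid = profile.grid
    out = np.full(len(intervals), np.nan)
    for k, iv in enumerate(intervals):
        if iv.chrom != profile.chrom:
            raise ValueError(f"interval on {iv.chrom}, profile is {profile.chrom}")
        total_w = 0.0
        total = 0.0
        for i in grid.bins_overlapping(iv):
            s = profile.scores[i]
            if not np.isfinite(s):
                continue
            b = grid.bin_interval(iv.chrom, i)
            w = min(iv.end, b.end) - max(iv.start, b.start)
            total += w * s
            total_w += w
        if total_w > 0:
            out[k] = total / total_w
    return out
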