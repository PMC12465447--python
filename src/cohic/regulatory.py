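"""Enhancer classification and intergenic enhancer-gene assignment.

Enhancers are H3K27ac peaks more than 2 Kb (edge distance, strict) from
every H3K4me3-bound TSS; a TSS counts as H3K4me3-bound when its +/- 1 Kb
window overlaps an H3K4me3 peak. An enhancer is intergenic when it overlaps
no gene body. Gene-level assignment considers only intergenic regions
immediately flanking a gene, with no intervening protein-coding gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compartments import CompartmentProfile, score_at_intervals
from .genome import Gene, GenomicInterval, PeakSet, interval_distance
from .stats import correlation_t_test, TestResult

logger = logging.getLogger(__name__)

ENHANCER_MIN_TSS_DISTANCE = 2000  # bp, strict inequality
TSS_WINDOW_BP = 1000  # half-width of the H3K4me3-bound TSS window


@dataclass
class EnhancerCall:
    interval: GenomicInterval
    distance_to_nearest_active_tss: float  # inf when no bound TSS exists
    is_intergenic: bool
    flanking_gene_ids: tuple[str, ...] = ()


def _bound_tss_windows(
    h3k4me3: PeakSet, genes: Sequence[Gene], window_bp: int = TSS_WINDOW_BP
) -> list[GenomicInterval]:
    """TSS points (as 1 bp intervals) whose +/- window overlaps an H3K4me3 peak."""
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in h3k4me3:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    bound = []
    for g in genes:
        win = GenomicInterval(g.chrom, max(0, g.tss - window_bp), g.tss + window_bp + 1)
        if any(win.overlaps(p) for p in peaks_by_chrom.get(g.chrom, [])):
            bound.append(GenomicInterval(g.chrom, g.tss, g.tss + 1))
    return bound


def classify_enhancers(
    h3k27ac: PeakSet,
    h3k4me3: PeakSet,
    genes: Sequence[Gene],
    min_tss_distance: int = ENHANCER_MIN_TSS_DISTANCE,
    tss_window_bp: int = TSS_WINDOW_BP,
) -> list[EnhancerCall]:
    """H3K27ac peaks > ``min_tss_distance`` bp from every H3K4me3-bound TSS."""
    bound_tss = _bound_tss_windows(h3k4me3, genes, tss_window_bp)
    if not bound_tss:
        logger.warning("no H3K4me3-bound TSSs; every H3K27ac peak classifies as enhancer")
    tss_by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in bound_tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    bodies_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        bodies_by_chrom.setdefault(g.chrom, []).append(g.interval)
    calls = []
    for peak in h3k27ac:
        tss_list = tss_by_chrom.get(peak.chrom, [])
        d = min((interval_distance(peak, t) for t in tss_list), default=np.inf)
        if d > min_tss_distance:
            intergenic = not any(peak.overlaps(b) for b in bodies_by_chrom.get(peak.chrom, []))
            calls.append(EnhancerCall(peak, float(d), intergenic))
    return calls


def intergenic_enhancers_for_gene(
    gene: Gene, enhancers: Sequence[EnhancerCall], genes: Sequence[Gene]
) -> list[EnhancerCall]:
    """Intergenic enhancers in the regions immediately flanking ``gene``.

    On each side the search region extends from the gene body to the nearest
    protein-coding gene body (or the chromosome end if none); enhancers
    beyond an intervening protein-coding gene are thereby excluded.
    """
    left_bound = -np.inf
    right_bound = np.inf
    for other in genes:
        if other.id == gene.id or other.chrom != gene.chrom:
            continue
        if other.biotype != "protein_coding":
            continue
        if other.interval.end <= gene.interval.start:
            left_bound = max(left_bound, other.interval.end)
        elif other.interval.start >= gene.interval.end:
            right_bound = min(right_bound, other.interval.start)
    out = []
    for call in enhancers:
        iv = call.interval
        if not call.is_intergenic or iv.chrom != gene.chrom:
            continue
        in_left = left_bound <= iv.start and iv.end <= gene.interval.start
        in_right = gene.interval.end <= iv.start and iv.end <= right_bound
        if in_left or in_right:
            out.append(call)
    return out


def most_distal_enhancer_distance(gene: Gene, enhancers: Sequence[EnhancerCall]) -> float:
    """Max edge distance from the gene body to assigned enhancer midpoints (bp).

    NaN when the gene has no intergenic enhancers.
    """
    best = np.nan
    for call in enhancers:
        mid = int(call.interval.midpoint)
        body = gene.interval
        d = max(body.start - mid, mid - (body.end - 1), 0)
        if not np.isfinite(best) or d > best:
            best = float(d)
    return best


def promoter_regions(
    h3k27ac_early: PeakSet, h3k27ac_late: PeakSet, h3k4me3: PeakSet, genes: Sequence[Gene]
) -> list[GenomicInterval]:
    """Merged H3K27ac peaks (two stages) that overlap an H3K4me3-bound TSS."""
    from .genome import merge_peaks

    merged = merge_peaks(h3k27ac_early, h3k27ac_late)
    bound_tss = _bound_tss_windows(h3k4me3, genes)
    tss_by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in bound_tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    return [p for p in merged
            if any(p.overlaps(t) for t in tss_by_chrom.get(p.chrom, []))]


def promoter_density(
    coverage: dict[str, np.ndarray],
    regions: Sequence[GenomicInterval],
    library_size: float,
) -> np.ndarray:
    """Library-normalized read density per region: reads per Kb per million.

    ``coverage`` maps chromosome -> per-base read coverage. density =
    sum(coverage over region) * 1e9 / (library_size * region length in bp),
    i.e. coverage summed, per kilobase of region, per million reads.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    out = np.full(len(regions), np.nan)
    for k, r in enumerate(regions):
        track = coverage.get(r.chrom)
        if track is None:
            continue
        total = float(track[r.start:r.end].sum())
        out[k] = total * 1e9 / (len(r) * library_size)
    return out


def enhancer_distance_vs_delta_score(
    genes_down: Sequence[Gene],
    enhancers: Sequence[EnhancerCall],
    genes: Sequence[Gene],
    delta_profiles: dict[str, CompartmentProfile],
) -> tuple[list[dict], float, TestResult]:
    """Per-gene distal-enhancer distance vs the enhancer's compartment-score change.

    For each downregulated gene, takes its most distal intergenic enhancer
    (distance gene body edge -> enhancer midpoint) and the delta-score of
    that enhancer (length-weighted over overlapping bins), then tests the
    Pearson correlation across genes with the correlation t-test.
    """
    records = []
    for gene in genes_down:
        mine = intergenic_enhancers_for_gene(gene, enhancers, genes)
        if not mine:
            continue
        dist = most_distal_enhancer_distance(gene, mine)
        distal = max(
            mine,
            key=lambda c: max(gene.interval.start - int(c.interval.midpoint),
                              int(c.interval.midpoint) - (gene.interval.end - 1), 0),
        )
        prof = delta_profiles.get(gene.chrom)
        if prof is None:
            continue
        dscore = score_at_intervals(prof, [distal.interval])[0]
        if np.isfinite(dscore):
            records.append({"gene_id": gene.id, "distance_bp": dist, "delta_score": float(dscore)})
    if len(records) < 3:
        logger.warning("fewer than 3 usable genes; correlation undefined")
        return records, np.nan, TestResult(np.nan, np.nan, len(records), "correlation-t",
                                           notes="insufficient n")
    x = np.array([r["distance_bp"] for r in records])
    y = np.array([r["delta_score"] for r in records])
    result = correlation_t_test(x, y)
    return records, result.statistic_extra.get("r", np.nan), result
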