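"""Configuration-driven orchestration of the full analysis.

Stages: pair filtering -> binning -> pooling -> KR balancing -> compartment
scoring -> differential-compartment feature groups -> local gene-body
interactions -> enhancer classification and distal-enhancer statistics ->
report. All randomness is seeded through the config; reruns on identical
inputs produce byte-identical tables.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as comp
from . import contacts as ct
from . import local_interactions as li
from . import regulatory as reg
from . import stats as st
from .genome import (BinGrid, Gene, PeakSet, peak_coverage_track, read_bed,
                     read_chrom_sizes, read_gene_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run."""

    chrom_sizes: str = ""
    genes: str = ""
    expression: str = ""
    pairs_control: str = ""
    pairs_cko: str = ""
    peaks: dict = field(default_factory=dict)   # mark -> BED path
    output_dir: str = "cohic_out"

    bin_size_local: int = 5_000
    bin_size_compartment: int = 25_000
    group_size: int = 500
    min_pair_distance: int = 1_000
    enhancer_min_tss_distance: int = 2_000
    tss_window_bp: int = 1_000
    promoter_upstream_bp: int = 500
    pseudocount_fraction: float = 0.05
    mask_percentile: float = 2.0
    seed: int = 0

    _PATH_FIELDS = ("chrom_sizes", "genes", "expression", "pairs_control", "pairs_cko")
    _POSITIVE_FIELDS = ("bin_size_local", "bin_size_compartment", "group_size",
                        "min_pair_distance", "enhancer_min_tss_distance",
                        "tss_window_bp", "promoter_upstream_bp")


def validate_config(path) -> tuple[RunConfig | None, list[str]]:
    """Load and validate a YAML run config; all errors reported at once."""
    errors: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except Exception as exc:  # noqa: BLE001 - surfaced as a validation error
        return None, [f"cannot parse {path}: {exc}"]
    known = {f.name for f in dc_fields(RunConfig) if not f.name.startswith("_")}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r}{suggestion}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    for name in RunConfig._POSITIVE_FIELDS:
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive, got {getattr(cfg, name)}")
    for name in RunConfig._PATH_FIELDS:
        p = getattr(cfg, name)
        if not p:
            errors.append(f"missing required path: {name}")
        elif not Path(p).exists():
            errors.append(f"{name}: file not found: {p}")
    for mark, p in (cfg.peaks or {}).items():
        if not Path(p).exists():
            errors.append(f"peaks[{mark}]: file not found: {p}")
    if errors:
        return None, errors
    return cfg, []


def balanced_matrices(
    pairs_path, grid: BinGrid, min_pair_distance: int = 1_000,
    mask_percentile: float = 2.0,
) -> tuple[dict[str, ct.ContactMatrix], dict]:
    """Read, filter, bin and KR-balance one pairs file on a grid."""
    pairs = ct.read_pairs(pairs_path, grid.chrom_sizes)
    kept, filt_report = ct.filter_pairs(pairs, min_pair_distance)
    matrices, bin_report = ct.bin_pairs(kept, grid)
    for m in matrices.values():
        ct.kr_balance(m, mask_percentile=mask_percentile)
    report = {**filt_report.as_dict(), **bin_report}
    return matrices, report


def call_compartments(
    matrix: ct.ContactMatrix, h3k27ac: PeakSet, h3k9me3: PeakSet
) -> comp.CompartmentProfile:
    """Balanced matrix -> O/E -> correlation -> oriented eigenvector profile."""
    oe = ct.observed_over_expected(matrix)
    corr = ct.correlation_matrix(oe)
    scores = comp.compartment_eigenvector(corr)
    active = peak_coverage_track(h3k27ac, matrix.grid, matrix.chrom)
    repressive = peak_coverage_track(h3k9me3, matrix.grid, matrix.chrom)
    return comp.orient_eigenvector(scores, matrix.grid, matrix.chrom, active, repressive)


def write_bedgraph(path, grid: BinGrid, chrom: str, values: np.ndarray) -> None:
    with open(path, "wt") as fh:
        for i, v in enumerate(values):
            if np.isfinite(v):
                b = grid.bin_interval(chrom, i)
                fh.write(f"{chrom}\t{b.start}\t{b.end}\t{v:.6g}\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the output bundle; returns the report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "seed": cfg.seed}

    def stage(name):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("load-annotations")
        sizes = read_chrom_sizes(cfg.chrom_sizes)
        genes = read_gene_table(cfg.genes)
        peaks = {mark: read_bed(path, mark, sizes) for mark, path in cfg.peaks.items()}
        expr = pd.read_csv(cfg.expression, sep="\t")
        log2fc = dict(zip(expr["gene_id"], expr["log2fc"]))
        log2cpm = dict(zip(expr["gene_id"], expr["log2cpm_control"]))

        stage("contacts")
        grid5 = BinGrid(cfg.bin_size_local, sizes)
        grid25 = BinGrid(cfg.bin_size_compartment, sizes)
        mats = {}
        for cond, path in ((ct_lbl, p) for ct_lbl, p in
                           (("control", cfg.pairs_control), ("cko", cfg.pairs_cko))):
            pairs = list(ct.read_pairs(path, sizes))
            kept, filt = ct.filter_pairs(pairs, cfg.min_pair_distance)
            report[f"filter_{cond}"] = filt.as_dict()
            m5, _ = ct.bin_pairs(kept, grid5)
            m25, inter = ct.bin_pairs(kept, grid25)
            report[f"bin_{cond}"] = inter
            for m in list(m5.values()) + list(m25.values()):
                ct.kr_balance(m, mask_percentile=cfg.mask_percentile)
            mats[cond] = {"5k": m5, "25k": m25}

        stage("compartments")
        profiles = {cond: {} for cond in mats}
        deltas = {}
        for chrom in sizes:
            for cond in mats:
                profiles[cond][chrom] = call_compartments(
                    mats[cond]["25k"][chrom], peaks["H3K27ac"], peaks["H3K9me3"])
            deltas[chrom] = comp.delta_scores(profiles["control"][chrom],
                                              profiles["cko"][chrom])
            write_bedgraph(out / f"scores_control_{chrom}.bedGraph", grid25, chrom,
                           profiles["control"][chrom].scores)
            write_bedgraph(out / f"delta_scores_{chrom}.bedGraph", grid25, chrom,
                           deltas[chrom])
            write_bedgraph(out / f"weights_control_{chrom}.bedGraph", grid25, chrom,
                           mats["control"]["25k"][chrom].weights)

        stage("rank-and-group")
        groups = comp.rank_and_group(deltas, profiles["control"], cfg.group_size)
        gdf = pd.DataFrame({
            "group": np.arange(groups.n_groups),
            "n_bins": groups.group_sizes(),
            "mean_delta": comp._group_means(groups.bins["delta"].to_numpy(), groups),
            "mean_nearest_gene_log2fc": comp.group_feature_expression(
                groups, grid25, genes, log2fc, log2cpm),
            "genic_fraction": comp.group_feature_genic_fraction(groups, grid25, genes),
        })
        for mark in ("H3K27ac", "RAD21", "CTCF"):
            if mark in peaks:
                gdf[f"dist_{mark}"] = comp.group_feature_peak_distance(
                    groups, grid25, peaks[mark], genes, cfg.promoter_upstream_bp)
        gdf.to_csv(out / "ranked_groups.tsv", sep="\t", index=False)

        stage("local-interactions")
        rows = []
        for g in genes:
            s_ctrl = li.gene_body_interaction(mats["control"]["5k"][g.chrom],
                                              g.interval, g.id, "control")
            s_cko = li.gene_body_interaction(mats["cko"]["5k"][g.chrom],
                                             g.interval, g.id, "cko")
            rows.append({"transcript_id": g.id, "gene_id": g.id, "n_bins": s_ctrl.n_bins,
                         "score_ctrl": s_ctrl.score, "score_cko": s_cko.score})
        sc = pd.DataFrame(rows)
        pseudo = li.default_pseudocount(sc["score_ctrl"].to_numpy(),
                                        cfg.pseudocount_fraction)
        sc["fold_change"] = [
            li.interaction_fold_change(a, b, pseudo)
            for a, b in zip(sc["score_cko"], sc["score_ctrl"])
        ]
        sc.to_csv(out / "gene_body_interactions.tsv", sep="\t", index=False)

        stage("enhancers")
        calls = reg.classify_enhancers(peaks["H3K27ac"], peaks["H3K4me3"], genes,
                                       cfg.enhancer_min_tss_distance, cfg.tss_window_bp)
        with open(out / "enhancers.bed", "wt") as fh:
            for c in calls:
                label = "intergenic" if c.is_intergenic else "genic"
                fh.write(f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                         f"\t{label}\t{c.distance_to_nearest_active_tss:g}\n")
        down = [g for g in genes if log2fc.get(g.id, 0) < 0 and g.biotype == "protein_coding"]
        delta_profiles = {
            chrom: comp.CompartmentProfile(grid25, chrom, deltas[chrom])
            for chrom in sizes
        }
        records, r, tres = reg.enhancer_distance_vs_delta_score(
            down, calls, genes, delta_profiles)
        pd.DataFrame(records).to_csv(out / "distal_enhancer_records.tsv",
                                     sep="\t", index=False)
        report["enhancer_distance_correlation"] = {
            "r": r, "t": tres.statistic, "p": tres.p_value, "n": tres.n_effective}

        stage("stats")
        fc = sc["fold_change"].to_numpy()
        fc = fc[np.isfinite(fc)]
        sign = st.sign_test(fc - 1.0)
        report["gene_body_fold_change"] = {
            "median": float(np.median(fc)) if fc.size else np.nan,
            "sign_test_p": sign.p_value, "n": sign.n_effective}
        report["n_enhancers"] = len(calls)
        report["n_genes"] = len(genes)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
        return report
    except Exception:
        report["failed_stage"] = report["stages"][-1] if report["stages"] else "init"
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
        raise
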