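"""Canned synthetic recovery experiments.

Each experiment generates a fixture with the synthetic module, runs the
relevant pipeline stages from scratch, and scores the result against the
fixture's TruthManifest. These are the package's standard self-checks:
the acceptance script and the acceptance test suite both call them.

Problem sizes are desk-scale (a 20 Mb chromosome, ~2 x 10^6 contact
pairs) so a full run takes minutes; every size is set by the
SyntheticConfig the experiment builds and can be scaled up.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import compartments as comp
from . import contacts as ct
from . import local_interactions as li
from .fish3d import measure_probe_distance, Spot, spot_distance
from .genome import BinGrid, read_bed, read_chrom_sizes, read_gene_table
from .pipeline import call_compartments
from .regulatory import classify_enhancers, enhancer_distance_vs_delta_score
from .stats import moods_median_test, sign_test
from .synthetic import (CKO, CONTROL, SyntheticConfig, TruthManifest,
                        simulate_annotation, simulate_contacts,
                        simulate_dataset, simulate_fish_volume)


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1_000 + k) % (2 ** 31 - 1))


def kr_balancing_contract(seed: int = 0, n_matrices: int = 100) -> dict:
    """Row-sum and Sinkhorn-oracle agreement on random positive matrices."""
    rng = np.random.default_rng(seed)
    import scipy.sparse as sp

    max_rowsum_dev = 0.0
    max_oracle_dev = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(3, 51))
        dense = rng.uniform(0.1, 1.0, (n, n))
        dense = dense + dense.T
        grid = BinGrid(1, {"chrS": n})
        m = ct.ContactMatrix(grid, "chrS", sp.csr_matrix(dense))
        w = ct.kr_balance(m, tol=1e-10, mask_percentile=0)
        rs = np.nansum(m.balanced_dense(), axis=1)
        max_rowsum_dev = max(max_rowsum_dev, float(np.max(np.abs(rs - 1))))
        x = np.ones(n)
        for _ in range(200_000):
            s = x * (dense @ x)
            if np.max(np.abs(s - 1)) < 1e-12:
                break
            x = x / np.sqrt(s)
        max_oracle_dev = max(max_oracle_dev, float(np.max(np.abs(w - x))))
    return {"max_rowsum_dev": max_rowsum_dev,
            "max_sinkhorn_dev": max_oracle_dev,
            "n_matrices": n_matrices}


def _profiles_for_dataset(outdir, group_size: int = 50):
    """Run the compartment stages on an on-disk fixture; returns everything."""
    outdir = Path(outdir)
    sizes = read_chrom_sizes(outdir / "chrom.sizes")
    genes = read_gene_table(outdir / "genes.tsv")
    peaks = {m: read_bed(outdir / f"{m}.bed", m, sizes)
             for m in ("H3K27ac", "H3K4me3", "RAD21", "CTCF", "H3K9me3")}
    grid25 = BinGrid(25_000, sizes)
    profiles = {}
    for cond in (CONTROL, CKO):
        table = ct.read_pairs_table(outdir / f"pairs_{cond}.pairs", sizes)
        kept, _ = ct.filter_pairs_table(table)
        mats, _ = ct.bin_pairs_table(kept, grid25)
        profiles[cond] = {}
        for chrom, m in mats.items():
            ct.kr_balance(m)
            profiles[cond][chrom] = call_compartments(m, peaks["H3K27ac"],
                                                      peaks["H3K9me3"])
    deltas = {chrom: comp.delta_scores(profiles[CONTROL][chrom],
                                       profiles[CKO][chrom])
              for chrom in sizes}
    groups = comp.rank_and_group(deltas, profiles[CONTROL], group_size)
    return sizes, genes, peaks, grid25, profiles, deltas, groups


def compartment_and_flip_recovery(seed: int = 0, workdir=None) -> dict:
    """End-to-end run on the default fixture, scored against the manifest.

    Writes the fixture to disk and reads it back through the parsers, so the
    whole pipeline surface is exercised. Reports oriented-sign recovery per
    condition, the fraction of planted flips in the strongest-loss decile of
    the ranked A bins, and the per-mark peak-distance contrast between the
    strongest-loss group and the all-group mean.
    """
    cfg = SyntheticConfig()
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    outdir = Path(ctx.name if ctx else workdir)
    try:
        manifest = simulate_dataset(cfg, outdir, seed=_sub_seed(seed, 1))
        sizes, genes, peaks, grid25, profiles, deltas, groups = \
            _profiles_for_dataset(outdir)
        recovery = {}
        for cond in (CONTROL, CKO):
            agree = total = 0
            for chrom in sizes:
                scores = profiles[cond][chrom].scores
                truth = manifest.signs(chrom, cond)
                ok = np.isfinite(scores)
                agree += int((np.sign(scores[ok]) == truth[ok]).sum())
                total += int(ok.sum())
            recovery[cond] = 100.0 * agree / total
        n_decile = int(np.ceil(len(groups.bins) / 10))
        decile = set(zip(groups.bins["chrom"][:n_decile],
                         groups.bins["bin"][:n_decile]))
        flips = set(map(tuple, manifest.flipped_bins))
        flip_pct = 100.0 * len(flips & decile) / len(flips)
        dist_ratio = {}
        for mark in ("H3K27ac", "RAD21", "CTCF"):
            d = comp.group_feature_peak_distance(groups, grid25, peaks[mark], genes)
            dist_ratio[mark] = float(d[0] / np.nanmean(d))
        return {
            "sign_recovery_pct": min(recovery.values()),
            "sign_recovery_per_condition": recovery,
            "n_bins": sum(BinGrid(25_000, sizes).n_bins(c) for c in sizes),
            "flips_in_top_decile_pct": flip_pct,
            "n_flips": len(flips),
            "strongest_group_distance_ratio": dist_ratio,
        }
    finally:
        if ctx:
            ctx.cleanup()


def loop_depletion_recovery(seed: int = 0) -> dict:
    """Gene-body interaction fold changes with 50 loop-depleted target genes."""
    cfg = SyntheticConfig(n_target_genes=50, n_filler_genes=60,
                          n_loop_depleted=50, enhancer_max_distance=100_000)
    genes, peaks, sizes, manifest = simulate_annotation(cfg, seed=_sub_seed(seed, 2))
    grid5 = BinGrid(5_000, sizes)
    mats = {}
    for k, cond in enumerate((CONTROL, CKO)):
        pairs = simulate_contacts(genes, manifest, cfg, cond,
                                  seed=_sub_seed(seed, 3 + k))
        kept, _ = ct.filter_pairs_table(pairs)
        m, _ = ct.bin_pairs_table(kept, grid5)
        for chrom in sizes:
            ct.kr_balance(m[chrom])
        mats[cond] = m
    fc = {}
    for g in genes:
        s_ctrl = li.gene_body_interaction(mats[CONTROL][g.chrom], g.interval)
        s_cko = li.gene_body_interaction(mats[CKO][g.chrom], g.interval)
        fc[g.id] = li.interaction_fold_change(s_cko, s_ctrl)
    depleted = np.array([fc[g] for g in manifest.loop_depleted_genes
                         if np.isfinite(fc[g])])
    unperturbed = np.array([v for gid, v in fc.items()
                            if gid not in manifest.loop_depleted_genes
                            and np.isfinite(v)])
    res = sign_test(depleted - 1.0)
    return {
        "depleted_median_fc": float(np.median(depleted)),
        "depleted_sign_test_p": res.p_value,
        "n_depleted": len(depleted),
        "unperturbed_median_fc": float(np.median(unperturbed)),
        "n_unperturbed": len(unperturbed),
    }


def _distance_correlation(flip_mode: str, seed: int) -> dict:
    # loop-free fixture: promoter-enhancer loops would add a distance-
    # dependent A-like signal at enhancer bins, confounding the pure
    # compartment-flip effect this experiment isolates
    cfg = SyntheticConfig(n_chroms=2, n_target_genes=60, n_filler_genes=80,
                          n_enhancers_per_target=1, n_flipped_bins=60,
                          flip_mode=flip_mode, depth=3_000_000,
                          loop_boost=1.0, n_loop_depleted=0)
    genes, peaks, sizes, manifest = simulate_annotation(cfg, seed=seed)
    grid25 = BinGrid(25_000, sizes)
    profiles = {}
    for k, cond in enumerate((CONTROL, CKO)):
        pairs = simulate_contacts(genes, manifest, cfg, cond,
                                  seed=_sub_seed(seed, 7 + k))
        kept, _ = ct.filter_pairs_table(pairs)
        mats, _ = ct.bin_pairs_table(kept, grid25)
        profiles[cond] = {}
        for chrom in sizes:
            ct.kr_balance(mats[chrom])
            profiles[cond][chrom] = call_compartments(mats[chrom],
                                                      peaks["H3K27ac"],
                                                      peaks["H3K9me3"])
    delta_profiles = {
        chrom: comp.CompartmentProfile(
            grid25, chrom,
            comp.delta_scores(profiles[CONTROL][chrom], profiles[CKO][chrom]))
        for chrom in sizes
    }
    calls = classify_enhancers(peaks["H3K27ac"], peaks["H3K4me3"], genes)
    gene_map = {g.id: g for g in genes}
    down = [gene_map[gid] for gid in manifest.target_genes]
    records, r, res = enhancer_distance_vs_delta_score(down, calls, genes,
                                                       delta_profiles)
    return {"r": r, "p": res.p_value, "n_genes": len(records)}


def distance_dependence_recovery(seed: int = 0) -> dict:
    """Fig-4K-style correlation under distal-only vs uniform flip planting."""
    distal = _distance_correlation("enhancers_distal", _sub_seed(seed, 11))
    uniform = _distance_correlation("enhancers_all", _sub_seed(seed, 12))
    return {
        "distal_r": distal["r"], "distal_p": distal["p"],
        "distal_n_genes": distal["n_genes"],
        "uniform_r": uniform["r"], "uniform_p": uniform["p"],
    }


def fish_recovery(seed: int = 0, n_placements: int = 200) -> dict:
    """Planted-blob distance recovery at SNR 5 plus the 3-4-5 analytic case."""
    rng = np.random.default_rng(seed)
    voxel_diag = float(np.sqrt(0.3 ** 2 + 0.1 ** 2 + 0.1 ** 2))
    errors = []
    for k in range(n_placements):
        sep = float(rng.uniform(0.5, 5.0))
        va, vb, ca, cb = simulate_fish_volume(sep, snr=5.0,
                                              seed=_sub_seed(seed, 100 + k))
        true = float(np.linalg.norm(ca - cb))
        errors.append(abs(measure_probe_distance(va, vb) - true))
    errors = np.asarray(errors)
    d345 = spot_distance(Spot((0.0, 0.0, 0.0), 1, 1.0),
                         Spot((0.0, 3.0, 4.0), 1, 1.0))
    return {
        "within_voxel_diag_pct": 100.0 * float((errors <= voxel_diag).mean()),
        "n_placements": n_placements,
        "median_error_um": float(np.median(errors)),
        "analytic_345_um": d345,
    }


def null_type_one_error(seed: int = 0, n_reps: int = 10_000,
                        alpha: float = 0.05) -> dict:
    """Rejection rates of the sign and Mood's tests under the null."""
    rng = np.random.default_rng(seed)
    sign_rej = 0
    moods_rej = 0
    for _ in range(n_reps):
        d = rng.normal(size=15)
        if sign_test(d).p_value <= alpha:
            sign_rej += 1
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        if moods_median_test([a, b]).p_value <= alpha:
            moods_rej += 1
    return {"sign_rejection_rate": sign_rej / n_reps,
            "moods_rejection_rate": moods_rej / n_reps,
            "n_reps": n_reps, "alpha": alpha}
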