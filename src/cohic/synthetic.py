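"""Synthetic two-condition Hi-C / ChIP-seq / RNA-seq / FISH fixture generator.

Generates a desk-scale genome with an alternating A/B compartment
checkerboard, protein-coding genes placed mostly in A blocks, intergenic
enhancer clusters downstream of designated target genes, mark-specific
ChIP peaks, two-condition contact-pair files with power-law distance
decay, compartment structure and gene-body/promoter-enhancer loop
enrichment, negative-binomial expression counts, and two-channel FISH
volumes. Every planted perturbation (A-to-B compartment flips at
intergenic enhancer bins, loop depletion at target genes, differential
expression) is recorded in a TruthManifest so downstream recovery can be
scored.

Contact probability model, per intra-chromosomal 5 Kb bin pair (i, j):

    P(i, j)  proportional to  (1 + |i-j|)^(-alpha) * (1 + kappa*c_i*c_j) * L(i, j)

with compartment signs c in {+1, -1} per condition, compartment strength
kappa, and loop factor L boosting pairs within target-gene bodies and
promoter-enhancer pairs (the boost excess is scaled by the depletion
factor in the perturbed condition for loop-depleted genes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinGrid, Gene, GenomicInterval, PeakSet
from .fish3d import Volume3D

CONTROL = "control"
CKO = "cko"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic fixture (sizes, strengths, rates)."""

    n_chroms: int = 1
    chrom_length: int = 20_000_000
    block_size: int = 1_000_000          # A/B compartment block width
    sim_bin_size: int = 5_000
    compartment_bin_size: int = 25_000

    n_target_genes: int = 20
    n_filler_genes: int = 60
    target_gene_length: int = 30_000
    filler_gene_length: int = 20_000
    intergene_gap: int = 10_000
    b_block_gene_fraction: float = 0.1   # fillers spilling into B blocks

    n_enhancers_per_target: int = 2
    enhancer_width: int = 1_500
    enhancer_min_distance: int = 20_000
    enhancer_max_distance: int = 400_000
    spacer_gene_length: int = 5_000      # silent gene closing each target cassette

    n_flipped_bins: int = 30
    flip_mode: str = "enhancers_all"     # enhancers_all | enhancers_distal | none
    distal_threshold_bp: int = 100_000

    n_loop_depleted: int = 10
    loop_boost: float = 3.0
    depletion_factor: float = 0.5        # multiplies the boost excess in cKO

    kappa: float = 0.6
    decay_alpha: float = 1.0
    depth: int = 2_000_000
    short_range_rate: float = 0.005      # sub-1Kb artifact pairs
    inter_chrom_rate: float = 0.002      # only when n_chroms > 1

    de_log2fc_down: float = -2.0
    n_reps: int = 3
    nb_dispersion: float = 0.1
    mean_a: float = 500.0
    mean_b: float = 50.0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass
class TruthManifest:
    """Ground truth for every planted perturbation in a synthetic fixture."""

    rng_seed: int
    compartment_sign: dict      # chrom -> {"control": [...], "cko": [...]} per 25 Kb bin
    flipped_bins: list          # [(chrom, bin25), ...] control-A bins flipped to B in cKO
    loop_depleted_genes: dict   # gene_id -> depletion factor
    de_genes: dict              # gene_id -> true log2FC
    enhancer_layout: dict       # gene_id -> [{"chrom","start","end","distance_bp"}, ...]
    target_genes: list = field(default_factory=list)
    silent_genes: list = field(default_factory=list)  # zero-expression spacer genes

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        d["flipped_bins"] = [tuple(t) for t in d["flipped_bins"]]
        return cls(**d)

    def signs(self, chrom: str, condition: str) -> np.ndarray:
        return np.asarray(self.compartment_sign[chrom][condition], dtype=int)


def _block_signs(cfg: SyntheticConfig) -> list[tuple[int, int, int]]:
    """(start, end, sign) blocks across one chromosome, A first."""
    blocks = []
    pos = 0
    sign = +1
    while pos < cfg.chrom_length:
        end = min(pos + cfg.block_size, cfg.chrom_length)
        blocks.append((pos, end, sign))
        pos = end
        sign = -sign
    return blocks


def simulate_annotation(
    cfg: SyntheticConfig, seed: int = 0
) -> tuple[list[Gene], dict[str, PeakSet], dict[str, int], TruthManifest]:
    """Lay out genes, enhancers and ChIP peaks; plant compartment flips.

    Target genes receive intergenic enhancer clusters downstream at edge-to-
    midpoint distances drawn from the configured range; every enhancer is
    > 2 Kb from all TSSs by construction. H3K4me3 marks every TSS, H3K27ac
    marks promoters and enhancers, RAD21 marks target promoters/enhancers,
    CTCF marks block boundaries, and H3K9me3 tiles B blocks.
    """
    rng = np.random.default_rng(seed)
    sizes = cfg.chrom_sizes()
    genes: list[Gene] = []
    enhancer_layout: dict[str, list[dict]] = {}
    peaks: dict[str, list[tuple]] = {m: [] for m in
                                     ("H3K27ac", "H3K4me3", "RAD21", "CTCF", "H3K9me3")}

    n_targets_left = cfg.n_target_genes
    n_fillers_left = cfg.n_filler_genes
    n_b_fillers = int(round(cfg.n_filler_genes * cfg.b_block_gene_fraction))
    gene_idx = 0
    target_ids: list[str] = []
    silent_ids: list[str] = []

    for chrom in cfg.chrom_names():
        blocks = _block_signs(cfg)
        a_blocks = [b for b in blocks if b[2] > 0]
        b_blocks = [b for b in blocks if b[2] < 0]

        for bstart, bend, _ in a_blocks:
            cursor = bstart + cfg.intergene_gap
            while cursor < bend - cfg.intergene_gap:
                if n_targets_left > 0:
                    length = cfg.target_gene_length
                    dists = np.sort(rng.integers(cfg.enhancer_min_distance,
                                                 cfg.enhancer_max_distance + 1,
                                                 size=cfg.n_enhancers_per_target))
                    span = (length + int(dists[-1]) + cfg.enhancer_width
                            + cfg.intergene_gap + cfg.spacer_gene_length
                            + cfg.intergene_gap)
                    if cursor + span > bend - cfg.intergene_gap:
                        # not enough room for a full cassette; try a filler instead
                        if n_fillers_left > 0 and cursor + cfg.filler_gene_length \
                                + cfg.intergene_gap <= bend - cfg.intergene_gap:
                            gene_idx += 1
                            gid = f"gene{gene_idx:04d}"
                            iv = GenomicInterval(chrom, cursor, cursor + cfg.filler_gene_length,
                                                 "+" if gene_idx % 2 else "-")
                            genes.append(Gene(gid, iv))
                            n_fillers_left -= 1
                            cursor += cfg.filler_gene_length + cfg.intergene_gap
                            continue
                        break
                    gene_idx += 1
                    gid = f"gene{gene_idx:04d}"
                    iv = GenomicInterval(chrom, cursor, cursor + length, "+")
                    genes.append(Gene(gid, iv))
                    target_ids.append(gid)
                    n_targets_left -= 1
                    layout = []
                    for d in dists:
                        mid = iv.end - 1 + int(d)
                        e_start = mid - cfg.enhancer_width // 2
                        e_end = e_start + cfg.enhancer_width
                        layout.append({"chrom": chrom, "start": int(e_start),
                                       "end": int(e_end), "distance_bp": int(d)})
                        peaks["H3K27ac"].append((chrom, e_start, e_end, 8.0))
                        if rng.random() < 0.7:
                            peaks["RAD21"].append((chrom, e_start, e_end, 5.0))
                    enhancer_layout[gid] = layout
                    # silent spacer gene closes the cassette so the target's
                    # flanking intergenic region holds only its own enhancers
                    sp_start = iv.end - 1 + int(dists[-1]) + cfg.enhancer_width // 2 \
                        + cfg.intergene_gap
                    gene_idx += 1
                    sid = f"gene{gene_idx:04d}"
                    genes.append(Gene(sid, GenomicInterval(
                        chrom, sp_start, sp_start + cfg.spacer_gene_length, "+")))
                    silent_ids.append(sid)
                    cursor += span
                elif n_fillers_left > n_b_fillers:
                    length = cfg.filler_gene_length
                    if cursor + length + cfg.intergene_gap > bend - cfg.intergene_gap:
                        break
                    gene_idx += 1
                    gid = f"gene{gene_idx:04d}"
                    iv = GenomicInterval(chrom, cursor, cursor + length,
                                         "+" if gene_idx % 2 else "-")
                    genes.append(Gene(gid, iv))
                    n_fillers_left -= 1
                    cursor += length + cfg.intergene_gap
                else:
                    break

        # a few genes in B blocks (low expression; keeps layouts realistic)
        for bstart, bend, _ in b_blocks:
            if n_fillers_left <= 0:
                break
            cursor = bstart + 3 * cfg.intergene_gap
            if cursor + cfg.filler_gene_length < bend - cfg.intergene_gap:
                gene_idx += 1
                gid = f"gene{gene_idx:04d}"
                iv = GenomicInterval(chrom, cursor, cursor + cfg.filler_gene_length,
                                     "+" if gene_idx % 2 else "-")
                genes.append(Gene(gid, iv))
                n_fillers_left -= 1

        for bstart, bend, sign in blocks:
            if bstart > 0:
                peaks["CTCF"].append((chrom, bstart - 500, bstart + 500, 6.0))
            if sign < 0:
                pos = bstart + 2_000
                while pos + 20_000 < bend:
                    peaks["H3K9me3"].append((chrom, pos, pos + 20_000, 4.0))
                    pos += 25_000

    for g in genes:
        tss = g.tss
        peaks["H3K4me3"].append((g.chrom, max(0, tss - 500), tss + 500, 10.0))
        peaks["H3K27ac"].append((g.chrom, max(0, tss - 500), tss + 500, 6.0))
        if g.id in target_ids:
            peaks["RAD21"].append((g.chrom, max(0, tss - 400), tss + 400, 7.0))

    peak_sets = {
        mark: PeakSet(mark,
                      [GenomicInterval(c, int(s), int(e)) for c, s, e, _ in plist],
                      [v for _, _, _, v in plist])
        for mark, plist in peaks.items()
    }

    # --- compartment signs per 25 Kb bin, control and cKO -------------------
    grid25 = BinGrid(cfg.compartment_bin_size, sizes)
    compartment_sign: dict[str, dict[str, list[int]]] = {}
    for chrom in cfg.chrom_names():
        n25 = grid25.n_bins(chrom)
        ctrl = np.empty(n25, dtype=int)
        for i in range(n25):
            mid = i * cfg.compartment_bin_size + cfg.compartment_bin_size // 2
            block = min(mid // cfg.block_size, (cfg.chrom_length - 1) // cfg.block_size)
            ctrl[i] = +1 if block % 2 == 0 else -1
        compartment_sign[chrom] = {CONTROL: ctrl.tolist(), CKO: ctrl.tolist()}

    # --- plant A->B flips at intergenic enhancer bins -----------------------
    flipped: list[tuple[str, int]] = []
    if cfg.flip_mode != "none" and cfg.n_flipped_bins > 0:
        candidates = []
        for gid, layout in enhancer_layout.items():
            if cfg.flip_mode == "enhancers_distal":
                # only each gene's most distal enhancer, when beyond threshold
                distal = max(layout, key=lambda e: e["distance_bp"])
                pool = [distal] if distal["distance_bp"] > cfg.distal_threshold_bp else []
            else:
                pool = layout
            for enh in pool:
                chrom = enh["chrom"]
                b25 = (enh["start"] + enh["end"]) // 2 // cfg.compartment_bin_size
                if compartment_sign[chrom][CONTROL][b25] > 0:
                    candidates.append((chrom, int(b25)))
        candidates = sorted(set(candidates))
        if candidates:
            take = min(cfg.n_flipped_bins, len(candidates))
            idx = rng.choice(len(candidates), size=take, replace=False)
            flipped = sorted(candidates[i] for i in idx)
            for chrom, b25 in flipped:
                compartment_sign[chrom][CKO][b25] = -1

    # --- differential expression and loop depletion labels ------------------
    de_genes = {gid: cfg.de_log2fc_down for gid in target_ids}
    depleted = {gid: cfg.depletion_factor
                for gid in target_ids[: cfg.n_loop_depleted]}

    manifest = TruthManifest(
        rng_seed=seed,
        compartment_sign=compartment_sign,
        flipped_bins=flipped,
        loop_depleted_genes=depleted,
        de_genes=de_genes,
        enhancer_layout=enhancer_layout,
        target_genes=target_ids,
        silent_genes=silent_ids,
    )
    return genes, peak_sets, sizes, manifest


def _signs_5kb(manifest: TruthManifest, cfg: SyntheticConfig, chrom: str,
               condition: str) -> np.ndarray:
    signs25 = manifest.signs(chrom, condition)
    ratio = cfg.compartment_bin_size // cfg.sim_bin_size
    n5 = int(np.ceil(cfg.chrom_length / cfg.sim_bin_size))
    return np.repeat(signs25, ratio)[:n5]


def _loop_boosts(genes: list[Gene], manifest: TruthManifest, cfg: SyntheticConfig,
                 chrom: str, condition: str) -> dict[int, list[tuple[int, float]]]:
    """Per-diagonal loop boosts: offset d -> [(i, factor), ...]."""
    boosts: dict[int, list[tuple[int, float]]] = {}
    bs = cfg.sim_bin_size
    gene_by_id = {g.id: g for g in genes}
    for gid in manifest.target_genes:
        g = gene_by_id[gid]
        if g.chrom != chrom:
            continue
        factor = cfg.loop_boost
        if condition == CKO and gid in manifest.loop_depleted_genes:
            factor = 1.0 + (cfg.loop_boost - 1.0) * manifest.loop_depleted_genes[gid]
        b_lo = g.interval.start // bs
        b_hi = (g.interval.end - 1) // bs
        for i in range(b_lo, b_hi + 1):
            for j in range(i, b_hi + 1):
                boosts.setdefault(j - i, []).append((i, factor))
        promoter_bin = g.tss // bs
        for enh in manifest.enhancer_layout.get(gid, []):
            e_bin = ((enh["start"] + enh["end"]) // 2) // bs
            i, j = min(promoter_bin, e_bin), max(promoter_bin, e_bin)
            boosts.setdefault(j - i, []).append((i, factor))
    return boosts


def simulate_contacts(
    genes: list[Gene],
    manifest: TruthManifest,
    cfg: SyntheticConfig,
    condition: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample contact pairs for one condition; returns a shuffled pair table.

    Columns: chrom1, pos1, chrom2, pos2, strand1, strand2. Depth is split
    across chromosomes by length; a small fraction of sub-1 Kb pairs and
    (for multi-chromosome genomes) inter-chromosomal pairs is injected to
    exercise the pair filters.
    """
    rng = np.random.default_rng(seed)
    frames = []
    chroms = cfg.chrom_names()
    n_inter = int(round(cfg.depth * cfg.inter_chrom_rate)) if len(chroms) > 1 else 0
    n_short_total = int(round(cfg.depth * cfg.short_range_rate))
    depth_main = cfg.depth - n_inter - n_short_total
    per_chrom = [depth_main // len(chroms)] * len(chroms)
    per_chrom[0] += depth_main - sum(per_chrom)

    for chrom, depth in zip(chroms, per_chrom):
        c = _signs_5kb(manifest, cfg, chrom, condition).astype(float)
        n5 = len(c)
        boosts = _loop_boosts(genes, manifest, cfg, chrom, condition)
        probs = []
        offsets = np.empty(n5 + 1, dtype=np.int64)
        offsets[0] = 0
        for d in range(n5):
            decay = (1.0 + d) ** (-cfg.decay_alpha)
            vals = decay * (1.0 + cfg.kappa * c[: n5 - d] * c[d:])
            for i, factor in boosts.get(d, []):
                if i < n5 - d:
                    vals[i] *= factor
            probs.append(vals)
            offsets[d + 1] = offsets[d] + (n5 - d)
        p = np.concatenate(probs)
        p /= p.sum()
        counts = rng.multinomial(depth, p)
        nz = np.nonzero(counts)[0]
        reps = counts[nz]
        d_arr = np.searchsorted(offsets, nz, side="right") - 1
        i_arr = nz - offsets[d_arr]
        j_arr = i_arr + d_arr
        i_rep = np.repeat(i_arr, reps)
        j_rep = np.repeat(j_arr, reps)
        bs = cfg.sim_bin_size
        pos1 = i_rep * bs + rng.integers(0, bs, size=i_rep.size)
        pos2 = j_rep * bs + rng.integers(0, bs, size=j_rep.size)
        pos1 = np.minimum(pos1, cfg.chrom_length - 1)
        pos2 = np.minimum(pos2, cfg.chrom_length - 1)
        lo = np.minimum(pos1, pos2)
        hi = np.maximum(pos1, pos2)
        frames.append(pd.DataFrame({"chrom1": chrom, "pos1": lo,
                                    "chrom2": chrom, "pos2": hi}))

    n_short_per = [n_short_total // len(chroms)] * len(chroms)
    n_short_per[0] += n_short_total - sum(n_short_per)
    for chrom, n_short in zip(chroms, n_short_per):
        if n_short <= 0:
            continue
        p1 = rng.integers(0, cfg.chrom_length - 1_000, size=n_short)
        p2 = p1 + rng.integers(0, 1_000, size=n_short)
        frames.append(pd.DataFrame({"chrom1": chrom, "pos1": p1,
                                    "chrom2": chrom, "pos2": p2}))

    if n_inter > 0:
        c1 = rng.integers(0, len(chroms), size=n_inter)
        c2 = (c1 + 1 + rng.integers(0, len(chroms) - 1, size=n_inter)) % len(chroms)
        df = pd.DataFrame({
            "chrom1": np.array(chroms)[np.minimum(c1, c2)],
            "pos1": rng.integers(0, cfg.chrom_length, size=n_inter),
            "chrom2": np.array(chroms)[np.maximum(c1, c2)],
            "pos2": rng.integers(0, cfg.chrom_length, size=n_inter),
        })
        frames.append(df)

    pairs = pd.concat(frames, ignore_index=True)
    pairs["strand1"] = "."
    pairs["strand2"] = "."
    pairs = pairs.iloc[rng.permutation(len(pairs))].reset_index(drop=True)
    return pairs


def write_pairs_table(path, pairs: pd.DataFrame, chrom_sizes: dict[str, int]) -> None:
    """Write a pair table in 4DN pairs text format."""
    with open(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2\n")
        for name, length in chrom_sizes.items():
            fh.write(f"#chromsize: {name} {length}\n")
        out = pairs.copy()
        out.insert(0, "readID", ".")
        out.to_csv(fh, sep="\t", header=False, index=False)


def simulate_expression(
    genes: list[Gene],
    manifest: TruthManifest,
    cfg: SyntheticConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial expression counts per condition with planted log2FCs.

    Genes in A blocks draw from a high baseline mean, B-block genes from a
    low one; de_genes get their true log2FC applied to the cKO mean. With
    dispersion 0 counts are Poisson. Returns per-gene counts, mean CPM per
    condition, control log2 CPM, and the estimated log2 fold change.
    """
    rng = np.random.default_rng(seed)
    grid25 = BinGrid(cfg.compartment_bin_size, cfg.chrom_sizes())

    silent = set(manifest.silent_genes)

    def baseline(g: Gene) -> float:
        if g.id in silent:
            return 0.0
        b25 = int(g.interval.midpoint) // cfg.compartment_bin_size
        sign = manifest.signs(g.chrom, CONTROL)[b25]
        return cfg.mean_a if sign > 0 else cfg.mean_b

    rows = []
    for g in genes:
        mu_ctrl = baseline(g)
        mu_cko = mu_ctrl * 2.0 ** manifest.de_genes.get(g.id, 0.0)
        counts = {}
        for cond, mu in ((CONTROL, mu_ctrl), (CKO, mu_cko)):
            for r in range(cfg.n_reps):
                if cfg.nb_dispersion <= 0:
                    k = rng.poisson(mu)
                else:
                    size = 1.0 / cfg.nb_dispersion
                    k = rng.negative_binomial(size, size / (size + mu))
                counts[f"{cond}_rep{r + 1}"] = int(k)
        rows.append({"gene_id": g.id, **counts})
    df = pd.DataFrame(rows)

    ctrl_cols = [c for c in df.columns if c.startswith(CONTROL)]
    cko_cols = [c for c in df.columns if c.startswith(f"{CKO}_")]
    lib_ctrl = df[ctrl_cols].sum(axis=0)
    lib_cko = df[cko_cols].sum(axis=0)
    cpm_ctrl = (df[ctrl_cols] / lib_ctrl * 1e6).mean(axis=1)
    cpm_cko = (df[cko_cols] / lib_cko * 1e6).mean(axis=1)
    df["cpm_control"] = cpm_ctrl
    df["cpm_cko"] = cpm_cko
    df["log2cpm_control"] = np.log2(cpm_ctrl + 1e-9)
    df["log2fc"] = np.log2((cpm_cko + 0.5) / (cpm_ctrl + 0.5))
    return df


def simulate_fish_volume(
    separation_um: float,
    snr: float = 5.0,
    shape: tuple[int, int, int] = (21, 48, 48),
    spacing: tuple[float, float, float] = (0.3, 0.1, 0.1),
    blob_sigma_um: float = 0.2,
    background: float = 10.0,
    seed: int = 0,
) -> tuple[Volume3D, Volume3D, np.ndarray, np.ndarray]:
    """Two-channel FISH volume with Gaussian probe blobs at a set separation.

    Channel A's blob is placed near the volume center; channel B's at
    ``separation_um`` along a random direction (kept inside bounds).
    Poisson shot noise is added so peak-above-background over noise sigma
    equals ``snr``. Returns (vol_a, vol_b, center_a_um, center_b_um).
    """
    rng = np.random.default_rng(seed)
    spacing_arr = np.asarray(spacing)
    extent = (np.asarray(shape) - 1) * spacing_arr
    margin = 3 * blob_sigma_um + spacing_arr
    for _ in range(1000):
        center_a = extent / 2 + rng.uniform(-0.3, 0.3, size=3) * (extent / 2 - margin)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center_b = center_a + separation_um * direction
        if np.all(center_b >= margin) and np.all(center_b <= extent - margin):
            break
    else:
        center_b = center_a.copy()

    amplitude = snr * np.sqrt(background)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1) * spacing_arr

    def channel(center):
        d2 = ((coords - center) ** 2).sum(axis=-1)
        signal = background + amplitude * np.exp(-d2 / (2 * blob_sigma_um ** 2))
        return Volume3D(rng.poisson(signal).astype(float), spacing)

    return channel(center_a), channel(center_b), center_a, center_b


def write_annotation_files(
    outdir,
    genes: list[Gene],
    peak_sets: dict[str, PeakSet],
    chrom_sizes: dict[str, int],
) -> None:
    """Write chrom.sizes, the gene table, and one BED per mark."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "chrom.sizes", "wt") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")
    pd.DataFrame(
        [{"gene_id": g.id, "chrom": g.chrom, "start": g.interval.start,
          "end": g.interval.end, "strand": g.interval.strand, "biotype": g.biotype}
         for g in genes]
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    for mark, ps in peak_sets.items():
        with open(outdir / f"{mark}.bed", "wt") as fh:
            for p, s in zip(ps.peaks, ps.signal):
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{mark}\t{s:g}\t{p.strand}\n")


def simulate_dataset(cfg: SyntheticConfig, outdir, seed: int = 0) -> TruthManifest:
    """Generate and write a complete two-condition fixture dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, peak_sets, sizes, manifest = simulate_annotation(cfg, seed=seed)
    write_annotation_files(outdir, genes, peak_sets, sizes)
    for k, condition in enumerate((CONTROL, CKO)):
        pairs = simulate_contacts(genes, manifest, cfg, condition, seed=seed + 11 + k)
        write_pairs_table(outdir / f"pairs_{condition}.pairs", pairs, sizes)
    expr = simulate_expression(genes, manifest, cfg, seed=seed + 29)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    manifest.to_json(outdir / "manifest.json")
    return manifest
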