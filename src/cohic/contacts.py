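"""Hi-C contact pairs, binned contact matrices, and matrix normalization.

The flow mirrors a standard Hi-C post-mapping pipeline: valid pairs are
filtered (minimum 1 Kb intra-chromosomal separation, exact-duplicate
removal), binned per chromosome into symmetric sparse count matrices,
balanced with Knight-Ruiz matrix scaling, and converted to distance-
normalized observed/expected and correlation matrices for compartment
calling. Inter-chromosomal pairs are counted but excluded from matrices.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import BinGrid

logger = logging.getLogger(__name__)

MIN_PAIR_DISTANCE = 1000  # bp; pairs closer than this are presumed artifacts


@dataclass(frozen=True)
class ContactPair:
    """One valid Hi-C contact, canonically ordered so (chrom1,pos1) <= (chrom2,pos2)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str = "."
    strand2: str = "."

    @staticmethod
    def make(chrom1, pos1, chrom2, pos2, strand1=".", strand2=".") -> "ContactPair":
        if (chrom1, pos1) > (chrom2, pos2):
            chrom1, pos1, chrom2, pos2 = chrom2, pos2, chrom1, pos1
            strand1, strand2 = strand2, strand1
        return ContactPair(chrom1, int(pos1), chrom2, int(pos2), strand1, strand2)

    @property
    def is_intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def distance(self) -> int | None:
        return abs(self.pos2 - self.pos1) if self.is_intra else None


@dataclass
class FilterReport:
    n_input: int = 0
    n_short_range: int = 0
    n_duplicate: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict:
        return vars(self).copy()


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_pairs(path, chrom_sizes: dict[str, int] | None = None) -> Iterator[ContactPair]:
    """Stream 4DN-pairs-format text as canonically ordered ContactPairs.

    Columns: readID chrom1 pos1 chrom2 pos2 [strand1 strand2]. Header lines
    start with '#'; '#chromsize:' declarations are validated against
    ``chrom_sizes`` when given.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#chromsize:") and chrom_sizes is not None:
                    name, length = line.split()[1:3]
                    if name in chrom_sizes and chrom_sizes[name] != int(length):
                        raise ValueError(
                            f"{path}:{lineno}: header declares {name} length {length}, "
                            f"expected {chrom_sizes[name]}"
                        )
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns, got {len(parts)}")
            strand1 = parts[5] if len(parts) > 5 else "."
            strand2 = parts[6] if len(parts) > 6 else "."
            yield ContactPair.make(parts[1], int(parts[2]), parts[3], int(parts[4]), strand1, strand2)


def write_pairs(path, pairs: Iterable[ContactPair], chrom_sizes: dict[str, int] | None = None) -> None:
    """Write pairs in 4DN pairs text format."""
    with open(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2\n")
        if chrom_sizes:
            for name, length in chrom_sizes.items():
                fh.write(f"#chromsize: {name} {length}\n")
        for p in pairs:
            fh.write(f".\t{p.chrom1}\t{p.pos1}\t{p.chrom2}\t{p.pos2}\t{p.strand1}\t{p.strand2}\n")


def filter_pairs(
    pairs: Iterable[ContactPair], min_distance: int = MIN_PAIR_DISTANCE
) -> tuple[list[ContactPair], FilterReport]:
    """Drop short-range intra-chromosomal pairs and exact duplicates.

    Intra-chromosomal pairs with separation < ``min_distance`` are removed
    (the boundary is inclusive: separation == min_distance is kept).
    Duplicates are exact coordinate+strand matches; the first occurrence
    is retained.
    """
    report = FilterReport()
    seen: set[tuple] = set()
    kept: list[ContactPair] = []
    for p in pairs:
        report.n_input += 1
        if p.is_intra and p.distance < min_distance:
            report.n_short_range += 1
            continue
        key = (p.chrom1, p.pos1, p.chrom2, p.pos2, p.strand1, p.strand2)
        if key in seen:
            report.n_duplicate += 1
            continue
        seen.add(key)
        kept.append(p)
    report.n_kept = len(kept)
    return kept, report


class ContactMatrix:
    """Symmetric sparse binned contact matrix for one chromosome.

    ``counts`` is upper-triangle-complete symmetric CSR; ``weights`` is the
    KR balancing vector (NaN at masked bins). The balanced matrix has
    entries w_i * counts[i,j] * w_j with unit row sums on unmasked bins.
    """

    def __init__(self, grid: BinGrid, chrom: str, counts: sp.spmatrix):
        n = grid.n_bins(chrom)
        counts = sp.csr_matrix(counts)
        if counts.shape != (n, n):
            raise ValueError(f"counts shape {counts.shape} != ({n},{n}) for {chrom}")
        self.grid = grid
        self.chrom = chrom
        self.counts = counts
        self.weights: np.ndarray | None = None
        self.balance_converged: bool | None = None
        self.balance_iterations: int | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True at bins excluded from balancing (weight NaN)."""
        if self.weights is None:
            return np.zeros(self.n_bins, dtype=bool)
        return ~np.isfinite(self.weights)

    def marginals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def balanced_dense(self) -> np.ndarray:
        """Dense balanced matrix with NaN at masked rows/columns."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; call kr_balance first")
        w = self.weights
        out = np.asarray(self.counts.todense(), dtype=float) * np.outer(w, w)
        bad = ~np.isfinite(w)
        out[bad, :] = np.nan
        out[:, bad] = np.nan
        return out

    def balanced_submatrix(self, bin_lo: int, bin_hi: int) -> np.ndarray:
        """Dense balanced submatrix over bins [bin_lo, bin_hi)."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; call kr_balance first")
        w = self.weights[bin_lo:bin_hi]
        sub = np.asarray(self.counts[bin_lo:bin_hi, bin_lo:bin_hi].todense(), dtype=float)
        out = sub * np.outer(w, w)
        bad = ~np.isfinite(w)
        out[bad, :] = np.nan
        out[:, bad] = np.nan
        return out

    def save(self, prefix) -> None:
        """Persist as (bin1, bin2, count) TSV plus a JSON grid sidecar."""
        prefix = Path(prefix)
        coo = sp.triu(self.counts).tocoo()
        df = pd.DataFrame({"bin1": coo.row, "bin2": coo.col, "count": coo.data.astype(int)})
        df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        meta = {
            "chrom": self.chrom,
            "bin_size": self.grid.bin_size,
            "chrom_sizes": self.grid.chrom_sizes,
            "weights": None if self.weights is None else
                [None if not np.isfinite(w) else float(w) for w in self.weights],
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, prefix) -> "ContactMatrix":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        grid = BinGrid(meta["bin_size"], meta["chrom_sizes"])
        n = grid.n_bins(meta["chrom"])
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        upper = sp.coo_matrix((df["count"], (df["bin1"], df["bin2"])), shape=(n, n))
        counts = upper + sp.triu(upper, k=1).T
        m = cls(grid, meta["chrom"], counts)
        if meta.get("weights") is not None:
            m.weights = np.array([np.nan if w is None else w for w in meta["weights"]])
        return m


def bin_pairs(
    pairs: Iterable[ContactPair], grid: BinGrid
) -> tuple[dict[str, ContactMatrix], dict]:
    """Bin intra-chromosomal pairs into per-chromosome ContactMatrix objects.

    Each pair increments counts[bin1, bin2] and its mirror; both ends in one
    bin increment the diagonal once. Inter-chromosomal pairs are tallied in
    the report but not stored. A matrix is produced for every chromosome in
    the grid, even if empty.
    """
    per_chrom: dict[str, tuple[list[int], list[int]]] = {c: ([], []) for c in grid.chrom_sizes}
    n_inter = 0
    n_intra = 0
    for p in pairs:
        if not p.is_intra:
            n_inter += 1
            continue
        if p.chrom1 not in per_chrom:
            raise ValueError(f"pair on chromosome {p.chrom1} absent from grid")
        b1 = grid.bin_of(p.chrom1, p.pos1)
        b2 = grid.bin_of(p.chrom2, p.pos2)
        rows, cols = per_chrom[p.chrom1]
        rows.append(min(b1, b2))
        cols.append(max(b1, b2))
        n_intra += 1
    matrices = {}
    for chrom, (rows, cols) in per_chrom.items():
        n = grid.n_bins(chrom)
        upper = sp.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        ).tocsr()
        counts = upper + sp.triu(upper, k=1).T
        matrices[chrom] = ContactMatrix(grid, chrom, counts)
    report = {"n_intra": n_intra, "n_inter": n_inter}
    return matrices, report


def read_pairs_table(path, chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Vectorized 4DN-pairs reader: whole file into a canonically ordered table.

    Same semantics as ``read_pairs`` (which streams ContactPair objects);
    use this for large files. Columns: chrom1, pos1, chrom2, pos2, strand1,
    strand2.
    """
    names = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                     dtype={"chrom1": str, "chrom2": str})
    if df[["chrom1", "pos1", "chrom2", "pos2"]].isna().any().any():
        raise ValueError(f"{path}: malformed pair records (missing columns)")
    df = df.drop(columns=["readID"])
    df["strand1"] = df["strand1"].fillna(".")
    df["strand2"] = df["strand2"].fillna(".")
    flip = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["pos1"] > df["pos2"]))
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        df.loc[flip, [a, b]] = df.loc[flip, [b, a]].to_numpy()
    if chrom_sizes is not None:
        unknown = (set(df["chrom1"]) | set(df["chrom2"])) - set(chrom_sizes)
        if unknown:
            raise ValueError(f"{path}: pairs on chromosomes absent from table: {sorted(unknown)}")
    return df


def filter_pairs_table(
    df: pd.DataFrame, min_distance: int = MIN_PAIR_DISTANCE
) -> tuple[pd.DataFrame, FilterReport]:
    """Vectorized equivalent of ``filter_pairs`` on a pair table."""
    report = FilterReport(n_input=len(df))
    intra = df["chrom1"] == df["chrom2"]
    short = intra & ((df["pos2"] - df["pos1"]).abs() < min_distance)
    report.n_short_range = int(short.sum())
    df = df[~short]
    dup = df.duplicated(subset=["chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"])
    report.n_duplicate = int(dup.sum())
    df = df[~dup]
    report.n_kept = len(df)
    return df.reset_index(drop=True), report


def bin_pairs_table(
    df: pd.DataFrame, grid: BinGrid
) -> tuple[dict[str, ContactMatrix], dict]:
    """Vectorized equivalent of ``bin_pairs`` on a pair table."""
    intra = df["chrom1"] == df["chrom2"]
    n_inter = int((~intra).sum())
    matrices = {}
    n_intra = 0
    for chrom in grid.chrom_sizes:
        n = grid.n_bins(chrom)
        sub = df[intra & (df["chrom1"] == chrom)]
        if len(sub):
            pos1 = sub["pos1"].to_numpy()
            pos2 = sub["pos2"].to_numpy()
            if pos1.min() < 0 or pos2.max() >= grid.chrom_sizes[chrom]:
                raise ValueError(f"position beyond {chrom} length")
            b1 = pos1 // grid.bin_size
            b2 = pos2 // grid.bin_size
            rows = np.minimum(b1, b2)
            cols = np.maximum(b1, b2)
            upper = sp.coo_matrix((np.ones(len(sub)), (rows, cols)), shape=(n, n)).tocsr()
        else:
            upper = sp.csr_matrix((n, n))
        counts = upper + sp.triu(upper, k=1).T
        matrices[chrom] = ContactMatrix(grid, chrom, counts)
        n_intra += len(sub)
    return matrices, {"n_intra": n_intra, "n_inter": n_inter}


def pool_matrices(matrices: Sequence[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of raw counts across same-grid matrices.

    Balancing weights are dropped; re-balance the pooled matrix.
    """
    if not matrices:
        raise ValueError("nothing to pool")
    first = matrices[0]
    for m in matrices[1:]:
        if m.chrom != first.chrom or m.grid.bin_size != first.grid.bin_size \
                or m.grid.chrom_sizes != first.grid.chrom_sizes:
            raise ValueError("pool_matrices requires identical grid and chromosome")
    total = first.counts.copy()
    for m in matrices[1:]:
        total = total + m.counts
    return ContactMatrix(first.grid, first.chrom, total)


def _kr_bnewt(A, tol: float, max_iter: int, delta: float = 0.1, Delta: float = 3.0):
    """Knight-Ruiz inner-outer Newton iteration for symmetric matrix balancing.

    Finds x > 0 with x_i * (A x)_i = 1 for all i, i.e. diag(x) A diag(x)
    doubly stochastic. Inner loop is conjugate gradient on the Newton system.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    n_outer = 0
    while rout > rt and n_outer < max_iter:
        n_outer += 1
        k = 0
        y = e.copy()
        inner_tol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > inner_tol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                if not neg.any():
                    break
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = ((Delta - y[big]) / ap[big]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 2 * n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        eta = g * rat
        if g * eta ** 2 > 0.1:
            eta = max(eta, g * eta ** 2)
        eta = min(eta, etamax)
        eta = max(eta, stop_tol / max(np.sqrt(rout), 1e-300))
    converged = rout <= rt
    return x, converged, n_outer


def kr_balance(
    matrix: ContactMatrix,
    tol: float = 1e-8,
    max_iter: int = 200,
    mask_percentile: float = 2.0,
    mask_median_fraction: float = 0.2,
) -> np.ndarray:
    """Knight-Ruiz balance a contact matrix in place; returns the weight vector.

    Low-coverage bins are masked (weight NaN) before balancing: bins with a
    zero marginal, or a marginal below the ``mask_percentile`` percentile of
    non-zero marginals. The percentile cutoff is capped at
    ``mask_median_fraction`` times the median non-zero marginal so the rule
    only removes near-empty rows (which break the Newton iteration), never
    structurally low-contact regions. The balanced matrix w_i c_ij w_j has
    row sums 1 on unmasked bins. Non-convergence is flagged, not raised.
    """
    marg = matrix.marginals()
    nonzero = marg[marg > 0]
    if nonzero.size == 0:
        raise ValueError(f"matrix for {matrix.chrom} is empty; cannot balance")
    cutoff = np.percentile(nonzero, mask_percentile) if mask_percentile > 0 else 0.0
    cutoff = min(cutoff, mask_median_fraction * float(np.median(nonzero)))
    keep = marg >= max(cutoff, 1e-300)
    keep &= marg > 0
    if keep.sum() == 0:
        raise ValueError(f"all bins masked for {matrix.chrom}")
    sub = matrix.counts[np.ix_(keep.nonzero()[0], keep.nonzero()[0])].astype(float)
    # pre-scale so row sums start near 1; improves Newton conditioning
    scale = np.asarray(sub.sum(axis=1)).ravel().mean()
    A = sub / scale
    x, converged, n_iter = _kr_bnewt(A, tol=tol, max_iter=max_iter)
    if not converged:
        logger.warning("KR balancing did not converge for %s within %d outer iterations",
                       matrix.chrom, max_iter)
    weights = np.full(matrix.n_bins, np.nan)
    weights[keep] = x / np.sqrt(scale)
    matrix.weights = weights
    matrix.balance_converged = bool(converged)
    matrix.balance_iterations = n_iter
    return weights


class ExpectedProfile:
    """Mean balanced contact per diagonal offset (distance-decay profile)."""

    def __init__(self, bin_size: int, values: np.ndarray):
        self.bin_size = bin_size
        self.values = np.asarray(values, dtype=float)

    def __getitem__(self, offset: int) -> float:
        if not 0 <= offset < len(self.values):
            return np.nan
        return self.values[offset]


def expected_by_distance(matrix: ContactMatrix) -> ExpectedProfile:
    """Per-offset mean of balanced entries over unmasked bin pairs.

    Offsets with no unmasked pairs are NaN.
    """
    dense = matrix.balanced_dense()
    n = matrix.n_bins
    values = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(dense, offset=d)
        ok = np.isfinite(diag)
        if ok.any():
            values[d] = diag[ok].mean()
    return ExpectedProfile(matrix.grid.bin_size, values)


def observed_over_expected(matrix: ContactMatrix, profile: ExpectedProfile | None = None) -> np.ndarray:
    """Dense O/E matrix: balanced(i,j) / expected(|i-j|), NaN where undefined."""
    if profile is None:
        profile = expected_by_distance(matrix)
    dense = matrix.balanced_dense()
    n = matrix.n_bins
    offsets = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = profile.values[offsets]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = dense / exp
    oe[~np.isfinite(oe)] = np.nan
    return oe


def correlation_matrix(oe: np.ndarray, min_shared: int = 3) -> np.ndarray:
    """Pairwise Pearson correlation between rows of an O/E matrix.

    Correlations use only columns where both rows are non-missing; pairs
    sharing fewer than ``min_shared`` columns, and zero-variance rows, are
    NaN. The diagonal of defined rows is 1.
    """
    X = np.asarray(oe, dtype=float)
    V = np.isfinite(X).astype(float)
    X0 = np.where(np.isfinite(X), X, 0.0)
    n = V @ V.T
    Sx = X0 @ V.T
    Sxx = (X0 * X0) @ V.T
    Sxy = X0 @ X0.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * Sxy - Sx * Sx.T
        varx = n * Sxx - Sx ** 2
        vary = varx.T
        corr = cov / np.sqrt(varx * vary)
    corr[n < min_shared] = np.nan
    corr[~np.isfinite(corr)] = np.nan
    defined = np.isfinite(np.diagonal(corr))
    corr[np.diag_indices_from(corr)] = np.where(defined, 1.0, np.nan)
    return corr
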