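"""Pair parsing/filtering, binning, KR balancing, O/E and correlation."""

import numpy as np
import pytest
import scipy.sparse as sp

from cohic.contacts import (ContactMatrix, ContactPair, bin_pairs,
                            bin_pairs_table, correlation_matrix,
                            expected_by_distance, filter_pairs,
                            filter_pairs_table, kr_balance,
                            observed_over_expected, pool_matrices, read_pairs,
                            read_pairs_table, write_pairs)
from cohic.genome import BinGrid


def matrix_from_dense(dense, bin_size=1):
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    grid = BinGrid(bin_size, {"chrX": n * bin_size})
    return ContactMatrix(grid, "chrX", sp.csr_matrix(dense))


def sinkhorn_weights(dense, tol=1e-12, max_iter=100_000):
    """Independent symmetric Sinkhorn-Knopp scaling oracle (row sums -> 1)."""
    A = np.asarray(dense, dtype=float)
    x = np.ones(A.shape[0])
    for _ in range(max_iter):
        s = x * (A @ x)
        if np.max(np.abs(s - 1)) < tol:
            break
        x = x / np.sqrt(s)
    return x


class TestReadPairs:
    def test_parse_and_canonicalize(self, tmp_path):
        p = tmp_path / "x.pairs"
        p.write_text("## pairs format v1.0\n"
                     ".\tchr1\t100\tchr1\t5100\t+\t-\n"
                     ".\tchr1\t5100\tchr1\t100\t+\t-\n")
        pairs = list(read_pairs(p))
        assert all(q.pos1 == 100 and q.pos2 == 5100 for q in pairs)
        # canonicalization swaps strands along with positions
        assert pairs[1].strand1 == "-" and pairs[1].strand2 == "+"

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "x.pairs"
        p.write_text(".\tchr1\t100\tchr1\t5100\n.\tchr1\t100\n")
        with pytest.raises(ValueError, match="2"):
            list(read_pairs(p))

    def test_header_chromsize_validated(self, tmp_path):
        p = tmp_path / "x.pairs"
        p.write_text("#chromsize: chr1 999\n.\tchr1\t1\tchr1\t5000\n")
        with pytest.raises(ValueError):
            list(read_pairs(p, {"chr1": 20_000}))

    def test_table_reader_matches_streaming(self, tmp_path, rng):
        p = tmp_path / "x.pairs"
        lines = ["## pairs\n"]
        for _ in range(200):
            a, b = sorted(rng.integers(0, 50_000, 2))
            c1, c2 = sorted(rng.choice(["chr1", "chr2"], 2))
            lines.append(f".\t{c2}\t{a}\t{c1}\t{b}\t+\t-\n")
        p.write_text("".join(lines))
        streamed = [(q.chrom1, q.pos1, q.chrom2, q.pos2, q.strand1, q.strand2)
                    for q in read_pairs(p)]
        table = [tuple(r) for r in read_pairs_table(p).itertuples(index=False)]
        assert streamed == table


class TestFilterPairs:
    def make(self, d):
        return ContactPair.make("chr1", 10_000, "chr1", 10_000 + d)

    def test_minimum_distance_boundary_inclusive(self):
        kept, rep = filter_pairs([self.make(999), self.make(1000), self.make(1001)])
        assert [p.distance for p in kept] == [1000, 1001]
        assert rep.n_short_range == 1

    def test_exact_duplicates_collapsed(self):
        kept, rep = filter_pairs([self.make(5000), self.make(5000), self.make(5001)])
        assert len(kept) == 2 and rep.n_duplicate == 1

    def test_inter_chromosomal_pairs_not_distance_filtered(self):
        p = ContactPair.make("chr1", 10, "chr2", 20)
        kept, rep = filter_pairs([p])
        assert kept == [p] and rep.n_short_range == 0

    def test_empty_input(self):
        kept, rep = filter_pairs([])
        assert kept == [] and rep.n_input == 0

    def test_table_filter_matches_streaming(self, tmp_path, rng):
        pairs = [ContactPair.make("chr1", int(a), "chr1", int(a) + int(d))
                 for a, d in zip(rng.integers(0, 90_000, 500), rng.integers(0, 3_000, 500))]
        pairs += pairs[:50]  # duplicates
        kept_s, rep_s = filter_pairs(pairs)
        p = tmp_path / "x.pairs"
        write_pairs(p, pairs)
        kept_t, rep_t = filter_pairs_table(read_pairs_table(p))
        assert rep_s.as_dict() == rep_t.as_dict()
        assert len(kept_s) == len(kept_t)


class TestBinPairs:
    def test_basic_increments_and_mirror(self, small_grid):
        pairs = [ContactPair.make("chr1", 100, "chr1", 5100)]
        mats, rep = bin_pairs(pairs, small_grid)
        m = mats["chr1"].counts
        assert m[0, 1] == 1 == m[1, 0] and rep["n_intra"] == 1

    def test_same_bin_diagonal_single_increment(self, small_grid):
        pairs = [ContactPair.make("chr1", 15_000, "chr1", 16_000)]
        mats, _ = bin_pairs(pairs, small_grid)
        assert mats["chr1"].counts[3, 3] == 1

    def test_additivity(self, small_grid):
        pairs = [ContactPair.make("chr1", 100, "chr1", 5100)] * 10
        mats, _ = bin_pairs(pairs, small_grid)
        assert mats["chr1"].counts[0, 1] == 10

    def test_position_beyond_chromosome_raises(self, small_grid):
        with pytest.raises(ValueError):
            bin_pairs([ContactPair.make("chr1", 0, "chr1", 100_000)], small_grid)

    def test_inter_chromosomal_counted_not_stored(self):
        grid = BinGrid(5000, {"chr1": 50_000, "chr2": 50_000})
        mats, rep = bin_pairs([ContactPair.make("chr1", 10, "chr2", 10)], grid)
        assert rep["n_inter"] == 1
        assert mats["chr1"].counts.nnz == 0 and mats["chr2"].counts.nnz == 0

    def test_order_independence(self, small_grid, rng):
        pairs = [ContactPair.make("chr1", int(a), "chr1", int(b))
                 for a, b in rng.integers(0, 99_999, size=(300, 2))]
        kept, _ = filter_pairs(pairs)
        m1, _ = bin_pairs(kept, small_grid)
        shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
        kept2, _ = filter_pairs(shuffled)
        m2, _ = bin_pairs(kept2, small_grid)
        assert (m1["chr1"].counts != m2["chr1"].counts).nnz == 0

    def test_table_binning_matches_streaming(self, small_grid, tmp_path, rng):
        pairs = [ContactPair.make("chr1", int(a), "chr1", int(b))
                 for a, b in rng.integers(0, 99_999, size=(300, 2))]
        m1, _ = bin_pairs(pairs, small_grid)
        p = tmp_path / "x.pairs"
        write_pairs(p, pairs)
        m2, _ = bin_pairs_table(read_pairs_table(p), small_grid)
        assert (m1["chr1"].counts != m2["chr1"].counts).nnz == 0


class TestPoolMatrices:
    def test_counts_sum(self, small_grid):
        a, _ = bin_pairs([ContactPair.make("chr1", 100, "chr1", 5100)] * 3, small_grid)
        b, _ = bin_pairs([ContactPair.make("chr1", 100, "chr1", 5100)] * 4, small_grid)
        pooled = pool_matrices([a["chr1"], b["chr1"]])
        assert pooled.counts[0, 1] == 7

    def test_identity_and_zero(self, small_grid):
        a, _ = bin_pairs([ContactPair.make("chr1", 100, "chr1", 5100)], small_grid)
        zero = ContactMatrix(small_grid, "chr1", sp.csr_matrix((20, 20)))
        single = pool_matrices([a["chr1"]])
        with_zero = pool_matrices([a["chr1"], zero])
        assert (single.counts != a["chr1"].counts).nnz == 0
        assert (with_zero.counts != a["chr1"].counts).nnz == 0

    def test_grid_mismatch_raises(self, small_grid):
        other = ContactMatrix(BinGrid(5000, {"chr1": 50_000}), "chr1",
                              sp.csr_matrix((10, 10)))
        zero = ContactMatrix(small_grid, "chr1", sp.csr_matrix((20, 20)))
        with pytest.raises(ValueError):
            pool_matrices([zero, other])

    def test_pool_equals_binning_concatenated_streams(self, small_grid, rng):
        s1 = [ContactPair.make("chr1", int(a), "chr1", int(b))
              for a, b in rng.integers(0, 99_999, size=(100, 2))]
        s2 = [ContactPair.make("chr1", int(a), "chr1", int(b))
              for a, b in rng.integers(0, 99_999, size=(150, 2))]
        m1, _ = bin_pairs(s1, small_grid)
        m2, _ = bin_pairs(s2, small_grid)
        pooled = pool_matrices([m1["chr1"], m2["chr1"]])
        direct, _ = bin_pairs(s1 + s2, small_grid)
        assert (pooled.counts != direct["chr1"].counts).nnz == 0


class TestKrBalance:
    def test_already_balanced_2x2(self):
        m = matrix_from_dense([[0, 1], [1, 0]])
        w = kr_balance(m, mask_percentile=0)
        bal = m.balanced_dense()
        assert np.allclose(np.nansum(bal, axis=1), 1.0, atol=1e-8)
        assert np.allclose(w, [1, 1], atol=1e-6)

    def test_matches_sinkhorn_oracle_on_positive_matrix(self, rng):
        dense = rng.uniform(0.5, 2.0, (3, 3))
        dense = dense + dense.T
        m = matrix_from_dense(dense)
        w = kr_balance(m, tol=1e-10, mask_percentile=0)
        oracle = sinkhorn_weights(dense)
        assert np.allclose(w, oracle, atol=1e-6)

    def test_row_sum_contract_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 50))
            dense = rng.uniform(0.1, 1.0, (n, n))
            dense = dense + dense.T
            m = matrix_from_dense(dense)
            kr_balance(m, tol=1e-10, mask_percentile=0)
            assert m.balance_converged
            rs = np.nansum(m.balanced_dense(), axis=1)
            assert np.max(np.abs(rs - 1)) < 1e-6

    def test_scale_invariance(self, rng):
        dense = rng.uniform(0.5, 1.5, (8, 8))
        dense = dense + dense.T
        w1 = kr_balance(matrix_from_dense(dense), tol=1e-12, mask_percentile=0)
        w2 = kr_balance(matrix_from_dense(dense * 16.0), tol=1e-12, mask_percentile=0)
        assert np.allclose(w2, w1 / 4.0, rtol=1e-6)

    def test_zero_row_masked_then_balanced(self):
        dense = np.array([[0.0, 0, 0], [0, 0, 2], [0, 2, 1]])
        m = matrix_from_dense(dense)
        w = kr_balance(m, mask_percentile=0)
        assert np.isnan(w[0]) and np.isfinite(w[1:]).all()
        rs = np.nansum(m.balanced_dense()[1:, :], axis=1)
        assert np.allclose(rs, 1.0, atol=1e-6)

    def test_fully_masked_raises(self):
        m = matrix_from_dense(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            kr_balance(m)


class TestExpectedAndOE:
    def balanced_uniform(self, n=6, v=1.0):
        m = matrix_from_dense(np.full((n, n), v))
        kr_balance(m, mask_percentile=0)
        return m

    def test_constant_matrix_constant_profile(self):
        m = self.balanced_uniform()
        prof = expected_by_distance(m)
        assert np.allclose(prof.values, prof.values[0])

    def test_profile_matches_brute_force(self, rng):
        dense = rng.uniform(0.2, 2.0, (12, 12))
        dense = dense + dense.T
        m = matrix_from_dense(dense)
        kr_balance(m, mask_percentile=0)
        bal = m.balanced_dense()
        prof = expected_by_distance(m)
        n = 12
        for d in range(n):
            vals = [bal[i, i + d] for i in range(n - d)]
            assert np.isclose(prof.values[d], np.mean(vals))

    def test_offset_beyond_size_missing(self):
        prof = expected_by_distance(self.balanced_uniform(4))
        assert np.isnan(prof[10])

    def test_oe_identity_when_matrix_equals_expected(self):
        m = self.balanced_uniform()
        oe = observed_over_expected(m)
        assert np.allclose(oe, 1.0)

    def test_oe_scales_locally(self, rng):
        dense = np.full((6, 6), 2.0)
        m = matrix_from_dense(dense)
        kr_balance(m, mask_percentile=0)
        prof = expected_by_distance(m)
        bal = m.balanced_dense()
        bal[1, 3] *= 2
        bal[3, 1] *= 2
        oe = bal / prof.values[np.abs(np.subtract.outer(range(6), range(6)))]
        assert np.isclose(oe[1, 3], 2.0) and np.isclose(oe[0, 2], 1.0)

    def test_masked_bin_row_missing(self):
        dense = np.array([[0.0, 0, 0], [0, 1, 2], [0, 2, 1]])
        m = matrix_from_dense(dense)
        kr_balance(m, mask_percentile=0)
        oe = observed_over_expected(m)
        assert np.isnan(oe[0]).all() and np.isnan(oe[:, 0]).all()


class TestCorrelationMatrix:
    def test_identical_rows_correlate_to_one(self):
        row = np.array([1.0, 2.0, 3.0, 4.0])
        oe = np.vstack([row, row, -row, row * 2 + 7])
        corr = correlation_matrix(oe, min_shared=3)
        assert np.isclose(corr[0, 1], 1.0)
        assert np.isclose(corr[0, 2], -1.0)
        assert np.isclose(corr[0, 3], 1.0)  # affine of the same row

    def test_matches_brute_force_oracle(self, rng):
        oe = rng.normal(size=(20, 20))
        oe[3, 7] = np.nan
        corr = correlation_matrix(oe, min_shared=3)
        for i in range(20):
            for j in range(20):
                ok = np.isfinite(oe[i]) & np.isfinite(oe[j])
                expected = np.corrcoef(oe[i, ok], oe[j, ok])[0, 1]
                assert abs(corr[i, j] - expected) < 1e-10

    def test_entries_bounded_and_symmetric(self, rng):
        oe = rng.normal(size=(15, 15))
        corr = correlation_matrix(oe)
        finite = corr[np.isfinite(corr)]
        assert np.all(finite <= 1 + 1e-12) and np.all(finite >= -1 - 1e-12)
        assert np.allclose(corr, corr.T, equal_nan=True)

    def test_zero_variance_row_missing(self):
        oe = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2,
                        np.arange(5.0) ** 0.5])
        corr = correlation_matrix(oe, min_shared=3)
        assert np.isnan(corr[0, 1]) and np.isnan(corr[0, 0])


class TestPersistence:
    def test_tsv_round_trip(self, small_grid, rng, tmp_path):
        pairs = [ContactPair.make("chr1", int(a), "chr1", int(b))
                 for a, b in rng.integers(0, 99_999, size=(200, 2))]
        mats, _ = bin_pairs(pairs, small_grid)
        m = mats["chr1"]
        kr_balance(m, mask_percentile=0)
        m.save(tmp_path / "m")
        back = ContactMatrix.load(tmp_path / "m")
        assert (back.counts != m.counts).nnz == 0
        assert np.allclose(back.weights, m.weights, equal_nan=True)
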