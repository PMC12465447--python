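"""Compartment eigenvectors, orientation, delta ranking, and group features."""

import numpy as np
import pytest

from cohic.compartments import (CompartmentProfile, compartment_eigenvector,
                                delta_scores, group_feature_expression,
                                group_feature_genic_fraction,
                                group_feature_peak_distance,
                                intergenic_peak_filter, orient_eigenvector,
                                rank_and_group, score_at_intervals)
from cohic.genome import BinGrid, GenomicInterval

from conftest import make_gene, make_peaks


def two_block_corr(n_a=10, n_b=10):
    c = np.ones((n_a + n_b, n_a + n_b))
    c[:n_a, n_a:] = -1
    c[n_a:, :n_a] = -1
    return c


class TestEigenvector:
    def test_checkerboard_two_block_structure(self):
        v = compartment_eigenvector(two_block_corr())
        assert np.allclose(np.abs(v), np.abs(v[0]))
        assert np.all(np.sign(v[:10]) == np.sign(v[0]))
        assert np.all(np.sign(v[10:]) == -np.sign(v[0]))

    def test_agrees_with_dense_eigensolver_oracle(self, rng):
        for _ in range(10):
            m = rng.normal(size=(30, 30))
            m = 0.5 * (m + m.T)
            v = compartment_eigenvector(m)
            evals, evecs = np.linalg.eigh(m)
            lead = evecs[:, np.argmax(np.abs(evals))]
            cos = abs(v @ lead) / (np.linalg.norm(v) * np.linalg.norm(lead))
            assert cos > 1 - 1e-8

    def test_all_equal_rows_flat_eigenvector(self):
        v = compartment_eigenvector(np.ones((8, 8)))
        assert np.allclose(np.abs(v), np.abs(v[0]))

    def test_missing_rows_propagate(self):
        c = two_block_corr(5, 5).astype(float)
        c[2, :] = np.nan
        c[:, 2] = np.nan
        v = compartment_eigenvector(c)
        assert np.isnan(v[2]) and np.isfinite(np.delete(v, 2)).all()

    def test_too_few_bins_gives_missing_profile(self):
        c = np.full((5, 5), np.nan)
        c[0, 0] = c[1, 1] = 1.0
        assert np.isnan(compartment_eigenvector(c)).all()

    def test_permutation_invariance_up_to_sign(self, rng):
        m = rng.normal(size=(20, 20))
        m = 0.5 * (m + m.T)
        v = compartment_eigenvector(m)
        perm = rng.permutation(20)
        vp = compartment_eigenvector(m[np.ix_(perm, perm)])
        restored = np.empty(20)
        restored[perm] = vp
        assert min(np.max(np.abs(restored - v)), np.max(np.abs(restored + v))) < 1e-8


class TestOrientation:
    def setup_method(self):
        self.grid = BinGrid(25_000, {"chr1": 250_000})

    def test_anticorrelated_scores_flipped(self):
        active = np.arange(10.0)
        scores = -np.arange(10.0) + 4.5
        prof = orient_eigenvector(scores, self.grid, "chr1", active, np.zeros(10))
        assert prof.scores[-1] > 0 and prof.orientation_evidence > 0

    def test_correlated_scores_unchanged(self):
        active = np.arange(10.0)
        scores = np.arange(10.0) - 4.5
        prof = orient_eigenvector(scores, self.grid, "chr1", active, np.zeros(10))
        assert np.allclose(prof.scores, scores)

    def test_flat_evidence_unresolved(self):
        prof = orient_eigenvector(np.arange(10.0), self.grid, "chr1",
                                  np.ones(10), np.ones(10))
        assert not prof.orientation_resolved


class TestDeltaScores:
    def make_profile(self, scores):
        grid = BinGrid(25_000, {"chr1": 25_000 * len(scores)})
        return CompartmentProfile(grid, "chr1", np.asarray(scores, float))

    def test_identical_profiles_zero_delta(self):
        a = self.make_profile([0.5, -0.5, 0.5])
        b = self.make_profile([0.5, -0.5, 0.5])
        assert np.allclose(delta_scores(a, b), 0.0)

    def test_missing_propagates(self):
        a = self.make_profile([0.5, np.nan, 0.5])
        b = self.make_profile([0.5, -0.5, 0.5])
        d = delta_scores(a, b)
        assert np.isnan(d[1]) and np.isfinite(d[[0, 2]]).all()

    def test_scale_free(self):
        a = self.make_profile([1.0, -1.0, 2.0])
        b = self.make_profile([10.0, -10.0, 20.0])  # same shape, x10
        assert np.allclose(delta_scores(a, b), 0.0, atol=1e-12)


class TestRankAndGroup:
    def profiles_with_deltas(self, n_bins, deltas, scores=None):
        grid = BinGrid(25_000, {"chr1": 25_000 * n_bins})
        s = np.ones(n_bins) if scores is None else np.asarray(scores, float)
        prof = CompartmentProfile(grid, "chr1", s)
        return {"chr1": np.asarray(deltas, float)}, {"chr1": prof}

    def test_sets_of_500_partition(self, rng):
        deltas, profs = self.profiles_with_deltas(1200, rng.normal(size=1200))
        groups = rank_and_group(deltas, profs, group_size=500)
        assert groups.group_sizes() == [500, 500, 200]

    def test_small_groups_remainder(self):
        deltas, profs = self.profiles_with_deltas(7, np.arange(7.0))
        groups = rank_and_group(deltas, profs, group_size=3)
        assert groups.group_sizes() == [3, 3, 1]

    def test_sorted_most_negative_first_with_tie_break(self):
        deltas, profs = self.profiles_with_deltas(5, [0.2, -0.1, -0.1, -0.5, 0.0])
        groups = rank_and_group(deltas, profs, group_size=2)
        assert groups.bins["bin"].tolist() == [3, 1, 2, 4, 0]

    def test_only_control_a_bins_ranked(self):
        deltas, profs = self.profiles_with_deltas(
            6, np.arange(6.0), scores=[1, -1, 1, -1, 1, np.nan])
        groups = rank_and_group(deltas, profs, group_size=10)
        assert sorted(groups.bins["bin"]) == [0, 2, 4]

    def test_concatenation_reproduces_sorted_list(self, rng):
        deltas, profs = self.profiles_with_deltas(950, rng.normal(size=950))
        groups = rank_and_group(deltas, profs, group_size=500)
        d = groups.bins["delta"].to_numpy()
        assert len(groups.bins) == 950
        assert np.all(np.diff(d) >= 0)
        assert groups.bins["bin"].nunique() == 950

    def test_no_a_bins_empty(self):
        deltas, profs = self.profiles_with_deltas(4, np.arange(4.0),
                                                  scores=[-1, -1, -1, -1])
        groups = rank_and_group(deltas, profs)
        assert groups.n_groups == 0 and groups.group_sizes() == []


class TestGroupFeatures:
    def setup_method(self):
        self.grid = BinGrid(25_000, {"chr1": 250_000})
        deltas = {"chr1": np.linspace(-1, 1, 10)}
        profs = {"chr1": CompartmentProfile(self.grid, "chr1", np.ones(10))}
        self.groups = rank_and_group(deltas, profs, group_size=5)

    def test_expression_feature_single_gene(self):
        gene = make_gene("g1", "chr1", 0, 250_000)
        vals = group_feature_expression(self.groups, self.grid, [gene],
                                        {"g1": -2.0}, {"g1": 3.0})
        assert np.allclose(vals, -2.0)

    def test_low_cpm_gene_excluded(self):
        gene = make_gene("g1", "chr1", 0, 250_000)
        vals = group_feature_expression(self.groups, self.grid, [gene],
                                        {"g1": -2.0}, {"g1": 0.0})
        assert np.isnan(vals).all()

    def test_genic_fraction_extremes(self):
        all_genic = [make_gene("g1", "chr1", 0, 250_000)]
        assert np.allclose(group_feature_genic_fraction(self.groups, self.grid,
                                                        all_genic), 1.0)
        assert np.allclose(group_feature_genic_fraction(self.groups, self.grid, []),
                           0.0)

    def test_genic_fraction_matches_interval_scan_oracle(self, rng):
        genes = [make_gene(f"g{k}", "chr1", int(s), int(s) + 8_000)
                 for k, s in enumerate(rng.integers(0, 240_000, 6))]
        vals = group_feature_genic_fraction(self.groups, self.grid, genes)
        gof = self.groups.group_of
        for g_idx in range(self.groups.n_groups):
            rows = self.groups.bins[gof == g_idx]
            hits = 0
            for b in rows["bin"]:
                iv = self.grid.bin_interval("chr1", b)
                hits += any(iv.overlaps(g.interval) for g in genes)
            assert np.isclose(vals[g_idx], hits / len(rows))

    def test_peak_filter_removes_genic_and_promoter_peaks(self):
        genes = [make_gene("g1", "chr1", 50_000, 60_000, "+")]
        peaks = make_peaks("H3K27ac", [
            ("chr1", 52_000, 53_000),   # inside gene body
            ("chr1", 49_600, 49_900),   # in 500 bp upstream promoter window
            ("chr1", 100_000, 101_000),  # intergenic survivor
        ])
        surviving = intergenic_peak_filter(peaks, genes, 500)
        assert [(p.start, p.end) for p in surviving] == [(100_000, 101_000)]

    def test_peak_distance_feature(self):
        genes = []
        peaks = make_peaks("H3K27ac", [("chr1", 0, 1_000)])
        vals = group_feature_peak_distance(self.groups, self.grid, peaks, genes)
        gof = self.groups.group_of
        for g_idx in range(self.groups.n_groups):
            rows = self.groups.bins[gof == g_idx]
            dists = []
            for b in rows["bin"]:
                iv = self.grid.bin_interval("chr1", b)
                dists.append(max(iv.start - 1_000, 0))
            assert np.isclose(vals[g_idx], np.mean(dists))


class TestScoreAtIntervals:
    def setup_method(self):
        grid = BinGrid(100, {"chr1": 1_000})
        scores = np.arange(10.0)
        self.prof = CompartmentProfile(grid, "chr1", scores)

    def test_interval_inside_one_bin(self):
        v = score_at_intervals(self.prof, [GenomicInterval("chr1", 310, 360)])
        assert v[0] == 3.0

    def test_equal_straddle_is_mean(self):
        v = score_at_intervals(self.prof, [GenomicInterval("chr1", 250, 350)])
        assert np.isclose(v[0], 2.5)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(50):
            s = int(rng.integers(0, 900))
            e = s + int(rng.integers(1, 100))
            got = score_at_intervals(self.prof, [GenomicInterval("chr1", s, e)])[0]
            per_base = np.mean([self.prof.scores[p // 100] for p in range(s, e)])
            assert np.isclose(got, per_base)

    def test_missing_bins_excluded(self):
        self.prof.scores[3] = np.nan
        v = score_at_intervals(self.prof, [GenomicInterval("chr1", 250, 450)])
        assert np.isclose(v[0], (2.0 * 50 + 4.0 * 50) / 100)
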