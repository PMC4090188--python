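"""LD statistics, EM haplotype frequencies, block detection, haplotype
score tests, sharing segments and interval intersection."""

import itertools

import numpy as np
import pytest
from scipy import stats

from earmap.formats import MarkerMap
from earmap.haplotypes import (
    detect_blocks, em_haplotype_frequencies, hap_score_test,
    intersect_intervals, ld_pair, recode_major_minor, shared_segments,
)


def _map(m, spacing=1000, chrom="5"):
    return MarkerMap(
        [f"m{j}" for j in range(m)], [chrom] * m,
        list(range(spacing, spacing * (m + 1), spacing)),
        ["A"] * m, ["G"] * m,
    )


def _from_haps(haps, geno_factory, spacing=1000):
    """Build an unphased genotype matrix from a (2n, m) haplotype stack."""
    haps = np.asarray(haps)
    n = haps.shape[0] // 2
    dosage = haps[0::2] + haps[1::2]
    return geno_factory(dosage.astype(float), markers=_map(haps.shape[1], spacing))


class TestLdPair:
    def test_identical_markers_full_ld(self, geno_factory):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, 200).astype(float)
        g = geno_factory(np.column_stack([col, col]))
        ld = ld_pair(g, "m0", "m1")
        assert ld.r2 == pytest.approx(1.0, abs=1e-6)
        assert abs(ld.d_prime) == pytest.approx(1.0, abs=1e-6)

    def test_independent_markers_low_ld(self, geno_factory):
        rng = np.random.default_rng(1)
        n = 500
        g = geno_factory(np.column_stack([
            rng.binomial(2, 0.5, n), rng.binomial(2, 0.5, n)]).astype(float))
        ld = ld_pair(g, "m0", "m1")
        assert ld.r2 < 0.02         # E[r2] ~ 1/(2n) under independence

    def test_no_double_het_equals_gamete_counting(self, geno_factory):
        """Without double heterozygotes, phase is unambiguous and EM must
        equal direct gamete counting."""
        haps = np.array([
            [0, 0], [0, 0], [1, 1], [1, 1], [0, 0], [0, 1],
            [1, 1], [1, 0], [0, 1], [0, 1], [1, 0], [1, 0],
        ])
        g = _from_haps(haps, geno_factory)
        # verify construction has no double hets
        assert not ((g.dosage == 1).sum(axis=1) == 2).any()
        ld = ld_pair(g, "m0", "m1")
        n_h = len(haps)
        for pair in itertools.product((0, 1), repeat=2):
            direct = (haps == np.asarray(pair)).all(axis=1).mean()
            assert ld.hap_freqs[pair] == pytest.approx(direct, abs=1e-9)

    def test_monomorphic_raises(self, geno_factory):
        g = geno_factory(np.column_stack([
            np.zeros(10), np.arange(10) % 3]).astype(float))
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(g, "m0", "m1")

    def test_r2_symmetric(self, geno_factory):
        rng = np.random.default_rng(2)
        g = geno_factory(rng.integers(0, 3, (100, 2)).astype(float))
        assert ld_pair(g, "m0", "m1").r2 == pytest.approx(
            ld_pair(g, "m1", "m0").r2, rel=1e-9)


class TestEmFrequencies:
    def test_unambiguous_sample_equals_counts(self, geno_factory):
        haps = np.array([
            [0, 0, 0], [0, 0, 0],
            [1, 1, 1], [1, 1, 1],
            [0, 0, 0], [1, 1, 1],
            [0, 0, 0], [0, 0, 0],
        ])
        g = _from_haps(haps, geno_factory)
        em = em_haplotype_frequencies(g, ["m0", "m1", "m2"])
        assert em.converged
        for h, f in zip(em.haplotypes, em.frequencies):
            direct = (haps == np.asarray(h)).all(axis=1).mean()
            assert f == pytest.approx(direct, abs=1e-7)

    def test_single_double_het_stays_symmetric(self, geno_factory):
        g = geno_factory(np.array([[1.0, 1.0]]))
        em = em_haplotype_frequencies(g, ["m0", "m1"])
        pairs = dict(em.posteriors[0])
        assert len(pairs) == 2
        for p in pairs.values():
            assert p == pytest.approx(0.5)

    def test_known_frequencies_recovered(self, geno_factory):
        rng = np.random.default_rng(3)
        pool = [(0, 0), (1, 1), (1, 0)]
        freqs = [0.5, 0.3, 0.2]
        n = 2000
        hap_draws = rng.choice(len(pool), size=2 * n, p=freqs)
        haps = np.asarray([pool[k] for k in hap_draws])
        g = _from_haps(haps, geno_factory)
        em = em_haplotype_frequencies(g, ["m0", "m1"])
        for h, f_true in zip(pool, freqs):
            se = np.sqrt(f_true * (1 - f_true) / (2 * n))
            assert em.frequency_of(h) == pytest.approx(f_true, abs=3.5 * se)

    def test_loglik_nondecreasing(self, geno_factory):
        rng = np.random.default_rng(4)
        g = geno_factory(rng.integers(0, 3, (80, 4)).astype(float))
        em = em_haplotype_frequencies(g, ["m0", "m1", "m2", "m3"])
        assert (np.diff(em.loglik_trace) > -1e-9).all()

    def test_window_bound_enforced(self, geno_factory):
        g = geno_factory(np.zeros((2, 13)))
        with pytest.raises(ValueError, match="enumeration bound"):
            em_haplotype_frequencies(g, [f"m{j}" for j in range(13)])


class TestBlocks:
    def test_perfect_ld_single_block(self, geno_factory):
        rng = np.random.default_rng(5)
        base = rng.binomial(1, 0.5, (400, 1))
        haps = np.repeat(base, 4, axis=1)
        g = _from_haps(haps, geno_factory)
        blocks = detect_blocks(g)
        assert len(blocks) == 1
        assert (blocks[0].first_index, blocks[0].last_index) == (0, 3)

    def test_two_clusters_exclude_separator(self, geno_factory):
        rng = np.random.default_rng(6)
        a = rng.binomial(1, 0.5, (600, 1))
        b = rng.binomial(1, 0.5, (600, 1))
        sep = rng.binomial(1, 0.5, (600, 1))
        haps = np.hstack([a, a, a, sep, b, b, b])
        g = _from_haps(haps, geno_factory)
        blocks = detect_blocks(g)
        spans = sorted((blk.first_index, blk.last_index) for blk in blocks)
        assert spans == [(0, 2), (4, 6)]

    def test_independent_markers_no_blocks(self, geno_factory):
        rng = np.random.default_rng(7)
        haps = rng.binomial(1, 0.5, (600, 5))
        g = _from_haps(haps, geno_factory)
        assert detect_blocks(g) == []

    def test_single_marker_returns_empty(self, geno_factory):
        g = geno_factory(np.array([[0.0], [1.0], [2.0]]))
        assert detect_blocks(g) == []


class TestHapScore:
    def test_single_marker_reduces_to_score_z_squared(self, geno_factory):
        """For one marker the global statistic equals n*r^2, the squared
        score-test z of the marker regression."""
        rng = np.random.default_rng(8)
        n = 150
        d = rng.binomial(2, 0.4, n).astype(float)
        y = 0.4 * d + rng.normal(size=n)
        g = geno_factory(d[:, None])
        trait = {f"i{i}": y[i] for i in range(n)}
        res = hap_score_test(g, ["m0"], trait, min_freq=0.0)
        r = np.corrcoef(d, y)[0, 1]
        assert res.df == 1
        assert res.global_stat == pytest.approx(n * r * r, rel=1e-8)

    def test_permutation_null_calibration(self, geno_factory):
        """Trait independent of haplotypes: the global statistic has mean
        ~ df and uniform P-values over permutations."""
        rng = np.random.default_rng(9)
        n = 120
        haps = rng.binomial(1, 0.5, (2 * n, 2))
        g = _from_haps(haps, geno_factory)
        y = rng.normal(size=n)
        stats_, ps = [], []
        for _ in range(300):
            perm = rng.permutation(n)
            trait = {f"i{i}": y[perm[i]] for i in range(n)}
            res = hap_score_test(g, ["m0", "m1"], trait, min_freq=0.01)
            stats_.append(res.global_stat)
            ps.append(res.global_p)
        df = res.df
        assert np.mean(stats_) == pytest.approx(df, rel=0.15)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_sign_flips_with_trait_negation(self, geno_factory):
        rng = np.random.default_rng(10)
        n = 200
        haps = rng.binomial(1, 0.5, (2 * n, 2))
        # haplotype (1,1) carries a positive effect
        eff = ((haps[0::2] == 1).all(axis=1).astype(float)
               + (haps[1::2] == 1).all(axis=1).astype(float))
        y = 1.0 * eff + rng.normal(size=n)
        g = _from_haps(haps, geno_factory)
        t1 = {f"i{i}": y[i] for i in range(n)}
        t2 = {f"i{i}": -y[i] for i in range(n)}
        r1 = hap_score_test(g, ["m0", "m1"], t1)
        r2 = hap_score_test(g, ["m0", "m1"], t2)
        k = r1.haplotypes.index("GG")
        assert r1.scores[k] > 0
        np.testing.assert_allclose(r1.scores, -np.asarray(r2.scores), rtol=1e-9)

    def test_affine_invariance_of_global_stat(self, geno_factory):
        rng = np.random.default_rng(11)
        n = 100
        haps = rng.binomial(1, 0.5, (2 * n, 2))
        y = rng.normal(size=n)
        g = _from_haps(haps, geno_factory)
        r1 = hap_score_test(g, ["m0", "m1"], {f"i{i}": y[i] for i in range(n)})
        r2 = hap_score_test(g, ["m0", "m1"],
                            {f"i{i}": 3.0 * y[i] - 7.0 for i in range(n)})
        assert r1.global_stat == pytest.approx(r2.global_stat, rel=1e-9)

    def test_rare_haplotypes_pooled(self, geno_factory):
        rng = np.random.default_rng(12)
        n = 300
        # one haplotype is very rare
        pool = [(0, 0), (1, 1), (1, 0)]
        freqs = [0.55, 0.43, 0.02]
        draws = rng.choice(3, 2 * n, p=freqs)
        haps = np.asarray([pool[k] for k in draws])
        g = _from_haps(haps, geno_factory)
        y = rng.normal(size=n)
        res = hap_score_test(g, ["m0", "m1"], {f"i{i}": y[i] for i in range(n)},
                             min_freq=0.05)
        assert res.n_pooled >= 1
        assert res.df == len(res.haplotypes) - 1


class TestSharedSegments:
    def test_all_identical_single_segment(self):
        haps = np.zeros((4, 6), dtype=int)
        segs = shared_segments(haps, _map(6))
        assert len(segs) == 1
        assert segs[0].n_markers == 6
        assert segs[0].bp_length == 5000

    def test_middle_mismatch_splits(self):
        haps = np.zeros((3, 5), dtype=int)
        haps[2, 2] = 1
        segs = shared_segments(haps, _map(5))
        assert [(s.first_index, s.last_index) for s in segs] == [(0, 1), (3, 4)]

    def test_segments_maximal_non_adjacent(self):
        rng = np.random.default_rng(13)
        haps = rng.binomial(1, 0.5, (6, 40))
        segs = shared_segments(haps, _map(40))
        for a, b in zip(segs, segs[1:]):
            assert b.first_index > a.last_index + 1

    def test_unphased_genotypes_raise(self, geno_factory):
        g = geno_factory(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="phased"):
            shared_segments(g)

    def test_major_minor_display_coding(self):
        haps = np.array([[0, 1], [0, 1], [1, 0]])
        coded = recode_major_minor(haps)
        np.testing.assert_array_equal(coded, [[1, 1], [1, 1], [2, 2]])


class TestIntersectIntervals:
    def test_reported_region_arithmetic(self):
        """Sharing span x block span -> 3.07-Mb style overlap."""
        out = intersect_intervals(
            [(30.23e6, 34.02e6)], [(28.0e6, 33.30e6)])
        assert out == [(30.23e6, 33.30e6)]
        assert (out[0][1] - out[0][0]) == pytest.approx(3.07e6)

    def test_disjoint_empty(self):
        assert intersect_intervals([(0, 1)], [(2, 3)]) == []

    def test_identity(self):
        assert intersect_intervals([(5, 9)], [(5, 9)]) == [(5, 9)]

    def test_merge_overlapping_pieces(self):
        out = intersect_intervals([(0, 10), (5, 20)], [(3, 15)])
        assert out == [(3, 15)]
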