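"""Population-genetic statistics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetscan.core import Window
from hetscan.popgen import (fst, het_rate, ld_decay, ld_r2,
                            nucleotide_diversity, p_distance, site_stats,
                            tajimas_d, window_mean_he, window_stats_table)

from conftest import make_matrix, random_matrix
from oracles import (he_oracle, hudson_fst_oracle, p_distance_oracle,
                     pi_site_oracle, r2_oracle, tajimas_d_oracle,
                     window_pi_oracle)


class TestSiteStats:
    def test_half_half_frequency(self):
        m = make_matrix(np.array([[0], [0], [2], [2]]))
        s = site_stats(m)
        assert s["p_alt"][0] == 0.5 and s["he"][0] == 0.5

    def test_monomorphic_he_zero(self):
        m = make_matrix(np.array([[0], [0], [0], [0]]))
        assert site_stats(m)["he"][0] == 0.0

    def test_missing_excluded_from_allele_count(self):
        # codes (0,1,2,MISSING): 3 alt copies of 6 -> p = 0.5
        m = make_matrix(np.array([[0], [1], [2], [-1]]))
        s = site_stats(m)
        assert s["p_alt"][0] == 0.5 and s["n_chrom"][0] == 6

    def test_matches_oracle_on_random_columns(self, rng):
        m = random_matrix(rng, 8, 60, missing_rate=0.25)
        s = site_stats(m)
        for k in range(m.n_sites):
            col = m.genotypes[:, k].tolist()
            expected = he_oracle(col)
            if np.isnan(expected):
                assert np.isnan(s["he"][k])
            else:
                assert s["he"][k] == pytest.approx(expected, abs=1e-12)

    def test_empty_subset_rejected(self):
        m = make_matrix(np.array([[0], [1]]))
        with pytest.raises(ValueError):
            site_stats(m, [])


class TestWindowHe:
    def test_mean_of_two_sites(self):
        # He 0.5 (p=.5) and 0.375 (p=.25) -> mean 0.4375
        m = make_matrix(np.array([[0, 0], [0, 0], [2, 0], [2, 2]]),
                        positions=[10, 20])
        assert window_mean_he(m, Window("chr1", 0, 100)) == \
            pytest.approx(0.4375)

    def test_empty_window_undefined(self):
        m = make_matrix(np.array([[1]]), positions=[500])
        assert np.isnan(window_mean_he(m, Window("chr1", 0, 100)))


class TestHetRate:
    def test_percentage_normalisation(self, rng):
        G = np.zeros((1, 50), dtype=np.int8)
        G[0, :] = 1
        pos = np.sort(rng.choice(np.arange(1, 25_001), 50, replace=False))
        m = make_matrix(G, positions=pos)
        assert het_rate(m, Window("chr1", 0, 25_000), "s1") == \
            pytest.approx(50 / 25_000 * 100)

    def test_all_hom_is_zero(self):
        m = make_matrix(np.array([[0, 2, 0]]), positions=[5, 10, 15])
        assert het_rate(m, Window("chr1", 0, 25_000), "s1") == 0.0

    def test_terminal_window_uses_actual_span(self):
        # 10 het calls in a 5,000-bp terminal window -> 0.2%
        G = np.ones((1, 10), dtype=np.int8)
        m = make_matrix(G, positions=list(range(95_001, 95_011)))
        assert het_rate(m, Window("chr1", 95_000, 100_000), "s1") == \
            pytest.approx(10 / 5000 * 100)


class TestPi:
    def test_single_site_formula(self):
        # n=4, j=2 -> pi_s = 2*2*2/(4*3) = 2/3; window 100 bp
        m = make_matrix(np.array([[0], [2]]), positions=[50])
        assert nucleotide_diversity(m, Window("chr1", 0, 100)) == \
            pytest.approx((8 / 12) / 100)

    def test_monomorphic_window_zero(self):
        m = make_matrix(np.array([[0, 0], [0, 0]]), positions=[10, 20])
        assert nucleotide_diversity(m, Window("chr1", 0, 100)) == 0.0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 2, 20, missing_rate=0.2, span=400)
            w = Window("chr1", 0, 400)
            cols = [m.genotypes[:, k].tolist() for k in range(m.n_sites)]
            assert nucleotide_diversity(m, w) == \
                pytest.approx(window_pi_oracle(cols, 400), abs=1e-12)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        m = make_matrix(np.zeros((5, 4), dtype=np.int8),
                        positions=[10, 20, 30, 40])
        assert np.isnan(tajimas_d(m, Window("chr1", 0, 100)))

    def test_intermediate_frequencies_positive(self):
        # every site at j = n/2: excess intermediate-frequency variants
        G = np.zeros((5, 12), dtype=np.int8)
        G[:2, :] = 2
        G[2, :] = 1  # j = 5 of n = 10 at every site
        m = make_matrix(G, positions=list(range(10, 130, 10)))
        assert tajimas_d(m, Window("chr1", 0, 200)) > 0

    def test_matches_independent_formula(self, rng):
        for _ in range(50):
            n_samp = int(rng.integers(4, 12))
            m = random_matrix(rng, n_samp, int(rng.integers(5, 30)),
                              missing_rate=0.15, span=1000)
            w = Window("chr1", 0, 1000)
            cols = [m.genotypes[:, k].tolist() for k in range(m.n_sites)]
            expected = tajimas_d_oracle(cols)
            got = tajimas_d(m, w)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)


class TestFst:
    def test_fixed_difference_is_one(self):
        G = np.vstack([np.zeros((20, 10)), np.full((20, 10), 2)])
        m = make_matrix(G, pop_classes=["wild"] * 20 + ["breeding"] * 20)
        assert fst(m, None, m.wild_ids(), m.cultivar_ids()) == \
            pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self, rng):
        G = rng.integers(0, 3, size=(200, 40))
        Gdup = np.vstack([G, G])
        m = make_matrix(Gdup, pop_classes=["wild"] * 200 + ["breeding"] * 200)
        # Hudson bias for a duplicated group is -1/(n-1), tiny at n=400
        assert abs(fst(m, None, m.wild_ids(), m.cultivar_ids())) < 0.02

    def test_identical_groups_rejected(self):
        m = make_matrix(np.array([[0], [1]]))
        with pytest.raises(ValueError):
            fst(m, None, ["s1"], ["s1"])

    def test_matches_ratio_of_averages_oracle(self, rng):
        for _ in range(20):
            m = random_matrix(rng, 20, 20, missing_rate=0.1)
            a = m.sample_ids[:10]
            b = m.sample_ids[10:]
            cols_a = [m.genotypes[:10, k].tolist() for k in range(20)]
            cols_b = [m.genotypes[10:, k].tolist() for k in range(20)]
            assert fst(m, None, a, b) == \
                pytest.approx(hudson_fst_oracle(cols_a, cols_b), abs=1e-12)


class TestPDistance:
    def test_identical_vectors_zero(self):
        m = make_matrix(np.array([[0, 1, 2], [0, 1, 2]]))
        assert p_distance(m, ["s1"], ["s2"]) == 0.0

    def test_opposite_homozygotes_one(self):
        m = make_matrix(np.array([[0, 0, 0], [2, 2, 2]]))
        assert p_distance(m, ["s1"], ["s2"]) == 1.0

    def test_matches_pair_enumeration(self, rng):
        m = random_matrix(rng, 6, 30, missing_rate=0.2)
        a, b = m.sample_ids[:3], m.sample_ids[3:]
        rows_a = [m.genotypes[i].tolist() for i in range(3)]
        rows_b = [m.genotypes[i].tolist() for i in range(3, 6)]
        assert p_distance(m, a, b) == \
            pytest.approx(p_distance_oracle(rows_a, rows_b), abs=1e-12)


class TestLD:
    def test_duplicated_site_r2_one(self):
        m = make_matrix(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]))
        assert ld_r2(m, 0, 1) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        G = np.array([[0, 2], [0, 2], [1, 1], [1, 1], [2, 0], [2, 0]])
        m = make_matrix(G)
        assert ld_r2(m, 0, 1) == pytest.approx(1.0)

    def test_monomorphic_site_undefined(self):
        m = make_matrix(np.array([[0, 0], [0, 1], [0, 2]]))
        assert np.isnan(ld_r2(m, 0, 1))

    def test_matches_textbook_oracle(self, rng):
        m = random_matrix(rng, 12, 10, missing_rate=0.2)
        for a, b in [(0, 1), (2, 7), (4, 9)]:
            expected = r2_oracle(m.genotypes[:, a].tolist(),
                                 m.genotypes[:, b].tolist())
            got = ld_r2(m, a, b)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_single_site_empty_curve(self):
        m = make_matrix(np.array([[0], [1], [2]]))
        res = ld_decay(m, max_dist=1000, bin_bp=100)
        assert res.decay_curve["n_pairs"].sum() == 0

    def test_block_copied_genotypes_have_full_ld(self, rng):
        base = rng.integers(0, 3, size=(30, 1))
        G = np.repeat(base, 8, axis=1)
        pos = np.arange(1, 9) * 1000  # all within 8 kb
        m = make_matrix(G.astype(np.int8), positions=pos)
        res = ld_decay(m, max_dist=10_000, bin_bp=1000)
        scored = res.decay_curve[res.decay_curve["n_pairs"] > 0]
        np.testing.assert_allclose(scored["mean_r2"].to_numpy(), 1.0)

    def test_independent_sites_small_mean_r2(self, rng):
        m = random_matrix(rng, 60, 80, missing_rate=0.0, span=4000)
        res = ld_decay(m, max_dist=4000, bin_bp=4000)
        mean = res.decay_curve["mean_r2"].iloc[0]
        # E[r^2] ~ 1/(n-1) under independence
        assert mean < 5.0 / 59


class TestInvariances:
    def test_ref_alt_swap_invariance(self, rng):
        """He, pi, Tajima's D and FST are unchanged by flipping which
        allele is called reference (code g -> 2 - g)."""
        m = random_matrix(rng, 16, 40, missing_rate=0.1, span=2000)
        G2 = m.genotypes.copy()
        keep_missing = G2 == -1
        G2 = (2 - G2).astype(np.int8)
        G2[keep_missing] = -1
        m2 = make_matrix(G2, positions=m.sites["pos"].tolist())
        w = Window("chr1", 0, 2000)
        a, b = m.sample_ids[:8], m.sample_ids[8:]
        assert window_mean_he(m, w) == pytest.approx(window_mean_he(m2, w))
        assert nucleotide_diversity(m, w) == \
            pytest.approx(nucleotide_diversity(m2, w))
        d1, d2 = tajimas_d(m, w), tajimas_d(m2, w)
        assert d1 == pytest.approx(d2, nan_ok=True)
        assert fst(m, w, a, b) == pytest.approx(fst(m2, w, a, b),
                                                nan_ok=True)

    def test_sample_order_permutation_invariance(self, rng):
        m = random_matrix(rng, 12, 30, missing_rate=0.1, span=1500)
        perm = rng.permutation(12)
        m2 = make_matrix(m.genotypes[perm],
                         positions=m.sites["pos"].tolist(),
                         sample_ids=[m.sample_ids[i] for i in perm])
        w = Window("chr1", 0, 1500)
        subset = m.sample_ids[:6]
        assert window_mean_he(m, w, subset) == \
            pytest.approx(window_mean_he(m2, w, subset), nan_ok=True)
        assert nucleotide_diversity(m, w, subset) == \
            pytest.approx(nucleotide_diversity(m2, w, subset))


class TestWindowTable:
    def test_batch_equals_single_window_ops(self, rng):
        m = random_matrix(rng, 10, 120, missing_rate=0.1, span=6000)
        ws = [Window("chr1", s, min(s + 1000, 6000))
              for s in range(0, 6000, 500)]
        table = window_stats_table(m, ws)
        for row, w in zip(table.itertuples(), ws):
            assert row.mean_he == pytest.approx(window_mean_he(m, w),
                                                nan_ok=True, abs=1e-12)
            assert row.pi == pytest.approx(nucleotide_diversity(m, w),
                                           abs=1e-12)
            assert row.tajimas_d == pytest.approx(tajimas_d(m, w),
                                                  nan_ok=True, abs=1e-9)
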