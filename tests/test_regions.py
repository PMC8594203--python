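"""Het/hom partition, block frequency and trait segregation."""

import numpy as np
import pandas as pd
import pytest

from hetscan.core import RegionCall, TraitTable
from hetscan.regions import (classify_het_hom_regions,
                             compare_region_diversity, highly_het_blocks,
                             per_accession_het_blocks, segregation_scan,
                             trait_segregation)

from conftest import make_matrix
from oracles import (interval_union_oracle, quantile_oracle,
                     welch_t_oracle, wilcoxon_exact_oracle)


def _single_sample_matrix(het_positions, length, extra_hom=()):
    """One accession with het calls at given 1-based positions."""
    pos = sorted(set(het_positions) | set(extra_hom))
    codes = [1 if p in set(het_positions) else 0 for p in pos]
    return make_matrix(np.array([codes], dtype=np.int8), positions=pos)


class TestClassifyRegions:
    def test_all_hom_single_region(self):
        m = _single_sample_matrix([], 300_000, extra_hom=range(1000, 300_000,
                                                               5000))
        regions = classify_het_hom_regions(
            m, "s1", chrom_lengths={"chr1": 300_000})
        assert len(regions) == 1
        r = regions[0]
        assert r.label == "homozygous" and (r.start0, r.end0) == (0, 300_000)

    def test_rate_boundary_49_of_25kb_is_homozygous(self):
        # 49 het SNPs in one 25-kb window: 0.00196 < 0.002
        m49 = _single_sample_matrix(range(1000, 1000 + 49 * 100, 100),
                                    200_000)
        regions = classify_het_hom_regions(
            m49, "s1", chrom_lengths={"chr1": 200_000}, min_len=0)
        assert all(r.label == "homozygous" for r in regions)
        # one more het call tips the first windows over the threshold
        m50 = _single_sample_matrix(range(1000, 1000 + 50 * 100, 100),
                                    200_000)
        regions = classify_het_hom_regions(
            m50, "s1", chrom_lengths={"chr1": 200_000}, min_len=0)
        assert any(r.label == "heterozygous" for r in regions)

    def test_partition_is_disjoint(self, small_cohort):
        _, matrix, _, _ = small_cohort
        regions = classify_het_hom_regions(
            matrix, matrix.cultivar_ids()[0],
            chrom_lengths={"chr1": 2_000_000})
        # base-level check on a 1-kb grid: no base claimed twice
        grid = np.zeros(2_000_000 // 1000, dtype=np.int8)
        for r in regions:
            code = 1 if r.label == "heterozygous" else 2
            seg = grid[r.start0 // 1000:r.end0 // 1000]
            assert (seg == 0).all()  # no base claimed twice
            grid[r.start0 // 1000:r.end0 // 1000] = code

    def test_matches_interval_union_oracle(self, rng):
        # random het calls; rebuild expected regions per label by hand
        length = 150_000
        pos = np.sort(rng.choice(np.arange(1, length), 400, replace=False))
        codes = rng.choice([0, 1], size=400, p=[0.5, 0.5])
        m = make_matrix(np.array([codes], dtype=np.int8), positions=pos)
        regions = classify_het_hom_regions(
            m, "s1", window=20_000, step=5_000, rate_threshold=0.002,
            min_len=0, chrom_lengths={"chr1": length})
        pos0 = pos - 1
        het_w, hom_w = [], []
        start = 0
        while start < length:
            end = min(start + 20_000, length)
            n_het = int(((pos0 >= start) & (pos0 < end) & (codes == 1)).sum())
            (het_w if n_het / (end - start) >= 0.002 else hom_w).append(
                (start, end))
            start += 5_000
        het_expected = interval_union_oracle(het_w, length)
        got_het = [(r.start0, r.end0) for r in regions
                   if r.label == "heterozygous"]
        assert got_het == het_expected
        hom_cover = interval_union_oracle(hom_w, length)
        het_mask = np.zeros(length, bool)
        for s, e in het_expected:
            het_mask[s:e] = True
        hom_mask = np.zeros(length, bool)
        for s, e in hom_cover:
            hom_mask[s:e] = True
        hom_mask &= ~het_mask
        got_hom = [(r.start0, r.end0) for r in regions
                   if r.label == "homozygous"]
        assert got_hom == interval_union_oracle(
            [(i, i + 1) for i in np.flatnonzero(hom_mask)], length)

    def test_threshold_monotonicity(self, rng):
        length = 200_000
        pos = np.sort(rng.choice(np.arange(1, length), 500, replace=False))
        codes = rng.choice([0, 1], size=500)
        m = make_matrix(np.array([codes], dtype=np.int8), positions=pos)
        spans = []
        for thr in (0.0005, 0.002, 0.008):
            regions = classify_het_hom_regions(
                m, "s1", min_len=0, chrom_lengths={"chr1": length},
                rate_threshold=thr)
            spans.append((
                sum(r.span for r in regions if r.label == "homozygous"),
                sum(r.span for r in regions if r.label == "heterozygous")))
        assert spans[0][0] <= spans[1][0] <= spans[2][0]
        assert spans[0][1] >= spans[1][1] >= spans[2][1]


class TestCompareRegionDiversity:
    def _regions(self):
        return [RegionCall("chr1", 0, 50_000, "heterozygous", 1.0),
                RegionCall("chr1", 50_000, 100_000, "homozygous", 0.0)]

    def _stats(self, het_vals, hom_vals):
        rows = []
        for i, v in enumerate(het_vals):
            rows.append({"chrom": "chr1", "start": i * 1000,
                         "end": i * 1000 + 500, "pi": v})
        for i, v in enumerate(hom_vals):
            rows.append({"chrom": "chr1", "start": 50_000 + i * 1000,
                         "end": 50_000 + i * 1000 + 500, "pi": v})
        return pd.DataFrame(rows)

    def test_identical_distributions_p_one(self):
        df = compare_region_diversity(
            self._regions(), self._stats([1, 2, 3], [1, 2, 3]),
            value_cols=("pi",), per_chrom=False)
        assert df["t"][0] == 0.0 and df["p"][0] == pytest.approx(1.0)

    def test_separated_distributions_significant(self, rng):
        het = 0.01 + rng.normal(0, 1e-5, 10)
        hom = 0.001 + rng.normal(0, 1e-5, 10)
        df = compare_region_diversity(
            self._regions(), self._stats(het, hom), value_cols=("pi",),
            per_chrom=False)
        assert df["p"][0] < 0.001
        t, p = welch_t_oracle(list(het), list(hom))
        assert df["t"][0] == pytest.approx(t, abs=1e-9)
        assert df["p"][0] == pytest.approx(p, abs=1e-12)

    def test_undersized_class_reports_nan(self):
        df = compare_region_diversity(
            self._regions(), self._stats([1.0], [1, 2, 3]),
            value_cols=("pi",), per_chrom=False)
        assert np.isnan(df["t"][0])


class TestHetBlocks:
    def test_zero_het_accession_has_no_blocks(self):
        G = np.array([[0, 0, 0, 0], [1, 1, 1, 1]], dtype=np.int8)
        m = make_matrix(G, positions=[100, 200, 20_100, 20_200])
        calls = per_accession_het_blocks(m, ["s1", "s2"],
                                         chrom_lengths={"chr1": 40_000})
        assert calls.calls[0].sum() == 0

    def test_two_by_two_cutoff_example(self):
        # counts (0, 4; 8, 12) -> mean 6 -> blocks at 8 and 12 only
        # window1 = first 12 sites (pos < 20 kb), window2 = last 16 sites
        pos = ([100 + 100 * i for i in range(12)]
               + [20_100 + 100 * i for i in range(16)])
        G = np.zeros((2, 28), dtype=np.int8)
        G[0, 12:16] = 1                 # acc1 window2: 4 het
        G[1, :8] = 1                    # acc2 window1: 8 het
        G[1, 16:28] = 1                 # acc2 window2: 12 het
        m = make_matrix(G, positions=pos)
        calls = per_accession_het_blocks(m, ["s1", "s2"],
                                         chrom_lengths={"chr1": 40_000})
        assert calls.cutoff == pytest.approx(6.0)
        assert calls.counts.tolist() == [[0, 4], [8, 12]]
        assert calls.calls.tolist() == [[False, False], [True, True]]

    def test_cutoff_matches_recount(self, small_cohort):
        _, matrix, _, _ = small_cohort
        calls = per_accession_het_blocks(matrix, matrix.cultivar_ids(),
                                         chrom_lengths={"chr1": 2_000_000})
        assert calls.cutoff == pytest.approx(calls.counts.mean())
        assert (calls.calls == (calls.counts > calls.cutoff)).all()
        assert (calls.calls.sum(axis=0) <= len(calls.sample_ids)).all()


class TestHighlyHetBlocks:
    def _calls_with_freqs(self, freqs, n_acc=100):
        """BlockCalls whose per-window frequencies approximate freqs."""
        from hetscan.core import Window
        from hetscan.regions import BlockCalls
        n_w = len(freqs)
        calls = np.zeros((n_acc, n_w), dtype=bool)
        for k, f in enumerate(freqs):
            calls[: int(round(f * n_acc)), k] = True
        windows = [Window("chr1", k * 20_000, (k + 1) * 20_000)
                   for k in range(n_w)]
        return BlockCalls(windows, [f"a{i}" for i in range(n_acc)],
                          calls.astype(int), calls, 0.5)

    def test_tie_saturation_all_marked(self):
        table, regions = highly_het_blocks(self._calls_with_freqs([0.4] * 10))
        assert table["is_highly_het"].all()
        assert len(regions) == 1  # adjacent windows merge into one region

    def test_top_five_of_hundred(self):
        freqs = [i / 100 for i in range(100)]
        table, _ = highly_het_blocks(self._calls_with_freqs(freqs), 0.95)
        n_marked = int(table["is_highly_het"].sum())
        assert abs(n_marked - 5) <= 1
        cutoff = quantile_oracle(table["frequency"].tolist(), 0.95)
        assert (table["frequency"][table["is_highly_het"]] >= cutoff).all()

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError):
            highly_het_blocks(self._calls_with_freqs([0.1]), 1.5)

    def test_planted_blocks_recovered(self, small_cohort):
        from hetscan.core import filter_sites
        from hetscan.simulate import score_recovery
        _, matrix, _, truth = small_cohort
        mf = filter_sites(matrix)
        calls = per_accession_het_blocks(mf, mf.cultivar_ids(),
                                         chrom_lengths={"chr1": 2_000_000})
        _, regions = highly_het_blocks(calls)
        sens, prec = score_recovery(regions, truth.blocks)
        assert sens == 1.0


class TestTraitSegregation:
    def _setup(self, het_vals, hom_vals):
        from hetscan.core import Window
        from hetscan.regions import BlockCalls
        n = len(het_vals) + len(hom_vals)
        ids = [f"a{i}" for i in range(n)]
        calls = np.zeros((n, 1), dtype=bool)
        calls[: len(het_vals), 0] = True
        bc = BlockCalls([Window("chr1", 0, 20_000)], ids,
                        calls.astype(int), calls, 0.0)
        tt = TraitTable(pd.DataFrame(
            {"y": list(het_vals) + list(hom_vals)},
            index=pd.Index(ids, name="sample_id")))
        block = RegionCall("chr1", 0, 20_000, "highly_het_block", 1.0)
        return block, bc, tt

    def test_exact_extreme_ranking(self):
        block, bc, tt = self._setup([10, 11, 12], [1, 2, 3])
        res = trait_segregation(block, bc, tt, "y")
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == 15.0  # het ranks 4+5+6

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=5).tolist()
            y = rng.normal(size=6).tolist()
            block, bc, tt = self._setup(x, y)
            res = trait_segregation(block, bc, tt, "y")
            assert res.p_value == pytest.approx(
                wilcoxon_exact_oracle(x, y), abs=1e-12)

    def test_empty_group_flagged(self):
        block, bc, tt = self._setup([], [1.0, 2.0, 3.0])
        res = trait_segregation(block, bc, tt, "y")
        assert not res.defined

    def test_scan_adds_bh_column(self, rng):
        block, bc, tt = self._setup(rng.normal(size=8).tolist(),
                                    rng.normal(size=8).tolist())
        df = segregation_scan([block], bc, tt)
        assert "q_bh" in df.columns and len(df) == 1
        assert df["q_bh"][0] >= df["p"][0] - 1e-12
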