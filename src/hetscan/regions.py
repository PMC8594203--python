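"""Heterozygous/homozygous genome partition and highly heterozygous blocks.

The genome of a single reference accession is scanned in 25-kb sliding
windows (5-kb step): a window whose heterozygous-SNP rate (het calls per
bp) falls below a threshold (default 0.002, i.e. 50 het SNPs per 25 kb)
is homozygous, otherwise heterozygous.  Overlapping window labels are
resolved by taking the union of heterozygous windows; the homozygous
partition is the union of homozygous windows minus that het union, so no
base carries both labels.  Only merged regions longer than ``min_len``
(default 50 kb) are retained.

Separately, every cultivar accession is scored in non-overlapping 20-kb
windows; a window with more het SNPs than the cohort-wide mean count is
a heterozygous block for that accession.  Windows whose population
frequency of het-block calls reaches the empirical top 5% are "highly
heterozygous blocks" — candidate balancing-selection targets — and trait
segregation between het and hom accession groups at each block is tested
with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (GenotypeMatrix, RegionCall, TraitTable, Window,
                   make_windows, merge_intervals, subtract_intervals)


def _chrom_lengths_from(matrix: GenotypeMatrix,
                        chrom_lengths: dict[str, int] | None
                        ) -> dict[str, int]:
    if chrom_lengths is not None:
        return dict(chrom_lengths)
    out = {}
    for chrom in matrix.chrom_names():
        lo, hi = matrix.chrom_site_range(chrom)
        out[chrom] = int(matrix.sites["pos"].iloc[lo:hi].max())
    return out


def _window_het_counts(matrix: GenotypeMatrix, sample_rows: np.ndarray,
                       windows: Sequence[Window]) -> np.ndarray:
    """(n_samples x n_windows) heterozygous-call counts via prefix sums."""
    is_het = (matrix.genotypes[sample_rows] == 1)
    cs = np.concatenate(
        (np.zeros((sample_rows.size, 1), dtype=np.int64),
         np.cumsum(is_het, axis=1, dtype=np.int64)), axis=1)
    counts = np.empty((sample_rows.size, len(windows)), dtype=np.int64)
    for k, w in enumerate(windows):
        lo, hi = matrix.window_site_range(w)
        counts[:, k] = cs[:, hi] - cs[:, lo]
    return counts


# -- reference-accession partition ---------------------------------------

def classify_het_hom_regions(matrix: GenotypeMatrix, reference_sample: str,
                             window: int = 25_000, step: int = 5_000,
                             rate_threshold: float = 0.002,
                             min_len: int = 50_000,
                             chrom_lengths: dict[str, int] | None = None
                             ) -> list[RegionCall]:
    """Partition the genome into heterozygous and homozygous regions.

    ``rate_threshold`` applies to the per-bp fraction (het SNPs / span);
    windows with rate < threshold are homozygous.  Regions with span
    <= ``min_len`` are discarded.  Output regions are disjoint across the
    two labels; the score is the mean window rate over the region.
    """
    lengths = _chrom_lengths_from(matrix, chrom_lengths)
    windows = make_windows(lengths, window, step)  # validates step <= window
    row = matrix.sample_indices([reference_sample])
    counts = _window_het_counts(matrix, row, windows)[0]
    spans = np.array([w.span for w in windows])
    rates = counts / spans
    is_het = rates >= rate_threshold

    het_iv = merge_intervals(
        (w.chrom, w.start, w.end) for w, h in zip(windows, is_het) if h
    ) if is_het.any() else []
    hom_src = [(w.chrom, w.start, w.end)
               for w, h in zip(windows, is_het) if not h]
    hom_iv = subtract_intervals(hom_src, het_iv) if hom_src else []

    def _score(chrom, s, e):
        sel = [r for w, r in zip(windows, rates)
               if w.chrom == chrom and w.start < e and w.end > s]
        return float(np.mean(sel)) if sel else 0.0

    out: list[RegionCall] = []
    for label, ivs in (("heterozygous", het_iv), ("homozygous", hom_iv)):
        for chrom, s, e in ivs:
            if e - s <= min_len:
                continue
            n_win = sum(1 for w in windows
                        if w.chrom == chrom and w.start < e and w.end > s)
            out.append(RegionCall(chrom, s, e, label, _score(chrom, s, e),
                                  n_windows=n_win))
    out.sort(key=lambda r: (r.chrom, r.start0))
    return out


def compare_region_diversity(regions: Sequence[RegionCall],
                             window_stats: pd.DataFrame,
                             value_cols: Sequence[str] = ("pi", "tajimas_d",
                                                          "fst"),
                             per_chrom: bool = True) -> pd.DataFrame:
    """Welch two-tailed t-test of window statistics between het and hom
    regions, per chromosome and genome-wide.

    A statistic window belongs to the region class whose interval contains
    its midpoint; unassigned windows are ignored.  Chromosome rows with
    fewer than 2 windows in either class report NaN (test undefined).
    """
    het = [(r.chrom, r.start0, r.end0) for r in regions
           if r.label == "heterozygous"]
    hom = [(r.chrom, r.start0, r.end0) for r in regions
           if r.label == "homozygous"]

    def _assign(chrom: str, mid: float) -> str | None:
        for s, e in ((s, e) for c, s, e in het if c == chrom):
            if s <= mid < e:
                return "het"
        for s, e in ((s, e) for c, s, e in hom if c == chrom):
            if s <= mid < e:
                return "hom"
        return None

    ws = window_stats.copy()
    mids = (ws["start"] + ws["end"]) / 2.0
    ws["_class"] = [_assign(c, m) for c, m in zip(ws["chrom"], mids)]

    scopes = [("genome", ws)]
    if per_chrom:
        scopes += [(c, g) for c, g in ws.groupby("chrom", sort=False)]
    rows = []
    for scope, df in scopes:
        for col in value_cols:
            a = df.loc[df["_class"] == "het", col].dropna().to_numpy()
            b = df.loc[df["_class"] == "hom", col].dropna().to_numpy()
            if a.size >= 2 and b.size >= 2:
                if np.var(a) == 0 and np.var(b) == 0:
                    t, p = ((0.0, 1.0) if a.mean() == b.mean()
                            else (np.inf, 0.0))
                else:
                    t, p = stats.ttest_ind(a, b, equal_var=False)
            else:
                t, p = float("nan"), float("nan")
            rows.append({"scope": scope, "statistic": col,
                         "mean_het": a.mean() if a.size else float("nan"),
                         "mean_hom": b.mean() if b.size else float("nan"),
                         "n_het": a.size, "n_hom": b.size,
                         "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


# -- per-accession 20-kb heterozygous blocks ------------------------------

@dataclass
class BlockCalls:
    """Het-block calls for every (accession, 20-kb window) pair."""

    windows: list[Window]
    sample_ids: list[str]
    counts: np.ndarray   # (n_accessions, n_windows) het-SNP counts
    calls: np.ndarray    # boolean, count > cutoff
    cutoff: float        # cohort mean het-SNP count per window


def per_accession_het_blocks(matrix: GenotypeMatrix,
                             cultivar_samples: Sequence[str],
                             window: int = 20_000,
                             chrom_lengths: dict[str, int] | None = None
                             ) -> BlockCalls:
    """Call heterozygous blocks per accession in non-overlapping windows.

    The cutoff is the mean het-SNP count over all (accession, window)
    pairs, recomputed from the data at hand — never a fixed constant.
    A window is a het block for an accession iff its count is strictly
    above the cutoff.
    """
    lengths = _chrom_lengths_from(matrix, chrom_lengths)
    windows = make_windows(lengths, window, None)
    rows = matrix.sample_indices(cultivar_samples)
    counts = _window_het_counts(matrix, rows, windows)
    cutoff = float(counts.mean())
    return BlockCalls(windows=windows, sample_ids=list(cultivar_samples),
                      counts=counts, calls=counts > cutoff, cutoff=cutoff)


def highly_het_blocks(block_calls: BlockCalls, quantile: float = 0.95
                      ) -> tuple[pd.DataFrame, list[RegionCall]]:
    """Population-frequency table plus merged highly heterozygous blocks.

    Frequency per window = het accessions / evaluated accessions; the
    cutoff is the empirical ``quantile`` (linear interpolation between
    order statistics), and windows with frequency >= cutoff qualify —
    ties can saturate the marked set.  Adjacent qualifying windows merge.
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    n_called = block_calls.calls.shape[0]
    freq = block_calls.calls.mean(axis=0)
    cutoff = float(np.quantile(freq, quantile))
    marked = freq >= cutoff
    table = pd.DataFrame({
        "chrom": [w.chrom for w in block_calls.windows],
        "start": [w.start for w in block_calls.windows],
        "end": [w.end for w in block_calls.windows],
        "het_count": block_calls.calls.sum(axis=0),
        "n_called": n_called,
        "frequency": freq,
        "is_highly_het": marked,
    })
    regions: list[RegionCall] = []
    if marked.any():
        ivs = merge_intervals((w.chrom, w.start, w.end)
                              for w, m in zip(block_calls.windows, marked) if m)
        for chrom, s, e in ivs:
            sel = [f for w, f, m in zip(block_calls.windows, freq, marked)
                   if m and w.chrom == chrom and w.start < e and w.end > s]
            regions.append(RegionCall(chrom, s, e, "highly_het_block",
                                      float(max(sel)), n_windows=len(sel)))
    return table, regions


# -- trait segregation ----------------------------------------------------

@dataclass
class SegregationResult:
    block: RegionCall
    trait_name: str
    n_het: int
    n_hom: int
    statistic: float   # rank-sum W of the het group
    p_value: float
    defined: bool = True


def _block_membership(block: RegionCall, block_calls: BlockCalls
                      ) -> np.ndarray:
    """Accession is heterozygous at a merged block if any constituent
    window is a het-block call for it (union rule)."""
    cols = [k for k, w in enumerate(block_calls.windows)
            if w.chrom == block.chrom and w.start < block.end0
            and w.end > block.start0]
    if not cols:
        raise ValueError("block overlaps no scored window")
    return block_calls.calls[:, cols].any(axis=1)


def trait_segregation(block: RegionCall, block_calls: BlockCalls,
                      traits: TraitTable, trait_name: str
                      ) -> SegregationResult:
    """Two-sided Wilcoxon rank-sum test of a quantitative trait between
    het-block and hom-block accession groups at one block.

    Exact enumeration when both groups have <= 10 members and no ties;
    otherwise the tie-corrected normal approximation.
    """
    if traits.kind(trait_name) != "quantitative":
        raise ValueError(f"trait {trait_name!r} is not quantitative")
    is_het = _block_membership(block, block_calls)
    vals = traits.get(trait_name, block_calls.sample_ids).to_numpy(float)
    ok = ~np.isnan(vals)
    x = vals[ok & is_het]
    y = vals[ok & ~is_het]
    if x.size == 0 or y.size == 0:
        return SegregationResult(block, trait_name, x.size, y.size,
                                 float("nan"), float("nan"), defined=False)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank-sum W
    return SegregationResult(block, trait_name, int(x.size), int(y.size),
                             w, float(res.pvalue))


def segregation_scan(blocks: Sequence[RegionCall], block_calls: BlockCalls,
                     traits: TraitTable,
                     trait_names: Sequence[str] | None = None
                     ) -> pd.DataFrame:
    """Run trait_segregation for every (block, quantitative trait) pair;
    adds Benjamini-Hochberg q-values across tests as an extra column."""
    if trait_names is None:
        trait_names = [t for t in traits.trait_names
                       if traits.kind(t) == "quantitative"]
    rows = []
    for block in blocks:
        for t in trait_names:
            r = trait_segregation(block, block_calls, traits, t)
            rows.append({"chrom": block.chrom, "start": block.start0,
                         "end": block.end0, "trait": t, "n_het": r.n_het,
                         "n_hom": r.n_hom, "W": r.statistic,
                         "p": r.p_value, "defined": r.defined})
    df = pd.DataFrame(rows)
    if len(df):
        q = np.full(len(df), np.nan)
        ok = df["defined"].to_numpy() & ~df["p"].isna().to_numpy()
        if ok.any():
            q[ok] = stats.false_discovery_control(df.loc[ok, "p"], method="bh")
        df["q_bh"] = q
    return df


__all__ = [
    "classify_het_hom_regions", "compare_region_diversity",
    "per_accession_het_blocks", "highly_het_blocks", "BlockCalls",
    "trait_segregation", "segregation_scan", "SegregationResult",
]
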