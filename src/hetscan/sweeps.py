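"""Selective-sweep detection from wild/cultivar diversity ratios.

For 50-kb sliding windows (10-kb step) the mean expected heterozygosity
He (or nucleotide diversity pi) is computed separately in the wild
panel and the cultivar panel; the per-window ratio wild/cultivar is
large where cultivars have lost diversity.  Windows in the empirical
top fraction (``top_q``) of defined ratios are candidate sweep windows;
overlapping/book-ended candidates merge into sweep regions, and regions
supported by both the He scan and the pi scan form the ``sweep_both``
set that is summarised against the gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (GeneAnnotation, GenotypeMatrix, RegionCall, Window,
                   intersect_regions, merge_intervals)
from .popgen import window_stats_table


@dataclass
class RatioScan:
    statistic: str            # "he" or "pi"
    windows: pd.DataFrame     # chrom,start,end,n_sites,value_wild,
    #                           value_cultivar,ratio,above
    threshold: float          # empirical top-q cutoff of defined ratios
    top_q: float


@dataclass
class SweepSet:
    regions: list[RegionCall]
    total_span_bp: int
    genome_fraction: float
    genes: dict[RegionCall, list[str]] = field(default_factory=dict)
    n_genes: int = 0
    de_overlap: list[str] = field(default_factory=list)


def ratio_scan(matrix: GenotypeMatrix, wild_samples: Sequence[str],
               cultivar_samples: Sequence[str], windows: Sequence[Window],
               statistic: str = "he", top_q: float = 0.01,
               min_sites: int = 5,
               include_zero_denominator: bool = False) -> RatioScan:
    """Per-window wild/cultivar ratio of He or pi with the top-q cutoff.

    Windows with fewer than ``min_sites`` SNPs, or with a zero cultivar
    value, have an undefined ratio and are excluded from the quantile
    (optionally, zero-denominator windows can instead be auto-marked).
    ``above`` is ``ratio >= threshold``.
    """
    if statistic not in ("he", "pi"):
        raise ValueError("statistic must be 'he' or 'pi'")
    if not wild_samples or not cultivar_samples:
        raise ValueError("both sample groups must be non-empty")
    col = "mean_he" if statistic == "he" else "pi"
    tw = window_stats_table(matrix, windows, wild_samples,
                            with_tajimas_d=False)
    tc = window_stats_table(matrix, windows, cultivar_samples,
                            with_tajimas_d=False)
    vw = tw[col].to_numpy(float)
    vc = tc[col].to_numpy(float)
    n_sites = tw["n_sites"].to_numpy()
    zero_den = vc == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero_den, np.nan, vw / np.where(zero_den, 1, vc))
    ratio = np.where(n_sites < min_sites, np.nan, ratio)
    defined = ~np.isnan(ratio)
    if not defined.any():
        raise ValueError("all window ratios are undefined")
    threshold = float(np.quantile(ratio[defined], 1.0 - top_q))
    above = defined & (ratio >= threshold)
    if include_zero_denominator:
        above |= zero_den & (n_sites >= min_sites)
    df = pd.DataFrame({
        "chrom": tw["chrom"], "start": tw["start"], "end": tw["end"],
        "n_sites": n_sites, "value_wild": vw, "value_cultivar": vc,
        "ratio": ratio, "above": above,
    })
    return RatioScan(statistic=statistic, windows=df, threshold=threshold,
                     top_q=top_q)


def call_sweeps(scan: RatioScan) -> list[RegionCall]:
    """Merge overlapping/book-ended above-threshold windows into sweep
    regions; the score of a region is the maximum constituent ratio."""
    df = scan.windows
    above = df[df["above"]]
    if above.empty:
        return []
    label = f"sweep_{scan.statistic}"
    ivs = merge_intervals(zip(above["chrom"], above["start"], above["end"]))
    out = []
    for chrom, s, e in ivs:
        sel = above[(above["chrom"] == chrom) & (above["start"] < e)
                    & (above["end"] > s)]
        out.append(RegionCall(chrom, s, e, label,
                              float(sel["ratio"].max()), n_windows=len(sel)))
    return out


def intersect_sweeps(he_sweeps: Sequence[RegionCall],
                     pi_sweeps: Sequence[RegionCall]) -> list[RegionCall]:
    """Regions where the He scan and the pi scan both call a sweep
    (pairwise interval intersections of span >= 1 bp, labelled
    ``sweep_both``; parents carry the two source intervals)."""
    out = []
    for a in he_sweeps:
        for b in pi_sweeps:
            if a.chrom != b.chrom:
                continue
            s, e = max(a.start0, b.start0), min(a.end0, b.end0)
            if e > s:
                out.append(RegionCall(
                    a.chrom, s, e, "sweep_both",
                    float(min(a.score, b.score)),
                    n_windows=min(a.n_windows, b.n_windows),
                    parents=((a.chrom, a.start0, a.end0),
                             (b.chrom, b.start0, b.end0))))
    out.sort(key=lambda r: (r.chrom, r.start0))
    return out


def sweep_summary(sweeps: Sequence[RegionCall],
                  chrom_lengths: dict[str, int],
                  annotation: GeneAnnotation | None = None,
                  de_genes: Sequence[str] | None = None) -> SweepSet:
    """Total span, genome fraction and gene content of a sweep set.

    ``de_genes`` is an optional externally supplied gene list (e.g.
    differentially expressed genes) that is merely intersected with the
    sweep gene set.
    """
    span = sum(r.span for r in sweeps)
    genome = sum(chrom_lengths.values())
    genes: dict[RegionCall, list[str]] = {}
    all_genes: set[str] = set()
    if annotation is not None:
        genes = intersect_regions(list(sweeps), annotation)
        all_genes = {g for gl in genes.values() for g in gl}
    de_overlap = sorted(all_genes & set(de_genes)) if de_genes else []
    return SweepSet(regions=list(sweeps), total_span_bp=int(span),
                    genome_fraction=span / genome if genome else 0.0,
                    genes=genes, n_genes=len(all_genes),
                    de_overlap=de_overlap)


__all__ = ["RatioScan", "SweepSet", "ratio_scan", "call_sweeps",
           "intersect_sweeps", "sweep_summary"]
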