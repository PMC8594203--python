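"""Per-site and per-window population-genetic statistics.

All estimators work on dosage-coded diploid genotypes with per-site
complete-observation handling of missing calls (the non-missing sample
set, and hence the chromosome count n, varies site by site; nothing is
imputed).

Definitions
-----------
* Expected heterozygosity per site: ``He = 1 - p^2 - (1-p)^2`` with p the
  alternate-allele frequency among non-missing allele copies.
* Nucleotide diversity per site: the unbiased pairwise estimator
  ``pi_s = 2 j (n - j) / (n (n - 1))`` with j alternate copies out of n;
  a window's pi is the sum of per-site values divided by the window span.
* Tajima's D: standard 1989 normalisation of ``pi_total - S/a1`` using
  the constants evaluated at the modal per-site chromosome count.
* FST: Hudson's estimator as a ratio of per-site averages
  (numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)``,
  denominator ``p1(1-p2) + p2(1-p1)``); Nei's GST available as an option.
* p-distance between groups: mean over cross-group sample pairs of the
  mean normalised dosage distance ``|g_i - g_j| / 2`` over shared calls.
* LD: squared Pearson correlation of dosages over pairwise-complete
  samples, binned by distance for the decay curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Window

log = logging.getLogger(__name__)


# -- per-site allele accounting ------------------------------------------

def _allele_counts(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt copies j, total non-missing copies n) per site for a
    (samples x sites) dosage slice."""
    called = G != MISSING
    j = np.where(called, G, 0).sum(axis=0, dtype=np.int64)
    n = 2 * called.sum(axis=0, dtype=np.int64)
    return j, n


def site_stats(matrix: GenotypeMatrix,
               samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-site frequency and heterozygosity table.

    Columns: chrom, pos, n_chrom, call_rate, p_alt, maf, he.  Sites with
    zero non-missing calls get NaN frequencies (flagged undefined).
    """
    idx = matrix.sample_indices(samples)
    if idx.size == 0:
        raise ValueError("sample subset is empty")
    G = matrix.genotypes[idx]
    j, n = _allele_counts(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, j / np.maximum(n, 1), np.nan)
    he = 1.0 - p ** 2 - (1.0 - p) ** 2
    return pd.DataFrame({
        "chrom": matrix.sites["chrom"],
        "pos": matrix.sites["pos"],
        "n_chrom": n,
        "call_rate": n / (2 * idx.size),
        "p_alt": p,
        "maf": np.minimum(p, 1 - p),
        "he": he,
    })


def _per_site_arrays(matrix: GenotypeMatrix, sample_idx: np.ndarray
                     ) -> dict[str, np.ndarray]:
    """he, pi, segregating flag and n per site for a sample subset."""
    G = matrix.genotypes[sample_idx]
    j, n = _allele_counts(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, j / np.maximum(n, 1), np.nan)
        he = 1.0 - p ** 2 - (1.0 - p) ** 2
        pi = np.where(n >= 2, 2.0 * j * (n - j) / (np.maximum(n, 2)
                                                   * np.maximum(n - 1, 1)), 0.0)
    seg = (j > 0) & (j < n)
    return {"he": he, "pi": pi, "seg": seg, "n": n, "j": j}


# -- single-window operations --------------------------------------------

def window_mean_he(matrix: GenotypeMatrix, window: Window,
                   samples: Sequence[str] | None = None) -> float:
    """Unweighted mean per-site He over SNPs in the window (NaN if none)."""
    idx = matrix.sample_indices(samples)
    lo, hi = matrix.window_site_range(window)
    if hi <= lo:
        return float("nan")
    arr = _per_site_arrays(matrix, idx)
    he = arr["he"][lo:hi]
    he = he[~np.isnan(he)]
    return float(he.mean()) if he.size else float("nan")


def het_rate(matrix: GenotypeMatrix, window: Window, sample: str) -> float:
    """Heterozygous calls per bp of window x 100, for one accession.

    Length-normalises by the actual span, so terminal partial windows are
    comparable to full ones.  Missing calls never count.
    """
    i = matrix.sample_indices([sample])[0]
    lo, hi = matrix.window_site_range(window)
    n_het = int((matrix.genotypes[i, lo:hi] == 1).sum())
    return 100.0 * n_het / window.span


def nucleotide_diversity(matrix: GenotypeMatrix, window: Window,
                         samples: Sequence[str] | None = None) -> float:
    """Window pi per bp: sum of per-site pairwise diversity / span."""
    idx = matrix.sample_indices(samples)
    lo, hi = matrix.window_site_range(window)
    arr = _per_site_arrays(matrix, idx)
    return float(arr["pi"][lo:hi].sum() / window.span)


def _tajima_constants(n: int) -> tuple[float, float]:
    """(a1, e1, e2) -> returns (e1, e2) bundled with a1 for D."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(matrix: GenotypeMatrix, window: Window,
              samples: Sequence[str] | None = None,
              min_segsites: int = 3) -> float:
    """Tajima's D over the window; NaN when S < min_segsites or the modal
    chromosome count is < 4.

    pi here is the window *sum* of per-site pairwise diversity (not per
    bp), matching the units of S/a1.
    """
    idx = matrix.sample_indices(samples)
    lo, hi = matrix.window_site_range(window)
    arr = _per_site_arrays(matrix, idx)
    return _tajimas_d_from_arrays(arr["pi"][lo:hi], arr["seg"][lo:hi],
                                  arr["n"][lo:hi], min_segsites)


def _tajimas_d_from_arrays(pi_s: np.ndarray, seg: np.ndarray, n_s: np.ndarray,
                           min_segsites: int) -> float:
    informative = n_s >= 2
    S = int(seg[informative].sum())
    if S < max(min_segsites, 1):
        return float("nan")
    counts = np.bincount(n_s[informative])
    n = int(np.argmax(counts))  # modal chromosome count in the window
    if n < 4:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    pi_total = float(pi_s[informative].sum())
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - S / a1) / math.sqrt(var)


# -- FST and distances ----------------------------------------------------

def _group_freqs(matrix: GenotypeMatrix, group: Sequence[str],
                 lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    idx = matrix.sample_indices(group)
    G = matrix.genotypes[idx, lo:hi]
    j, n = _allele_counts(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, j / np.maximum(n, 1), np.nan)
    return p, n


def _hudson_components(p1, n1, p2, n2):
    ok = (n1 >= 2) & (n2 >= 2)
    p1, n1, p2, n2 = p1[ok], n1[ok], p2[ok], n2[ok]
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst(matrix: GenotypeMatrix,
        window_or_sites: Window | np.ndarray | None,
        group_a: Sequence[str], group_b: Sequence[str],
        estimator: str = "hudson") -> float:
    """Between-group FST over a window (or site index array / all sites).

    Default is Hudson's estimator as a ratio of per-site averages; pass
    ``estimator="nei"`` for Nei's GST (ratio of average gene diversities).
    Sites with fewer than 2 allele copies in either group are skipped.
    Values are reported unclamped (slightly negative windows are real
    sampling noise under Hudson's estimator).
    """
    if list(group_a) == list(group_b):
        raise ValueError("FST requires two distinct groups")
    if isinstance(window_or_sites, Window):
        lo, hi = matrix.window_site_range(window_or_sites)
        p1, n1 = _group_freqs(matrix, group_a, lo, hi)
        p2, n2 = _group_freqs(matrix, group_b, lo, hi)
    else:
        p1, n1 = _group_freqs(matrix, group_a, 0, matrix.n_sites)
        p2, n2 = _group_freqs(matrix, group_b, 0, matrix.n_sites)
        if window_or_sites is not None:
            sel = np.asarray(window_or_sites)
            p1, n1, p2, n2 = p1[sel], n1[sel], p2[sel], n2[sel]
    if estimator == "hudson":
        num, den = _hudson_components(p1, n1, p2, n2)
        dsum = float(den.sum())
        if dsum == 0 or num.size == 0:
            return float("nan")
        return float(num.sum() / dsum)
    elif estimator == "nei":
        ok = (n1 >= 2) & (n2 >= 2)
        p1, p2 = p1[ok], p2[ok]
        if p1.size == 0:
            return float("nan")
        pbar = (p1 + p2) / 2.0
        ht = (2 * pbar * (1 - pbar)).mean()
        hs = ((2 * p1 * (1 - p1)) + (2 * p2 * (1 - p2))).mean() / 2.0
        if ht == 0:
            return float("nan")
        return float(1.0 - hs / ht)
    raise ValueError(f"unknown estimator {estimator!r}")


def p_distance(matrix: GenotypeMatrix, group_a: Sequence[str],
               group_b: Sequence[str]) -> float:
    """Mean cross-group pairwise normalised dosage distance in [0, 1].

    For each sample pair the distance is the mean of |g_i - g_j| / 2 over
    sites where both have calls; pairs sharing no called site are skipped
    with a warning.
    """
    ia = matrix.sample_indices(group_a)
    ib = matrix.sample_indices(group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("groups must be non-empty")
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    G = matrix.genotypes
    dists = []
    for i in ia:
        gi = G[i]
        oki = gi != MISSING
        for jdx in ib:
            gj = G[jdx]
            ok = oki & (gj != MISSING)
            n = int(ok.sum())
            if n == 0:
                log.warning("p_distance: no shared calls for pair (%s, %s)",
                            matrix.sample_ids[i], matrix.sample_ids[jdx])
                continue
            dists.append(np.abs(gi[ok].astype(float) - gj[ok]).sum() / (2.0 * n))
    return float(np.mean(dists)) if dists else float("nan")


# -- linkage disequilibrium ----------------------------------------------

def ld_r2(matrix: GenotypeMatrix, site_a: int, site_b: int,
          samples: Sequence[str] | None = None) -> float:
    """Squared Pearson correlation of dosages (pairwise-complete); NaN
    when either site is monomorphic in the complete subset."""
    idx = matrix.sample_indices(samples)
    ga = matrix.genotypes[idx, site_a].astype(float)
    gb = matrix.genotypes[idx, site_b].astype(float)
    ok = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[ok], gb[ok]
    if ga.size < 2 or ga.std() == 0 or gb.std() == 0:
        return float("nan")
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


@dataclass
class LDResult:
    pairs: pd.DataFrame          # site_a, site_b, distance_bp, r2
    decay_curve: pd.DataFrame    # bin_start, bin_end, n_pairs, mean_r2
    decay_point_bp: float | None  # midpoint of first bin with mean r2 <= 0.2


def _enumerate_pairs(matrix: GenotypeMatrix, max_dist: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    lefts, rights = [], []
    for chrom in matrix.chrom_names():
        lo, hi = matrix.chrom_site_range(chrom)
        pos = matrix.sites["pos"].to_numpy()[lo:hi]
        hi_idx = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(pos.size):
            h = hi_idx[i]
            if h > i + 1:
                lefts.append(np.full(h - i - 1, lo + i))
                rights.append(np.arange(lo + i + 1, lo + h))
    if not lefts:
        return (np.empty(0, dtype=int),) * 2
    return np.concatenate(lefts), np.concatenate(rights)


def _pair_r2(matrix: GenotypeMatrix, idx: np.ndarray,
             a: np.ndarray, b: np.ndarray, chunk: int = 20000) -> np.ndarray:
    """Vectorised pairwise-complete r^2 for site index pairs (a, b)."""
    G = matrix.genotypes[idx].astype(np.float64)
    M = G != MISSING
    out = np.empty(a.size)
    for s in range(0, a.size, chunk):
        aa, bb = a[s:s + chunk], b[s:s + chunk]
        ga, gb = G[:, aa], G[:, bb]
        ok = M[:, aa] & M[:, bb]
        n = ok.sum(axis=0)
        ga = np.where(ok, ga, 0.0)
        gb = np.where(ok, gb, 0.0)
        sa, sb = ga.sum(0), gb.sum(0)
        saa, sbb = (ga * ga).sum(0), (gb * gb).sum(0)
        sab = (ga * gb).sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sab - sa * sb / np.maximum(n, 1)
            va = saa - sa * sa / np.maximum(n, 1)
            vb = sbb - sb * sb / np.maximum(n, 1)
            r2 = np.where((n >= 2) & (va > 0) & (vb > 0),
                          cov ** 2 / np.maximum(va * vb, 1e-300), np.nan)
        out[s:s + chunk] = r2
    return out


def ld_decay(matrix: GenotypeMatrix, samples: Sequence[str] | None = None,
             max_dist: int = 1_000_000, bin_bp: int = 1000,
             max_pairs: int = 1_000_000, seed: int = 0,
             keep_pairs: bool = False) -> LDResult:
    """r^2 decay curve: all intra-chromosome site pairs within
    ``max_dist``, averaged in ``bin_bp`` distance bins.

    When the pair count exceeds ``max_pairs`` a uniform seeded subsample
    is scored instead.  ``decay_point_bp`` is the midpoint of the first
    bin whose mean r^2 drops to <= 0.2.
    """
    idx = matrix.sample_indices(samples)
    a, b = _enumerate_pairs(matrix, max_dist)
    if a.size > max_pairs:
        rng = np.random.default_rng(seed)
        take = rng.choice(a.size, size=max_pairs, replace=False)
        take.sort()
        a, b = a[take], b[take]
    pos = matrix.sites["pos"].to_numpy()
    dist = pos[b] - pos[a]
    r2 = _pair_r2(matrix, idx, a, b) if a.size else np.empty(0)
    ok = ~np.isnan(r2)
    edges = np.arange(0, max_dist + bin_bp, bin_bp)
    which = np.clip(np.digitize(dist[ok], edges) - 1, 0, edges.size - 2)
    n_pairs = np.bincount(which, minlength=edges.size - 1)
    sums = np.bincount(which, weights=r2[ok], minlength=edges.size - 1)
    with np.errstate(invalid="ignore"):
        means = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
    curve = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                          "n_pairs": n_pairs, "mean_r2": means})
    decay_point = None
    hit = np.flatnonzero((n_pairs > 0) & (means <= 0.2))
    if hit.size:
        k = int(hit[0])
        decay_point = float((edges[k] + edges[k + 1]) / 2.0)
    pairs_df = (pd.DataFrame({"site_a": a, "site_b": b,
                              "distance_bp": dist, "r2": r2})
                if keep_pairs else
                pd.DataFrame(columns=["site_a", "site_b", "distance_bp", "r2"]))
    return LDResult(pairs=pairs_df, decay_curve=curve,
                    decay_point_bp=decay_point)


# -- batched window tables (cumulative-sum aggregation) -------------------

def window_stats_table(matrix: GenotypeMatrix, windows: Sequence[Window],
                       samples: Sequence[str] | None = None,
                       min_segsites: int = 3,
                       with_tajimas_d: bool = True) -> pd.DataFrame:
    """Vectorised per-window n_sites / mean_he / pi (and Tajima's D).

    Equivalent to calling the single-window operations per window;
    overlapping sliding windows are handled via prefix sums so the cost
    is O(sites + windows).
    """
    idx = matrix.sample_indices(samples)
    arr = _per_site_arrays(matrix, idx)
    he = np.nan_to_num(arr["he"], nan=0.0)
    he_def = ~np.isnan(arr["he"])
    cs_he = np.concatenate(([0.0], np.cumsum(he)))
    cs_hedef = np.concatenate(([0], np.cumsum(he_def)))
    cs_pi = np.concatenate(([0.0], np.cumsum(arr["pi"])))
    rows = []
    for w in windows:
        lo, hi = matrix.window_site_range(w)
        n_sites = hi - lo
        n_he = cs_hedef[hi] - cs_hedef[lo]
        mean_he = (cs_he[hi] - cs_he[lo]) / n_he if n_he else float("nan")
        pi = (cs_pi[hi] - cs_pi[lo]) / w.span
        row = {"chrom": w.chrom, "start": w.start, "end": w.end,
               "n_sites": n_sites, "mean_he": mean_he, "pi": pi}
        if with_tajimas_d:
            row["tajimas_d"] = _tajimas_d_from_arrays(
                arr["pi"][lo:hi], arr["seg"][lo:hi], arr["n"][lo:hi],
                min_segsites)
        rows.append(row)
    return pd.DataFrame(rows)


def window_fst_table(matrix: GenotypeMatrix, windows: Sequence[Window],
                     group_a: Sequence[str], group_b: Sequence[str],
                     estimator: str = "hudson") -> pd.DataFrame:
    """Per-window Hudson FST (ratio of averages within each window)."""
    p1, n1 = _group_freqs(matrix, group_a, 0, matrix.n_sites)
    p2, n2 = _group_freqs(matrix, group_b, 0, matrix.n_sites)
    ok = (n1 >= 2) & (n2 >= 2)
    num = np.zeros(matrix.n_sites)
    den = np.zeros(matrix.n_sites)
    num[ok], den[ok] = _hudson_components(p1, n1, p2, n2)
    cs_num = np.concatenate(([0.0], np.cumsum(num)))
    cs_den = np.concatenate(([0.0], np.cumsum(den)))
    rows = []
    for w in windows:
        lo, hi = matrix.window_site_range(w)
        d = cs_den[hi] - cs_den[lo]
        f = (cs_num[hi] - cs_num[lo]) / d if d > 0 else float("nan")
        rows.append({"chrom": w.chrom, "start": w.start, "end": w.end,
                     "fst": f})
    return pd.DataFrame(rows)


__all__ = [
    "site_stats", "window_mean_he", "het_rate", "nucleotide_diversity",
    "tajimas_d", "fst", "p_distance", "ld_r2", "ld_decay", "LDResult",
    "window_stats_table", "window_fst_table",
]
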