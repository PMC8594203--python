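"""Independent brute-force/enumeration oracles for the statistics.

Everything here is deliberately written as plain loops over explicit
allele copies or sample pairs (math.fsum, itertools), sharing no code
path with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

MISSING = -1


def _alleles(code: int) -> list[int]:
    return {0: [0, 0], 1: [0, 1], 2: [1, 1]}[code]


def he_oracle(column) -> float:
    """1 - sum p_i^2 over allele frequencies from explicit copies."""
    copies = []
    for g in column:
        if g != MISSING:
            copies.extend(_alleles(g))
    if not copies:
        return float("nan")
    n = len(copies)
    out = 1.0
    for allele in (0, 1):
        out -= (copies.count(allele) / n) ** 2
    return out


def p_alt_oracle(column) -> float:
    copies = []
    for g in column:
        if g != MISSING:
            copies.extend(_alleles(g))
    return copies.count(1) / len(copies) if copies else float("nan")


def pi_site_oracle(column) -> float:
    """Mean pairwise difference over all chromosome-copy pairs."""
    copies = []
    for g in column:
        if g != MISSING:
            copies.extend(_alleles(g))
    if len(copies) < 2:
        return 0.0
    diffs = [int(a != b) for a, b in itertools.combinations(copies, 2)]
    return math.fsum(diffs) / len(diffs)


def window_pi_oracle(columns, span: int) -> float:
    return math.fsum(pi_site_oracle(c) for c in columns) / span


def tajimas_d_oracle(columns, min_segsites: int = 3) -> float:
    """Independent re-derivation of the 1989 normalisation."""
    per_site = []
    for col in columns:
        copies = []
        for g in col:
            if g != MISSING:
                copies.extend(_alleles(g))
        if len(copies) >= 2:
            per_site.append(copies)
    S = sum(1 for c in per_site if 0 < c.count(1) < len(c))
    if S < max(min_segsites, 1):
        return float("nan")
    sizes = sorted(len(c) for c in per_site)
    # modal size, smallest wins ties (np.argmax over bincount does too)
    n = max(set(sizes), key=lambda v: (sizes.count(v), -v))
    if n < 4:
        return float("nan")
    a1 = math.fsum(1.0 / i for i in range(1, n))
    a2 = math.fsum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    pi_total = math.fsum(pi_site_oracle_from_copies(c) for c in per_site)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - S / a1) / math.sqrt(var)


def pi_site_oracle_from_copies(copies) -> float:
    diffs = [int(a != b) for a, b in itertools.combinations(copies, 2)]
    return math.fsum(diffs) / len(diffs) if diffs else 0.0


def hudson_fst_oracle(cols_a, cols_b) -> float:
    """Ratio of per-site averages, spelled out site by site."""
    nums, dens = [], []
    for ca, cb in zip(cols_a, cols_b):
        copies_a, copies_b = [], []
        for g in ca:
            if g != MISSING:
                copies_a.extend(_alleles(g))
        for g in cb:
            if g != MISSING:
                copies_b.extend(_alleles(g))
        n1, n2 = len(copies_a), len(copies_b)
        if n1 < 2 or n2 < 2:
            continue
        p1 = copies_a.count(1) / n1
        p2 = copies_b.count(1) / n2
        nums.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                    - p2 * (1 - p2) / (n2 - 1))
        dens.append(p1 * (1 - p2) + p2 * (1 - p1))
    d = math.fsum(dens)
    return math.fsum(nums) / d if d != 0 else float("nan")


def p_distance_oracle(rows_a, rows_b) -> float:
    """Explicit enumeration over all cross-group sample pairs."""
    dists = []
    for ga in rows_a:
        for gb in rows_b:
            shared = [(x, y) for x, y in zip(ga, gb)
                      if x != MISSING and y != MISSING]
            if not shared:
                continue
            dists.append(math.fsum(abs(x - y) / 2.0 for x, y in shared)
                         / len(shared))
    return math.fsum(dists) / len(dists) if dists else float("nan")


def r2_oracle(xs, ys) -> float:
    """Textbook Pearson correlation squared on pairwise-complete data."""
    pairs = [(x, y) for x, y in zip(xs, ys)
             if x != MISSING and y != MISSING]
    n = len(pairs)
    if n < 2:
        return float("nan")
    mx = math.fsum(x for x, _ in pairs) / n
    my = math.fsum(y for _, y in pairs) / n
    sxx = math.fsum((x - mx) ** 2 for x, _ in pairs)
    syy = math.fsum((y - my) ** 2 for _, y in pairs)
    sxy = math.fsum((x - mx) * (y - my) for x, y in pairs)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy * sxy / (sxx * syy)


def welch_t_oracle(a, b) -> tuple[float, float]:
    """Welch statistic + two-sided p via the t distribution."""
    from scipy.stats import t as tdist
    na, nb = len(a), len(b)
    ma = math.fsum(a) / na
    mb = math.fsum(b) / nb
    va = math.fsum((x - ma) ** 2 for x in a) / (na - 1)
    vb = math.fsum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p


def chi2_oracle(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, cell by cell."""
    from scipy.stats import chi2 as chi2dist
    rows = len(table)
    cols = len(table[0])
    total = math.fsum(math.fsum(r) for r in table)
    rsum = [math.fsum(r) for r in table]
    csum = [math.fsum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            exp = rsum[i] * csum[j] / total
            stat += (table[i][j] - exp) ** 2 / exp
    dof = (rows - 1) * (cols - 1)
    return stat, float(chi2dist.sf(stat, dof))


def wilcoxon_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating every assignment of the
    pooled (tie-free) values to the first group."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    mean_w = n * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, n):
        w = sum(ranks[v] for v in combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def mood_median_oracle(a, b) -> tuple[float, float]:
    """Grand-median 2x2 split (ties to the <=-median cell) + chi-square."""
    pooled = sorted(a + b)
    m = len(pooled)
    med = (pooled[m // 2] if m % 2 else
           (pooled[m // 2 - 1] + pooled[m // 2]) / 2.0)
    table = [[sum(1 for v in a if v > med), sum(1 for v in b if v > med)],
             [sum(1 for v in a if v <= med), sum(1 for v in b if v <= med)]]
    if 0 in [sum(r) for r in table] or \
            0 in [table[0][j] + table[1][j] for j in (0, 1)]:
        return 0.0, 1.0
    return chi2_oracle(table)


def windows_oracle(length, size, step):
    """Plain loop enumeration of sliding windows."""
    out = []
    start = 0
    while start < length:
        out.append((start, min(start + size, length)))
        start += step
    return out


def interval_union_oracle(intervals, universe_end):
    """Base-level boolean union, read back as maximal runs."""
    covered = [False] * universe_end
    for s, e in intervals:
        for i in range(s, min(e, universe_end)):
            covered[i] = True
    runs = []
    i = 0
    while i < universe_end:
        if covered[i]:
            j = i
            while j < universe_end and covered[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def intersect_oracle(regions, genes):
    """O(n*m) pairwise half-open overlap check."""
    out = {}
    for r_chrom, r_s, r_e, key in regions:
        hits = []
        for g_id, g_chrom, g_s, g_e in genes:
            if g_chrom == r_chrom and g_s < r_e and g_e > r_s:
                hits.append(g_id)
        out[key] = hits
    return out


def quantile_oracle(values, q):
    """Linear interpolation between order statistics, by hand."""
    vs = sorted(values)
    h = (len(vs) - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, len(vs) - 1)
    return vs[lo] + (h - lo) * (vs[hi] - vs[lo])
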