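"""Genotype-class trait association tests.

Accessions are grouped by genotype class at a candidate SNP (hom-ref /
het / hom-alt) or by the cross of classes at two SNPs.  Quantitative
traits are compared with Welch's two-tailed t-test, categorical traits
with Pearson's chi-square; two-locus combination classes are compared
with Mood's median test (overall plus all pairwise tests with Bonferroni
adjustment and a compact letter display).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix, SiteRecord, TraitTable

log = logging.getLogger(__name__)

CLASS_NAMES = {0: "hom_ref", 1: "het", 2: "hom_alt"}


@dataclass
class GenotypeGroups:
    snp: SiteRecord
    groups: dict[str, list[str]]          # class -> sample ids
    min_group_size: int
    flagged: list[str] = field(default_factory=list)  # classes below floor


@dataclass
class AssocResult:
    snps: tuple
    trait_name: str
    test: str
    group_summaries: pd.DataFrame
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    warnings: list[str] = field(default_factory=list)
    defined: bool = True
    letters: dict[str, str] | None = None
    pairwise: pd.DataFrame | None = None


def genotype_groups(matrix: GenotypeMatrix, snp: tuple[str, int],
                    samples: Sequence[str] | None = None,
                    min_group_size: int = 5) -> GenotypeGroups:
    """Partition samples by genotype class at one SNP; missing calls are
    excluded and undersized classes flagged."""
    chrom, pos = snp
    j = matrix.site_index(chrom, pos)
    idx = matrix.sample_indices(samples)
    ids = np.asarray(matrix.sample_ids, dtype=object)[idx]
    g = matrix.genotypes[idx, j]
    groups = {name: ids[g == code].tolist()
              for code, name in CLASS_NAMES.items()}
    flagged = [name for name, members in groups.items()
               if 0 < len(members) < min_group_size]
    return GenotypeGroups(snp=matrix.site_record(j), groups=groups,
                          min_group_size=min_group_size, flagged=flagged)


def _summaries(named_values: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = [{"class": k, "n": v.size,
             "mean": float(np.mean(v)) if v.size else float("nan"),
             "median": float(np.median(v)) if v.size else float("nan")}
            for k, v in named_values.items()]
    return pd.DataFrame(rows)


def quantitative_assoc(groups: GenotypeGroups, traits: TraitTable,
                       trait_name: str,
                       pair: tuple[str, str] = ("het", "hom_ref")
                       ) -> AssocResult:
    """Welch two-tailed t-test of a quantitative trait between two
    genotype classes (e.g. heterozygous vs homozygous-reference)."""
    a_name, b_name = pair
    vals = {}
    for name in pair:
        v = traits.get(trait_name, groups.groups[name]).to_numpy(float)
        vals[name] = v[~np.isnan(v)]
    a, b = vals[a_name], vals[b_name]
    warnings = [f"group {n} below min size {groups.min_group_size}"
                for n in pair if len(vals[n]) < groups.min_group_size]
    if a.size < 2 or b.size < 2:
        return AssocResult((groups.snp,), trait_name, "t_test",
                           _summaries(vals), float("nan"), float("nan"),
                           warnings=warnings + ["group too small"],
                           defined=False)
    if np.var(a) == 0 and np.var(b) == 0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return AssocResult((groups.snp,), trait_name, "t_test",
                       _summaries(vals), float(t), float(p),
                       warnings=warnings)


def categorical_assoc(groups: GenotypeGroups, traits: TraitTable,
                      trait_name: str) -> AssocResult:
    """Pearson chi-square (no continuity correction) on the genotype
    class x trait category contingency table.

    Zero-margin rows/columns are dropped with a warning; cells with
    expected count < 5 set a warning flag.
    """
    records = []
    for name, members in groups.groups.items():
        for v in traits.get(trait_name, members):
            if pd.notna(v):
                records.append((name, v))
    if not records:
        return AssocResult((groups.snp,), trait_name, "chi_square",
                           pd.DataFrame(), float("nan"), float("nan"),
                           warnings=["no data"], defined=False)
    df = pd.DataFrame(records, columns=["class", "value"])
    table = pd.crosstab(df["class"], df["value"])
    warnings = []
    dropped = table.index[(table.sum(axis=1) == 0)].tolist() \
        + table.columns[(table.sum(axis=0) == 0)].tolist()
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if dropped:
        warnings.append(f"dropped zero-margin levels: {dropped}")
        log.warning("categorical_assoc: %s", warnings[-1])
    if table.shape[0] < 2 or table.shape[1] < 2:
        return AssocResult((groups.snp,), trait_name, "chi_square",
                           table.reset_index(), float("nan"), float("nan"),
                           warnings=warnings + ["degenerate table"],
                           defined=False)
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                    correction=False)
    if (expected < 5).any():
        warnings.append("expected count < 5 in some cells")
    return AssocResult((groups.snp,), trait_name, "chi_square",
                       table.reset_index(), float(chi2), float(p),
                       warnings=warnings)


# -- Mood's median test & letter display ----------------------------------

def _mood_median_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """2x2 above/<=-median chi-square; ties at the grand median go to the
    '<= median' cell.  Degenerate splits return (0, 1)."""
    pooled = np.concatenate([a, b])
    med = np.median(pooled)
    above = np.array([(a > med).sum(), (b > med).sum()], dtype=float)
    below = np.array([a.size, b.size]) - above
    table = np.array([above, below])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _letter_display(class_names: list[str], sig: set[frozenset]
                    ) -> dict[str, str]:
    """Greedy compact letter display: walk the classes in order, join the
    first letter-group with no significant member, else open a new one."""
    letter_groups: list[list[str]] = []
    for name in class_names:
        placed = False
        for grp in letter_groups:
            if all(frozenset((name, other)) not in sig for other in grp):
                grp.append(name)
                placed = True
        if not placed:
            letter_groups.append([name])
    letters: dict[str, str] = {name: "" for name in class_names}
    for i, grp in enumerate(letter_groups):
        ch = chr(ord("a") + i)
        for name in grp:
            letters[name] += ch
    return letters


def _combo_classes(matrix: GenotypeMatrix, snp_a: tuple[str, int],
                   snp_b: tuple[str, int],
                   samples: Sequence[str] | None) -> dict[str, list[str]]:
    ja = matrix.site_index(*snp_a)
    jb = matrix.site_index(*snp_b)
    idx = matrix.sample_indices(samples)
    ids = np.asarray(matrix.sample_ids, dtype=object)[idx]
    ga = matrix.genotypes[idx, ja]
    gb = matrix.genotypes[idx, jb]
    out: dict[str, list[str]] = {}
    ok = (ga != MISSING) & (gb != MISSING)
    for i in np.flatnonzero(ok):
        name = f"{CLASS_NAMES[int(ga[i])]}/{CLASS_NAMES[int(gb[i])]}"
        out.setdefault(name, []).append(ids[i])
    return out


def allele_combination_assoc(matrix: GenotypeMatrix,
                             snp_a: tuple[str, int], snp_b: tuple[str, int],
                             traits: TraitTable, trait_name: str,
                             samples: Sequence[str] | None = None,
                             min_group_size: int = 5,
                             alpha: float = 0.05,
                             adjust: str = "bonferroni") -> AssocResult:
    """Two-locus genotype-class comparison of a quantitative trait.

    Overall Mood's median test across eligible combination classes, then
    all pairwise median tests with Bonferroni (default) or BH adjustment;
    classes that share no significant pairwise difference share a letter.
    """
    combos = _combo_classes(matrix, snp_a, snp_b, samples)
    vals: dict[str, np.ndarray] = {}
    for name, members in combos.items():
        v = traits.get(trait_name, members).to_numpy(float)
        v = v[~np.isnan(v)]
        if v.size >= min_group_size:
            vals[name] = v
    names = sorted(vals)
    ja, jb = matrix.site_index(*snp_a), matrix.site_index(*snp_b)
    snps = (matrix.site_record(ja), matrix.site_record(jb))
    if len(names) < 2:
        return AssocResult(snps, trait_name, "median_test",
                           _summaries(vals), float("nan"), float("nan"),
                           warnings=["fewer than 2 eligible classes"],
                           defined=False)
    pooled = np.concatenate([vals[n] for n in names])
    if np.unique(pooled).size == 1:
        overall_stat, overall_p = 0.0, 1.0
    else:
        try:
            res = stats.median_test(*[vals[n] for n in names],
                                    ties="below", correction=False)
            overall_stat, overall_p = float(res.statistic), float(res.pvalue)
        except ValueError:  # all values on one side of the grand median
            overall_stat, overall_p = 0.0, 1.0
    pairs = list(itertools.combinations(names, 2))
    n_pairs = len(pairs)
    rows = []
    sig: set[frozenset] = set()
    raw_ps = []
    for a_name, b_name in pairs:
        a, b = vals[a_name], vals[b_name]
        if np.unique(np.concatenate([a, b])).size == 1:
            s, p = 0.0, 1.0
        else:
            s, p = _mood_median_test(a, b)
        raw_ps.append(p)
        rows.append({"class_a": a_name, "class_b": b_name,
                     "statistic": s, "p": p})
    if adjust == "bonferroni":
        adj = [min(1.0, p * n_pairs) for p in raw_ps]
    elif adjust == "bh":
        adj = list(stats.false_discovery_control(raw_ps, method="bh"))
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for row, ap in zip(rows, adj):
        row["adjusted_p"] = ap
        if ap < alpha:
            sig.add(frozenset((row["class_a"], row["class_b"])))
    # letters assigned in descending-median order, the usual display order
    order = sorted(names, key=lambda n: -np.median(vals[n]))
    letters = _letter_display(order, sig)
    return AssocResult(snps, trait_name, "median_test", _summaries(vals),
                       overall_stat, overall_p,
                       letters=letters, pairwise=pd.DataFrame(rows))


def combination_frequency(matrix: GenotypeMatrix,
                          snp_a: tuple[str, int], snp_b: tuple[str, int],
                          group_wild: Sequence[str],
                          group_cultivar: Sequence[str]
                          ) -> tuple[pd.DataFrame, float, float]:
    """Two-locus genotype-class combination frequencies per population
    plus a chi-square test of the frequency difference.

    Returns (table, chi2, p); the table has one row per combination with
    counts and frequencies in each population.
    """
    if not group_wild or not group_cultivar:
        raise ValueError("groups must be non-empty")
    rows = {}
    for pop, group in (("wild", group_wild), ("cultivar", group_cultivar)):
        combos = _combo_classes(matrix, snp_a, snp_b, group)
        for name, members in combos.items():
            rows.setdefault(name, {"wild": 0, "cultivar": 0})
            rows[name][pop] = len(members)
    table = (pd.DataFrame.from_dict(rows, orient="index")
             .rename_axis("combination").reset_index()
             .sort_values("combination").reset_index(drop=True))
    for pop in ("wild", "cultivar"):
        total = table[pop].sum()
        table[f"freq_{pop}"] = table[pop] / total if total else np.nan
    counts = table[["wild", "cultivar"]].to_numpy().T
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
        return table, 0.0, 1.0
    if np.array_equal(table["freq_wild"].to_numpy(),
                      table["freq_cultivar"].to_numpy()):
        return table, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return table, float(chi2), float(p)


__all__ = [
    "CLASS_NAMES", "GenotypeGroups", "AssocResult", "genotype_groups",
    "quantitative_assoc", "categorical_assoc", "allele_combination_assoc",
    "combination_frequency",
]
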