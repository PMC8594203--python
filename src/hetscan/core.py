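"""Core containers and genomic-interval primitives.

Genotypes are dosage-coded diploid calls on biallelic SNPs:
``0`` = homozygous reference, ``1`` = heterozygous, ``2`` = homozygous
alternate, ``-1`` (:data:`MISSING`) = no call.  A :class:`GenotypeMatrix`
holds the ``(n_samples, n_sites)`` int8 array together with site and
sample metadata; all coordinates are 0-based half-open internally and
converted to 1-based only at the VCF boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: population classes treated as "cultivar" in wild-vs-cultivar contrasts
CULTIVAR_CLASSES = ("landrace", "breeding")
POP_CLASSES = ("wild",) + CULTIVAR_CLASSES


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP locus (``pos`` is 1-based, as in VCF)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    pop_class: str | None = None
    country: str | None = None


@dataclass(frozen=True)
class Window:
    """Genomic window, 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionCall:
    """A labelled merged genomic interval with its defining statistic.

    Labels in use: ``heterozygous``/``homozygous`` (reference-accession
    partition), ``highly_het_block`` (population-frequency blocks),
    ``sweep_he``/``sweep_pi``/``sweep_both`` (diversity-ratio sweeps).
    """

    chrom: str
    start0: int
    end0: int
    label: str
    score: float
    n_windows: int = 1
    parents: tuple = ()

    def __post_init__(self) -> None:
        if self.end0 <= self.start0:
            raise ValueError(f"empty region [{self.start0}, {self.end0})")

    @property
    def span(self) -> int:
        return self.end0 - self.start0


class GeneAnnotation:
    """Gene intervals (0-based half-open) with unique ids."""

    def __init__(self, genes: pd.DataFrame):
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(genes.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if genes["gene_id"].duplicated().any():
            dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (genes["start"] >= genes["end"]).any():
            raise ValueError("gene intervals must satisfy start < end")
        if "strand" not in genes.columns:
            genes = genes.assign(strand=".")
        self.genes = genes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)


class TraitTable:
    """Per-accession trait values with a quantitative/categorical schema.

    Schema maps trait name to ``("quantitative", None)`` or
    ``("categorical", levels)``; inferred from dtypes when not given.
    """

    def __init__(self, values: pd.DataFrame, schema: dict | None = None):
        if values.index.name != "sample_id":
            raise ValueError("trait table must be indexed by sample_id")
        self.values = values
        if schema is None:
            schema = {}
            for col in values.columns:
                if pd.api.types.is_numeric_dtype(values[col]):
                    schema[col] = ("quantitative", None)
                else:
                    levels = tuple(sorted(values[col].dropna().unique()))
                    schema[col] = ("categorical", levels)
        self.schema = schema
        for name, (kind, levels) in self.schema.items():
            if kind == "categorical":
                observed = set(values[name].dropna().unique())
                if not observed.issubset(set(levels)):
                    raise ValueError(
                        f"trait {name!r} has values outside declared levels"
                    )

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def kind(self, trait_name: str) -> str:
        return self.schema[trait_name][0]

    def get(self, trait_name: str, sample_ids: Sequence[str]) -> pd.Series:
        return self.values.loc[list(sample_ids), trait_name]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNP sites, dosage-coded with missingness.

    ``sites`` columns: chrom, pos (1-based), ref, alt, id.  Sites must be
    sorted by (chrom, pos) with each chromosome forming one contiguous run.
    ``samples`` columns: sample_id, pop_class, country.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n_samples, n_sites = self.genotypes.shape
        if n_samples != len(self.samples) or n_sites != len(self.sites):
            raise ValueError(
                f"genotype array {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        if n_sites:
            chroms = self.sites["chrom"].to_numpy()
            pos = self.sites["pos"].to_numpy()
            if (pos < 1).any():
                raise ValueError("positions must be >= 1")
            seen: set[str] = set()
            prev = None
            for i, c in enumerate(chroms):
                if c != prev:
                    if c in seen:
                        raise ValueError(
                            f"chromosome {c} is not a contiguous run of sites"
                        )
                    seen.add(c)
                    prev = c
                elif pos[i] <= pos[i - 1]:
                    raise ValueError(
                        f"sites not sorted/unique at {c}:{pos[i]}"
                    )

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def sample_indices(self, sample_ids: Sequence[str] | None) -> np.ndarray:
        if sample_ids is None:
            return np.arange(self.n_samples)
        lookup = {s: i for i, s in enumerate(self.samples["sample_id"])}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return np.asarray([lookup[s] for s in sample_ids], dtype=int)

    def samples_by_class(self, *pop_classes: str) -> list[str]:
        mask = self.samples["pop_class"].isin(pop_classes)
        return self.samples.loc[mask, "sample_id"].tolist()

    def cultivar_ids(self) -> list[str]:
        return self.samples_by_class(*CULTIVAR_CLASSES)

    def wild_ids(self) -> list[str]:
        return self.samples_by_class("wild")

    def _chrom_index(self) -> dict[str, tuple[int, int, np.ndarray]]:
        """chrom -> (lo, hi, positions); built lazily, sites are immutable
        by convention (subsetting returns a new matrix)."""
        cache = getattr(self, "_chrom_cache", None)
        if cache is None:
            cache = {}
            chroms = self.sites["chrom"].to_numpy()
            pos = self.sites["pos"].to_numpy()
            if len(chroms):
                bounds = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
                starts = np.concatenate(([0], bounds))
                ends = np.concatenate((bounds, [len(chroms)]))
                for s, e in zip(starts, ends):
                    cache[chroms[s]] = (int(s), int(e), pos[s:e])
            self._chrom_cache = cache
        return cache

    def chrom_site_range(self, chrom: str) -> tuple[int, int]:
        """Index range [lo, hi) of this chromosome's sites (contiguous)."""
        entry = self._chrom_index().get(chrom)
        return (entry[0], entry[1]) if entry else (0, 0)

    def site_index(self, chrom: str, pos: int) -> int:
        entry = self._chrom_index().get(chrom)
        if entry is None:
            raise KeyError(f"no site at {chrom}:{pos}")
        lo, _, pos_arr = entry
        i = int(np.searchsorted(pos_arr, pos))
        if i >= pos_arr.size or pos_arr[i] != pos:
            raise KeyError(f"no site at {chrom}:{pos}")
        return lo + i

    def window_site_range(self, window: Window) -> tuple[int, int]:
        """Index range of sites whose 0-based position lies in the window."""
        entry = self._chrom_index().get(window.chrom)
        if entry is None:
            return 0, 0
        lo, _, pos_arr = entry
        a = int(np.searchsorted(pos_arr, window.start + 1, side="left"))
        b = int(np.searchsorted(pos_arr, window.end + 1, side="left"))
        return lo + a, lo + b

    def site_record(self, i: int) -> SiteRecord:
        row = self.sites.iloc[i]
        return SiteRecord(row["chrom"], int(row["pos"]), row["ref"],
                          row["alt"], row.get("id"))

    def subset_sites(self, site_mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.loc[np.asarray(site_mask)].reset_index(drop=True),
            samples=self.samples.copy(),
            genotypes=self.genotypes[:, np.asarray(site_mask)].copy(),
        )

    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))


# -- site filters ---------------------------------------------------------

def filter_sites(matrix: GenotypeMatrix, maf_min: float = 0.05,
                 integrity_min: float = 0.8) -> GenotypeMatrix:
    """Keep sites with MAF strictly above ``maf_min`` and call rate
    (integrity) strictly above ``integrity_min``.

    MAF is computed from non-missing allele counts; the sample set is
    unchanged.  Idempotent by construction.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 < integrity_min <= 1):
        raise ValueError("integrity_min must be in (0, 1]")
    if matrix.n_samples == 0:
        raise ValueError("cannot filter a matrix with zero samples")
    G = matrix.genotypes
    called = G != MISSING
    n_called = called.sum(axis=0)
    alt_copies = np.where(called, G, 0).sum(axis=0)
    n_chrom = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_chrom > 0, alt_copies / np.maximum(n_chrom, 1), 0.0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    integrity = n_called / matrix.n_samples
    keep = (maf > maf_min) & (integrity > integrity_min)
    return matrix.subset_sites(keep)


# -- windows --------------------------------------------------------------

def make_windows(chrom_lengths: Mapping[str, int], size: int,
                 step: int | None = None) -> list[Window]:
    """Sliding (or non-overlapping when ``step`` is None) windows.

    Windows start at 0 and advance by ``step``; the terminal window is
    truncated at the chromosome end and kept whenever its span is >= 1 bp.
    ``step > size`` is rejected because it would silently drop sites.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if step is None:
        step = size
    if step <= 0:
        raise ValueError("step must be positive")
    if step > size:
        raise ValueError("step > size would leave gaps between windows")
    out: list[Window] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            out.append(Window(chrom, start, min(start + size, length)))
            start += step
    return out


# -- interval algebra -----------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[str, int, int]]
                    ) -> list[tuple[str, int, int]]:
    """Union of half-open intervals; overlapping or book-ended runs merge."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for chrom, s, e in intervals:
        if chrom not in by_chrom:
            by_chrom[chrom] = []
            order.append(chrom)
        by_chrom[chrom].append((s, e))
    merged: list[tuple[str, int, int]] = []
    for chrom in order:
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def subtract_intervals(base: Iterable[tuple[str, int, int]],
                       remove: Iterable[tuple[str, int, int]]
                       ) -> list[tuple[str, int, int]]:
    """Set difference base \\ remove on half-open intervals."""
    base_m = merge_intervals(base)
    remove = list(remove)
    rem_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in (merge_intervals(remove) if remove else []):
        rem_by_chrom.setdefault(chrom, []).append((s, e))
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in base_m:
        pieces = [(s, e)]
        for rs, re_ in rem_by_chrom.get(chrom, []):
            nxt = []
            for ps, pe in pieces:
                if re_ <= ps or rs >= pe:
                    nxt.append((ps, pe))
                    continue
                if rs > ps:
                    nxt.append((ps, rs))
                if re_ < pe:
                    nxt.append((re_, pe))
            pieces = nxt
        out.extend((chrom, ps, pe) for ps, pe in pieces)
    return out


def intersect_regions(regions: Sequence[RegionCall],
                      genes: GeneAnnotation) -> dict[RegionCall, list[str]]:
    """Map each region to the gene ids overlapping it by >= 1 bp.

    Half-open interval overlap; a gene may appear under several regions.
    """
    result: dict[RegionCall, list[str]] = {}
    gdf = genes.genes
    for region in regions:
        sel = gdf[(gdf["chrom"] == region.chrom)
                  & (gdf["start"] < region.end0)
                  & (gdf["end"] > region.start0)]
        result[region] = sel["gene_id"].tolist()
    return result


__all__ = [
    "MISSING", "CULTIVAR_CLASSES", "POP_CLASSES",
    "SiteRecord", "SampleInfo", "Window", "RegionCall",
    "GeneAnnotation", "TraitTable", "GenotypeMatrix",
    "filter_sites", "make_windows",
    "merge_intervals", "subtract_intervals", "intersect_regions",
]
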