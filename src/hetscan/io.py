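"""Reading and writing the standard file formats.

VCF input goes through cyvcf2 (htslib); only biallelic SNP records are
retained, with a logged count of exclusions.  VCF output is a minimal
GT-only v4.2 emitter so that simulated cohorts round-trip exactly.
Sample metadata, trait tables and chromosome lengths are plain TSV;
gene annotation is GFF3 (``gene`` features) or 4+-column BED; region
calls are emitted as BED with the defining statistic in the score column.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (MISSING, GeneAnnotation, GenotypeMatrix, RegionCall,
                   TraitTable)

log = logging.getLogger(__name__)


class VcfParseError(ValueError):
    pass


class SampleMismatchError(ValueError):
    pass


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("sample metadata TSV needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    for col in ("pop_class", "country"):
        if col not in df.columns:
            df[col] = None
    return df[["sample_id", "pop_class", "country"]]


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], dtype={0: str, 1: int},
                     usecols=[0, 1])
    return dict(zip(df["chrom"], df["length"]))


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("trait TSV needs a 'sample_id' column")
    return TraitTable(df.set_index("sample_id"))


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.values.reset_index().to_csv(path, sep="\t", index=False)


# -- VCF ------------------------------------------------------------------

# cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TYPE_TO_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)

_BASES = frozenset("ACGT")


def read_vcf(path: str | Path,
             metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Load a diploid VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (count logged).  Phased
    and unphased separators are treated identically.  When ``metadata``
    is given, every VCF sample must appear in it; offenders are listed.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib reports the offending position
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    vcf_samples = list(vcf.samples)
    if metadata is not None:
        known = set(metadata["sample_id"])
        offenders = [s for s in vcf_samples if s not in known]
        if offenders:
            raise SampleMismatchError(
                f"VCF samples absent from metadata: {offenders}")
        meta = metadata.set_index("sample_id").loc[vcf_samples].reset_index()
    else:
        meta = pd.DataFrame({"sample_id": vcf_samples,
                             "pop_class": None, "country": None})

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    ids: list[str | None] = []
    codes: list[np.ndarray] = []
    n_excluded = 0
    try:
        for variant in vcf:
            if (len(variant.ALT) != 1 or len(variant.REF) != 1
                    or len(variant.ALT[0]) != 1
                    or variant.REF.upper() not in _BASES
                    or variant.ALT[0].upper() not in _BASES):
                n_excluded += 1
                continue
            chroms.append(variant.CHROM)
            pos.append(variant.POS)
            ref.append(variant.REF.upper())
            alt.append(variant.ALT[0].upper())
            ids.append(variant.ID)
            codes.append(_GT_TYPE_TO_CODE[variant.gt_types])
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record in {path} after "
            f"{len(pos) + n_excluded} records: {exc}") from exc
    if n_excluded:
        log.info("read_vcf: excluded %d multiallelic/non-SNP records",
                 n_excluded)
    genotypes = (np.vstack(codes).T if codes
                 else np.empty((len(vcf_samples), 0), dtype=np.int8))
    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref,
                          "alt": alt, "id": ids})
    matrix = GenotypeMatrix(sites=sites, samples=meta, genotypes=genotypes)
    matrix.n_excluded_records = n_excluded  # type: ignore[attr-defined]
    return matrix


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF v4.2; MISSING becomes ``./.``."""
    matrix.validate()  # raises on unsorted sites
    sites = matrix.sites
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in matrix.chrom_names():
        lo, hi = matrix.chrom_site_range(chrom)
        max_pos = int(sites["pos"].iloc[lo:hi].max())
        lines.append(f"##contig=<ID={chrom},length={max_pos}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                   "INFO", "FORMAT"] + matrix.sample_ids
    lines.append("\t".join(header_cols))
    G = matrix.genotypes
    chrom_a = sites["chrom"].to_numpy()
    pos_a = sites["pos"].to_numpy()
    ref_a = sites["ref"].to_numpy()
    alt_a = sites["alt"].to_numpy()
    id_a = sites["id"].to_numpy() if "id" in sites else np.full(len(sites), None)
    gt_str = np.empty(G.shape, dtype=object)
    for code, s in _CODE_TO_GT.items():
        gt_str[G == code] = s
    for j in range(matrix.n_sites):
        rid = id_a[j] if id_a[j] not in (None, "") and id_a[j] == id_a[j] else "."
        row = [chrom_a[j], str(pos_a[j]), str(rid), ref_a[j], alt_a[j],
               ".", "PASS", ".", "GT"]
        row.extend(gt_str[:, j])
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# -- annotation -----------------------------------------------------------

def _parse_gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """GFF3 (feature type ``gene``; 1-based closed -> 0-based half-open)
    or BED with >= 4 columns (already 0-based half-open)."""
    path = Path(path)
    first_data = None
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first_data = line
                break
    if first_data is None:
        return GeneAnnotation(pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand"]))
    is_gff = len(first_data.rstrip("\n").split("\t")) >= 8
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if is_gff:
                if f[2] != "gene":
                    continue
                gid = (_parse_gff3_attr(f[8], "ID")
                       or _parse_gff3_attr(f[8], "Name")
                       or f"gene_{len(rows)}")
                rows.append((gid, f[0], int(f[3]) - 1, int(f[4]),
                             f[6] if len(f) > 6 else "."))
            else:
                if len(f) < 4:
                    raise ValueError("BED annotation needs >= 4 columns")
                rows.append((f[3], f[0], int(f[1]), int(f[2]),
                             f[5] if len(f) > 5 else "."))
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


# -- BED output -----------------------------------------------------------

def write_regions_bed(regions: Sequence[RegionCall], path: str | Path) -> None:
    """Regions as BED: chrom, start0, end0, label, score."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlabel\tscore\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start0}\t{r.end0}\t{r.label}"
                     f"\t{r.score:.6g}\n")


def read_regions_bed(path: str | Path, label: str | None = None
                     ) -> list[RegionCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(RegionCall(
                chrom=f[0], start0=int(f[1]), end0=int(f[2]),
                label=f[3] if len(f) > 3 and label is None else (label or "region"),
                score=float(f[4]) if len(f) > 4 else 0.0))
    return out


__all__ = [
    "VcfParseError", "SampleMismatchError",
    "read_sample_metadata", "read_chrom_lengths", "read_traits",
    "write_traits", "read_vcf", "write_vcf", "read_gene_annotation",
    "write_regions_bed", "read_regions_bed",
]
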