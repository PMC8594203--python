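"""Synthetic diploid cohorts for a domestication scenario.

The generator emulates the population structure the analysis assumes:
a small, diverse wild-progenitor panel and a larger cultivar panel that

* carries a genome-wide heterozygote excess (clonal propagation and
  outcrossing modelled as a negative inbreeding-like coefficient F),
* has drifted allele frequencies (bottleneck modelled as a Beta draw
  around the wild frequency with concentration ``drift_concentration``),
* is nearly fixed inside planted selective-sweep regions, and
* is heterozygous with high per-site probability inside planted
  balancing-selection blocks,

plus traits causally linked to genotype class at designated SNPs.  A
TruthSet records every planted interval and causal SNP so that recovery
by the scans can be scored.  All randomness flows from one seed through
one generator, in a fixed draw order (positions, wild frequencies,
cultivar frequencies, wild genotypes, cultivar genotypes, missingness,
then traits), so identical configs give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, RegionCall, TraitTable


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start0: int
    end0: int
    value: float  # cultivar target allele frequency, or het probability


@dataclass(frozen=True)
class CausalSNP:
    trait_name: str
    chrom: str
    pos: int                      # 1-based, must exist in the matrix
    kind: str = "quantitative"    # or "categorical"
    het_effect: float = 0.0
    hom_alt_effect: float = 0.0
    noise_sd: float = 1.0
    baseline: float = 0.0
    het_log_odds: float = 0.0     # categorical: log-odds by class
    hom_alt_log_odds: float = 0.0
    levels: tuple[str, str] = ("negative", "positive")


# Default planted regions, aligned to the 20-kb block grid so that the
# top-5% population-frequency rule is well-posed at desk scale: 3 blocks
# of 180 kb = 27 of 500 windows (~5.4%); 5 sweeps of 200 kb.
_DEFAULT_SWEEPS = (
    PlantedRegion("chr1", 1_000_000, 1_200_000, 0.98),
    PlantedRegion("chr1", 2_500_000, 2_700_000, 0.98),
    PlantedRegion("chr1", 4_000_000, 4_200_000, 0.98),
    PlantedRegion("chr2", 1_500_000, 1_700_000, 0.98),
    PlantedRegion("chr2", 3_500_000, 3_700_000, 0.98),
)
_DEFAULT_BLOCKS = (
    PlantedRegion("chr1", 600_000, 780_000, 0.9),
    PlantedRegion("chr2", 600_000, 780_000, 0.9),
    PlantedRegion("chr2", 2_600_000, 2_780_000, 0.9),
)
_DEFAULT_CAUSAL = (
    CausalSNP("root_weight", "chr1", 0, kind="quantitative",
              het_effect=1.5, hom_alt_effect=0.5, noise_sd=1.0,
              baseline=20.0),
    CausalSNP("starch_content", "chr2", 0, kind="quantitative",
              het_effect=0.0, hom_alt_effect=2.0, noise_sd=1.0,
              baseline=25.0),
    CausalSNP("cbb_resistance", "chr1", 0, kind="categorical",
              het_log_odds=1.5, hom_alt_log_odds=-1.0,
              levels=("susceptible", "resistant")),
)


@dataclass
class SimConfig:
    """Desk-scale domestication scenario (2 x 5 Mb, 14 wild + 200
    cultivars, 4 SNPs per kb raw density, U-shaped wild site-frequency
    spectrum).

    ``f_background`` is an inbreeding-like coefficient applied to the
    cultivar genotype draw: het probability 2p(1-p)(1-F), so negative F
    produces the cultivars' genome-wide heterozygote excess.  Causal SNPs
    with pos=0 are anchored at simulation time to the SNP nearest the
    centre of the first balancing block (quantitative het-effect traits)
    or the first sweep (hom-alt traits) on their chromosome.
    """

    n_chrom: int = 2
    chrom_length_bp: int = 5_000_000
    snp_density: float = 0.004
    n_wild: int = 14
    n_cultivar: int = 200
    landrace_fraction: float = 0.1
    wild_beta: tuple[float, float] = (0.5, 0.5)
    drift_concentration: float = 30.0
    f_background: float = -0.1
    sweep_regions: tuple[PlantedRegion, ...] = _DEFAULT_SWEEPS
    balancing_blocks: tuple[PlantedRegion, ...] = _DEFAULT_BLOCKS
    causal_snps: tuple[CausalSNP, ...] = _DEFAULT_CAUSAL
    missing_rate: float = 0.02
    seed: int = 0

    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp
                for i in range(self.n_chrom)}

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        """Build from plain YAML/JSON data: planted regions may be
        [chrom, start0, end0, value] lists, causal SNPs field dicts."""
        raw = dict(raw)
        for key in ("sweep_regions", "balancing_blocks"):
            if key in raw:
                raw[key] = tuple(
                    r if isinstance(r, PlantedRegion) else PlantedRegion(*r)
                    for r in raw[key])
        if "causal_snps" in raw:
            raw["causal_snps"] = tuple(
                c if isinstance(c, CausalSNP) else CausalSNP(**c)
                for c in raw["causal_snps"])
        if "wild_beta" in raw:
            raw["wild_beta"] = tuple(raw["wild_beta"])
        return cls(**raw)

    def validate(self) -> None:
        if not (-1.0 < self.f_background < 1.0):
            raise ValueError("f_background must be in (-1, 1)")
        for frac in (self.snp_density, self.missing_rate,
                     self.landrace_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        lengths = self.chrom_lengths()
        planted = list(self.sweep_regions) + list(self.balancing_blocks)
        for r in planted:
            if r.chrom not in lengths or not (
                    0 <= r.start0 < r.end0 <= lengths[r.chrom]):
                raise ValueError(f"planted region out of bounds: {r}")
            if not (0 <= r.value <= 1):
                raise ValueError(f"planted value outside [0,1]: {r}")
        for c in self.causal_snps:
            if c.chrom not in lengths:
                raise ValueError(
                    f"causal SNP chromosome {c.chrom!r} not in genome")
        for a in planted:
            for b in planted:
                if a is not b and a.chrom == b.chrom \
                        and a.start0 < b.end0 and b.start0 < a.end0:
                    raise ValueError(f"planted regions overlap: {a} / {b}")


@dataclass
class TruthSet:
    sweeps: list[PlantedRegion]
    blocks: list[PlantedRegion]
    causal: list[CausalSNP]


def _region_mask(chroms: np.ndarray, pos0: np.ndarray,
                 regions: Sequence[PlantedRegion]) -> np.ndarray:
    mask = np.zeros(pos0.size, dtype=bool)
    for r in regions:
        mask |= (chroms == r.chrom) & (pos0 >= r.start0) & (pos0 < r.end0)
    return mask


def _draw_positions(rng: np.random.Generator, length: int, n: int
                    ) -> np.ndarray:
    """n sorted unique 0-based positions ~ uniform over the chromosome."""
    draw = rng.integers(0, length, size=int(n * 1.2) + 10)
    uniq = np.unique(draw)
    while uniq.size < n:
        extra = rng.integers(0, length, size=n)
        uniq = np.unique(np.concatenate([uniq, extra]))
    if uniq.size > n:
        keep = np.sort(rng.choice(uniq.size, size=n, replace=False))
        uniq = uniq[keep]
    return uniq


def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeMatrix, TruthSet]:
    """Draw the cohort genotype matrix and its truth set.

    Wild genotypes are Hardy-Weinberg at p ~ Beta(a, b); cultivar
    frequencies drift via Beta(p*k, (1-p)*k) except inside sweeps where
    they are pinned to the target; cultivar genotypes use het probability
    2p'(1-p')(1-F) — overridden to the block value inside balancing
    blocks — with the remaining mass split between the homozygote
    classes in proportion to their Hardy-Weinberg weights.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lengths = config.chrom_lengths()
    chrom_arrs, pos_arrs = [], []
    for chrom, length in lengths.items():
        n = int(round(length * config.snp_density))
        pos0 = _draw_positions(rng, length, n)
        chrom_arrs.append(np.full(pos0.size, chrom, dtype=object))
        pos_arrs.append(pos0)
    chroms = np.concatenate(chrom_arrs)
    pos0 = np.concatenate(pos_arrs)
    n_sites = pos0.size

    a, b = config.wild_beta
    p_wild = np.clip(rng.beta(a, b, size=n_sites), 1e-6, 1 - 1e-6)
    k = config.drift_concentration
    p_cult = np.clip(rng.beta(p_wild * k, (1 - p_wild) * k), 1e-6, 1 - 1e-6)
    sweep_mask = _region_mask(chroms, pos0, config.sweep_regions)
    for r in config.sweep_regions:
        m = (chroms == r.chrom) & (pos0 >= r.start0) & (pos0 < r.end0)
        p_cult[m] = r.value

    g_wild = rng.binomial(2, p_wild, size=(config.n_wild, n_sites)
                          ).astype(np.int8)

    h = 2.0 * p_cult * (1 - p_cult) * (1 - config.f_background)
    for r in config.balancing_blocks:
        m = (chroms == r.chrom) & (pos0 >= r.start0) & (pos0 < r.end0)
        h[m] = r.value
    if (h > 1.0).any():
        bad = int(np.flatnonzero(h > 1.0)[0])
        raise ValueError(
            f"infeasible heterozygote probability > 1 at "
            f"{chroms[bad]}:{pos0[bad] + 1}")
    hw_hom = p_cult ** 2 + (1 - p_cult) ** 2
    p2 = (1 - h) * (p_cult ** 2) / hw_hom
    p0 = (1 - h) * ((1 - p_cult) ** 2) / hw_hom
    u = rng.random(size=(config.n_cultivar, n_sites))
    g_cult = np.where(u < p0, 0, np.where(u < p0 + h, 1, 2)).astype(np.int8)

    G = np.vstack([g_wild, g_cult])
    if config.missing_rate > 0:
        drop = rng.random(size=G.shape) < config.missing_rate
        G[drop] = MISSING

    refs = np.full(n_sites, "A", dtype=object)
    alts = np.full(n_sites, "G", dtype=object)
    sites = pd.DataFrame({"chrom": chroms, "pos": pos0 + 1, "ref": refs,
                          "alt": alts, "id": None})
    n_land = int(round(config.n_cultivar * config.landrace_fraction))
    samples = pd.DataFrame({
        "sample_id": ([f"W{i + 1:03d}" for i in range(config.n_wild)]
                      + [f"C{i + 1:03d}" for i in range(config.n_cultivar)]),
        "pop_class": (["wild"] * config.n_wild + ["landrace"] * n_land
                      + ["breeding"] * (config.n_cultivar - n_land)),
        "country": None,
    })
    matrix = GenotypeMatrix(sites=sites, samples=samples, genotypes=G)
    causal = [_anchor_causal(c, matrix, config) for c in config.causal_snps]
    truth = TruthSet(sweeps=list(config.sweep_regions),
                     blocks=list(config.balancing_blocks), causal=causal)
    return matrix, truth


def _anchor_causal(c: CausalSNP, matrix: GenotypeMatrix,
                   config: SimConfig) -> CausalSNP:
    """Resolve pos=0 placeholders to a real SNP position."""
    if c.pos != 0:
        matrix.site_index(c.chrom, c.pos)  # must exist
        return c
    het_driven = (c.kind == "categorical" and c.het_log_odds != 0) or \
        (c.kind == "quantitative" and abs(c.het_effect) >= abs(c.hom_alt_effect))
    pool = config.balancing_blocks if het_driven else config.sweep_regions
    region = next((r for r in pool if r.chrom == c.chrom), None)
    if region is None:
        region = next((r for r in list(config.balancing_blocks)
                       + list(config.sweep_regions)
                       if r.chrom == c.chrom), None)
    if region is not None:
        centre = (region.start0 + region.end0) // 2
    else:  # no planted region on this chromosome: anchor mid-chromosome
        centre = config.chrom_lengths()[c.chrom] // 2
    lo, hi = matrix.chrom_site_range(c.chrom)
    pos = matrix.sites["pos"].to_numpy()[lo:hi]
    j = int(np.argmin(np.abs(pos - (centre + 1))))
    return replace(c, pos=int(pos[j]))


def simulate_traits(matrix: GenotypeMatrix, truth: TruthSet,
                    config: SimConfig,
                    rng: np.random.Generator | None = None) -> TraitTable:
    """Traits from genotype classes at the causal SNPs.

    Quantitative: baseline + class effects + N(0, sd).  Categorical:
    Bernoulli with logit = sum of class log-odds.  A missing genotype at
    a causal SNP contributes zero effect.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = matrix.n_samples
    by_trait: dict[str, list[CausalSNP]] = {}
    for c in truth.causal:
        by_trait.setdefault(c.trait_name, []).append(c)
    cols: dict[str, np.ndarray] = {}
    schema: dict[str, tuple] = {}
    for trait, specs in by_trait.items():
        kind = specs[0].kind
        if kind == "quantitative":
            value = np.full(n, specs[0].baseline, dtype=float)
            for c in specs:
                g = matrix.genotypes[:, matrix.site_index(c.chrom, c.pos)]
                value += np.where(g == 1, c.het_effect,
                                  np.where(g == 2, c.hom_alt_effect, 0.0))
                value += rng.normal(0.0, c.noise_sd, size=n)
            cols[trait] = value
            schema[trait] = ("quantitative", None)
        else:
            logit = np.zeros(n)
            for c in specs:
                g = matrix.genotypes[:, matrix.site_index(c.chrom, c.pos)]
                logit += np.where(g == 1, c.het_log_odds,
                                  np.where(g == 2, c.hom_alt_log_odds, 0.0))
            prob = 1.0 / (1.0 + np.exp(-logit))
            draw = rng.random(n) < prob
            levels = specs[0].levels
            cols[trait] = np.where(draw, levels[1], levels[0])
            schema[trait] = ("categorical", tuple(sorted(levels)))
    df = pd.DataFrame(cols, index=pd.Index(matrix.sample_ids,
                                           name="sample_id"))
    return TraitTable(df, schema)


def simulate_cohort(config: SimConfig
                    ) -> tuple[GenotypeMatrix, TraitTable, TruthSet]:
    """Genotypes then traits from a single seeded stream."""
    rng = np.random.default_rng(config.seed)
    matrix, truth = simulate_genotypes(config, rng)
    traits = simulate_traits(matrix, truth, config, rng)
    return matrix, traits, truth


# -- truth files and recovery scoring ------------------------------------

def write_truth(truth: TruthSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, regions in (("truth_sweeps.bed", truth.sweeps),
                          ("truth_blocks.bed", truth.blocks)):
        with open(outdir / name, "w") as fh:
            fh.write("#chrom\tstart\tend\tvalue\n")
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start0}\t{r.end0}\t{r.value:g}\n")
    rows = []
    for c in truth.causal:
        rows.append({"trait_name": c.trait_name, "chrom": c.chrom,
                     "pos": c.pos, "kind": c.kind,
                     "het_effect": c.het_effect,
                     "hom_alt_effect": c.hom_alt_effect,
                     "noise_sd": c.noise_sd, "baseline": c.baseline,
                     "het_log_odds": c.het_log_odds,
                     "hom_alt_log_odds": c.hom_alt_log_odds})
    pd.DataFrame(rows, columns=["trait_name", "chrom", "pos", "kind",
                                "het_effect", "hom_alt_effect", "noise_sd",
                                "baseline", "het_log_odds",
                                "hom_alt_log_odds"]
                 ).to_csv(outdir / "truth_causal.tsv", sep="\t", index=False)


def read_truth_regions(path: str | Path) -> list[PlantedRegion]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(PlantedRegion(f[0], int(f[1]), int(f[2]),
                                     float(f[3]) if len(f) > 3 else 0.0))
    return out


def score_recovery(called: Sequence[RegionCall],
                   truth_intervals: Sequence[PlantedRegion],
                   min_reciprocal_overlap: float = 0.5
                   ) -> tuple[float, float]:
    """(sensitivity, precision) of called regions against planted truth.

    A truth interval is recovered when some called region overlaps it by
    at least ``min_reciprocal_overlap`` of both spans; precision is the
    matched fraction of called regions (NaN when nothing was called).
    """
    def _overlap(a_s, a_e, b_s, b_e):
        return max(0, min(a_e, b_e) - max(a_s, b_s))

    recovered = 0
    matched_called: set[int] = set()
    for t in truth_intervals:
        hit = False
        for i, c in enumerate(called):
            if c.chrom != t.chrom:
                continue
            ov = _overlap(c.start0, c.end0, t.start0, t.end0)
            if ov >= min_reciprocal_overlap * (t.end0 - t.start0) \
                    and ov >= min_reciprocal_overlap * c.span:
                hit = True
                matched_called.add(i)
        recovered += hit
    sensitivity = recovered / len(truth_intervals) if truth_intervals else 1.0
    precision = (len(matched_called) / len(called)) if called else float("nan")
    return sensitivity, precision


__all__ = [
    "PlantedRegion", "CausalSNP", "SimConfig", "TruthSet",
    "simulate_genotypes", "simulate_traits", "simulate_cohort",
    "write_truth", "read_truth_regions", "score_recovery",
]
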