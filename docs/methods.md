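# Methods

This note documents the statistical definitions, the synthetic-cohort
generator, the numerical conventions and the open design choices made
in `hetscan`, in the package's own terms.

## Estimators

All statistics operate on unphased dosage-coded diploid genotypes
(0 = hom-ref, 1 = het, 2 = hom-alt, −1 = missing) at biallelic SNPs.
Missing data are handled by per-site complete observation: the
non-missing sample set, and hence the allele-copy count n, varies site
by site and nothing is imputed.

**Expected heterozygosity.** He = 1 − p² − (1−p)² with p the
alternate-allele frequency among non-missing copies; for a biallelic
site He ∈ [0, 0.5], maximal at p = 0.5. Window He is the unweighted
mean over SNPs in the window.

**Nucleotide diversity.** Per site, the unbiased pairwise estimator
π̂ₛ = 2j(n−j)/(n(n−1)) with j alternate copies of n; window π is the
sum of per-site values divided by the *actual* window span, so terminal
partial windows are length-normalised, not dropped (dropping them would
bias chromosome ends).

**Tajima's D.** D = (π_total − S/a₁)/√(e₁S + e₂S(S−1)) with the
standard constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ evaluated at n.
π_total is the window *sum* of per-site π̂ₛ (same units as S/a₁); S is
the count of segregating sites. Because n varies per site under
missingness, the constants use the modal per-site chromosome count in
the window; D is reported undefined when S < 3 (configurable) or the
modal n < 4.

**F<sub>ST</sub>.** Hudson's estimator as a ratio of per-site averages:
Σₛ[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / Σₛ[p₁(1−p₂) +
p₂(1−p₁)], skipping sites with fewer than two copies in either group.
Ratio-of-averages is stable in window scans where per-site ratios are
noisy. Slightly negative window values are genuine sampling noise and
are reported unclamped. Nei's G_ST (1 − H̄_S/H̄_T on per-site average
gene diversities) is available as an option. A note on estimator
choice: the per-window F<sub>ST</sub> and π estimators here are fixed
and oracle-checkable; other toolchains' unstated variants will differ
in the third decimal, not in the window ranking.

**p-distance.** For a sample pair, the mean of |gᵢ−gⱼ|/2 over shared
non-missing sites (a normalised dosage distance in [0, 1]); between
groups, the mean over all cross-group pairs, skipping (with a warning)
pairs that share no called site. This is a deliberate definition for
unphased diploid data, where sequence-style p-distance is ill-posed.

**LD.** r² is the squared Pearson correlation of dosages over
pairwise-complete samples. The decay curve averages r² of all
intra-chromosome pairs within 1 Mb in 1-kb bins; when the pair count
exceeds 10⁶ a uniform seeded subsample is scored. The decay point is
the midpoint of the first bin with mean r² ≤ 0.2.

**Tests.** Group diversity contrasts and quantitative genotype-class
comparisons use Welch's unequal-variance two-tailed t-test (the robust
default when class sizes and variances differ). Trait segregation uses
the two-sided Wilcoxon rank-sum test: exact enumeration when both
groups have ≤ 10 members and no ties, otherwise the tie-corrected
normal approximation. Categorical association uses Pearson's
chi-square without continuity correction, dropping zero margins with a
warning and flagging expected counts < 5. Two-locus combination
classes are compared with Mood's median test (2×2 above/≤-median split
per pair, ties assigned to the ≤-median cell); pairwise p-values are
Bonferroni-adjusted by default (Benjamini–Hochberg optional), and the
compact letter display is assigned greedily in descending-median
order: a class joins every existing letter group with which it has no
significant pairwise difference, else opens a new letter. Block
segregation scans add a BH q-value column across all block × trait
tests; per-chromosome region t-tests report raw p-values.

## Region and block calling conventions

Coordinates are 0-based half-open internally; VCF I/O converts to and
from 1-based, BED output is native 0-based half-open.

*Het/hom partition.* The 25-kb/5-kb sliding windows of the reference
accession are labelled homozygous when het calls per bp fall below
0.002 (i.e. 50 het SNPs per full window; the threshold applies to the
fraction, and is a parameter). Overlapping windows produce label
conflicts; a base is heterozygous if *any* overlapping window is het
(union of the rarer label preserves signal), and the homozygous
partition is the union of homozygous windows minus the het union, so
the two labels are disjoint by construction. Regions with span
≤ 50 kb are discarded. Raising the rate threshold monotonically grows
the homozygous span.

*Blocks.* The per-accession het-block cutoff is always recomputed as
the mean het-SNP count over all (accession, 20-kb window) pairs in the
cohort at hand — it is an output, not a constant. A window is a block
for an accession when its count is strictly above the cutoff. The
population-frequency cutoff for highly heterozygous blocks is the
empirical quantile with linear interpolation between order statistics;
windows at or above it qualify, so ties can saturate the marked set.
For a merged multi-window block, an accession counts as heterozygous
if any constituent window is a block call for it (union rule, matching
the region convention).

*Sweep scan.* Ratios are oriented wild/cultivar so large values mean
diversity lost in cultivars. Windows with fewer than 5 SNPs
(configurable) or a zero cultivar value are excluded from the quantile
rather than assigned extreme ratios; a flag can instead auto-mark
zero-denominator windows. Above-threshold windows that overlap or are
book-ended merge; with 50-kb/10-kb windows consecutive candidates
always overlap. Scan thresholds are dataset-specific outputs, never
constants. F<sub>ST</sub> contrasts against the small wild panel use
an optional seeded down-sampling of cultivars (default 14) to balance
panel sizes.

## The synthetic cohort

The generator produces the statistical structure the scans consume —
site-frequency and heterozygosity patterns — not sequence-level
realism.

- **Genome and density**: 2 chromosomes × 5 Mb, 4 SNPs/kb raw.
  After the MAF > 0.05 filter on the U-shaped spectrum this leaves
  ~2.9 SNPs/kb, chosen so that planted balancing blocks (per-site het
  probability 0.9) clear the 0.002 region threshold with margin
  (≈ 64 > 50 het calls per 25 kb) while background accessions
  (~0.3 het fraction) stay far below it.
- **Wild panel** (n = 14): Hardy–Weinberg genotypes at
  p ~ Beta(0.5, 0.5), the U-shape mimicking a neutral site-frequency
  spectrum.
- **Cultivar panel** (n = 200; 10% landrace, 90% breeding line):
  frequencies drift as p′ ~ Beta(pk, (1−p)k) with concentration
  k = 30 (a moderate bottleneck that preserves most diversity);
  genotypes are drawn with het probability 2p′(1−p′)(1−F) and the
  remaining mass split between homozygote classes by their
  Hardy–Weinberg weights. The default F = −0.1 creates the
  genome-wide ~10% heterozygote excess characteristic of clonally
  propagated outcrossers.
- **Planted sweeps**: five 200-kb regions where the cultivar alternate
  frequency is pinned at 0.98 (cultivar He ≈ 0.04 versus a wild
  background ≈ 0.3).
- **Planted balancing blocks**: three 180-kb regions (9 × 20-kb
  windows, aligned to the block grid) where every cultivar's per-site
  het probability is 0.9. Block sizes total ~5.4% of the 20-kb
  windows so the top-5% frequency rule can cover them.
- **Traits**: quantitative traits are baseline + genotype-class
  effects at causal SNPs + Gaussian noise; categorical traits are
  Bernoulli with logit equal to the summed class log-odds. Missing
  genotypes contribute zero effect. Causal SNPs given as `pos=0` are
  anchored at simulation time to the SNP nearest the centre of an
  appropriate planted region.
- **Determinism**: one seed, one generator, fixed draw order
  (positions, wild frequencies, cultivar frequencies, wild genotypes,
  cultivar genotypes, missingness, traits); identical configs yield
  byte-identical VCFs.

**Scan quantile for this scenario.** The top-1% rule of a full-genome
scan matches a genome where sweeps occupy ~1.65%. Here the planted
sweeps occupy 10% of the desk-scale genome, so the default analysis
configuration for the bundled scenario uses `top_q = 0.10`: the marked
quota must be commensurate with the swept fraction or the scan cannot
cover the truth regardless of signal strength. `ratio_scan` itself
defaults to 0.01 for real-genome use.

### What the simulator does and does not show

Sites are drawn independently (no linkage), so LD-based behaviour must
be exercised with the block-copy construction used in the LD tests,
and haplotype structure, recombination maps, mutation-rate
heterogeneity and pedigree/clonal structure are absent. Three
consequences worth knowing:

- Passing recovery tests show the scans detect frequency/heterozygosity
  structure of the planted kind at realistic panel sizes; they do not
  certify performance under real LD, population stratification or
  variant-calling artefacts.
- Planted balancing blocks elevate cultivar allele frequencies toward
  0.5 without touching the wild panel, so wild–cultivar F<sub>ST</sub>
  inside blocks is *higher* than background in this cohort — the
  opposite of the empirical expectation that balancing selection
  maintains the same polymorphism in both panels. The π and He
  contrasts, which the directional checks use, are unaffected.
- Because blocks are heterozygous in effectively every cultivar, the
  het/hom accession split at planted blocks is degenerate (empty hom
  group) and trait segregation there is reported as undefined rather
  than forced. The segregation statistic itself is validated by exact
  enumeration and null calibration on constructed groups, and
  SNP-level trait links are tested through genotype classes. A
  carrier-frequency block model (het in ~90% of cultivars) was
  evaluated and rejected: under the U-shaped background spectrum,
  background window frequencies reach ~1.0 often enough to swamp a
  0.9-frequency block signal in the top-5% rule.

## Numerical conventions and degenerate inputs

- Quantiles use linear interpolation between order statistics
  (`numpy.quantile` default), documented because tie saturation at the
  cutoff changes how many windows qualify.
- Welch tests on two zero-variance samples return t = 0, p = 1 when
  means agree (and p = 0 otherwise); chi-square tables that lose a
  margin are reduced with a warning and reported undefined if fewer
  than 2×2 remains; Mood's test returns (0, 1) when all values tie at
  the grand median.
- Empty windows give NaN mean He and zero π; zero-variance sites give
  NaN r²; F<sub>ST</sub> with zero pooled denominator is NaN.
- `filter_sites` uses strict inequalities (MAF > 0.05, call rate
  > 0.8) and is idempotent.
- Statistics are invariant to permuting samples and to swapping the
  ref/alt labelling of any site; both invariances are property-tested.

## Problem sizes used in the checks

The bundled verification suite runs entirely on simulated data:
statistic-versus-oracle comparisons use ≥ 1,000 random small instances
per estimator at 10⁻⁹ tolerance (exact enumeration where defined);
sweep and block recovery aggregate 20 seeded replicates of the default
cohort, scored at reciprocal overlap 0.5; null calibration of the
Welch, chi-square and Wilcoxon paths uses 1,000 replicates with groups
of 60; the acceptance script replicates the full analysis over 10
seeds. These sizes keep a complete run in the low tens of seconds on
one CPU while leaving the binomial error of the calibration estimates
well inside the stated bands.

## Known limitations

Beyond the simulator caveats above: the pipeline is SNP-only (indels
are excluded at VCF ingestion, as every downstream statistic is
SNP-based); phase is ignored throughout, so phased multi-SNP
haplotype analyses are out of scope (two-locus genotype-class
combinations are the supported abstraction); no composite-likelihood
or haplotype-based sweep statistics (iHS, XP-EHH) are provided; and
mixed-model GWAS is deliberately not part of the package — the
association module consumes externally nominated candidate SNPs.
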