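"""Simulate a domestication cohort and write its files.

Generates the default desk-scale scenario — 14 wild progenitors plus
200 cultivars on a 2 x 5 Mb genome, with 5 planted selective sweeps,
3 planted balancing-selection blocks and genotype-linked traits — and
writes VCF, sample/trait TSVs and the truth files.
"""

from pathlib import Path

from hetscan import SimConfig, simulate_cohort, write_truth, write_vcf
from hetscan.io import write_traits

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=1)
matrix, traits, truth = simulate_cohort(cfg)

write_vcf(matrix, out / "genotypes.vcf")
matrix.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
write_traits(traits, out / "traits.tsv")
write_truth(truth, out)

n_wild = len(matrix.wild_ids())
n_cult = len(matrix.cultivar_ids())
print(f"cohort: {n_wild} wild + {n_cult} cultivar accessions, "
      f"{matrix.n_sites} SNPs on {cfg.n_chrom} chromosomes")
print(f"planted: {len(truth.sweeps)} sweeps, {len(truth.blocks)} "
      f"balancing blocks, {len(truth.causal)} causal SNPs")
print(f"files written to {out}/")
# The truth BED files are what the recovery scoring in later examples
# compares the scan calls against.
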