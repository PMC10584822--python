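"""Build a small synthetic reciprocal cross and inspect its structure.

The generator draws two parental haplotypes that differ at SNPs, gene/TE
annotation, and per-cytosine methylomes for egg, sperm, zygote and globular
embryo, with egg-vs-sperm DMRs planted on the 50-bp grid.
"""

import zygometh as z

config = z.SimConfig(
    genome_length=100_000,
    n_chromosomes=2,
    snp_rate=0.02,
    n_planted_dmrs={"CG": 12, "CHG": 8, "CHH": 8},
    depth=10.0,
    seed=42,
)
genomes = z.simulate_parental_genomes(config)
truth = z.simulate_methylomes(genomes, config)

print(f"chromosomes: {list(genomes.maternal)}")
print(f"SNPs between the haplotypes: {len(genomes.snps)} "
      f"({genomes.snps.df['ambiguous_pair'].ne('').mean():.1%} bisulfite-ambiguous)")
print(f"annotated intervals: {genomes.annotation['feature'].value_counts().to_dict()}")
print(f"context-complete cytosines on the N-masked reference: {len(truth.sites)}")
print(truth.sites["context"].value_counts().to_string())
print("\nplanted egg-vs-sperm DMRs (first rows):")
print(truth.planted_dmrs.head(5).to_string(index=False))
print("\nEach planted window holds >=5 cytosines of its context whose true "
      "egg and sperm levels differ by the configured effect size; these are "
      "the regions the DMR caller and the remodeling estimator must recover.")
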