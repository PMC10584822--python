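"""Partition hybrid-zygote reads into parental alleles via their SNP bases.

The reference is N-masked at every SNP; each read is then classified from
the bases it shows at the SNPs it covers.  C/T SNPs are skipped on
plus-strand reads (bisulfite conversion makes them uninformative there) and
G/A SNPs on minus-strand reads.  The simulation records every read's true
allele, so assignment purity can be measured directly.
"""

import numpy as np

import zygometh as z

config = z.SimConfig(
    genome_length=100_000,
    n_chromosomes=2,
    snp_rate=0.02,
    n_planted_dmrs={},
    depth=10.0,
    n_replicates=1,
    seed=42,
)
genomes = z.simulate_parental_genomes(config)
truth = z.simulate_methylomes(genomes, config)
reads = z.generate_bisulfite_reads(truth, config, cell_types=["zygote"])[("zygote", 0)]

result = z.assign_alleles(reads, genomes.snps, mode="bisulfite")
print(f"hybrid zygote reads: {reads.n_reads}")
print(f"assignment: {result.counts}")
print(f"assigned fraction: {result.assigned_fraction:.3f}")

assigned = np.isin(result.labels, (0, 1))
purity = (result.labels[assigned] == reads.true_allele[assigned]).mean()
print(f"purity vs hidden truth: {purity:.4f}")

mat, pat = z.allelic_cytosine_counts(reads, result, truth.masked_reference,
                                     sites=truth.sites)
print(f"cytosines with >=3 maternal-allele reads: {len(mat.sites)}; "
      f"paternal: {len(pat.sites)}")
print("Purity 1.0 confirms that with error-free reads and the per-strand "
      "ambiguity rule, no read is attributed to the wrong parent; the "
      "allelic profiles feed the remodeling analysis.")
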