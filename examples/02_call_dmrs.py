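"""Call egg-vs-sperm DMRs on simulated bisulfite reads and annotate them.

Pipeline: simulate reads for both gametes (2 replicates), extract and pool
per-cytosine counts, apply the >=3x coverage filter, test 50-bp windows
(Fisher's exact test + BH FDR, context cutoffs CG>0.5 / CHG>0.3 / CHH>0.1)
and classify each DMR by overlap with genes and TEs.
"""

import zygometh as z
from zygometh import dmrscan

config = z.SimConfig(
    genome_length=100_000,
    n_chromosomes=2,
    snp_rate=0.0,
    n_planted_dmrs={"CG": 12, "CHG": 8, "CHH": 8},
    depth=20.0,
    seed=42,
)
genomes = z.simulate_parental_genomes(config)
truth = z.simulate_methylomes(genomes, config)


def pooled_sites(cell):
    per_rep = []
    for rep in range(config.n_replicates):
        reads = z.generate_bisulfite_reads(truth, config, cell_types=[cell], replicates=[rep])
        per_rep.append(
            z.extract_cytosine_counts(reads[(cell, rep)], truth.masked_reference,
                                      sites=truth.sites)
        )
    return z.filter_coverage(z.pool_replicates(per_rep, mode="sum"), min_depth=3)


dmrs = dmrscan.call_dmrs(pooled_sites("egg"), pooled_sites("sperm"))
dmrs = dmrscan.annotate_dmrs(
    dmrs, genomes.feature_intervals("gene"), genomes.feature_intervals("TE")
)

print(f"DMRs called: {len(dmrs)} "
      f"(planted: {len(truth.planted_dmrs)})")
print("\nper context (hyper = egg > sperm):")
print(dmrs.groupby(["context", "direction"]).size().to_string())
print("\nfeature classes:")
print(dmrs["feature_class"].value_counts().to_string())

planted = set(zip(truth.planted_dmrs["chrom"], truth.planted_dmrs["start"],
                  truth.planted_dmrs["context"]))
called = set(zip(dmrs["chrom"], dmrs["start"], dmrs["context"]))
print(f"\nrecall vs planted truth: {len(planted & called) / len(planted):.2f}; "
      f"precision: {len(planted & called) / len(called):.2f}")
print("A recall/precision near 1 means the windowed Fisher+FDR scan recovers "
      "exactly the regions where the gamete methylomes truly differ.")
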