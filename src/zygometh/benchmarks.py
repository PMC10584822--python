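"""End-to-end validation studies on synthetic crosses with known truth.

Each routine builds a cross with the study conditions it states, runs the
actual pipeline (never the truth shortcuts) and measures how well the
planted structure is recovered.  They back both the acceptance test suite
and ``scripts/acceptance.py``; problem sizes are chosen so every study runs
in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dmrscan, remodeling
from .allelesplit import (
    MATERNAL,
    PATERNAL,
    assign_alleles,
    pooled_allelic_profiles,
)
from .config import SimConfig
from .imprinting import classify_imprinting
from .methcall import extract_cytosine_counts, filter_coverage, pool_replicates
from .simulate import (
    generate_allelic_expression_counts,
    generate_bisulfite_reads,
    sample_cytosine_counts,
    simulate_methylomes,
    simulate_parental_genomes,
)


def _pooled_sample_sites(truth, config, cell_type, replicates=None):
    """Simulate reads for one cell type, extract and pool over replicates."""
    per_rep = []
    reps = list(replicates or range(config.n_replicates))
    for rep in reps:
        readsets = generate_bisulfite_reads(
            truth, config, cell_types=[cell_type], replicates=[rep]
        )
        per_rep.append(
            extract_cytosine_counts(
                readsets[(cell_type, rep)], truth.masked_reference, sites=truth.sites
            )
        )
    return filter_coverage(pool_replicates(per_rep, mode="sum"), min_depth=3)


# ---------------------------------------------------------------------------
# DMR calling: recall / precision on planted CG DMRs + matched null
# ---------------------------------------------------------------------------

def dmr_benchmark(
    seed: int = 0,
    genome_length: int = 1_000_000,
    n_dmrs: int = 200,
    depth: float = 30.0,
    effect: float = 0.8,
) -> dict:
    """Egg-vs-sperm CG DMR calling on a genome with planted DMRs.

    Defaults: 1-Mb genome, 200 planted CG DMRs of effect 0.8, read depth 30,
    two replicates per gamete.  Recall and precision are measured against the
    planted windows (a call matches if it overlaps a planted interval of its
    context).
    """
    config = SimConfig(
        genome_length=genome_length,
        n_chromosomes=2,
        snp_rate=0.0,
        n_planted_dmrs={"CG": n_dmrs},
        planted_effect={"CG": effect},
        depth=depth,
        seed=seed,
    )
    genomes = simulate_parental_genomes(config)
    truth = simulate_methylomes(genomes, config)
    egg = _pooled_sample_sites(truth, config, "egg")
    sperm = _pooled_sample_sites(truth, config, "sperm")
    dmrs = dmrscan.call_dmrs(egg, sperm, contexts=["CG"])

    planted = truth.planted_dmrs
    planted_keys = set(
        zip(planted["chrom"], planted["start"], planted["context"])
    )
    called_keys = set(zip(dmrs["chrom"], dmrs["start"], dmrs["context"]))
    n_hit = len(planted_keys & called_keys)
    recall = n_hit / len(planted_keys) if planted_keys else float("nan")
    precision = (
        len({k for k in called_keys if k in planted_keys}) / len(called_keys)
        if called_keys
        else float("nan")
    )
    return {
        "recall": recall,
        "precision": precision,
        "n_planted": len(planted_keys),
        "n_called": len(called_keys),
    }


def null_dmr_calibration(
    seed: int = 0,
    n_runs: int = 20,
    genome_length: int = 50_000,
    depth: float = 30.0,
) -> dict:
    """False-positive calibration under the null (identical methylomes).

    Two samples are drawn from the same egg methylome (≈1000 windows at the
    default 50-kb genome) at the given per-site depth, ``n_runs`` times.
    Reports the mean fraction of tested CG windows with raw p < 0.05 and the
    mean post-FDR DMR count.
    """
    config = SimConfig(
        genome_length=genome_length,
        n_chromosomes=1,
        snp_rate=0.0,
        n_planted_dmrs={},
        depth=depth,
        seed=seed,
    )
    genomes = simulate_parental_genomes(config)
    truth = simulate_methylomes(genomes, config)

    raw_fracs, dmr_counts, window_counts = [], [], []
    for run in range(n_runs):
        s1 = sample_cytosine_counts(truth, "egg", depth, seed=2 * run)
        s2 = sample_cytosine_counts(truth, "egg", depth, seed=2 * run + 1)
        paired = dmrscan.filter_windows(
            dmrscan.pair_windows(
                dmrscan.bin_windows(s1), dmrscan.bin_windows(s2)
            )
        )
        grp = dmrscan.window_methylation(
            paired[paired["context"] == "CG"].reset_index(drop=True)
        )
        p = dmrscan.fisher_exact_batch(
            grp["n_meth_1"], grp["n_unmeth_1"], grp["n_meth_2"], grp["n_unmeth_2"]
        )
        fdr = dmrscan.bh_adjust(p)
        raw_fracs.append((p < 0.05).mean() if p.size else 0.0)
        dmr_counts.append(
            int(((np.abs(grp["delta"]) > 0.5) & (fdr < 0.05)).sum())
        )
        window_counts.append(len(grp))
    return {
        "mean_raw_p_fraction": float(np.mean(raw_fracs)),
        "mean_dmr_count": float(np.mean(dmr_counts)),
        "mean_windows_tested": float(np.mean(window_counts)),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# remodeling-coefficient recovery and stage contrast
# ---------------------------------------------------------------------------

def _rho_config(seed: int, genome_length: int, n_dmrs: int, rho: float) -> SimConfig:
    # hybrid strand depth 33 per replicate: pooled over 2 replicates and
    # halved by allele splitting (~92% of reads carry a usable SNP at
    # snp_rate 0.02) this lands near 30 allele-specific reads per cytosine
    return SimConfig(
        genome_length=genome_length,
        n_chromosomes=2,
        snp_rate=0.02,
        n_planted_dmrs={"CG": n_dmrs},
        planted_effect={"CG": 0.8},
        rho={"CG": rho, "CHG": rho, "CHH": rho},
        depth=30.0,
        hybrid_depth=33.0,
        seed=seed,
    )


def _allelic_summary(truth, config, dmrs, cell_type, with_sample_level=False):
    readsets = generate_bisulfite_reads(truth, config, cell_types=[cell_type])
    reps = [readsets[(cell_type, r)] for r in range(config.n_replicates)]
    mat_prof, pat_prof, _ = pooled_allelic_profiles(
        reps, truth.genomes.snps, truth.masked_reference, sites=truth.sites
    )
    sample_sites = None
    if with_sample_level:
        sample_sites = filter_coverage(
            pool_replicates(
                [
                    extract_cytosine_counts(r, truth.masked_reference, sites=truth.sites)
                    for r in reps
                ],
                mode="sum",
            ),
            min_depth=3,
        )
    return remodeling.allelic_levels_at_dmrs(
        dmrs, mat_prof, pat_prof, sample_sites=sample_sites
    )


def rho_recovery(
    seed: int = 0,
    rho_values=(0.0, 0.25, 0.5, 0.75, 1.0),
    genome_length: int = 250_000,
    n_dmrs: int = 500,
) -> dict:
    """Recover the paternal remodeling coefficient from zygote allelic data.

    For each true rho, a cross with 500 planted CG E–S DMRs (effect 0.8) is
    simulated, DMRs are re-detected from the gametes, zygote reads are
    allele-split (~30 allele-specific reads per cytosine) and rho is
    estimated.  Returns ``{rho_true: {"rho_hat", "n_dmrs", ...}}``.
    """
    base = _rho_config(seed, genome_length, n_dmrs, 1.0)
    genomes = simulate_parental_genomes(base)
    truth0 = simulate_methylomes(genomes, base)
    egg = _pooled_sample_sites(truth0, base, "egg")
    sperm = _pooled_sample_sites(truth0, base, "sperm")
    dmrs = remodeling.select_es_dmrs(egg, sperm, contexts=["CG"])

    out = {}
    for rho in rho_values:
        config = _rho_config(seed, genome_length, n_dmrs, rho)
        truth = simulate_methylomes(genomes, config)
        summary = _allelic_summary(truth, config, dmrs, "zygote")
        est = remodeling.estimate_rho(summary, "CG", seed=seed)
        out[rho] = {
            "rho_hat": est.rho,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "n_dmrs": est.n_dmrs,
        }
    return out


def stage_contrast(
    seed: int = 0,
    genome_length: int = 150_000,
    n_cg_dmrs: int = 150,
    n_chh_dmrs: int = 120,
) -> dict:
    """Zygote-vs-globular-embryo contrast at full remodeling (rho = 1).

    The zygote's paternal allele matches the egg (rho_hat ≈ 1) while the
    globular embryo reverts to gamete-of-origin levels (rho_hat ≈ 0); the
    zygote's total CHH level at E–S CHH DMRs parallels the lower parent
    (deviation ≈ 0).
    """
    config = SimConfig(
        genome_length=genome_length,
        n_chromosomes=2,
        snp_rate=0.02,
        n_planted_dmrs={"CG": n_cg_dmrs, "CHH": n_chh_dmrs},
        planted_effect={"CG": 0.8, "CHH": 0.4},
        rho={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
        chh_rule="lower_parent",
        depth=30.0,
        hybrid_depth=33.0,
        seed=seed,
    )
    genomes = simulate_parental_genomes(config)
    truth = simulate_methylomes(genomes, config)
    egg = _pooled_sample_sites(truth, config, "egg")
    sperm = _pooled_sample_sites(truth, config, "sperm")
    dmrs = remodeling.select_es_dmrs(egg, sperm, contexts=["CG", "CHH"])

    summaries = {
        stage: _allelic_summary(truth, config, dmrs, stage, with_sample_level=True)
        for stage in ("zygote", "globular_embryo")
    }
    contrast = remodeling.compare_stages(summaries, contexts=("CG",), seed=seed)

    def _value(stage, stat):
        row = contrast[
            (contrast["stage"] == stage) & (contrast["statistic"] == stat)
        ]
        return float(row["value"].iloc[0]) if len(row) else float("nan")

    return {
        "rho_zygote": _value("zygote", "rho"),
        "rho_globular_embryo": _value("globular_embryo", "rho"),
        "chh_lower_parent_dev_zygote": _value("zygote", "lower_parent_dev"),
        "n_cg_dmrs": int((dmrs["context"] == "CG").sum()),
        "n_chh_dmrs": int((dmrs["context"] == "CHH").sum()),
    }


# ---------------------------------------------------------------------------
# allele assignment purity
# ---------------------------------------------------------------------------

def assignment_purity(
    seed: int = 0, genome_length: int = 100_000, depth: float = 10.0
) -> dict:
    """Allele-splitting of an error-free hybrid with no bisulfite-ambiguous
    SNPs: every assigned read should match its hidden allele of origin."""
    config = SimConfig(
        genome_length=genome_length,
        n_chromosomes=2,
        snp_rate=0.02,
        ambiguous_snp_fraction=0.0,
        n_planted_dmrs={},
        depth=depth,
        n_replicates=1,
        seed=seed,
    )
    genomes = simulate_parental_genomes(config)
    truth = simulate_methylomes(genomes, config)
    readsets = generate_bisulfite_reads(truth, config, cell_types=["zygote"])
    reads = readsets[("zygote", 0)]
    res = assign_alleles(reads, genomes.snps, mode="bisulfite")
    assigned = np.isin(res.labels, (MATERNAL, PATERNAL))
    correct = res.labels[assigned] == reads.true_allele[assigned]
    return {
        "purity": float(correct.mean()) if assigned.any() else float("nan"),
        "assigned_fraction": res.assigned_fraction,
        "n_reads": reads.n_reads,
        "n_conflicting": res.counts["conflicting"],
    }


# ---------------------------------------------------------------------------
# imprinting
# ---------------------------------------------------------------------------

def imprinting_benchmark(
    seed: int = 0, maternal_fraction: float = 0.9, n_genes: int = 2000
) -> dict:
    """Recovery of planted PEGs/MEGs from reciprocal-cross allelic counts.

    The global maternal read fraction is 0.9 by default (a maternally
    dominated transcriptome), so PEG recovery demonstrates that imprinting is
    distinguished from background maternal bias.  Also checks that no
    genotype-biased (sequence-specific) gene is called imprinted.
    """
    config = SimConfig(
        n_expressed_genes=n_genes,
        maternal_fraction=maternal_fraction,
        seed=seed,
    )
    expr = generate_allelic_expression_counts(config)
    calls = classify_imprinting(expr.crosses["AxB"], expr.crosses["BxA"])
    by_gene = calls.set_index("gene")["label"]
    peg_recall = float((by_gene.loc[expr.pegs] == "PEG").mean())
    meg_recall = float((by_gene.loc[expr.megs] == "MEG").mean())
    confusions = int(
        by_gene.loc[expr.seq_specific].isin(["PEG", "MEG"]).sum()
    )
    return {
        "peg_recall": peg_recall,
        "meg_recall": meg_recall,
        "n_pegs": len(expr.pegs),
        "n_megs": len(expr.megs),
        "seq_specific_confusions": confusions,
    }


def imprinting_null(
    seed: int = 0, n_runs: int = 20, n_genes: int = 2000
) -> dict:
    """False imprinting-call rate with no imprinted genes planted
    (balanced allelic expression): mean fraction of testable genes labelled
    PEG or MEG across ``n_runs`` simulated reciprocal experiments."""
    rates = []
    for run in range(n_runs):
        config = SimConfig(
            n_expressed_genes=n_genes,
            n_pegs=0,
            n_megs=0,
            n_seq_specific=0,
            maternal_fraction=0.5,
            seed=seed,
        )
        expr = generate_allelic_expression_counts(config, seed=seed * 1009 + run)
        calls = classify_imprinting(expr.crosses["AxB"], expr.crosses["BxA"])
        testable = (calls["label"] != "untestable").sum()
        false_calls = calls["label"].isin(["PEG", "MEG"]).sum()
        rates.append(false_calls / testable if testable else 0.0)
    return {
        "mean_false_call_rate": float(np.mean(rates)),
        "n_runs": n_runs,
        "n_genes": n_genes,
    }
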