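"""The synthetic cross must reproduce its own declared structure exactly."""

import numpy as np
import pytest

import zygometh as z
from zygometh.config import CELL_GENOTYPE


def test_identical_config_gives_identical_outputs(toy_config):
    a = z.simulate_parental_genomes(toy_config)
    b = z.simulate_parental_genomes(toy_config)
    assert a.maternal == b.maternal
    assert a.paternal == b.paternal
    assert a.snps.df.equals(b.snps.df)
    assert a.annotation.equals(b.annotation)
    ta = z.simulate_methylomes(a, toy_config)
    tb = z.simulate_methylomes(b, toy_config)
    for key in ta.levels:
        np.testing.assert_array_equal(ta.levels[key], tb.levels[key])
    ra = z.generate_bisulfite_reads(ta, toy_config, cell_types=["zygote"], replicates=[0])
    rb = z.generate_bisulfite_reads(tb, toy_config, cell_types=["zygote"], replicates=[0])
    x, y = ra[("zygote", 0)], rb[("zygote", 0)]
    np.testing.assert_array_equal(x.start, y.start)
    np.testing.assert_array_equal(x.call_meth, y.call_meth)
    np.testing.assert_array_equal(x.snp_base, y.snp_base)


def test_zero_snp_rate_gives_identical_haplotypes(toy_config):
    cfg = toy_config.with_(snp_rate=0.0)
    g = z.simulate_parental_genomes(cfg)
    assert g.maternal == g.paternal
    assert len(g.snps) == 0


def test_paternal_differs_from_maternal_only_at_snps(toy_cross):
    g = toy_cross["genomes"]
    for chrom in g.maternal:
        mat = np.frombuffer(g.maternal[chrom].encode(), np.uint8)
        pat = np.frombuffer(g.paternal[chrom].encode(), np.uint8)
        diff = np.nonzero(mat != pat)[0] + 1
        pos, m, p, _ = g.snps.chrom_arrays(chrom)
        np.testing.assert_array_equal(diff, pos)
        # recorded alleles agree with the sequences
        assert all(g.maternal[chrom][q - 1] == b for q, b in zip(pos, m))
        assert all(g.paternal[chrom][q - 1] == b for q, b in zip(pos, p))


def test_empty_annotation_when_fractions_zero(toy_config):
    cfg = toy_config.with_(te_fraction=0.0, gene_fraction=0.0, n_planted_dmrs={})
    g = z.simulate_parental_genomes(cfg)
    assert g.annotation.empty
    truth = z.simulate_methylomes(g, cfg)
    assert set(truth.compartment) == {"intergenic"}


def test_sizing_error_when_genome_too_small():
    cfg = z.SimConfig(
        genome_length=3000, n_chromosomes=1, n_planted_dmrs={"CG": 500}, seed=0
    )
    g = z.simulate_parental_genomes(cfg)
    with pytest.raises(z.SimulationSizeError):
        z.simulate_methylomes(g, cfg)


@pytest.mark.parametrize("rho,expect", [(1.0, "egg"), (0.0, "sperm")])
def test_remodeling_limits(toy_config, rho, expect):
    """rho=1 copies the egg level onto the zygote paternal allele; rho=0
    leaves it at the sperm level (CG and CHG)."""
    cfg = toy_config.with_(rho={"CG": rho, "CHG": rho, "CHH": rho})
    g = z.simulate_parental_genomes(cfg)
    t = z.simulate_methylomes(g, cfg)
    ctx = t.sites["context"].to_numpy()
    for c in ("CG", "CHG"):
        m = ctx == c
        np.testing.assert_allclose(
            t.level("zygote", "paternal")[m], t.level(expect, expect_allele(expect))[m]
        )


def expect_allele(cell):
    return CELL_GENOTYPE[cell] if cell in ("egg", "sperm") else "paternal"


def test_remodeling_midpoint(toy_config):
    cfg = toy_config.with_(rho={"CG": 0.5, "CHG": 0.5, "CHH": 0.5})
    g = z.simulate_parental_genomes(cfg)
    t = z.simulate_methylomes(g, cfg)
    m = t.sites["context"].to_numpy() == "CG"
    egg = t.level("egg", "maternal")[m]
    sperm = t.level("sperm", "paternal")[m]
    np.testing.assert_allclose(t.level("zygote", "paternal")[m], 0.5 * (egg + sperm))
    # at a planted hyper DMR with levels 0.9/0.1 the midpoint is 0.5
    row = t.planted_dmrs[t.planted_dmrs["context"] == "CG"].iloc[0]
    in_dmr = (
        m
        & (t.sites["chrom"].to_numpy() == row["chrom"])
        & (t.sites["pos"].to_numpy() > row["start"])
        & (t.sites["pos"].to_numpy() <= row["end"])
    )
    np.testing.assert_allclose(t.level("zygote", "paternal")[in_dmr], 0.5)


def test_chh_lower_parent_rule(toy_cross):
    t = toy_cross["truth"]
    m = t.sites["context"].to_numpy() == "CHH"
    lower = np.minimum(t.level("egg", "maternal"), t.level("sperm", "paternal"))
    np.testing.assert_allclose(t.level("zygote", "paternal")[m], lower[m])
    np.testing.assert_allclose(t.level("zygote", "maternal")[m], lower[m])


def test_globular_embryo_reverts_to_gamete_levels(toy_cross):
    t = toy_cross["truth"]
    for ctx in ("CG", "CHG"):
        m = t.sites["context"].to_numpy() == ctx
        np.testing.assert_allclose(
            t.level("globular_embryo", "paternal")[m], t.level("sperm", "paternal")[m]
        )
        np.testing.assert_allclose(
            t.level("globular_embryo", "maternal")[m], t.level("egg", "maternal")[m]
        )


def test_planted_dmrs_satisfy_their_contract(toy_cross):
    """Each planted window holds >= 5 context cytosines whose egg/sperm gap
    reaches the configured effect size."""
    t = toy_cross["truth"]
    cfg = toy_cross["config"]
    chrom = t.sites["chrom"].to_numpy()
    pos = t.sites["pos"].to_numpy()
    ctx = t.sites["context"].to_numpy()
    egg = t.level("egg", "maternal")
    sperm = t.level("sperm", "paternal")
    for _, row in t.planted_dmrs.iterrows():
        m = (
            (chrom == row["chrom"])
            & (pos > row["start"])
            & (pos <= row["end"])
            & (ctx == row["context"])
        )
        assert m.sum() >= 5
        gap = egg[m] - sperm[m]
        effect = cfg.planted_effect[row["context"]]
        if row["direction"] == "hyper":
            assert np.all(gap >= effect - 1e-12)
        else:
            assert np.all(-gap >= effect - 1e-12)
    # counts match the request
    counts = t.planted_dmrs["context"].value_counts().to_dict()
    assert counts == {k: v for k, v in cfg.n_planted_dmrs.items() if v}


def test_read_call_states_converge_to_truth():
    """Empirical methylation of read calls approaches the true level; with a
    fully unmethylated genome only conversion failures look methylated."""
    cfg = z.SimConfig(
        genome_length=1000,
        n_chromosomes=1,
        snp_rate=0.0,
        te_fraction=0.0,
        gene_fraction=0.0,
        meth_baseline={c: {"gene": 0, "TE": 0, "intergenic": 0} for c in z.CONTEXTS},
        level_concentration=1e9,
        n_planted_dmrs={},
        conversion_failure=0.01,
        depth=60.0,
        n_replicates=1,
        seed=5,
    )
    g = z.simulate_parental_genomes(cfg)
    t = z.simulate_methylomes(g, cfg)
    # tighten the truth to exactly zero for the closed-form check
    for key in t.levels:
        t.levels[key][:] = 0.0
    reads = z.generate_bisulfite_reads(t, cfg, cell_types=["egg"], replicates=[0])
    calls = reads[("egg", 0)].call_meth
    n = calls.size
    assert n > 8000
    se = np.sqrt(0.01 * 0.99 / n)
    assert abs(calls.mean() - 0.01) < 3 * se


def test_truth_consistency_at_high_depth():
    """Per-site empirical levels converge to the truth (3·SE at depth ~5000)."""
    cfg = z.SimConfig(
        genome_length=600,
        n_chromosomes=1,
        snp_rate=0.0,
        n_planted_dmrs={},
        conversion_failure=0.0,
        depth=5000.0,
        n_replicates=1,
        seed=7,
    )
    g = z.simulate_parental_genomes(cfg)
    t = z.simulate_methylomes(g, cfg)
    reads = z.generate_bisulfite_reads(t, cfg, cell_types=["egg"], replicates=[0])
    sites = z.extract_cytosine_counts(reads[("egg", 0)], t.masked_reference, sites=t.sites)
    depth = (sites["n_meth"] + sites["n_unmeth"]).to_numpy()
    level = sites["n_meth"].to_numpy() / depth
    row_in_truth = sites.merge(
        t.sites.reset_index(), on=["chrom", "pos", "strand"], how="left"
    )["index"].to_numpy()
    truth_level = t.level("egg", "maternal")[row_in_truth]
    se = np.sqrt(np.maximum(truth_level * (1 - truth_level), 1e-6) / depth)
    within3 = np.abs(level - truth_level) <= 3 * se
    assert within3.mean() > 0.985  # ~99.7% expected under the binomial
    assert np.all(np.abs(level - truth_level) <= 6 * se)


def test_depth_zero_yields_empty_readsets(toy_cross):
    t = toy_cross["truth"]
    cfg = toy_cross["config"]
    reads = z.generate_bisulfite_reads(
        t, cfg, cell_types=["egg"], replicates=[0], depth=0.0
    )
    assert reads[("egg", 0)].n_reads == 0


def test_snp_base_on_read_matches_allele_of_origin(toy_cross):
    g = toy_cross["genomes"]
    reads = toy_cross["reads"][("zygote", 0)]
    for i in np.random.default_rng(0).integers(0, reads.n_reads, 50):
        sel = reads.snp_read == i
        allele = reads.true_allele[i]
        chrom = reads.chrom_names[reads.chrom[i]]
        hap = g.maternal if allele == 0 else g.paternal
        for pos, base in zip(reads.snp_pos[sel], reads.snp_base[sel]):
            assert hap[chrom][pos - 1] == base


def test_expression_counts_structure(toy_config):
    expr = z.generate_allelic_expression_counts(toy_config)
    expr2 = z.generate_allelic_expression_counts(toy_config)
    for cross in ("AxB", "BxA"):
        assert expr.crosses[cross].equals(expr2.crosses[cross])  # determinism
    tab = expr.crosses["AxB"].set_index("gene")
    total = tab["mat_count"] + tab["pat_count"]
    pegs = tab.loc[expr.pegs]
    frac_pat = pegs["pat_count"].sum() / (pegs["pat_count"] + pegs["mat_count"]).sum()
    assert frac_pat >= 0.95  # PEGs draw >=95% paternal reads
    background = tab.drop(expr.pegs + expr.megs + expr.seq_specific)
    bg_frac = background["mat_count"].sum() / (
        background["mat_count"] + background["pat_count"]
    ).sum()
    assert abs(bg_frac - 0.5) < 0.02  # balanced mixing proportion
    # sequence-specific genes flip bias with the parental role
    seq1 = expr.crosses["AxB"].set_index("gene").loc[expr.seq_specific]
    seq2 = expr.crosses["BxA"].set_index("gene").loc[expr.seq_specific]
    assert seq1["mat_count"].sum() > 5 * seq1["pat_count"].sum()
    assert seq2["pat_count"].sum() > 5 * seq2["mat_count"].sum()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        z.SimConfig(snp_rate=1.5)
    with pytest.raises(ValueError):
        z.SimConfig(te_fraction=0.7, gene_fraction=0.5)
    with pytest.raises(ValueError):
        z.SimConfig(rho={"CG": 1.2})
    with pytest.raises(ValueError):
        z.SimConfig(chh_rule="mean")
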