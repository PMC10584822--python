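"""Synthetic reciprocal-cross generator.

Emulates the statistical structure of an allele-specific bisulfite study of
plant gametes and early embryos: two parental haplotypes differing at SNPs,
gene/TE/intergenic annotation, per-cytosine methylomes for egg, sperm, zygote
and globular embryo with planted egg-vs-sperm DMRs, a parametric remodeling
rule for the paternal allele in the zygote (CG/CHG level moves a fraction
``rho`` of the way from the sperm level toward the egg level; CHH follows the
lower parent by default), bisulfite reads with incomplete-conversion noise,
and allelic expression counts with imprinted genes.  All randomness is driven
by ``SimConfig.seed``; identical configurations yield identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allelesplit import SnpTable, build_nmasked_reference
from .config import CELL_GENOTYPE, CELL_TYPES, CONTEXTS, SimConfig
from .reads import ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AMBIG_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}  # C/T and G/A pairs


class SimulationSizeError(ValueError):
    """The genome cannot host the requested planted DMRs or annotation."""


@dataclass
class ParentalGenomes:
    """Two haplotypes on shared coordinates plus SNPs and annotation."""

    maternal: dict  # chrom -> sequence (the backbone reference)
    paternal: dict
    snps: SnpTable
    annotation: pd.DataFrame  # chrom, start, end (0-based half-open), feature

    def feature_intervals(self, feature: str) -> pd.DataFrame:
        return self.annotation[self.annotation["feature"] == feature].reset_index(
            drop=True
        )


@dataclass
class TruthSet:
    """Ground truth of one simulated cross (the acceptance oracle).

    ``levels[(cell_type, allele)]`` is a float array aligned with ``sites``
    (the cytosines of the N-masked backbone).  ``planted_dmrs`` records the
    intervals, direction and true gamete levels of every planted egg-vs-sperm
    DMR.  Read-level allele truth lives in each ReadSet's ``true_allele``.
    """

    config: SimConfig
    genomes: ParentalGenomes
    masked_reference: dict
    sites: pd.DataFrame  # chrom, pos, strand, context, tri
    compartment: np.ndarray  # per site: gene / TE / intergenic
    levels: dict  # (cell_type, allele) -> np.ndarray
    planted_dmrs: pd.DataFrame  # chrom, start, end, context, direction, egg_level, sperm_level
    pegs: list = field(default_factory=list)
    megs: list = field(default_factory=list)
    seq_specific: list = field(default_factory=list)

    def level(self, cell_type: str, allele: str) -> np.ndarray:
        return self.levels[(cell_type, allele)]


# ---------------------------------------------------------------------------
# genomes, SNPs, annotation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _place_intervals(
    rng: np.random.Generator, length: int, target_bases: int, mean_len: int
) -> list:
    """Non-overlapping random intervals totalling ~``target_bases``."""
    placed = []  # sorted (start, end)
    total = 0
    tries = 0
    import bisect

    while total < target_bases and tries < 20000:
        tries += 1
        size = max(50, int(rng.gamma(4.0, mean_len / 4.0)))
        if size >= length:
            size = max(50, length // 2)
        start = int(rng.integers(0, length - size))
        end = start + size
        i = bisect.bisect_left(placed, (start, end))
        if i > 0 and placed[i - 1][1] > start:
            continue
        if i < len(placed) and placed[i][0] < end:
            continue
        placed.insert(i, (start, end))
        total += size
    return placed


def simulate_parental_genomes(config: SimConfig) -> ParentalGenomes:
    """Draw the maternal backbone, the SNP-divergent paternal haplotype,
    the biallelic SNP table and gene/TE annotation."""
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    n_chrom = config.n_chromosomes
    chrom_len = [config.genome_length // n_chrom] * n_chrom
    chrom_len[-1] += config.genome_length - sum(chrom_len)

    maternal, paternal = {}, {}
    snp_rows = []
    ann_rows = []
    for k, L in enumerate(chrom_len):
        chrom = f"chr{k + 1}"
        codes = _random_sequence(rng, L)
        seq = _BASES[codes].tobytes().decode("ascii")
        maternal[chrom] = seq

        # SNPs
        pos0 = np.nonzero(rng.random(L) < config.snp_rate)[0]
        ref = np.array(list(seq), "U1")[pos0] if pos0.size else np.empty(0, "U1")
        alt = np.empty(pos0.size, "U1")
        if pos0.size:
            if config.ambiguous_snp_fraction is None:
                others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
                pick = rng.integers(0, 3, pos0.size)
                alt = np.array(
                    [others[b][i] for b, i in zip(ref, pick)], "U1"
                )
            else:
                make_amb = rng.random(pos0.size) < config.ambiguous_snp_fraction
                safe = {
                    b: [c for c in "ACGT" if c != b and c != _AMBIG_PARTNER[b]]
                    for b in "ACGT"
                }
                pick = rng.integers(0, 2, pos0.size)
                alt = np.array(
                    [
                        _AMBIG_PARTNER[b] if a else safe[b][i]
                        for b, a, i in zip(ref, make_amb, pick)
                    ],
                    "U1",
                )
        pat_arr = np.frombuffer(seq.encode("ascii"), np.uint8).copy()
        if pos0.size:
            pat_arr[pos0] = np.char.encode(alt).view(np.uint8)
        paternal[chrom] = pat_arr.tobytes().decode("ascii")
        for p, m, a in zip(pos0 + 1, ref, alt):
            snp_rows.append((chrom, int(p), str(m), str(a)))

        # annotation: genes first, TEs independently (may overlap genes)
        for s, e in _place_intervals(
            rng, L, int(config.gene_fraction * L), config.gene_mean_length
        ):
            ann_rows.append((chrom, s, e, "gene"))
        for s, e in _place_intervals(
            rng, L, int(config.te_fraction * L), config.te_mean_length
        ):
            ann_rows.append((chrom, s, e, "TE"))

    snps = SnpTable(
        pd.DataFrame(snp_rows, columns=["chrom", "pos", "maternal", "paternal"])
        if snp_rows
        else SnpTable.empty().df
    )
    annotation = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "feature"]
    ).sort_values(["chrom", "start"], ignore_index=True)
    return ParentalGenomes(
        maternal=maternal, paternal=paternal, snps=snps, annotation=annotation
    )


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _site_compartments(sites: pd.DataFrame, annotation: pd.DataFrame) -> np.ndarray:
    """gene/TE/intergenic per site; TE wins where a TE lies inside a gene
    (TE methylation dominates the local baseline)."""
    comp = np.full(len(sites), "intergenic", dtype="U10")
    for feature in ("gene", "TE"):
        ann = annotation[annotation["feature"] == feature]
        for chrom, grp in ann.groupby("chrom", sort=False):
            sel = sites["chrom"].to_numpy() == chrom
            if not sel.any():
                continue
            pos0 = sites.loc[sel, "pos"].to_numpy() - 1
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            j = np.searchsorted(starts, pos0, side="right") - 1
            inside = (j >= 0) & (pos0 < ends[np.maximum(j, 0)])
            # intervals of one feature may abut; check previous too
            idx = np.nonzero(sel)[0][inside]
            comp[idx] = feature
    return comp


def _window_compartment(chrom, start, end, gene_iv, te_iv):
    """Compartment of a window if it lies wholly inside one, else None."""

    def _state(iv):
        # iv: dict chrom -> (starts, ends) sorted
        arr = iv.get(chrom)
        if arr is None:
            return "none"
        starts, ends = arr
        j = np.searchsorted(starts, start, side="right") - 1
        contained = j >= 0 and end <= ends[j]
        k0 = np.searchsorted(ends, start, side="right")
        k1 = np.searchsorted(starts, end, side="left")
        overlaps = k1 > k0
        if contained:
            return "contains"
        return "overlap" if overlaps else "none"

    g, t = _state(gene_iv), _state(te_iv)
    if t == "contains" and g == "none":
        return "TE"
    if g == "contains" and t == "none":
        return "gene"
    if g == "none" and t == "none":
        return "intergenic"
    return None


def _interval_index(annotation: pd.DataFrame, feature: str) -> dict:
    out = {}
    ann = annotation[annotation["feature"] == feature]
    for chrom, grp in ann.groupby("chrom", sort=False):
        order = grp.sort_values("start")
        out[chrom] = (order["start"].to_numpy(), order["end"].to_numpy())
    return out


def simulate_methylomes(genomes: ParentalGenomes, config: SimConfig) -> TruthSet:
    """True per-cytosine levels for every (cell type, allele), with planted
    egg-vs-sperm DMRs and the zygotic remodeling rule applied."""
    from .methcall import reference_cytosines

    rng = np.random.default_rng([config.seed, 202])
    masked = build_nmasked_reference(genomes.maternal, genomes.snps)
    sites = reference_cytosines(masked)
    comp = _site_compartments(sites, genomes.annotation)

    context = sites["context"].to_numpy()
    base = np.empty(len(sites), dtype=np.float64)
    k = config.level_concentration
    for ctx in CONTEXTS:
        for cname in ("gene", "TE", "intergenic"):
            m = config.meth_baseline[ctx][cname]
            mask = (context == ctx) & (comp == cname)
            if not mask.any():
                continue
            a = max(m * k, 1e-3)
            b = max((1.0 - m) * k, 1e-3)
            base[mask] = rng.beta(a, b, size=int(mask.sum()))
    egg = base.copy()
    sperm = base.copy()

    # ---- plant egg-vs-sperm DMRs on the 50-bp grid -----------------------
    w = config.window
    pos = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    win_start = (pos - 1) // w * w
    gene_iv = _interval_index(genomes.annotation, "gene")
    te_iv = _interval_index(genomes.annotation, "TE")

    planted_rows = []
    used = set()
    for ctx in CONTEXTS:
        n_wanted = int(config.n_planted_dmrs.get(ctx, 0))
        if n_wanted == 0:
            continue
        ctx_mask = context == ctx
        win_counts = (
            pd.DataFrame(
                {"chrom": chrom_arr[ctx_mask], "start": win_start[ctx_mask]}
            )
            .groupby(["chrom", "start"])
            .size()
        )
        eligible = []
        for (chrom, s), c in win_counts.items():
            if c < 5:
                continue
            s = int(s)
            key = (chrom, s)
            if key in used:
                continue
            if _window_compartment(chrom, s, s + w, gene_iv, te_iv) is None:
                continue
            eligible.append(key)
        if len(eligible) < n_wanted:
            raise SimulationSizeError(
                f"only {len(eligible)} eligible {ctx} windows for "
                f"{n_wanted} requested planted DMRs; increase genome_length"
            )
        eligible.sort()
        chosen = rng.choice(len(eligible), size=n_wanted, replace=False)
        effect = float(config.planted_effect[ctx])
        hi = min(1.0, 0.5 + effect / 2.0)
        lo = max(0.0, hi - effect)
        for i, ci in enumerate(chosen):
            chrom, s = eligible[ci]
            used.add((chrom, s))
            hyper = rng.random() < 0.5  # hyper = egg > sperm
            e_lv, s_lv = (hi, lo) if hyper else (lo, hi)
            in_win = (
                ctx_mask
                & (chrom_arr == chrom)
                & (win_start == s)
            )
            egg[in_win] = e_lv
            sperm[in_win] = s_lv
            planted_rows.append(
                (chrom, s, s + w, ctx, "hyper" if hyper else "hypo", e_lv, s_lv)
            )

    planted = pd.DataFrame(
        planted_rows,
        columns=["chrom", "start", "end", "context", "direction", "egg_level", "sperm_level"],
    ).sort_values(["chrom", "start"], ignore_index=True)

    # ---- zygote and globular embryo rules --------------------------------
    is_chh = context == "CHH"
    lower = np.minimum(egg, sperm)

    zyg_mat = egg.copy()
    zyg_pat = np.empty_like(egg)
    for ctx in ("CG", "CHG"):
        m = context == ctx
        r = float(config.rho.get(ctx, 1.0))
        zyg_pat[m] = r * egg[m] + (1.0 - r) * sperm[m]
    if config.chh_rule == "lower_parent":
        zyg_mat[is_chh] = lower[is_chh]
        zyg_pat[is_chh] = lower[is_chh]
    else:  # rho_mix
        r = float(config.rho.get("CHH", 1.0))
        zyg_pat[is_chh] = r * egg[is_chh] + (1.0 - r) * sperm[is_chh]

    # parental allele-specific methylation is reestablished in the globular
    # embryo (CG/CHG back to gamete-of-origin); CHH keeps the lower-parent level
    ge_mat = egg.copy()
    ge_pat = sperm.copy()
    if config.chh_rule == "lower_parent":
        ge_mat[is_chh] = lower[is_chh]
        ge_pat[is_chh] = lower[is_chh]

    levels = {
        ("egg", "maternal"): egg,
        ("egg", "paternal"): egg.copy(),
        ("sperm", "maternal"): sperm.copy(),
        ("sperm", "paternal"): sperm,
        ("zygote", "maternal"): zyg_mat,
        ("zygote", "paternal"): zyg_pat,
        ("globular_embryo", "maternal"): ge_mat,
        ("globular_embryo", "paternal"): ge_pat,
    }
    return TruthSet(
        config=config,
        genomes=genomes,
        masked_reference=masked,
        sites=sites,
        compartment=comp,
        levels=levels,
        planted_dmrs=planted,
    )


# ---------------------------------------------------------------------------
# bisulfite reads
# ---------------------------------------------------------------------------

def _ragged(lo: np.ndarray, hi: np.ndarray):
    """Expand per-read [lo, hi) ranges into (read_index, flat_index) arrays."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    read_idx = np.repeat(np.arange(lo.size), counts)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    flat = np.repeat(lo, counts) + (np.arange(total) - offsets)
    return read_idx, flat


def generate_bisulfite_reads(
    truth: TruthSet,
    config: SimConfig | None = None,
    cell_types: Sequence[str] | None = None,
    replicates: Sequence[int] | None = None,
    depth: float | None = None,
) -> dict:
    """Simulate per-sample, per-replicate read sets.

    Returns ``{(cell_type, replicate): ReadSet}``.  Each read covers the
    cytosines of its own strand within its interval; the unconverted state is
    Bernoulli(true level of the read's allele), and unmethylated cytosines
    additionally read as unconverted with probability ``conversion_failure``.
    The base recorded at a covered SNP is the allele-of-origin base.
    """
    config = config or truth.config
    cell_types = list(cell_types or CELL_TYPES)
    replicates = list(replicates or range(config.n_replicates))

    chrom_names = list(truth.masked_reference)
    chrom_len = np.array([len(truth.masked_reference[c]) for c in chrom_names])

    # per-chromosome, per-strand site positions + global row index
    site_lookup = {}
    sites = truth.sites
    for ci, chrom in enumerate(chrom_names):
        for strand in "+-":
            sel = (sites["chrom"].to_numpy() == chrom) & (
                sites["strand"].to_numpy() == strand
            )
            site_lookup[(ci, strand)] = (
                sites.loc[sel, "pos"].to_numpy(np.int64),
                np.nonzero(sel)[0],
            )
    snp_lookup = {
        ci: truth.genomes.snps.chrom_arrays(chrom)
        for ci, chrom in enumerate(chrom_names)
    }

    out = {}
    for cell in cell_types:
        genotype = CELL_GENOTYPE[cell]
        lv_mat = truth.level(cell, "maternal")
        lv_pat = truth.level(cell, "paternal")
        d = depth if depth is not None else config.depth_for(cell)
        for rep in replicates:
            rng = np.random.default_rng(
                [config.seed, 303, CELL_TYPES.index(cell), rep]
            )
            parts = []
            for ci, L in enumerate(chrom_len):
                # `depth` = strand-specific coverage per cytosine, so total
                # fragment coverage is twice that
                n_reads = int(rng.poisson(2.0 * L * d / config.read_length))
                rl = min(config.read_length, int(L))
                start = rng.integers(0, max(int(L) - rl, 0) + 1, n_reads)
                end = np.minimum(start + rl, int(L))
                is_rev = rng.random(n_reads) < 0.5
                if genotype == "maternal":
                    allele = np.zeros(n_reads, np.int8)
                elif genotype == "paternal":
                    allele = np.ones(n_reads, np.int8)
                else:
                    allele = (rng.random(n_reads) < 0.5).astype(np.int8)

                call_read_l, call_pos_l, call_meth_l = [], [], []
                for strand, rev in (("+", False), ("-", True)):
                    rmask = is_rev == rev
                    ridx = np.nonzero(rmask)[0]
                    pos_arr, grow = site_lookup[(ci, strand)]
                    lo = np.searchsorted(pos_arr, start[ridx] + 1)
                    hi = np.searchsorted(pos_arr, end[ridx], side="right")
                    local_read, flat = _ragged(lo, hi)
                    read_of_call = ridx[local_read]
                    gsite = grow[flat]
                    p = np.where(
                        allele[read_of_call] == 0, lv_mat[gsite], lv_pat[gsite]
                    )
                    meth = rng.random(p.size) < p
                    if config.conversion_failure > 0:
                        fail = rng.random(p.size) < config.conversion_failure
                        meth = meth | (~meth & fail)
                    call_read_l.append(read_of_call)
                    call_pos_l.append(pos_arr[flat])
                    call_meth_l.append(meth)

                spos, smat, spat, _ = snp_lookup[ci]
                lo = np.searchsorted(spos, start + 1)
                hi = np.searchsorted(spos, end, side="right")
                snp_read, sflat = _ragged(lo, hi)
                snp_base = np.where(
                    allele[snp_read] == 0, smat[sflat], spat[sflat]
                )

                parts.append(
                    ReadSet(
                        chrom_names=chrom_names,
                        chrom=np.full(n_reads, ci, np.int32),
                        start=start.astype(np.int64),
                        end=end.astype(np.int64),
                        is_reverse=is_rev,
                        true_allele=allele,
                        call_read=np.concatenate(call_read_l),
                        call_pos=np.concatenate(call_pos_l),
                        call_meth=np.concatenate(call_meth_l),
                        snp_read=snp_read,
                        snp_pos=spos[sflat] if sflat.size else np.empty(0, np.int64),
                        snp_base=snp_base.astype("U1"),
                    )
                )
            out[(cell, rep)] = concat_readsets(parts)
    return out


def concat_readsets(parts: Sequence[ReadSet]) -> ReadSet:
    """Concatenate read sets sharing one chrom_names list."""
    if not parts:
        return ReadSet(
            chrom_names=[],
            chrom=np.empty(0, np.int32),
            start=np.empty(0, np.int64),
            end=np.empty(0, np.int64),
            is_reverse=np.empty(0, bool),
            true_allele=np.empty(0, np.int8),
        )
    if len(parts) == 1:
        return parts[0]
    names = parts[0].chrom_names
    for p in parts[1:]:
        if p.chrom_names != names:
            raise ValueError("read sets use different chromosome name tables")
    offsets = np.cumsum([0] + [p.n_reads for p in parts])
    return ReadSet(
        chrom_names=names,
        chrom=np.concatenate([p.chrom for p in parts]),
        start=np.concatenate([p.start for p in parts]),
        end=np.concatenate([p.end for p in parts]),
        is_reverse=np.concatenate([p.is_reverse for p in parts]),
        true_allele=np.concatenate([p.true_allele for p in parts]),
        call_read=np.concatenate(
            [p.call_read + o for p, o in zip(parts, offsets)]
        ),
        call_pos=np.concatenate([p.call_pos for p in parts]),
        call_meth=np.concatenate([p.call_meth for p in parts]),
        snp_read=np.concatenate([p.snp_read + o for p, o in zip(parts, offsets)]),
        snp_pos=np.concatenate([p.snp_pos for p in parts]),
        snp_base=np.concatenate([p.snp_base for p in parts]),
    )


def sample_cytosine_counts(
    truth: TruthSet,
    cell_type: str,
    depth: float,
    seed: int,
    conversion_failure: float | None = None,
) -> pd.DataFrame:
    """Direct per-cytosine binomial count sampling (no individual reads).

    Coverage is Poisson(``depth``) per site; for hybrid cell types the
    covering reads split binomially between alleles.  Used for calibration
    runs where read-level structure is irrelevant.
    """
    rng = np.random.default_rng([truth.config.seed, 404, seed])
    cf = (
        truth.config.conversion_failure
        if conversion_failure is None
        else conversion_failure
    )
    n = len(truth.sites)
    d = rng.poisson(depth, n)
    lv_mat = truth.level(cell_type, "maternal")
    lv_pat = truth.level(cell_type, "paternal")
    p_mat = lv_mat + (1.0 - lv_mat) * cf
    p_pat = lv_pat + (1.0 - lv_pat) * cf
    if CELL_GENOTYPE[cell_type] == "hybrid":
        d_mat = rng.binomial(d, 0.5)
        n_meth = rng.binomial(d_mat, p_mat) + rng.binomial(d - d_mat, p_pat)
    elif CELL_GENOTYPE[cell_type] == "maternal":
        n_meth = rng.binomial(d, p_mat)
    else:
        n_meth = rng.binomial(d, p_pat)
    out = truth.sites.copy()
    out["n_meth"] = n_meth
    out["n_unmeth"] = d - n_meth
    return out[(out["n_meth"] + out["n_unmeth"]) > 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# allelic expression counts
# ---------------------------------------------------------------------------

@dataclass
class AllelicExpression:
    """Reciprocal-cross allelic count tables plus the planted truth.

    ``crosses`` maps ``"AxB"`` (genome A as mother) and ``"BxA"`` to
    DataFrames with columns ``gene, mat_count, pat_count``.
    """

    crosses: dict
    pegs: list
    megs: list
    seq_specific: list


def generate_allelic_expression_counts(
    config: SimConfig,
    genes: Sequence[str] | int | None = None,
    seed: int | None = None,
    maternal_fraction: float | None = None,
) -> AllelicExpression:
    """Negative-binomially dispersed allelic counts for both reciprocal
    crosses, with planted PEGs (≥95% paternal reads in both crosses), MEGs
    (mirror) and genotype-biased (sequence-specific) genes."""
    if genes is None:
        genes = config.n_expressed_genes
    if isinstance(genes, int):
        genes = [f"g{i:05d}" for i in range(genes)]
    genes = list(genes)
    mf = config.maternal_fraction if maternal_fraction is None else maternal_fraction
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, 505]
    )
    n = len(genes)
    n_special = config.n_pegs + config.n_megs + config.n_seq_specific
    if n_special > n:
        raise ValueError("gene list smaller than the designated imprinted sets")
    special = rng.choice(n, size=n_special, replace=False)
    pegs = [genes[i] for i in special[: config.n_pegs]]
    megs = [genes[i] for i in special[config.n_pegs : config.n_pegs + config.n_megs]]
    seqsp = [genes[i] for i in special[config.n_pegs + config.n_megs :]]

    purity = config.imprint_purity
    # per-gene maternal fraction in each cross; genome A is the mother in AxB
    frac = {"AxB": np.full(n, mf), "BxA": np.full(n, mf)}
    idx = {g: i for i, g in enumerate(genes)}
    for g in pegs:
        frac["AxB"][idx[g]] = 1.0 - purity
        frac["BxA"][idx[g]] = 1.0 - purity
    for g in megs:
        frac["AxB"][idx[g]] = purity
        frac["BxA"][idx[g]] = purity
    for g in seqsp:  # biased toward genome A regardless of parental role
        frac["AxB"][idx[g]] = purity
        frac["BxA"][idx[g]] = 1.0 - purity

    r = config.expr_dispersion
    p_nb = r / (r + config.expr_mean)
    crosses = {}
    for cross in ("AxB", "BxA"):
        total = rng.negative_binomial(r, p_nb, size=n)
        mat = rng.binomial(total, frac[cross])
        crosses[cross] = pd.DataFrame(
            {"gene": genes, "mat_count": mat, "pat_count": total - mat}
        )
    return AllelicExpression(crosses=crosses, pegs=pegs, megs=megs, seq_specific=seqsp)
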