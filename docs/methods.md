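# Methods

This note documents the models, rules and numerical choices behind
`zygometh`, what the synthetic-data generator does and does not emulate,
and the problem sizes the validation studies use.

## Cytosine sites and contexts

The unit of all methylation arithmetic is one reference cytosine on one
strand. Context is a pure function of the reference trinucleotide read
5'→3' on the site's own strand: CG if the next base is G; CHG if the
pattern is C-H-G; CHH if C-H-H (H ∈ {A, C, T}); undefined (and excluded)
when the trinucleotide runs off the sequence end or contains an N — which
is how cytosines adjacent to N-masked SNPs drop out. CG sites are reported
per strand, not merged into symmetric pairs. The methylation level of a
site is n_meth / (n_meth + n_unmeth), where n_meth counts unconverted
(methylated-looking) read observations. Sites require ≥3 reads by default
(`filter_coverage(min_depth=3)`), and ≥3 *allele-specific* reads on the
allelic side; both are flags.

Replicates can be pooled two ways: summed counts (the construction used for
testing, since Fisher's test needs counts) or the mean of per-replicate
levels (the figure-style summary). Both are exposed.

## Allele splitting

SNP positions are replaced by N in the backbone reference
(`build_nmasked_reference`), removing alignment and context bias between
alleles; allele assignment then reads the bases a fragment shows at the
SNPs it covers. Bisulfite chemistry makes a C/T variant uninformative on
plus-strand reads (an unmethylated C reads as T) and a G/A variant
uninformative on minus-strand reads; such SNPs are skipped for the affected
strand only — the complementary strand still uses them. A read is assigned
to a parent only if *every* usable covered SNP matches that parent; a read
matching both parents at different SNPs, or showing a base matching
neither, is `conflicting` and discarded rather than majority-voted
(configurable in principle, but the conservative rule is the default and
the one validated). RNA mode uses all SNPs. Reads are single fragments;
paired-end bookkeeping is out of scope.

## DMR scanning

Windows tile the fixed grid 0, 50, 100, … per chromosome (no sliding, no
merging by default; a merge utility exists). A window enters testing only
if it holds ≥5 cytosines of the context, each at ≥3× coverage, in **both**
samples. The test is Fisher's exact test on the 2×2 table of pooled
(meth, unmeth) counts — pooled over replicates and over the window's
cytosines, the only construction that yields a 2×2 table. Two-sided p is
the sum of hypergeometric probabilities of tables (at fixed margins) no
more probable than the observed one; the scalar implementation enumerates
with exact integer arithmetic, and the vectorized batch path (scipy
hypergeometric pmf, ties included at 1e-10 relative tolerance) is
unit-tested against it at 1e-9. A degenerate all-zero margin yields p = 1.
BH adjustment (via statsmodels) runs across all tested windows of a
context; DMRs require |Δm| above the context cutoff (CG 0.5, CHG 0.3,
CHH 0.1) and FDR < 0.05. A raw-p mode exists behind a flag. Direction is
`hyper` when sample 1 (egg, in the egg-vs-sperm comparison) exceeds
sample 2.

For the density-difference statistic, a window's "informative sequenced
cytosines" is the summed sequencing depth over its context cytosines
(≥20 required in both samples); an alternative reading that multiplies by
the site count is exposed as `informative="depth_times_sites"`. The level
must reach the context ratio threshold (0.5/0.3/0.1) in at least one
sample.

Feature annotation classifies each DMR by ≥1-bp overlap with precedence
TE_gene (overlaps both a TE and a gene) > TE > gene_body > intergenic.
DMR-set overlaps are counted within context; the reported Jaccard is
base-level (intersection over union of covered bases).

## The remodeling coefficient

At egg-vs-sperm DMRs, the zygote's paternal allelic level is modeled as a
convex combination of the two gamete levels,

    m_pat = m_sperm + ρ·(m_egg − m_sperm),  ρ ∈ [0, 1],

and ρ is estimated per context by weighted least squares through the
origin in the variables x = m_egg − m_sperm, y = m_pat − m_sperm:

    ρ̂ = Σ w_i x_i y_i / Σ w_i x_i²,

with w_i the paternal allelic depth of DMR i, clipped to [0, 1], and a
1000-resample bootstrap percentile CI over DMRs (fixed seed). Only
testable DMRs (≥3 allelic cytosines on each allele) with
|m_egg − m_sperm| ≥ 0.2 enter — the estimator is undefined where the
gametes barely differ — and ≥20 such DMRs are required (an explicit error
otherwise). m_egg and m_sperm are the DMR's own measured gamete levels
(m1/m2 from the scan), not the truth; at the validated depths the
resulting errors-in-variables attenuation is ≈0.5% and the incomplete-
conversion offset (+0.005·(1−m)) smaller still, both inside the ±0.05
recovery target. The CI quantifies DMR-resampling noise, not these small
systematic terms. ρ̂ is symmetric in DMR direction (mirroring all levels
m → 1−m leaves it unchanged; asserted in tests).

Per-DMR classification of the paternal level: `maternal_match` if within
0.1 of the egg level while ≥0.2 from the sperm level, `paternal_match`
mirrored, else `intermediate`; thresholds are parameters — the underlying
observation is boxplot proximity, so the defaults are a reasonable but not
unique reading.

ρ is estimated for CG and CHG by default. CHH behaves differently (the
zygote parallels the *lower* parent regardless of its sex), so CHH is
summarized by the lower-parent deviation
mean(m_zygote,total − min(m_egg, m_sperm)) over CHH DMRs, which is ≈0
under the lower-parent rule.

## Imprinting classification

Per cross, each gene's paternal count is tested against proportion 0.5
with an exact two-sided binomial test (genes with total < 10 in either
cross are untestable), BH-adjusted within the cross. A PEG requires
log2((pat+1)/(mat+1)) > 1 and adjusted p < 0.01 in **both** reciprocal
crosses; MEG mirrored. The pseudocount is display-only — the test uses
raw counts. Bias following the genotype (same genomic parent favored in
both crosses, i.e. opposite parental roles) is `sequence_specific`. The
binomial substitutes for a count-model (negative-binomial regression)
test: with a single count pair per gene and cross there is no dispersion
to estimate, and the classification thresholds are kept verbatim. Under a
strongly maternal transcriptome the 0.5-centered cut-offs will (by
design) call pervasive maternal bias MEG; an optional mode re-centers the
test at an estimated global maternal fraction to look for imprinting over
and above maternal dominance — off by default, since the standard
cut-offs imply 0.5.

## What the generator emulates — and what it does not

`SimConfig` describes a cross between two inbred parents: a random
backbone genome split into gene / TE / intergenic compartments; a second
haplotype differing at Bernoulli-placed biallelic SNPs (alternate alleles
drawn uniformly, or forced C↔T / G↔A at a configurable rate); per-cytosine
methylation levels drawn from Beta distributions around rice-like
compartment means (CG: TE 0.90 / gene 0.55 / intergenic 0.45; CHG: 0.60 /
0.20 / 0.30; CHH: 0.15 / 0.05 / 0.08). Egg and sperm share every
non-planted level, so planted DMRs are the only true differences; each
planted DMR occupies one 50-bp grid window lying wholly inside one
compartment with ≥5 context cytosines, set to 0.5 ± effect/2 (defaults:
CG 0.8, CHG 0.6, CHH 0.4). The zygote applies the ρ rule to the paternal
allele (maternal allele keeps egg levels); under `chh_rule="lower_parent"`
both zygote alleles take min(egg, sperm) at CHH sites. The globular embryo
reverts CG/CHG to gamete-of-origin levels and keeps CHH at the lower
parent. Reads are uniform fragments (default 150 bp, two replicates);
`depth` means strand-specific coverage per cytosine, so fragment coverage
is twice that. Each covered cytosine's state is Bernoulli(true level),
then flipped to unconverted with probability `conversion_failure`
(default 0.005) when unmethylated. The recorded base at a covered SNP is
the allele-of-origin base; base-call errors are off. A count-level sampler
(`sample_cytosine_counts`) draws per-site binomial counts directly and is
used for the many-run null calibrations, where read-level structure is
irrelevant.

Expression counts: gene totals are negative-binomial (mean 100,
dispersion 5); background genes split maternal:paternal at a global
mixing fraction (0.5, or 0.9 for the maternally-dominated setting), PEGs
draw 97% paternal reads in both crosses, MEGs the mirror, and
sequence-specific genes favor one genotype in both crosses. The generator
accepts a gene count directly, since toy genomes carry too few annotated
genes for classification studies.

Deliberately **not** emulated: alignment and mapping bias (the pipeline
starts from aligned, methylation-called fragments), PCR duplicates,
base-call errors, indels and structural variants between haplotypes,
methylation spatial autocorrelation beyond the planted windows,
cell-to-cell heterogeneity, partial remodeling heterogeneity across loci
(ρ is a single per-context constant), and biological replicate dispersion
(replicates are resampling noise only — matching the pooled-count Fisher
test, which likewise models no overdispersion). Passing tests therefore
show the machinery is correct and calibrated under its stated model, not
that real libraries are free of these artifacts.

## Validation studies and problem sizes

The studies in `zygometh.benchmarks` back both `tests/test_acceptance.py`
and `scripts/acceptance.py`; sizes were chosen so each runs in minutes on
one CPU:

- DMR recovery: 1-Mb genome, 200 planted CG DMRs (effect 0.8), depth 30,
  two replicates → recall and precision ≥0.9 (measured ≈1.0).
- Null calibration: 50-kb genome (~1000 windows), depth 30, 20 runs of
  two draws from one methylome → raw-p fraction ≤0.075, mean post-FDR DMR
  count ≤1 (measured 0).
- ρ recovery: 250-kb genome, 500 planted CG DMRs, gamete depth 30, hybrid
  strand depth 33 per replicate (×2 replicates, halved by allele
  splitting, ~92% assignable at snp_rate 0.02 → ≈30 allele-specific reads
  per cytosine) at ρ ∈ {0, 0.25, 0.5, 0.75, 1} → |ρ̂ − ρ| ≤ 0.05
  (measured ≤0.002).
- Stage contrast: 150-kb genome, 150 CG + 120 CHH DMRs, ρ = 1 zygote vs
  reverted embryo → ρ̂_zygote ≥ 0.9, ρ̂_GE ≤ 0.1, CHH deviation within
  ±0.05.
- Imprinting: 2000 genes, 20 PEGs / 50 MEGs / 10 sequence-specific at 90%
  maternal background → recall ≥0.9 each, zero sequence-specific
  confusions; 20-run null → false-call rate ≤1% of testable genes.
- Exact machinery: Fisher p vs exhaustive integer enumeration for all 2×2
  tables with row margins ≤30 (≤1e-9); BH vs the definitional step-up
  formula on 10⁴ random vectors; context vs the 3-mer table (64 × 2
  strands); allele assignment vs a brute-force classifier for all base
  combinations over ≤3 SNPs, plus 100% assignment purity on an error-free
  hybrid without bisulfite-ambiguous SNPs.

## Numerical and degenerate-input choices

- Coordinates: cytosine and SNP positions are 1-based (CX/VCF
  convention); intervals (reads, windows, BED, DMRs) are 0-based
  half-open. Window grids start at 0; a trailing sub-50-bp chromosome
  remainder is kept as a short window.
- The coverage filter is ≥3 reads (not >3), matching the allelic filter's
  "at least three"; exposed as a flag.
- Fisher with an all-zero margin returns p = 1; `bh_adjust` of an empty
  vector is empty; `pool_replicates` refuses replicate sets sharing no
  chromosome (mismatched references).
- Bootstrap CIs are percentile CIs over DMR resamples with a fixed seed;
  endpoints are widened if needed so the interval always contains ρ̂.
- `allelic_bias_test(0, 0)` returns NaN sentinels; classification marks
  such genes untestable.
- All generator randomness flows from `SimConfig.seed` through
  per-purpose `numpy` SeedSequence keys, so identical configurations give
  byte-identical genomes, SNP tables, truth levels and reads.

## Known limitations

- ρ is a per-context scalar; locus-level heterogeneity in remodeling
  (e.g. PEGs escaping remodeling) is visible in the per-DMR classes but
  not modeled by the estimator.
- The pooled-count Fisher test understates variance if biological
  replicates are overdispersed; no dispersion model is fitted
  (a deliberate non-goal).
- Under strong global allelic bias the default 0.5-centered imprinting
  cut-offs conflate pervasive bias with imprinting for the favored
  parent; use the re-centered mode to separate them.
- The simulator's independence assumptions (no LD between SNPs, no
  methylation autocorrelation) make the synthetic assignment and DMR
  problems somewhat easier than real data; purity and calibration results
  bound the algorithmic, not the biological, error.
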