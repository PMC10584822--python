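"""Configuration for the synthetic reciprocal-cross study.

A single :class:`SimConfig` describes everything the generator needs: the two
parental haplotypes (one is the reference backbone, the other differs at SNPs),
genome composition (gene / transposable-element / intergenic compartments),
per-context methylation baselines, planted egg-vs-sperm DMRs, the zygotic
remodeling rule for the paternal allele, bisulfite read parameters, and
allelic expression-count parameters for the imprinting analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

CONTEXTS = ("CG", "CHG", "CHH")
COMPARTMENTS = ("gene", "TE", "intergenic")
CELL_TYPES = ("egg", "sperm", "zygote", "globular_embryo")

#: genotype composition of each simulated cell type in the cross
#: (maternal parent is the reference backbone)
CELL_GENOTYPE = {
    "egg": "maternal",
    "sperm": "paternal",
    "zygote": "hybrid",
    "globular_embryo": "hybrid",
}


def _default_baseline() -> dict:
    # Rice-like compartment means: dense CG/CHG methylation on TEs, moderate
    # gene-body CG, low CHH everywhere with a TE excess.
    return {
        "CG": {"gene": 0.55, "TE": 0.90, "intergenic": 0.45},
        "CHG": {"gene": 0.20, "TE": 0.60, "intergenic": 0.30},
        "CHH": {"gene": 0.05, "TE": 0.15, "intergenic": 0.08},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cross.

    ``depth`` is the mean strand-specific coverage per cytosine (the number of
    reads that actually report a given cytosine), not total fragment coverage;
    ``hybrid_depth`` overrides it for hybrid cell types so that the
    post-allele-splitting depth can be controlled directly.
    """

    genome_length: int = 200_000
    n_chromosomes: int = 2
    snp_rate: float = 0.02
    #: fraction of SNPs forced to be bisulfite-ambiguous (C/T or G/A pairs);
    #: ``None`` draws alternate alleles uniformly (≈1/3 ambiguous by chance)
    ambiguous_snp_fraction: float | None = None
    te_fraction: float = 0.25
    gene_fraction: float = 0.35
    gene_mean_length: int = 2000
    te_mean_length: int = 600
    meth_baseline: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_baseline
    )
    #: per-cytosine spread of levels around the compartment mean
    #: (Beta concentration; larger = tighter)
    level_concentration: float = 8.0
    n_planted_dmrs: Mapping[str, int] = field(
        default_factory=lambda: {"CG": 40, "CHG": 30, "CHH": 30}
    )
    planted_effect: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.6, "CHH": 0.4}
    )
    #: remodeling coefficient of the paternal allele in the zygote, per context
    rho: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 1.0, "CHG": 1.0, "CHH": 1.0}
    )
    chh_rule: str = "lower_parent"  # or "rho_mix"
    window: int = 50
    read_length: int = 150
    depth: float = 30.0
    hybrid_depth: float | None = None
    conversion_failure: float = 0.005
    n_replicates: int = 2
    # allelic expression counts
    n_expressed_genes: int = 2000
    n_pegs: int = 20
    n_megs: int = 50
    n_seq_specific: int = 10
    maternal_fraction: float = 0.5
    imprint_purity: float = 0.97
    expr_mean: float = 100.0
    expr_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.genome_length < self.n_chromosomes:
            raise ValueError("genome_length must be >= n_chromosomes")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        for name in ("snp_rate", "conversion_failure", "maternal_fraction",
                     "imprint_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ambiguous_snp_fraction is not None and not (
            0.0 <= self.ambiguous_snp_fraction <= 1.0
        ):
            raise ValueError("ambiguous_snp_fraction must be in [0, 1] or None")
        if self.te_fraction < 0 or self.gene_fraction < 0:
            raise ValueError("compartment fractions must be non-negative")
        if self.te_fraction + self.gene_fraction > 1.0:
            raise ValueError("te_fraction + gene_fraction must be <= 1")
        for ctx, levels in self.meth_baseline.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r} in meth_baseline")
            for comp, m in levels.items():
                if comp not in COMPARTMENTS or not 0.0 <= m <= 1.0:
                    raise ValueError(f"bad baseline {ctx}/{comp}={m}")
        for ctx, r in self.rho.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rho[{ctx}] must be in [0, 1], got {r}")
        for ctx, e in self.planted_effect.items():
            if not 0.0 < e <= 1.0:
                raise ValueError(f"planted_effect[{ctx}] must be in (0, 1]")
        if self.chh_rule not in ("lower_parent", "rho_mix"):
            raise ValueError("chh_rule must be 'lower_parent' or 'rho_mix'")
        if self.depth < 0 or (self.hybrid_depth is not None and self.hybrid_depth < 0):
            raise ValueError("depth must be non-negative")
        if self.read_length < 1 or self.window < 1:
            raise ValueError("read_length and window must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_pegs + self.n_megs + self.n_seq_specific > self.n_expressed_genes:
            raise ValueError("more designated genes than n_expressed_genes")
        if self.expr_mean <= 0 or self.expr_dispersion <= 0:
            raise ValueError("expr_mean and expr_dispersion must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    @property
    def depth_for(self):
        def _depth(cell_type: str) -> float:
            if CELL_GENOTYPE.get(cell_type) == "hybrid" and self.hybrid_depth is not None:
                return self.hybrid_depth
            return self.depth

        return _depth
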