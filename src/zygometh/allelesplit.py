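"""SNP-based partitioning of hybrid reads into parental alleles.

Alignment bias between the parental haplotypes is avoided by N-masking: every
SNP position in the backbone reference is replaced by N before alignment and
methylation calling, and the allele of each read is decided afterwards from
the bases it shows at the SNPs it covers.  Bisulfite chemistry makes C/T
variants uninformative on plus-strand reads (an unmethylated C reads as T)
and, symmetrically, G/A variants uninformative on minus-strand reads; such
SNPs are skipped for the affected strand, mirroring SNPsplit's conservative
rule.  Reads matching both parents at different SNPs, or showing a base that
matches neither parent, are classed as conflicting and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .methcall import extract_cytosine_counts, filter_coverage
from .reads import BisRead, ReadSet

MATERNAL, PATERNAL, UNASSIGNED, CONFLICTING = 0, 1, 2, 3
LABEL_NAMES = {0: "maternal", 1: "paternal", 2: "unassigned", 3: "conflicting"}


def _pair_flag(a: str, b: str) -> str:
    pair = {a, b}
    if pair == {"C", "T"}:
        return "CT"
    if pair == {"G", "A"}:
        return "GA"
    return ""


class SnpTable:
    """Biallelic SNPs between the two parental genomes.

    Wraps a DataFrame with columns ``chrom, pos (1-based), maternal,
    paternal, ambiguous_pair`` where ``ambiguous_pair`` is ``"CT"``, ``"GA"``
    or ``""``: C/T and G/A allele pairs are indistinguishable after bisulfite
    conversion on the affected strand.
    """

    COLUMNS = ["chrom", "pos", "maternal", "paternal", "ambiguous_pair"]

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "ambiguous_pair" not in df.columns:
            df["ambiguous_pair"] = [
                _pair_flag(m, p) for m, p in zip(df["maternal"], df["paternal"])
            ]
        if (df["maternal"] == df["paternal"]).any():
            raise ValueError("SNP rows must be biallelic (maternal != paternal)")
        df = df.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate SNP positions")
        self.df = df[self.COLUMNS]
        self._by_chrom = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            self._by_chrom[chrom] = (
                grp["pos"].to_numpy(np.int64),
                grp["maternal"].to_numpy("U1"),
                grp["paternal"].to_numpy("U1"),
                grp["ambiguous_pair"].to_numpy("U2"),
            )

    def __len__(self) -> int:
        return len(self.df)

    def chrom_arrays(self, chrom: str):
        """(positions, maternal, paternal, ambiguous_pair) for one chromosome."""
        empty = (
            np.empty(0, np.int64),
            np.empty(0, "U1"),
            np.empty(0, "U1"),
            np.empty(0, "U2"),
        )
        return self._by_chrom.get(chrom, empty)

    @classmethod
    def empty(cls) -> "SnpTable":
        return cls(
            pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "pos": pd.Series(dtype=np.int64),
                    "maternal": pd.Series(dtype=str),
                    "paternal": pd.Series(dtype=str),
                }
            )
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SnpTable":
        return cls(
            pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
        )


def build_nmasked_reference(
    reference: Mapping[str, str], snps: SnpTable, check_allele: str = "maternal"
) -> dict:
    """Replace every SNP position of the backbone reference with N.

    The reference is expected to be the ``check_allele`` haplotype; rows whose
    recorded allele disagrees with the reference base raise a ``ValueError``
    listing the offending positions.
    """
    masked = {}
    bad = []
    for chrom, seq in reference.items():
        pos, mat, pat, _ = snps.chrom_arrays(chrom)
        if pos.size == 0:
            masked[chrom] = seq
            continue
        if pos.max() > len(seq):
            raise ValueError(f"SNP position beyond end of {chrom}")
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        expect = mat if check_allele == "maternal" else pat
        ref_base = arr[pos - 1].view("S1").astype("U1")
        mism = ref_base != expect
        if mism.any():
            bad.extend(
                f"{chrom}:{p} ref={r} {check_allele}={e}"
                for p, r, e in zip(pos[mism][:10], ref_base[mism][:10], expect[mism][:10])
            )
        arr[pos - 1] = ord("N")
        masked[chrom] = arr.tobytes().decode("ascii")
    for chrom in snps.df["chrom"].unique():
        if chrom not in reference:
            raise ValueError(f"SNP chromosome {chrom!r} absent from reference")
    if bad:
        raise ValueError(
            "SNP alleles inconsistent with the reference: " + "; ".join(bad)
        )
    return masked


def _usable_mask(amb: np.ndarray, is_reverse, mode: str) -> np.ndarray:
    """Which SNP observations may be used for assignment.

    In bisulfite mode C/T SNPs are skipped on plus-strand reads and G/A SNPs
    on minus-strand reads; RNA mode uses every SNP.
    """
    if mode == "rna":
        return np.ones(amb.shape, bool)
    if mode != "bisulfite":
        raise ValueError(f"mode must be 'bisulfite' or 'rna', got {mode!r}")
    rev = np.broadcast_to(np.asarray(is_reverse, bool), amb.shape)
    return ~(((amb == "CT") & ~rev) | ((amb == "GA") & rev))


def assign_read_allele(read: BisRead, snps: SnpTable, mode: str = "bisulfite") -> str:
    """Classify one read as maternal / paternal / unassigned / conflicting."""
    pos, mat, pat, amb = snps.chrom_arrays(read.chrom)
    lo = np.searchsorted(pos, read.start + 1)
    hi = np.searchsorted(pos, read.end, side="right")
    observed = dict(read.snp_bases)
    n_mat = n_pat = n_other = n_usable = 0
    for i in range(lo, hi):
        if not _usable_mask(amb[i : i + 1], read.strand == "-", mode)[0]:
            continue
        base = observed.get(int(pos[i]))
        if base is None:
            continue
        n_usable += 1
        if base == mat[i]:
            n_mat += 1
        elif base == pat[i]:
            n_pat += 1
        else:
            n_other += 1
    if n_usable == 0:
        return "unassigned"
    if n_other or (n_mat and n_pat):
        return "conflicting"
    return "maternal" if n_mat else "paternal"


@dataclass
class AssignmentResult:
    """Per-read allele labels plus summary counts."""

    labels: np.ndarray  # int8 codes (MATERNAL/PATERNAL/UNASSIGNED/CONFLICTING)
    counts: dict

    @property
    def assigned_fraction(self) -> float:
        total = self.labels.size
        if total == 0:
            return float("nan")
        return (self.counts["maternal"] + self.counts["paternal"]) / total


def assign_alleles(
    reads: ReadSet, snps: SnpTable, mode: str = "bisulfite"
) -> AssignmentResult:
    """Vectorized allele assignment of a whole read set."""
    n = reads.n_reads
    n_usable = np.zeros(n, np.int64)
    n_mat = np.zeros(n, np.int64)
    n_pat = np.zeros(n, np.int64)
    n_other = np.zeros(n, np.int64)

    if reads.snp_pos.size:
        obs_chrom = reads.chrom[reads.snp_read]
        for ci, chrom in enumerate(reads.chrom_names):
            sel = obs_chrom == ci
            if not sel.any():
                continue
            pos, mat, pat, amb = snps.chrom_arrays(chrom)
            opos = reads.snp_pos[sel]
            oread = reads.snp_read[sel]
            obase = reads.snp_base[sel]
            if pos.size == 0:
                continue
            j = np.searchsorted(pos, opos)
            known = (j < pos.size) & (pos[np.minimum(j, pos.size - 1)] == opos)
            j, oread, obase = j[known], oread[known], obase[known]
            usable = _usable_mask(amb[j], reads.is_reverse[oread], mode)
            j, oread, obase = j[usable], oread[usable], obase[usable]
            m = obase == mat[j]
            p = obase == pat[j]
            np.add.at(n_usable, oread, 1)
            np.add.at(n_mat, oread[m], 1)
            np.add.at(n_pat, oread[p], 1)
            np.add.at(n_other, oread[~(m | p)], 1)

    labels = np.full(n, UNASSIGNED, np.int8)
    conflict = (n_other > 0) | ((n_mat > 0) & (n_pat > 0))
    labels[(n_usable > 0) & conflict] = CONFLICTING
    pure_mat = (n_mat == n_usable) & (n_usable > 0) & ~conflict
    pure_pat = (n_pat == n_usable) & (n_usable > 0) & ~conflict
    labels[pure_mat] = MATERNAL
    labels[pure_pat] = PATERNAL
    counts = {name: int((labels == code).sum()) for code, name in LABEL_NAMES.items()}
    return AssignmentResult(labels=labels, counts=counts)


@dataclass
class AlleleMethProfile:
    """Per-cytosine methylation restricted to one parental allele.

    ``sites`` keeps only cytosines covered by at least ``min_allelic_reads``
    allele-assigned reads.
    """

    allele: str
    sites: pd.DataFrame
    min_allelic_reads: int = 3


def allelic_cytosine_counts(
    reads: ReadSet,
    assignment: AssignmentResult,
    reference: Mapping[str, str],
    sites: pd.DataFrame | None = None,
    min_allelic_reads: int = 3,
):
    """Extract maternal- and paternal-allele cytosine counts from a hybrid.

    Unassigned and conflicting reads are excluded; sites covered by fewer
    than ``min_allelic_reads`` allele-specific reads are dropped (default 3).
    Returns ``(maternal_profile, paternal_profile)``.
    """
    profiles = []
    for code, name in ((MATERNAL, "maternal"), (PATERNAL, "paternal")):
        sub = reads.subset(assignment.labels == code)
        counts = extract_cytosine_counts(sub, reference, sites=sites)
        counts = filter_coverage(counts, min_depth=min_allelic_reads)
        profiles.append(
            AlleleMethProfile(allele=name, sites=counts, min_allelic_reads=min_allelic_reads)
        )
    return tuple(profiles)


def pooled_allelic_profiles(
    readsets,
    snps: SnpTable,
    reference: Mapping[str, str],
    sites: pd.DataFrame | None = None,
    mode: str = "bisulfite",
    min_allelic_reads: int = 3,
):
    """Allele-split several replicates of one hybrid sample and pool them.

    Each replicate is assigned independently; allelic counts are summed over
    replicates before the ≥``min_allelic_reads`` filter.  Returns
    ``(maternal_profile, paternal_profile, assignments)``.
    """
    from .methcall import pool_replicates

    per_allele = {MATERNAL: [], PATERNAL: []}
    assignments = []
    for reads in readsets:
        res = assign_alleles(reads, snps, mode=mode)
        assignments.append(res)
        for code in (MATERNAL, PATERNAL):
            sub = reads.subset(res.labels == code)
            per_allele[code].append(
                extract_cytosine_counts(sub, reference, sites=sites)
            )
    profiles = []
    for code, name in ((MATERNAL, "maternal"), (PATERNAL, "paternal")):
        pooled = pool_replicates(per_allele[code], mode="sum")
        pooled = filter_coverage(pooled, min_depth=min_allelic_reads)
        profiles.append(
            AlleleMethProfile(allele=name, sites=pooled, min_allelic_reads=min_allelic_reads)
        )
    return profiles[0], profiles[1], assignments
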