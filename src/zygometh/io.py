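"""Readers and writers for the plain-text formats the pipeline exchanges.

- FASTA for the parental haplotypes and N-masked references;
- Bismark-style CX reports for per-cytosine counts
  (chrom, pos, strand, count-methylated, count-unmethylated, context, tri);
- BED-like TSVs for annotation intervals and DMR tables;
- simple TSVs for SNP tables and allelic count tables.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

CX_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]


def read_fasta(path) -> dict:
    """FASTA file into {name: sequence} (names cut at first whitespace)."""
    seqs: dict = {}
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cx_report(sites: pd.DataFrame, path) -> None:
    """Write a site table as a (headerless) Bismark-compatible CX report."""
    df = sites.copy()
    if "tri" not in df.columns:
        df["tri"] = "."
    df[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_cx_report(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=CX_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str, "tri": str},
    )
    return df[CX_COLUMNS]


def read_bed(path, feature: str | None = None) -> pd.DataFrame:
    """BED (0-based half-open) into chrom/start/end(/feature)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    if feature is not None:
        out["feature"] = feature
    elif df.shape[1] > 3:
        out["feature"] = df.iloc[:, 3]
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "feature"] if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_dmrs(dmrs: pd.DataFrame, path) -> None:
    """DMRs as a BED-like TSV with a header line."""
    cols = [
        c
        for c in [
            "chrom", "start", "end", "context", "m1", "m2", "delta",
            "p", "fdr", "direction", "feature_class",
        ]
        if c in dmrs.columns
    ]
    dmrs[cols].to_csv(path, sep="\t", index=False)


def read_allelic_counts(path) -> pd.DataFrame:
    """Per-gene allelic count table (gene, mat_count, pat_count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "mat_count", "pat_count"}
    if not required <= set(df.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    return df


def write_allelic_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)
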