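"""Simplified aligned bisulfite read records.

The package starts from "aligned, methylation-called" fragments rather than
FASTQ: each record carries its interval, strand, the converted/unconverted
state of every covered cytosine on its own strand, and the observed base at
every covered SNP position.  :class:`ReadSet` is the columnar (NumPy-backed)
batch container the pipeline operates on; :class:`BisRead` is the scalar view
used by record-level APIs.  Read sets round-trip through a tab-delimited text
format (one line per read).

Coordinates: read intervals are 0-based half-open; cytosine and SNP positions
are 1-based (CX-report / VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

ALLELE_NAMES = {0: "maternal", 1: "paternal", -1: None}


@dataclass(frozen=True)
class BisRead:
    """One aligned bisulfite fragment."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    meth_calls: tuple  # ((pos, is_methylated), ...) pos 1-based
    snp_bases: tuple = ()  # ((pos, base), ...) pos 1-based
    true_allele: str | None = None  # hidden simulation truth; never used by the pipeline


@dataclass
class ReadSet:
    """Columnar collection of :class:`BisRead` records."""

    chrom_names: list
    chrom: np.ndarray  # int32 code per read
    start: np.ndarray  # int64, 0-based
    end: np.ndarray
    is_reverse: np.ndarray  # bool
    true_allele: np.ndarray  # int8: 0=maternal, 1=paternal, -1=unknown
    call_read: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    call_pos: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    call_meth: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    snp_read: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    snp_pos: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    snp_base: np.ndarray = field(default_factory=lambda: np.empty(0, "U1"))

    @property
    def n_reads(self) -> int:
        return int(self.start.size)

    @property
    def n_calls(self) -> int:
        return int(self.call_pos.size)

    def __len__(self) -> int:
        return self.n_reads

    def __iter__(self) -> Iterator[BisRead]:
        call_order = np.argsort(self.call_read, kind="stable")
        snp_order = np.argsort(self.snp_read, kind="stable")
        call_split = np.searchsorted(self.call_read[call_order], np.arange(self.n_reads + 1))
        snp_split = np.searchsorted(self.snp_read[snp_order], np.arange(self.n_reads + 1))
        for i in range(self.n_reads):
            ci = call_order[call_split[i] : call_split[i + 1]]
            si = snp_order[snp_split[i] : snp_split[i + 1]]
            yield BisRead(
                chrom=self.chrom_names[self.chrom[i]],
                start=int(self.start[i]),
                end=int(self.end[i]),
                strand="-" if self.is_reverse[i] else "+",
                meth_calls=tuple(
                    (int(p), bool(m))
                    for p, m in zip(self.call_pos[ci], self.call_meth[ci])
                ),
                snp_bases=tuple(
                    (int(p), str(b)) for p, b in zip(self.snp_pos[si], self.snp_base[si])
                ),
                true_allele=ALLELE_NAMES[int(self.true_allele[i])],
            )

    @classmethod
    def from_reads(cls, records: Sequence[BisRead]) -> "ReadSet":
        chrom_names = sorted({r.chrom for r in records})
        code = {c: i for i, c in enumerate(chrom_names)}
        allele_code = {"maternal": 0, "paternal": 1, None: -1}
        call_read, call_pos, call_meth = [], [], []
        snp_read, snp_pos, snp_base = [], [], []
        for i, r in enumerate(records):
            for p, m in r.meth_calls:
                call_read.append(i)
                call_pos.append(p)
                call_meth.append(m)
            for p, b in r.snp_bases:
                snp_read.append(i)
                snp_pos.append(p)
                snp_base.append(b)
        return cls(
            chrom_names=chrom_names,
            chrom=np.array([code[r.chrom] for r in records], np.int32),
            start=np.array([r.start for r in records], np.int64),
            end=np.array([r.end for r in records], np.int64),
            is_reverse=np.array([r.strand == "-" for r in records], bool),
            true_allele=np.array(
                [allele_code[r.true_allele] for r in records], np.int8
            ),
            call_read=np.array(call_read, np.int64),
            call_pos=np.array(call_pos, np.int64),
            call_meth=np.array(call_meth, bool),
            snp_read=np.array(snp_read, np.int64),
            snp_pos=np.array(snp_pos, np.int64),
            snp_base=np.array(snp_base, "U1"),
        )

    def subset(self, mask: np.ndarray) -> "ReadSet":
        """Reads selected by boolean ``mask`` (calls/SNP observations follow)."""
        mask = np.asarray(mask, bool)
        new_index = np.full(self.n_reads, -1, np.int64)
        new_index[mask] = np.arange(int(mask.sum()))
        ckeep = mask[self.call_read]
        skeep = mask[self.snp_read]
        return ReadSet(
            chrom_names=list(self.chrom_names),
            chrom=self.chrom[mask],
            start=self.start[mask],
            end=self.end[mask],
            is_reverse=self.is_reverse[mask],
            true_allele=self.true_allele[mask],
            call_read=new_index[self.call_read[ckeep]],
            call_pos=self.call_pos[ckeep],
            call_meth=self.call_meth[ckeep],
            snp_read=new_index[self.snp_read[skeep]],
            snp_pos=self.snp_pos[skeep],
            snp_base=self.snp_base[skeep],
        )

    # -- text round trip ---------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write one tab-delimited line per read.

        Columns: chrom, start, end, strand, calls ("pos:M" / "pos:U" joined
        by ";", "." if none), snps ("pos=base" joined by ";", "." if none),
        origin (mat/pat/. — simulation truth, never read by the pipeline).
        """
        origin = {0: "mat", 1: "pat", -1: "."}
        with open(path, "w") as fh:
            for r in self:
                calls = (
                    ";".join(f"{p}:{'M' if m else 'U'}" for p, m in r.meth_calls)
                    or "."
                )
                snps = ";".join(f"{p}={b}" for p, b in r.snp_bases) or "."
                tag = {"maternal": "mat", "paternal": "pat", None: "."}[r.true_allele]
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{calls}\t{snps}\t{tag}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "ReadSet":
        records = []
        names = {"mat": "maternal", "pat": "paternal", ".": None}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, strand, calls, snps, tag = line.rstrip("\n").split("\t")
                meth_calls = tuple(
                    (int(tok.split(":")[0]), tok.split(":")[1] == "M")
                    for tok in calls.split(";")
                    if tok != "."
                )
                snp_bases = tuple(
                    (int(tok.split("=")[0]), tok.split("=")[1])
                    for tok in snps.split(";")
                    if tok != "."
                )
                records.append(
                    BisRead(
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        meth_calls=meth_calls,
                        snp_bases=snp_bases,
                        true_allele=names[tag],
                    )
                )
        return cls.from_reads(records)
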