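"""Cytosine context assignment and per-cytosine methylation calling.

The unit of all downstream arithmetic is a *cytosine site*: one reference
cytosine on one strand, with its trinucleotide context (CG, CHG or CHH with
H ∈ {A, C, T}) and counts of methylated-looking (unconverted) and converted
observations.  Collections of sites are plain pandas DataFrames with columns
``chrom, pos, strand, context, n_meth, n_unmeth`` (``pos`` is 1-based; ``tri``
carries the reference trinucleotide when available).  The schema is
interchangeable with Bismark's CX report (see :mod:`zygometh.io`).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SITE_KEY = ["chrom", "pos", "strand"]


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def call_context(sequence: str, pos: int, strand: str) -> str | None:
    """Context of the cytosine at 1-based ``pos`` on ``strand``.

    Returns ``"CG"``, ``"CHG"``, ``"CHH"``, or ``None`` when the trinucleotide
    runs off the sequence end or contains an N.  Raises ``ValueError`` if the
    base at (pos, strand) is not a cytosine — that is a contract violation,
    not a missing context.
    """
    if not 1 <= pos <= len(sequence):
        raise ValueError(f"pos {pos} outside sequence of length {len(sequence)}")
    if strand == "+":
        tri = sequence[pos - 1 : pos + 2].upper()
    elif strand == "-":
        tri = _revcomp(sequence[max(pos - 3, 0) : pos].upper())
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if tri[0] != "C":
        raise ValueError(
            f"base at pos={pos} strand={strand} is {tri[0]!r}, expected 'C'"
        )
    if len(tri) < 2 or tri[1] == "N":
        return None
    if tri[1] == "G":
        return "CG"
    if len(tri) < 3 or tri[2] == "N":
        return None
    return "CHG" if tri[2] == "G" else "CHH"


def reference_cytosines(reference: Mapping[str, str]) -> pd.DataFrame:
    """Enumerate every reference cytosine with a complete, N-free context.

    Both strands are reported (a G on the forward strand is a C on the
    reverse).  Returns columns ``chrom, pos, strand, context, tri`` sorted by
    (chrom, pos, strand).
    """
    frames = []
    for chrom in reference:
        seq = reference[chrom].upper()
        code = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = code.size
        C, G, N = ord("C"), ord("G"), ord("N")
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in zip(b"ACGTN", b"TGCAN"):
            comp[a] = b

        for strand in "+-":
            if strand == "+":
                idx = np.nonzero(code == C)[0]
                b1 = np.where(idx + 1 < n, code[np.minimum(idx + 1, n - 1)], N)
                b2 = np.where(idx + 2 < n, code[np.minimum(idx + 2, n - 1)], N)
            else:
                idx = np.nonzero(code == G)[0]
                b1 = np.where(idx - 1 >= 0, comp[code[np.maximum(idx - 1, 0)]], N)
                b2 = np.where(idx - 2 >= 0, comp[code[np.maximum(idx - 2, 0)]], N)
            is_cg = b1 == G
            b1_h = (b1 != G) & (b1 != N)
            is_chg = b1_h & (b2 == G)
            is_chh = b1_h & (b2 != G) & (b2 != N)
            keep = is_cg | is_chg | is_chh
            idx, b1, b2 = idx[keep], b1[keep], b2[keep]
            context = np.where(
                is_cg[keep], "CG", np.where(is_chg[keep], "CHG", "CHH")
            )
            tri = np.char.add(
                np.char.add("C", b1.astype(np.uint32).view("U1")),
                b2.astype(np.uint32).view("U1"),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "strand": strand,
                        "context": context,
                        "tri": tri,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "tri"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(SITE_KEY, kind="stable", ignore_index=True)


def extract_cytosine_counts(
    reads,
    reference: Mapping[str, str],
    sites: pd.DataFrame | None = None,
    drop_zero: bool = True,
) -> pd.DataFrame:
    """Aggregate per-read methylation calls into per-cytosine counts.

    ``reads`` is a :class:`zygometh.reads.ReadSet`.  ``n_meth`` counts
    unconverted (methylated-looking) observations, ``n_unmeth`` converted
    ones; strands are kept separate.  Reads whose interval falls outside the
    reference are rejected (the count of rejects is logged).  Calls at
    positions that are not context-complete cytosines of the reference
    (e.g. N-masked SNP positions) are ignored.
    """
    if sites is None:
        sites = reference_cytosines(reference)
    sites = sites.reset_index(drop=True)

    n_meth = np.zeros(len(sites), dtype=np.int64)
    n_unmeth = np.zeros(len(sites), dtype=np.int64)
    n_rejected = 0

    if reads.n_reads:
        # validity of each read's interval
        chrom_len = np.array(
            [len(reference.get(name, "")) for name in reads.chrom_names]
        )
        known = np.array([name in reference for name in reads.chrom_names])
        read_ok = (
            known[reads.chrom]
            & (reads.start >= 0)
            & (reads.end <= chrom_len[reads.chrom])
        )
        n_rejected = int((~read_ok).sum())
        if n_rejected:
            logger.warning("rejected %d reads outside the reference", n_rejected)

        # per (chrom, strand) sorted site-position lookup
        lookup = {}
        for (chrom, strand), grp in sites.groupby(["chrom", "strand"], sort=False):
            lookup[(chrom, strand)] = (
                grp["pos"].to_numpy(np.int64),
                grp.index.to_numpy(np.int64),
            )

        call_ok = read_ok[reads.call_read]
        call_chrom = reads.chrom[reads.call_read]
        call_rev = reads.is_reverse[reads.call_read]
        for ci, chrom in enumerate(reads.chrom_names):
            for strand, rev in (("+", False), ("-", True)):
                mask = call_ok & (call_chrom == ci) & (call_rev == rev)
                if not mask.any():
                    continue
                pos = reads.call_pos[mask]
                meth = reads.call_meth[mask]
                arr = lookup.get((chrom, strand))
                if arr is None:
                    continue
                site_pos, site_row = arr
                j = np.searchsorted(site_pos, pos)
                ok = (j < site_pos.size) & (site_pos[np.minimum(j, site_pos.size - 1)] == pos)
                rows = site_row[j[ok]]
                np.add.at(n_meth, rows[meth[ok]], 1)
                np.add.at(n_unmeth, rows[~meth[ok]], 1)

    out = sites.copy()
    out["n_meth"] = n_meth
    out["n_unmeth"] = n_unmeth
    if drop_zero:
        out = out[(out["n_meth"] + out["n_unmeth"]) > 0].reset_index(drop=True)
    out.attrs["n_rejected_reads"] = n_rejected
    return out


def filter_coverage(sites: pd.DataFrame, min_depth: int = 3) -> pd.DataFrame:
    """Keep sites sequenced at least ``min_depth`` times (default 3)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = sites["n_meth"] + sites["n_unmeth"]
    return sites[depth >= min_depth].reset_index(drop=True)


def pool_replicates(
    site_collections: Sequence[pd.DataFrame], mode: str = "sum"
) -> pd.DataFrame:
    """Combine replicate site tables.

    ``mode="sum"`` adds counts per site (the construction used for testing);
    ``mode="mean_level"`` returns the arithmetic mean of per-replicate levels
    (the figure-style summary), in a ``level`` column.
    """
    if not site_collections:
        raise ValueError("no replicates given")
    if len(site_collections) > 1:
        chrom_sets = [set(df["chrom"].unique()) for df in site_collections]
        nonempty = [s for s in chrom_sets if s]
        if len(nonempty) > 1 and not set.intersection(*nonempty):
            raise ValueError("replicates share no chromosomes: mismatched references?")
    cols = SITE_KEY + ["context"]
    if mode == "sum":
        cat = pd.concat(site_collections, ignore_index=True)
        keep_tri = "tri" in cat.columns
        agg = {"n_meth": "sum", "n_unmeth": "sum"}
        if keep_tri:
            agg["tri"] = "first"
        out = cat.groupby(cols, sort=False, as_index=False).agg(agg)
        return out.sort_values(SITE_KEY, kind="stable", ignore_index=True)
    if mode == "mean_level":
        levels = []
        for i, df in enumerate(site_collections):
            depth = df["n_meth"] + df["n_unmeth"]
            d = df.loc[depth > 0, cols].copy()
            d[f"level_{i}"] = (df["n_meth"] / depth)[depth > 0]
            levels.append(d.set_index(cols))
        merged = pd.concat(levels, axis=1)
        out = merged.mean(axis=1).rename("level").reset_index()
        return out.sort_values(SITE_KEY, kind="stable", ignore_index=True)
    raise ValueError(f"unknown mode {mode!r}")


def methylation_level(sites: pd.DataFrame) -> pd.Series:
    """Per-site methylation level n_meth / (n_meth + n_unmeth) (NaN at depth 0)."""
    depth = sites["n_meth"] + sites["n_unmeth"]
    with np.errstate(invalid="ignore"):
        return sites["n_meth"] / depth.where(depth > 0)
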