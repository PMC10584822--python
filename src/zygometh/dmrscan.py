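"""Windowed DMR calling between two samples.

The genome is tiled into fixed 50-bp bins; per context, bins with at least
five cytosines each sequenced at three-fold coverage or better in both
samples are tested with Fisher's exact test on the pooled (meth, unmeth)
counts, adjusted by Benjamini–Hochberg within the context.  Bins with an
absolute methylation difference above the context cutoff (CG 0.5, CHG 0.3,
CHH 0.1) and FDR < 0.05 are reported as DMRs, oriented hyper when sample 1
exceeds sample 2.  Also provides the density-difference statistic for
distribution plots, DMR feature annotation (gene body / TE / TE-gene /
intergenic) and DMR-set overlap summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

DELTA_THRESHOLDS = {"CG": 0.5, "CHG": 0.3, "CHH": 0.1}
RATIO_THRESHOLDS = {"CG": 0.5, "CHG": 0.3, "CHH": 0.1}

WINDOW_KEY = ["chrom", "start", "end", "context"]


def bin_windows(
    sites: pd.DataFrame,
    window: int = 50,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pool cytosine counts of one sample into fixed genomic windows.

    Windows lie on the grid 0, 50, 100, … per chromosome; the trailing
    remainder of a chromosome is kept as a short window when ``chrom_sizes``
    is given.  Returns per (chrom, window, context): site count, pooled
    counts and the minimum per-site depth.
    """
    if sites.empty:
        return pd.DataFrame(
            columns=WINDOW_KEY + ["n_sites", "n_meth", "n_unmeth", "min_depth"]
        )
    df = sites[["chrom", "pos", "context", "n_meth", "n_unmeth"]].copy()
    df["start"] = (df["pos"] - 1) // window * window
    df["depth"] = df["n_meth"] + df["n_unmeth"]
    g = df.groupby(["chrom", "start", "context"], sort=False).agg(
        n_sites=("pos", "size"),
        n_meth=("n_meth", "sum"),
        n_unmeth=("n_unmeth", "sum"),
        min_depth=("depth", "min"),
    )
    out = g.reset_index()
    out["end"] = out["start"] + window
    if chrom_sizes:
        sizes = out["chrom"].map(chrom_sizes)
        out["end"] = np.minimum(out["end"], sizes.fillna(out["end"]).astype(np.int64))
    return out[WINDOW_KEY + ["n_sites", "n_meth", "n_unmeth", "min_depth"]].sort_values(
        ["chrom", "start", "context"], kind="stable", ignore_index=True
    )


def pair_windows(w1: pd.DataFrame, w2: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two samples' window tables on (chrom, window, context)."""
    return w1.merge(w2, on=WINDOW_KEY, suffixes=("_1", "_2"))


def filter_windows(
    paired: pd.DataFrame, min_sites: int = 5, min_site_depth: int = 3
) -> pd.DataFrame:
    """Keep windows with ≥ ``min_sites`` cytosines, each at ≥
    ``min_site_depth`` coverage, in BOTH samples."""
    keep = (
        (paired["n_sites_1"] >= min_sites)
        & (paired["n_sites_2"] >= min_sites)
        & (paired["min_depth_1"] >= min_site_depth)
        & (paired["min_depth_2"] >= min_site_depth)
    )
    return paired[keep].reset_index(drop=True)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Computed by exact integer enumeration: the sum of hypergeometric
    probabilities (at the observed margins) of all tables no more probable
    than the observed one.  A degenerate (all-zero) margin yields p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2, K = a + b, c + d, a + c
    N = n1 + n2
    if n1 == 0 or n2 == 0 or K == 0 or K == N:
        return 1.0
    k_min, k_max = max(0, K - n2), min(K, n1)
    observed = comb(n1, a) * comb(n2, c)
    total = 0
    tail = 0
    for k in range(k_min, k_max + 1):
        w = comb(n1, k) * comb(n2, K - k)
        total += w
        if w <= observed:
            tail += w
    return tail / total


def fisher_exact_batch(
    m1: np.ndarray, u1: np.ndarray, m2: np.ndarray, u2: np.ndarray
) -> np.ndarray:
    """Vectorized two-sided Fisher p-values for many 2x2 tables.

    Same definition as :func:`fisher_exact_2x2`, evaluated with the
    hypergeometric pmf in floating point (ties included with a 1e-10
    relative tolerance).
    """
    m1 = np.asarray(m1, np.int64)
    u1 = np.asarray(u1, np.int64)
    m2 = np.asarray(m2, np.int64)
    u2 = np.asarray(u2, np.int64)
    n1, n2 = m1 + u1, m2 + u2
    K = m1 + m2
    N = n1 + n2
    p = np.ones(m1.size, dtype=np.float64)
    ok = (n1 > 0) & (n2 > 0) & (K > 0) & (K < N)
    if not ok.any():
        return p
    idx = np.nonzero(ok)[0]
    k_min = np.maximum(0, K[idx] - n2[idx])
    k_max = np.minimum(K[idx], n1[idx])
    table_of, k = _ragged_support(k_min, k_max)
    pmf = stats.hypergeom.pmf(k, N[idx][table_of], n1[idx][table_of], K[idx][table_of])
    obs = stats.hypergeom.pmf(m1[idx], N[idx], n1[idx], K[idx])
    include = pmf <= obs[table_of] * (1.0 + 1e-10)
    tail = np.zeros(idx.size)
    np.add.at(tail, table_of, np.where(include, pmf, 0.0))
    p[idx] = np.minimum(tail, 1.0)
    return p


def _ragged_support(k_min: np.ndarray, k_max: np.ndarray):
    counts = k_max - k_min + 1
    total = int(counts.sum())
    table_of = np.repeat(np.arange(k_min.size), counts)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    k = np.repeat(k_min, counts) + (np.arange(total) - offsets)
    return table_of, k


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def window_methylation(paired: pd.DataFrame) -> pd.DataFrame:
    """Append m1, m2 and delta = m1 - m2 to a paired window table."""
    out = paired.copy()
    d1 = out["n_meth_1"] + out["n_unmeth_1"]
    d2 = out["n_meth_2"] + out["n_unmeth_2"]
    out["m1"] = np.where(d1 > 0, out["n_meth_1"] / d1, np.nan)
    out["m2"] = np.where(d2 > 0, out["n_meth_2"] / d2, np.nan)
    out["delta"] = out["m1"] - out["m2"]
    return out


def call_dmrs(
    sites1: pd.DataFrame,
    sites2: pd.DataFrame,
    contexts: Sequence[str] | None = None,
    window: int = 50,
    min_sites: int = 5,
    min_site_depth: int = 3,
    delta_thresholds: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    use_raw_p: bool = False,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Call DMRs between two per-cytosine count tables.

    Per context: pool counts into windows, keep well-covered windows,
    Fisher-test each, BH-adjust across all tested windows of the context,
    and report windows with |delta| above the context cutoff and FDR (or raw
    p with ``use_raw_p``) below ``alpha``.  Direction is ``hyper`` when
    sample 1 exceeds sample 2.
    """
    thresholds = dict(DELTA_THRESHOLDS)
    if delta_thresholds:
        thresholds.update(delta_thresholds)
    w1 = bin_windows(sites1, window=window, chrom_sizes=chrom_sizes)
    w2 = bin_windows(sites2, window=window, chrom_sizes=chrom_sizes)
    paired = filter_windows(
        pair_windows(w1, w2), min_sites=min_sites, min_site_depth=min_site_depth
    )
    paired = window_methylation(paired)

    results = []
    for ctx in contexts or sorted(paired["context"].unique()):
        grp = paired[paired["context"] == ctx].reset_index(drop=True)
        if grp.empty:
            continue
        grp["p"] = fisher_exact_batch(
            grp["n_meth_1"], grp["n_unmeth_1"], grp["n_meth_2"], grp["n_unmeth_2"]
        )
        grp["fdr"] = bh_adjust(grp["p"].to_numpy())
        tau = thresholds[ctx]
        stat = grp["p"] if use_raw_p else grp["fdr"]
        keep = (grp["delta"].abs() > tau) & (stat < alpha)
        hits = grp[keep].copy()
        hits["direction"] = np.where(hits["delta"] > 0, "hyper", "hypo")
        results.append(hits)
    if not results:
        return pd.DataFrame(
            columns=WINDOW_KEY
            + [
                "n_sites_1", "n_meth_1", "n_unmeth_1", "min_depth_1",
                "n_sites_2", "n_meth_2", "n_unmeth_2", "min_depth_2",
                "m1", "m2", "delta", "p", "fdr", "direction",
            ]
        )
    out = pd.concat(results, ignore_index=True)
    return out.sort_values(["chrom", "start", "context"], kind="stable", ignore_index=True)


def annotate_dmrs(
    dmrs: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    te_intervals: pd.DataFrame,
) -> pd.DataFrame:
    """Classify each DMR by any-overlap (≥1 bp) with the annotation.

    Precedence: TE_gene (overlaps both a TE and a gene) > TE > gene_body >
    intergenic.  Interval tables use 0-based half-open coordinates.
    """
    trees = {}
    for name, ann in (("gene", gene_intervals), ("TE", te_intervals)):
        for chrom, grp in ann.groupby("chrom", sort=False):
            tree = IntervalTree()
            for s, e in zip(grp["start"], grp["end"]):
                if e > s:
                    tree.addi(int(s), int(e))
            trees[(name, chrom)] = tree
    labels = []
    for chrom, s, e in zip(dmrs["chrom"], dmrs["start"], dmrs["end"]):
        in_gene = bool(trees.get(("gene", chrom), IntervalTree()).overlap(s, e))
        in_te = bool(trees.get(("TE", chrom), IntervalTree()).overlap(s, e))
        if in_te and in_gene:
            labels.append("TE_gene")
        elif in_te:
            labels.append("TE")
        elif in_gene:
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    out = dmrs.copy()
    out["feature_class"] = labels
    return out


def density_difference(
    sites1: pd.DataFrame,
    sites2: pd.DataFrame,
    contexts: Sequence[str] | None = None,
    window: int = 50,
    min_informative: int = 20,
    ratio_thresholds: Mapping[str, float] | None = None,
    informative: str = "depth_sum",
) -> pd.DataFrame:
    """Per-window fractional methylation differences for density plots.

    A window is kept when it holds at least ``min_informative`` informative
    sequenced cytosines (the summed sequencing depth over the window's
    context cytosines; ``informative="depth_times_sites"`` multiplies by the
    site count instead) in BOTH samples, and its level reaches the context
    ratio threshold (CG 0.5, CHG 0.3, CHH 0.1) in at least one sample.
    """
    ratios = dict(RATIO_THRESHOLDS)
    if ratio_thresholds:
        ratios.update(ratio_thresholds)
    paired = window_methylation(
        pair_windows(bin_windows(sites1, window), bin_windows(sites2, window))
    )
    if paired.empty:
        return paired.assign(difference=pd.Series(dtype=float))
    for s in ("1", "2"):
        info = paired[f"n_meth_{s}"] + paired[f"n_unmeth_{s}"]
        if informative == "depth_times_sites":
            info = info * paired[f"n_sites_{s}"]
        elif informative != "depth_sum":
            raise ValueError("informative must be 'depth_sum' or 'depth_times_sites'")
        paired[f"informative_{s}"] = info
    tau = paired["context"].map(ratios)
    keep = (
        (paired["informative_1"] >= min_informative)
        & (paired["informative_2"] >= min_informative)
        & ((paired["m1"] >= tau) | (paired["m2"] >= tau))
    )
    out = paired[keep].reset_index(drop=True)
    out["difference"] = out["m1"] - out["m2"]
    if contexts:
        out = out[out["context"].isin(contexts)].reset_index(drop=True)
    return out


def density_histogram(
    differences: np.ndarray, n_bins: int = 100
) -> pd.DataFrame:
    """Binned frequency table of fractional differences over [-1, 1]."""
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.asarray(differences, float), bins=edges)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_center": (edges[:-1] + edges[1:]) / 2.0,
            "frequency": counts / total if total else counts.astype(float),
        }
    )


@dataclass
class OverlapResult:
    """Summary of the overlap between two same-comparison DMR sets."""

    n_a: int
    n_b: int
    n_shared: int  # DMRs of A overlapping ≥1 bp of a same-context DMR of B
    n_a_only: int
    n_b_only: int
    fraction_shared: float  # n_shared / n_a
    jaccard: float  # base-level, same-context


def overlap_dmr_sets(set_a: pd.DataFrame, set_b: pd.DataFrame) -> OverlapResult:
    """Overlap two DMR tables (same reference), matching within context."""

    def _overlapping(x: pd.DataFrame, y: pd.DataFrame) -> int:
        total = 0
        for (chrom, ctx), gx in x.groupby(["chrom", "context"], sort=False):
            gy = y[(y["chrom"] == chrom) & (y["context"] == ctx)]
            if gy.empty:
                continue
            ys = gy.sort_values("start")
            starts = ys["start"].to_numpy()
            ends = ys["end"].to_numpy()
            # DMR grids may be merged: an interval overlaps if any y-start is
            # before its end and the matching y-end after its start
            for s, e in zip(gx["start"], gx["end"]):
                j0 = np.searchsorted(ends, s, side="right")
                j1 = np.searchsorted(starts, e, side="left")
                if j1 > j0:
                    total += 1
        return total

    def _bases(x: pd.DataFrame, y: pd.DataFrame):
        inter = 0
        len_x = int((x["end"] - x["start"]).sum()) if len(x) else 0
        len_y = int((y["end"] - y["start"]).sum()) if len(y) else 0
        for (chrom, ctx), gx in x.groupby(["chrom", "context"], sort=False):
            gy = y[(y["chrom"] == chrom) & (y["context"] == ctx)]
            for s, e in zip(gx["start"], gx["end"]):
                ov = np.minimum(gy["end"], e) - np.maximum(gy["start"], s)
                inter += int(ov[ov > 0].sum())
        union = len_x + len_y - inter
        return inter / union if union else float("nan")

    n_a, n_b = len(set_a), len(set_b)
    shared_a = _overlapping(set_a, set_b)
    shared_b = _overlapping(set_b, set_a)
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        n_shared=shared_a,
        n_a_only=n_a - shared_a,
        n_b_only=n_b - shared_b,
        fraction_shared=shared_a / n_a if n_a else float("nan"),
        jaccard=_bases(set_a, set_b),
    )


def merge_adjacent_dmrs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Merge touching same-context, same-direction DMR windows (optional
    utility; DMRs are reported per 50-bp bin by default)."""
    if dmrs.empty:
        return dmrs.copy()
    rows = []
    sdf = dmrs.sort_values(["chrom", "context", "direction", "start"])
    for (chrom, ctx, direction), grp in sdf.groupby(
        ["chrom", "context", "direction"], sort=False
    ):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_e is not None and s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                if cur_e is not None:
                    rows.append((chrom, cur_s, cur_e, ctx, direction))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e, ctx, direction))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context", "direction"])
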