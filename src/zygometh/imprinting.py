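"""PEG/MEG classification from reciprocal-cross allelic read counts.

A gene is imprinted when its allelic bias follows the parental *role* in both
reciprocal crosses: a PEG (paternally expressed gene) is paternal-biased with
|log2 ratio| > 1 and BH-adjusted p < 0.01 in both crosses; a MEG is the
mirror.  A gene whose bias follows the *genotype* instead — favoring the same
genomic parent whether it served as mother or father — is sequence-specific,
not imprinted.  Bias is tested per cross with an exact two-sided binomial
test of the paternal count against the expected allelic proportion (0.5 by
default); the displayed log2 ratio uses a pseudocount of 1 on both alleles
but the test uses raw counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .dmrscan import bh_adjust

LABELS = ("PEG", "MEG", "biallelic", "sequence_specific", "untestable")


def allelic_bias_test(maternal_count: int, paternal_count: int) -> tuple:
    """(log2 paternal/maternal ratio, exact binomial two-sided p vs 0.5).

    The ratio carries a pseudocount of 1 on both alleles; the test does not.
    Both counts zero yields (nan, nan) — an untestable sentinel.
    """
    m, p = int(maternal_count), int(paternal_count)
    if m < 0 or p < 0:
        raise ValueError("counts must be non-negative")
    if m == 0 and p == 0:
        return (math.nan, math.nan)
    log2_ratio = math.log2((p + 1) / (m + 1))
    pval = stats.binomtest(p, m + p, 0.5).pvalue
    return (log2_ratio, float(pval))


def _per_cross(
    counts: pd.DataFrame, min_total: int, expected_maternal_fraction: float
) -> pd.DataFrame:
    out = counts[["gene", "mat_count", "pat_count"]].copy()
    total = out["mat_count"] + out["pat_count"]
    out["total"] = total
    out["log2_ratio"] = np.log2((out["pat_count"] + 1) / (out["mat_count"] + 1))
    p0 = 1.0 - expected_maternal_fraction
    pvals = np.full(len(out), np.nan)
    testable = (total >= min_total).to_numpy()
    for i, (pc, t) in enumerate(zip(out["pat_count"], total)):
        if testable[i]:
            pvals[i] = stats.binomtest(int(pc), int(t), p0).pvalue
    out["p"] = pvals
    out["padj"] = np.nan
    if testable.any():
        out.loc[testable, "padj"] = bh_adjust(pvals[testable])
    out["testable"] = testable
    return out


def classify_imprinting(
    cross1: pd.DataFrame,
    cross2: pd.DataFrame,
    min_total: int = 10,
    log2fc: float = 1.0,
    alpha: float = 0.01,
    expected_maternal_fraction: float = 0.5,
) -> pd.DataFrame:
    """Label genes from the two reciprocal crosses.

    ``cross1`` is genome A × genome B (A as mother), ``cross2`` the
    reciprocal; both are DataFrames with columns ``gene, mat_count,
    pat_count``.  BH adjustment is applied within each cross over its
    testable genes (total ≥ ``min_total``).  Labels:

    - ``PEG`` — paternal-biased (log2 ratio > ``log2fc``, adjusted p <
      ``alpha``) in both crosses;
    - ``MEG`` — maternal-biased in both;
    - ``sequence_specific`` — significantly biased toward the same genomic
      parent in both crosses (opposite parental roles);
    - ``untestable`` — missing from a cross or under ``min_total`` in either;
    - ``biallelic`` — everything else.

    ``expected_maternal_fraction`` re-centers the test away from 0.5 (e.g.
    at an estimated global maternal read fraction, to look for imprinting
    over and above maternal dominance); the default 0.5 matches the standard
    allelic cut-offs.
    """
    c1 = _per_cross(cross1, min_total, expected_maternal_fraction)
    c2 = _per_cross(cross2, min_total, expected_maternal_fraction)
    merged = c1.merge(c2, on="gene", how="outer", suffixes=("_1", "_2"))

    lab = np.full(len(merged), "biallelic", dtype="U20")
    testable = (
        merged["testable_1"].eq(True) & merged["testable_2"].eq(True)
    ).to_numpy()
    lab[~testable] = "untestable"

    def _sig(side, s):
        if side == "pat":
            bias = merged[f"log2_ratio_{s}"] > log2fc
        else:
            bias = merged[f"log2_ratio_{s}"] < -log2fc
        return (bias & (merged[f"padj_{s}"] < alpha)).to_numpy() & testable

    pat1, pat2 = _sig("pat", 1), _sig("pat", 2)
    mat1, mat2 = _sig("mat", 1), _sig("mat", 2)
    lab[pat1 & pat2] = "PEG"
    lab[mat1 & mat2] = "MEG"
    # genome A is maternal in cross 1 and paternal in cross 2
    lab[(mat1 & pat2) | (pat1 & mat2)] = "sequence_specific"
    merged["label"] = lab
    return merged


def imprinting_summary(calls: pd.DataFrame) -> pd.Series:
    """Label counts of a classification table."""
    return calls["label"].value_counts().reindex(LABELS, fill_value=0)
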