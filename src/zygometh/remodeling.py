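"""Tracking egg-vs-sperm DMRs into the hybrid zygote and early embryo.

The central question: at regions where egg and sperm methylomes differ
(E–S DMRs), does the paternal allele in the fertilized zygote keep the sperm
level, or is it remodeled toward the maternal (egg) level?  The degree of
remodeling is summarized by a coefficient rho, the fraction of the way the
paternal allelic level has moved from the sperm level toward the egg level:

    m_pat = m_sperm + rho * (m_egg - m_sperm)

estimated per context by depth-weighted least squares over testable DMRs,

    rho_hat = sum_i w_i (m_pat,i - m_sperm,i)(m_egg,i - m_sperm,i)
            / sum_i w_i (m_egg,i - m_sperm,i)^2,

clipped to [0, 1], with a bootstrap percentile CI over DMRs.  rho = 1 is a
full maternal match, rho = 0 no remodeling.  CHH behaves differently (the
zygote parallels the lower parental level), so CHH is summarized by the
lower-parent deviation mean(m_zygote - min(m_egg, m_sperm)) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dmrscan

SUMMARY_COLUMNS = [
    "chrom", "start", "end", "context", "direction",
    "m_egg", "m_sperm", "m_mat", "m_pat",
    "depth_mat", "depth_pat", "n_sites_mat", "n_sites_pat",
    "m_sample", "testable", "dmr_class",
]


class InsufficientDMRsError(ValueError):
    """Too few testable, well-separated DMRs to estimate rho."""


def select_es_dmrs(egg_sites: pd.DataFrame, sperm_sites: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """DMRs between egg (sample 1) and sperm (sample 2) cytosine reports.

    ``hyper`` means egg > sperm.  Accepts the :func:`zygometh.dmrscan.call_dmrs`
    keyword arguments.
    """
    return dmrscan.call_dmrs(egg_sites, sperm_sites, **kwargs)


def _pool_sites_in_intervals(
    sites: pd.DataFrame, dmrs: pd.DataFrame
) -> pd.DataFrame:
    """Per-DMR pooled (n_sites, n_meth, n_unmeth) of context-matching sites."""
    n = len(dmrs)
    n_sites = np.zeros(n, np.int64)
    n_meth = np.zeros(n, np.int64)
    n_unmeth = np.zeros(n, np.int64)
    if sites is None or sites.empty or dmrs.empty:
        return pd.DataFrame(
            {"n_sites": n_sites, "n_meth": n_meth, "n_unmeth": n_unmeth}
        )
    for (chrom, ctx), grp in dmrs.groupby(["chrom", "context"], sort=False):
        sub = sites[
            (sites["chrom"] == chrom) & (sites["context"] == ctx)
        ]
        if sub.empty:
            continue
        pos0 = sub["pos"].to_numpy() - 1  # 0-based for interval comparison
        order = grp.sort_values("start")
        starts = order["start"].to_numpy()
        ends = order["end"].to_numpy()
        rows = order.index.to_numpy()
        j = np.searchsorted(starts, pos0, side="right") - 1
        inside = (j >= 0) & (pos0 < ends[np.maximum(j, 0)])
        tgt = rows[j[inside]]
        np.add.at(n_sites, tgt, 1)
        np.add.at(n_meth, tgt, sub["n_meth"].to_numpy()[inside])
        np.add.at(n_unmeth, tgt, sub["n_unmeth"].to_numpy()[inside])
    return pd.DataFrame({"n_sites": n_sites, "n_meth": n_meth, "n_unmeth": n_unmeth})


def classify_dmr(
    m_pat: float,
    m_egg: float,
    m_sperm: float,
    match_tol: float = 0.1,
    distinct_tol: float = 0.2,
) -> str:
    """maternal_match / paternal_match / intermediate for one paternal level.

    ``maternal_match``: within ``match_tol`` of the egg level while at least
    ``distinct_tol`` away from the sperm level (mirrored for
    ``paternal_match``); anything else is ``intermediate``.
    """
    if np.isnan(m_pat):
        return "untestable"
    near_egg = abs(m_pat - m_egg) < match_tol and abs(m_pat - m_sperm) >= distinct_tol
    near_sperm = abs(m_pat - m_sperm) < match_tol and abs(m_pat - m_egg) >= distinct_tol
    if near_egg:
        return "maternal_match"
    if near_sperm:
        return "paternal_match"
    return "intermediate"


def allelic_levels_at_dmrs(
    dmrs: pd.DataFrame,
    maternal_profile,
    paternal_profile,
    sample_sites: pd.DataFrame | None = None,
    min_sites_allelic: int = 3,
    match_tol: float = 0.1,
    distinct_tol: float = 0.2,
) -> pd.DataFrame:
    """Allelic methylation of a hybrid sample at each E–S DMR.

    ``maternal_profile`` / ``paternal_profile`` are
    :class:`zygometh.allelesplit.AlleleMethProfile` objects (or bare site
    DataFrames) from the hybrid sample; their sites already passed the ≥3
    allele-specific-read filter.  A DMR with fewer than ``min_sites_allelic``
    testable cytosines on either allele is marked untestable.  ``m_egg`` and
    ``m_sperm`` are the DMR's own gamete levels (m1/m2).  ``sample_sites``,
    when given, adds the hybrid sample's total (unsplit) level ``m_sample``.
    """
    dmrs = dmrs.reset_index(drop=True)
    mat_sites = getattr(maternal_profile, "sites", maternal_profile)
    pat_sites = getattr(paternal_profile, "sites", paternal_profile)

    out = dmrs[["chrom", "start", "end", "context", "direction"]].copy()
    out["m_egg"] = dmrs["m1"]
    out["m_sperm"] = dmrs["m2"]
    for name, sites in (("mat", mat_sites), ("pat", pat_sites)):
        pooled = _pool_sites_in_intervals(sites, dmrs)
        depth = pooled["n_meth"] + pooled["n_unmeth"]
        with np.errstate(invalid="ignore"):
            out[f"m_{name}"] = np.where(
                depth > 0, pooled["n_meth"] / depth.replace(0, 1), np.nan
            )
        out.loc[depth == 0, f"m_{name}"] = np.nan
        out[f"depth_{name}"] = depth
        out[f"n_sites_{name}"] = pooled["n_sites"]
    if sample_sites is not None:
        pooled = _pool_sites_in_intervals(sample_sites, dmrs)
        depth = pooled["n_meth"] + pooled["n_unmeth"]
        out["m_sample"] = np.where(depth > 0, pooled["n_meth"] / depth.where(depth > 0), np.nan)
    else:
        out["m_sample"] = np.nan
    out["testable"] = (
        (out["n_sites_mat"] >= min_sites_allelic)
        & (out["n_sites_pat"] >= min_sites_allelic)
    )
    out["dmr_class"] = [
        classify_dmr(mp, me, ms, match_tol, distinct_tol) if t else "untestable"
        for mp, me, ms, t in zip(out["m_pat"], out["m_egg"], out["m_sperm"], out["testable"])
    ]
    return out[SUMMARY_COLUMNS]


@dataclass
class RhoEstimate:
    """Remodeling coefficient with bootstrap percentile CI."""

    context: str
    rho: float
    ci_low: float
    ci_high: float
    n_dmrs: int


def estimate_rho(
    summary: pd.DataFrame,
    context: str,
    min_gap: float = 0.2,
    min_dmrs: int = 20,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> RhoEstimate:
    """Depth-weighted least-squares rho over testable, well-separated DMRs.

    Only DMRs with |m_egg - m_sperm| >= ``min_gap`` enter (the estimator is
    undefined where the gametes do not differ).  Raises
    :class:`InsufficientDMRsError` below ``min_dmrs`` usable rows.
    """
    rows = summary[
        (summary["context"] == context)
        & summary["testable"]
        & summary["m_pat"].notna()
        & ((summary["m_egg"] - summary["m_sperm"]).abs() >= min_gap)
        & (summary["depth_pat"] > 0)
    ]
    if len(rows) < min_dmrs:
        raise InsufficientDMRsError(
            f"{len(rows)} usable {context} DMRs (< {min_dmrs}); "
            "cannot estimate the remodeling coefficient"
        )
    x = (rows["m_egg"] - rows["m_sperm"]).to_numpy(float)
    y = (rows["m_pat"] - rows["m_sperm"]).to_numpy(float)
    w = rows["depth_pat"].to_numpy(float)

    def _rho(xi, yi, wi):
        return float(np.clip((wi * xi * yi).sum() / (wi * xi * xi).sum(), 0.0, 1.0))

    rho = _rho(x, y, w)
    rng = np.random.default_rng(seed)
    n = x.size
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        i = rng.integers(0, n, n)
        boot[b] = _rho(x[i], y[i], w[i])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RhoEstimate(
        context=context,
        rho=rho,
        ci_low=float(min(lo, rho)),
        ci_high=float(max(hi, rho)),
        n_dmrs=n,
    )


def chh_lower_parent_statistic(summary: pd.DataFrame) -> float:
    """Mean deviation of the hybrid's total CHH level from the lower parent,
    mean(m_sample - min(m_egg, m_sperm)) over testable CHH DMRs.  Near zero
    when the zygote parallels the lower parental level."""
    rows = summary[
        (summary["context"] == "CHH") & summary["m_sample"].notna()
    ]
    if rows.empty:
        return float("nan")
    lower = np.minimum(rows["m_egg"], rows["m_sperm"])
    return float((rows["m_sample"] - lower).mean())


def compare_stages(
    summaries: dict,
    contexts=("CG", "CHG"),
    min_gap: float = 0.2,
    min_dmrs: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-context rho across developmental stages.

    ``summaries`` maps a stage label (zygote, two_cell, globular_embryo, …)
    to its :func:`allelic_levels_at_dmrs` table.  Returns one row per
    (stage, context) with the rho estimate and CI, plus a CHH
    ``lower_parent_dev`` row per stage when CHH DMRs are present.
    """
    rows = []
    for stage, summary in summaries.items():
        for ctx in contexts:
            est = estimate_rho(
                summary, ctx, min_gap=min_gap, min_dmrs=min_dmrs, seed=seed
            )
            rows.append(
                {
                    "stage": stage,
                    "context": ctx,
                    "statistic": "rho",
                    "value": est.rho,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_dmrs": est.n_dmrs,
                }
            )
        chh = chh_lower_parent_statistic(summary)
        if not np.isnan(chh):
            rows.append(
                {
                    "stage": stage,
                    "context": "CHH",
                    "statistic": "lower_parent_dev",
                    "value": chh,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_dmrs": int(
                        ((summary["context"] == "CHH") & summary["m_sample"].notna()).sum()
                    ),
                }
            )
    return pd.DataFrame(rows)
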