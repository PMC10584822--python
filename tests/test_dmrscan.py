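"""Windowed DMR calling, Fisher/BH machinery, annotation and overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import zygometh as z
from zygometh import dmrscan


def _sites(rows, context="CG"):
    """rows: (chrom, pos, n_meth, n_unmeth)"""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])
    df["strand"] = "+"
    df["context"] = context
    return df


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_window_grid_arithmetic():
    # 1-based position 51 lands in the window [50, 100)
    w = dmrscan.bin_windows(_sites([("c", 51, 1, 1)]))
    assert (w["start"].iloc[0], w["end"].iloc[0]) == (50, 100)
    w = dmrscan.bin_windows(_sites([("c", 50, 1, 1)]))
    assert w["start"].iloc[0] == 0


def test_empty_sites_give_empty_windows():
    assert dmrscan.bin_windows(_sites([])).empty


def test_window_pooling_matches_brute_force(rng):
    n = 400
    rows = [
        ("c%d" % rng.integers(1, 3), int(rng.integers(1, 2000)),
         int(rng.integers(0, 6)), int(rng.integers(0, 6)))
        for _ in range(n)
    ]
    sites = _sites(rows)
    sites = sites[(sites["n_meth"] + sites["n_unmeth"]) > 0].reset_index(drop=True)
    w = dmrscan.bin_windows(sites)
    oracle = {}
    for _, r in sites.iterrows():
        key = (r["chrom"], (r["pos"] - 1) // 50 * 50)
        s, m, u, d = oracle.get(key, (0, 0, 0, np.inf))
        oracle[key] = (
            s + 1, m + r["n_meth"], u + r["n_unmeth"],
            min(d, r["n_meth"] + r["n_unmeth"]),
        )
    got = {
        (r["chrom"], r["start"]): (r["n_sites"], r["n_meth"], r["n_unmeth"], r["min_depth"])
        for _, r in w.iterrows()
    }
    assert got == oracle


def _paired_window(n1, d1, n2, d2, n_sites=5, min_depth=3, context="CG"):
    return pd.DataFrame(
        {
            "chrom": ["c"], "start": [0], "end": [50], "context": [context],
            "n_sites_1": [n_sites], "n_meth_1": [n1], "n_unmeth_1": [d1 - n1],
            "min_depth_1": [min_depth],
            "n_sites_2": [n_sites], "n_meth_2": [n2], "n_unmeth_2": [d2 - n2],
            "min_depth_2": [min_depth],
        }
    )


@pytest.mark.parametrize(
    "n_sites,min_depth,kept",
    [(4, 5, False), (5, 2, False), (5, 3, True), (6, 10, True)],
)
def test_filter_windows_requires_sites_and_depth_in_both(n_sites, min_depth, kept):
    w = _paired_window(10, 20, 5, 20, n_sites=n_sites, min_depth=min_depth)
    out = dmrscan.filter_windows(w)
    assert (len(out) == 1) is kept


def test_filter_windows_checks_both_samples():
    w = _paired_window(10, 20, 5, 20)
    w["n_sites_2"] = 4
    assert dmrscan.filter_windows(w).empty


# ---------------------------------------------------------------------------
# Fisher's exact test and BH
# ---------------------------------------------------------------------------

def test_fisher_symmetric_table_is_one():
    assert dmrscan.fisher_exact_2x2(5, 5, 5, 5) == 1.0


def test_fisher_extreme_table_matches_enumeration():
    # margins (10,10,10,10): only the two extreme tables are as improbable
    # as observed -> p = 2 / C(20,10)
    from math import comb

    assert dmrscan.fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(
        2 / comb(20, 10), abs=1e-15
    )


def test_fisher_degenerate_margins_are_one():
    assert dmrscan.fisher_exact_2x2(0, 0, 0, 0) == 1.0
    assert dmrscan.fisher_exact_2x2(3, 2, 0, 0) == 1.0
    assert dmrscan.fisher_exact_2x2(0, 4, 0, 6) == 1.0


def test_fisher_agrees_with_scipy(rng):
    """Independent cross-check against scipy's implementation."""
    for _ in range(300):
        a, b, c, d = rng.integers(0, 25, 4)
        ours = dmrscan.fisher_exact_2x2(a, b, c, d)
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, abs=1e-9)


def test_fisher_batch_matches_scalar(rng):
    a, b, c, d = (rng.integers(0, 120, 200) for _ in range(4))
    batch = dmrscan.fisher_exact_batch(a, b, c, d)
    for i in range(200):
        assert batch[i] == pytest.approx(
            dmrscan.fisher_exact_2x2(a[i], b[i], c[i], d[i]), abs=1e-9
        )


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        dmrscan.fisher_exact_2x2(-1, 2, 3, 4)


def _bh_oracle(p):
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_bh_worked_example():
    np.testing.assert_allclose(
        dmrscan.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
    )


def test_bh_single_value_unchanged():
    np.testing.assert_allclose(dmrscan.bh_adjust([0.2]), [0.2])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60
    )
)
def test_bh_matches_definitional_formula(p):
    got = dmrscan.bh_adjust(p)
    np.testing.assert_allclose(got, _bh_oracle(p), atol=1e-12)
    assert np.all((got >= np.asarray(p) - 1e-12) & (got <= 1.0))


# ---------------------------------------------------------------------------
# call_dmrs
# ---------------------------------------------------------------------------

def _window_sites(chrom, start, levels1, levels2, depth, context="CG"):
    """Two site tables with 1 site per position inside one window."""
    rows1, rows2 = [], []
    for i, (l1, l2) in enumerate(zip(levels1, levels2)):
        pos = start + 2 * i + 1
        rows1.append((chrom, pos, round(l1 * depth), depth - round(l1 * depth)))
        rows2.append((chrom, pos, round(l2 * depth), depth - round(l2 * depth)))
    return _sites(rows1, context), _sites(rows2, context)


def test_cg_delta_below_cutoff_is_not_a_dmr():
    s1, s2 = _window_sites("c", 0, [0.9] * 5, [0.45] * 5, depth=100)
    out = dmrscan.call_dmrs(s1, s2)
    assert out.empty  # delta 0.45 < 0.5 despite a tiny p


def test_chh_dmr_above_cutoff_with_small_fdr():
    s1, s2 = _window_sites("c", 0, [0.30] * 5, [0.15] * 5, depth=200, context="CHH")
    out = dmrscan.call_dmrs(s1, s2)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["direction"] == "hyper"
    assert row["delta"] == pytest.approx(0.15)
    assert row["fdr"] < 0.05


def test_every_emitted_dmr_satisfies_thresholds(toy_cross):
    truth = toy_cross["truth"]
    s1 = z.sample_cytosine_counts(truth, "egg", 20, seed=1)
    s2 = z.sample_cytosine_counts(truth, "sperm", 20, seed=2)
    dmrs = dmrscan.call_dmrs(s1, s2)
    assert len(dmrs) > 0
    for _, r in dmrs.iterrows():
        assert abs(r["delta"]) > dmrscan.DELTA_THRESHOLDS[r["context"]]
        assert r["fdr"] < 0.05
        assert r["direction"] == ("hyper" if r["delta"] > 0 else "hypo")


def test_call_dmrs_symmetry(toy_cross):
    truth = toy_cross["truth"]
    s1 = z.sample_cytosine_counts(truth, "egg", 20, seed=1)
    s2 = z.sample_cytosine_counts(truth, "sperm", 20, seed=2)
    ab = dmrscan.call_dmrs(s1, s2)
    ba = dmrscan.call_dmrs(s2, s1)
    key = ["chrom", "start", "context"]
    m = ab.merge(ba, on=key, suffixes=("_ab", "_ba"))
    assert len(m) == len(ab) == len(ba)
    np.testing.assert_allclose(m["delta_ab"], -m["delta_ba"])
    np.testing.assert_allclose(m["p_ab"], m["p_ba"], rtol=1e-10)
    assert (
        m["direction_ab"].map({"hyper": "hypo", "hypo": "hyper"}) == m["direction_ba"]
    ).all()


def test_raw_p_mode_is_more_permissive(toy_cross):
    truth = toy_cross["truth"]
    s1 = z.sample_cytosine_counts(truth, "egg", 12, seed=3)
    s2 = z.sample_cytosine_counts(truth, "sperm", 12, seed=4)
    strict = dmrscan.call_dmrs(s1, s2)
    loose = dmrscan.call_dmrs(s1, s2, use_raw_p=True)
    assert len(loose) >= len(strict)


# ---------------------------------------------------------------------------
# annotation / density / overlap
# ---------------------------------------------------------------------------

def _iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_annotation_precedence():
    dmrs = pd.DataFrame(
        {
            "chrom": ["c"] * 4,
            "start": [0, 100, 200, 300],
            "end": [50, 150, 250, 350],
            "context": ["CG"] * 4,
        }
    )
    genes = _iv([("c", 0, 60), ("c", 90, 260)])
    tes = _iv([("c", 120, 140), ("c", 320, 400)])
    out = dmrscan.annotate_dmrs(dmrs, genes, tes)
    assert list(out["feature_class"]) == ["gene_body", "TE_gene", "gene_body", "TE"]


def test_annotation_matches_brute_force_oracle(rng):
    genes = _iv([("c", int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 5000, 30), rng.integers(20, 400, 30))])
    tes = _iv([("c", int(s), int(s) + int(l)) for s, l in
               zip(rng.integers(0, 5000, 30), rng.integers(10, 200, 30))])
    dmrs = pd.DataFrame(
        {
            "chrom": "c",
            "start": rng.integers(0, 5000, 100) // 50 * 50,
        }
    )
    dmrs["end"] = dmrs["start"] + 50
    dmrs["context"] = "CG"
    out = dmrscan.annotate_dmrs(dmrs, genes, tes)

    def overlaps(iv, s, e):
        return any(s < ie and e > is_ for is_, ie in zip(iv["start"], iv["end"]))

    for _, r in out.iterrows():
        g = overlaps(genes, r["start"], r["end"])
        t = overlaps(tes, r["start"], r["end"])
        want = "TE_gene" if g and t else "TE" if t else "gene_body" if g else "intergenic"
        assert r["feature_class"] == want


def test_density_informative_depth_rule():
    # 1 CG site at depth 19 in each sample -> excluded; depth 20 -> kept
    for depth, expected in ((19, 0), (20, 1)):
        s1 = _sites([("c", 1, depth, 0)])
        s2 = _sites([("c", 1, depth - 2, 2)])
        out = dmrscan.density_difference(s1, s2)
        assert len(out) == expected


def test_density_ratio_rule_in_either_sample():
    # CG levels 0.4 and 0.3: neither reaches 0.5 -> excluded
    s1 = _sites([("c", 1, 8, 12)])
    s2 = _sites([("c", 1, 6, 14)])
    assert dmrscan.density_difference(s1, s2).empty
    # one sample at 0.6 -> kept
    s1b = _sites([("c", 1, 12, 8)])
    out = dmrscan.density_difference(s1b, s2)
    assert len(out) == 1
    assert out["difference"].iloc[0] == pytest.approx(0.3)


def test_density_identical_samples_all_zero(toy_cross):
    s = z.sample_cytosine_counts(toy_cross["truth"], "egg", 15, seed=8)
    out = dmrscan.density_difference(s, s)
    assert len(out) > 0
    np.testing.assert_allclose(out["difference"], 0.0)


def test_density_histogram_is_a_frequency_table():
    h = dmrscan.density_histogram(np.array([-0.5, 0.0, 0.0, 0.5]), n_bins=4)
    assert h["frequency"].sum() == pytest.approx(1.0)
    assert len(h) == 4


def _dmr_table(keys):
    rows = [("c", s, s + 50, ctx) for s, ctx in keys]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context"])


def test_overlap_identical_and_disjoint_sets():
    a = _dmr_table([(0, "CG"), (100, "CG"), (200, "CHH")])
    same = dmrscan.overlap_dmr_sets(a, a.copy())
    assert same.fraction_shared == 1.0 and same.jaccard == 1.0
    b = _dmr_table([(400, "CG"), (500, "CHH")])
    disjoint = dmrscan.overlap_dmr_sets(a, b)
    assert disjoint.n_shared == 0 and disjoint.jaccard == 0.0
    # same interval, different context does not count as shared
    c = _dmr_table([(0, "CHG")])
    assert dmrscan.overlap_dmr_sets(_dmr_table([(0, "CG")]), c).n_shared == 0


def test_overlap_matches_pairwise_oracle(rng):
    a = _dmr_table(
        [(int(s) * 50, rng.choice(["CG", "CHH"])) for s in rng.integers(0, 60, 25)]
    ).drop_duplicates(["start", "context"])
    b = _dmr_table(
        [(int(s) * 50, rng.choice(["CG", "CHH"])) for s in rng.integers(0, 60, 25)]
    ).drop_duplicates(["start", "context"])
    res = dmrscan.overlap_dmr_sets(a, b)
    shared = 0
    for _, ra in a.iterrows():
        if any(
            (ra["context"] == rb["context"])
            and (ra["start"] < rb["end"])
            and (ra["end"] > rb["start"])
            for _, rb in b.iterrows()
        ):
            shared += 1
    assert res.n_shared == shared
    assert res.n_a_only == len(a) - shared


def test_merge_adjacent_dmrs():
    dmrs = pd.DataFrame(
        {
            "chrom": ["c"] * 3,
            "start": [0, 50, 150],
            "end": [50, 100, 200],
            "context": ["CG"] * 3,
            "direction": ["hyper"] * 3,
        }
    )
    merged = dmrscan.merge_adjacent_dmrs(dmrs)
    assert len(merged) == 2
    assert (merged["end"] - merged["start"]).tolist() == [100, 50]
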