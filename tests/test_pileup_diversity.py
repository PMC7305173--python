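"""Pileups, nucleotide diversity, pooling, subsampling, outliers, category tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdiv.diversity import (
    SampleGrouping,
    bh_adjust,
    category_enrichment,
    compare_categories,
    flag_outlier_genes,
    gene_diversity,
    site_diversity,
    site_diversity_track,
)
from microdiv.genome import GeneAnnotation
from microdiv.pileup import PileupMatrix, pool_counts, subsample_coverage


def _pm(arr, contig="c"):
    return PileupMatrix({contig: np.asarray(arr, dtype=np.int64)})


@pytest.mark.parametrize(
    "counts,expected",
    [((10, 0, 0, 0), 0.0), ((5, 5, 0, 0), 0.5), ((6, 3, 1, 0), 0.54)],
)
def test_site_diversity_values(counts, expected):
    assert site_diversity(counts) == pytest.approx(expected)


def test_site_diversity_zero_coverage_undefined():
    with pytest.raises(ValueError):
        site_diversity((0, 0, 0, 0))
    track = site_diversity_track(np.array([[0, 0, 0, 0], [1, 0, 0, 0]]))
    assert np.isnan(track[0]) and track[1] == 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1000), min_size=4, max_size=4).filter(lambda c: sum(c) > 0))
def test_site_diversity_bounds(counts):
    pi = site_diversity(counts)
    assert 0.0 <= pi <= 0.75 + 1e-12
    assert (pi == 0.0) == (sum(c > 0 for c in counts) == 1)


def test_gene_diversity_averages_over_qualifying_positions():
    arr = np.zeros((120, 4), dtype=np.int64)
    arr[:100, 0] = 10  # gene span: 100 covered positions
    arr[50] = [5, 5, 0, 0]  # one 50/50 site
    gene = GeneAnnotation("g1", "c", 0, 99)  # 99 positions, 1 polymorphic
    out = gene_diversity(_pm(arr), [gene], min_depth=5)
    # one site at pi=0.5 among 99 qualifying positions
    assert out.loc[0, "pi"] == pytest.approx(0.5 / 99)
    assert out.loc[0, "n_sites_used"] == 99


def test_gene_below_depth_floor_is_missing():
    arr = np.zeros((60, 4), dtype=np.int64)
    arr[:, 0] = 4
    gene = GeneAnnotation("g1", "c", 0, 60)
    out = gene_diversity(_pm(arr), [gene], min_depth=5)
    assert np.isnan(out.loc[0, "pi"]) and out.loc[0, "n_sites_used"] == 0


def test_gene_outside_bounds_errors():
    with pytest.raises(ValueError, match="outside pileup bounds"):
        gene_diversity(_pm(np.zeros((10, 4))), [GeneAnnotation("g", "c", 0, 30)])


def test_pooling_recomputes_rather_than_averages():
    a = _pm([[10, 0, 0, 0]])
    b = _pm([[0, 10, 0, 0]])
    pooled = pool_counts({"a": a, "b": b})["pooled"]
    # per-sample pi are both 0 but the pooled site is 50/50
    assert site_diversity(pooled.counts["c"][0]) == pytest.approx(0.5)


def test_pooling_is_associative_and_identity(rng):
    mats = {
        s: _pm(rng.integers(0, 30, size=(50, 4)))
        for s in ("s1", "s2", "s3", "s4")
    }
    one = pool_counts(mats, {"just_s1": ["s1"]})["just_s1"]
    assert np.array_equal(one.counts["c"], mats["s1"].counts["c"])
    blocks = pool_counts(mats, {"b1": ["s1", "s2"], "b2": ["s3", "s4"]})
    meadow_direct = pool_counts(mats)["pooled"]
    meadow_nested = pool_counts(blocks, {"m": ["b1", "b2"]})["m"]
    assert np.array_equal(meadow_direct.counts["c"], meadow_nested.counts["c"])


def test_pooled_pi_dominates_weighted_mean_of_sample_pi(rng):
    """Jensen: pi on pooled counts >= coverage-weighted mean of per-sample pi."""
    for _ in range(50):
        counts = rng.integers(0, 40, size=(2, 4))
        if counts.sum(axis=1).min() == 0:
            continue
        pooled_pi = site_diversity(counts.sum(axis=0))
        covs = counts.sum(axis=1)
        weighted = sum(site_diversity(c) * n for c, n in zip(counts, covs)) / covs.sum()
        assert pooled_pi >= weighted - 1e-12


def test_pool_rejects_mismatched_references():
    with pytest.raises(ValueError, match="different reference"):
        pool_counts({"a": _pm(np.zeros((5, 4))), "b": _pm(np.zeros((6, 4)))})


def test_subsampling_identity_and_determinism(rng):
    arr = rng.integers(0, 20, size=(40, 4))
    pm = _pm(arr)
    cov = arr.sum(axis=1)
    same = subsample_coverage(pm, 1, seed=0)
    assert np.array_equal(
        subsample_coverage(pm, 5, seed=3).counts["c"],
        subsample_coverage(pm, 5, seed=3).counts["c"],
    )
    exact = subsample_coverage(_pm([[3, 2, 0, 0]]), 5, seed=1)
    assert np.array_equal(exact.counts["c"][0], [3, 2, 0, 0])  # depth == target


@pytest.mark.parametrize("n", [2, 5])
def test_with_replacement_subsampling_bias_is_exact(n):
    """E[pi_hat] = ((n-1)/n) pi under multinomial resampling.

    The oracle enumerates Binomial(n, p) outcomes exactly; the estimator is
    then checked empirically over many positions.
    """
    p = 0.4
    pi_true = 2 * p * (1 - p)
    # exact enumeration oracle
    exact = sum(
        math.comb(n, k) * p**k * (1 - p) ** (n - k) * (1 - (k / n) ** 2 - ((n - k) / n) ** 2)
        for k in range(n + 1)
    )
    assert exact == pytest.approx((n - 1) / n * pi_true, abs=1e-12)
    L = 20_000
    arr = np.tile(np.array([[600, 400, 0, 0]], dtype=np.int64), (L, 1))
    sub = subsample_coverage(_pm(arr), n, seed=7, with_replacement=True)
    est = np.nanmean(site_diversity_track(sub.counts["c"]))
    assert est == pytest.approx(exact, abs=4 * 0.3 / np.sqrt(L))


def test_hypergeometric_subsampling_biases_downward():
    arr = np.tile(np.array([[500, 500, 0, 0]], dtype=np.int64), (5_000, 1))
    sub = subsample_coverage(_pm(arr), 5, seed=8)
    est = np.nanmean(site_diversity_track(sub.counts["c"]))
    assert est < 0.5  # direction of the low-coverage bias


def test_outlier_flags_are_strict():
    vals = np.full(20, 0.01)
    assert not flag_outlier_genes(vals).any()  # SD = 0, strict inequality
    vals = np.concatenate([np.full(99, 0.01), [0.05]])
    flags = flag_outlier_genes(vals, k_sd=2.5)
    mu, sd = vals.mean(), vals.std(ddof=1)
    assert vals[flags].min() > mu + 2.5 * sd
    assert flags[-1] and flags.sum() == 1


def test_category_enrichment_matches_exact_hypergeometric():
    families = pd.Series(["fam"] * 5 + ["other"] * 95)
    flags = np.zeros(100, dtype=bool)
    flags[:5] = True  # whole family flagged
    flags[5:10] = True  # plus 5 others
    out = category_enrichment(flags, families).set_index("family")
    # P(X >= 5) drawing 10 from 100 with 5 successes
    exact = sum(
        math.comb(5, k) * math.comb(95, 10 - k) for k in (5,)
    ) / math.comb(100, 10)
    assert out.loc["fam", "p"] == pytest.approx(exact, rel=1e-9)
    # family absent from flags: upper tail includes k=0, so p is large
    none = category_enrichment(np.zeros(100, dtype=bool) | (families == "other"), families)
    assert none.set_index("family").loc["fam", "p"] >= 0.5
    # flags = everything: p = 1 for every family
    allf = category_enrichment(np.ones(100, dtype=bool), families)
    assert np.allclose(allf["p"], 1.0)


def test_welch_category_comparison(rng):
    stats_df = pd.DataFrame(
        {"category": ["a"] * 3 + ["b"] * 3, "pi": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}
    )
    res = compare_categories(stats_df, "a")
    assert res["t"] == pytest.approx(0.0) and res["p"] == pytest.approx(1.0)
    big = pd.DataFrame(
        {
            "category": ["a"] * 50 + ["b"] * 500,
            "pi": np.concatenate(
                [rng.normal(0.03, 0.005, 50), rng.normal(0.02, 0.005, 500)]
            ),
        }
    )
    assert compare_categories(big, "a")["p"] < 1e-6
    tiny = pd.DataFrame({"category": ["a", "b", "b"], "pi": [1.0, 1.0, 1.0]})
    assert compare_categories(tiny, "a")["degenerate"]


def test_benjamini_hochberg_step_up():
    q = bh_adjust([0.01, 0.02, 0.04])
    assert np.allclose(q, [0.03, 0.03, 0.04])


def test_sample_grouping_levels():
    md = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "replicate": ["r1", "r1", "r2", "r2"],
            "plot": ["p1", "p1", "p2", "p2"],
            "block": ["b1", "b1", "b2", "b2"],
        }
    )
    g = SampleGrouping(md)
    assert g.groups("sample") == {s: [s] for s in md["sample_id"]}
    assert g.groups("replicate") == {"r1": ["s1", "s2"], "r2": ["s3", "s4"]}
    assert g.groups("meadow") == {"meadow": ["s1", "s2", "s3", "s4"]}
    with pytest.raises(ValueError):
        g.groups("county")
    with pytest.raises(ValueError, match="missing columns"):
        SampleGrouping(md.drop(columns=["block"]))
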