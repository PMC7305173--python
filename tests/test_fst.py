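"""Hudson F_ST estimator, gene aggregation, window scan, and sweep confirmation."""

import numpy as np
import pandas as pd
import pytest

from microdiv.diversity import bh_adjust
from microdiv.fst import (
    confirm_sweeps,
    gene_fst,
    hudson_site_fst,
    site_fst_table,
    window_scan,
)
from microdiv.genome import GeneAnnotation
from microdiv.pileup import PileupMatrix


def test_fixed_difference_gives_fst_one():
    num, den = hudson_site_fst(1.0, 100, 0.0, 100)
    assert num == pytest.approx(1.0) and den == pytest.approx(1.0)


def test_equal_frequencies_give_negative_numerator():
    num, den = hudson_site_fst(0.5, 100, 0.5, 100)
    assert num == pytest.approx(-2 * 0.25 / 99)
    assert den == pytest.approx(0.5)


def test_partial_differentiation_value():
    num, den = hudson_site_fst(0.8, 100, 0.2, 100)
    assert num == pytest.approx(0.35677, abs=1e-5)
    assert den == pytest.approx(0.68)
    assert num / den == pytest.approx(0.5247, abs=1e-4)


def test_tiny_sample_sizes_undefined():
    num, den = hudson_site_fst(0.5, 1, 0.5, 100)
    assert np.isnan(num) and np.isnan(den)


def test_ratio_of_averages_differs_from_mean_of_ratios():
    nums = np.array([0.3, -0.1])
    dens = np.array([0.5, 0.5])
    ratio_of_averages = nums.sum() / dens.sum()
    mean_of_ratios = np.mean(nums / dens)
    assert ratio_of_averages == pytest.approx(0.2)
    assert mean_of_ratios == pytest.approx(0.2)  # equal here by construction
    nums2 = np.array([0.3, 0.1])
    dens2 = np.array([0.5, 0.2])
    assert nums2.sum() / dens2.sum() == pytest.approx(4 / 7)
    assert np.mean(nums2 / dens2) == pytest.approx(0.55)


def _two_block_pileups():
    """Gene g1 has one fixed-difference site; g2 is undercovered in block 1."""
    L = 40
    b1 = np.zeros((L, 4), dtype=np.int64)
    b2 = np.zeros((L, 4), dtype=np.int64)
    b1[:20, 0] = 30
    b2[:20, 0] = 30
    b1[5] = [30, 0, 0, 0]
    b2[5] = [0, 30, 0, 0]  # fixed difference at site 5
    b1[20:, 0] = 2  # gene 2: below min_cov in block 1
    b2[20:, 0] = 30
    genes = [GeneAnnotation("g1", "c", 0, 18), GeneAnnotation("g2", "c", 21, 39)]
    snps = pd.DataFrame(
        {"contig": ["c", "c"], "pos": [5, 25], "major": ["A", "A"], "minor": ["C", "C"]}
    )
    return PileupMatrix({"c": b1}), PileupMatrix({"c": b2}), snps, genes


def test_gene_fst_fixed_difference_and_coverage_rules():
    p1, p2, snps, genes = _two_block_pileups()
    out = gene_fst(p1, p2, snps, genes, min_cov=20, coverage_sd_k=10).set_index("gene_id")
    assert out.loc["g1", "fst"] == pytest.approx(1.0)
    assert np.isnan(out.loc["g2", "fst"])  # site below 20x in one block


def test_gene_coverage_outlier_exclusion():
    L = 400
    b1 = np.zeros((L, 4), dtype=np.int64)
    b2 = np.zeros((L, 4), dtype=np.int64)
    b1[:, 0] = 30
    b2[:, 0] = 30
    b1[380:, 0] = 3000  # last gene: wildly high coverage in block 1
    genes = [GeneAnnotation(f"g{i}", "c", i * 20, i * 20 + 18) for i in range(20)]
    snps = pd.DataFrame({"contig": [], "pos": [], "major": [], "minor": []})
    out = gene_fst(
        PileupMatrix({"c": b1}), PileupMatrix({"c": b2}), snps, genes,
        coverage_sd_k=2.0,
    ).set_index("gene_id")
    assert out.loc["g19", "excluded"]
    assert not out.loc[[f"g{i}" for i in range(19)], "excluded"].any()


def test_site_table_requires_segregation_across_the_pair():
    p1, p2, snps, genes = _two_block_pileups()
    # make site 5 monomorphic across both blocks
    p2.counts["c"][5] = [30, 0, 0, 0]
    tab = site_fst_table(p1, p2, snps, min_cov=20)
    assert tab.empty


def _track(values, contig="c"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(values))],
            "contig": contig,
            "start": np.arange(len(values)) * 100,
            "fst": values,
        }
    )


def test_flat_track_yields_no_candidates(rng):
    track = _track(rng.normal(0.02, 0.01, 200))
    assert window_scan(track) == []


def test_implanted_block_is_found_and_extended(rng):
    vals = rng.normal(0.02, 0.01, 100)
    vals[40:46] = 0.5
    loci = window_scan(_track(vals))
    assert len(loci) == 1
    genes = loci[0]["gene_ids"]
    assert {"g40", "g41", "g42", "g43", "g44", "g45"} <= set(genes)
    assert loci[0]["mean_fst"] > 0.2


def test_distant_loci_are_not_merged(rng):
    vals = rng.normal(0.02, 0.01, 150)
    vals[20:26] = 0.5
    vals[76:82] = 0.5
    loci = window_scan(_track(vals))
    assert len(loci) == 2
    assert not (set(loci[0]["gene_ids"]) & set(loci[1]["gene_ids"]))


def test_missing_genes_are_skipped_in_window_composition(rng):
    vals = rng.normal(0.02, 0.01, 60).astype(object)
    vals[10:50] = np.nan  # only 20 valued genes remain
    track = _track(np.asarray(vals, dtype=float))
    assert window_scan(track) == []  # no error, NaNs skipped


def test_confirmation_accepts_joint_signal_and_rejects_fst_only(rng):
    genes = [f"g{i}" for i in range(100)]
    locus = genes[40:46]
    decoy = genes[70:76]
    records = []
    gene_of = []
    for g in genes:
        for _ in range(10):
            in_locus = g in locus
            r2 = rng.beta(8, 2) if in_locus else rng.beta(1, 8)
            records.append({"r2": r2, "Dprime": r2, "n": 40})
            gene_of.append(g)
    records = pd.DataFrame(records)
    gene_of = pd.Series(gene_of)
    pi_rows = []
    for b in ("B1", "B2"):
        for g in genes:
            pi = 0.001 if (g in locus and b == "B1") else rng.normal(0.02, 0.004)
            pi_rows.append({"gene_id": g, "block": b, "pi": pi})
    pi_df = pd.DataFrame(pi_rows)
    candidates = [
        {"contig": "c", "gene_ids": locus, "mean_fst": 0.4, "n_genes": 6},
        {"contig": "c", "gene_ids": decoy, "mean_fst": 0.4, "n_genes": 6},
    ]
    out = confirm_sweeps(candidates, records, gene_of, pi_df).set_index("locus_id")
    assert bool(out.loc[1, "confirmed"])
    assert not bool(out.loc[2, "confirmed"])
    assert out.loc[1, "dpi_B1"] < 0  # direction of the diversity change reported
    # q-values never fall below their p-values
    assert out.loc[1, "q_linkage"] >= out.loc[1, "p_linkage"]


def test_bh_on_candidate_pvalues():
    q = bh_adjust([0.001, 0.02, 0.2])
    assert np.allclose(q, [0.003, 0.03, 0.2])


def test_locus_without_linkage_records_is_unconfirmable():
    records = pd.DataFrame({"r2": [0.1] * 5, "Dprime": [0.1] * 5, "n": [40] * 5})
    gene_of = pd.Series(["g1"] * 5)
    pi_df = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(10)] * 2,
         "block": ["B1"] * 10 + ["B2"] * 10,
         "pi": 0.02}
    )
    cand = [{"contig": "c", "gene_ids": ["g7", "g8"], "mean_fst": 0.5, "n_genes": 2}]
    out = confirm_sweeps(cand, records, gene_of, pi_df)
    assert out.iloc[0]["unconfirmable"]
    assert not out.iloc[0]["confirmed"]
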