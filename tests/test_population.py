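"""Haplotype-pool generator: linkage limits, MAF targets, block structure, sweeps."""

import numpy as np
import pytest

from microdiv.fst import hudson_site_fst
from microdiv.genome import make_reference
from microdiv.linkage import linkage_stats
from microdiv.population import (
    apply_block_structure,
    balding_nichols_freqs,
    implant_sweep,
    make_population,
    true_gene_fst,
)


def _pair_r2_from_matrix(mat, i, j):
    a, b = mat[:, i], mat[:, j]
    st = linkage_stats(
        int(np.sum((a == 0) & (b == 0))),
        int(np.sum((a == 0) & (b == 1))),
        int(np.sum((a == 1) & (b == 0))),
        int(np.sum((a == 1) & (b == 1))),
    )
    return st


def test_clonal_limit_two_haplotype_classes_and_r2_one():
    """rho=0 with equal-frequency founders: every pair fully linked."""
    ref = make_reference(1, 5_000, 0, seed=0)
    pool = make_population(
        ref, 50, maf_distribution=np.full(50, 0.5), rho_sim=0.0,
        n_haplotypes=100, seed=3,
    )
    mat = pool.haplotypes["B1"]
    # exactly two haplotype classes overall
    assert len({tuple(row) for row in mat}) == 2
    for i in range(0, 49, 7):
        st = _pair_r2_from_matrix(mat, i, i + 1)
        assert st is not None
        assert st["r2"] == pytest.approx(1.0)
        assert st["four_haplotypes"] is False


def test_maf_target_recovered_under_free_recombination():
    """Site-independent draws hit the target frequency to binomial error."""
    ref = make_reference(1, 50_000, 0, seed=0)
    H = 500
    pool = make_population(
        ref, 100, maf_distribution=np.full(100, 0.3), rho_sim=1e6,
        n_haplotypes=H, seed=4,
    )
    f = pool.realized_freqs()
    sd = np.sqrt(0.3 * 0.7 / H)
    assert np.all(np.abs(f - 0.3) < 5 * sd)
    assert abs(f.mean() - 0.3) < 3 * sd / np.sqrt(100) * 10


def test_free_recombination_matches_independent_draw_oracle(rng):
    """Mean r^2 under huge rho equals that of brute-force independent sites."""
    ref = make_reference(1, 50_000, 0, seed=0)
    H = 200
    pool = make_population(ref, 60, rho_sim=1e6, n_haplotypes=H, seed=5)
    mat = pool.haplotypes["B1"]

    def mean_r2(m):
        vals = []
        for i in range(0, 58, 3):
            st = _pair_r2_from_matrix(m, i, i + 1)
            if st is not None:
                vals.append(st["r2"])
        return np.mean(vals)

    ours = mean_r2(mat)
    # independent-draw oracle with the same frequencies
    oracle = np.mean(
        [
            mean_r2((rng.random((H, 60)) < pool.global_freqs).astype(np.uint8))
            for _ in range(20)
        ]
    )
    assert ours == pytest.approx(oracle, abs=0.02)


def test_site_budget_enforced():
    ref = make_reference(1, 100, 0, seed=0)
    with pytest.raises(ValueError, match="exceeds genome length"):
        make_population(ref, 101, seed=0)
    with pytest.raises(ValueError, match="n_haplotypes"):
        make_population(ref, 10, n_haplotypes=1, seed=0)


def test_no_differentiation_at_fst_zero(rng):
    ref = make_reference(1, 30_000, 0, seed=0)
    pool = make_population(ref, 2000, rho_sim=1e5, n_haplotypes=400, seed=6)
    pool = apply_block_structure(pool, 2, 0.0, seed=7)
    assert np.array_equal(pool.block_freqs["B1"], pool.block_freqs["B2"])
    # sampled per-site Hudson numerators average at or below zero
    cov = 100
    p1 = rng.binomial(cov, pool.realized_freqs("B1")) / cov
    p2 = rng.binomial(cov, pool.realized_freqs("B2")) / cov
    num, _ = hudson_site_fst(p1, cov, p2, cov)
    assert np.nanmean(num) <= 0.002


def test_balding_nichols_extreme_divergence(rng):
    f = np.full(5000, 0.5)
    p1 = balding_nichols_freqs(f, 0.99, rng)
    p2 = balding_nichols_freqs(f, 0.99, rng)
    # most sites near-fixed for one allele in each block
    assert np.mean(np.minimum(p1, 1 - p1) < 0.05) > 0.9
    assert np.mean(np.abs(p1 - p2) > 0.9) > 0.4


def test_sweep_complete_fixes_block():
    ref = make_reference(1, 20_000, 30, seed=8)
    pool = make_population(ref, 400, rho_sim=50.0, seed=9)
    pool = apply_block_structure(pool, 2, 0.05, seed=10)
    order = [g.gene_id for g in ref.genes_sorted()]
    run = order[10:16]
    swept = implant_sweep(pool, run, "B1", 1.0, seed=11)
    genes = {g.gene_id: g for g in ref.genes_sorted()}
    lo = genes[run[0]].start
    hi = genes[run[-1]].end
    cols = np.where((swept.site_pos >= lo) & (swept.site_pos < hi))[0]
    assert len(cols) > 0
    sub = swept.haplotypes["B1"][:, cols]
    assert np.all(sub == sub[0])  # monomorphic: per-site pi = 0 in the block
    # other block untouched
    assert np.array_equal(swept.haplotypes["B2"], pool.haplotypes["B2"])
    assert swept.sweeps[0].gene_ids == run


def test_sweep_zero_strength_is_identity():
    ref = make_reference(1, 20_000, 30, seed=8)
    pool = make_population(ref, 400, rho_sim=50.0, seed=9)
    pool = apply_block_structure(pool, 2, 0.05, seed=10)
    order = [g.gene_id for g in ref.genes_sorted()]
    out = implant_sweep(pool, order[0:5], "B1", 0.0, seed=12)
    for b in pool.blocks:
        assert np.array_equal(out.haplotypes[b], pool.haplotypes[b])


def test_sweep_requires_contiguous_gene_run():
    ref = make_reference(1, 20_000, 30, seed=8)
    pool = make_population(ref, 400, rho_sim=50.0, seed=9)
    order = [g.gene_id for g in ref.genes_sorted()]
    with pytest.raises(ValueError, match="contiguous"):
        implant_sweep(pool, [order[0], order[2], order[3], order[4], order[5]], "B1", 0.5)
    with pytest.raises(ValueError, match="at least 5"):
        implant_sweep(pool, order[0:3], "B1", 0.5)


def test_sweep_elevates_truth_table_fst():
    """A strong partial sweep stands >2.5 genome SDs above mean true F_ST."""
    ref = make_reference(1, 60_000, 90, seed=13)
    pool = make_population(ref, 1200, rho_sim=200.0, seed=14)
    pool = apply_block_structure(pool, 2, 0.03, seed=15)
    order = [g.gene_id for g in ref.genes_sorted()]
    run = order[40:46]
    swept = implant_sweep(pool, run, "B1", 0.9, seed=16)
    tab = true_gene_fst(swept, "B1", "B2").set_index("gene_id")
    fst = tab["fst"].dropna()
    background = fst.drop(index=[g for g in run if g in fst.index])
    locus_mean = fst.loc[[g for g in run if g in fst.index]].mean()
    assert locus_mean > background.mean() + 2.5 * background.std(ddof=1)
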