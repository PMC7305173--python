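"""Track-level fixture studies for the sweep scan.

Full read simulation is the right substrate for the pipeline's I/O stages,
but the window scan and sweep confirmation operate on per-gene summary
tracks.  This module derives those tracks directly from a haplotype pool —
per-gene Hudson F_ST with binomially sampled block coverages, per-site-pair
linkage measured on haplotype draws, and per-block per-gene diversity from
realized frequencies — so scan behaviour can be studied at hundreds of genes
in seconds.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from .fst import hudson_site_fst
from .genome import ReferenceGenome
from .linkage import linkage_stats
from .population import (
    HaplotypePool,
    apply_block_structure,
    implant_sweep,
    make_population,
    true_gene_pi,
)


def sampled_gene_fst_track(
    pool: HaplotypePool,
    block_a: str,
    block_b: str,
    coverage: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene ratio-of-averages F_ST with binomial read sampling at each site.

    Allele counts in each block are Binomial(coverage, realized block
    frequency); Hudson components use the sampled frequencies with
    n = coverage, matching how the pipeline reads depths off the pileup.
    """
    rng = np.random.default_rng(seed)
    f1 = pool.realized_freqs(block_a)
    f2 = pool.realized_freqs(block_b)
    c1 = rng.binomial(coverage, f1)
    c2 = rng.binomial(coverage, f2)
    p1 = c1 / coverage
    p2 = c2 / coverage
    seg = (c1 + c2 > 0) & (c1 + c2 < 2 * coverage)
    num, den = hudson_site_fst(p1, coverage, p2, coverage)
    rows = []
    for gene in pool.ref.genes_sorted():
        mask = (
            (pool.site_contigs == gene.contig_id)
            & (pool.site_pos >= gene.start)
            & (pool.site_pos < gene.end)
            & seg
            & (den > 0)
        )
        den_sum = float(den[mask].sum())
        rows.append(
            {
                "gene_id": gene.gene_id,
                "contig": gene.contig_id,
                "start": gene.start,
                "n_sites": int(mask.sum()),
                "fst": float(num[mask].sum() / den_sum) if den_sum > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def haplotype_linkage_records(
    pool: HaplotypePool,
    max_distance: int = 800,
    min_obs: int = 30,
) -> tuple[pd.DataFrame, pd.Series]:
    """Site-pair LD measured on pooled haplotype draws (meadow-wide).

    Every haplotype row across blocks acts as one co-observation of the two
    sites — the idealized limit of a read pair spanning both.  Only pairs
    within ``max_distance`` bp (the span assessable from read geometry) are
    tabulated.  Returns the records plus each pair's containing gene
    (midpoint rule), aligned by index.
    """
    mats = np.vstack([pool.haplotypes[b] for b in pool.blocks])
    rows = []
    order = np.lexsort((pool.site_pos, pool.site_contigs.astype(str)))
    pos = pool.site_pos[order]
    contigs = pool.site_contigs[order]
    cols = mats[:, order]
    n_sites = len(pos)
    for i in range(n_sites):
        j = i + 1
        while j < n_sites and contigs[j] == contigs[i] and pos[j] - pos[i] <= max_distance:
            a, b = cols[:, i], cols[:, j]
            if len(a) >= min_obs:
                n11 = int(np.sum((a == 0) & (b == 0)))
                n10 = int(np.sum((a == 0) & (b == 1)))
                n01 = int(np.sum((a == 1) & (b == 0)))
                n00 = int(np.sum((a == 1) & (b == 1)))
                st = linkage_stats(n11, n10, n01, n00)
                if st is not None:
                    rows.append(
                        {
                            "contig": contigs[i],
                            "pos1": int(pos[i]),
                            "pos2": int(pos[j]),
                            "distance": int(pos[j] - pos[i]),
                            "effect_pair": None,
                            **st,
                        }
                    )
            j += 1
    records = pd.DataFrame(rows)
    gene_of = pd.Series([None] * len(records), index=records.index, dtype=object)
    if len(records):
        genes = pool.ref.genes_sorted()
        starts_by_contig: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for c in pool.ref.contigs:
            gs = [g for g in genes if g.contig_id == c]
            starts_by_contig[c] = (
                np.array([g.start for g in gs]),
                np.array([g.end for g in gs]),
                [g.gene_id for g in gs],
            )
        mids = ((records["pos1"] + records["pos2"]) // 2).to_numpy()
        for idx, (c, m) in enumerate(zip(records["contig"], mids)):
            starts, ends, ids = starts_by_contig[c]
            k = np.searchsorted(starts, m, side="right") - 1
            if k >= 0 and m < ends[k]:
                gene_of.iloc[idx] = ids[k]
    return records, gene_of


def block_gene_pi(pool: HaplotypePool) -> pd.DataFrame:
    """Long-format per-gene, per-block expected diversity from realized freqs."""
    wide = true_gene_pi(pool)
    rows = []
    for b in pool.blocks:
        sub = wide[["gene_id"]].copy()
        sub["block"] = b
        sub["pi"] = wide[f"pi_{b}"]
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def sweep_scan_study(
    ref: ReferenceGenome,
    n_sites: int = 3000,
    rho_sim: float = 40.0,
    fst_target: float = 0.05,
    n_haplotypes: int = 200,
    sweep_specs: list[tuple[int, int, float]] = (),
    decoy_specs: list[tuple[int, int]] = (),
    coverage: int = 100,
    seed: int = 0,
) -> dict:
    """Build a complete scan fixture: pool, tracks, and truth.

    ``sweep_specs`` is a list of (first_gene_index, n_genes, strength) runs
    implanted in block B1.  ``decoy_specs`` gives (first_gene_index, n_genes)
    runs that receive inflated *measured* F_ST only — emulating a mapping or
    coverage artifact that distorts the estimate without any change in the
    underlying population, so diversity and linkage at those genes remain at
    background.  A population change that genuinely shifts block frequencies
    would also raise pooled linkage (differentiation induces mixture LD), so
    an "F_ST-only" negative control is necessarily a measurement artifact.
    Returns a dict with the pool, the sampled F_ST track, haplotype linkage
    records (+ gene assignment), per-block per-gene pi, and the true sweep /
    decoy gene id lists.
    """
    pool = make_population(
        ref, n_sites, rho_sim=rho_sim, n_haplotypes=n_haplotypes, seed=seed
    )
    pool = apply_block_structure(pool, 2, fst_target, seed=seed + 1)
    order = [g.gene_id for g in ref.genes_sorted()]
    sweep_genes: list[list[str]] = []
    for k, (start, n, strength) in enumerate(sweep_specs):
        run = order[start : start + n]
        pool = implant_sweep(pool, run, "B1", strength, seed=seed + 2 + k)
        sweep_genes.append(run)
    fst_track = sampled_gene_fst_track(pool, "B1", "B2", coverage=coverage, seed=seed + 50)
    decoy_genes: list[list[str]] = []
    decoy_rng = np.random.default_rng(seed + 60)
    for start, n in decoy_specs:
        run = order[start : start + n]
        decoy_genes.append(run)
        sel = fst_track["gene_id"].isin(run)
        fst_track.loc[sel, "fst"] = decoy_rng.uniform(0.4, 0.6, size=int(sel.sum()))
    records, gene_of = haplotype_linkage_records(pool)
    return {
        "pool": pool,
        "fst_track": fst_track,
        "linkage_records": records,
        "linkage_gene": gene_of,
        "pi_per_gene_block": block_gene_pi(pool),
        "sweep_genes": sweep_genes,
        "decoy_genes": decoy_genes,
    }
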