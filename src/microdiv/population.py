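"""Synthetic haplotype populations with tunable linkage and block structure.

The population model is deliberately simple so its limits are verifiable:
haplotypes are drawn by a copy-or-refresh walk along the segregating sites.
Between adjacent sites a crossover occurs with probability set by ``rho_sim``
(the expected number of crossovers per haplotype draw across the genome); if
no crossover occurs the haplotype keeps its current lineage's allele, and on a
crossover it draws a fresh allele from the site's target frequency.  Hence

* ``rho_sim = 0``   -> a strictly two-clone population (all site pairs in
  complete linkage, r^2 = 1 when frequencies match),
* ``rho_sim`` large -> site-independent draws (linkage equilibrium).

Spatial differentiation between blocks is injected by drawing per-block allele
frequencies from a Balding-Nichols beta distribution around each site's global
frequency; its parameter F is the expected Hudson F_ST.  Truth tables always
record *realized* haplotype-matrix frequencies, so downstream recovery checks
are exact regardless of sampling noise in the generators.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BASES, GeneAnnotation, ReferenceGenome


@dataclasses.dataclass
class SweepTruth:
    """An implanted sweep locus (contiguous run of genes in one block)."""

    gene_ids: list[str]
    block_id: str
    strength: float
    contig_id: str
    start: int
    end: int


@dataclasses.dataclass
class HaplotypePool:
    """Segregating sites plus per-block haplotype matrices.

    ``haplotypes[block]`` is a (n_haplotypes x n_sites) uint8 matrix; entry 1
    means the haplotype carries the derived (alternate) allele at that site.
    """

    ref: ReferenceGenome
    site_contigs: np.ndarray  # (S,) contig ids, str
    site_pos: np.ndarray  # (S,) 0-based positions within contig
    ref_alleles: np.ndarray  # (S,) str
    alt_alleles: np.ndarray  # (S,) str
    global_freqs: np.ndarray  # (S,) target derived-allele frequency
    rho_sim: float
    haplotypes: dict[str, np.ndarray]  # block_id -> (H, S) uint8
    block_freqs: dict[str, np.ndarray]  # block_id -> (S,) Balding-Nichols target
    sweeps: list[SweepTruth] = dataclasses.field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_pos)

    @property
    def blocks(self) -> list[str]:
        return list(self.haplotypes)

    def realized_freqs(self, block: str | None = None) -> np.ndarray:
        """Derived-allele frequency per site, realized in the haplotype matrix.

        ``block=None`` pools all blocks (the meadow-wide population).
        """
        if block is not None:
            return self.haplotypes[block].mean(axis=0)
        mats = np.vstack(list(self.haplotypes.values()))
        return mats.mean(axis=0)

    def site_index(self) -> dict[tuple[str, int], int]:
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.site_contigs, self.site_pos))
        }


def _copy_refresh_haplotypes(
    freqs: np.ndarray,
    site_contigs: np.ndarray,
    site_pos: np.ndarray,
    rho_sim: float,
    n_haplotypes: int,
    genome_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw haplotypes with the copy-or-refresh walk (see module docstring).

    The walk restarts (fresh draw) at the first site of each contig.
    """
    S = len(freqs)
    H = n_haplotypes
    out = np.empty((H, S), dtype=np.uint8)
    if S == 0:
        return out
    # crossover probability for each inter-site interval
    cross_p = np.zeros(S)
    cross_p[0] = 1.0  # first site always drawn fresh
    for i in range(1, S):
        if site_contigs[i] != site_contigs[i - 1]:
            cross_p[i] = 1.0
        else:
            d = site_pos[i] - site_pos[i - 1]
            cross_p[i] = 1.0 - np.exp(-rho_sim * d / genome_length)
    fresh = rng.random((H, S)) < cross_p[None, :]
    draws = (rng.random((H, S)) < freqs[None, :]).astype(np.uint8)
    col = draws[:, 0]
    out[:, 0] = col
    for i in range(1, S):
        col = np.where(fresh[:, i], draws[:, i], col)
        out[:, i] = col
    return out


def make_population(
    ref: ReferenceGenome,
    n_sites: int,
    maf_distribution=None,
    rho_sim: float = 5.0,
    n_haplotypes: int = 200,
    seed: int = 0,
) -> HaplotypePool:
    """Sample segregating-site positions and draw an unstructured haplotype pool.

    ``maf_distribution`` is a callable ``f(rng, n) -> (n,)`` array of target
    derived-allele frequencies in (0, 1); the default draws minor allele
    frequencies uniformly on [0.05, 0.5], matching the >=5% MAF regime the SNP
    caller targets.  A fixed array of frequencies is also accepted.
    """
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    total = ref.total_length
    if n_sites > total:
        raise ValueError(f"n_sites={n_sites} exceeds genome length {total}")
    rng = np.random.default_rng(seed)

    # sample site positions without replacement across the concatenated genome
    flat = np.sort(rng.choice(total, size=n_sites, replace=False))
    contig_ids = list(ref.contigs)
    lengths = np.array([len(ref.contigs[c]) for c in contig_ids])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    which = np.searchsorted(offsets, flat, side="right") - 1
    site_contigs = np.array([contig_ids[w] for w in which], dtype=object)
    site_pos = flat - offsets[which]

    if maf_distribution is None:
        freqs = rng.uniform(0.05, 0.5, size=n_sites)
    elif callable(maf_distribution):
        freqs = np.asarray(maf_distribution(rng, n_sites), dtype=float)
    else:
        freqs = np.asarray(maf_distribution, dtype=float)
        if len(freqs) != n_sites:
            raise ValueError("maf_distribution array length must equal n_sites")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("site frequencies must lie strictly within (0, 1)")

    ref_alleles = np.array(
        [ref.contigs[c][int(p)] for c, p in zip(site_contigs, site_pos)], dtype=object
    )
    base_idx = {b: i for i, b in enumerate(BASES)}
    alt_alleles = np.empty(n_sites, dtype=object)
    for i, rb in enumerate(ref_alleles):
        choices = [b for b in BASES if b != rb]
        alt_alleles[i] = choices[rng.integers(3)]
    del base_idx

    haps = _copy_refresh_haplotypes(
        freqs, site_contigs, site_pos, rho_sim, n_haplotypes, total, rng
    )
    return HaplotypePool(
        ref=ref,
        site_contigs=site_contigs,
        site_pos=site_pos,
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
        global_freqs=freqs,
        rho_sim=rho_sim,
        haplotypes={"B1": haps},
        block_freqs={"B1": freqs.copy()},
    )


def balding_nichols_freqs(
    global_freqs: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw subpopulation frequencies Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if fst == 0:
        return global_freqs.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(global_freqs * scale, (1.0 - global_freqs) * scale)


def apply_block_structure(
    pool: HaplotypePool, n_blocks: int, fst_target: float, seed: int = 0
) -> HaplotypePool:
    """Split the pool into ``n_blocks`` differentiated blocks.

    Per-block allele frequencies follow a Balding-Nichols distribution with
    parameter ``fst_target`` around each site's global frequency; per-block
    haplotype matrices are regenerated with the pool's ``rho_sim`` so linkage
    structure is preserved within blocks.
    """
    if not (0 <= fst_target < 1):
        raise ValueError("fst_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    H = next(iter(pool.haplotypes.values())).shape[0]
    total = pool.ref.total_length
    haplotypes: dict[str, np.ndarray] = {}
    block_freqs: dict[str, np.ndarray] = {}
    for b in range(n_blocks):
        bid = f"B{b + 1}"
        f_b = balding_nichols_freqs(pool.global_freqs, fst_target, rng)
        # avoid exactly-degenerate frequencies from beta underflow
        f_b = np.clip(f_b, 1e-12, 1 - 1e-12)
        block_freqs[bid] = f_b
        haplotypes[bid] = _copy_refresh_haplotypes(
            f_b, pool.site_contigs, pool.site_pos, pool.rho_sim, H, total, rng
        )
    return dataclasses.replace(
        pool, haplotypes=haplotypes, block_freqs=block_freqs, sweeps=list(pool.sweeps)
    )


def implant_sweep(
    pool: HaplotypePool,
    gene_ids: list[str],
    block_id: str,
    sweep_strength: float,
    seed: int = 0,
) -> HaplotypePool:
    """Drive one local haplotype toward fixation over a contiguous gene run.

    Each haplotype of the designated block has its locus segment replaced by
    the segment of a single "sweep" haplotype with probability
    ``sweep_strength``.  This lowers within-block diversity at the locus,
    raises between-block differentiation, and raises within-locus linkage —
    the joint signature the sweep scan looks for.  ``sweep_strength = 1``
    renders the locus monomorphic in the block; ``0`` is the identity.
    """
    if not (0 <= sweep_strength <= 1):
        raise ValueError("sweep_strength must be in [0, 1]")
    if len(gene_ids) < 5:
        raise ValueError("a sweep locus must span at least 5 genes (the scan window)")
    order = pool.ref.genes_sorted()
    idx = {g.gene_id: i for i, g in enumerate(order)}
    try:
        positions = sorted(idx[g] for g in gene_ids)
    except KeyError as e:
        raise ValueError(f"unknown gene id {e.args[0]}") from None
    if positions != list(range(positions[0], positions[-1] + 1)):
        raise ValueError("sweep gene_ids must form a contiguous run in genome order")
    run = [order[i] for i in positions]
    if len({g.contig_id for g in run}) != 1:
        raise ValueError("sweep gene run must lie on a single contig")
    contig = run[0].contig_id
    start, end = run[0].start, run[-1].end
    if block_id not in pool.haplotypes:
        raise ValueError(f"unknown block {block_id}")

    new_haps = {b: m.copy() for b, m in pool.haplotypes.items()}
    mask = (pool.site_contigs == contig) & (pool.site_pos >= start) & (pool.site_pos < end)
    cols = np.where(mask)[0]
    if sweep_strength > 0 and len(cols) > 0:
        rng = np.random.default_rng(seed)
        mat = new_haps[block_id]
        sweep_row = mat[rng.integers(mat.shape[0])].copy()
        replace = rng.random(mat.shape[0]) < sweep_strength
        if sweep_strength >= 1.0:
            replace[:] = True
        mat[np.ix_(replace, cols)] = sweep_row[cols]
    sweeps = list(pool.sweeps) + [
        SweepTruth(
            gene_ids=[g.gene_id for g in run],
            block_id=block_id,
            strength=sweep_strength,
            contig_id=contig,
            start=start,
            end=end,
        )
    ]
    return dataclasses.replace(pool, haplotypes=new_haps, sweeps=sweeps)


# ------------------------------------------------------------------ truth


def true_site_table(pool: HaplotypePool) -> pd.DataFrame:
    """Per-site realized derived-allele frequency, overall and per block."""
    df = pd.DataFrame(
        {
            "contig": pool.site_contigs,
            "pos": pool.site_pos + 1,  # 1-based in emitted tables
            "ref": pool.ref_alleles,
            "alt": pool.alt_alleles,
            "freq": pool.realized_freqs(),
        }
    )
    for b in pool.blocks:
        df[f"freq_{b}"] = pool.realized_freqs(b)
    return df


def _gene_site_mask(pool: HaplotypePool, gene: GeneAnnotation) -> np.ndarray:
    return (
        (pool.site_contigs == gene.contig_id)
        & (pool.site_pos >= gene.start)
        & (pool.site_pos < gene.end)
    )


def true_gene_pi(pool: HaplotypePool) -> pd.DataFrame:
    """Per-gene expected nucleotide diversity, overall and per block.

    pi at a site with derived frequency p is 2p(1-p); the per-gene value
    averages over all gene positions (non-segregating positions contribute 0),
    matching the estimator's average over covered positions.
    """
    freqs = {None: pool.realized_freqs()}
    for b in pool.blocks:
        freqs[b] = pool.realized_freqs(b)
    rows = []
    for gene in pool.ref.genes_sorted():
        mask = _gene_site_mask(pool, gene)
        row: dict = {"gene_id": gene.gene_id, "n_sites": int(mask.sum())}
        for key, f in freqs.items():
            pi_sites = 2.0 * f[mask] * (1.0 - f[mask])
            label = "pi" if key is None else f"pi_{key}"
            row[label] = float(pi_sites.sum() / gene.length)
        rows.append(row)
    return pd.DataFrame(rows)


def true_gene_fst(pool: HaplotypePool, block_a: str, block_b: str) -> pd.DataFrame:
    """Per-gene Hudson F_ST (ratio of averages) from realized block frequencies.

    Frequencies are population truths, so no finite-sample correction applies:
    numerator (p1-p2)^2, denominator p1(1-p2)+p2(1-p1), summed over sites
    segregating in the pooled pair of blocks.
    """
    p1 = pool.realized_freqs(block_a)
    p2 = pool.realized_freqs(block_b)
    pooled = 0.5 * (p1 + p2)
    seg = (pooled > 0) & (pooled < 1)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    rows = []
    for gene in pool.ref.genes_sorted():
        mask = _gene_site_mask(pool, gene) & seg & (den > 0)
        n = int(mask.sum())
        fst = float(num[mask].sum() / den[mask].sum()) if n else np.nan
        rows.append({"gene_id": gene.gene_id, "n_sites": n, "fst": fst})
    return pd.DataFrame(rows)


def write_truth_tables(pool: HaplotypePool, outdir: str | Path) -> dict[str, Path]:
    """Write site, gene-pi, gene-fst and sweep truth tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["sites"] = outdir / "truth_sites.tsv"
    true_site_table(pool).to_csv(paths["sites"], sep="\t", index=False)
    paths["gene_pi"] = outdir / "truth_gene_pi.tsv"
    true_gene_pi(pool).to_csv(paths["gene_pi"], sep="\t", index=False)
    blocks = pool.blocks
    frames = []
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            df = true_gene_fst(pool, blocks[i], blocks[j])
            df.insert(1, "block_pair", f"{blocks[i]}-{blocks[j]}")
            frames.append(df)
    if frames:
        paths["gene_fst"] = outdir / "truth_gene_fst.tsv"
        pd.concat(frames).to_csv(paths["gene_fst"], sep="\t", index=False)
    paths["sweeps"] = outdir / "truth_sweeps.tsv"
    pd.DataFrame(
        [
            {
                "locus": i + 1,
                "block": s.block_id,
                "strength": s.strength,
                "contig": s.contig_id,
                "start": s.start + 1,
                "end": s.end,
                "gene_ids": ",".join(s.gene_ids),
            }
            for i, s in enumerate(pool.sweeps)
        ]
    ).to_csv(paths["sweeps"], sep="\t", index=False)
    return paths
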