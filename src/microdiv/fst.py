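"""Hudson F_ST between blocks, the moving-window differentiation scan, and
sweep confirmation.

Per-site Hudson components (with finite-sample correction, n = read coverage
at the site in each block):

    numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

Per-gene F_ST is a *ratio of averages*: numerators and denominators are summed
over the gene's qualifying sites before dividing.  Sites need >= 20x coverage
in both blocks; genes with unusual coverage (outside mean +/- 2 SD across
genes in either block) are excluded.

The scan slides a 5-gene window along each contig and flags windows whose mean
F_ST exceeds the genomic mean by more than 2.5 SD, extending hits while the
running mean stays above that cutoff.  Candidates are then confirmed only if
linkage inside the locus significantly exceeds the genomic background
(one-sided Wilcoxon rank-sum) AND per-gene diversity inside the locus differs
from the background in at least one block (Welch t-test), both after
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import bh_adjust
from .genome import GeneAnnotation
from .pileup import PileupMatrix

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def hudson_site_fst(p1, n1, p2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Hudson numerator and denominator; vectorized; n <= 1 gives NaN."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 <= 1) | (n2 <= 1)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def site_fst_table(
    pileup_b1: PileupMatrix,
    pileup_b2: PileupMatrix,
    snps: pd.DataFrame,
    min_cov: int = 20,
) -> pd.DataFrame:
    """Per-site Hudson components at called SNP sites, biallelic major/minor.

    A site qualifies when the major+minor coverage reaches ``min_cov`` in both
    blocks and the site segregates across the pooled pair of blocks.
    """
    sites = snps.drop_duplicates(subset=["contig", "pos"])
    rows = []
    for _, r in sites.iterrows():
        contig, pos = r["contig"], int(r["pos"])
        mi, ni = _BASE_IDX[r["major"]], _BASE_IDX[r["minor"]]
        c1 = pileup_b1.counts[contig][pos]
        c2 = pileup_b2.counts[contig][pos]
        n1 = int(c1[mi] + c1[ni])
        n2 = int(c2[mi] + c2[ni])
        if n1 < min_cov or n2 < min_cov:
            continue
        minor_total = int(c1[ni] + c2[ni])
        if minor_total == 0 or minor_total == n1 + n2:
            continue  # not segregating across this block pair
        p1 = c1[ni] / n1
        p2 = c2[ni] / n2
        num, den = hudson_site_fst(p1, n1, p2, n2)
        rows.append(
            {"contig": contig, "pos": pos, "p1": float(p1), "p2": float(p2),
             "n1": n1, "n2": n2, "num": float(num), "den": float(den)}
        )
    return pd.DataFrame(
        rows, columns=["contig", "pos", "p1", "p2", "n1", "n2", "num", "den"]
    )


def _gene_mean_coverage(pileup: PileupMatrix, genes: list[GeneAnnotation]) -> pd.Series:
    cov = pileup.coverage()
    return pd.Series(
        {g.gene_id: float(cov[g.contig_id][g.start : g.end].mean()) for g in genes}
    )


def gene_fst(
    pileup_b1: PileupMatrix,
    pileup_b2: PileupMatrix,
    snps: pd.DataFrame,
    genes: list[GeneAnnotation],
    min_cov: int = 20,
    coverage_sd_k: float = 2.0,
) -> pd.DataFrame:
    """Ratio-of-averages Hudson F_ST per gene between two block pileups.

    Genes whose mean coverage in either block falls outside mean +/- k SD
    (computed across genes, per block) are excluded; genes with no qualifying
    segregating site have F_ST = NaN.
    """
    site_tab = site_fst_table(pileup_b1, pileup_b2, snps, min_cov=min_cov)
    cov1 = _gene_mean_coverage(pileup_b1, genes)
    cov2 = _gene_mean_coverage(pileup_b2, genes)
    excluded = pd.Series(False, index=cov1.index)
    for cov in (cov1, cov2):
        mu, sd = cov.mean(), cov.std(ddof=1)
        if sd > 0:
            excluded |= (cov < mu - coverage_sd_k * sd) | (cov > mu + coverage_sd_k * sd)
    rows = []
    for g in genes:
        if excluded[g.gene_id]:
            rows.append(
                {"gene_id": g.gene_id, "contig": g.contig_id, "start": g.start,
                 "n_sites": 0, "fst": np.nan,
                 "mean_cov_b1": cov1[g.gene_id], "mean_cov_b2": cov2[g.gene_id],
                 "excluded": True}
            )
            continue
        if len(site_tab):
            mask = (
                (site_tab["contig"] == g.contig_id)
                & (site_tab["pos"] >= g.start)
                & (site_tab["pos"] < g.end)
            )
            sub = site_tab[mask]
        else:
            sub = site_tab
        den_sum = float(sub["den"].sum()) if len(sub) else 0.0
        fst = float(sub["num"].sum() / den_sum) if den_sum > 0 else np.nan
        rows.append(
            {"gene_id": g.gene_id, "contig": g.contig_id, "start": g.start,
             "n_sites": int(len(sub)), "fst": fst,
             "mean_cov_b1": cov1[g.gene_id], "mean_cov_b2": cov2[g.gene_id],
             "excluded": False}
        )
    return pd.DataFrame(rows)


def gene_fst_from_frequencies(
    p1: np.ndarray, n1, p2: np.ndarray, n2, gene_index: np.ndarray
) -> pd.DataFrame:
    """Ratio-of-averages F_ST per gene directly from block frequencies/depths.

    Convenience for calibration studies where allele frequencies (not pileups)
    are the natural inputs; ``gene_index`` assigns each site to a gene.
    """
    num, den = hudson_site_fst(p1, n1, p2, n2)
    df = pd.DataFrame({"gene": gene_index, "num": num, "den": den}).dropna()
    out = df.groupby("gene").agg(num=("num", "sum"), den=("den", "sum"), n_sites=("num", "size"))
    out["fst"] = out["num"] / out["den"]
    return out.reset_index()


# ------------------------------------------------------------------- scan


def window_scan(
    fst_track: pd.DataFrame, window: int = 5, k_sd: float = 2.5
) -> list[dict]:
    """Moving-window scan for runs of genes with elevated F_ST.

    ``fst_track`` needs gene_id, contig, start, fst; genes with NaN F_ST are
    skipped, so windows are runs of ``window`` consecutive *valued* genes and
    never span contigs.  The threshold is genomic mean + k_sd * SD of per-gene
    F_ST.  Overlapping extended windows merge into one locus.
    """
    valued = fst_track.dropna(subset=["fst"]).sort_values(["contig", "start"])
    vals = valued["fst"].to_numpy()
    if len(vals) < 2:
        return []
    thresh = float(np.mean(vals) + k_sd * np.std(vals, ddof=1))
    loci: list[dict] = []
    for contig, sub in valued.groupby("contig", sort=False):
        v = sub["fst"].to_numpy()
        gids = sub["gene_id"].to_numpy()
        n = len(v)
        if n < window:
            continue
        csum = np.concatenate([[0.0], np.cumsum(v)])
        intervals = []
        for i in range(n - window + 1):
            if (csum[i + window] - csum[i]) / window > thresh:
                l, r = i, i + window - 1
                grew = True
                while grew:
                    grew = False
                    if l > 0 and (csum[r + 1] - csum[l - 1]) / (r - l + 2) > thresh:
                        l -= 1
                        grew = True
                    if r < n - 1 and (csum[r + 2] - csum[l]) / (r - l + 2) > thresh:
                        r += 1
                        grew = True
                intervals.append((l, r))
        merged: list[list[int]] = []
        for l, r in sorted(intervals):
            if merged and l <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], r)
            else:
                merged.append([l, r])
        for l, r in merged:
            loci.append(
                {
                    "contig": contig,
                    "gene_ids": list(gids[l : r + 1]),
                    "mean_fst": float(v[l : r + 1].mean()),
                    "threshold": thresh,
                    "n_genes": r - l + 1,
                }
            )
    return loci


def assign_pairs_to_genes(
    records: pd.DataFrame, genes: list[GeneAnnotation]
) -> pd.Series:
    """Gene id of the gene containing a site pair's midpoint (NaN if none)."""
    out = []
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for _, r in records.iterrows():
        mid = (r["pos1"] + r["pos2"]) // 2
        hit = None
        for g in by_contig.get(r["contig"], []):
            if g.start <= mid < g.end:
                hit = g.gene_id
                break
        out.append(hit)
    return pd.Series(out, index=records.index)


def confirm_sweeps(
    candidates: list[dict],
    linkage_records: pd.DataFrame,
    linkage_gene: pd.Series,
    pi_per_gene_block: pd.DataFrame,
    snps: pd.DataFrame | None = None,
    alpha: float = 0.05,
    linkage_metric: str = "r2",
) -> pd.DataFrame:
    """Test scan candidates for the joint sweep signature.

    ``linkage_gene`` aligns with ``linkage_records`` and assigns each site pair
    to a gene (see :func:`assign_pairs_to_genes`).  ``pi_per_gene_block`` has
    columns gene_id, block, pi.  Per locus: a one-sided Wilcoxon rank-sum tests
    whether site-pair linkage inside the locus exceeds the rest of the genome,
    and per block a two-sided Welch t-test compares per-gene pi inside vs
    outside.  All p-values are BH-corrected together; a locus is confirmed iff
    q_linkage < alpha and q_pi < alpha in at least one block.
    """
    blocks = sorted(pi_per_gene_block["block"].unique())
    rows = []
    pvals: list[float] = []
    pv_index: list[tuple[int, str]] = []
    for li, cand in enumerate(candidates):
        locus_genes = set(cand["gene_ids"])
        in_mask = linkage_gene.isin(locus_genes).to_numpy()
        ld_in = linkage_records.loc[in_mask, linkage_metric].to_numpy()
        ld_out = linkage_records.loc[~in_mask, linkage_metric].to_numpy()
        row = {
            "locus_id": li + 1,
            "contig": cand["contig"],
            "gene_ids": ",".join(cand["gene_ids"]),
            "n_genes": cand["n_genes"],
            "mean_fst": cand["mean_fst"],
            "n_ld_pairs_in": len(ld_in),
            "mean_ld_in": float(np.mean(ld_in)) if len(ld_in) else np.nan,
            "mean_ld_out": float(np.mean(ld_out)) if len(ld_out) else np.nan,
        }
        if len(ld_in) == 0 or len(ld_out) == 0:
            row["p_linkage"] = np.nan
            row["unconfirmable"] = "no linkage records in locus"
        else:
            try:
                _, p = stats.mannwhitneyu(ld_in, ld_out, alternative="greater")
            except ValueError:  # all values identical
                p = 1.0
            row["p_linkage"] = float(p)
            row["unconfirmable"] = ""
            pvals.append(float(p))
            pv_index.append((li, "linkage"))
        for b in blocks:
            sub = pi_per_gene_block[pi_per_gene_block["block"] == b].dropna(subset=["pi"])
            pi_in = sub.loc[sub["gene_id"].isin(locus_genes), "pi"].to_numpy()
            pi_out = sub.loc[~sub["gene_id"].isin(locus_genes), "pi"].to_numpy()
            if len(pi_in) < 2 or len(pi_out) < 2:
                row[f"p_pi_{b}"] = np.nan
                row[f"dpi_{b}"] = np.nan
                continue
            if np.var(pi_in) == 0 and np.var(pi_out) == 0:
                p = 1.0
                t = 0.0
            else:
                t, p = stats.ttest_ind(pi_in, pi_out, equal_var=False)
            row[f"p_pi_{b}"] = float(p)
            row[f"dpi_{b}"] = float(np.mean(pi_in) - np.mean(pi_out))
            pvals.append(float(p))
            pv_index.append((li, f"pi_{b}"))
        if snps is not None and "effect" in snps.columns and "gene_id" in snps.columns:
            in_snps = snps[snps["gene_id"].isin(locus_genes)]
            n = int((in_snps["effect"] == "nonsynonymous").sum())
            s = int((in_snps["effect"] == "synonymous").sum())
            row["ns_ratio"] = n / s if s else np.nan
        rows.append(row)

    qvals = bh_adjust(pvals) if pvals else np.array([])
    qmap: dict[tuple[int, str], float] = dict(zip(pv_index, qvals))
    for li, row in enumerate(rows):
        row["q_linkage"] = qmap.get((li, "linkage"), np.nan)
        pi_qs = []
        for b in blocks:
            q = qmap.get((li, f"pi_{b}"), np.nan)
            row[f"q_pi_{b}"] = q
            if not np.isnan(q):
                pi_qs.append(q)
        row["confirmed"] = bool(
            not row["unconfirmable"]
            and not np.isnan(row["q_linkage"])
            and row["q_linkage"] < alpha
            and any(q < alpha for q in pi_qs)
        )
    return pd.DataFrame(rows)
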