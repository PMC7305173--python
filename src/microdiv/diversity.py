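"""Nucleotide diversity, sample pooling levels, outlier genes, and category tests.

Per-site nucleotide diversity is pi = 1 - (A^2 + C^2 + G^2 + T^2) where the
letters are the observed base *proportions* at that position — the expected
probability that two reads drawn at the position differ.  Per-gene diversity
is the unweighted mean of per-site pi over gene positions with coverage at or
above the depth floor (monomorphic covered positions contribute zero).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneAnnotation
from .pileup import PileupMatrix

POOLING_LEVELS = ("sample", "replicate", "plot", "block", "meadow")


def site_diversity(counts) -> float:
    """pi at one position from a length-4 count vector; coverage must be >= 1."""
    counts = np.asarray(counts, dtype=float)
    cov = counts.sum()
    if cov < 1:
        raise ValueError("site_diversity undefined at zero coverage")
    p = counts / cov
    return float(1.0 - np.dot(p, p))


def site_diversity_track(arr: np.ndarray) -> np.ndarray:
    """Vectorized pi for an (L, 4) count matrix; NaN where coverage is zero."""
    cov = arr.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = arr / cov[:, None]
        pi = 1.0 - (p * p).sum(axis=1)
    pi[cov == 0] = np.nan
    return pi


def gene_diversity(
    pileup: PileupMatrix,
    genes: list[GeneAnnotation],
    min_depth: int = 5,
) -> pd.DataFrame:
    """Per-gene mean pi over qualifying positions (coverage >= min_depth).

    Returns columns gene_id, category, pi, n_sites_used, mean_coverage,
    snp_like (count of positions with pi > 0).  Genes with no qualifying
    position get pi = NaN.
    """
    rows = []
    for gene in genes:
        arr = pileup.counts.get(gene.contig_id)
        if arr is None or gene.end > len(arr):
            raise ValueError(f"gene {gene.gene_id} outside pileup bounds")
        sub = arr[gene.start : gene.end]
        cov = sub.sum(axis=1)
        ok = cov >= min_depth
        n_used = int(ok.sum())
        if n_used:
            pi_vals = site_diversity_track(sub[ok])
            pi = float(np.mean(pi_vals))
            poly = int(np.count_nonzero(pi_vals > 0))
        else:
            pi, poly = np.nan, 0
        rows.append(
            {
                "gene_id": gene.gene_id,
                "category": gene.category,
                "pi": pi,
                "n_sites_used": n_used,
                "mean_coverage": float(cov.mean()) if len(cov) else 0.0,
                "n_polymorphic": poly,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- groupings


@dataclasses.dataclass
class SampleGrouping:
    """Maps samples to the nested spatial design (replicate/plot/block)."""

    metadata: pd.DataFrame  # columns sample_id, replicate, plot, block

    REQUIRED = ("sample_id", "replicate", "plot", "block")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.metadata["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")

    def groups(self, level: str) -> dict[str, list[str]]:
        """Group label -> sample ids at a pooling level."""
        if level not in POOLING_LEVELS:
            raise ValueError(f"level must be one of {POOLING_LEVELS}")
        md = self.metadata
        if level == "sample":
            return {s: [s] for s in md["sample_id"]}
        if level == "meadow":
            return {"meadow": list(md["sample_id"])}
        return {
            str(g): sub["sample_id"].tolist() for g, sub in md.groupby(level, sort=True)
        }


# ------------------------------------------------------ outliers & tests


def flag_outlier_genes(values, k_sd: float = 2.5) -> np.ndarray:
    """Boolean flags for values strictly above mean + k_sd * SD.

    NaNs are never flagged and are excluded from the mean/SD.
    """
    v = np.asarray(values, dtype=float)
    if np.sum(~np.isnan(v)) < 2:
        raise ValueError("need at least 2 defined values")
    mu = np.nanmean(v)
    sd = np.nanstd(v, ddof=1)
    with np.errstate(invalid="ignore"):
        return (v > mu + k_sd * sd) & ~np.isnan(v)


def category_enrichment(flags, families: pd.Series) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of families among flagged genes.

    ``flags`` is a boolean vector aligned with ``families`` (gene -> family
    label).  For each family: population N = all genes, successes K = family
    members, draws n = flagged genes, observed k = flagged family members;
    p = P(X >= k).
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(families):
        raise ValueError("flags and families must align")
    N = len(families)
    n = int(flags.sum())
    rows = []
    for fam, members in families.groupby(families):
        K = len(members)
        k = int(flags[families == fam].sum())
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"family": fam, "family_size": K, "flagged": k, "p": p})
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def compare_categories(
    gene_stats: pd.DataFrame,
    category: str,
    value_col: str = "pi",
    category_col: str = "category",
) -> dict:
    """Welch two-sample t-test of a category's per-gene values vs all others.

    Degenerate inputs (either group < 2 genes, or zero variance in both) give
    p = 1 with ``degenerate=True``.
    """
    df = gene_stats.dropna(subset=[value_col])
    a = df.loc[df[category_col] == category, value_col].to_numpy()
    b = df.loc[df[category_col] != category, value_col].to_numpy()
    if len(a) < 2 or len(b) < 2 or (np.var(a) == 0 and np.var(b) == 0):
        return {"category": category, "t": 0.0, "p": 1.0, "n_a": len(a), "n_b": len(b),
                "degenerate": True}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "category": category,
        "t": float(t),
        "p": float(p),
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "degenerate": False,
    }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
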