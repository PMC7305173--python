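"""Linkage disequilibrium from read-pair haplotypes.

Haplotypes come only from physical co-observation: two segregating sites
contribute a 2x2 table entry when one read pair covers both with Phred >= 30
bases matching the called major/minor alleles.  Site pairs spanned by fewer
than 30 informative read pairs are dropped.  From the 2x2 counts,

    D  = p_AB - p_A p_B
    r2 = D^2 / (p_A (1-p_A) p_B (1-p_B))
    D' = |D| / D_max,  D_max = min(p_A(1-p_B), (1-p_A)p_B)      if D > 0
                       D_max = min(p_A p_B, (1-p_A)(1-p_B))      if D < 0

with D = 0 mapped to D' = 0 by convention.  D' < 1 exactly when all four
haplotype classes are observed — the signal of recombination (or recurrent
mutation) between the sites.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .filtering import AlignedPair

EFFECT_SHORT = {"nonsynonymous": "N", "synonymous": "S"}


def linkage_stats(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> dict | None:
    """LD statistics from one 2x2 read-pair haplotype table.

    Returns None when either site is monomorphic within the table (the
    denominators vanish).
    """
    n = n_AB + n_Ab + n_aB + n_ab
    if n == 0:
        return None
    p_AB = n_AB / n
    p_A = (n_AB + n_Ab) / n
    p_B = (n_AB + n_aB) / n
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        return None
    D = p_AB - p_A * p_B
    r2 = D * D / (p_A * (1 - p_A) * p_B * (1 - p_B))
    if D > 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    elif D < 0:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    else:
        d_max = 0.0
    dprime = abs(D) / d_max if d_max > 0 else 0.0
    return {
        "n": n,
        "n_AB": n_AB,
        "n_Ab": n_Ab,
        "n_aB": n_aB,
        "n_ab": n_ab,
        "p_A": p_A,
        "p_B": p_B,
        "D": D,
        "r2": r2,
        "Dprime": dprime,
        "four_haplotypes": bool(min(n_AB, n_Ab, n_aB, n_ab) > 0),
    }


def extract_pair_haplotypes(
    pairs: list[AlignedPair],
    snps: pd.DataFrame,
    min_base_quality: int = 30,
    min_pairs: int = 30,
) -> pd.DataFrame:
    """Tabulate allele co-observations on read pairs for every SNP-site pair.

    ``snps`` must carry contig, pos (0-based), major, minor and (optionally)
    effect.  Bases below the quality floor, or matching neither called allele,
    are discarded.  When both mates of a pair cover the same site, mate 1 wins.
    Returns one row per retained site pair (>= ``min_pairs`` observations) with
    the 2x2 counts, LD statistics and the N/S effect pair.
    """
    unique_sites = snps.drop_duplicates(subset=["contig", "pos"])
    by_contig: dict[str, dict[int, tuple[str, str]]] = {}
    effect_at: dict[tuple[str, int], str] = {}
    for _, r in unique_sites.iterrows():
        by_contig.setdefault(r["contig"], {})[int(r["pos"])] = (r["major"], r["minor"])
    if "effect" in snps.columns:
        for (contig, pos), grp in snps.groupby(["contig", "pos"]):
            effs = set(grp["effect"]) - {"unknown"}
            # a site overlapping genes with conflicting effects is left unlabeled
            effect_at[(contig, int(pos))] = effs.pop() if len(effs) == 1 else "mixed"

    site_pos_by_contig = {
        c: np.array(sorted(d), dtype=np.int64) for c, d in by_contig.items()
    }
    tables: dict[tuple[str, int, int], np.ndarray] = {}
    for pair in pairs:
        if not pair.same_contig:
            continue
        contig = pair.contig_id
        spos = site_pos_by_contig.get(contig)
        if spos is None or len(spos) == 0:
            continue
        alleles = by_contig[contig]
        obs: dict[int, int] = {}  # site pos -> 0 (major) / 1 (minor)
        for mate in (pair.r1, pair.r2):
            if mate.seq is None:
                continue
            lo = np.searchsorted(spos, mate.start)
            hi = np.searchsorted(spos, mate.end)
            for p in spos[lo:hi]:
                p = int(p)
                if p in obs:
                    continue  # first mate's call wins on overlap
                off = p - mate.start
                if mate.quals is not None and mate.quals[off] < min_base_quality:
                    continue
                base = mate.seq[off]
                major, minor = alleles[p]
                if base == major:
                    obs[p] = 0
                elif base == minor:
                    obs[p] = 1
                # other bases: excluded from the 2x2 table
        if len(obs) < 2:
            continue
        for p1, p2 in itertools.combinations(sorted(obs), 2):
            key = (contig, p1, p2)
            t = tables.get(key)
            if t is None:
                t = tables[key] = np.zeros((2, 2), dtype=np.int64)
            t[obs[p1], obs[p2]] += 1

    rows = []
    for (contig, p1, p2), t in tables.items():
        n = int(t.sum())
        if n < min_pairs:
            continue
        st = linkage_stats(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
        if st is None:
            continue
        e1 = EFFECT_SHORT.get(effect_at.get((contig, p1), ""), None)
        e2 = EFFECT_SHORT.get(effect_at.get((contig, p2), ""), None)
        effect_pair = "".join(sorted([e1, e2])) if e1 and e2 else None
        rows.append(
            {"contig": contig, "pos1": p1, "pos2": p2, "distance": p2 - p1,
             "effect_pair": effect_pair, **st}
        )
    cols = ["contig", "pos1", "pos2", "distance", "effect_pair", "n",
            "n_AB", "n_Ab", "n_aB", "n_ab", "p_A", "p_B", "D", "r2",
            "Dprime", "four_haplotypes"]
    return pd.DataFrame(rows, columns=cols)


def linkage_decay(
    records: pd.DataFrame, bin_width: int = 50, max_distance: int | None = None
) -> pd.DataFrame:
    """Mean r2 and D' per distance bin, weighted by the pair count n."""
    if records.empty:
        raise ValueError("no linkage records")
    df = records.copy()
    if max_distance is not None:
        df = df[df["distance"] <= max_distance]
    df["bin"] = (df["distance"] // bin_width) * bin_width
    out = []
    for b, grp in df.groupby("bin", sort=True):
        w = grp["n"].to_numpy(dtype=float)
        out.append(
            {
                "bin_start": int(b),
                "bin_end": int(b) + bin_width,
                "n_site_pairs": len(grp),
                "total_read_pairs": int(w.sum()),
                "mean_r2": float(np.average(grp["r2"], weights=w)),
                "mean_Dprime": float(np.average(grp["Dprime"], weights=w)),
            }
        )
    return pd.DataFrame(out)


def stratify_by_effect(records: pd.DataFrame) -> dict:
    """Unweighted class means of r2 and D' for NN, SS and NS site pairs.

    The N:S linkage ratios use pairs whose *both* sites carry the class label;
    ratios are NaN when a class is empty.
    """
    out: dict = {}
    for cls in ("NN", "SS", "NS"):
        sub = records[records["effect_pair"] == cls]
        out[f"n_{cls}"] = len(sub)
        out[f"r2_{cls}"] = float(sub["r2"].mean()) if len(sub) else np.nan
        out[f"Dprime_{cls}"] = float(sub["Dprime"].mean()) if len(sub) else np.nan
    out["r2_N_over_S"] = (
        out["r2_NN"] / out["r2_SS"]
        if out["n_NN"] and out["n_SS"] and out["r2_SS"] > 0
        else np.nan
    )
    out["Dprime_N_over_S"] = (
        out["Dprime_NN"] / out["Dprime_SS"]
        if out["n_NN"] and out["n_SS"] and out["Dprime_SS"] > 0
        else np.nan
    )
    return out


def four_haplotype_fraction(records: pd.DataFrame) -> float:
    """Fraction of retained site pairs showing all four haplotype classes."""
    if records.empty:
        raise ValueError("no linkage records")
    return float(records["four_haplotypes"].mean())
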