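"""Null-model SNP calling and coding-effect classification.

A position is called a SNP on the pooled (by default meadow-wide) pileup when
its leading non-major allele both (a) reaches a count whose upper-tail
probability under a sequencing-error binomial is at or below the false-positive
target, and (b) has frequency at or above the minor-allele-frequency cutoff.

The error null assumes each sequenced base is wrong with probability epsilon
(default 1e-4); a *specific* alternate base then appears with epsilon/3, since
errors are spread uniformly over the three alternates.  A config switch tests
the more conservative "any non-reference base" rate instead.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .genome import BASES, GeneAnnotation, ReferenceGenome
from .pileup import PileupMatrix


def _binom_tail_threshold(coverage: int, eps_alt: float, alpha: float) -> int:
    """Smallest k with P(Binomial(coverage, eps_alt) >= k) <= alpha; coverage+1
    if no such k exists (position uncallable at this alpha)."""
    if alpha >= 1.0:
        return 1
    # sf(k-1) = P(X >= k); search the short prefix where the tail still exceeds alpha
    k = int(stats.binom.isf(alpha, coverage, eps_alt))  # P(X > k) <= alpha
    # isf gives the smallest k with sf(k) <= alpha, so threshold is k + 1 ... verify
    while k >= 1 and stats.binom.sf(k - 1, coverage, eps_alt) <= alpha:
        k -= 1
    k += 1
    while k <= coverage and stats.binom.sf(k - 1, coverage, eps_alt) > alpha:
        k += 1
    return k


def _simulated_tail_threshold(
    coverage: int, eps_alt: float, alpha: float, seed: int, n_draws: int = 2_000_000
) -> int:
    """Importance-sampled estimate of the binomial tail threshold.

    Direct resampling cannot resolve tails of order 1e-6 without >= 1e8 draws;
    drawing from a proposal binomial with an inflated error rate and
    reweighting (stratified tail estimation) resolves them with ~1e6 draws.
    """
    rng = np.random.default_rng(seed)
    q = min(0.5, max(eps_alt * 50, 20.0 / max(coverage, 1)))
    half = n_draws // 2
    # defensive mixture: half the draws from the null itself (covers the bulk),
    # half from an inflated-rate proposal (covers the far tail)
    x = np.concatenate(
        [
            rng.binomial(coverage, eps_alt, size=half),
            rng.binomial(coverage, q, size=n_draws - half),
        ]
    )
    log_p = stats.binom.logpmf(x, coverage, eps_alt)
    log_mix = np.logaddexp(
        log_p + np.log(0.5), stats.binom.logpmf(x, coverage, q) + np.log(0.5)
    )
    w = np.exp(log_p - log_mix)
    ks = np.arange(1, coverage + 1)
    order = np.argsort(x)
    x_sorted = x[order]
    w_sorted = w[order]
    cum_from_right = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
    idx = np.searchsorted(x_sorted, ks, side="left")
    tail = cum_from_right[idx] / n_draws  # P(X >= k) estimate for each k
    passing = np.where(tail <= alpha)[0]
    if len(passing) == 0:
        return coverage + 1
    return int(ks[passing[0]])


@dataclasses.dataclass
class ErrorNullModel:
    """Sequencing-error null for minimum alternate-allele counts."""

    error_rate: float = 1e-4
    alpha: float = 1e-6
    mode: str = "analytic"  # or "simulated"
    split_error_rate: bool = True  # epsilon/3 per specific alternate base
    seed: int = 0
    _cache: dict[int, int] = dataclasses.field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.error_rate < 1):
            raise ValueError("error_rate must be in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.mode not in ("analytic", "simulated"):
            raise ValueError("mode must be 'analytic' or 'simulated'")

    @property
    def eps_alt(self) -> float:
        return self.error_rate / 3.0 if self.split_error_rate else self.error_rate

    def threshold(self, coverage: int) -> int:
        """Minimum alternate count at this coverage; coverage+1 if uncallable."""
        if coverage < 1:
            raise ValueError("coverage must be >= 1")
        if coverage not in self._cache:
            if self.mode == "analytic":
                k = _binom_tail_threshold(coverage, self.eps_alt, self.alpha)
            else:
                k = _simulated_tail_threshold(
                    coverage, self.eps_alt, self.alpha, self.seed + coverage
                )
            self._cache[coverage] = k
        return self._cache[coverage]

    def thresholds(self, coverages: np.ndarray) -> np.ndarray:
        uniq = np.unique(coverages[coverages >= 1])
        mapping = {int(c): self.threshold(int(c)) for c in uniq}
        out = np.full(len(coverages), np.iinfo(np.int64).max, dtype=np.int64)
        for c, k in mapping.items():
            out[coverages == c] = k
        return out


def error_count_threshold(
    coverage: int,
    error_rate: float = 1e-4,
    alpha: float = 1e-6,
    mode: str = "analytic",
    seed: int = 0,
    split_error_rate: bool = True,
) -> int:
    """Functional wrapper around :class:`ErrorNullModel`."""
    model = ErrorNullModel(error_rate, alpha, mode, split_error_rate, seed)
    return model.threshold(coverage)


# ------------------------------------------------------------------ calling

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def call_snps(
    pileup: PileupMatrix,
    model: ErrorNullModel,
    ref: ReferenceGenome | None = None,
    maf: float = 0.05,
    classify: bool = True,
) -> pd.DataFrame:
    """Call segregating sites on a pooled pileup.

    Returns one row per (site, gene context): contig, pos (0-based internal),
    ref, major, minor, major_count, minor_count, coverage, minor_freq, effect,
    gene_id.  The MAF rule is inclusive (frequency >= maf).  Multi-allelic
    positions keep the top two alleles; remaining counts stay visible in the
    pileup.  ``uncallable`` positions (alpha unreachable at the coverage) are
    never called.
    """
    rows = []
    for contig, arr in pileup.counts.items():
        cov = arr.sum(axis=1)
        candidate = cov >= 1
        if not candidate.any():
            continue
        order = np.argsort(arr, axis=1)  # ascending
        major_idx = order[:, 3]
        minor_idx = order[:, 2]
        major_ct = np.take_along_axis(arr, major_idx[:, None], axis=1)[:, 0]
        minor_ct = np.take_along_axis(arr, minor_idx[:, None], axis=1)[:, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            minor_freq = np.where(cov > 0, minor_ct / cov, 0.0)
        thr = model.thresholds(cov)
        called = candidate & (minor_ct >= thr) & (minor_freq >= maf)
        for pos in np.where(called)[0]:
            rows.append(
                {
                    "contig": contig,
                    "pos": int(pos),
                    "ref": ref.contigs[contig][pos] if ref else "N",
                    "major": BASES[major_idx[pos]],
                    "minor": BASES[minor_idx[pos]],
                    "major_count": int(major_ct[pos]),
                    "minor_count": int(minor_ct[pos]),
                    "coverage": int(cov[pos]),
                    "minor_freq": float(minor_freq[pos]),
                }
            )
    snps = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "major", "minor",
            "major_count", "minor_count", "coverage", "minor_freq",
        ],
    )
    if classify and ref is not None and len(snps):
        snps = annotate_effects(snps, ref)
    else:
        snps["effect"] = "intergenic" if len(snps) else pd.Series(dtype=object)
        snps["gene_id"] = None
    return snps


# ------------------------------------------------------------------ effects


def classify_effect(
    contig_seq: str, gene: GeneAnnotation, pos: int, alt_base: str
) -> str:
    """Coding effect of substituting ``alt_base`` at 0-based ``pos`` in a gene.

    The alternate is substituted into the reference codon (reverse-complemented
    frame for minus-strand genes) and translated with the standard code.
    Positions in an incomplete terminal codon return "unknown".
    """
    if not (gene.start <= pos < gene.end):
        raise ValueError("position outside gene")
    offset = pos - gene.start if gene.strand == "+" else gene.end - 1 - pos
    codon_i = offset // 3
    codon_start_off = codon_i * 3
    if gene.strand == "+":
        cs = gene.start + codon_start_off
        codon = contig_seq[cs : cs + 3]
        within = pos - cs
    else:
        ce = gene.end - codon_start_off
        codon = str(Seq(contig_seq[ce - 3 : ce]).reverse_complement())
        within = ce - 1 - pos
        alt_base = str(Seq(alt_base).complement())
    if len(codon) < 3:
        return "unknown"
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    if "N" in codon or "N" in mutated:
        return "unknown"
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def annotate_effects(snps: pd.DataFrame, ref: ReferenceGenome) -> pd.DataFrame:
    """Attach effect and gene_id; overlapping genes yield one row per gene."""
    genes_by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in ref.genes_sorted():
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    out_rows = []
    for _, row in snps.iterrows():
        hits = [
            g
            for g in genes_by_contig.get(row["contig"], [])
            if g.start <= row["pos"] < g.end
        ]
        if not hits:
            r = dict(row)
            r["effect"] = "intergenic"
            r["gene_id"] = None
            out_rows.append(r)
            continue
        for g in hits:
            r = dict(row)
            r["effect"] = classify_effect(
                ref.contigs[row["contig"]], g, int(row["pos"]), row["minor"]
            )
            r["gene_id"] = g.gene_id
            out_rows.append(r)
    return pd.DataFrame(out_rows)


def population_summaries(snps: pd.DataFrame, genome_length: int) -> dict:
    """Headline per-population numbers: SNP density and the N:S ratio."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    n_sites = snps.drop_duplicates(subset=["contig", "pos"]).shape[0]
    n = int((snps["effect"] == "nonsynonymous").sum())
    s = int((snps["effect"] == "synonymous").sum())
    return {
        "n_snps": n_sites,
        "snps_per_mb": n_sites * 1e6 / genome_length,
        "n_nonsynonymous": n,
        "n_synonymous": s,
        "ns_ratio": (n / s) if s > 0 else np.nan,
    }


# --------------------------------------------------------------------- I/O


def write_snp_tsv(snps: pd.DataFrame, path: str | Path) -> None:
    out = snps.copy()
    out["pos"] = out["pos"] + 1  # 1-based in emitted tables
    out.to_csv(path, sep="\t", index=False)


def read_snp_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df


def write_vcf(snps: pd.DataFrame, ref: ReferenceGenome, path: str | Path) -> None:
    """Minimal VCF 4.2: ALT is the called minor allele, INFO carries counts."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, seq in ref.contigs.items():
            fh.write(f"##contig=<ID={c},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Pooled coverage">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Minor allele count">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        seen = set()
        for _, r in snps.iterrows():
            key = (r["contig"], r["pos"])
            if key in seen:
                continue
            seen.add(key)
            info = f"DP={r['coverage']};AC={r['minor_count']};AF={r['minor_freq']:.6g}"
            fh.write(
                f"{r['contig']}\t{r['pos'] + 1}\t.\t{r['ref']}\t{r['minor']}\t.\tPASS\t{info}\n"
            )
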