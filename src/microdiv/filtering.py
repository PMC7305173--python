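"""Read-pair filters, genome-sample inclusion, and relative abundance.

A pair passes when (1) both mates map to the same contig with an end-to-end
template span of at most 1500 bp, (2) the combined pair identity — one minus
summed edit distance over summed aligned length — is at least 96%, and
(3) at least one mate has MAPQ strictly greater than 1.  Rules are evaluated
in that order and a failing pair is attributed to the first rule it breaks.

A genome-sample combination enters the analysis only when at least half of the
genome is covered at 5x or more by passing pairs (breadth criterion).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MateAln:
    """One aligned mate: 0-based half-open reference span."""

    start: int
    end: int
    mapq: int
    edit_distance: int
    aligned_length: int
    seq: str | None = None
    quals: np.ndarray | None = None  # Phred scores per aligned base

    def __post_init__(self) -> None:
        if self.edit_distance > self.aligned_length:
            raise ValueError("edit distance cannot exceed aligned length")


@dataclasses.dataclass
class AlignedPair:
    read_id: str
    contig_id: str  # contig of mate 1
    contig_id2: str  # contig of mate 2
    r1: MateAln
    r2: MateAln

    @property
    def same_contig(self) -> bool:
        return self.contig_id == self.contig_id2

    @property
    def span(self) -> int:
        """Leftmost to rightmost aligned base across both mates."""
        return max(self.r1.end, self.r2.end) - min(self.r1.start, self.r2.start)


@dataclasses.dataclass
class FilterReport:
    total: int = 0
    fail_span: int = 0
    fail_identity: int = 0
    fail_mapq: int = 0
    passing: int = 0
    malformed: int = 0

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def pair_identity(pair: AlignedPair) -> float:
    """Combined percent identity of a read pair, as a fraction in [0, 1].

    identity = 1 - (NM1 + NM2) / (aligned_len1 + aligned_len2); indel columns
    count through the edit distance.  Soft-clipped bases are outside the
    aligned length and therefore outside the denominator.
    """
    alen = pair.r1.aligned_length + pair.r2.aligned_length
    if alen == 0:
        raise ValueError(f"pair {pair.read_id}: no aligned bases")
    return 1.0 - (pair.r1.edit_distance + pair.r2.edit_distance) / alen


def filter_pairs(
    pairs: list[AlignedPair],
    max_span: int = 1500,
    min_identity: float = 0.96,
    min_mapq: int = 1,
) -> tuple[list[AlignedPair], FilterReport]:
    """Apply the three pair rules; attribution is first-failed-rule.

    The MAPQ rule is strict: max(mate MAPQs) must exceed ``min_mapq``, so a
    pair with MAPQs (1, 1) fails at the default.
    """
    report = FilterReport()
    passing: list[AlignedPair] = []
    for pair in pairs:
        report.total += 1
        if not pair.same_contig or pair.span > max_span:
            report.fail_span += 1
            continue
        if pair_identity(pair) < min_identity:
            report.fail_identity += 1
            continue
        if max(pair.r1.mapq, pair.r2.mapq) <= min_mapq:
            report.fail_mapq += 1
            continue
        report.passing += 1
        passing.append(pair)
    return passing, report


# ------------------------------------------------------------------ SAM I/O


def read_pairs_from_sam(path: str | Path) -> tuple[list[AlignedPair], dict[str, int]]:
    """Read primary alignments from SAM/BAM and assemble them into pairs.

    Secondary and supplementary records are ignored.  Records whose mate never
    appears are counted as malformed and skipped with a warning.  Returns the
    pairs and the contig-length map from the header.
    """
    pending: dict[str, tuple[str, MateAln]] = {}
    pairs: list[AlignedPair] = []
    orphans = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        ref_lengths = dict(zip(fh.references, fh.lengths))
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            quals = np.asarray(rec.query_qualities, dtype=np.int16) if rec.query_qualities is not None else None
            mate = MateAln(
                start=rec.reference_start,
                end=rec.reference_end,
                mapq=rec.mapping_quality,
                edit_distance=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                aligned_length=rec.query_alignment_length,
                seq=rec.query_alignment_sequence,
                quals=quals,
            )
            key = rec.query_name
            if key in pending:
                contig1, first = pending.pop(key)
                if rec.is_read1:
                    pairs.append(AlignedPair(key, rec.reference_name, contig1, mate, first))
                else:
                    pairs.append(AlignedPair(key, contig1, rec.reference_name, first, mate))
            else:
                pending[key] = (rec.reference_name, mate)
    if pending:
        orphans = len(pending)
        warnings.warn(f"{path}: {orphans} unpaired primary records skipped")
    return pairs, ref_lengths


def filter_sam(
    in_path: str | Path,
    out_path: str | Path | None = None,
    max_span: int = 1500,
    min_identity: float = 0.96,
    min_mapq: int = 1,
) -> tuple[list[AlignedPair], FilterReport, dict[str, int]]:
    """Filter a SAM/BAM file; optionally write the passing records back out."""
    pairs, ref_lengths = read_pairs_from_sam(in_path)
    passing, report = filter_pairs(pairs, max_span, min_identity, min_mapq)
    if out_path is not None:
        keep = {p.read_id for p in passing}
        with pysam.AlignmentFile(str(in_path), "r", check_sq=False) as src:
            with pysam.AlignmentFile(str(out_path), "w", template=src) as dst:
                for rec in src:
                    if rec.query_name in keep and not rec.is_secondary and not rec.is_supplementary:
                        dst.write(rec)
    logger.info(
        "%s: %d/%d pairs pass (span fail %d, identity fail %d, mapq fail %d)",
        in_path, report.passing, report.total,
        report.fail_span, report.fail_identity, report.fail_mapq,
    )
    return passing, report, ref_lengths


# ------------------------------------------------- coverage and inclusion


def coverage_depth(
    pairs: list[AlignedPair], ref_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-position read-base coverage from aligned mate spans (no base-quality
    mask; this is the genome-breadth coverage, not the pileup)."""
    if not ref_lengths:
        raise ValueError("empty genome: no contigs")
    cov = {c: np.zeros(l + 1, dtype=np.int64) for c, l in ref_lengths.items()}
    for pair in pairs:
        for contig, mate in ((pair.contig_id, pair.r1), (pair.contig_id2, pair.r2)):
            d = cov[contig]
            d[mate.start] += 1
            d[mate.end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in cov.items()}


def breadth_at_depth(
    coverage: dict[str, np.ndarray], min_depth: int = 5
) -> float:
    """Fraction of genome positions with coverage >= min_depth."""
    total = sum(len(v) for v in coverage.values())
    if total == 0:
        raise ValueError("empty genome: no positions")
    covered = sum(int(np.count_nonzero(v >= min_depth)) for v in coverage.values())
    return covered / total


def select_genome_samples(
    breadth: pd.DataFrame, min_breadth: float = 0.5
) -> pd.DataFrame:
    """Mark genome-sample combinations passing the breadth criterion.

    ``breadth`` needs columns genome, sample, breadth; the returned frame adds
    a boolean ``include`` (breadth >= min_breadth, inclusive).  The number of
    rows is the number of evaluated candidates (n_genomes x n_samples when the
    table is complete).
    """
    out = breadth.copy()
    out["include"] = out["breadth"] >= min_breadth
    return out


def relative_abundance(
    mapped_reads: pd.DataFrame, total_reads: pd.Series | dict[str, int]
) -> pd.DataFrame:
    """Relative DNA abundance: reads mapped to each genome / total sample reads.

    ``mapped_reads`` has columns genome, sample, n_mapped.  Totals of zero are
    an error.
    """
    totals = pd.Series(total_reads)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"non-positive read totals for samples: {bad}")
    out = mapped_reads.copy()
    out["abundance"] = out["n_mapped"] / out["sample"].map(totals)
    if (out["abundance"] < 0).any() or (out["abundance"] > 1).any():
        raise ValueError("mapped read counts exceed sample totals")
    return out
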