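"""Simulate aligned paired reads from a haplotype pool.

Reads are emitted already aligned (their true coordinates are known by
construction), as coordinate-sorted SAM with proper-pair flags, MAPQ, NM tags
and per-base qualities.  The geometry mimics 2 x 250 bp sequencing trimmed to
<= 200 bp, with an inter-mate gap drawn from a truncated normal (median 383 bp)
and a hard template-span cap matching the read-pair filter's 1500 bp rule.

Substitution errors are injected per base (uniform over the three alternate
bases) at the same rate the SNP null model assumes.  A small fraction of decoy
pairs violating the span / identity / MAPQ filters is injected so that the
filtering stage has true negatives to remove.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import BASES
from .population import HaplotypePool, write_truth_tables

_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}


@dataclasses.dataclass(frozen=True)
class SampleInfo:
    """One sequencing sample and its position in the spatial design."""

    sample_id: str
    block: str
    plot: str
    depth: str = "d1"
    replicate: str = "r1"


def default_sample_plan(
    blocks: list[str], plots_per_block: int = 2, samples_per_plot: int = 2
) -> list[SampleInfo]:
    """Nested design: blocks contain plots, plots contain replicate samples."""
    plan = []
    for b in blocks:
        for p in range(1, plots_per_block + 1):
            plot = f"{b}P{p}"
            for s in range(1, samples_per_plot + 1):
                plan.append(
                    SampleInfo(
                        sample_id=f"{plot}S{s}",
                        block=b,
                        plot=plot,
                        depth=f"d{s}",
                        replicate=f"{plot}r{s}",
                    )
                )
    return plan


def write_metadata(plan: list[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "plot": s.plot,
                "block": s.block,
                "depth": s.depth,
                "replicate": s.replicate,
            }
            for s in plan
        ]
    ).to_csv(path, sep="\t", index=False)


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_IDX_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BYTE_TO_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_IDX[_b] = _i


def simulate_reads(
    pool: HaplotypePool,
    sample_plan: list[SampleInfo],
    outdir: str | Path,
    coverage_per_sample: float = 10.0,
    read_length: int = 200,
    insert_median: float = 383.0,
    insert_sd: float = 120.0,
    max_span: int = 1500,
    error_rate: float = 1e-4,
    low_quality_fraction: float = 0.02,
    decoy_fraction: float = 0.01,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one coordinate-sorted SAM per sample; returns sample -> path.

    ``coverage_per_sample`` is the expected mean depth; the pair count per
    contig is Poisson.  Raises ``ValueError`` if no proper pair fits a contig.
    """
    if coverage_per_sample <= 0:
        raise ValueError("coverage_per_sample must be positive")
    ref = pool.ref
    contig_ids = list(ref.contigs)
    lengths = np.array([len(ref.contigs[c]) for c in contig_ids])
    if np.any(lengths < 2 * read_length):
        raise ValueError(
            f"contig shorter than one proper pair (2 x {read_length} bp); "
            "reduce read_length or lengthen contigs"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in zip(contig_ids, lengths)],
        }
    )
    ref_arrays = {c: _seq_array(ref.contigs[c]) for c in contig_ids}
    # per-contig site positions and column indices, for fast in-window lookup
    site_pos_by_contig: dict[str, np.ndarray] = {}
    site_col_by_contig: dict[str, np.ndarray] = {}
    for c in contig_ids:
        mask = pool.site_contigs == c
        site_pos_by_contig[c] = pool.site_pos[mask].astype(np.int64)
        site_col_by_contig[c] = np.where(mask)[0]
    alt_bytes = np.array([ord(a) for a in pool.alt_alleles], dtype=np.uint8)

    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    q_hi, q_lo = 37, 20
    for sample in sample_plan:
        if sample.block not in pool.haplotypes:
            raise ValueError(f"sample {sample.sample_id}: unknown block {sample.block}")
        haps = pool.haplotypes[sample.block]
        records = []
        for ci, contig in enumerate(contig_ids):
            L = int(lengths[ci])
            n_pairs = rng.poisson(coverage_per_sample * L / (2 * read_length))
            refarr = ref_arrays[contig]
            spos = site_pos_by_contig[contig]
            scol = site_col_by_contig[contig]
            for p in range(n_pairs):
                hap_row = haps[rng.integers(haps.shape[0])]
                decoy = rng.random() < decoy_fraction
                decoy_mode = rng.integers(3) if decoy else -1
                span_cap = min(max_span, L)
                if decoy and decoy_mode == 0 and L > max_span:
                    # span-violating decoy: template longer than the filter cap
                    span = int(rng.integers(max_span + 1, min(2 * max_span, L) + 1))
                else:
                    if decoy and decoy_mode == 0:
                        decoy_mode = 1  # contig too short for a span decoy
                    gap = rng.normal(insert_median, insert_sd)
                    gap = float(np.clip(gap, 0, span_cap - 2 * read_length))
                    span = 2 * read_length + int(round(gap))
                start = int(rng.integers(0, L - span + 1))
                name = f"{sample.sample_id}:{contig}:{p}"
                mate_starts = (start, start + span - read_length)
                mate_recs = []
                for mi, ms in enumerate(mate_starts):
                    seq = refarr[ms : ms + read_length].copy()
                    # substitute derived alleles carried by this haplotype
                    lo = np.searchsorted(spos, ms)
                    hi = np.searchsorted(spos, ms + read_length)
                    if hi > lo:
                        idx = slice(lo, hi)
                        carry = hap_row[scol[idx]] == 1
                        at = spos[idx][carry] - ms
                        seq[at] = alt_bytes[scol[idx]][carry]
                    # sequencing errors, uniform over the 3 alternate bases
                    err_rate = error_rate
                    if decoy and decoy_mode == 1:
                        err_rate = 0.08  # low-identity decoy
                    if err_rate > 0:
                        errs = np.where(rng.random(read_length) < err_rate)[0]
                        if len(errs):
                            shift = rng.integers(1, 4, size=len(errs))
                            cur = _BYTE_TO_IDX[seq[errs]].astype(np.int64)
                            seq[errs] = _IDX_TO_BYTE[(cur + shift) % 4]
                    nm = int(np.count_nonzero(seq != refarr[ms : ms + read_length]))
                    qual = np.full(read_length, q_hi, dtype=np.uint8)
                    low = rng.random(read_length) < low_quality_fraction
                    qual[low] = q_lo
                    a = pysam.AlignedSegment(header)
                    a.query_name = name
                    a.reference_id = ci
                    a.reference_start = ms
                    a.cigarstring = f"{read_length}M"
                    a.query_sequence = seq.tobytes().decode()
                    a.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in qual)
                    )
                    a.mapping_quality = int(rng.integers(0, 2)) if (decoy and decoy_mode == 2) else 42
                    flag = 0x1 | 0x2 | 0x40 if mi == 0 else 0x1 | 0x2 | 0x80
                    flag |= 0x20 if mi == 0 else 0x10
                    a.flag = flag
                    a.next_reference_id = ci
                    a.set_tag("NM", nm)
                    mate_recs.append(a)
                mate_recs[0].next_reference_start = mate_recs[1].reference_start
                mate_recs[1].next_reference_start = mate_recs[0].reference_start
                mate_recs[0].template_length = span
                mate_recs[1].template_length = -span
                records.extend(mate_recs)
        records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
        path = outdir / f"{sample.sample_id}.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for a in records:
                fh.write(a)
        paths[sample.sample_id] = path
    return paths


def simulate_study(
    pool: HaplotypePool,
    sample_plan: list[SampleInfo],
    outdir: str | Path,
    seed: int = 0,
    **read_kwargs,
) -> dict[str, Path]:
    """Write the full synthetic-study bundle: reference FASTA + gene calls,
    per-sample SAMs, sample metadata, and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pool.ref.write_fasta(outdir / "reference.fasta")
    pool.ref.write_gff3(outdir / "genes.gff3")
    pool.ref.write_prodigal_tsv(outdir / "genes.tsv")
    write_metadata(sample_plan, outdir / "metadata.tsv")
    sam_paths = simulate_reads(pool, sample_plan, outdir / "alignments", seed=seed, **read_kwargs)
    write_truth_tables(pool, outdir / "truth")
    out = {"reference": outdir / "reference.fasta", "gff": outdir / "genes.gff3",
           "metadata": outdir / "metadata.tsv"}
    out.update(sam_paths)
    return out
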