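"""Base-count pileups: construction, pooling, and coverage subsampling.

The pileup is the substrate for every population statistic: per position, the
counts of A, C, G and T contributed by Phred >= 30 bases of filtered read
pairs.  Pooling across samples sums counts position-wise — statistics are then
recomputed on the pooled counts, never averaged from per-sample values.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import AlignedPair
from .genome import BASES

_BYTE_TO_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_IDX[_b] = _i


@dataclasses.dataclass
class PileupMatrix:
    """Per-contig (length x 4) base-count matrices, columns ordered A,C,G,T."""

    counts: dict[str, np.ndarray]
    provenance: str = "sample"

    def __post_init__(self) -> None:
        for c, arr in self.counts.items():
            if arr.ndim != 2 or arr.shape[1] != 4:
                raise ValueError(f"contig {c}: counts must be (L, 4)")
            if (arr < 0).any():
                raise ValueError(f"contig {c}: negative counts")

    @classmethod
    def zeros(cls, ref_lengths: dict[str, int], provenance: str = "sample") -> "PileupMatrix":
        return cls(
            {c: np.zeros((l, 4), dtype=np.int64) for c, l in ref_lengths.items()},
            provenance=provenance,
        )

    @classmethod
    def from_pairs(
        cls,
        pairs: list[AlignedPair],
        ref_lengths: dict[str, int],
        min_baseq: int = 30,
        provenance: str = "sample",
    ) -> "PileupMatrix":
        """Accumulate Q >= min_baseq bases of (already filtered) pairs."""
        pm = cls.zeros(ref_lengths, provenance=provenance)
        skipped = 0
        for pair in pairs:
            for contig, mate in ((pair.contig_id, pair.r1), (pair.contig_id2, pair.r2)):
                if mate.seq is None:
                    skipped += 1
                    continue
                seq = np.frombuffer(mate.seq.encode(), dtype=np.uint8)
                if len(seq) != mate.end - mate.start:
                    skipped += 1  # gapped alignment: not produced by this pipeline
                    continue
                idx = _BYTE_TO_IDX[seq]
                ok = idx >= 0
                if mate.quals is not None and min_baseq > 0:
                    ok &= np.asarray(mate.quals) >= min_baseq
                pos = np.arange(mate.start, mate.end)[ok]
                np.add.at(pm.counts[contig], (pos, idx[ok].astype(np.int64)), 1)
        if skipped:
            warnings.warn(f"{skipped} mates lacked sequence or had gapped alignments; skipped")
        return pm

    def coverage(self) -> dict[str, np.ndarray]:
        return {c: arr.sum(axis=1) for c, arr in self.counts.items()}

    def copy(self) -> "PileupMatrix":
        return PileupMatrix({c: a.copy() for c, a in self.counts.items()}, self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Long-format TSV-ready table (1-based positions)."""
        frames = []
        for c, arr in self.counts.items():
            df = pd.DataFrame(arr, columns=list(BASES))
            df.insert(0, "pos", np.arange(1, len(arr) + 1))
            df.insert(0, "contig", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def write_tsv(self, path: str | Path, omit_empty: bool = True) -> None:
        df = self.to_frame()
        if omit_empty:
            df = df[df[list(BASES)].sum(axis=1) > 0]
        df.to_csv(path, sep="\t", index=False)


def pool_counts(
    pileups: dict[str, PileupMatrix],
    groups: dict[str, list[str]] | None = None,
    provenance: str = "pooled",
) -> dict[str, PileupMatrix]:
    """Sum pileups position-wise within each group of samples.

    ``groups`` maps group label -> member sample ids; ``None`` pools everything
    into one group named by ``provenance``.  All pileups must share contigs and
    lengths.
    """
    if groups is None:
        groups = {provenance: list(pileups)}
    shapes = None
    out: dict[str, PileupMatrix] = {}
    for gname, members in groups.items():
        acc: dict[str, np.ndarray] | None = None
        for s in members:
            pm = pileups[s]
            sig = {c: a.shape for c, a in pm.counts.items()}
            if shapes is None:
                shapes = sig
            elif sig != shapes:
                raise ValueError(f"pileup {s} is on a different reference")
            if acc is None:
                acc = {c: a.astype(np.int64).copy() for c, a in pm.counts.items()}
            else:
                for c in acc:
                    acc[c] += pm.counts[c]
        if acc is None:
            raise ValueError(f"group {gname} has no samples")
        out[gname] = PileupMatrix(acc, provenance=gname)
    return out


def subsample_coverage(
    pileup: PileupMatrix,
    target_depth: int,
    seed: int = 0,
    with_replacement: bool = False,
) -> PileupMatrix:
    """Subsample each position's base counts to a fixed depth.

    Positions with coverage below ``target_depth`` are dropped (zeroed);
    positions at exactly ``target_depth`` are kept as-is when sampling without
    replacement.  Without-replacement draws are hypergeometric (a draw of
    ``target_depth`` sequenced bases from the observed ones); the
    with-replacement (multinomial) mode has the exact E[pi_hat] = ((n-1)/n) pi
    bias and exists for bias verification.
    """
    if target_depth < 1:
        raise ValueError("target_depth must be >= 1")
    rng = np.random.default_rng(seed)
    new: dict[str, np.ndarray] = {}
    for contig, arr in pileup.counts.items():
        cov = arr.sum(axis=1)
        out = np.zeros_like(arr)
        eligible = np.where(cov >= target_depth)[0]
        for i in eligible:
            row = arr[i]
            if not with_replacement:
                if cov[i] == target_depth:
                    out[i] = row
                else:
                    out[i] = rng.multivariate_hypergeometric(row, target_depth)
            else:
                out[i] = rng.multinomial(target_depth, row / cov[i])
        new[contig] = out
    return PileupMatrix(new, provenance=f"{pileup.provenance}@{target_depth}x")
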