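"""Reference genomes and gene annotations.

A "representative genome" is the single assembled genome against which all
samples of one species population are mapped.  Genes are simple intervals
(0-based, half-open internally); coding genes have lengths divisible by 3 so
that synonymous/nonsynonymous classification is well defined everywhere.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

BASES = "ACGT"

GENE_CATEGORIES = ("ribosomal", "biosynthetic", "other")


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    """One gene call: 0-based half-open interval on a contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    category: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class ReferenceGenome:
    """Contigs plus gene annotations for one representative genome."""

    contigs: dict[str, str]  # contig_id -> sequence (A/C/G/T)
    genes: list[GeneAnnotation]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if len(seq) == 0:
                raise ValueError(f"contig {cid} is empty")
        for g in self.genes:
            if g.contig_id not in self.contigs:
                raise ValueError(f"gene {g.gene_id} references unknown contig {g.contig_id}")
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(f"gene {g.gene_id} extends past end of contig {g.contig_id}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs.items()}

    def genes_sorted(self) -> list[GeneAnnotation]:
        """Genes ordered by contig (input order) then start coordinate."""
        order = {cid: i for i, cid in enumerate(self.contigs)}
        return sorted(self.genes, key=lambda g: (order[g.contig_id], g.start))

    # ---------------------------------------------------------------- I/O

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for cid, seq in self.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        """GFF3 CDS records; coordinates 1-based inclusive per the standard."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for cid, seq in self.contigs.items():
                fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
            for g in self.genes_sorted():
                attrs = f"ID={g.gene_id};category={g.category}"
                fh.write(
                    f"{g.contig_id}\tmicrodiv\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
                )

    def write_prodigal_tsv(self, path: str | Path) -> None:
        """Prodigal-style tabular gene calls (1-based inclusive coordinates)."""
        with open(path, "w") as fh:
            fh.write("gene_id\tcontig\tstart\tend\tstrand\tcategory\n")
            for g in self.genes_sorted():
                strand = "1" if g.strand == "+" else "-1"
                fh.write(f"{g.gene_id}\t{g.contig_id}\t{g.start + 1}\t{g.end}\t{strand}\t{g.category}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read CDS records from a GFF3 file into 0-based half-open annotations."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] not in ("CDS", "gene"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                GeneAnnotation(
                    gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}-{fields[4]}"),
                    contig_id=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                    category=attrs.get("category", "other"),
                )
            )
    return genes


def load_reference(fasta: str | Path, gff: str | Path | None = None) -> ReferenceGenome:
    contigs = read_fasta(fasta)
    genes = read_gff3(gff) if gff is not None else []
    return ReferenceGenome(contigs=contigs, genes=genes)


def make_reference(
    n_contigs: int,
    contig_length: int,
    n_genes: int,
    seed: int,
    gene_length: int = 300,
    min_gap: int = 20,
    category_weights: dict[str, float] | None = None,
) -> ReferenceGenome:
    """Generate a random reference genome with tiled, non-overlapping genes.

    Genes are distributed as evenly as possible over contigs and placed left to
    right with random intergenic gaps of at least ``min_gap`` bp.  ``gene_length``
    must be divisible by 3.  Raises ``ValueError`` when the requested genes do
    not fit on the contigs.
    """
    if n_contigs < 1 or contig_length < 1:
        raise ValueError("need at least one contig of positive length")
    if gene_length % 3 != 0:
        raise ValueError("gene_length must be divisible by 3")
    rng = np.random.default_rng(seed)
    if category_weights is None:
        category_weights = {"ribosomal": 0.06, "biosynthetic": 0.10, "other": 0.84}
    cats = list(category_weights)
    cat_p = np.array([category_weights[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()

    contigs: dict[str, str] = {}
    for i in range(n_contigs):
        seq = "".join(rng.choice(list(BASES), size=contig_length))
        contigs[f"contig_{i + 1}"] = seq

    # even split of genes over contigs
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1

    genes: list[GeneAnnotation] = []
    gid = 0
    for i, cid in enumerate(contigs):
        k = per_contig[i]
        if k == 0:
            continue
        needed = k * gene_length + (k + 1) * min_gap
        if needed > contig_length:
            raise ValueError(
                f"cannot place {k} genes of {gene_length} bp with gaps >= {min_gap} bp "
                f"on a {contig_length} bp contig (needs {needed} bp)"
            )
        slack = contig_length - k * gene_length - (k + 1) * min_gap
        # distribute the slack randomly over the k+1 gaps
        extra = rng.multinomial(slack, np.ones(k + 1) / (k + 1))
        pos = 0
        for j in range(k):
            pos += min_gap + int(extra[j])
            gid += 1
            genes.append(
                GeneAnnotation(
                    gene_id=f"gene_{gid:05d}",
                    contig_id=cid,
                    start=pos,
                    end=pos + gene_length,
                    strand="+" if rng.random() < 0.5 else "-",
                    category=str(rng.choice(cats, p=cat_p)),
                )
            )
            pos += gene_length
    return ReferenceGenome(contigs=contigs, genes=genes)
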