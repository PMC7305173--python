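"""End-to-end orchestration: filter -> profile -> call SNPs -> linkage -> F_ST scan."""

from __future__ import annotations

import itertools
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .diversity import SampleGrouping, gene_diversity
from .filtering import breadth_at_depth, coverage_depth, filter_sam, select_genome_samples
from .fst import assign_pairs_to_genes, confirm_sweeps, gene_fst, window_scan
from .genome import load_reference
from .linkage import extract_pair_haplotypes, four_haplotype_fraction, linkage_decay
from .pileup import PileupMatrix, pool_counts
from .snps import ErrorNullModel, call_snps, population_summaries, write_snp_tsv, write_vcf

logger = logging.getLogger(__name__)


STAGES = ("filter", "profile", "call-snps", "linkage", "fst-scan")


def run_all(config: RunConfig, stop_after: str | None = None) -> dict:
    """Execute the pipeline and return the run report (also written as JSON).

    Stages, in order: per-sample read-pair filtering and breadth-based
    inclusion; Q30 pileups pooled at every spatial level with per-gene
    diversity; meadow-wide SNP calling under the error null; read-pair
    linkage; per-block-pair gene F_ST, window scan, and sweep confirmation.
    ``stop_after`` truncates the run after the named stage, so single-stage
    invocations recompute the same artifacts the full run writes.  All outputs
    are TSV under ``config.outdir``.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config_hash": config.digest(), "stages": {}}

    ref = load_reference(config.reference, config.genes)
    genes = ref.genes_sorted()
    metadata = pd.read_csv(config.metadata, sep="\t")
    required = {"sample_id", "plot", "block", "replicate"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata {config.metadata} missing columns: {sorted(missing)}")
    grouping = SampleGrouping(metadata)

    # ---------------------------------------------------------- filtering
    aln_dir = Path(config.alignments)
    pairs_by_sample: dict[str, list] = {}
    filter_rows = []
    breadth_rows = []
    ref_lengths = ref.contig_lengths()
    for sample in metadata["sample_id"]:
        sam = aln_dir / f"{sample}.sam"
        if not sam.exists():
            sam = aln_dir / f"{sample}.bam"
        if not sam.exists():
            raise FileNotFoundError(f"no alignment file for sample {sample} in {aln_dir}")
        passing, rep, _ = filter_sam(
            sam, None, config.max_span, config.min_identity, config.min_mapq
        )
        pairs_by_sample[sample] = passing
        filter_rows.append({"sample_id": sample, **rep.as_dict()})
        cov = coverage_depth(passing, ref_lengths)
        breadth_rows.append(
            {
                "genome": "reference",
                "sample": sample,
                "breadth": breadth_at_depth(cov, config.breadth_depth),
            }
        )
    pd.DataFrame(filter_rows).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    inclusion = select_genome_samples(pd.DataFrame(breadth_rows), config.min_breadth)
    inclusion.to_csv(outdir / "inclusion.tsv", sep="\t", index=False)
    included = inclusion.loc[inclusion["include"], "sample"].tolist()
    report["stages"]["filter"] = {
        "samples": len(pairs_by_sample),
        "pairs_pass": int(sum(r["passing"] for r in filter_rows)),
        "pairs_total": int(sum(r["total"] for r in filter_rows)),
        "samples_included": len(included),
        "candidates_evaluated": len(inclusion),
    }
    if not included:
        raise RuntimeError("no sample passed the breadth criterion")

    if stop_after == "filter":
        report["runtime_s"] = round(time.time() - t0, 2)
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    # ------------------------------------------------------------ pileups
    pileups = {
        s: PileupMatrix.from_pairs(pairs_by_sample[s], ref_lengths, config.min_baseq, s)
        for s in included
    }
    md_included = metadata[metadata["sample_id"].isin(included)]
    grouping = SampleGrouping(md_included)
    pooled: dict[str, dict[str, PileupMatrix]] = {}
    for level in ("sample", "replicate", "plot", "block", "meadow"):
        pooled[level] = pool_counts(pileups, grouping.groups(level))
    meadow = pooled["meadow"]["meadow"]

    # ------------------------------------------------- per-gene diversity
    frames = []
    for level, groups in pooled.items():
        for gname, pm in groups.items():
            df = gene_diversity(pm, genes, config.min_depth)
            df.insert(0, "group", gname)
            df.insert(0, "scale", level)
            frames.append(df)
    gene_stats = pd.concat(frames, ignore_index=True)
    gene_stats.to_csv(outdir / "gene_stats.tsv", sep="\t", index=False)
    report["stages"]["profile"] = {
        "genes": len(genes),
        "levels": {lv: len(g) for lv, g in pooled.items()},
    }

    if stop_after == "profile":
        report["runtime_s"] = round(time.time() - t0, 2)
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    # --------------------------------------------------------------- SNPs
    model = ErrorNullModel(
        config.error_rate, config.fpr, config.snp_mode, config.split_error_rate, config.seed
    )
    snps = call_snps(meadow, model, ref, config.maf)
    write_snp_tsv(snps, outdir / "snps.tsv")
    write_vcf(snps, ref, outdir / "snps.vcf")
    summ = population_summaries(snps, ref.total_length)
    report["stages"]["snps"] = summ

    if stop_after == "call-snps":
        report["runtime_s"] = round(time.time() - t0, 2)
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    # ------------------------------------------------------------ linkage
    all_pairs = [p for s in included for p in pairs_by_sample[s]]
    records = extract_pair_haplotypes(all_pairs, snps, config.min_baseq, config.min_pairs)
    rec_out = records.copy()
    rec_out[["pos1", "pos2"]] += 1
    rec_out.to_csv(outdir / "linkage.tsv", sep="\t", index=False)
    if len(records):
        linkage_decay(records, config.ld_bin_width).to_csv(
            outdir / "linkage_decay.tsv", sep="\t", index=False
        )
        report["stages"]["linkage"] = {
            "site_pairs": len(records),
            "mean_r2": float(records["r2"].mean()),
            "mean_Dprime": float(records["Dprime"].mean()),
            "four_haplotype_fraction": four_haplotype_fraction(records),
        }
    else:
        report["stages"]["linkage"] = {"site_pairs": 0}

    if stop_after == "linkage":
        report["runtime_s"] = round(time.time() - t0, 2)
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    # ------------------------------------------------------- F_ST & scan
    blocks = sorted(pooled["block"])
    pi_rows = []
    for b in blocks:
        df = gene_diversity(pooled["block"][b], genes, config.min_depth)
        df["block"] = b
        pi_rows.append(df[["gene_id", "block", "pi"]])
    pi_per_gene_block = pd.concat(pi_rows, ignore_index=True)

    linkage_gene = (
        assign_pairs_to_genes(records, genes) if len(records) else pd.Series(dtype=object)
    )
    fst_frames = []
    sweep_frames = []
    for b1, b2 in itertools.combinations(blocks, 2):
        ft = gene_fst(
            pooled["block"][b1], pooled["block"][b2], snps, genes,
            config.fst_min_cov, config.coverage_sd_k,
        )
        ft.insert(0, "block_pair", f"{b1}-{b2}")
        fst_frames.append(ft)
        candidates = window_scan(ft, config.window, config.k_sd)
        if candidates:
            sweeps = confirm_sweeps(
                candidates, records, linkage_gene, pi_per_gene_block, snps, config.alpha
            )
            sweeps.insert(0, "block_pair", f"{b1}-{b2}")
            sweep_frames.append(sweeps)
    fst_all = pd.concat(fst_frames, ignore_index=True) if fst_frames else pd.DataFrame()
    fst_all.to_csv(outdir / "gene_fst.tsv", sep="\t", index=False)
    sweep_all = (
        pd.concat(sweep_frames, ignore_index=True) if sweep_frames else pd.DataFrame()
    )
    sweep_all.to_csv(outdir / "sweep_loci.tsv", sep="\t", index=False)
    report["stages"]["fst_scan"] = {
        "block_pairs": len(fst_frames),
        "genes_with_fst": int(fst_all["fst"].notna().sum()) if len(fst_all) else 0,
        "candidate_loci": int(len(sweep_all)),
        "confirmed_loci": int(sweep_all["confirmed"].sum()) if len(sweep_all) else 0,
    }

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
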