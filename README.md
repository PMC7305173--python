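# microdiv

Strain-level population genetics from metagenomic read mappings.

Soil (and other environmental) bacterial populations are rarely cultivable,
but deep shotgun metagenomes sampled across space carry their within-species
genetic structure: every read pair is a tiny haplotype drawn from the wild
population. `microdiv` turns per-sample read alignments against one
representative genome per species into:

- **per-gene nucleotide diversity** π at nested spatial pooling scales
  (sample → replicate → plot → block → whole site), recomputed on pooled
  base counts rather than averaged,
- **SNP calls** against a sequencing-error null model with an explicit
  false-positive target and a minor-allele-frequency floor,
- **linkage disequilibrium** (r², D′) measured only on alleles physically
  co-observed within one read pair — no statistical phasing,
- **Hudson F_ST** between spatial blocks as a per-gene ratio of averages, and
- a **selective-sweep scan**: a moving 5-gene window over the F_ST track with
  candidate loci confirmed by jointly elevated linkage and shifted diversity.

A synthetic-data module simulates aligned paired reads from a haplotype
population with tunable recombination, Balding–Nichols block differentiation
and implantable sweep loci, writing truth tables alongside — so the whole
pipeline is testable end-to-end with known answers.

## The statistics

At a genomic position with Q≥30 base proportions A, C, G, T:

```
π = 1 − (A² + C² + G² + T²)
```

the probability that two reads drawn at that position differ. Per-gene π is
the unweighted mean over positions with coverage ≥ 5×.

A position is a SNP when its leading non-major allele has count
`k ≥ k_min(coverage)` — the smallest k with `P(Binom(cov, ε/3) ≥ k) ≤ 10⁻⁶`
under the per-base error rate ε (default 10⁻⁴) — and frequency ≥ 5%.

For two segregating sites co-covered by n read pairs with 2×2 haplotype
counts, with p_A, p_B the marginal allele frequencies and p_AB the joint:

```
D  = p_AB − p_A p_B
r² = D² / (p_A(1−p_A) p_B(1−p_B))
D′ = |D| / D_max
```

D′ < 1 exactly when all four haplotype combinations are observed — direct
evidence of recombination (or recurrent mutation) between the sites.

Between two blocks with allele frequencies p₁, p₂ at read depths n₁, n₂,
Hudson's per-site components are

```
num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
den = p₁(1−p₂) + p₂(1−p₁)
```

and per-gene F_ST = Σnum / Σden over qualifying sites (≥ 20× in both blocks;
genes with coverage outside mean ± 2 SD excluded).

## Worked example

Simulate a two-block study (40 kb genome, 60 genes, 800 segregating sites,
8 samples at ~12×, one 6-gene sweep at strength 0.95 in block B1) and run the
full pipeline:

```
microdiv simulate --outdir demo --seed 2 --contig-length 40000 --n-genes 60 \
    --n-sites 800 --coverage 12 --sweep-genes 6 --sweep-strength 0.95
microdiv run-all --reference demo/reference.fasta --genes demo/genes.gff3 \
    --metadata demo/metadata.tsv --alignments demo/alignments --outdir demo/results
```

which prints:

```
filter: {'samples': 8, 'pairs_pass': 9684, 'pairs_total': 9783, 'samples_included': 8, 'candidates_evaluated': 8}
profile: {'genes': 60, 'levels': {'sample': 8, 'replicate': 8, 'plot': 4, 'block': 2, 'meadow': 1}}
snps: {'n_snps': 789, 'snps_per_mb': 19725.0, 'n_nonsynonymous': 311, 'n_synonymous': 92, 'ns_ratio': 3.380434782608696}
linkage: {'site_pairs': 2671, 'mean_r2': 0.9561382632159183, 'mean_Dprime': 0.9944465591998696, 'four_haplotype_fraction': 0.02920254586297267}
fst_scan: {'block_pairs': 1, 'genes_with_fst': 57, 'candidate_loci': 1, 'confirmed_loci': 1}
```

Reading the output: 9684 of 9783 read pairs survive the span/identity/MAPQ
filters (the simulator plants ~1% decoy pairs); 789 of the 800 implanted
segregating sites are called as SNPs (19,725 SNPs/Mb at this density — none
at error-only positions); mean r² ≈ 0.96 reflects the low-recombination
population simulated here, with only 2.9% of site pairs showing all four
haplotypes; and the scan finds exactly one high-F_ST locus — the implanted
sweep — and confirms it by its elevated linkage and collapsed diversity in
the swept block. Full per-gene/per-site tables land in `demo/results/*.tsv`.

Every stage is also importable (`from microdiv import call_snps, gene_fst,
...`) and runnable individually (`microdiv filter`, `microdiv profile`,
`microdiv call-snps`, `microdiv linkage`, `microdiv fst-scan`).

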