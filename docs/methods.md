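# Methods

This note documents the models, estimators, defaults and design decisions
behind `microdiv`, and what the synthetic-data validation does and does not
demonstrate about real metagenomes.

## Read-pair filtering and inclusion

A read pair enters the analysis only if (1) both mates map to the same contig
with an end-to-end template span ≤ 1500 bp, (2) the combined pair identity —
`1 − (NM₁+NM₂)/(alen₁+alen₂)`, with indels counted through the edit distance
and soft-clipped bases excluded from the denominator — is ≥ 0.96, and (3) at
least one mate has MAPQ strictly greater than 1. Rules are applied in that
order and each failing pair is attributed to the first rule it breaks, so the
report's categories sum to the total. Only primary alignments are considered.
Both identity thresholds are inclusive (a pair at exactly 0.96 passes).

A genome–sample combination is analyzed only when ≥ 50% of the genome is
covered at ≥ 5× by passing pairs. Note that MAPQ semantics depend on the
index the reads were mapped against; the filter applies the stated rule to
whatever MAPQ the input carries and does not attempt to reproduce any
particular competitive-mapping setup.

## Pileups and nucleotide diversity

Pileups count A/C/G/T per position from bases with Phred ≥ 30. The Q30 mask
is applied to **all** statistics (π, SNP calling, linkage) rather than to SNP
and linkage analyses only: maintaining two inconsistent pileups invites
subtle coverage-definition bugs, and the mask's effect on π is a uniform,
small thinning. A config switch (`min_baseq`) restores unmasked behaviour.
Genome-breadth coverage, by contrast, is computed from full aligned spans
without the quality mask.

Per-site π = 1 − Σ p_b²; per-gene π is the **unweighted** mean over gene
positions with coverage ≥ 5× (monomorphic covered positions contribute 0,
positions below the floor are excluded from numerator and denominator).
Whether sites should instead be coverage-weighted is genuinely open; equal
weighting was chosen as the simpler estimator and is applied consistently.

Pooling across samples sums base counts position-wise and **recomputes** π on
the pooled counts. This matters: two samples fixed for different alleles each
have π = 0 but pool to π = 0.5. By Jensen's inequality pooled π at a site is
always ≥ the coverage-weighted mean of per-sample π, so diversity estimates
grow (weakly) with pooling scale when spatial structure exists.

Coverage subsampling draws a fixed depth per position **without replacement**
(multivariate hypergeometric), modelling a thinner sequencing run. A
with-replacement (multinomial) mode exists because its bias is exactly
analysable: E[π̂] = ((n−1)/n)·π, verified by exact enumeration at n ∈ {2, 5}.
The hypergeometric draw's bias is smaller but in the same downward direction.

## SNP calling

The null model: a sequenced base is erroneous with probability ε = 10⁻⁴ by
default, and an error lands on a *specific* alternate base with ε/3 (errors
uniform over the three alternates). The minimum alternate count at coverage c
is the smallest k with `P(Binom(c, ε/3) ≥ k) ≤ α`, α = 10⁻⁶. A position is a
SNP when its leading non-major allele reaches that count **and** frequency
≥ 5% (inclusive). Calls are made once on the pooled, site-wide pileup;
per-block or per-sample re-calling is available but not the default.

Decisions worth surfacing:

- ε/3 vs ε: testing "any non-reference base" instead of a specific alternate
  is more conservative; `split_error_rate=False` selects it.
- ε itself is configurable because "a Phred-30 error rate" can be read as
  10⁻³ while an error rate of 0.01% is 10⁻⁴; the default is 10⁻⁴ and either
  is one flag away. At the pooled coverages the pipeline targets (hundreds
  fold), the 5% MAF floor dominates both choices.
- The exact binomial tail is the default threshold mode. A `simulated` mode
  estimates the same tail by Monte Carlo with a defensive-mixture importance
  sampler (half the draws from the null, half from an inflated-rate
  proposal), since a 10⁻⁶ tail cannot be resolved by naive resampling at
  practical draw counts; the two modes agree exactly on the tested coverage
  grid.
- At coverages where even k = c fails the α target the position is
  uncallable; the threshold returns c + 1 so such positions can never pass.

Coding effects substitute the minor allele into the reference codon (in the
transcribed frame for minus-strand genes) and translate with the standard
code; positions in incomplete terminal codons are `unknown` and excluded
from N:S. Overlapping genes yield one classified row per gene context.

## Linkage disequilibrium

Haplotypes come only from physical co-observation: a site pair contributes
one 2×2 table entry per read pair that covers both sites with Q ≥ 30 bases
matching the called major/minor alleles (other bases are excluded, not
lumped; when both mates cover a site, mate 1's base is used). Site pairs with
fewer than 30 informative pairs are dropped — strictly: 29 is out. The
assessable distance is capped by read geometry (with 200 bp mates and a
~383 bp median gap, roughly 770–850 bp).

From counts: D = p_AB − p_A·p_B, r² = D²/(p_A q_A p_B q_B), D′ = |D|/D_max
with the sign-dependent D_max, and D = 0 mapped to D′ = 0. Tables monomorphic
at either site are skipped. Two identities are enforced by exhaustive test
over all tables with n ≤ 12: r² ≤ D′², and D′ < 1 ⇔ all four classes
observed. Distance is measured between site coordinates. Genome means of
r²/D′ are unweighted across retained site pairs; decay curves weight bins by
pair count. N/S stratification uses pairs whose *both* sites carry the class.

## Hudson F_ST and the sweep scan

Per site, with block allele frequencies p₁, p₂ and read depths n₁, n₂
(reads are treated as independent draws from the population — at the scale
of a soil sample nearly every read pair comes from a distinct cell):

    num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    den = p₁(1−p₂) + p₂(1−p₁)

Sites qualify at ≥ 20× biallelic coverage in both blocks and must segregate
across the pooled pair of blocks. Per-gene F_ST is the **ratio of averages**
Σnum/Σden — not the average of per-site ratios, which is badly behaved at
low-den sites. Genes whose mean coverage in either block falls outside
mean ± 2 SD (across genes) are excluded as likely copy-number or mapping
artifacts. Per-site estimates may legitimately be negative; the per-gene
ratio is ≤ 1 and equals 1 only for all-fixed differences. All block pairs
are computed.

The scan slides a 5-gene window (step 1) along each contig over genes with
defined F_ST — missing genes are skipped, not zero-filled, because zeros
would deflate the genomic SD; windows never span contigs. The threshold is
genomic mean + 2.5 SD of per-gene F_ST. Seed windows extend gene-by-gene in
both directions while the running mean stays above threshold; overlapping
extended windows merge. Extension deliberately trades precision for recall:
loci typically include a few background genes flanking a true sweep.

Candidates are confirmed by two orthogonal signals, Benjamini–Hochberg
corrected together across all loci × tests (q < 0.05):

1. **Linkage**: one-sided Wilcoxon rank-sum of per-site-pair r² inside the
   locus (pairs assigned to genes by midpoint) vs the rest of the genome —
   an *increase* is required. r² is the default metric; D′ is computed too.
2. **Diversity**: two-sided Welch t-test of per-gene π inside vs outside,
   per block; significance in ≥ 1 block suffices, and the direction of the
   change is reported rather than presumed (observed sweeps reduce π, but
   the test is two-sided by design).

A locus without linkage records is reported as unconfirmable, never
confirmed.

## The synthetic-data generator

The generator is a fixture factory with verifiable limits, not a coalescent
simulator.

**Population model.** Haplotypes are drawn by a copy-or-refresh walk over the
segregating sites: between adjacent sites a crossover occurs with probability
`1 − exp(−ρ·d/L)` (ρ = expected crossovers per haplotype draw across the
genome of length L); without a crossover the walk keeps its current lineage's
allele, with one it draws fresh from the site's target frequency. ρ = 0 gives
a strictly two-clone population (r² = 1 everywhere at matched frequencies);
ρ → ∞ gives site-independent draws. In between, realized per-site
frequencies regress toward the local linkage block's founding draw — which
is why **truth tables always record realized haplotype-matrix frequencies**,
making downstream recovery checks exact by construction.

**Block structure.** Per-block allele frequencies follow Balding–Nichols:
Beta(p(1−F)/F, (1−p)(1−F)/F) around each site's global frequency, with
F the target F_ST — under which the Hudson estimator is unbiased (expected
numerator 2F·p(1−p), denominator 2p(1−p)). Block haplotype matrices are
regenerated from the block frequencies with the same ρ.

**Sweeps.** `implant_sweep` replaces, with probability = strength, each
block haplotype's segment over a contiguous gene run by one chosen "sweep"
haplotype's segment: strength 1 renders the locus monomorphic in that block
(π = 0), partial strengths reduce π, raise F_ST and raise pooled linkage
jointly — the signature the scan confirms.

**Decoys.** An "F_ST-only" negative control cannot be built by changing the
population: any genuine frequency shift between blocks also raises pooled
linkage (mixture LD from differentiation). Decoy loci are therefore
*measurement* artifacts — inflated values injected into the measured F_ST
track, emulating a mapping/coverage artifact — with diversity and linkage
left at background, which is exactly the failure mode the confirmation step
exists to reject.

**Reads.** Pairs are emitted pre-aligned (coordinates known by construction;
no aligner, hence no aligner nondeterminism), as coordinate-sorted SAM with
proper-pair flags, NM tags and per-base qualities. Geometry: 200 bp mates,
inter-mate gap ~ Normal(383, 120) truncated to [0, span cap], template span
capped at 1500 bp. Qualities are two-level (Q37 / Q20, default 2% low) —
just enough to exercise the Q30 mask. Substitution errors are injected per
base at the null model's ε, uniform over the three alternates. A configurable
fraction (default 1%) of decoy pairs violates the span, identity, or MAPQ
rule so the filter stage has true negatives. Identical seeds give
byte-identical outputs.

**What this does not capture:** coalescent genealogies, indels and structural
variation, GC- or position-dependent error profiles, real quality-score
distributions, cross-species read mixtures beyond the decoys, and copy-number
variation. Passing tests therefore demonstrate estimator correctness and
pipeline integrity under a controlled generating model — not robustness to
every artifact of real soil metagenomes.

## Validation problem sizes

The packaged checks use: 10⁶ monomorphic sites at 300× for the SNP
false-positive rate; 5,000 sites × 100× per block × 10 seeds per F_ST
calibration target (tolerance ±0.03 at F ∈ {0, 0.1, 0.3}); a 330 kb,
500-gene, 11,000-site fixture with two implanted sweeps (strengths 1.0 and
0.9, 10 genes each), two decoy loci and 20 null-track seeds for the sweep
scan (background ρ = 6000 so that background LD decays to the sampling floor
within the read-pair span, giving the linkage test contrast); and an 8-sample
40 kb read-level study for end-to-end determinism. These sizes make the full
validation run in a few minutes on one CPU while keeping every tolerance a
pre-stated statistical band (binomial/Monte-Carlo), not a fitted one.

## Numerical and interface conventions

All coordinates are 0-based half-open internally; every emitted format uses
its standard's convention (GFF3 and the SNP/linkage TSVs 1-based, SAM via
pysam, VCF 4.2 with ALT = minor allele). Outlier gene flagging uses strict
`> mean + 2.5·SD` with the sample SD over all genes with defined values.
Hypergeometric enrichment is upper-tail (`P(X ≥ k)`). Welch tests report
p = 1 with a degeneracy flag when either group has < 2 values or both have
zero variance. The BH correction pools whatever family of tests one run
produces. Thread count never affects results; the pipeline is single-pass
deterministic given the config and seed.
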