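# Methods

This note documents the statistical procedures implemented in `targetsnp`,
the defaults chosen where the underlying workflow leaves a decision open,
and what the synthetic-data tests do and do not demonstrate.

## Panel design: the perfect-SNP screen

A candidate variant is retained as a panel target iff, over the discovery
cohort's diploid genotypes:

1. MAF > 0.4 (strict), with MAF the smallest observed allele frequency;
   each non-missing diploid genotype contributes two alleles and missing
   genotypes are excluded from the denominator;
2. missing rate < 0.2 (strict);
3. heterozygous-call rate < 0.2 (strict) — interpreted as the per-locus
   fraction of heterozygous sample genotypes (discovery panels are inbred
   lines, so this screens residual heterozygosity and paralog collapse),
   not expected heterozygosity;
4. no other segregating site within the flanking window: two-sided,
   100 bp on each side, boundary inclusive (a variant exactly 100 bp away
   disqualifies). The window convention is ours; the underlying protocol
   only states "100 bp flanking sequence", and the inclusive two-sided
   reading is the conservative one for primer design;
5. exactly two observed alleles.

The screen is idempotent and monotone in each threshold (tested). Major and
minor alleles are assigned by descending observed frequency, ties broken
lexicographically. Flanks are extracted from the reference in 1-based
inclusive coordinates; flanks running off a contig are N-padded and flagged,
and a reference base that matches neither panel allele raises a warning.

## Genotype calling

Let counts c_a be reads per allele at one (sample, locus) and f_a = c_a / Σc
over **all** reads at the locus, noise alleles included (a `top_two_only`
mode renormalises over the two most abundant alleles; which convention the
upstream protocol used is not documented, so both are provided). With major
allele = argmax c (lexicographic tie-break):

- f_major > 0.7 (strict) → homozygous;
- else f_major ≥ 0.35 and f_minor ≥ 0.35 → heterozygous ("more than 0.35"
  is implemented inclusively so the 65/35 and 50/50 cases are heterozygous);
- else → missing. This covers the ambiguous gap (e.g. 69/31) that the two
  rules leave undefined; treating it as missing is the conservative choice.
- total depth < `min_depth` (default 20 reads) → missing regardless. Real
  runs of this assay average ~2000× per locus, so 20 is a permissive floor;
  it is configurable.

The caller is scale-invariant in the counts (tested exhaustively on a count
grid). Against a marker panel, any call involving a non-panel allele is set
missing and tallied. Calling is stateless per cell; no imputation.

## Sequencing QC

Alignment rate = aligned reads / total reads; target alignment rate =
on-target reads / total reads. Per-SNP depth = bases on the SNP / read
length (equal to the read count when every counted read covers its SNP, as
with the built-in exact-context matcher). Uniformity index = fraction of a
variety's SNPs with depth > 10% of that variety's own mean SNP depth; the
run-level mean of these is also reported. Run average depth = S/(M·N·L)
with S total bases, M varieties, N SNPs, L mean read length. Per-variety
sequence depth = the variety's target bases / total panel target length,
with the target length per locus taken as the amplicon span
(2·flank_width + 1).

The bundled read matcher (`count_alleles_from_reads`) assigns a read to
allele *a* of a locus iff the read contains the exact string
`flank_left[-w:] + a + flank_right[:w]` (default w = 15). It exists so the
synthetic pipeline runs end-to-end without an external aligner; it is exact
matching only and is not a replacement for genome alignment on real data.

## Diversity statistics

With allele frequencies P_i at a locus:

- He = 1 − Σ P_i² (Nei's gene diversity), deliberately **without**
  small-sample correction: the statistic's natural biallelic maximum is then
  exactly 0.5, the convention under which panel summaries are usually
  printed;
- PIC = 1 − Σ P_i² − Σ_{i<j} 2 P_i² P_j², evaluated exactly over all allele
  pairs; for biallelic loci PIC = He − 2p²q² ≤ He with maximum 0.375;
- Ho = heterozygous calls / non-missing calls.

Missing genotypes are excluded locus-wise (complete case per locus). Values
are kept at full precision internally and rounded only for display.
Per-population summaries additionally count monomorphic loci (PIC = 0),
which flags markers fixed within a market class.

## Core-marker selection

The pairwise indicator X_ij = 1 iff samples of pair j carry unequal,
**both non-missing** genotypes at SNP i — a missing call cannot certify a
difference, so missing-vs-anything counts 0 (conservative). All steps use
n(n−1)/2 pairs. The greedy search:

1. pick argmax_i Σ_j X_ij;
2. repeatedly add the SNP resolving the most still-unresolved pairs;
3. break ties by preferring a chromosome not yet in the set (spreading the
   core set across the genome), then by lowest panel index to make runs
   deterministic; every tie and its resolution is logged;
4. stop at saturation (no SNP adds a pair) or at `k_max`.

Discrimination power after each step = fraction of samples whose multilocus
genotype over the selected subset is unique (strict vector equality,
missing included). Redundancy groups use the same strict equality by
default; a `missing_tolerant` mode merges samples connected by pairwise
compatibility and is an upper bound on redundancy, not an equivalence.
Deduplication before selection (finding the minimal set separating
non-redundant varieties) is available via `deduplicate` and the `--dedupe`
CLI flag — both orders are exposed because published workflows are
ambiguous about which was used.

Greedy set cover is a heuristic: `exhaustive_minimum` enumerates all
subsets on small instances, and the test suite verifies that greedy always
reaches full-panel power and never reports a smaller set than the optimum
(it matches the optimum in ≥ half of random small instances).

## Population structure

**Simple matching distance** d(a,b) = differing loci / loci scored in both;
pairs sharing no locus get 1.0 plus a warning. Restricted to complete data
it is a metric (spot-checked on random instances).

**Neighbor joining** is the standard Saitou–Nei agglomeration. Negative
branch lengths are clamped to zero with the deficit transferred to the
sister branch. The implementation is cross-checked against scikit-bio's NJ
(identical topologies) and against the closed-form three-taxon solution.

**PCA** centres dosage codes per locus after locus-mean imputation of
missing cells and uses a full SVD; coordinates are equivariant under sample
permutation up to component sign.

**AMOVA** partitions variance over the 2N implicit haplotypes at three
levels: among groups, among samples within groups, and within samples
(heterozygosity). The molecular distance is the number of differing
alleles, which for binary allele indicators equals squared Euclidean
distance, so sums of squares reduce to per-locus moment formulas; a direct
summation over the explicit haplotype distance matrix is kept as a test
oracle and agrees to 1e-9. With exactly two haplotypes per individual the
expected-mean-square coefficient of the among-individual component is
exactly 2 at both levels; the among-group coefficient uses the standard
unequal-size correction. Negative components are clamped to zero before
percentages (raw values retained). Loci with any missing call are excluded
(keeps the two formulations exactly equal); Phi statistics are derived from
the clamped components. Significance uses a randomization test: sample
labels permuted among groups (sizes preserved), p = (1 + #{perm ≥ obs}) /
(n_perm + 1), default 999 permutations, seed mandatory in the CLI, with the
permutation distribution returned for plotting.

**Fst.** The default pairwise estimator is Nei (1987): per locus, Hs and Ht
with harmonic-mean sample-size corrections, Fst = (mean Ht − mean Hs)/mean
Ht over loci polymorphic in the pair; monomorphic loci are skipped, and a
pair with none is reported undefined. Negative estimates are reported raw
with a clamped copy. Weir–Cockerham (1984) theta is provided as an
alternative (`estimator="wc"`, and `global_fst` for all populations
jointly). The two estimators answer different questions: with two sampled
demes, Nei's Gst estimates the realised differentiation of those demes and
its expectation under a Balding–Nichols model with parameter F is
≈ F/(2 − F), whereas Weir–Cockerham theta estimates F itself. Parameter-
recovery tests therefore use theta; cross-estimator values should not be
expected to coincide.

## Synthetic data generator

`simulate_structured_genotypes` draws ancestral frequencies uniform on
[0.1, 0.9], per-population frequencies from Beta(c·p, c·(1−p)) with
c = (1−F)/F (Balding–Nichols; F = 0 shares frequencies exactly), and
genotypes Binomial(2, p_pop). Defaults mirror the shape of a real variety
collection: five subpopulations of sizes (98, 44, 24, 14, 91) totalling 271
samples, 92 loci, and F = 0.25 — the middle of the pairwise-Fst range
(≈0.13–0.48) typically seen among market-class subpopulations of a crop
collection. `simulate_allele_counts` draws per-cell depth from a negative
binomial (default mean 2064, matching a real run of this assay; dispersion
10) and reads from a multinomial with mass 1 − e on the true allele(s)
(split evenly for heterozygotes, error mass spread over the other
nucleotides; default e = 0.01). `make_toy_panel` plants candidate variants
of known categories (perfect, MAF-failing, missingness-failing,
heterozygosity-failing, flank-failing with a companion variant 50 bp away,
multiallelic) on a synthetic contig whose reference base equals the major
allele, so the screen's exactness can be asserted. Everything is
deterministic under a seed, including file bytes.

What the generator does **not** emulate: linkage between loci (all loci are
independent, so simulated panels discriminate varieties far more easily
than real ones — the simulated 271×92 collection is fully fingerprinted by
~9 SNPs), admixed individuals, allele-specific PCR bias, PCR chimeras,
index hopping, and depth correlation between loci within a sample beyond
the negative-binomial dispersion. Passing tests therefore validate the
*algorithms* against known truth, not the field performance of any
particular panel.

## Problem sizes and numerics

The validation suite runs the caller at the full 271 × 92 collection shape
(depth 100, 1% error), the selector oracle on 50 random instances of ≤ 20
samples × ≤ 12 SNPs, Fst recovery at 200 samples × 100 loci, and the
end-to-end pipeline at 271 × 92 — sizes chosen so the whole suite completes
in a few seconds while keeping the statistical checks well-powered.
Tolerances: AMOVA oracle equality at 1e-9 (identical arithmetic reordered);
stochastic checks use fixed seeds with bounds derived from binomial
concentration (e.g. |Fst| < 0.02 under the null at 200 × 100). Tie-breaks
are everywhere deterministic (lexicographic or lowest-index) and logged
where scientifically meaningful (selection ties).

## Known limitations

- The caller assumes biallelic panel loci; third alleles are treated as
  noise or cause a missing call, never a genotype.
- AMOVA's complete-locus filtering discards information under heavy
  missingness; pairwise-complete AMOVA is not implemented.
- The NJ implementation is O(n³) and intended for collection-scale (≤ a few
  thousand samples) trees.
- `missing_tolerant` redundancy grouping is transitive-closure based and
  can chain distinct genotypes through missing cells.
- The randomization test permutes at the sample-among-groups level only;
  nested permutation schemes (e.g. subpopulations within populations) are
  not implemented.
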