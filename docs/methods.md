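# Methods

This note documents the models implemented in `allelic`, the defaults and
why they hold, what the simulator does and does not emulate, and the places
where the design was genuinely open.

## Reference panel

Each normal sample's per-SNV depth is filtered at coverage > 10 (strict: a
site at exactly 10 reads is dropped) and divided by the sample's mean depth
over the *retained* sites; using retained sites keeps uncovered loci from
deflating the mean. In male samples, X and Y values are then doubled so the
panel expresses a diploid-equivalent baseline; the mean is computed before
the doubling, so a male sample's genome-wide normalization is unaffected by
its sex chromosomes beyond their depth contribution. Female Y sites are
dropped rather than zero-filled — zero medians would blow up the log ratio
downstream. The panel value at a locus is the median of the normalized
depths across contributing samples (even cohort: mean of the two central
values); loci seen in fewer than `min_samples` samples (default 1) are
omitted. The panel is a gzipped TSV with a genome-build header line.

## Copy-number model

**LRR.** `LRR = log2(tumor_norm / panel_median)` per locus, tumor depth
filtered and normalized exactly as panel samples. Log base 2 is the
standard Log-R-ratio convention. Loci missing from the panel, or with a
non-positive panel value, are skipped and counted in the skip log.

**Ploidy parameter.** Because a tumor-only sample is normalized to its own
mean depth, the LRR baseline is its mean genome copy number, not 2. The
class centers are therefore `log2(c / ploidy)` with `ploidy` the expected
mean copy number. Near-diploid samples work at the default 2; markedly
aneuploid karyotypes need the parameter raised to their mean copy number,
or every class is systematically shifted. The simulator's
`KaryotypeSpec.mean_copy_number()` supplies this value for studies with
known truth, and the purity benchmark keeps it fixed at the pure-tumor
value across all contamination levels (the analyst does not re-tune per
mixture).

**Segmentation.** CBS: the arc (i, j] maximizing the circular max-t
statistic is tested by permutation (default 1,000 permutations, alpha 0.01,
minimum 10 markers per segment). Because permuting the values preserves
their multiset, the pooled-variance factor cancels and the scan uses a
scale-free score; permutation proceeds in blocks with early stopping once
significance is impossible. Accepted arcs contribute up to two boundaries
and the pieces are re-tested recursively. On a 0.585-step with sd-0.05
noise (the trisomy-vs-diploid contrast at ~40x) the breakpoint is localized
to the exact marker in essentially every replicate.

**Class assignment.** Nearest expected LRR with boundaries at midpoints of
adjacent class centers; at or beyond the 4/5 midpoint is amplification
(total estimated as `round(ploidy * 2^LRR)`, floored at 5). The rule is
monotone in LRR by construction.

**Allelic imbalance.** `AI_snp = |RAF − 0.5|` over heterozygous SNVs;
segments longer than 100 kb with ≥ 20 het SNVs get a two-cluster split of
their AI values under the k-means (squared-Euclidean) criterion. In one
dimension the optimal 2-partition is contiguous in sorted order, so the
objective is solved exactly by a prefix-sum scan — deterministic, no
restarts, and never beaten by Lloyd iteration (asserted against
scikit-learn in the tests). `AI_seg = AF_h / AF_L` with `AF_L` floored at
`af_l_epsilon = 1e-3`; identical values tie to `AI_seg = 1`.

**Imbalance decision.** A segment is declared allelically imbalanced when
all three hold:

1. `AF_h ≥ min_af_h` (default 0.2). At ~40x, RAF noise is binomial with
   sd ≈ 0.08; folded at 0.5, pure noise yields an upper-cluster mean around
   0.12, so an absolute floor well above that level is required — 0.2 sits
   roughly three cluster-mean standard errors above the noise ceiling while
   staying below the smallest genuine signal of interest (the 3:1
   tetrasomy, expected AI 0.25).
2. `AI_seg ≥ 1.4` **or** `AF_L ≥ min_af_h`. The ratio detects bimodal
   mixtures of balanced and shifted sites; at high purity an imbalanced
   segment shifts *every* het site, both cluster means are high and the
   ratio degenerates to ~1 — the `AF_L` branch catches that regime (pure
   copy-neutral LOH has every AI at 0.5).
3. `AF_h` is nearer the imbalanced candidate's expected AI
   (`M/(M+m) − 0.5`: 0.5 for (2,0), 0.25 for (3,1)) than the balanced
   expectation 0. This nearest-state check is what makes low-purity LOH
   fail *gracefully*: at 25% tumor content the LOH signal is AI ≈ 0.125,
   closer to balance than to (2,0), and the segment reverts to (1,1) — the
   same contamination-masking behavior seen in real mixture experiments.

Class 1 is always (1,0) and class 3 always (2,1) (a trisomy has no balanced
integer state). Segments failing the AI preconditions inherit the balanced
default of their class, keeping genome coverage total. Amplified segments
take the minor count minimizing `|expected AI − AF_h|`.

## ASE model

**Filters.** Het SNVs need DP > 15, QD > 2, MQ > 35, MQRankSum > −12.5,
ReadPosRankSum > −8, FS < 60 (all strict at the boundary, with missing
annotations dropped and logged) and must fall in an exon of the supplied
gene models. RNA sites need total coverage ≥ 10; genes need CPM ≥ 1 (when a
CPM table is supplied; absent table disables the gate, a gene absent from a
provided table counts as unexpressed) and at least one covered SNV.

**Aggregation and phasing.** On imbalanced segments the WGS reference
fraction identifies the amplified haplotype per SNV (RAF > 0.5 → reference
allele is major); sites at exactly 0.5 are uninformative and skipped. On
balanced segments true phase is unknowable from counts, so pseudo-phasing
assigns each SNV's larger RNA count to the major haplotype (ties to the
reference allele). WGS depths are aggregated under the same orientation to
form the denominator of the odds ratio.

**Tests.** Exact two-sided binomial p-values by the minimum-likelihood
method (sum of all outcome probabilities not exceeding the observed one,
with a 1 + 1e−7 relative guard against float ties) under p0 = 1/2 (model 1)
and p0 = M/(M+m) (model 2). BH step-up q-values are computed separately per
model across all tested genes. The RNA/WGS odds ratio uses
Haldane–Anscombe 0.5 pseudocounts so zero counts stay finite.

**Classification.** `q1 > 0.05` → BALANCED. On an imbalanced segment,
rejecting model 1 while retaining model 2 → CNV_DRIVEN_ASE; rejecting both
→ CNV_INDEPENDENT_ASE. On a balanced segment the two nulls coincide, so a
model-1 rejection is CNV_INDEPENDENT_ASE only if the odds ratio clears the
gate (> 2 or < 0.5); the gate is restricted to balanced segments because on
imbalanced ones the WGS odds already differ from 1 and the two models
separate the hypotheses by themselves. Genes on (N,0) LOH segments are
untestable (no heterozygous expression expected), as are genes mapping to
no segment or split evenly across two segments (assignment is by majority
of covered SNVs).

## Simulator

The generator produces the pipeline's input tables directly at the count
level: Poisson site depth, binomial allele splits, lognormal CPM. It
emulates purity as a (M,m)-vs-(1,1) mixture at the read-fraction level —
the same dilution a read-mixing experiment produces — but does **not**
model mapping bias, sequencing error, GC waves, subclonal heterogeneity or
overdispersed RNA counts; passing tests demonstrate the statistical
machinery on its stated noise model, not robustness to those artifacts.

Study conditions (fixed): a 4 x 10 Mb genome — diploid chromosome,
half-diploid/half-trisomic chromosome, copy-neutral LOH chromosome,
3:1 tetrasomic chromosome (mean copy number 2.625); 50 SNVs/Mb with het
fraction 0.67; WGS depth 40x; RNA ~50 reads per SNV and 1–3 het SNVs per
gene; purity grid 1.0/0.75/0.5/0.25. Genes are blocks of consecutive het
SNVs allotted to segments in proportion to het content, with per-gene
expression fractions defaulting to the copy ratio and overridable to inject
CNV-independent effects (overrides leave the layout byte-identical, so a
first pass can be used to choose target genes).

The sensitivity benchmark uses 2–4 SNVs/gene at ~60 reads per SNV
(120–240 reads/gene). This follows an a-priori power calculation: for the
trisomy contrast (2/3 vs 1/2) the exact binomial at a BH-effective level of
~0.02 has only ~55–65 % power at 50 reads and reaches 90 % near 120 reads,
so a ≥ 0.9-sensitivity benchmark must sit in that regime; all benchmark
genes still satisfy the ≥ 50 reads/gene reporting floor.

## Numerical and degenerate-input choices

* Coverage floors are strict exactly as stated: depth > 10, DP > 15,
  RNA ≥ 10, CPM ≥ 1.
* Chromosomes with fewer markers than `cbs_min_markers` become one trivial
  segment with a warning; an empty tumor/panel intersection is an error.
* `binomial_ase_test` returns exactly 1.0 when every outcome is included
  (the observed point is the mode), avoiding a 1 − 1e−16 artifact.
* Writers emit '%.6g' floats, '.' for missing, stable column order;
  coordinates are 1-based inclusive internally, converted at BED export.
* All randomness (CBS permutations, simulators) flows from explicit seeds;
  k-means needs none because the 1-D solver is exact.

## Known limitations

* No automatic purity or ploidy estimation: the ploidy parameter must be
  set by the analyst for markedly aneuploid samples, and subclonal or
  fractional copy numbers are out of scope.
* CN-LOH recall degrades by design below ~50 % tumor content; at 25 %
  purity those segments revert to (1,1), and gains fade as the LRR
  contrast compresses toward the class midpoints.
* Pseudo-phasing on balanced segments biases the aggregated major fraction
  upward for multi-SNV genes; the BH correction and the odds-ratio gate
  absorb this at the simulated depths (type-I ≈ 0 in the 2,000-gene null
  study), but very deep RNA coverage with many SNVs per gene would warrant
  a phasing-aware null.
* Mapping-bias correction (e.g. WASP) and variant calling are upstream of
  this package; it consumes their tables and trusts their genotypes.
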