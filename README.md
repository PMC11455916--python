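# allelic

Allele-specific copy number (asCN) and allele-specific expression (ASE)
calling from paired tumor WGS and RNA-seq — without a matched normal sample.

## The problem

In aneuploid tumors, RNA-only ASE callers conflate two very different
phenomena: a gene can be transcribed unequally from its two alleles because
of a *cis*-regulatory change, or simply because one allele is present in
more genomic copies than the other. Telling these apart requires the
allele-specific copy number of the segment each gene sits on. `allelic`
estimates asCN from tumor WGS depth and allele fractions against a reference
panel of normal samples, then tests each gene's RNA allele counts against
both an equal-expression null and a copy-number-derived null, classifying
significant genes as **CNV-driven** or **CNV-independent** ASE.

## The model

**Copy number.** For every SNV locus with coverage > 10, depth normalized to
the sample mean is compared to the panel median as a log R ratio

```
LRR = log2( tumor_norm_depth / panel_median_depth )
```

Circular binary segmentation (max-t arc statistic, permutation p-values)
partitions each chromosome into constant-LRR segments. A segment with mean
LRR closest to `log2(c / ploidy)` gets total copy class `c ∈ {1, 2, 3, 4,
≥5}`. Allelic imbalance per heterozygous SNV is `AI_snp = |RAF − 0.5|`
(RAF = reference-allele fraction); within each segment > 100 kb holding
≥ 20 het SNVs, a two-cluster 1-D k-means split (solved exactly) gives the
high/low cluster means `AF_h ≥ AF_L` and the segment statistic
`AI_seg = AF_h / AF_L`. Combining class and imbalance yields the integer
state (major, minor): e.g. class 2 balanced → (1,1), class 2 imbalanced →
(2,0) copy-neutral LOH, class 3 → (2,1), class 4 imbalanced → (3,1).

**Expression.** Heterozygous exonic SNVs passing GATK-style quality gates
(DP > 15, QD > 2, MQ > 35, MQRankSum > −12.5, ReadPosRankSum > −8, FS < 60)
and RNA coverage ≥ 10 are aggregated per gene (CPM ≥ 1) into major/minor
haplotype counts — WGS-frequency-guided on imbalanced segments,
pseudo-phased by the larger RNA count on balanced ones. Exact two-sided
binomial tests are run under

* model 1: `k_major ~ Binom(n, 1/2)` — equal expression;
* model 2: `k_major ~ Binom(n, M/(M+m))` — expression follows the asCN,

with Benjamini–Hochberg FDR 0.05 per model and an RNA/WGS odds-ratio gate
(> 2 or < 0.5) on balanced segments. Rejecting model 1 but not model 2 is
CNV-driven ASE; rejecting both is CNV-independent ASE.

## Worked example

```python
from allelic import (AscnConfig, AseModel, CopyNumberModel, default_karyotype,
                     exact_panel, simulate_rna_counts, simulate_tumor_wgs)
from allelic.io import GeneModel

spec = default_karyotype(purity=1.0, seed=7)   # known 4-chromosome karyotype
tumor, truth = simulate_tumor_wgs(spec)        # tumor WGS SNV table at 40x
panel = exact_panel(tumor[["chrom", "pos"]])   # diploid reference panel

cn = CopyNumberModel(tumor, panel,
                     AscnConfig(ploidy=spec.mean_copy_number(), seed=3)).fit()
print(cn.summary())

rna, genes, cpm = simulate_rna_counts(truth, n_genes=200, seed=11,
                                      effects={"gene0000": 0.9})
ase = AseModel(rna, tumor[tumor["is_het"]], cn.segments,
               GeneModel(genes[["gene_id", "chrom", "start", "end"]]), cpm).fit()
print(ase.summary())
```

prints

```
Allele-specific copy number profile
  ploidy baseline: 2.625   CBS alpha: 0.01   markers used: 2000
  skipped: {'low_depth': 0, 'not_in_panel': 0, 'nonpositive_panel': 0}
  segments: 5
  chrom      start        end  markers  mean_lrr  class  state    AI_seg
  1           10001    9990001      500    -0.407      2  (1,1)   3.05741
  2           10001    4990001      250    -0.419      2  (1,1)   3.82328
  2         5010001    9990001      250     0.172      3  (2,1)   1.90779
  3           10001    9990001      500    -0.404      2  (2,0)         1
  4           10001    9990001      500     0.598      4  (3,1)   1.36708
Allele-specific expression calls
  genes: 200  tested: 151  (FDR 0.05)
  CNV_DRIVEN_ASE         70
  CNV_INDEPENDENT_ASE    2
  BALANCED               79
  NOT_TESTABLE           49
```

Every simulated chromosome comes back with its true state — including the
copy-neutral LOH chromosome 3, invisible in depth alone (mean LRR equals the
diploid chromosomes') but flagged by its saturated allelic imbalance. The 49
untestable genes sit on the (2,0) chromosome, where no heterozygous
expression is expected, or fall below the CPM floor; the trisomic and
tetrasomic genes expressing at their copy ratio are classified CNV-driven,
and the injected 90:10 disomic gene comes back CNV-independent. Note the
ploidy argument: a tumor normalized to its own mean depth is referenced to
its *mean* genome copy number (2.625 here), so markedly aneuploid samples
need the ploidy parameter set accordingly.

A shell interface wraps the same models:

```
allelic simulate --out sim/ --seed 5
allelic build-panel --samples sim/panel_samples.tsv.gz --out panel.tsv.gz
allelic call-ascn --tumor sim/tumor.tsv --panel sim/panel.tsv.gz \
    --ploidy 2.625 --out segments.tsv
allelic call-ase --rna-counts sim/rna_counts.tsv --wgs sim/tumor.tsv \
    --segments segments.tsv --genes sim/genes.bed --cpm sim/cpm.tsv \
    --out ase_results.tsv
```

## Layout

* `allelic.panel` — normal-sample depth normalization and the panel median
* `allelic.segmentation` — circular binary segmentation of LRR
* `allelic.ascn` — `CopyNumberModel` / `CopyNumberResults` and the asCN ops
* `allelic.ase` — `AseModel` / `AseResults`, filters, binomial tests, BH FDR
* `allelic.simulate` — synthetic panels, tumors and RNA counts with truth
* `allelic.io`, `allelic.cli` — VCF/TSV/BED readers and writers, CLI verbs

See `docs/methods.md` for the modelling choices, defaults and limitations.
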