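"""Gene-level allele-specific expression calling against two null models.

RNA-seq allele counts at heterozygous exonic SNVs are aggregated per gene
into major/minor haplotype counts. On allelically imbalanced copy-number
segments the WGS reference-allele frequency phases each SNV (the allele with
RAF > 0.5 belongs to the amplified haplotype); on balanced segments a
pseudo-phasing assigns each SNV's larger RNA count to the major haplotype.
The aggregated counts are tested with an exact two-sided binomial test under

* model 1 - both alleles equally expressed (p0 = 0.5), and
* model 2 - expression follows the allele-specific copy number
  (p0 = major / (major + minor) of the segment).

Genes rejecting model 1 but not model 2 are ASE genes driven by the somatic
copy-number change; genes rejecting both are CNV-independent ASE. P-values
are Benjamini-Hochberg adjusted per model across all tested genes, and on
balanced segments an additional RNA/WGS odds-ratio gate (> 2 or < 0.5)
guards against weak-effect calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

ASE_CLASSES = ("CNV_DRIVEN_ASE", "CNV_INDEPENDENT_ASE", "BALANCED", "NOT_TESTABLE")

RESULT_COLUMNS = [
    "gene_id", "n_snvs", "major_count", "minor_count",
    "p_model1", "q_model1", "p_model2", "q_model2", "odds_ratio", "ase_class",
]

_TIE_GUARD = 1 + 1e-7  # relative tolerance when comparing point probabilities


@dataclass
class FilterThresholds:
    """Variant-quality, coverage and decision thresholds.

    WGS het-SNV gates are strict in the stated direction: DP > 15, QD > 2,
    MQ > 35, MQRankSum > -12.5, ReadPosRankSum > -8, FS < 60. RNA-seq sites
    need total count >= 10 and genes CPM >= 1 to be testable. ASE calls use
    BH FDR 0.05 and, on balanced segments, an odds ratio > 2 or < 0.5.
    """

    min_dp: float = 15.0
    min_qd: float = 2.0
    min_mq: float = 35.0
    min_mqranksum: float = -12.5
    min_readposranksum: float = -8.0
    max_fs: float = 60.0
    min_rna_total: int = 10
    min_cpm: float = 1.0
    fdr_alpha: float = 0.05
    or_high: float = 2.0
    or_low: float = 0.5

    def __post_init__(self):
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")


@dataclass
class GeneAseInput:
    """One gene's testable SNVs plus its copy-number segment link.

    snvs : DataFrame with columns pos, rna_ref, rna_alt, wgs_raf,
        wgs_ref_depth, wgs_alt_depth (WGS depths feed the odds ratio).
    major, minor : segment asCN state; None when the gene maps to no
        segment (or ambiguously to several).
    """

    gene_id: str
    snvs: pd.DataFrame
    major: int | None = None
    minor: int | None = None
    cpm: float | None = None


@dataclass
class AggregatedCounts:
    rna_major: int
    rna_minor: int
    wgs_major: float
    wgs_minor: float
    n_snvs: int
    n_skipped: int = 0


_ANNOTATIONS = ["DP", "QD", "MQ", "MQRankSum", "ReadPosRankSum", "FS"]


def filter_het_snvs(records: pd.DataFrame, thresholds: FilterThresholds,
                    gene_model=None):
    """Keep heterozygous SNVs passing all quality gates inside exons.

    ``records`` needs columns chrom, pos, is_het and the six GATK-style
    annotations (DP, QD, MQ, MQRankSum, ReadPosRankSum, FS). Records with a
    missing annotation are dropped and counted. ``gene_model`` (optional)
    restricts to positions overlapping an exon.

    Returns (kept DataFrame, log dict).
    """
    t = thresholds
    df = records.copy()
    log = {"input": len(df)}
    missing_cols = [c for c in _ANNOTATIONS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"variant records missing annotations {missing_cols}")
    df = df[df["is_het"].astype(bool)]
    log["non_het"] = log["input"] - len(df)
    has_all = df[_ANNOTATIONS].notna().all(axis=1)
    log["missing_annotation"] = int((~has_all).sum())
    df = df[has_all]
    ok = (
        (df["DP"] > t.min_dp) & (df["QD"] > t.min_qd) & (df["MQ"] > t.min_mq)
        & (df["MQRankSum"] > t.min_mqranksum)
        & (df["ReadPosRankSum"] > t.min_readposranksum)
        & (df["FS"] < t.max_fs)
    )
    log["failed_quality"] = int((~ok).sum())
    df = df[ok]
    if gene_model is not None:
        exonic = df.apply(
            lambda r: bool(gene_model.genes_at(r["chrom"], int(r["pos"]))), axis=1
        ) if len(df) else pd.Series([], dtype=bool)
        log["non_exonic"] = int((~exonic).sum()) if len(df) else 0
        df = df[exonic] if len(df) else df
    log["kept"] = len(df)
    return df.reset_index(drop=True), log


def filter_rna_counts(counts: pd.DataFrame, thresholds: FilterThresholds) -> pd.DataFrame:
    """Drop RNA SNVs with total coverage below the floor (< 10 excluded)."""
    total = counts["rna_ref"] + counts["rna_alt"]
    return counts[total >= thresholds.min_rna_total].reset_index(drop=True)


def aggregate_gene_counts(gene: GeneAseInput) -> AggregatedCounts:
    """Aggregate a gene's SNV counts into major/minor haplotype totals.

    Unbalanced segment (major != minor): the allele with WGS RAF > 0.5 is the
    amplified (major) haplotype at every SNV; sites with RAF exactly 0.5 are
    uninformative and skipped. Balanced segment: pseudo-phasing, each SNV's
    larger RNA count goes to the major haplotype (ties: reference allele).
    WGS depths are aggregated with the same per-SNV orientation.
    """
    if gene.major is None or gene.minor is None:
        raise ValueError(f"gene {gene.gene_id}: no segment link")
    unbalanced = gene.major != gene.minor
    rna_major = rna_minor = 0
    wgs_major = wgs_minor = 0.0
    skipped = 0
    used = 0
    for r in gene.snvs.itertuples(index=False):
        if unbalanced:
            if r.wgs_raf > 0.5:
                ref_is_major = True
            elif r.wgs_raf < 0.5:
                ref_is_major = False
            else:
                skipped += 1
                continue
        else:
            ref_is_major = r.rna_ref >= r.rna_alt
        if ref_is_major:
            rna_major += int(r.rna_ref)
            rna_minor += int(r.rna_alt)
            wgs_major += float(r.wgs_ref_depth)
            wgs_minor += float(r.wgs_alt_depth)
        else:
            rna_major += int(r.rna_alt)
            rna_minor += int(r.rna_ref)
            wgs_major += float(r.wgs_alt_depth)
            wgs_minor += float(r.wgs_ref_depth)
        used += 1
    return AggregatedCounts(rna_major, rna_minor, wgs_major, wgs_minor, used, skipped)


def expected_major_fraction(major: int, minor: int) -> float:
    """Major-haplotype expression fraction implied by the asCN state."""
    if major + minor < 1:
        raise ValueError("major + minor must be >= 1")
    if minor == 0:
        raise ValueError("minor = 0: no heterozygous expression expected")
    return major / (major + minor)


def binomial_ase_test(k_major: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value by the minimum-likelihood method.

    Sums Binom(k; n, p0) over every outcome k whose point probability does
    not exceed that of the observed k_major (with a small relative guard
    against float ties).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k_major <= n:
        raise ValueError("k_major must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    include = pmf <= pmf[k_major] * _TIE_GUARD
    if include.all():
        return 1.0
    return float(min(pmf[include].sum(), 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j>=rank(i)} m p_(j)/j."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def wgs_rna_odds_ratio(rna_major, rna_minor, wgs_major_depth, wgs_minor_depth) -> float:
    """RNA vs WGS allelic odds ratio with Haldane-Anscombe 0.5 pseudocounts."""
    rna_odds = (rna_major + 0.5) / (rna_minor + 0.5)
    wgs_odds = (wgs_major_depth + 0.5) / (wgs_minor_depth + 0.5)
    return float(rna_odds / wgs_odds)


def call_ase(genes: list[GeneAseInput],
             thresholds: FilterThresholds | None = None):
    """Test and classify every gene; returns (results DataFrame, log dict).

    Classification (q at fdr_alpha): genes keeping model 1 are BALANCED.
    Genes rejecting model 1 on an unbalanced segment are CNV_DRIVEN_ASE when
    model 2 is retained and CNV_INDEPENDENT_ASE when it is also rejected. On
    balanced segments the two nulls coincide, so rejection of model 1 is
    CNV_INDEPENDENT_ASE provided the RNA/WGS odds ratio clears the gate
    (> or_high or < or_low); otherwise the gene stays BALANCED. Genes failing
    CPM/coverage/segment requirements, or sitting on a (N,0) LOH segment, are
    NOT_TESTABLE.
    """
    thresholds = thresholds or FilterThresholds()
    rows = []
    log = {"no_segment": 0, "loh_segment": 0, "low_cpm": 0,
           "no_covered_snv": 0, "raf_tie_skipped": 0}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        row = {c: np.nan for c in RESULT_COLUMNS}
        row["gene_id"] = gene.gene_id
        row["ase_class"] = "NOT_TESTABLE"
        row["n_snvs"] = 0
        rows.append(row)
        if gene.cpm is not None and gene.cpm < thresholds.min_cpm:
            log["low_cpm"] += 1
            continue
        if gene.major is None or gene.minor is None:
            log["no_segment"] += 1
            continue
        if gene.minor == 0:
            log["loh_segment"] += 1
            continue
        snvs = filter_rna_counts(gene.snvs, thresholds)
        if snvs.empty:
            log["no_covered_snv"] += 1
            continue
        agg = aggregate_gene_counts(
            GeneAseInput(gene.gene_id, snvs, gene.major, gene.minor, gene.cpm))
        log["raf_tie_skipped"] += agg.n_skipped
        if agg.n_snvs == 0 or agg.rna_major + agg.rna_minor == 0:
            log["no_covered_snv"] += 1
            continue
        n = agg.rna_major + agg.rna_minor
        p2_null = expected_major_fraction(gene.major, gene.minor)
        row.update(
            n_snvs=agg.n_snvs,
            major_count=agg.rna_major,
            minor_count=agg.rna_minor,
            p_model1=binomial_ase_test(agg.rna_major, n, 0.5),
            p_model2=binomial_ase_test(agg.rna_major, n, p2_null),
            odds_ratio=wgs_rna_odds_ratio(
                agg.rna_major, agg.rna_minor, agg.wgs_major, agg.wgs_minor),
            _unbalanced=gene.major != gene.minor,
        )
        row["ase_class"] = None  # decided after BH
    results = pd.DataFrame(rows)
    tested = results["ase_class"].isna()
    results.loc[tested, "q_model1"] = bh_fdr(results.loc[tested, "p_model1"])
    results.loc[tested, "q_model2"] = bh_fdr(results.loc[tested, "p_model2"])
    a = thresholds.fdr_alpha
    for i in results.index[tested]:
        q1, q2 = results.at[i, "q_model1"], results.at[i, "q_model2"]
        orr = results.at[i, "odds_ratio"]
        if q1 > a:
            cls = "BALANCED"
        elif results.at[i, "_unbalanced"]:
            cls = "CNV_DRIVEN_ASE" if q2 > a else "CNV_INDEPENDENT_ASE"
        else:
            strong = orr > thresholds.or_high or orr < thresholds.or_low
            cls = "CNV_INDEPENDENT_ASE" if strong else "BALANCED"
        results.at[i, "ase_class"] = cls
    if "_unbalanced" in results.columns:
        results = results.drop(columns=["_unbalanced"])
    results = results[RESULT_COLUMNS].sort_values("gene_id").reset_index(drop=True)
    results["n_snvs"] = results["n_snvs"].astype(int)
    return results, log


def _segment_index(segments: pd.DataFrame):
    """Per-chromosome sorted (starts, ends, row-index) arrays for lookup."""
    index = {}
    for chrom, sub in segments.groupby("chrom"):
        sub = sub.sort_values("start")
        index[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                        sub.index.to_numpy())
    return index


def _locate_segment(index, chrom, pos):
    if chrom not in index:
        return None
    starts, ends, rows = index[chrom]
    i = np.searchsorted(starts, pos, side="right") - 1
    if i >= 0 and pos <= ends[i]:
        return int(rows[i])
    return None


def build_gene_inputs(rna_counts: pd.DataFrame, wgs_hets: pd.DataFrame,
                      segments: pd.DataFrame, gene_model,
                      cpm: dict | None = None,
                      thresholds: FilterThresholds | None = None):
    """Join RNA counts, WGS het SNVs, segments and gene models per gene.

    rna_counts : DataFrame (chrom, pos, rna_ref, rna_alt), e.g. from
        :func:`allelic.io.read_ase_counts`.
    wgs_hets : filtered het SNVs (chrom, pos, ref_depth, alt_depth).
    segments : asCN segments (chrom, start, end, major, minor).
    gene_model : :class:`allelic.io.GeneModel`.
    cpm : optional {gene_id: CPM}; genes absent from a provided table count
        as unexpressed. ``None`` disables the CPM gate.

    A gene spanning several segments is assigned to the one holding the
    majority of its covered SNVs; ties leave the gene without a segment
    (NOT_TESTABLE downstream). Returns (list of GeneAseInput, log dict).
    """
    thresholds = thresholds or FilterThresholds()
    wgs = wgs_hets.copy()
    wgs["wgs_raf"] = wgs["ref_depth"] / (wgs["ref_depth"] + wgs["alt_depth"])
    merged = rna_counts.merge(
        wgs[["chrom", "pos", "ref_depth", "alt_depth", "wgs_raf"]],
        on=["chrom", "pos"], how="inner")
    merged = merged.rename(
        columns={"ref_depth": "wgs_ref_depth", "alt_depth": "wgs_alt_depth"})
    log = {"rna_snvs": len(rna_counts), "het_matched": len(merged),
           "segment_ties": 0}
    seg_index = _segment_index(segments)
    per_gene: dict[str, list] = {}
    for r in merged.itertuples(index=False):
        for gid in gene_model.genes_at(r.chrom, int(r.pos)):
            per_gene.setdefault(gid, []).append(r)
    genes = []
    for gid in sorted(per_gene):
        snvs = pd.DataFrame(per_gene[gid]).rename(columns={"position": "pos"})
        snvs = snvs.sort_values("pos").reset_index(drop=True)
        covered = filter_rna_counts(snvs, thresholds)
        basis = covered if len(covered) else snvs
        seg_votes = [
            s for s in (
                _locate_segment(seg_index, r.chrom, int(r.pos))
                for r in basis.itertuples(index=False))
            if s is not None
        ]
        major = minor = None
        if seg_votes:
            counts = pd.Series(seg_votes).value_counts()
            if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
                log["segment_ties"] += 1
            else:
                seg = segments.loc[counts.index[0]]
                major, minor = int(seg["major"]), int(seg["minor"])
        gene_cpm = None if cpm is None else float(cpm.get(gid, 0.0))
        genes.append(GeneAseInput(
            gid, snvs[["chrom", "pos", "rna_ref", "rna_alt", "wgs_raf",
                       "wgs_ref_depth", "wgs_alt_depth"]],
            major, minor, gene_cpm))
    return genes, log


class AseModel:
    """Gene-level ASE model for one sample.

    Parameters mirror :func:`build_gene_inputs`; ``fit`` joins the inputs,
    runs both binomial null models with BH adjustment, and classifies genes.

    Examples
    --------
    >>> res = AseModel(rna, wgs_hets, segments, gene_model, cpm).fit()
    >>> res.results["ase_class"].value_counts()
    """

    def __init__(self, rna_counts, wgs_hets, segments, gene_model,
                 cpm=None, thresholds: FilterThresholds | None = None):
        self.rna_counts = rna_counts
        self.wgs_hets = wgs_hets
        self.segments = segments
        self.gene_model = gene_model
        self.cpm = cpm
        self.thresholds = thresholds or FilterThresholds()

    def fit(self) -> "AseResults":
        genes, build_log = build_gene_inputs(
            self.rna_counts, self.wgs_hets, self.segments, self.gene_model,
            self.cpm, self.thresholds)
        results, call_log = call_ase(genes, self.thresholds)
        return AseResults(self, results, {**build_log, **call_log})


class AseResults:
    """Per-gene ASE calls with p/q-values, odds ratios and class labels."""

    def __init__(self, model, results: pd.DataFrame, log: dict):
        self.model = model
        self.results = results
        self.log = dict(log)

    def class_counts(self) -> pd.Series:
        return self.results["ase_class"].value_counts()

    def summary(self) -> str:
        counts = self.class_counts()
        tested = int((self.results["ase_class"] != "NOT_TESTABLE").sum())
        lines = [
            "Allele-specific expression calls",
            f"  genes: {len(self.results)}  tested: {tested}"
            f"  (FDR {self.model.thresholds.fdr_alpha:g})",
        ]
        for cls in ASE_CLASSES:
            lines.append(f"  {cls:<22} {int(counts.get(cls, 0))}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Volcano-style view: log2 odds ratio vs -log10 model-1 p."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        tested = self.results.dropna(subset=["p_model1", "odds_ratio"])
        for cls, sub in tested.groupby("ase_class"):
            ax.scatter(np.log2(sub["odds_ratio"]),
                       -np.log10(np.maximum(sub["p_model1"], 1e-300)),
                       s=8, label=cls)
        ax.set_xlabel("log2 odds ratio (RNA vs WGS)")
        ax.set_ylabel("-log10 p (model 1)")
        ax.legend(fontsize=7)
        return ax
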