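"""Readers and writers for the formats the pipeline touches.

Conventions: 1-based inclusive coordinates internally (VCF-style); BED
export converts to 0-based half-open. TSVs are tab-delimited, '.' marks a
missing value, floats are written '%.6g', gzip is autodetected from the
extension. Writers have a stable column order so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import fmt_float, sort_genomic
from .ascn import CN_AMP, SEGMENT_COLUMNS, AscnConfig
from .ase import RESULT_COLUMNS, FilterThresholds

ASE_COUNT_COLUMNS = ["contig", "position", "refAllele", "altAllele",
                     "refCount", "altCount", "totalCount"]


def _open(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


# ---------------------------------------------------------------- VCF input

def read_vcf_sites(path, sample: int = 0) -> pd.DataFrame:
    """Biallelic SNVs from a VCF: depths, het flag, quality annotations.

    Depths come from the sample's AD field (DP as total-only fallback);
    multiallelic and indel records are skipped with counts stored in
    ``df.attrs['skipped']``. INFO QD/MQ/MQRankSum/ReadPosRankSum/FS are
    carried through when present (NaN otherwise).
    """
    from cyvcf2 import VCF

    rows = []
    skipped = {"multiallelic": 0, "indel": 0, "no_genotype": 0}
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped["indel"] += 1
            continue
        gt = v.gt_types
        if gt is None or len(gt) <= sample or gt[sample] == 2:
            skipped["no_genotype"] += 1
            continue
        is_het = bool(gt[sample] == 1)
        ad = v.format("AD")
        if ad is not None and ad.shape[1] >= 2 and ad[sample][0] >= 0:
            ref_d, alt_d = int(ad[sample][0]), int(ad[sample][1])
        else:
            dp = v.format("DP")
            total = int(dp[sample][0]) if dp is not None else 0
            ref_d, alt_d = total, 0
        info = dict(v.INFO)
        rows.append({
            "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
            "ref_depth": ref_d, "alt_depth": alt_d, "is_het": is_het,
            "DP": info.get("DP", np.nan), "QD": info.get("QD", np.nan),
            "MQ": info.get("MQ", np.nan),
            "MQRankSum": info.get("MQRankSum", np.nan),
            "ReadPosRankSum": info.get("ReadPosRankSum", np.nan),
            "FS": info.get("FS", np.nan),
        })
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df


def read_snv_table(path) -> pd.DataFrame:
    """Tumor/normal SNV observations from a VCF or a TSV.

    TSV needs at least chrom, pos, ref_depth, alt_depth, is_het; extra
    columns (quality annotations) pass through.
    """
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_vcf_sites(p)
    df = pd.read_csv(_open(p), sep="\t", dtype={"chrom": str}, na_values=".")
    required = {"chrom", "pos", "ref_depth", "alt_depth", "is_het"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{p}: missing columns {missing}")
    return df


# ------------------------------------------------------- RNA allele counts

def read_ase_counts(path) -> pd.DataFrame:
    """ASEReadCounter-style table -> (chrom, pos, rna_ref, rna_alt).

    totalCount different from refCount + altCount beyond otherBases draws a
    warning; the row is kept using refCount + altCount.
    """
    df = pd.read_csv(_open(path), sep="\t")
    missing = [c for c in ASE_COUNT_COLUMNS if c not in df.columns
               and c != "totalCount"]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    if "totalCount" in df.columns and len(df):
        other = df["otherBases"] if "otherBases" in df.columns else 0
        mismatch = df["totalCount"] != df["refCount"] + df["altCount"] + other
        if mismatch.any():
            warnings.warn(
                f"{path}: {int(mismatch.sum())} rows with totalCount != "
                "refCount + altCount (+otherBases); using refCount + altCount")
    out = pd.DataFrame({
        "chrom": df["contig"].astype(str), "pos": df["position"],
        "rna_ref": df["refCount"], "rna_alt": df["altCount"],
    })
    return out


def write_ase_counts(df: pd.DataFrame, path) -> None:
    """Write (chrom, pos, rna_ref, rna_alt) in ASEReadCounter column layout."""
    with _open(path, "wt") as fh:
        fh.write("\t".join(ASE_COUNT_COLUMNS) + "\n")
        for r in df.itertuples(index=False):
            total = int(r.rna_ref) + int(r.rna_alt)
            fh.write(f"{r.chrom}\t{r.pos}\tN\tN\t{r.rna_ref}\t{r.rna_alt}\t{total}\n")


# ----------------------------------------------------------------- segments

def write_segments(segments: pd.DataFrame, path) -> None:
    """Segments TSV; cn_class 5 is written as its label 'AMP'."""
    with _open(path, "wt") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for r in segments.itertuples(index=False):
            label = "AMP" if r.cn_class >= CN_AMP else str(int(r.cn_class))
            fh.write("\t".join([
                str(r.chrom), str(int(r.start)), str(int(r.end)),
                str(int(r.n_markers)), fmt_float(r.mean_lrr), label,
                fmt_float(r.af_h), fmt_float(r.af_l), fmt_float(r.ai_seg),
                str(int(r.major)), str(int(r.minor)),
            ]) + "\n")


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(_open(path), sep="\t", dtype={"chrom": str}, na_values=".")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["cn_class"] = df["cn_class"].map(
        lambda v: CN_AMP if str(v) == "AMP" else int(v))
    for col in ("af_h", "af_l", "ai_seg"):
        df[col] = df[col].where(df[col].notna(), None)
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{path}: segment with start > end")
    return df[SEGMENT_COLUMNS]


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    """BED export of segments (0-based half-open), name = 'major,minor'."""
    with _open(path, "wt") as fh:
        for r in segments.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.start) - 1}\t{int(r.end)}"
                     f"\t{int(r.major)},{int(r.minor)}\n")


# ------------------------------------------------------------- gene results

def write_gene_results(results: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results.itertuples(index=False):
            fh.write("\t".join([
                str(r.gene_id), str(int(r.n_snvs)),
                "." if pd.isna(r.major_count) else str(int(r.major_count)),
                "." if pd.isna(r.minor_count) else str(int(r.minor_count)),
                fmt_float(r.p_model1), fmt_float(r.q_model1),
                fmt_float(r.p_model2), fmt_float(r.q_model2),
                fmt_float(r.odds_ratio), str(r.ase_class),
            ]) + "\n")


# -------------------------------------------------------------- gene models

class GeneModel:
    """Exon intervals per gene with fast position-to-gene lookup.

    ``exons`` uses 1-based inclusive coordinates. Blocks of the same gene
    must not overlap each other.
    """

    def __init__(self, exons: pd.DataFrame):
        required = {"gene_id", "chrom", "start", "end"}
        missing = sorted(required - set(exons.columns))
        if missing:
            raise ValueError(f"gene model missing columns {missing}")
        if (exons["start"] > exons["end"]).any():
            raise ValueError("gene model: exon with start > end")
        for gid, sub in exons.groupby("gene_id"):
            sub = sub.sort_values("start")
            if (sub["start"].to_numpy()[1:] <= sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"gene {gid}: overlapping exon blocks")
        self.exons = exons.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in exons.groupby("chrom"):
            tree = IntervalTree()
            for r in sub.itertuples(index=False):
                tree[int(r.start): int(r.end) + 1] = r.gene_id
            self._trees[str(chrom)] = tree

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        tree = self._trees.get(str(chrom))
        if tree is None:
            return set()
        return {iv.data for iv in tree[pos]}

    def gene_ids(self) -> list[str]:
        return sorted(self.exons["gene_id"].unique())


def read_gene_bed(path) -> GeneModel:
    """Gene models from BED12 (blocks = exons) or BED4/BED6 (one block)."""
    rows = []
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: need >= 4 BED columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{ln}: bad interval {start}-{end}")
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                for size, off in zip(sizes, offsets):
                    rows.append({"gene_id": name, "chrom": chrom,
                                 "start": start + off + 1,
                                 "end": start + off + size})
            else:
                rows.append({"gene_id": name, "chrom": chrom,
                             "start": start + 1, "end": end})
    return GeneModel(pd.DataFrame(rows))


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    """One-block BED from a (gene_id, chrom, start, end) frame (1-based in)."""
    with _open(path, "wt") as fh:
        for r in genes.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.start) - 1}\t{int(r.end)}\t{r.gene_id}\n")


def read_cpm(path) -> dict:
    """{gene_id: CPM} from a two-column TSV (gene_id, cpm)."""
    df = pd.read_csv(_open(path), sep="\t")
    cols = list(df.columns)
    if "gene_id" not in cols or "cpm" not in cols:
        raise ValueError(f"{path}: need columns gene_id, cpm")
    return dict(zip(df["gene_id"], df["cpm"].astype(float)))


def write_cpm(cpm: dict, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("gene_id\tcpm\n")
        for gid in sorted(cpm):
            fh.write(f"{gid}\t{fmt_float(cpm[gid])}\n")


# ------------------------------------------------- depth tables for panels

def read_depth_tables(path, sex_map: dict | None = None):
    """Multi-sample 4-column depth TSV (chrom, pos, sample_id, depth).

    Returns a list of :class:`allelic.panel.SampleDepthTable`, one per
    sample, with sexes looked up in ``sex_map`` ('unknown' if absent).
    """
    from .panel import SampleDepthTable

    df = pd.read_csv(_open(path), sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "sample_id", "depth"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sex_map = sex_map or {}
    tables = []
    for sid, sub in df.groupby("sample_id", sort=True):
        tables.append(SampleDepthTable(
            sample_id=str(sid), sex=sex_map.get(str(sid), "unknown"),
            depths=sub.rename(columns={"depth": "raw_depth"})[
                ["chrom", "pos", "raw_depth"]]))
    return tables


def write_depth_tables(tables, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("chrom\tpos\tsample_id\tdepth\n")
        for t in tables:
            for r in t.depths.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.pos}\t{t.sample_id}\t{r.raw_depth}\n")


def read_sex_map(path) -> dict:
    df = pd.read_csv(_open(path), sep="\t")
    if "sample_id" not in df.columns or "sex" not in df.columns:
        raise ValueError(f"{path}: need columns sample_id, sex")
    return dict(zip(df["sample_id"].astype(str), df["sex"].astype(str)))


# ------------------------------------------------------------ configuration

@dataclass
class RunConfig:
    """Validated configuration for the pipeline commands."""

    genome_build: str = "unspecified"
    seed: int = 0
    log_level: str = "INFO"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    ascn: AscnConfig = field(default_factory=AscnConfig)
    paths: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """YAML config -> RunConfig; unknown keys anywhere are rejected."""
    import yaml

    with _open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for section, cls in (("thresholds", FilterThresholds), ("ascn", AscnConfig)):
        if section in raw:
            sec = raw.pop(section) or {}
            names = {f.name for f in dataclasses.fields(cls)}
            bad = set(sec) - names
            if bad:
                raise ValueError(f"{path}: unknown {section} keys {sorted(bad)}")
            kwargs[section] = cls(**sec)
    cfg = RunConfig(**raw, **kwargs)
    cfg.ascn.seed = cfg.ascn.seed or cfg.seed
    return cfg


def write_run_summary(summary: dict, path) -> None:
    """Machine-readable per-command run summary (counts of sites handled)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
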