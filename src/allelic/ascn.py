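"""Allele-specific copy number calling from tumor WGS against a normal panel.

The model: tumor depth at panel SNV loci, normalized to the sample mean, is
compared to the panel median as a log R ratio LRR = log2(tumor / panel).
CBS partitions each chromosome into constant-LRR segments; the segment mean
LRR is assigned to the integer total copy number c in {1..4, >=5} whose
expected LRR log2(c / ploidy) is nearest. Allelic imbalance within a segment
is summarised from heterozygous SNVs: AI_snp = |RAF - 0.5| per site, a 1-D
k-means split of the AI values into high/low clusters with means AF_h / AF_L,
and the segment ratio AI_seg = AF_h / AF_L. The (major, minor) state is then
the integer split of the total consistent with the observed imbalance.

Imbalance decision. A segment is called allelically imbalanced when three
conditions hold: (1) AF_h >= min_af_h, an absolute floor set above the level
that binomial sampling noise alone produces at typical WGS depth; (2) either
AI_seg >= ai_imbalance_threshold (a bimodal high/low mix) or AF_L >= min_af_h
(a uniform shift: at high purity every het site in an imbalanced segment is
displaced, so the high/low ratio degenerates to ~1); and (3) AF_h lies nearer
the imbalanced candidate state's expected AI (M/(M+m) - 0.5) than the
balanced expectation of 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, fmt_float
from .panel import MIN_RAW_DEPTH
from .segmentation import CbsParams, segment_sequence

CN_AMP = 5  # class label for high amplification (>= 5 total copies)

SEGMENT_COLUMNS = [
    "chrom", "start", "end", "n_markers", "mean_lrr", "cn_class",
    "af_h", "af_l", "ai_seg", "major", "minor",
]


@dataclass
class AscnConfig:
    """Tunable parameters of the copy-number caller.

    ploidy : expected baseline total copies (2 for near-diploid tumors);
        segment LRR is referenced to log2(c / ploidy).
    cbs_alpha, cbs_min_markers, cbs_n_perm : CBS split acceptance.
    ai_imbalance_threshold : minimum AI_seg for the bimodal imbalance route.
    min_af_h : absolute AI floor for declaring imbalance (and the AF_L level
        accepted as a uniform-shift signal).
    af_l_epsilon : floor applied to AF_L before the AI_seg division.
    min_seg_length / min_het_snps : preconditions for computing AI_seg.
    seed : drives CBS permutations and k-means restarts.
    """

    ploidy: float = 2.0
    cbs_alpha: float = 0.01
    cbs_min_markers: int = 10
    cbs_n_perm: int = 1000
    ai_imbalance_threshold: float = 1.4
    min_af_h: float = 0.2
    af_l_epsilon: float = 1e-3
    min_seg_length: int = 100_000
    min_het_snps: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not 0 < self.cbs_alpha < 1:
            raise ValueError("cbs_alpha must be in (0, 1)")

    def cbs_params(self) -> CbsParams:
        return CbsParams(alpha=self.cbs_alpha, min_markers=self.cbs_min_markers,
                         n_perm=self.cbs_n_perm, seed=self.seed)


def compute_lrr(tumor_norm_depth, panel_median_depth):
    """LRR = log2(tumor normalized depth / panel median normalized depth)."""
    t = np.asarray(tumor_norm_depth, dtype=float)
    p = np.asarray(panel_median_depth, dtype=float)
    if np.any(t <= 0) or np.any(p <= 0):
        raise ValueError("compute_lrr: depths must be positive")
    return np.log2(t / p)


def classify_cn(mean_lrr: float, ploidy: float = 2.0) -> int:
    """Total copy-number class {1, 2, 3, 4, 5} (5 = amplification, >= 5 copies).

    The expected LRR of c copies is log2(c / ploidy); the class whose
    expectation is nearest wins, with boundaries at midpoints of adjacent
    expectations and everything at or beyond the 4/5 midpoint amplified.
    """
    if not np.isfinite(mean_lrr):
        raise ValueError("classify_cn: mean_lrr must be finite")
    if ploidy < 1:
        raise ValueError("classify_cn: ploidy must be >= 1")
    centers = np.log2(np.arange(1, 6) / ploidy)
    midpoints = (centers[:-1] + centers[1:]) / 2
    return int(np.searchsorted(midpoints, mean_lrr, side="left")) + 1


def compute_ai_snp(raf):
    """Per-site allelic imbalance AI_snp = |RAF - 0.5|."""
    raf = np.asarray(raf, dtype=float)
    if np.any((raf < 0) | (raf > 1)):
        raise ValueError("RAF must lie in [0, 1]")
    return np.abs(raf - 0.5)


def two_means_1d(values) -> tuple[float, float]:
    """Globally optimal two-cluster k-means of 1-D data -> (high, low) means.

    The optimal squared-Euclidean 2-partition of scalars is contiguous in
    sorted order, so a single prefix-sum scan over the n - 1 contiguous
    splits solves the k-means objective exactly (no Lloyd restarts, no local
    optima).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise ValueError("need at least two values")
    cum = np.cumsum(v)
    cum2 = np.cumsum(v * v)
    k = np.arange(1, n)
    # within-cluster SSE of v[:k] and v[k:] for every split point k
    lo_sse = cum2[k - 1] - cum[k - 1] ** 2 / k
    hi_sse = (cum2[-1] - cum2[k - 1]) - (cum[-1] - cum[k - 1]) ** 2 / (n - k)
    best = int(np.argmin(lo_sse + hi_sse)) + 1
    return float(v[best:].mean()), float(v[:best].mean())


def compute_ai_seg(het_ais, config: AscnConfig | None = None):
    """High/low AI cluster means and their ratio for one segment.

    The heterozygous-SNV AI values are split into two groups by the k-means
    criterion (squared Euclidean), solved exactly for 1-D data; AF_h and
    AF_L are the higher and lower group means and AI_seg = AF_h / AF_L
    (AF_L floored at af_l_epsilon). Equal-mean (degenerate) clusters yield
    AI_seg = 1.0.

    Returns (af_h, af_l, ai_seg).
    """
    config = config or AscnConfig()
    ais = np.asarray(het_ais, dtype=float)
    if ais.size == 0:
        raise ValueError("compute_ai_seg: empty AI list")
    if ais.size == 1 or np.ptp(ais) < 1e-15:
        v = float(ais[0])
        return v, v, 1.0
    af_h, af_l = two_means_1d(ais)
    if af_h == af_l:
        return af_h, af_l, 1.0
    ai_seg = af_h / max(af_l, config.af_l_epsilon)
    return af_h, af_l, ai_seg


def _expected_ai(major: int, minor: int) -> float:
    return major / (major + minor) - 0.5


def _is_imbalanced(af_h, ai_seg, expected_ai_imb, config: AscnConfig) -> bool:
    if af_h is None or ai_seg is None:
        return False
    af_l = af_h / ai_seg if ai_seg > 0 else af_h
    if af_h < config.min_af_h:
        return False
    if ai_seg < config.ai_imbalance_threshold and af_l < config.min_af_h:
        return False
    # nearest-state check: AF_h closer to the imbalanced expectation than to 0
    return abs(af_h - expected_ai_imb) < abs(af_h)


def estimate_ascn(cn_class: int, af_h, ai_seg, config: AscnConfig | None = None,
                  total_copies: int | None = None) -> tuple[int, int]:
    """Map (CN class, segment AI summary) to an integer (major, minor) state.

    Undefined AI (af_h or ai_seg is None) falls back to the balanced default
    of the class. Class 3 has a single heterozygous state (2,1); class 1 is
    (1,0). For amplifications the minor allele count is the integer
    minimizing |expected AI - AF_h| given the estimated total.
    """
    config = config or AscnConfig()
    if cn_class == 1:
        return (1, 0)
    if cn_class == 2:
        return (2, 0) if _is_imbalanced(af_h, ai_seg, _expected_ai(2, 0), config) else (1, 1)
    if cn_class == 3:
        return (2, 1)
    if cn_class == 4:
        return (3, 1) if _is_imbalanced(af_h, ai_seg, _expected_ai(3, 1), config) else (2, 2)
    total = int(total_copies) if total_copies is not None else CN_AMP
    total = max(total, CN_AMP)
    if af_h is None or ai_seg is None:
        return ((total + 1) // 2, total // 2)
    minors = np.arange(0, total // 2 + 1)
    errs = [abs(_expected_ai(total - m, m) - af_h) for m in minors]
    m = int(minors[int(np.argmin(errs))])
    return (total - m, m)


def _prepare_markers(tumor: pd.DataFrame, panel: pd.DataFrame):
    """Depth-filter, normalize and join tumor SNVs with the panel."""
    t = tumor.copy()
    required = {"chrom", "pos", "ref_depth", "alt_depth", "is_het"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"tumor table missing columns {sorted(missing)}")
    t["depth"] = t["ref_depth"] + t["alt_depth"]
    skip = {"low_depth": int((t["depth"] <= MIN_RAW_DEPTH).sum()),
            "not_in_panel": 0, "nonpositive_panel": 0}
    t = t[t["depth"] > MIN_RAW_DEPTH].copy()
    if t.empty:
        raise ValueError("no tumor sites with depth > 10")
    t["norm_depth"] = t["depth"] / t["depth"].mean()
    t["raf"] = t["ref_depth"] / t["depth"]
    merged = t.merge(panel[["chrom", "pos", "median_norm_depth"]],
                     on=["chrom", "pos"], how="left")
    skip["not_in_panel"] = int(merged["median_norm_depth"].isna().sum())
    merged = merged.dropna(subset=["median_norm_depth"])
    bad = merged["median_norm_depth"] <= 0
    skip["nonpositive_panel"] = int(bad.sum())
    merged = merged[~bad].copy()
    if merged.empty:
        raise ValueError("no overlapping loci between tumor and panel")
    merged["lrr"] = compute_lrr(merged["norm_depth"], merged["median_norm_depth"])
    return merged, skip


def call_ascn(tumor: pd.DataFrame, panel: pd.DataFrame,
              config: AscnConfig | None = None):
    """Segment the genome and call (major, minor) copy number per segment.

    Parameters
    ----------
    tumor : DataFrame (chrom, pos, ref_depth, alt_depth, is_het).
    panel : DataFrame (chrom, pos, median_norm_depth, ...).
    config : AscnConfig.

    Returns (segments DataFrame, marker DataFrame, skip log dict). Segments
    carry SEGMENT_COLUMNS; markers carry per-site lrr and the index of the
    segment containing them. Deterministic for a fixed config seed.
    """
    config = config or AscnConfig()
    markers, skip = _prepare_markers(tumor, panel)
    chroms = sorted(markers["chrom"].unique(), key=chrom_sort_key)
    seeds = np.random.SeedSequence(config.seed).spawn(len(chroms))
    params = config.cbs_params()
    rows = []
    markers = markers.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    markers["segment"] = -1
    for chrom, ss in zip(chroms, seeds):
        idx = markers.index[markers["chrom"] == chrom]
        sub = markers.loc[idx]
        lrr = sub["lrr"].to_numpy()
        if len(lrr) < config.cbs_min_markers:
            warnings.warn(
                f"chromosome {chrom}: only {len(lrr)} markers; single segment")
            spans = [(0, len(lrr))]
        else:
            spans = segment_sequence(lrr, params, np.random.default_rng(ss))
        for si, (a, b) in enumerate(spans):
            seg = sub.iloc[a:b]
            markers.loc[seg.index, "segment"] = len(rows)
            mean_lrr = float(seg["lrr"].mean())
            cn = classify_cn(mean_lrr, config.ploidy)
            start, end = int(seg["pos"].iloc[0]), int(seg["pos"].iloc[-1])
            het = seg[seg["is_het"].astype(bool)]
            af_h = af_l = ai_seg = None
            if end - start + 1 > config.min_seg_length and len(het) >= config.min_het_snps:
                ais = compute_ai_snp(het["raf"].to_numpy())
                af_h, af_l, ai_seg = compute_ai_seg(ais, config)
            total = None
            if cn == CN_AMP:
                total = int(round(config.ploidy * 2.0 ** mean_lrr))
            major, minor = estimate_ascn(cn, af_h, ai_seg, config, total_copies=total)
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "n_markers": len(seg), "mean_lrr": mean_lrr, "cn_class": cn,
                "af_h": af_h, "af_l": af_l, "ai_seg": ai_seg,
                "major": major, "minor": minor,
            })
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return segments, markers, skip


class CopyNumberModel:
    """Allele-specific copy-number model for one tumor sample.

    Parameters
    ----------
    tumor : DataFrame (chrom, pos, ref_depth, alt_depth, is_het)
    panel : DataFrame (chrom, pos, median_norm_depth)
    config : AscnConfig, optional

    Examples
    --------
    >>> model = CopyNumberModel(tumor, panel, AscnConfig(ploidy=2))
    >>> res = model.fit()
    >>> res.segments[["chrom", "cn_class", "major", "minor"]]
    """

    def __init__(self, tumor: pd.DataFrame, panel: pd.DataFrame,
                 config: AscnConfig | None = None):
        self.tumor = pd.DataFrame(tumor)
        self.panel = pd.DataFrame(panel)
        self.config = config or AscnConfig()

    @classmethod
    def from_files(cls, tumor_path, panel_path, config=None):
        from . import io as _io
        from .panel import read_panel
        tumor = _io.read_snv_table(tumor_path)
        return cls(tumor, read_panel(panel_path), config)

    def fit(self) -> "CopyNumberResults":
        segments, markers, skip = call_ascn(self.tumor, self.panel, self.config)
        return CopyNumberResults(self, segments, markers, skip)


class CopyNumberResults:
    """Fitted asCN profile: segments, per-marker assignments, diagnostics."""

    def __init__(self, model, segments, markers, skip_log):
        self.model = model
        self.segments = segments
        self.markers = markers
        self.skip_log = dict(skip_log)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def marker_states(self) -> pd.DataFrame:
        """Per-marker (chrom, pos, major, minor) via segment membership."""
        seg = self.segments[["major", "minor", "cn_class"]]
        out = self.markers[["chrom", "pos", "segment", "is_het", "lrr"]].copy()
        out = out[out["segment"] >= 0]
        out["major"] = seg["major"].to_numpy()[out["segment"].to_numpy()]
        out["minor"] = seg["minor"].to_numpy()[out["segment"].to_numpy()]
        out["cn_class"] = seg["cn_class"].to_numpy()[out["segment"].to_numpy()]
        return out.reset_index(drop=True)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Allele-specific copy number profile",
            f"  ploidy baseline: {cfg.ploidy:g}   CBS alpha: {cfg.cbs_alpha:g}"
            f"   markers used: {len(self.markers)}",
            f"  skipped: {self.skip_log}",
            f"  segments: {self.n_segments}",
            "  chrom      start        end  markers  mean_lrr  class  state    AI_seg",
        ]
        for r in self.segments.itertuples(index=False):
            label = "AMP" if r.cn_class >= CN_AMP else str(r.cn_class)
            ai = fmt_float(r.ai_seg)
            lines.append(
                f"  {r.chrom:<6} {r.start:>10} {r.end:>10} {r.n_markers:>8}"
                f"  {r.mean_lrr:>8.3f}  {label:>5}  ({r.major},{r.minor})"
                f"  {ai:>8}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of marker LRR with fitted segment means overlaid."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0
        for chrom in sorted(self.markers["chrom"].unique(), key=chrom_sort_key):
            sub = self.markers[self.markers["chrom"] == chrom]
            x = np.arange(len(sub)) + offset
            ax.plot(x, sub["lrr"], ".", ms=2, alpha=0.4)
            for _, s in self.segments[self.segments["chrom"] == chrom].iterrows():
                inseg = (sub["pos"] >= s["start"]) & (sub["pos"] <= s["end"])
                xi = x[inseg.to_numpy()]
                if len(xi):
                    ax.plot([xi[0], xi[-1]], [s["mean_lrr"]] * 2, "r-", lw=2)
            offset += len(sub)
        ax.set_xlabel("marker index")
        ax.set_ylabel("LRR")
        return ax
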