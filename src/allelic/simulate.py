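"""Synthetic cohorts with known truth: panel, aneuploid tumor WGS, RNA counts.

The generator emulates the inputs of the calling pipeline at desk scale.
Depth is Poisson around the target coverage and allele splits are binomial --
a read-count noise model, not a read-level simulator (no mapping bias,
sequencing error, or GC waves). Normal-cell contamination is modelled by
mixing tumor allele copies (M, m) with a diploid (1, 1) background at
1 - purity, exactly the dilution that degrades copy-number recall in real
mixtures:

    site depth  ~ Poisson(mean_depth * (purity (M+m) + (1-purity) 2) / 2)
    ref reads   ~ Binomial(depth, f),
    f = (purity c_ref + (1-purity)) / (purity (M+m) + (1-purity) 2)

with c_ref the copy count of the reference allele under the site's phase.
RNA counts per SNV are Poisson totals split Binomial(total, f_true) where
f_true is the gene's true major-haplotype expression fraction; by default
genes express at their copy-number ratio, and per-gene overrides inject
CNV-independent allelic effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import spawn_rngs
from .panel import SampleDepthTable, build_panel, normalize_sample_depths


@dataclass
class SegmentSpec:
    chrom: str
    start: int
    end: int
    major: int
    minor: int


@dataclass
class KaryotypeSpec:
    """Ground-truth karyotype plus sampling conditions for one tumor."""

    segments: list[SegmentSpec]
    purity: float = 1.0
    mean_depth: float = 40.0
    n_snvs_per_mb: float = 50.0
    het_fraction: float = 0.67
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        seen: dict[str, list[tuple[int, int]]] = {}
        for s in self.segments:
            if s.start > s.end or s.minor > s.major or s.minor < 0:
                raise ValueError(f"bad segment spec {s}")
            for a, b in seen.get(s.chrom, []):
                if s.start <= b and a <= s.end:
                    raise ValueError(f"overlapping segments on {s.chrom}")
            seen.setdefault(s.chrom, []).append((s.start, s.end))

    def mean_copy_number(self) -> float:
        """Length-weighted mean total copy number of the pure tumor genome.

        Self-normalizing a tumor to its own average depth references the LRR
        to this quantity, so it is the natural setting of the caller's
        ploidy parameter for a sample of known karyotype.
        """
        lengths = np.array([s.end - s.start + 1 for s in self.segments], float)
        totals = np.array([s.major + s.minor for s in self.segments], float)
        return float((lengths * totals).sum() / lengths.sum())


def default_karyotype(purity: float = 1.0, mean_depth: float = 40.0,
                      seed: int = 0, chrom_mb: float = 10.0) -> KaryotypeSpec:
    """Four-chromosome study genome: diploid, half-trisomic, CN-LOH, 3:1 gain."""
    mb = int(chrom_mb * 1_000_000)
    segments = [
        SegmentSpec("1", 1, mb, 1, 1),
        SegmentSpec("2", 1, mb // 2, 1, 1),
        SegmentSpec("2", mb // 2 + 1, mb, 2, 1),
        SegmentSpec("3", 1, mb, 2, 0),
        SegmentSpec("4", 1, mb, 3, 1),
    ]
    return KaryotypeSpec(segments, purity=purity, mean_depth=mean_depth, seed=seed)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated tables."""

    spec: KaryotypeSpec
    snvs: pd.DataFrame                     # chrom,pos,is_het,ref_on_major,major,minor
    genes: pd.DataFrame | None = None      # filled by simulate_rna_counts


def _snv_positions(seg: SegmentSpec, per_mb: float) -> np.ndarray:
    n = max(int(round((seg.end - seg.start + 1) / 1e6 * per_mb)), 1)
    step = (seg.end - seg.start + 1) / n
    return (seg.start + (np.arange(n) + 0.5) * step).astype(int)


def simulate_panel(n_samples: int, n_sites: int = 1000, mean_depth: float = 40.0,
                   seed: int = 0, sites: pd.DataFrame | None = None,
                   spacing: int = 1000):
    """Diploid normal cohort depth tables plus their expected panel.

    Sites default to ``n_sites`` evenly spaced loci on chromosome 1; pass a
    (chrom, pos) frame to reuse e.g. tumor SNV positions. Depths are
    Poisson(mean_depth) per sample and site.

    Returns (list of SampleDepthTable, panel DataFrame built from them).
    """
    if n_samples < 1 or mean_depth < 1:
        raise ValueError("n_samples and mean_depth must be >= 1")
    rng = np.random.default_rng(seed)
    if sites is None:
        sites = pd.DataFrame({"chrom": "1",
                              "pos": spacing * (np.arange(n_sites) + 1)})
    tables = []
    for i in range(n_samples):
        depths = rng.poisson(mean_depth, len(sites))
        tables.append(SampleDepthTable(
            sample_id=f"normal{i:03d}", sex="female",
            depths=pd.DataFrame({"chrom": sites["chrom"].to_numpy(),
                                 "pos": sites["pos"].to_numpy(),
                                 "raw_depth": depths})))
    panel = build_panel([normalize_sample_depths(t) for t in tables])
    return tables, panel


def exact_panel(sites: pd.DataFrame) -> pd.DataFrame:
    """Noise-free diploid panel (median exactly 1.0) over the given loci."""
    return pd.DataFrame({"chrom": sites["chrom"].to_numpy(),
                         "pos": sites["pos"].to_numpy(),
                         "median_norm_depth": 1.0, "n_samples": 1})


def simulate_tumor_wgs(spec: KaryotypeSpec):
    """Tumor SNV table under the karyotype + purity mixture model.

    Returns (tumor DataFrame (chrom, pos, ref_depth, alt_depth, is_het),
    SimTruth). Homozygous sites are hom-alt (reference fraction 0); the het
    flag reflects the germline genotype, as produced by an upstream caller.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.purity
    rows = []
    for seg in spec.segments:
        pos = _snv_positions(seg, spec.n_snvs_per_mb)
        n = len(pos)
        is_het = rng.random(n) < spec.het_fraction
        ref_on_major = rng.random(n) < 0.5
        total_cn = p * (seg.major + seg.minor) + (1 - p) * 2
        depth = rng.poisson(spec.mean_depth * total_cn / 2, n)
        c_ref = np.where(ref_on_major, seg.major, seg.minor)
        f = np.where(is_het, (p * c_ref + (1 - p)) / total_cn, 0.0)
        ref = rng.binomial(depth, f)
        rows.append(pd.DataFrame({
            "chrom": seg.chrom, "pos": pos, "ref_depth": ref,
            "alt_depth": depth - ref, "is_het": is_het,
            "ref_on_major": ref_on_major, "major": seg.major,
            "minor": seg.minor,
        }))
    snvs = pd.concat(rows, ignore_index=True)
    tumor = snvs[["chrom", "pos", "ref_depth", "alt_depth", "is_het"]].copy()
    truth = SimTruth(spec=spec, snvs=snvs)
    return tumor, truth


def _truth_label(major: int, minor: int, f_true: float, cpm: float,
                 min_cpm: float = 1.0) -> str:
    if minor == 0 or cpm < min_cpm:
        return "NOT_TESTABLE"
    expected = major / (major + minor)
    if major != minor and np.isclose(f_true, expected):
        return "CNV_DRIVEN_ASE"
    if major == minor and np.isclose(f_true, 0.5):
        return "BALANCED"
    return "CNV_INDEPENDENT_ASE"


def simulate_rna_counts(truth: SimTruth, n_genes: int = 200,
                        snvs_per_gene: tuple[int, int] = (1, 3),
                        mean_depth: float = 50.0,
                        effects: dict[str, float] | None = None,
                        seed: int = 1):
    """RNA allele counts for genes laid over the tumor's heterozygous SNVs.

    Genes take consecutive blocks of het SNVs within one truth segment
    (block size uniform in ``snvs_per_gene``); each gene gets a lognormal CPM
    and a true major-haplotype fraction f_true -- the copy-number ratio by
    default, 0.5 on balanced segments, overridable per gene via ``effects``
    to inject CNV-independent ASE. Returns (rna DataFrame (chrom, pos,
    rna_ref, rna_alt), genes DataFrame, cpm dict); also stores the gene truth
    on ``truth.genes``.
    """
    rng_layout, rng_counts, rng_cpm = spawn_rngs(seed, 3)
    effects = effects or {}
    het = truth.snvs[truth.snvs["is_het"]].reset_index(drop=True)
    groups = list(het.groupby(["chrom", "major", "minor"], sort=True))
    total_het = len(het)
    gene_rows = []
    rna_rows = []
    cpm = {}
    gi = 0
    for (chrom, major, minor), sub in groups:
        # spread genes over segments in proportion to their het content
        quota = max(int(round(n_genes * len(sub) / total_het)), 1)
        placed = 0
        sub = sub.sort_values("pos").reset_index(drop=True)
        i = 0
        while i < len(sub) and gi < n_genes and placed < quota:
            k = int(rng_layout.integers(snvs_per_gene[0], snvs_per_gene[1] + 1))
            block = sub.iloc[i:i + k]
            i += k + 1  # leave a gap so genes never share SNVs
            if block.empty:
                break
            gid = f"gene{gi:04d}"
            gi += 1
            placed += 1
            gene_cpm = float(np.round(rng_cpm.lognormal(3.0, 1.0), 3))
            cpm[gid] = gene_cpm
            if gid in effects:
                f_true = float(effects[gid])
            elif minor == 0:
                f_true = 1.0
            elif major != minor:
                f_true = major / (major + minor)
            else:
                f_true = 0.5
            for r in block.itertuples(index=False):
                total = int(rng_counts.poisson(mean_depth))
                major_reads = int(rng_counts.binomial(total, f_true))
                ref = major_reads if r.ref_on_major else total - major_reads
                rna_rows.append({"chrom": chrom, "pos": int(r.pos),
                                 "rna_ref": ref, "rna_alt": total - ref})
            gene_rows.append({
                "gene_id": gid, "chrom": chrom,
                "start": int(block["pos"].min()) - 500,
                "end": int(block["pos"].max()) + 500,
                "n_snvs": len(block), "major": major, "minor": minor,
                "f_true": f_true, "cpm": gene_cpm,
                "label": _truth_label(major, minor, f_true, gene_cpm),
            })
    genes = pd.DataFrame(gene_rows)
    rna = pd.DataFrame(rna_rows)
    truth.genes = genes
    return rna, genes, cpm


def truth_segments(spec: KaryotypeSpec) -> pd.DataFrame:
    """Ground-truth segment table in the caller's segment layout.

    Lets ASE-only studies bypass copy-number calling and condition directly
    on the known karyotype.
    """
    return pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "major": s.major, "minor": s.minor,
    } for s in spec.segments])


def marker_state_agreement(marker_states: pd.DataFrame,
                           truth_snvs: pd.DataFrame) -> float:
    """Marker-weighted fraction of loci whose called (major, minor) is true."""
    merged = marker_states.merge(
        truth_snvs[["chrom", "pos", "major", "minor"]],
        on=["chrom", "pos"], suffixes=("_called", "_true"))
    if merged.empty:
        raise ValueError("no overlap between called markers and truth")
    hit = ((merged["major_called"] == merged["major_true"])
           & (merged["minor_called"] == merged["minor_true"]))
    return float(hit.mean())
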