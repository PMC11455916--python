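"""Copy-number reference panel built from normal-sample WGS depth tables.

The panel is the depth baseline for tumor copy-number calling: for every SNV
locus it stores the median depth across a cohort of normal samples, after each
sample has been normalized to its own mean depth. Male X/Y depths are doubled
so that the panel describes a *diploid-equivalent* baseline on the sex
chromosomes, which keeps the log R ratio centred at zero for copy-neutral
loci regardless of cohort sex composition.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, fmt_float, is_sex_chrom, is_y, sort_genomic

#: raw-depth floor shared by panel and tumor sites ("coverage over 10", strict)
MIN_RAW_DEPTH = 10

DEPTH_COLUMNS = ["chrom", "pos", "raw_depth"]
PANEL_COLUMNS = ["chrom", "pos", "median_norm_depth", "n_samples"]


@dataclass
class SampleDepthTable:
    """Per-sample WGS depth at defined SNV loci.

    Parameters
    ----------
    sample_id : str
    sex : {"male", "female", "unknown"}
    depths : DataFrame with columns chrom, pos (1-based), raw_depth
    """

    sample_id: str
    sex: str = "unknown"
    depths: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        d = pd.DataFrame(self.depths)
        missing = [c for c in DEPTH_COLUMNS if c not in d.columns]
        if missing:
            raise ValueError(f"sample {self.sample_id}: missing columns {missing}")
        if len(d) and (d["pos"] < 1).any():
            raise ValueError(f"sample {self.sample_id}: positions must be 1-based")
        if len(d) and (d["raw_depth"] < 0).any():
            raise ValueError(f"sample {self.sample_id}: negative depth")
        if d.duplicated(["chrom", "pos"]).any():
            raise ValueError(f"sample {self.sample_id}: duplicate (chrom, pos)")
        self.depths = d.reset_index(drop=True)


def normalize_sample_depths(table: SampleDepthTable) -> pd.DataFrame:
    """Normalize one sample's depths to its mean depth over retained sites.

    Sites with raw depth <= 10 are dropped first; each retained site's value is
    raw_depth / mean(raw_depth over retained sites). In male samples X and Y
    values are then doubled; in female samples Y sites are dropped. The mean is
    taken before the sex-chromosome doubling.

    Returns a DataFrame (chrom, pos, norm_depth). Raises on an empty table or
    on X/Y sites in a sample of unknown sex.
    """
    d = table.depths
    if d.empty:
        raise ValueError(f"sample {table.sample_id}: empty depth table")
    has_sex_sites = d["chrom"].map(is_sex_chrom).any()
    if has_sex_sites and table.sex not in ("male", "female"):
        raise ValueError(
            f"sample {table.sample_id}: sex must be known to normalize X/Y sites"
        )
    kept = d[d["raw_depth"] > MIN_RAW_DEPTH].copy()
    if kept.empty:
        raise ValueError(
            f"sample {table.sample_id}: no sites with depth > {MIN_RAW_DEPTH}"
        )
    mean_depth = kept["raw_depth"].mean()
    kept["norm_depth"] = kept["raw_depth"] / mean_depth
    if table.sex == "male":
        sexmask = kept["chrom"].map(is_sex_chrom)
        kept.loc[sexmask, "norm_depth"] *= 2.0
    elif table.sex == "female":
        kept = kept[~kept["chrom"].map(is_y)]
    out = kept[["chrom", "pos", "norm_depth"]].reset_index(drop=True)
    return out


def build_panel(tables: list[pd.DataFrame], min_samples: int = 1) -> pd.DataFrame:
    """Median normalized depth per locus across already-normalized samples.

    Parameters
    ----------
    tables : list of DataFrames (chrom, pos, norm_depth), one per sample,
        as produced by :func:`normalize_sample_depths`.
    min_samples : loci seen in fewer samples than this are omitted.

    Returns a panel DataFrame (chrom, pos, median_norm_depth, n_samples)
    sorted by chromosome then position. The median of an even number of
    samples is the mean of the two central values (numpy convention).
    """
    if not tables:
        raise ValueError("build_panel: need at least one sample")
    stacked = pd.concat(tables, ignore_index=True)
    grouped = stacked.groupby(["chrom", "pos"], sort=False)["norm_depth"]
    panel = grouped.agg(median_norm_depth="median", n_samples="size").reset_index()
    panel = panel[panel["n_samples"] >= min_samples]
    return sort_genomic(panel)


def write_panel(panel: pd.DataFrame, path, genome_build: str = "unspecified") -> None:
    """Serialize the panel as a (optionally gzipped) TSV with a build header."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(f"#genome_build={genome_build}\n")
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for row in panel.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{fmt_float(row.median_norm_depth)}"
                f"\t{row.n_samples}\n"
            )


def read_panel(path) -> pd.DataFrame:
    """Read a panel TSV written by :func:`write_panel`; gzip by extension."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline()
        build = "unspecified"
        if first.startswith("#"):
            if "=" in first:
                build = first.strip().split("=", 1)[1]
            header = fh.readline()
        else:
            header = first
        cols = header.rstrip("\n").split("\t")
        missing = [c for c in PANEL_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"panel file {path}: missing columns {missing}")
        panel = pd.read_csv(
            fh, sep="\t", names=cols, dtype={"chrom": str}, na_values="."
        )
    panel.attrs["genome_build"] = build
    return panel[PANEL_COLUMNS]


def panel_lookup(panel: pd.DataFrame) -> dict:
    """(chrom, pos) -> median_norm_depth mapping for fast joins."""
    return {
        (r.chrom, int(r.pos)): float(r.median_norm_depth)
        for r in panel.itertuples(index=False)
    }
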