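"""Small shared helpers: chromosome ordering, seed fan-out, float formatting."""

from __future__ import annotations

import re

import numpy as np

_SEX_CHROMS = {"X", "Y"}


def strip_chr(chrom: str) -> str:
    """Canonical chromosome token: 'chr1' -> '1', 'chrX' -> 'X'."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def is_x(chrom: str) -> bool:
    return strip_chr(chrom).upper() == "X"


def is_y(chrom: str) -> bool:
    return strip_chr(chrom).upper() == "Y"


def is_sex_chrom(chrom: str) -> bool:
    return strip_chr(chrom).upper() in _SEX_CHROMS


def chrom_sort_key(chrom: str):
    """Natural genomic order: 1..22 numerically, then X, Y, then anything else."""
    c = strip_chr(chrom).upper()
    if re.fullmatch(r"\d+", c):
        return (0, int(c), "")
    if c == "X":
        return (1, 0, "")
    if c == "Y":
        return (1, 1, "")
    return (2, 0, c)


def sort_genomic(df, chrom="chrom", pos="pos"):
    """Sort a DataFrame by natural chromosome order then position."""
    key = df[chrom].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df[pos].iloc[i]))
    return df.iloc[order].reset_index(drop=True)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a global seed out into independent per-stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def fmt_float(x) -> str:
    """Deterministic float formatting for writers ('%.6g', '.' for missing)."""
    if x is None:
        return "."
    try:
        if np.isnan(x):
            return "."
    except TypeError:
        pass
    return f"{x:.6g}"
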