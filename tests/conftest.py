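import pandas as pd
import pytest

from allelic import (AscnConfig, CopyNumberModel, default_karyotype,
                     exact_panel, simulate_tumor_wgs)


@pytest.fixture(scope="session")
def study_genome():
    """Pure-tumor study karyotype with its simulated WGS table and truth."""
    spec = default_karyotype(purity=1.0, seed=7)
    tumor, truth = simulate_tumor_wgs(spec)
    return spec, tumor, truth


@pytest.fixture(scope="session")
def study_fit(study_genome):
    """Fitted copy-number profile on the study genome (noise-free panel)."""
    spec, tumor, truth = study_genome
    panel = exact_panel(tumor[["chrom", "pos"]])
    config = AscnConfig(ploidy=spec.mean_copy_number(), seed=3)
    return CopyNumberModel(tumor, panel, config).fit(), truth


def make_depth_table(depths, chrom="1", start=1000, step=1000):
    """(chrom, pos, raw_depth) frame from a plain list of depths."""
    return pd.DataFrame({
        "chrom": chrom,
        "pos": [start + i * step for i in range(len(depths))],
        "raw_depth": depths,
    })
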