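import numpy as np
import pandas as pd
import pytest

from weedhyb.io import GenotypeMatrix
from weedhyb.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small neutral hybrid cohort with full ancestry truth."""
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length_bp=5_000_000,
        aim_density=10.0,
        neutral_snp_density=20.0,
        recomb_rate=1.5,
        g=3,
        n_lineages=8,
        n_panel_samples=6,
        seed=11,
    )
    cohort, crop, weed, truth = simulate_cohort(cfg)
    return cfg, cohort, crop, weed, truth


def make_matrix(codes, chrom="chr1", start_pos=100, spacing=100,
                ref="A", alt="G"):
    """GenotypeMatrix from a per-sample list of genotype-code lists."""
    codes = np.asarray(codes, dtype=np.int8)
    n_samples, n_sites = codes.shape
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": [start_pos + i * spacing for i in range(n_sites)],
            "ref": [ref] * n_sites,
            "alt": [alt] * n_sites,
        }
    )
    return GenotypeMatrix([f"s{i}" for i in range(n_samples)], sites, codes)
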