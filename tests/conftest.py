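import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ctdnacnv as c

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """3k-bin, 4-donor healthy simulation with planted outliers and GC bias."""
    params = c.HealthySimParams(
        n_bins=3000, n_samples=4, outlier_fraction=0.01, seed=1
    )
    return c.gen_healthy_bincounts(params)


@pytest.fixture(scope="session")
def nb_model():
    return c.NBModel(m=300.0, r=50.0)


@pytest.fixture(scope="session")
def grid_5mb():
    sizes = c.synthetic_chrom_sizes(600_000_000, 6)
    return c.GenomeGrid.from_chrom_sizes(sizes, 5_000_000)


@pytest.fixture(scope="session")
def small_cohort(grid_5mb):
    """Separable 3-type + normal cohort (15 samples each) with profiles."""
    sigs = c.separable_signatures(
        ["alpha", "beta", "gamma"], grid_5mb, passenger_rate=0.5
    )
    sigs.append(c.CancerSignature(type_name="normal"))
    n = {"alpha": 15, "beta": 15, "gamma": 15, "normal": 15}
    records, labels = c.gen_tumor_cohort(sigs, n, grid_5mb, seed=9)
    profiles = c.build_profiles(
        records, grid_5mb, samples=list(labels["sample"])
    )
    y = labels.set_index("sample")["type"].loc[profiles.samples]
    return profiles, y
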