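import numpy as np
import pandas as pd
import pytest

from methomics import MethylSimConfig, synthio
from methomics.methcall import RatioTable


def make_ratio_table(values: dict, groups: dict, positions=None) -> RatioTable:
    """Build a RatioTable directly from per-sample ratio lists."""
    n = len(next(iter(values.values())))
    if positions is None:
        positions = [100 + 10 * i for i in range(n)]
    idx = pd.MultiIndex.from_arrays(
        [["chr1"] * n, positions], names=["chrom", "pos"]
    )
    ratios = pd.DataFrame({s: pd.Series(v, index=idx, dtype=float) for s, v in values.items()})
    totals = ratios.notna().astype(float) * 10.0
    return RatioTable(ratios=ratios, totals=totals, groups=dict(groups))


@pytest.fixture(scope="session")
def small_methylome():
    """1,000 simulated CpGs, 3 tumor / 2 normal, with planted hypo and hyper."""
    cfg = MethylSimConfig(
        n_cpgs=1000, n_tumor=3, n_normal=2, frac_hypo=0.1, frac_hyper=0.1, seed=42
    )
    tables, truth = synthio.simulate_methylome(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def pipeline_fixture(tmp_path_factory):
    """A complete on-disk synthetic fixture shared by end-to-end tests."""
    d = tmp_path_factory.mktemp("fixture")
    paths = synthio.write_fixture(d, seed=4)
    return d, paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
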