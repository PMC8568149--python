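import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from methtrace import build_store
from methtrace.synth import MethylationLandscape, RegionEffect, simulate_records


@pytest.fixture(scope="session")
def small_landscape():
    """A compact two-chromosome landscape with a low-methylation interval."""
    return MethylationLandscape(
        chrom_lengths={"chr1": 20_000, "chr2": 12_000},
        background_mu=0.8,
        regions=[RegionEffect("chr1", 5_000, 8_000, 0.1)],
        cpg_density=0.02,
        coverage=10.0,
        read_length_median=2_000,
        site_seed=11,
    )


@pytest.fixture(scope="session")
def small_store(small_landscape, tmp_path_factory):
    """A built store holding two samples from the small landscape."""
    recs = list(simulate_records(small_landscape, "s1", "A", 101)) + list(
        simulate_records(small_landscape, "s2", "B", 102)
    )
    out = tmp_path_factory.mktemp("store") / "small.tsv.bgz"
    store = build_store(recs, out, samples=[("s1", "A"), ("s2", "B")])
    store._records = recs  # kept for oracle comparisons in tests
    return store


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
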