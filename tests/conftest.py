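import pandas as pd
import pytest

from atacmux import Fragment, SimConfig, simulate


def make_frags(*tuples):
    """(chrom, start, end, barcode[, support]) tuples -> list of Fragment."""
    return [Fragment(*t) if len(t) == 5 else Fragment(*t, 1) for t in tuples]


def pooled(result) -> pd.DataFrame:
    return pd.concat(result.fragments.values(), ignore_index=True)


@pytest.fixture(scope="session")
def small_sim():
    """A light hopping simulation shared by several tests."""
    cfg = SimConfig(
        n_samples=4,
        cells_per_sample=100,
        mean_fragments=300,
        hop_rate=0.2,
        doublet_rate=0.05,
        genome_length=2_000_000,
        n_peaks=200,
        seed=1,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """No hopping, no doublets: the identity limit of demultiplexing."""
    cfg = SimConfig(
        n_samples=3,
        cells_per_sample=60,
        mean_fragments=150,
        hop_rate=0.0,
        doublet_rate=0.0,
        genome_length=1_000_000,
        n_peaks=100,
        seed=2,
    )
    return simulate(cfg)
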