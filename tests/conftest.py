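import numpy as np
import pandas as pd
import pytest

from rrbskit.core import SiteMatrix, load_and_filter
from rrbskit.simulate import SimConfig, simulate_methylome, simulate_sample_frames

SMALL_CONFIG = SimConfig(seed=7, n_chrom=1, chrom_length=400_000,
                         n_genes=8, n_cgis=10, n_qtls=3)


@pytest.fixture(scope="session")
def default_sim():
    """Full-size synthetic methylome under the study conditions."""
    return simulate_methylome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_matrix(default_sim):
    frames = simulate_sample_frames(default_sim)
    return load_and_filter(frames, default_sim.samples)


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic methylome for fast structural tests."""
    return simulate_methylome(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    frames = simulate_sample_frames(small_sim)
    return load_and_filter(frames, small_sim.samples)


def make_matrix(rows, counts):
    """Hand-built SiteMatrix for arithmetic tests.

    rows: list of (chrom, pos, strand, context);
    counts: list (one per site) of lists of (meth, total) per sample,
    nine samples in Pre/In/Post x 1..3 order.
    """
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])
    meth = np.array([[m for m, _ in site] for site in counts])
    total = np.array([[t for _, t in site] for site in counts])
    samples = pd.DataFrame([
        {"name": f"{stage}_{r}", "stage": stage, "replicate": r}
        for stage in ("Pre", "In", "Post") for r in (1, 2, 3)
    ])
    return SiteMatrix(sites, meth, total, samples)
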