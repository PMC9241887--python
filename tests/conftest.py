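import numpy as np
import pytest

import microhic as mh


@pytest.fixture(scope="session")
def small_params():
    """A small, fast Rabl simulation: 4 chromosomes of 0.3-0.6 Mb."""
    return mh.SimulationParams(
        n_chrom=4,
        chrom_length_range=(300_000, 600_000),
        resolution=5_000,
        n_pairs=200_000,
        telomere_extent=20_000,
        centromere_width=20_000,
        domain_size_range=(10_000, 80_000),
    )


@pytest.fixture(scope="session")
def small_truth(small_params):
    return mh.simulate_truth(small_params, 42)


@pytest.fixture(scope="session")
def small_intensity(small_truth):
    return mh.expected_intensity(small_truth)


@pytest.fixture(scope="session")
def small_matrix(small_intensity):
    return mh.sample_contacts(small_intensity, 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_contact_matrix(rng, n_bins=30, resolution=1000, density=0.3,
                          n_chrom=1):
    """A random sparse symmetric contact matrix on 1 or more chromosomes."""
    per = n_bins // n_chrom
    layout = mh.GenomeLayout(
        tuple((f"c{k}", per * resolution) for k in range(n_chrom))
    )
    bt = mh.make_bins(layout, resolution)
    n = bt.n_bins
    iu = np.triu_indices(n)
    keep = rng.random(len(iu[0])) < density
    counts = rng.integers(1, 20, size=int(keep.sum()))
    return mh.ContactMatrix(bt, iu[0][keep], iu[1][keep], counts.astype(float))
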