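import warnings

import pytest

import blastoseq as bs

SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic embryo time-course (262 cells, 2000 genes + 92
    spike-ins), shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bs.generate_dataset(bs.SimConfig(seed=SEED))


@pytest.fixture(scope="session")
def default_expr(default_dataset):
    counts, genes, cells = default_dataset
    return bs.rpkm(counts, genes)


@pytest.fixture(scope="session")
def default_signatures(default_dataset):
    counts, genes, cells = default_dataset
    low, high = bs.reference_split(cells)
    de = bs.de_test(counts.subset_cells(low), counts.subset_cells(high))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bs.derive_signatures(de, n_top=50), de


@pytest.fixture(scope="session")
def default_assignment(default_dataset, default_expr, default_signatures):
    (sigs, _) = default_signatures
    return bs.assign_lineage(default_expr, sigs)
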