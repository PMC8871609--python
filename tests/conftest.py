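import numpy as np
import pytest

from colsel import (
    GenotypeTable,
    HaplotypeMatrix,
    make_colgene_fixture,
    simulate_two_haplogroup_locus,
)
from colsel.synthetic import TwoHaplogroupParams


@pytest.fixture(scope="session")
def model():
    return make_colgene_fixture()


@pytest.fixture(scope="session")
def two_hap():
    """A default-condition two-haplogroup simulation with exact truth."""
    return simulate_two_haplogroup_locus(TwoHaplogroupParams(seed=11))


@pytest.fixture(scope="session")
def two_hap_outgroup():
    return simulate_two_haplogroup_locus(
        TwoHaplogroupParams(seed=13, t_outgroup=5.0e6)
    )


def small_haplotype_matrix(columns, positions=None, **kw):
    """Build a HaplotypeMatrix from a list of per-site allele columns."""
    alleles = np.array(columns, dtype=np.int8).T
    n_sites = alleles.shape[1]
    return HaplotypeMatrix(
        alleles=alleles,
        positions=np.arange(n_sites) if positions is None else np.asarray(positions),
        sample_ids=[f"h{i}" for i in range(alleles.shape[0])],
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        **kw,
    )


def genotype_table(rows, population=None, positions=None):
    rows = np.array(rows, dtype=np.int8)
    n, s = rows.shape
    return GenotypeTable(
        genotypes=rows,
        positions=np.arange(s) if positions is None else np.asarray(positions),
        sample_ids=[f"s{i}" for i in range(n)],
        population=population or ["pop"] * n,
    )
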