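import numpy as np
import pytest

import salmix as sx
from salmix.genotype_io import BaselineRegistry, HierarchyMap


@pytest.fixture(scope="session")
def small_registry():
    """A modest hierarchical baseline with noise, shared across tests."""
    spec = sx.HierarchySpec(
        regions=3, catchments_per_region=2, sites_per_catchment=2, loci=6, seed=11
    )
    registry, truth = sx.simulate_registry(spec, n_per_site=30)
    return registry, truth


@pytest.fixture(scope="session")
def clean_registry():
    """Noise-free baseline: no missing data, no errors, no null alleles."""
    spec = sx.HierarchySpec(
        regions=3, catchments_per_region=2, sites_per_catchment=2, loci=6, seed=7
    )
    registry, truth = sx.simulate_registry(
        spec, n_per_site=30, missing_rate=0.0, error_rate=0.0, null_loci={}
    )
    return registry, truth


def disjoint_registry(n_units: int = 3, n: int = 30, n_loci: int = 2, alleles_per_unit: int = 2):
    """Baseline units with pairwise-disjoint allele sets (perfectly separable)."""
    loci = []
    for j in range(n_loci):
        loci.append(
            sx.Locus(f"L{j + 1}", tuple(range(1, n_units * alleles_per_unit + 1)))
        )
    colls = []
    s2c, c2r = {}, {}
    for u in range(n_units):
        own = np.arange(u * alleles_per_unit + 1, (u + 1) * alleles_per_unit + 1)
        rng = np.random.default_rng(u)
        g = rng.choice(own, size=(n, n_loci, 2))
        cid = f"U{u + 1}"
        colls.append(sx.SampleCollection(id=cid, site=cid, catchment=cid, genotypes=g))
        s2c[cid] = cid
        c2r[cid] = f"R{(u % 2) + 1}"
    return BaselineRegistry(loci=loci, collections=colls, hierarchy=HierarchyMap(s2c, c2r))


@pytest.fixture(scope="session")
def separable_registry():
    return disjoint_registry()
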