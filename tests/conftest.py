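import numpy as np
import pytest

from gremlkit import (GRM, GenotypeMatrix, SNPInfo, SimulationConfig,
                      compute_grm, simulate_genotypes, simulate_traits)


def make_genotypes(rng, n=10, m=20, missing_rate=0.0):
    """Random unstructured genotype matrix with HWE-ish dosages."""
    p = rng.uniform(0.1, 0.9, size=m)
    d = (rng.random((n, m)) < p).astype(np.int8) \
        + (rng.random((n, m)) < p).astype(np.int8)
    if missing_rate:
        d[rng.random((n, m)) < missing_rate] = -1
    ids = [("FAM", f"I{i:03d}") for i in range(n)]
    snps = [SNPInfo(f"snp{i}", "1", i + 1, "A", "B") for i in range(m)]
    return GenotypeMatrix(ids, snps, d)


def half_sib_config(n_families=10, offspring=5, n_snps=500, **kw):
    need = n_families * (1 + offspring)
    kw.setdefault("n_founders", need)
    return SimulationConfig(n_families=n_families,
                           offspring_per_family=offspring,
                           mating="half_sib", n_snps=n_snps, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def sim_small():
    """A reusable half-sib dataset (~200 animals) with GRM and one trait."""
    cfg = half_sib_config(n_families=11, offspring=5, n_snps=800,
                          h2=(0.5,), seed=11)
    gm, ped = simulate_genotypes(cfg)
    grm = compute_grm(gm)
    phen, bv = simulate_traits(grm, cfg)
    return {"config": cfg, "genotypes": gm, "pedigree": ped, "grm": grm,
            "phenotypes": phen, "breeding_values": bv}


@pytest.fixture(scope="session")
def sim_small_bivariate():
    """Half-sib dataset (~300 animals) with two correlated traits."""
    cfg = half_sib_config(
        n_families=17, offspring=5, n_snps=800, seed=23,
        h2=(0.5, 0.5), phenotypic_var=(1.0, 1.0),
        genetic_corr=np.array([[1.0, 0.6], [0.6, 1.0]]),
        residual_corr=np.array([[1.0, 0.3], [0.3, 1.0]]))
    gm, _ = simulate_genotypes(cfg)
    grm = compute_grm(gm)
    phen, bv = simulate_traits(grm, cfg)
    return {"config": cfg, "grm": grm, "phenotypes": phen,
            "breeding_values": bv}
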