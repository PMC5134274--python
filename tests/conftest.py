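import numpy as np
import pandas as pd
import pytest

from gpselect import grm, simpop


def toy_genotypes(dosage_columns, bp=None, chrom=None):
    """GenotypeMatrix from a list of per-variant dosage vectors."""
    X = np.column_stack([np.asarray(c, dtype=np.float64) for c in dosage_columns])
    m = X.shape[1]
    bp = bp if bp is not None else (np.arange(m) + 1) * 1000
    chrom = chrom if chrom is not None else np.ones(m, dtype=int)
    variants = pd.DataFrame({
        "id": [f"v{i}" for i in range(m)],
        "chrom": chrom,
        "bp": bp,
        "a1": "A",
        "a2": "B",
    })
    return grm.GenotypeMatrix(dosages=X, variants=variants,
                              ids=np.arange(1, X.shape[0] + 1))


@pytest.fixture(scope="session")
def unrelated_pop():
    """500 unrelated HW individuals x 4000 LE variants (shared, read-only)."""
    maps = simpop.make_chrom_maps(2, 2000, seed=5)
    return simpop.sim_unrelated_population(maps, 500, maf_low=0.05, ld_rho=0.0, seed=5)


@pytest.fixture(scope="session")
def family_pop():
    """Half-sib population (~630 bulls) x 3000 variants with LD (shared)."""
    ped = simpop.make_pedigree(n_sires=15, sons_per_sire=14, n_generations=3, seed=9)
    maps = simpop.make_chrom_maps(3, 1000, seed=9)
    pool = simpop.sim_founder_haplotypes(maps, 0.05, 0.9, 400, seed=9)
    G = simpop.gene_drop(ped, pool, morgans_per_chrom=1.0, seed=9)
    return ped, grm.filter_maf(G, 0.01)
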