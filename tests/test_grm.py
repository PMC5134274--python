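"""GRM construction, LD machinery, variant-set algebra and binary I/O."""

import numpy as np
import pandas as pd
import pytest

from gpselect import grm, simpop
from gpselect.grm import (
    build_grm,
    complement,
    ensure_pd,
    filter_maf,
    ld_exclusion_set,
    ld_r2,
    read_gcta_grm,
    read_plink,
    write_gcta_grm,
    write_plink,
)

from conftest import toy_genotypes


# ---------------------------------------------------------------------------
# MAF filtering
# ---------------------------------------------------------------------------

def test_filter_maf_rules():
    # monomorphic variant removed at any threshold
    G = toy_genotypes([np.zeros(100), np.ones(100)])
    out = filter_maf(G, 0.0)
    assert out.n_variants == 1 and out.variants["id"].iloc[0] == "v1"
    # single heterozygote among 100 individuals: p = 0.005 < 0.01
    rare = np.zeros(100)
    rare[0] = 1
    common = np.tile([0.0, 1.0, 2.0, 1.0], 25)
    G = toy_genotypes([rare, common])
    out = filter_maf(G, 0.01)
    assert out.variants["id"].tolist() == ["v1"]
    # min_maf = 0 keeps every polymorphic variant
    out = filter_maf(toy_genotypes([common, 2 - common]), 0.0)
    assert out.n_variants == 2
    with pytest.raises(ValueError):
        filter_maf(toy_genotypes([np.zeros(10)]), 0.01)


# ---------------------------------------------------------------------------
# GRM closed forms and invariances
# ---------------------------------------------------------------------------

def test_single_variant_closed_forms():
    # one variant with p = 0.5 (dosages 2 and 0)
    G = toy_genotypes([[2.0, 0.0]])
    K = build_grm(G, "yang")
    assert K.values[0, 1] == pytest.approx(-2.0, abs=1e-12)
    assert K.values[0, 0] == pytest.approx(2.0, abs=1e-12)
    # heterozygote diagonal at p = 0.5 is exactly 0
    G = toy_genotypes([[1.0, 1.0]])  # p = 0.5
    K = build_grm(G, "yang")
    assert K.values[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_crossprod_matches_dense_oracle(unrelated_pop):
    G = unrelated_pop.take_variants(np.arange(1000)).take_individuals(np.arange(200))
    K = build_grm(G, "crossprod")
    p = G.freqs
    W = (G.dosages.astype(np.float64) - 2 * p) / np.sqrt(2 * p * (1 - p))
    oracle = W @ W.T / G.n_variants
    assert np.abs(K.values - oracle).max() < 1e-10


def test_allele_flip_invariance(unrelated_pop):
    G = unrelated_pop.take_variants(np.arange(300)).take_individuals(np.arange(100))
    flipped = grm.GenotypeMatrix(2.0 - G.dosages, G.variants.copy(), G.ids)
    for mode in ("yang", "crossprod"):
        a = build_grm(G, mode).values
        b = build_grm(flipped, mode).values
        assert np.abs(a - b).max() < 1e-10


def test_unrelated_population_grm_moments():
    """Yang diagonal averages 1 and off-diagonals vanish for unrelated HW
    individuals."""
    maps = simpop.make_chrom_maps(4, 5000, seed=77)
    G = simpop.sim_unrelated_population(maps, 500, maf_low=0.05, ld_rho=0.0, seed=77)
    K = build_grm(G, "yang").values
    diag = np.diag(K)
    off = K[np.triu_indices(500, k=1)]
    assert diag.mean() == pytest.approx(1.0, abs=0.02)
    assert np.abs(off).mean() < 0.01


def test_build_grm_rejects_fixed_variants():
    with pytest.raises(ValueError):
        build_grm(toy_genotypes([np.zeros(10)]))


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_ld_r2_basic():
    x = np.arange(12) % 3
    G = toy_genotypes([x, 2.0 - x, np.random.default_rng(1).integers(0, 3, 12)])
    assert ld_r2(G, 0, 0) == pytest.approx(1.0)
    assert ld_r2(G, 0, 1) == pytest.approx(1.0)  # allele flip leaves r^2 alone
    with pytest.raises(ValueError):
        ld_r2(toy_genotypes([x, np.ones(12)]), 0, 1)


def test_ld_r2_null_level(unrelated_pop):
    rng = np.random.default_rng(2)
    n = unrelated_pop.n_individuals
    pairs = rng.choice(unrelated_pop.n_variants, size=(200, 2), replace=True)
    r2s = [ld_r2(unrelated_pop, i, k) for i, k in pairs if i != k]
    assert np.mean(r2s) < 1 / n + 3 / n


def test_ld_exclusion_set_rules():
    n = 100
    rng = np.random.default_rng(3)
    base = rng.integers(0, 3, n).astype(float)
    indep = rng.integers(0, 3, n).astype(float)
    # v0 selected; v1 = perfect proxy 1 kb away; v2 independent 3 Mb away
    G = toy_genotypes([base, base.copy(), indep],
                      bp=np.array([1_000_000, 1_001_000, 4_000_000]))
    out = ld_exclusion_set(G, np.array(["v0"]), window_bp=2_000_000, p_thresh=0.01)
    assert set(out) == {"v0", "v1"}
    assert ld_exclusion_set(G, np.array([]), 2_000_000, 0.01).size == 0
    with pytest.raises(KeyError):
        ld_exclusion_set(G, np.array(["nope"]), 2_000_000, 0.01)


def test_complement_set_arithmetic():
    cols = [np.tile([0.0, 1.0, 2.0, 1.0], 3) for _ in range(10)]
    G = toy_genotypes(cols)
    assert complement(G, np.array([])).n_variants == 10
    out = complement(G, np.array(["v0", "v1", "v2"]))
    assert out.n_variants == 7
    assert not set(out.variants["id"]) & {"v0", "v1", "v2"}
    out = complement(G, np.array(["v0"]), extra_excluded=np.array(["v5", "v6"]))
    assert out.n_variants == 7
    with pytest.raises(ValueError):
        complement(G, G.variants["id"].to_numpy())


# ---------------------------------------------------------------------------
# positive definiteness
# ---------------------------------------------------------------------------

def test_ensure_pd_identity_unchanged():
    K = grm.GRMatrix(np.eye(4), n_variants=10)
    assert ensure_pd(K, 1e-6) is K


def test_ensure_pd_bends_singular_matrix():
    K = grm.GRMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), n_variants=1)
    out = ensure_pd(K, 1e-6)
    evals = np.linalg.eigvalsh(out.values)
    assert evals.min() >= 1e-6 * 1.0 - 1e-12
    assert abs(out.values[0, 1] - 1.0) < 1e-5


@pytest.mark.parametrize("seed", range(5))
def test_ensure_pd_output_factorizes(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(20, 20))
    K = grm.GRMatrix(0.5 * (A + A.T), n_variants=5)
    out = ensure_pd(K, 1e-6)
    np.linalg.cholesky(out.values + 0 * np.eye(20))  # raises if not PD


# ---------------------------------------------------------------------------
# I/O round-trips
# ---------------------------------------------------------------------------

def test_plink_roundtrip(tmp_path, unrelated_pop):
    G = unrelated_pop.take_variants(np.arange(37)).take_individuals(np.arange(11))
    prefix = str(tmp_path / "toy")
    write_plink(G, prefix)
    back = read_plink(prefix)
    assert np.array_equal(back.dosages, G.dosages)
    assert back.variants["id"].tolist() == G.variants["id"].tolist()
    assert back.variants["bp"].tolist() == G.variants["bp"].tolist()


def test_plink_missing_genotypes_mean_imputed(tmp_path):
    G = toy_genotypes([np.tile([0.0, 1.0, 2.0, 1.0], 2)])
    prefix = str(tmp_path / "miss")
    write_plink(G, prefix)
    with open(prefix + ".bed", "rb") as fh:
        raw = bytearray(fh.read())
    raw[3] = (raw[3] & ~0b11) | 0b01  # first individual's call -> missing
    with open(prefix + ".bed", "wb") as fh:
        fh.write(bytes(raw))
    back = read_plink(prefix)
    expected_mean = np.tile([0.0, 1.0, 2.0, 1.0], 2)[1:].mean()
    assert back.dosages[0, 0] == pytest.approx(expected_mean, abs=1e-6)


def test_gcta_grm_roundtrip(tmp_path, unrelated_pop):
    G = unrelated_pop.take_variants(np.arange(500)).take_individuals(np.arange(60))
    K = build_grm(G, "yang")
    prefix = str(tmp_path / "k")
    write_gcta_grm(K, prefix)
    back = read_gcta_grm(prefix)
    assert back.n_variants == K.n_variants
    assert np.abs(back.values - K.values).max() < 1e-6  # float32 storage
    assert np.array_equal(back.ids.astype(int), K.ids)
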