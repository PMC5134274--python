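"""Synthetic-population generator: pedigrees, LD, gene dropping, records."""

import numpy as np
import pandas as pd
import pytest

from gpselect import simpop
from gpselect.simpop import (
    ChromMap,
    Pedigree,
    gene_drop,
    make_chrom_maps,
    make_pedigree,
    sim_bull_records,
    sim_founder_haplotypes,
    sim_phenotypes,
    sim_trait,
    sim_unrelated_population,
)


def _single_chrom(m, length=1_000_000, seed=0):
    return make_chrom_maps(1, m, length, seed=seed)[0]


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def test_minimal_pedigree():
    ped = make_pedigree(1, 1, 1, seed=1)
    assert ped.n == 2
    t = ped.table
    son = t[t["generation"] == 1].iloc[0]
    sire_cohort = t.set_index("id").loc[son["sire"], "cohort"]
    assert sire_cohort == "discovery"
    assert son["cohort"] == "validation"


def test_validation_cohort_has_discovery_sires():
    ped = make_pedigree(20, 10, 2, seed=7)
    t = ped.table
    last = t[t["generation"] == 2]
    assert len(last) == 200
    assert (last["cohort"] == "validation").all()
    assert (t[t["generation"] < 2]["cohort"] == "discovery").all()
    cohort_of = t.set_index("id")["cohort"]
    frac = (cohort_of.loc[last["sire"]].to_numpy() == "discovery").mean()
    assert frac == 1.0


def test_pedigree_determinism_and_errors():
    a = make_pedigree(5, 4, 3, seed=7)
    b = make_pedigree(5, 4, 3, seed=7)
    pd.testing.assert_frame_equal(a.table, b.table)
    with pytest.raises(ValueError):
        make_pedigree(0, 4, 3)
    with pytest.raises(ValueError):
        Pedigree(pd.DataFrame({"id": [1, 2], "sire": [2, 0], "dam": [0, 0],
                               "generation": [0, 0], "cohort": ["discovery"] * 2}))


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

def _adjacent_r2(h, lag=1):
    x = h.astype(float)
    a, b = x[:, :-lag], x[:, lag:]
    r = [np.corrcoef(a[:, j], b[:, j])[0, 1] for j in range(a.shape[1])]
    return np.nanmean(np.square(r))


def test_ld_zero_gives_independence():
    pool = sim_founder_haplotypes(_single_chrom(5001), 0.05, 0.0, 200, seed=2)
    mean_r2 = _adjacent_r2(pool.haplotypes)
    assert mean_r2 <= 3 / 200 + 0.01


def test_ld_decays_with_distance():
    pool = sim_founder_haplotypes(_single_chrom(2000), 0.05, 0.95, 200, seed=3)
    assert _adjacent_r2(pool.haplotypes, lag=1) > _adjacent_r2(pool.haplotypes, lag=50)


def test_two_haplotypes_one_variant_differ():
    cm = ChromMap(chrom_id=1, n_variants=1, length_bp=100, positions=np.array([50]))
    pool = sim_founder_haplotypes(cm, 0.4, 0.0, 2, seed=4)
    assert pool.haplotypes[0, 0] != pool.haplotypes[1, 0]


def test_maf_floor_and_argument_errors():
    pool = sim_founder_haplotypes(_single_chrom(500), 0.1, 0.5, 100, seed=5)
    p = pool.haplotypes.mean(axis=0)
    assert (np.minimum(p, 1 - p) >= 0.1 - 1e-12).all()
    with pytest.raises(ValueError):
        sim_founder_haplotypes(_single_chrom(10), 0.05, 1.0, 100, seed=5)
    with pytest.raises(ValueError):
        sim_founder_haplotypes(_single_chrom(10), 0.05, 0.5, 101, seed=5)


def test_haplotype_seed_determinism():
    a = sim_founder_haplotypes(_single_chrom(300), 0.05, 0.8, 50, seed=11)
    b = sim_founder_haplotypes(_single_chrom(300), 0.05, 0.8, 50, seed=11)
    assert np.array_equal(a.haplotypes, b.haplotypes)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _trio_pedigree():
    return Pedigree(pd.DataFrame({
        "id": [1, 2, 3, 4],
        "sire": [0, 0, 1, 1],
        "dam": [0, 0, 2, 2],
        "generation": [0, 0, 1, 1],
        "cohort": ["discovery"] * 4,
    }))


def test_no_recombination_copies_a_parental_gamete():
    ped = _trio_pedigree()
    pool = sim_founder_haplotypes(_single_chrom(400), 0.05, 0.5, 8, seed=6)
    G = gene_drop(ped, pool, morgans_per_chrom=0.0, seed=6)
    sire_haps = pool.haplotypes[0], pool.haplotypes[1]
    dam_haps = pool.haplotypes[2], pool.haplotypes[3]
    for child_row in (2, 3):
        child = G.dosages[child_row].astype(int)
        matched = False
        for hs in sire_haps:
            for hd in dam_haps:
                if np.array_equal(child, hs + hd):
                    matched = True
        assert matched


def test_fixed_site_transmission():
    ped = _trio_pedigree()
    pool = sim_founder_haplotypes(_single_chrom(50), 0.05, 0.0, 8, seed=7)
    pool.haplotypes[:4, 10] = 1  # both parents homozygous for the counted allele
    G = gene_drop(ped, pool, morgans_per_chrom=1.0, seed=7)
    assert (G.dosages[2:, 10] == 2).all()


def test_full_sib_genotypic_correlation_half():
    """Average full-sib correlation of standardized dosages is ~0.5.

    Loci are placed one per chromosome so they segregate independently and
    the realized relationship concentrates at its expectation; several sib
    pairs are averaged to damp the parental-draw lottery.
    """
    n_pairs = 8
    rows = [(1, 0, 0, 0, "discovery"), (2, 0, 0, 0, "discovery")]
    rows += [(3 + i, 1, 2, 1, "discovery") for i in range(2 * n_pairs)]
    ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "generation",
                                               "cohort"]))
    maps = make_chrom_maps(5000, 1, 1000, seed=8)
    pool = sim_founder_haplotypes(maps, 0.1, 0.0, 400, seed=8)
    G = gene_drop(ped, pool, morgans_per_chrom=1.0, seed=8)
    p = pool.haplotypes.mean(axis=0)  # founder frequencies are never 0 or 1
    w = (G.dosages.astype(float) - 2 * p) / np.sqrt(2 * p * (1 - p))
    rs = [np.corrcoef(w[2 + 2 * i], w[3 + 2 * i])[0, 1] for i in range(n_pairs)]
    assert np.mean(rs) == pytest.approx(0.5, abs=0.05)


def test_founder_shortage_raises():
    ped = make_pedigree(10, 2, 1, seed=1)
    pool = sim_founder_haplotypes(_single_chrom(50), 0.05, 0.0, 10, seed=1)
    with pytest.raises(ValueError, match="founder shortage"):
        gene_drop(ped, pool, 1.0, seed=1)


def test_allele_frequency_conservation():
    """Gene dropping is drift-only: offspring frequencies match the founders
    within 3 binomial SE."""
    ped = make_pedigree(20, 10, 2, seed=13)
    pool = sim_founder_haplotypes(_single_chrom(1000), 0.1, 0.5, 2 * 20, seed=13)
    G = gene_drop(ped, pool, morgans_per_chrom=1.0, seed=13)
    p0 = pool.haplotypes.mean(axis=0)
    last = G.take_individuals(np.flatnonzero(
        (ped.table["generation"] == 2).to_numpy()))
    p2 = last.freqs
    n_gametes = 2 * last.n_individuals
    se = np.sqrt(p0 * (1 - p0) / n_gametes)
    frac_within = np.mean(np.abs(p2 - p0) <= 3 * se + 1e-9)
    # drift through the 20-sire bottleneck adds variance beyond sampling SE;
    # the mean shift is what must vanish
    assert abs((p2 - p0).mean()) < 3 * np.sqrt(np.mean(p0 * (1 - p0)) / n_gametes)
    assert frac_within > 0.5


def test_gene_drop_determinism():
    ped = make_pedigree(4, 3, 2, seed=2)
    pool = sim_founder_haplotypes(_single_chrom(200), 0.05, 0.5, 16, seed=2)
    a = gene_drop(ped, pool, 1.0, seed=2)
    b = gene_drop(ped, pool, 1.0, seed=2)
    assert np.array_equal(a.dosages, b.dosages)


# ---------------------------------------------------------------------------
# traits and bull records
# ---------------------------------------------------------------------------

def test_heritability_realization():
    G = sim_unrelated_population(make_chrom_maps(1, 400, seed=14), 2500, seed=14)
    arch = sim_trait(G, n_qtl=40, target_h2=0.4, seed=14)
    y = sim_phenotypes(arch, seed=15)
    slope = np.polyfit(arch.tbv, y, 1)[0]
    assert slope == pytest.approx(1.0, abs=0.05)
    assert arch.tbv.var() / y.var() == pytest.approx(0.4, abs=0.05)


def test_bull_record_reliability_definitions():
    tbv = np.random.default_rng(16).normal(0, 2, 500)
    rec = sim_bull_records(tbv, h2=0.25, edc_range=(1e9, 1e9), seed=16)
    assert (rec["REL_EBV"] >= 0.999).all()
    rec = sim_bull_records(tbv, h2=0.25, edc_range=(135.0, 135.0), seed=16)
    assert rec["REL_EBV"].to_numpy() == pytest.approx(0.9)
    with pytest.raises(ValueError):
        sim_bull_records(tbv, h2=1.5, edc_range=(10, 20), seed=16)


def test_ebv_reliability_montecarlo():
    """cor(EBV, TBV)^2 over 5000 bulls matches the mean reliability."""
    tbv = np.random.default_rng(17).normal(0, 3, 5000)
    rec = sim_bull_records(tbv, h2=0.3, edc_range=(24.0, 971.0), seed=17)
    r2 = np.corrcoef(rec["EBV"], tbv)[0, 1] ** 2
    assert r2 == pytest.approx(rec["REL_EBV"].mean(), abs=0.05)


def test_bull_records_determinism():
    tbv = np.random.default_rng(18).normal(size=100)
    a = sim_bull_records(tbv, 0.3, (24, 971), seed=18)
    b = sim_bull_records(tbv, 0.3, (24, 971), seed=18)
    pd.testing.assert_frame_equal(a, b)


def test_unrelated_population_shape():
    G = sim_unrelated_population(make_chrom_maps(1, 100, seed=3), 50, seed=3)
    assert G.dosages.shape == (50, 100)
    assert set(np.unique(G.dosages)) <= {0.0, 1.0, 2.0}
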