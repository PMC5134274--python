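"""Synthetic dairy-cattle populations with known truth.

Generates the statistical structure the downstream analysis assumes:

* LD-structured dense biallelic variants (latent Gaussian AR(1) copula on
  founder haplotypes, parameter ``ld_rho``), with a guaranteed minor-allele
  frequency floor;
* multi-generation half-sib family pedigrees (sires tracked, dams drawn from
  an effectively infinite unrelated dam population), with a
  discovery/validation split on the last generation emulating a birth-year
  split where validation bulls are sons of discovery sires;
* gene dropping with recombination (Haldane map function on bp-proportional
  genetic distance);
* trait architectures (a few large-effect QTL or a fully polygenic
  background) with a target heritability; and
* progeny-information-driven pseudo-EBVs: per bull an effective daughter
  contribution (EDC) is drawn, the reliability follows
  ``REL = EDC / (EDC + alpha)`` with ``alpha = (4 - h2) / h2``, and the EBV
  combines parent-average and progeny information coherently so that
  de-regression round-trips without exclusions.

All operations are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .deregress import alpha_of, edc_from_rel
from .grm import GenotypeMatrix

__all__ = [
    "ChromMap",
    "Pedigree",
    "HaplotypePool",
    "TraitArchitecture",
    "make_chrom_maps",
    "make_pedigree",
    "sim_founder_haplotypes",
    "gene_drop",
    "sim_unrelated_population",
    "sim_trait",
    "sim_phenotypes",
    "sim_polygenic",
    "sim_bull_records",
]


# ---------------------------------------------------------------------------
# maps and pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromMap:
    """Physical map of one chromosome: strictly increasing 1-based positions."""

    chrom_id: int
    n_variants: int
    length_bp: int
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size != self.n_variants:
            raise ValueError("positions length disagrees with n_variants")
        if pos.size and (pos[0] < 1 or pos[-1] > self.length_bp):
            raise ValueError("positions must lie in [1, length_bp]")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")


def make_chrom_maps(n_chrom: int, variants_per_chrom: int, length_bp: int = 100_000_000,
                    seed: int = 0) -> list[ChromMap]:
    """Evenly sized chromosomes with uniformly scattered variant positions."""
    if n_chrom < 1 or variants_per_chrom < 1:
        raise ValueError("counts must be >= 1")
    if variants_per_chrom > length_bp:
        raise ValueError("more variants than base pairs")
    rng = np.random.default_rng(seed)
    maps = []
    for c in range(1, n_chrom + 1):
        pos = np.unique(rng.integers(1, length_bp + 1, size=variants_per_chrom))
        while pos.size < variants_per_chrom:   # top up collisions (rare)
            extra = rng.integers(1, length_bp + 1, size=variants_per_chrom - pos.size + 8)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=variants_per_chrom, replace=False))
        maps.append(ChromMap(chrom_id=c, n_variants=variants_per_chrom,
                             length_bp=length_bp, positions=pos))
    return maps


@dataclass
class Pedigree:
    """Pedigree table: id, sire, dam (0 = unknown), generation, cohort."""

    table: pd.DataFrame

    def __post_init__(self):
        need = {"id", "sire", "dam", "generation", "cohort"}
        if not need <= set(self.table.columns):
            raise ValueError(f"pedigree table must have columns {sorted(need)}")
        t = self.table
        gen = t.set_index("id")["generation"]
        for col in ("sire", "dam"):
            parents = t.loc[t[col] != 0, col]
            if not parents.isin(t["id"]).all():
                raise ValueError(f"{col} ids missing from pedigree")
            if parents.size and not (gen.loc[parents].to_numpy()
                                     < t.loc[t[col] != 0, "generation"].to_numpy()).all():
                raise ValueError("parents must precede offspring in generation order")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def founders(self) -> pd.DataFrame:
        t = self.table
        return t[(t["sire"] == 0) & (t["dam"] == 0)]


def make_pedigree(n_sires: int, sons_per_sire: int, n_generations: int,
                  validation_last_gen: bool = True, seed: int = 0) -> Pedigree:
    """Half-sib family pedigree over ``n_generations`` of sons.

    Generation 0 holds ``n_sires`` unrelated founder sires.  In each later
    generation every active sire gets ``sons_per_sire`` sons out of unknown,
    unrelated dams; the sires of the next generation are the first
    ``n_sires`` sons.  With ``validation_last_gen`` the last generation forms
    the validation cohort and everything earlier the discovery cohort, so
    every validation bull has a discovery-cohort sire under default mating.
    """
    if min(n_sires, sons_per_sire, n_generations) < 1:
        raise ValueError("all counts must be >= 1")
    rows = []
    next_id = 1
    sires = []
    for _ in range(n_sires):
        rows.append((next_id, 0, 0, 0, "discovery"))
        sires.append(next_id)
        next_id += 1
    for gen in range(1, n_generations + 1):
        cohort = "validation" if (validation_last_gen and gen == n_generations) else "discovery"
        sons = []
        for s in sires:
            for _ in range(sons_per_sire):
                rows.append((next_id, s, 0, gen, cohort))
                sons.append(next_id)
                next_id += 1
        sires = sons[:n_sires]
    table = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "cohort"])
    return Pedigree(table)


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """Binary founder haplotypes with the physical map they were drawn on."""

    haplotypes: np.ndarray          # (n_haplotypes, n_variants) uint8
    chrom_maps: list
    variants: pd.DataFrame          # id, chrom, bp, a1, a2

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


def _variant_table(chrom_maps: Sequence[ChromMap]) -> pd.DataFrame:
    frames = []
    for cm in chrom_maps:
        frames.append(pd.DataFrame({
            "id": [f"{cm.chrom_id}:{p}" for p in cm.positions],
            "chrom": cm.chrom_id,
            "bp": cm.positions,
            "a1": "A",
            "a2": "B",
        }))
    return pd.concat(frames, ignore_index=True)


def sim_founder_haplotypes(chrom_map, maf_low: float, ld_rho: float,
                           n_haplotypes: int, seed: int) -> HaplotypePool:
    """Simulate a founder haplotype pool with first-order Markov LD.

    A latent standard-normal AR(1) field with autocorrelation ``ld_rho`` is
    thresholded at per-variant frequency quantiles; adjacent-variant allelic
    correlation is a monotone function of ``ld_rho`` and vanishes at 0.  The
    threshold count is clipped so the realized founder MAF is >= ``maf_low``
    at every site (no monomorphic or rare sites survive).
    """
    if not 0.0 < maf_low < 0.5:
        raise ValueError("maf_low must be in (0, 0.5)")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must be in [0, 1)")
    if n_haplotypes < 2 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be an even number >= 2")
    chrom_maps = [chrom_map] if isinstance(chrom_map, ChromMap) else list(chrom_map)
    rng = np.random.default_rng(seed)
    blocks = []
    innov = np.sqrt(1.0 - ld_rho ** 2)
    kmin = max(1, int(np.ceil(maf_low * n_haplotypes)))
    for cm in chrom_maps:
        m = cm.n_variants
        eps = rng.standard_normal((n_haplotypes, m))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + innov * eps[:, j]
        p_target = rng.uniform(maf_low, 1.0 - maf_low, size=m)
        k = np.clip(np.rint(p_target * n_haplotypes).astype(int), kmin, n_haplotypes - kmin)
        zs = np.sort(z, axis=0)
        thr = np.take_along_axis(zs, (k - 1)[None, :], axis=0)
        blocks.append((z <= thr).astype(np.uint8))
    haps = np.concatenate(blocks, axis=1)
    return HaplotypePool(haplotypes=haps, chrom_maps=chrom_maps,
                         variants=_variant_table(chrom_maps))


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _recomb_probs(chrom_maps: Sequence[ChromMap], morgans_per_chrom: float) -> np.ndarray:
    """Per-site switch probabilities (Haldane), 0.5 at chromosome starts."""
    probs = []
    for cm in chrom_maps:
        r = np.empty(cm.n_variants)
        r[0] = 0.5
        if cm.n_variants > 1:
            d = np.diff(cm.positions) / cm.length_bp * morgans_per_chrom
            r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d))
        probs.append(r)
    return np.concatenate(probs)


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    switch = rng.random(r.size) < r
    use_b = np.cumsum(switch) % 2 == 1
    return np.where(use_b, hap_b, hap_a)


def gene_drop(pedigree: Pedigree, founders: HaplotypePool,
              morgans_per_chrom: float = 1.0, seed: int = 0) -> GenotypeMatrix:
    """Drop founder haplotypes through a pedigree with recombination.

    Founders receive consecutive pool haplotype pairs.  For parents recorded
    as unknown (dam = 0 in half-sib pedigrees) the gamete is a recombinant of
    two pool haplotypes drawn at random — an effectively infinite unrelated
    dam population sharing the founder allele frequencies.  Offspring dosage
    is the sum of the two inherited gametes.
    """
    if morgans_per_chrom < 0:
        raise ValueError("morgans_per_chrom must be >= 0")
    founder_ids = pedigree.founders["id"].to_numpy()
    if 2 * founder_ids.size > founders.n_haplotypes:
        raise ValueError(
            f"founder shortage: pedigree needs {2 * founder_ids.size} haplotypes, "
            f"pool has {founders.n_haplotypes}"
        )
    rng = np.random.default_rng(seed)
    r = _recomb_probs(founders.chrom_maps, morgans_per_chrom)
    pool = founders.haplotypes

    gametes: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, fid in enumerate(founder_ids):
        gametes[fid] = (pool[2 * i], pool[2 * i + 1])

    t = pedigree.table.sort_values(["generation", "id"])
    for row in t.itertuples(index=False):
        if row.id in gametes:
            continue
        if row.sire != 0:
            pat = _meiosis(*gametes[row.sire], r, rng)
        else:
            a, b = rng.integers(0, founders.n_haplotypes, size=2)
            pat = _meiosis(pool[a], pool[b], r, rng)
        if row.dam != 0:
            mat = _meiosis(*gametes[row.dam], r, rng)
        else:
            a, b = rng.integers(0, founders.n_haplotypes, size=2)
            mat = _meiosis(pool[a], pool[b], r, rng)
        gametes[row.id] = (pat, mat)

    ids = pedigree.table["id"].to_numpy()
    dosages = np.empty((ids.size, founders.n_variants), dtype=np.float32)
    for j, iid in enumerate(ids):
        g = gametes[iid]
        dosages[j] = g[0].astype(np.float32) + g[1]
    return GenotypeMatrix(dosages=dosages, variants=founders.variants.copy(), ids=ids)


def sim_unrelated_population(chrom_maps, n_individuals: int, maf_low: float = 0.01,
                             ld_rho: float = 0.0, seed: int = 0) -> GenotypeMatrix:
    """Unrelated Hardy-Weinberg individuals: random pairing of 2n haplotypes."""
    pool = sim_founder_haplotypes(chrom_maps, maf_low, ld_rho, 2 * n_individuals, seed)
    dosages = (pool.haplotypes[0::2] + pool.haplotypes[1::2]).astype(np.float32)
    return GenotypeMatrix(dosages=dosages, variants=pool.variants,
                          ids=np.arange(1, n_individuals + 1))


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Causal layer: QTL ids/effects, true breeding values, target h2."""

    qtl_ids: np.ndarray
    qtl_effects: np.ndarray
    tbv: np.ndarray
    target_h2: float


def sim_trait(G: GenotypeMatrix, n_qtl: int, target_h2: float, seed: int = 0,
              qtl_weight: float = 1.0, equal_variance_qtl: bool = False) -> TraitArchitecture:
    """Plant ``n_qtl`` large-effect QTL, optionally on a polygenic background.

    ``qtl_weight`` is the fraction of genetic variance carried by the named
    QTL; the remainder is a dense background of small standardized effects
    over all variants (the architecture dense-genotype traits are assumed to
    have).  ``qtl_weight=1`` gives a pure oligogenic trait, convenient for
    truth-recovery tests.

    With ``equal_variance_qtl`` each QTL contributes the same genetic
    variance (random sign, frequency-compensated effect size) instead of
    N(0,1) per-allele effects; replicated experiments then probe the same
    detection regime instead of re-rolling the effect-size lottery, at the
    cost of a less realistic effect-size spectrum.
    """
    if not 0.0 < target_h2 < 1.0:
        raise ValueError("target_h2 must be in (0, 1)")
    if not 1 <= n_qtl <= G.n_variants:
        raise ValueError("n_qtl out of range")
    if not 0.0 < qtl_weight <= 1.0:
        raise ValueError("qtl_weight must be in (0, 1]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(G.n_variants, size=n_qtl, replace=False))
    if equal_variance_qtl:
        pq = G.freqs[idx]
        effects = rng.choice([-1.0, 1.0], size=n_qtl) / np.sqrt(2.0 * pq * (1.0 - pq))
    else:
        effects = rng.standard_normal(n_qtl)
    tbv = G.dosages[:, idx].astype(np.float64) @ effects
    tbv -= tbv.mean()
    sd = tbv.std()
    if sd == 0.0:
        raise ValueError("QTL genotypes carry no variance; increase diversity")
    tbv *= np.sqrt(qtl_weight) / sd
    effects *= np.sqrt(qtl_weight) / sd
    if qtl_weight < 1.0:
        p = G.freqs
        u = rng.standard_normal(G.n_variants)
        bg = np.zeros(G.n_individuals)
        for lo in range(0, G.n_variants, 4096):
            hi = min(lo + 4096, G.n_variants)
            pc = p[lo:hi]
            w = (G.dosages[:, lo:hi].astype(np.float64) - 2.0 * pc) / np.sqrt(
                2.0 * pc * (1.0 - pc))
            bg += w @ u[lo:hi]
        bg -= bg.mean()
        tbv += bg * (np.sqrt(1.0 - qtl_weight) / bg.std())
    return TraitArchitecture(
        qtl_ids=G.variants["id"].to_numpy()[idx],
        qtl_effects=effects,
        tbv=tbv,
        target_h2=target_h2,
    )


def sim_phenotypes(arch: TraitArchitecture, seed: int = 0) -> np.ndarray:
    """Phenotypes with var(TBV)/var(y) equal to the target h2 in expectation."""
    rng = np.random.default_rng(seed)
    var_t = arch.tbv.var()
    var_e = var_t * (1.0 - arch.target_h2) / arch.target_h2
    return arch.tbv + rng.normal(0.0, np.sqrt(var_e), size=arch.tbv.size)


def sim_polygenic(G: GenotypeMatrix, h2: float, seed: int = 0):
    """Fully polygenic trait spanned by the markers of ``G``.

    Per-variant effects are drawn on the standardized scale so the genetic
    values lie exactly in the span of the crossprod GRM; returns
    ``(y, g)`` with genetic values scaled to variance ``h2`` and residual
    variance ``1 - h2``.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    m = G.n_variants
    p = G.freqs
    u = rng.standard_normal(m) / np.sqrt(m)
    w = (G.dosages.astype(np.float64) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    g = w @ u
    g = (g - g.mean()) / g.std() * np.sqrt(h2)
    y = g + rng.normal(0.0, np.sqrt(1.0 - h2), size=g.size)
    return y, g


# ---------------------------------------------------------------------------
# bull records
# ---------------------------------------------------------------------------

def sim_bull_records(tbv: np.ndarray, h2: float, edc_range: tuple, seed: int = 0,
                     pedigree: Pedigree | None = None) -> pd.DataFrame:
    """Simulate EBV / PA / reliability records from true breeding values.

    Per bull an effective daughter contribution ``EDC_EBV`` is drawn uniform
    in ``edc_range``, giving ``REL_EBV = EDC / (EDC + alpha)`` with
    ``alpha = (4 - h2) / h2``.  The EBV combines the parent average (from the
    sire's EBV when the pedigree is supplied; dams unknown) with an
    independent progeny-deviation record carrying ``EDC_prog`` effective
    daughters, weighted as Bayesian information combining.  This reproduces
    the textbook moment structure — ``EBV = REL*TBV + noise`` with noise
    variance ``REL(1 - REL) var(TBV)`` for bulls without parent information —
    and guarantees that de-regression round-trips without exclusions.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    low, high = edc_range
    if not 0.0 < low <= high:
        raise ValueError("edc_range must satisfy 0 < low <= high")
    tbv = np.asarray(tbv, dtype=np.float64)
    n = tbv.size
    rng = np.random.default_rng(seed)
    alpha = alpha_of(h2)
    sigma_t2 = float(tbv.var())
    if sigma_t2 == 0.0:
        raise ValueError("true breeding values have zero variance")

    if pedigree is not None:
        if pedigree.n != n:
            raise ValueError("pedigree and tbv disagree on individual count")
        ids = pedigree.table["id"].to_numpy()
        sire = pedigree.table["sire"].to_numpy()
        dam = pedigree.table["dam"].to_numpy()
        cohort = pedigree.table["cohort"].to_numpy()
        order = np.argsort(pedigree.table["generation"].to_numpy(), kind="stable")
    else:
        ids = np.arange(1, n + 1)
        sire = np.zeros(n, dtype=int)
        dam = np.zeros(n, dtype=int)
        cohort = np.full(n, "discovery")
        order = np.arange(n)

    pos = {int(i): j for j, i in enumerate(ids)}
    edc_ebv = rng.uniform(low, high, size=n)
    noise = rng.standard_normal(n)

    ebv = np.zeros(n)
    pa = np.zeros(n)
    rel_ebv = np.zeros(n)
    rel_sire = np.zeros(n)
    rel_dam = np.zeros(n)

    for j in order:
        rs = rel_ebv[pos[int(sire[j])]] if sire[j] else 0.0
        rd = rel_ebv[pos[int(dam[j])]] if dam[j] else 0.0
        pa_j = 0.0
        if sire[j]:
            pa_j += 0.5 * ebv[pos[int(sire[j])]]
        if dam[j]:
            pa_j += 0.5 * ebv[pos[int(dam[j])]]
        rel_pa = (rs + rd) / 4.0
        edc_pa = edc_from_rel(rel_pa, alpha)
        if edc_ebv[j] <= edc_pa:
            edc_ebv[j] = edc_pa + 1.0   # keep progeny information positive
        edc_prog = edc_ebv[j] - edc_pa
        # progeny-deviation record: tbv + noise with alpha*sigma_t2/EDC_prog
        y_prog = tbv[j] + noise[j] * np.sqrt(alpha * sigma_t2 / edc_prog)
        k = edc_prog / (edc_prog + edc_pa + alpha)
        ebv[j] = pa_j + k * (y_prog - pa_j)
        pa[j] = pa_j
        rel_sire[j] = rs
        rel_dam[j] = rd
        rel_ebv[j] = edc_ebv[j] / (edc_ebv[j] + alpha)

    return pd.DataFrame({
        "id": ids,
        "sire": sire,
        "dam": dam,
        "cohort": cohort,
        "EBV": ebv,
        "PA": pa,
        "REL_EBV": rel_ebv,
        "REL_sire": rel_sire,
        "REL_dam": rel_dam,
        "EDC_EBV": edc_ebv,
        "TBV": tbv,
        "h2": h2,
    })
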