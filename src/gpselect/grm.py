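"""Genomic relationship matrices, LD computations and variant-set algebra.

The genomic relationship matrix (GRM) is the realized additive relationship
between individuals computed from centered, frequency-scaled dosages.  Two
diagonal conventions are supported:

``yang``
    The heterozygosity-corrected diagonal
    ``1 + (1/N) sum_i (x_ij^2 - (1+2 p_i) x_ij + 2 p_i^2) / (2 p_i (1-p_i))``
    with the usual cross-product off-diagonals.  This is the convention used
    by GCTA and is the default.
``crossprod``
    ``W W' / N`` with ``w_ij = (x_ij - 2 p_i) / sqrt(2 p_i (1-p_i))``
    everywhere.  Positive semi-definite by construction; required whenever
    marker effects are back-solved from breeding values, because the
    back-solving identity assumes exactly this factorization.

Allele frequencies are always recomputed on the current analysis sample.
Dosages are stored as float32 (they may be imputed values in [0, 2]); all
linear algebra is accumulated in float64.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_VARIANT_COLUMNS = ("id", "chrom", "bp", "a1", "a2")

#: default eigenvalue floor (relative to the mean diagonal) used by ensure_pd
DEFAULT_PD_EPS = 1e-6

#: default MAF cut-off: variants with min(p, 1-p) <= this are dropped
DEFAULT_MIN_MAF = 0.01

#: chunk size (variants) for blocked matrix accumulation
_CHUNK = 2048


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_variants)`` array with values in ``[0, 2]``
        (hard calls 0/1/2 or imputed dosages).  Stored as float32.
    variants
        DataFrame with columns ``id, chrom, bp, a1, a2`` (1-based bp).
        ``a1`` is the dosage-counted allele.
    ids
        Individual identifiers, one per row of ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.dtype not in (np.float32, np.int8):
            self.dosages = self.dosages.astype(np.float32)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x variants array")
        self.ids = np.asarray(self.ids)
        if not isinstance(self.variants, pd.DataFrame):
            raise TypeError("variants must be a DataFrame")
        missing = set(_VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table lacks columns {sorted(missing)}")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant table and dosage matrix disagree on variant count")
        if len(self.ids) != self.dosages.shape[0]:
            raise ValueError("ids and dosage matrix disagree on individual count")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Allele frequency of the dosage-counted allele, on this sample."""
        return self.dosages.mean(axis=0, dtype=np.float64) / 2.0

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            ids=self.ids,
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            variants=self.variants,
            ids=self.ids[index],
        )

    def variant_indexer(self, variant_ids) -> np.ndarray:
        """Map variant ids to column indices, raising on unknown ids."""
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(pd.Index(np.asarray(variant_ids)))
        if (idx < 0).any():
            bad = np.asarray(variant_ids)[idx < 0]
            raise KeyError(f"variant id(s) not in genotype matrix: {bad[:5].tolist()}")
        return idx


@dataclass
class GRMatrix:
    """Symmetric realized-relationship matrix with provenance.

    ``n_variants`` is the N used in the 1/N averaging; ``source`` records
    whether the matrix was built from all, selected or complementary
    variants.
    """

    values: np.ndarray
    n_variants: int
    diag_mode: str = "yang"
    source: str = "all"
    ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if self.ids is None:
            self.ids = np.arange(n)
        self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def filter_maf(G: GenotypeMatrix, min_maf: float = DEFAULT_MIN_MAF) -> GenotypeMatrix:
    """Retain variants with minor allele frequency strictly above ``min_maf``.

    Frequencies are computed on the sample in ``G``.  Monomorphic variants
    are removed at any threshold >= 0.
    """
    if not 0.0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")
    p = G.freqs
    keep = np.minimum(p, 1.0 - p) > min_maf
    if not keep.any():
        raise ValueError("MAF filter removed every variant")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("MAF filter (> %g) removed %d of %d variants", min_maf, n_removed, keep.size)
    return G.take_variants(np.flatnonzero(keep))


def build_grm(G: GenotypeMatrix, diag_mode: str = "yang", source: str = "all") -> GRMatrix:
    """Build a GRM from dosages.

    Off-diagonals are always ``(1/N) sum_i (x_ij - 2p_i)(x_ik - 2p_i) /
    (2 p_i (1 - p_i))``.  With ``diag_mode='yang'`` the diagonal uses the
    heterozygosity-corrected form; with ``'crossprod'`` the matrix is exactly
    ``W W' / N``.
    """
    if diag_mode not in ("yang", "crossprod"):
        raise ValueError("diag_mode must be 'yang' or 'crossprod'")
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    p = G.freqs
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("fixed variants present; apply filter_maf first")

    n, m = G.n_individuals, G.n_variants
    A = np.zeros((n, n), dtype=np.float64)
    yang_diag = np.full(n, 1.0) if diag_mode == "yang" else None
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        x = G.dosages[:, lo:hi].astype(np.float64)
        pc = p[lo:hi]
        het = 2.0 * pc * (1.0 - pc)
        w = (x - 2.0 * pc) / np.sqrt(het)
        A += w @ w.T
        if yang_diag is not None:
            yang_diag += ((x * x - (1.0 + 2.0 * pc) * x + 2.0 * pc * pc) / het).sum(axis=1) / m
    A /= m
    if yang_diag is not None:
        np.fill_diagonal(A, yang_diag)
    return GRMatrix(values=A, n_variants=m, diag_mode=diag_mode, source=source, ids=G.ids)


def cross_grm(G_rows: GenotypeMatrix, G_cols: GenotypeMatrix, freqs: np.ndarray) -> np.ndarray:
    """Cross relationship block ``W_rows W_cols' / N`` at supplied frequencies.

    Used for direct mixed-model prediction of individuals outside the
    training set; ``freqs`` must be the training-sample frequencies so the
    centering matches the training GRM.
    """
    if G_rows.n_variants != G_cols.n_variants or G_rows.n_variants != len(freqs):
        raise ValueError("variant dimensions disagree")
    m = G_rows.n_variants
    out = np.zeros((G_rows.n_individuals, G_cols.n_individuals))
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        pc = freqs[lo:hi]
        scale = np.sqrt(2.0 * pc * (1.0 - pc))
        wr = (G_rows.dosages[:, lo:hi].astype(np.float64) - 2.0 * pc) / scale
        wc = (G_cols.dosages[:, lo:hi].astype(np.float64) - 2.0 * pc) / scale
        out += wr @ wc.T
    return out / m


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(G: GenotypeMatrix, i: int, k: int) -> float:
    """Squared Pearson correlation of two dosage vectors (allele-orientation
    invariant)."""
    x = G.dosages[:, i].astype(np.float64)
    y = G.dosages[:, k].astype(np.float64)
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero-variance variant in LD computation")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_block(G: GenotypeMatrix, anchor: int, others: np.ndarray) -> np.ndarray:
    """r^2 between one anchor column and many other columns (vectorized)."""
    x = G.dosages[:, anchor].astype(np.float64)
    Y = G.dosages[:, others].astype(np.float64)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = xc @ xc
    sy = (Yc * Yc).sum(axis=0)
    num = xc @ Yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((sx > 0) & (sy > 0), (num * num) / (sx * sy), 0.0)
    return r2


def ld_exclusion_set(
    G: GenotypeMatrix,
    selected,
    window_bp: int = 2_000_000,
    p_thresh: float = 0.01,
) -> np.ndarray:
    """Variants in significant LD with any selected variant, within a window.

    For each selected variant, same-chromosome variants with
    ``|bp - bp_sel| <= window_bp`` are tested with the allelic-correlation
    statistic ``n r^2 ~ chi2(1)``; those with p < ``p_thresh`` are excluded.
    The selected variants themselves are always part of the returned set.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not 0.0 < p_thresh < 1.0:
        raise ValueError("p_thresh must be in (0, 1)")
    selected = np.asarray(selected)
    if selected.size == 0:
        return selected
    sel_idx = G.variant_indexer(selected)
    chrom = G.variants["chrom"].to_numpy()
    bp = G.variants["bp"].to_numpy()
    n = G.n_individuals
    crit_r2 = stats.chi2.isf(p_thresh, df=1) / n
    excluded = set(sel_idx.tolist())
    for si in sel_idx:
        in_window = np.flatnonzero(
            (chrom == chrom[si]) & (np.abs(bp - bp[si]) <= window_bp)
        )
        others = in_window[in_window != si]
        if others.size == 0:
            continue
        r2 = _r2_block(G, si, others)
        excluded.update(others[r2 >= crit_r2].tolist())
    idx = np.array(sorted(excluded), dtype=int)
    return G.variants["id"].to_numpy()[idx]


def complement(G: GenotypeMatrix, selected, extra_excluded=()) -> GenotypeMatrix:
    """Restrict ``G`` to variants not in ``selected`` union ``extra_excluded``.

    This is the variant set behind the complementary GRM (GRMc); for simple
    panel-subset or p-value scenarios ``extra_excluded`` is empty and only
    the selected variants are removed.
    """
    selected = np.asarray(selected)
    extra = np.asarray(extra_excluded)
    # validate selected ids exist
    G.variant_indexer(selected)
    drop = np.union1d(selected, extra) if extra.size else selected
    keep = ~G.variants["id"].isin(drop).to_numpy()
    if not keep.any():
        raise ValueError("complement is empty: every variant excluded")
    return G.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# positive definiteness
# ---------------------------------------------------------------------------

def ensure_pd(K: GRMatrix, eps: float = DEFAULT_PD_EPS) -> GRMatrix:
    """Bend a GRM so all eigenvalues are >= ``eps * mean(diagonal)``.

    Returns the input unchanged when it already satisfies the bound;
    otherwise eigenvalues are floored and the matrix reassembled (logged).
    """
    A = 0.5 * (K.values + K.values.T)
    scale = float(np.mean(np.diag(A)))
    if scale <= 0.0:   # degenerate input; fall back to the diagonal magnitude
        scale = float(np.mean(np.abs(np.diag(A)))) or 1.0
    bound = eps * scale
    evals, evecs = np.linalg.eigh(A)
    if evals[0] >= bound:
        return K
    n_floored = int((evals < bound).sum())
    logger.warning(
        "GRM (%s, N=%d) bent for positive definiteness: %d eigenvalue(s) floored at %.3e",
        K.source, K.n_variants, n_floored, bound,
    )
    evals = np.maximum(evals, bound)
    fixed = (evecs * evals) @ evecs.T
    fixed = 0.5 * (fixed + fixed.T)
    return replace(K, values=fixed)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam I/O (bed v1.00, SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit genotype codes, SNP-major: 00=hom a1 (dosage 2), 10=het, 11=hom a2, 01=missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float64)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(G: GenotypeMatrix, prefix: str) -> None:
    """Write hard-call genotypes as a PLINK bed/bim/fam triplet.

    Imputed dosages are rounded to the nearest hard call; the bim carries
    (chrom, id, 0 cM, bp, a1, a2) with a1 the dosage-counted allele.
    """
    n, m = G.n_individuals, G.n_variants
    hard = np.rint(np.asarray(G.dosages, dtype=np.float64)).astype(np.int64)
    hard = np.clip(hard, 0, 2)
    codes = np.empty((n, m), dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        codes[hard == d] = c
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    idx = np.arange(n)
    byte_i, shift = idx // 4, 2 * (idx % 4)
    for j in range(m):
        np.bitwise_or.at(packed[j], byte_i, codes[:, j] << shift)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": G.variants["chrom"],
            "id": G.variants["id"],
            "cm": 0,
            "bp": G.variants["bp"],
            "a1": G.variants["a1"],
            "a2": G.variants["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": G.ids, "iid": G.ids, "pat": 0, "mat": 0, "sex": 0, "phen": -9}
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triplet; missing genotypes are mean-imputed."""
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phen"],
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK v1.00 bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if raw.size != m * n_bytes:
        raise ValueError("bed payload size inconsistent with bim/fam")
    raw = raw.reshape(m, n_bytes)
    shifts = np.arange(4) * 2
    codes = (raw[:, :, None] >> shifts) & 0b11            # (m, n_bytes, 4)
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T                    # (n, m)
    if np.isnan(dosages).any():
        col_mean = np.nanmean(dosages, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dosages))
        dosages[nan_r, nan_c] = col_mean[nan_c]
        logger.info("mean-imputed %d missing genotype calls on load", nan_r.size)
    variants = bim[["id", "chrom", "bp", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages=dosages.astype(np.float32), variants=variants,
                          ids=fam["iid"].to_numpy())


# ---------------------------------------------------------------------------
# GCTA GRM binary triplet I/O
# ---------------------------------------------------------------------------

def write_gcta_grm(K: GRMatrix, prefix: str) -> None:
    """Write a GRM as the GCTA binary triplet.

    ``<prefix>.grm.bin`` is the float32 lower triangle (row-major, diagonal
    included), ``<prefix>.grm.N.bin`` the per-pair variant count (constant
    here) and ``<prefix>.grm.id`` a two-column id file.
    """
    n = K.n
    tril = K.values[np.tril_indices(n)].astype(np.float32)
    tril.tofile(prefix + ".grm.bin")
    np.full(tril.size, K.n_variants, dtype=np.float32).tofile(prefix + ".grm.N.bin")
    pd.DataFrame({"fid": K.ids, "iid": K.ids}).to_csv(
        prefix + ".grm.id", sep="\t", header=False, index=False
    )


def read_gcta_grm(prefix: str) -> GRMatrix:
    """Read a GCTA binary GRM triplet."""
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"])
    n = len(ids)
    tril = np.fromfile(prefix + ".grm.bin", dtype=np.float32)
    if tril.size != n * (n + 1) // 2:
        raise ValueError("grm.bin size inconsistent with grm.id")
    counts = np.fromfile(prefix + ".grm.N.bin", dtype=np.float32)
    values = np.zeros((n, n), dtype=np.float64)
    il = np.tril_indices(n)
    values[il] = tril
    values = values + values.T - np.diag(np.diag(values))
    n_variants = int(round(float(counts[0]))) if counts.size else 0
    return GRMatrix(values=values, n_variants=n_variants, ids=ids["iid"].to_numpy())


def read_variant_ids(path: str) -> np.ndarray:
    """Read a one-id-per-line variant-set file."""
    with open(path) as fh:
        return np.array([line.strip() for line in fh if line.strip()])


def write_variant_ids(ids, path: str) -> None:
    with open(path, "w") as fh:
        for v in ids:
            fh.write(f"{v}\n")
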