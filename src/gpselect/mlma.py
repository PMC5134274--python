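"""Mixed-linear-model association (MLMA) scan.

The null model ``y = 1 mu + g + e`` with ``g ~ N(0, K sigma_g^2)`` is fitted
once by REML on a structure GRM (typically a medium-density panel subset);
the variance components are then fixed and every candidate variant is tested
by generalized least squares under ``V = K sigma_g^2 + I sigma_e^2``:

    b_hat = (x~' V^-1 x~)^-1 x~' V^-1 y~,   var(b_hat) = (x~' V^-1 x~)^-1,

with ``x~``, ``y~`` projected for the intercept, and a Wald chi-square(1)
p-value.  Candidate markers may themselves sit inside the structure GRM
(proximal contamination accepted); a leave-one-chromosome-out mode is
available but not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .greml import VarianceEstimate, VarianceModel, reml
from .grm import GenotypeMatrix, GRMatrix

logger = logging.getLogger(__name__)

__all__ = ["NullModel", "fit_null", "scan", "scan_loco",
           "expected_null_exceedances", "manhattan_table"]

_CHUNK = 4096
_TINY_P = np.finfo(float).tiny


@dataclass
class NullModel:
    """Fixed variance components and solve-in-V handles for the scan."""

    sigma2_g: float
    sigma2_e: float
    estimate: VarianceEstimate
    Vinv: np.ndarray

    @property
    def n(self) -> int:
        return self.Vinv.shape[0]

    @classmethod
    def from_components(cls, K: GRMatrix | np.ndarray, sigma2_g: float,
                        sigma2_e: float, estimate: VarianceEstimate = None) -> "NullModel":
        """Build directly from fixed components (used in tests and COJO refits)."""
        A = K.values if isinstance(K, GRMatrix) else np.asarray(K, dtype=np.float64)
        V = sigma2_g * A + sigma2_e * np.eye(A.shape[0])
        c = linalg.cho_factor(V, lower=True, check_finite=False)
        Vinv = linalg.cho_solve(c, np.eye(A.shape[0]), check_finite=False)
        return cls(sigma2_g=float(sigma2_g), sigma2_e=float(sigma2_e),
                   estimate=estimate, Vinv=Vinv)

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self.Vinv @ b


def fit_null(y: np.ndarray, K: GRMatrix) -> NullModel:
    """REML fit of the no-variant null model on the structure GRM."""
    est = reml(VarianceModel(y=y, K_list=[K]))
    return NullModel.from_components(K, est.sigma2_g[0], est.sigma2_e, estimate=est)


def scan(y: np.ndarray, G: GenotypeMatrix, null: NullModel) -> pd.DataFrame:
    """Per-variant GLS association test under the fixed null covariance.

    Returns a table with columns (Chr, SNP, bp, A1, A2, Freq, b, se, p, n,
    degenerate) mirroring the GCTA .mlma layout.  Zero-variance variants are
    emitted with p = 1 and the degenerate flag set rather than dropped.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if G.n_individuals != n or null.n != n:
        raise ValueError("dimensions of y, G and the null model disagree")
    A = null.Vinv
    ones = np.ones(n)
    a1 = A @ ones
    s11 = float(ones @ a1)
    Ay = A @ y
    s1y = float(ones @ Ay)

    m = G.n_variants
    b = np.empty(m)
    se = np.empty(m)
    pval = np.empty(m)
    degenerate = np.zeros(m, dtype=bool)
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        X = G.dosages[:, lo:hi].astype(np.float64)
        AX = A @ X
        xVx = np.einsum("ij,ij->j", X, AX)
        xV1 = X.T @ a1
        xVy = X.T @ Ay
        denom = xVx - xV1**2 / s11
        num = xVy - xV1 * s1y / s11
        bad = denom <= 1e-12 * s11
        denom_safe = np.where(bad, 1.0, denom)
        bc = np.where(bad, 0.0, num / denom_safe)
        sec = np.where(bad, np.inf, 1.0 / np.sqrt(denom_safe))
        chi2 = np.where(bad, 0.0, bc * bc * denom_safe)
        pc = np.where(bad, 1.0, np.maximum(stats.chi2.sf(chi2, df=1), _TINY_P))
        b[lo:hi], se[lo:hi], pval[lo:hi], degenerate[lo:hi] = bc, sec, pc, bad

    if degenerate.any():
        logger.info("%d zero-variance variants flagged degenerate", int(degenerate.sum()))
    return pd.DataFrame({
        "Chr": G.variants["chrom"].to_numpy(),
        "SNP": G.variants["id"].to_numpy(),
        "bp": G.variants["bp"].to_numpy(),
        "A1": G.variants["a1"].to_numpy(),
        "A2": G.variants["a2"].to_numpy(),
        "Freq": G.freqs,
        "b": b,
        "se": se,
        "p": pval,
        "n": n,
        "degenerate": degenerate,
    })


def scan_loco(y: np.ndarray, G: GenotypeMatrix, G_panel: GenotypeMatrix) -> pd.DataFrame:
    """Leave-one-chromosome-out scan (non-default alternative).

    For each chromosome the structure GRM is rebuilt from the panel variants
    on the *other* chromosomes and the null refitted, removing proximal
    contamination at the cost of one REML fit per chromosome.
    """
    from .grm import build_grm, ensure_pd

    chroms = np.unique(G.variants["chrom"])
    if chroms.size < 2:
        raise ValueError("leave-one-chromosome-out needs at least two chromosomes")
    panel_chrom = G_panel.variants["chrom"].to_numpy()
    parts = []
    for c in chroms:
        off = G_panel.take_variants(np.flatnonzero(panel_chrom != c))
        null_c = fit_null(y, ensure_pd(build_grm(off, diag_mode="yang",
                                                 source="structure-loco")))
        on = G.take_variants(np.flatnonzero(G.variants["chrom"].to_numpy() == c))
        parts.append(scan(y, on, null_c))
    out = pd.concat(parts, ignore_index=True)
    order = out.set_index("SNP").loc[G.variants["id"]].reset_index()
    return order[out.columns]


def expected_null_exceedances(n_tests: int, logp_threshold: float) -> float:
    """Tests expected past a -log10(p) threshold by chance: ``n * 10^-t``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if logp_threshold < 0:
        raise ValueError("logp_threshold must be >= 0")
    return n_tests * 10.0 ** (-logp_threshold)


def manhattan_table(assoc: pd.DataFrame, min_logp: float = 1.0) -> pd.DataFrame:
    """Plot-ready (Chr, bp, SNP, logp) table.

    ``-log10(p)`` is capped at the smallest positive representable p; rows
    below ``min_logp`` are dropped for compactness (pass 0 to keep all).
    """
    logp = -np.log10(np.maximum(assoc["p"].to_numpy(), _TINY_P))
    out = assoc[["Chr", "bp", "SNP"]].copy()
    out["logp"] = logp
    return out[out["logp"] >= min_logp].reset_index(drop=True)
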