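"""GBLUP training, back-solving of variant effects, scoring and validation.

Training fits the mixed model on the discovery animals only:

    g_hat_k = sigma_k^2 K_k V^-1 (y - X beta_hat),   V = sum_k sigma_k^2 K_k
                                                         + sigma_e^2 I,

one BLUP vector per fitted GRM (the selected-set GRM and, optionally, the
complementary GRMc).  Variant effects are then back-solved from the breeding
values,

    u = (1/N) W' K^+ g_hat        (standardized scale)
    a_i = u_i / sqrt(2 p_i (1-p_i))   (per-dosage scale),

which reproduces the training breeding values exactly when K = W W'/N
(crossprod diagonal) and g_hat lies in the column span of K — always true
for BLUP solutions.  Validation animals are scored as

    GEBV_j = sum_i a_i (x_ij - 2 p_i) + mean_offset,

with training-sample frequencies and the GLS intercept as offset.  For
two-component models the per-component GEBVs are summed after separate
back-solving.  Accuracy is the correlation between validation DRP and GEBV;
bias is the regression slope of DRP on GEBV (slope < 1 = over-dispersed
predictions).  The DRP is treated as a noiseless target (no reliability
correction of the accuracy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .greml import VarianceEstimate
from .grm import GenotypeMatrix, GRMatrix

logger = logging.getLogger(__name__)

__all__ = ["TrainedPredictor", "ValidationMetrics", "gblup_train",
           "backsolve_effects", "score", "validate", "RANK_TOL"]

#: relative eigenvalue cut-off when (pseudo-)inverting a component GRM
RANK_TOL = 1e-8


@dataclass
class TrainedPredictor:
    """Per-component BLUP breeding values over the training individuals."""

    gebv_components: list            # one (n_train,) vector per GRM
    mean_offset: float               # GLS intercept beta_hat
    estimate: VarianceEstimate
    sources: list                    # provenance per component (e.g. GRM/GRMc)
    train_ids: np.ndarray

    @property
    def gebv_train(self) -> np.ndarray:
        return np.sum(self.gebv_components, axis=0)


@dataclass
class ValidationMetrics:
    accuracy: float
    slope: float
    intercept: float
    n_validation: int
    defined: bool = True


def gblup_train(y_train: np.ndarray, K_list, est: VarianceEstimate) -> TrainedPredictor:
    """Mixed-model BLUP of per-component breeding values at fixed components."""
    y = np.asarray(y_train, dtype=np.float64).ravel()
    n = y.size
    mats, sources = [], []
    for K in K_list:
        if isinstance(K, GRMatrix):
            mats.append(K.values)
            sources.append(K.source)
        else:
            mats.append(np.asarray(K, dtype=np.float64))
            sources.append("unknown")
    if len(mats) != est.sigma2_g.size:
        raise ValueError("K_list length disagrees with the variance estimate")
    V = est.sigma2_e * np.eye(n)
    for s2, A in zip(est.sigma2_g, mats):
        V += s2 * A
    c = linalg.cho_factor(V, lower=True, check_finite=False)
    ones = np.ones(n)
    Vinv_1 = linalg.cho_solve(c, ones, check_finite=False)
    Vinv_y = linalg.cho_solve(c, y, check_finite=False)
    beta = float(ones @ Vinv_y) / float(ones @ Vinv_1)
    Vinv_r = Vinv_y - beta * Vinv_1
    gebvs = [s2 * (A @ Vinv_r) for s2, A in zip(est.sigma2_g, mats)]
    ids = None
    for K in K_list:
        if isinstance(K, GRMatrix):
            ids = K.ids
            break
    if ids is None:
        ids = np.arange(n)
    return TrainedPredictor(gebv_components=gebvs, mean_offset=beta, estimate=est,
                            sources=sources, train_ids=ids)


def _backsolve_one(ghat: np.ndarray, G_train: GenotypeMatrix,
                   K: GRMatrix | None = None) -> pd.DataFrame:
    """Back-solve per-variant effects for one component.

    Builds (or reuses) the crossprod GRM of the component's variants; when
    the training GRM used the heterozygosity-corrected diagonal the crossprod
    form is substituted with a warning and the maximum training-GEBV
    reconstruction discrepancy is reported.
    """
    p = G_train.freqs
    m = G_train.n_variants
    n = G_train.n_individuals
    scale = np.sqrt(2.0 * p * (1.0 - p))
    W = (G_train.dosages.astype(np.float64) - 2.0 * p) / scale
    if K is not None and K.diag_mode != "crossprod":
        logger.warning("training GRM used diag_mode=%s; back-solving with the "
                       "crossprod form", K.diag_mode)
    Kc = (W @ W.T) / m
    evals, evecs = np.linalg.eigh(Kc)
    # relative rank cut: directions below carry O(tol) of ghat but amplify
    # floating-point noise by 1/eigenvalue when inverted
    tol = RANK_TOL * evals.max()
    pos = evals > tol
    rank = int(pos.sum())
    if rank < n:
        logger.info("component GRM numerically singular: rank %d of %d "
                    "(pseudo-inverse used)", rank, n)
    Kp_g = evecs[:, pos] @ ((evecs[:, pos].T @ ghat) / evals[pos])
    u = (W.T @ Kp_g) / m
    recon = W @ u
    max_err = float(np.abs(recon - ghat).max())
    if max_err > 1e-6 * max(1.0, float(np.abs(ghat).max())):
        logger.warning("training-GEBV reconstruction discrepancy: max |W u - ghat| "
                       "= %.3e", max_err)
    return pd.DataFrame({
        "id": G_train.variants["id"].to_numpy(),
        "a1": G_train.variants["a1"].to_numpy(),
        "effect": u / scale,
        "freq": p,
    })


def backsolve_effects(pred: TrainedPredictor, G_train_list,
                      K_list=None) -> pd.DataFrame:
    """Per-dosage variant effects for every component, concatenated.

    ``G_train_list`` holds the training genotypes of each component's variant
    set, aligned with ``pred.gebv_components``; effects of the (disjoint)
    sets are stacked into one effects table usable by ``score``.
    """
    if isinstance(G_train_list, GenotypeMatrix):
        G_train_list = [G_train_list]
    if len(G_train_list) != len(pred.gebv_components):
        raise ValueError("one genotype set per trained component required")
    K_list = K_list or [None] * len(G_train_list)
    frames = []
    for ghat, G, K in zip(pred.gebv_components, G_train_list, K_list):
        frames.append(_backsolve_one(np.asarray(ghat, dtype=np.float64), G, K))
    return pd.concat(frames, ignore_index=True)


def score(G_any: GenotypeMatrix, effects: pd.DataFrame,
          mean_offset: float = 0.0) -> np.ndarray:
    """Score genotypes with back-solved effects (training-frequency centering)."""
    idx = G_any.variant_indexer(effects["id"].to_numpy())
    X = G_any.dosages[:, idx].astype(np.float64)
    a = effects["effect"].to_numpy(dtype=np.float64)
    p = effects["freq"].to_numpy(dtype=np.float64)
    return (X - 2.0 * p) @ a + mean_offset


def validate(drp_val: np.ndarray, gebv_val: np.ndarray) -> ValidationMetrics:
    """Accuracy (correlation) and bias (regression of DRP on GEBV)."""
    drp = np.asarray(drp_val, dtype=np.float64).ravel()
    gebv = np.asarray(gebv_val, dtype=np.float64).ravel()
    if drp.size != gebv.size or drp.size < 3:
        raise ValueError("need >= 3 paired validation records")
    if gebv.var() == 0.0:
        logger.warning("zero-variance GEBV: validation metrics undefined")
        return ValidationMetrics(accuracy=np.nan, slope=np.nan, intercept=np.nan,
                                 n_validation=drp.size, defined=False)
    fit = stats.linregress(gebv, drp)
    return ValidationMetrics(accuracy=float(fit.rvalue), slope=float(fit.slope),
                             intercept=float(fit.intercept), n_validation=drp.size)
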