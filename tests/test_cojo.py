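"""Variant selection: p-value thresholding and forward conditional-joint
selection against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gpselect import simpop
from gpselect.cojo import SelectionConfig, cojo_select, exclusion_for_grmc, select_pval
from gpselect.grm import build_grm
from gpselect.mlma import NullModel, fit_null, scan

from conftest import toy_genotypes


def _assoc_from_p(pvals):
    m = len(pvals)
    return pd.DataFrame({
        "Chr": np.ones(m, dtype=int), "SNP": [f"v{i}" for i in range(m)],
        "bp": (np.arange(m) + 1) * 1000, "A1": "A", "A2": "B",
        "Freq": 0.5, "b": 1.0, "se": 1.0, "p": pvals, "n": 100,
        "degenerate": False,
    })


def test_select_pval_thresholds():
    assoc = _assoc_from_p([1e-2, 1e-4, 1e-6])
    assert set(select_pval(assoc, 3.0)) == {"v1", "v2"}
    assert set(select_pval(assoc, 0.0)) == {"v0", "v1", "v2"}
    assert select_pval(assoc, 10.0).size == 0


def test_select_pval_null_count_is_binomial():
    rng = np.random.default_rng(10)
    assoc = _assoc_from_p(rng.uniform(size=20_000))
    k = select_pval(assoc, 3.0).size
    assert abs(k - 20) <= 3 * np.sqrt(20)


def _le_panel(n=800, m=120, n_qtl=3, seed=0, var_frac=0.06):
    """Linkage-equilibrium panel with planted large-effect QTL."""
    rng = np.random.default_rng(seed)
    maps = simpop.make_chrom_maps(1, m, seed=seed)
    G = simpop.sim_unrelated_population(maps, n, maf_low=0.1, ld_rho=0.0, seed=seed)
    qtl = np.sort(rng.choice(m, n_qtl, replace=False))
    p = G.freqs
    beta = np.zeros(m)
    beta[qtl] = rng.choice([-1, 1], n_qtl) / np.sqrt(2 * p[qtl] * (1 - p[qtl]))
    g = (G.dosages.astype(float) - 2 * p) @ beta
    g *= np.sqrt(var_frac * n_qtl) / g.std()
    y = g + rng.normal(0, np.sqrt(1 - var_frac * n_qtl), n)
    return G, y, G.variants["id"].to_numpy()[qtl]


def test_single_qualifying_candidate():
    G, y, qtl = _le_panel(n_qtl=1, seed=3, var_frac=0.1)
    null = NullModel.from_components(np.eye(y.size), 0.0, float(y.var()))
    assoc = scan(y, G, null)
    res = cojo_select(assoc, G, y, null, SelectionConfig.cojo5())
    assert list(res.selected) == list(qtl)
    # a single selected variant's joint effect equals its marginal effect
    row = assoc.set_index("SNP").loc[qtl[0]]
    assert res.report["joint_b"].iloc[0] == pytest.approx(row["b"], rel=1e-6)


def test_perfect_ld_duplicate_rejected():
    rng = np.random.default_rng(4)
    n = 400
    x = rng.integers(0, 3, n).astype(float)
    noise = rng.integers(0, 3, n).astype(float)
    y = x - x.mean() + rng.normal(0, 1.0, n)
    G = toy_genotypes([x, x.copy(), noise])
    null = NullModel.from_components(np.eye(n), 0.0, float(y.var()))
    assoc = scan(y, G, null)
    res = cojo_select(assoc, G, y, null, SelectionConfig.cojo5())
    assert res.n_selected == 1
    assert res.selected[0] in {"v0", "v1"}
    reasons = dict(zip(res.audit["id"], res.audit["reason"]))
    dup = ({"v0", "v1"} - set(res.selected)).pop()
    assert reasons[dup] in ("LD cap", "collinearity")


def test_le_panel_recovers_planted_qtl():
    G, y, qtl = _le_panel(seed=5)
    K = build_grm(G, "crossprod")
    null = fit_null(y, K)
    assoc = scan(y, G, null)
    res = cojo_select(assoc, G, y, null, SelectionConfig.cojo5())
    assert set(res.selected) == set(qtl)
    # orthogonal predictors: joint effects within 3 SE of marginal effects
    marg = assoc.set_index("SNP")
    for _, row in res.report.iterrows():
        assert abs(row["joint_b"] - marg.loc[row["id"], "b"]) \
            <= 3 * marg.loc[row["id"], "se"]


def test_forward_selection_near_optimal_all_subsets():
    """Final residual variance within 5% of the best same-size subset
    (exhaustive enumeration over <= 12 candidates)."""
    rng = np.random.default_rng(6)
    n, m = 150, 10
    L = rng.normal(size=(m, m))
    X = rng.normal(size=(n, m)) @ (np.eye(m) + 0.4 * L / np.abs(L).max())
    X = np.round(np.clip(X - X.min(), 0, None) % 3)  # dosage-like, correlated
    beta = np.zeros(m)
    beta[[1, 4, 7]] = [0.8, -0.7, 0.6]
    y = X @ beta + rng.normal(0, 1.0, n)
    G = toy_genotypes(list(X.T))
    null = NullModel.from_components(np.eye(n), 0.0, float(y.var()))
    assoc = scan(y, G, null)
    res = cojo_select(assoc, G, y, null,
                      SelectionConfig(mode="COJO3", logp_enter=3.0, r2_cap=0.99))
    k = res.n_selected
    assert k >= 1
    ones = np.ones((n, 1))
    def rss_of(cols):
        D = np.hstack([ones, X[:, list(cols)]])
        r = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        return r @ r
    best = min(rss_of(c) for c in itertools.combinations(range(m), k))
    got = rss_of([int(v[1:]) for v in res.selected])
    assert got <= best * 1.05


def test_selection_is_deterministic_and_variance_decreases():
    G, y, _ = _le_panel(seed=7)
    null = NullModel.from_components(np.eye(y.size), 0.0, float(y.var()))
    assoc = scan(y, G, null)
    r1 = cojo_select(assoc, G, y, null, SelectionConfig.cojo3())
    r2 = cojo_select(assoc, G, y, null, SelectionConfig.cojo3())
    assert list(r1.selected) == list(r2.selected)
    path = r1.residual_variance_path
    assert np.all(np.diff(path) < 0)


def test_top_n_mode_caps_selection():
    G, y, _ = _le_panel(n=600, m=100, n_qtl=5, seed=8, var_frac=0.05)
    null = NullModel.from_components(np.eye(y.size), 0.0, float(y.var()))
    assoc = scan(y, G, null)
    cfg = SelectionConfig(mode="COJO_TOPN", logp_enter=0.0, r2_cap=0.5,
                          max_ld_dist_bp=100e6, top_n=4)
    res = cojo_select(assoc, G, y, null, cfg)
    assert res.n_selected == 4
    assert np.all(np.diff(res.residual_variance_path) < 0)


def test_prefilter_bounds_selection():
    G, y, _ = _le_panel(seed=9)
    null = NullModel.from_components(np.eye(y.size), 0.0, float(y.var()))
    assoc = scan(y, G, null)
    res = cojo_select(assoc, G, y, null, SelectionConfig.cojo5())
    n_prefilter = (-np.log10(assoc["p"]) > 3).sum()
    assert res.n_selected <= n_prefilter


def test_exclusion_for_grmc_modes():
    rng = np.random.default_rng(11)
    n = 200
    base = rng.integers(0, 3, n).astype(float)
    cols = [base] + [base.copy() for _ in range(3)] + \
           [rng.integers(0, 3, n).astype(float)]
    bp = np.array([1_000_000, 1_100_000, 1_200_000, 1_300_000, 50_000_000])
    G = toy_genotypes(cols, bp=bp)
    sel = np.array(["v0"])
    # plain p-value selection: only the selected ids themselves
    assert list(exclusion_for_grmc(sel, G, mode="PVAL")) == ["v0"]
    # COJO: perfect-LD neighbours within the window are excluded too
    out = exclusion_for_grmc(sel, G, window_bp=2_000_000, p_thresh=0.01, mode="COJO5")
    assert set(out) == {"v0", "v1", "v2", "v3"}
    # lone variant with no window neighbours
    out = exclusion_for_grmc(np.array(["v4"]), G, mode="COJO5")
    assert list(out) == ["v4"]
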