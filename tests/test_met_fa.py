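"""Factor-analytic MET model: dense-oracle equivalence and limits."""

import numpy as np
import pandas as pd
import pytest

from metgains import MixedModel, SimConfig, blup_table, compare_structures, fit_met, generate_met, make_met
from metgains.met_fa import (
    FACovariance,
    _BalancedStats,
    _DenseStats,
    _ParamMap,
    _balanced_nll_grad,
    _dense_nll,
    _solve_mme,
)
from metgains._reml import design_matrix


# ----------------------------------------------------------------------
# Independent dense oracles (built with kron / explicit matrices, a
# different construction route than the package's index arithmetic)
# ----------------------------------------------------------------------

def oracle_design(met):
    plots = met.plots
    sites, genos = met.sites, met.genotypes
    s, g = len(sites), len(genos)
    si = plots["site_id"].map({x: i for i, x in enumerate(sites)}).to_numpy()
    gi = plots["genotype_id"].map({x: i for i, x in enumerate(genos)}).to_numpy()
    n = len(plots)
    X = design_matrix(si, s)
    rep_levels = sorted(set(zip(si, plots["replicate"])))
    ri = np.array([rep_levels.index(k) for k in zip(si, plots["replicate"])])
    Zr = design_matrix(ri, len(rep_levels))
    Zg = design_matrix(gi, g)
    Zge = design_matrix(si * g + gi, s * g)
    y = plots["yield_t_ha"].to_numpy(float)
    return y, X, Zr, rep_levels, Zg, Zge, s, g


def oracle_V(met, Sigma_ge, s2g, s2r, s2e):
    y, X, Zr, rep_levels, Zg, Zge, s, g = oracle_design(met)
    Gr = np.diag([s2r[site] for site, _ in rep_levels])
    V = s2e * np.eye(len(y)) + Zr @ Gr @ Zr.T + s2g * (Zg @ Zg.T)
    if Sigma_ge is not None:
        V += Zge @ np.kron(Sigma_ge, np.eye(g)) @ Zge.T
    return y, X, V


def oracle_reml(met, Sigma_ge, s2g, s2r, s2e):
    y, X, V = oracle_V(met, Sigma_ge, s2g, s2r, s2e)
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        - np.linalg.slogdet(X.T @ X)[1]
        + float(r @ Vi @ r)
    )


def oracle_blups(met, Sigma_ge, s2g, s2r, s2e):
    """Dense Henderson mixed-model-equation solve.

    Uses the G-scaled form (substituting u = G alpha), which stays
    well-posed when G is singular:

    ``[[X'X, X'Z G], [G Z'X, G Z'Z G + s2e G]] [b; alpha] = [X'y; G Z'y]``

    solved by minimum-norm least squares; u = G alpha is unique.
    """
    y, X, Zr, rep_levels, Zg, Zge, s, g = oracle_design(met)
    from scipy.linalg import block_diag

    Gr = np.diag([s2r[site] for site, _ in rep_levels])
    blocks = [Gr, s2g * np.eye(g)]
    Z = np.hstack([Zr, Zg])
    if Sigma_ge is not None:
        blocks.append(np.kron(Sigma_ge, np.eye(g)))
        Z = np.hstack([Z, Zge])
    G = block_diag(*blocks)
    ZG = Z @ G
    M = np.block([[X.T @ X, X.T @ ZG], [ZG.T @ X, ZG.T @ Z @ G + s2e * G]])
    rhs = np.concatenate([X.T @ y, G @ Z.T @ y])
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    beta = sol[: X.shape[1]]
    u = G @ sol[X.shape[1] :]
    n_r = Zr.shape[1]
    u_g = u[n_r : n_r + g]
    u_ge = u[n_r + g :].reshape(s, g) if Sigma_ge is not None else np.zeros((s, g))
    return beta, u_g, u_ge


def small_fa_met(seed, n_sites=3, entries=10, spread=True):
    cfg = SimConfig(
        n_series=1,
        sites_per_class=(n_sites, 0, 0),
        entries_per_trial=entries,
        n_checks=2,
        n_subblocks=2,
        sigma2_subblock=0.0,
        sigma2_ge_factor=0.04 if spread else 0.0,
        sigma2_ge_specific=0.02 if spread else 0.0,
        seed=seed,
    )
    plots, truth = generate_met(cfg)
    return make_met(plots), truth


# ----------------------------------------------------------------------
# Likelihood construction
# ----------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1])
def test_stratified_equals_dense_equals_oracle(seed):
    """The balanced stratified REML, the package dense REML and the
    independent kron-built oracle agree at arbitrary parameters."""
    met, _ = small_fa_met(seed, n_sites=3, entries=8)
    pm = _ParamMap(3, 1, True, None)
    st = _BalancedStats(met.plots, met.sites, met.genotypes)
    ds = _DenseStats(met.plots, met.sites, met.genotypes)
    rng = np.random.default_rng(seed)
    for _ in range(3):
        th = rng.normal(-2.0, 0.6, pm.n_free)
        L, d, s2g, s2r, s2e = pm.unpack(th)
        nb, gb = _balanced_nll_grad(th, pm, st)
        nd = _dense_nll(th, pm, ds)
        no = -oracle_reml(met, L @ L.T + np.diag(d), s2g, s2r, s2e)
        assert nb == pytest.approx(no, abs=1e-8)
        assert nd == pytest.approx(no, abs=1e-8)
        # analytic gradient vs central differences
        eps = 1e-6
        for i in np.random.default_rng(0).choice(pm.n_free, 4, replace=False):
            e = np.zeros(pm.n_free)
            e[i] = eps
            fd = (_balanced_nll_grad(th + e, pm, st)[0] - _balanced_nll_grad(th - e, pm, st)[0]) / (2 * eps)
            assert gb[i] == pytest.approx(fd, abs=1e-5)


def test_blups_match_dense_mme_oracle(small_met):
    """MME BLUPs equal the independent dense GLS/BLUP formulas to 1e-8."""
    plots, _ = small_met
    met = make_met(plots)
    fit = fit_met(met, n_factors=1)
    Sigma = fit.fa.implied()
    beta, u_g, u_ge = oracle_blups(met, Sigma, fit.sigma2_g, fit.rep_variances, fit.sigma2_e)
    np.testing.assert_allclose(fit.site_effects.to_numpy(), beta, atol=1e-8)
    np.testing.assert_allclose(fit.blups_g.to_numpy(), u_g, atol=1e-8)
    np.testing.assert_allclose(fit.blups_ge.to_numpy(), u_ge, atol=1e-8)


def test_optimum_beats_random_search():
    """Fitted restricted loglik >= best of 10^4 random parameter draws
    (independent random-search oracle on a 3-site FA(1) instance)."""
    met, _ = small_fa_met(3, n_sites=3, entries=10)
    fit = fit_met(met, n_factors=1)
    pm = _ParamMap(3, 1, True, None)
    st = _BalancedStats(met.plots, met.sites, met.genotypes)
    rng = np.random.default_rng(12345)
    best = -np.inf
    for _ in range(10_000):
        th = rng.uniform(-6.0, 1.0, pm.n_free)
        nll, _ = _balanced_nll_grad(th, pm, st)
        best = max(best, -nll)
    assert fit.reml_loglik >= best - 1e-9


def test_single_site_reduces_to_genotype_random_model():
    """One site, no factors: fit_met degenerates to the plain
    genotype-random replicated-trial model."""
    cfg = SimConfig(
        n_series=1, sites_per_class=(1, 0, 0), entries_per_trial=12, n_checks=2,
        n_subblocks=2, sigma2_subblock=0.0, sigma2_ge_factor=0.0,
        sigma2_ge_specific=0.0, seed=4,
    )
    plots, _ = generate_met(cfg)
    met = make_met(plots)
    fit = fit_met(met, n_factors=0)
    # same model assembled directly: intercept fixed, replicate and
    # genotype random — an entirely different code path
    cat_g = pd.Categorical(plots["genotype_id"], categories=met.genotypes)
    cat_r = pd.Categorical(plots["replicate"])
    Zg = design_matrix(cat_g.codes.astype(int), len(met.genotypes))
    Zr = design_matrix(cat_r.codes.astype(int), 2)
    direct = MixedModel(plots["yield_t_ha"].to_numpy(), np.ones((len(plots), 1)),
                        {"rep": Zr, "g": Zg}).fit()
    assert fit.sigma2_g == pytest.approx(direct.variances["g"], abs=1e-5)
    assert fit.sigma2_e == pytest.approx(direct.sigma2_e, abs=1e-5)
    np.testing.assert_allclose(fit.blups_g.to_numpy(), direct.blups["g"], atol=1e-5)


def test_full_shrinkage_limit_zero_genetic_variance(small_met):
    plots, _ = small_met
    met = make_met(plots)
    fit = fit_met(met, n_factors=1, fix={"sigma2_g": 0.0})
    assert (fit.blups_g == 0.0).all()


def test_no_shrinkage_limit_recovers_gls_means():
    """sigma2_g fixed huge: predictions approach the genotype means."""
    cfg = SimConfig(
        n_series=1, sites_per_class=(3, 0, 0), entries_per_trial=10, n_checks=2,
        n_subblocks=2, sigma2_subblock=0.0, sigma2_ge_factor=0.0,
        sigma2_ge_specific=0.0, sigma2_rep=0.0, seed=6,
    )
    plots, _ = generate_met(cfg)
    met = make_met(plots)
    base = fit_met(met, n_factors=0, include_ge=False)
    fit = fit_met(met, n_factors=0, include_ge=False,
                  fix={"sigma2_g": 1e6 * base.sigma2_e})
    pred = blup_table(fit, met).set_index("genotype_id")["predicted_yield_t_ha"]
    raw = plots.groupby("genotype_id")["yield_t_ha"].mean()
    gap = (pred.sort_index() - raw.sort_index()).abs().max()
    assert gap < 1e-3


def test_site_permutation_equivariance(small_met):
    """Reordering sites permutes the stratified likelihood's parameters
    and leaves the MME BLUPs unchanged."""
    plots, _ = small_met
    met = make_met(plots)
    perm = [2, 0, 1]
    met_p = make_met(plots, sites=[met.sites[i] for i in perm])
    pm = _ParamMap(3, 1, True, None)
    st = _BalancedStats(met.plots, met.sites, met.genotypes)
    st_p = _BalancedStats(met_p.plots, met_p.sites, met_p.genotypes)
    rng = np.random.default_rng(0)
    th = rng.normal(-2.0, 0.5, pm.n_free)
    L, d, s2g, s2r, s2e = pm.unpack(th)
    # same parameters expressed in the permuted site order
    th_p = pm.pack(L[perm], d[perm], s2g, s2r[perm], s2e)
    assert _balanced_nll_grad(th, pm, st)[0] == pytest.approx(
        _balanced_nll_grad(th_p, pm, st_p)[0], abs=1e-8
    )
    fa, fa_p = FACovariance(L, d), FACovariance(L[perm], d[perm])
    _, u, _ = _solve_mme(met, fa, s2g, s2r, s2e)
    _, u_p, _ = _solve_mme(met_p, fa_p, s2g, s2r[perm], s2e)
    np.testing.assert_allclose(u.to_numpy(), u_p.to_numpy(), atol=1e-8)


def test_implied_covariance_psd_and_correlations_bounded(small_met):
    plots, _ = small_met
    fit = fit_met(make_met(plots), n_factors=1)
    S = fit.fa.implied()
    assert np.linalg.eigvalsh(S).min() >= -1e-10
    rho = fit.fa.correlations()
    assert (np.abs(rho) <= 1.0 + 1e-12).all()


def simulate_fa_plots(rng, lam, D, s2g=0.0625, s2r=0.01, s2e=0.05, g=40, r=2):
    """Balanced plots from a fixed FA(1) truth (test-owned generator)."""
    s = len(lam)
    merit = rng.normal(0, np.sqrt(s2g), g)
    scores = rng.normal(size=g)
    rows = []
    for j in range(s):
        ge = lam[j] * scores + rng.normal(0, np.sqrt(D[j]), g)
        for rep in range(r):
            re = rng.normal(0, np.sqrt(s2r))
            y = 4.0 + merit + ge + re + rng.normal(0, np.sqrt(s2e), g)
            for i in range(g):
                rows.append((f"T{j}", 0, f"S{j}", f"G{i:03d}", False, rep + 1, 1, y[i]))
    return pd.DataFrame(
        rows,
        columns=["trial_id", "series", "site_id", "genotype_id", "is_check",
                 "replicate", "sub_block", "yield_t_ha"],
    )


def test_fa1_recovery_fixed_truth():
    """Strong fixed FA(1) truth, 8 sites: the ensemble-mean fitted
    Lambda Lambda' + D is entrywise within ~15% of truth over 20 sims
    (the full 200-replicate check lives in the acceptance suite)."""
    lam = np.linspace(0.3, 0.6, 8)
    D = np.full(8, 0.02)
    truth = np.outer(lam, lam) + np.diag(D)
    rng = np.random.default_rng(2024)
    est = np.zeros_like(truth)
    n_sims = 20
    for _ in range(n_sims):
        plots = simulate_fa_plots(rng, lam, D)
        est += fit_met(make_met(plots), n_factors=1).fa.implied()
    est /= n_sims
    rel = np.abs(est - truth) / np.abs(truth)
    assert rel.max() < 0.15


def test_compare_structures_single_site_one_row():
    cfg = SimConfig(n_series=1, sites_per_class=(1, 0, 0), entries_per_trial=10,
                    n_checks=2, n_subblocks=2, seed=2)
    plots, _ = generate_met(cfg)
    tab = compare_structures(make_met(plots), k_list=[0])
    assert len(tab) == 1
    assert set(tab.columns) == {"k", "reml_loglik", "n_params", "aic"}


def test_aic_model_selection():
    """AIC prefers the diagonal baseline under diagonal truth and k >= 1
    under strong FA(1) truth, in >= 80% of simulations."""
    def run(n_sims, factor_var):
        wins = 0
        for seed in range(n_sims):
            cfg = SimConfig(
                n_series=1, sites_per_class=(5, 0, 0), entries_per_trial=30,
                n_checks=2, n_subblocks=5, sigma2_subblock=0.0,
                sigma2_ge_factor=factor_var, sigma2_ge_specific=0.03,
                seed=500 + seed,
            )
            plots, _ = generate_met(cfg)
            tab = compare_structures(make_met(plots), k_list=[1]).set_index("k")
            if factor_var == 0.0:
                wins += tab.loc[0, "aic"] <= tab.loc[1, "aic"]
            else:
                wins += tab.loc[1, "aic"] < tab.loc[0, "aic"]
        return wins / n_sims

    assert run(15, 0.0) >= 0.8
    assert run(15, 0.25) >= 0.8
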