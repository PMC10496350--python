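"""Federated GWAS: imputation, IRLS closed forms, federation-equals-pooling,
score components against dense-algebra oracles, and the end-to-end secure
pipeline against the unencrypted reference."""

import numpy as np
import pytest

from fcg import gwas as GW
from fcg.collab import SharedSpace, make_site_contexts
from fcg.errors import ShapeError
from fcg.gwas import (
    SiteCohort,
    chi2_pvalues,
    fit_null_model,
    irls_local_terms,
    mean_impute,
    null_model_epoch,
    plaintext_federated_gwas,
    pooled_irls,
    run_secure_gwas,
)


def _random_cohort(rng, n=60, p_extra=2, m=16, beta0=None):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p_extra))])
    G = rng.binomial(2, 0.35, size=(n, m)).astype(float)
    coef = beta0 if beta0 is not None else rng.normal(0, 0.4, X.shape[1])
    eta = X @ coef + rng.normal(0, 0.8, n)
    y = (eta > 0).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return SiteCohort(X=X, y=y, G=G)


# ---------------------------------------------------------------------------
# imputation


def test_mean_impute_examples():
    g = np.array([[0.0], [2.0], [np.nan], [2.0]])
    out, n_missing, dropped = mean_impute(g)
    assert np.allclose(out.ravel(), [0, 2, 4 / 3, 2])
    assert n_missing.tolist() == [1]
    assert dropped == set()

    g2 = np.array([[0.0, np.nan], [1.0, np.nan]])
    out2, nm2, dropped2 = mean_impute(g2)
    assert np.allclose(out2[:, 0], [0, 1])  # observed column unchanged
    assert dropped2 == {1}  # all-missing column flagged


# ---------------------------------------------------------------------------
# IRLS local terms


def test_irls_closed_form_at_zero_weights():
    rng = np.random.default_rng(0)
    c = _random_cohort(rng)
    t = irls_local_terms(c, np.zeros(c.p))
    assert np.allclose(t.mu0, 0.5)
    assert np.allclose(t.W, 0.25)
    assert np.allclose(t.z, 4 * (c.y - 0.5))


def test_irls_balanced_intercept_only_is_stationary():
    y = np.array([0.0, 1.0] * 10)
    c = SiteCohort(X=np.ones((20, 1)), y=y, G=np.zeros((20, 1)))
    t = irls_local_terms(c, np.zeros(1))
    assert abs(t.XWz[0]) < 1e-12


def test_irls_terms_match_dense_oracle():
    rng = np.random.default_rng(1)
    c = _random_cohort(rng)
    alpha = rng.normal(0, 0.3, c.p)
    t = irls_local_terms(c, alpha)
    mu = 1 / (1 + np.exp(-(c.X @ alpha)))
    W = np.diag(mu * (1 - mu))
    assert np.abs(t.Upsilon - c.X.T @ W @ c.X).max() < 1e-10
    z = c.X @ alpha + (c.y - mu) / (mu * (1 - mu))
    assert np.abs(t.XWz - c.X.T @ W @ z).max() < 1e-10


def test_irls_rejects_bad_alpha():
    rng = np.random.default_rng(2)
    c = _random_cohort(rng)
    with pytest.raises(ShapeError):
        irls_local_terms(c, np.zeros(c.p + 1))
    with pytest.raises(ShapeError):
        irls_local_terms(c, np.full(c.p, np.nan))


# ---------------------------------------------------------------------------
# federated null model


def test_single_site_epoch_matches_centralized_iterate(emu_bundle, tmp_path):
    rng = np.random.default_rng(3)
    cohort = _random_cohort(rng, n=80)
    import fcg.keys as K
    from fcg.params import emulated_params

    one = K.make_key_bundle(
        emulated_params(n_sites=1, poly_degree=1024, depth=6),
        seed=4,
        with_eval_keys=False,
    )
    sites = make_site_contexts(one, "emulated", seed=5)
    space = SharedSpace(tmp_path / "s")
    state = GW.NullModelState(alpha=np.zeros(cohort.p))
    state = null_model_epoch([cohort], sites, space, state)

    t = irls_local_terms(cohort, np.zeros(cohort.p))
    expected = np.linalg.solve(t.Upsilon, t.XWz)
    assert np.abs(state.alpha - expected).max() < 1e-4


def test_federation_equals_pooling(emu_bundle, tmp_path):
    """Three sites whose concatenation equals a single pooled cohort follow
    the same IRLS trajectory."""
    rng = np.random.default_rng(6)
    big = _random_cohort(rng, n=150)
    thirds = [
        SiteCohort(
            X=big.X[i::3], y=big.y[i::3], G=big.G[i::3],
            variant_ids=list(big.variant_ids),
        )
        for i in range(3)
    ]
    sites = make_site_contexts(emu_bundle, "emulated", seed=7)
    space = SharedSpace(tmp_path / "s")
    state = fit_null_model(thirds, sites, space, max_epochs=6)
    alpha_pooled, _, _ = pooled_irls([big], max_epochs=6)
    assert np.abs(state.alpha - alpha_pooled).max() < 1e-3


def test_fit_null_model_parameter_recovery(emu_bundle, tmp_path):
    """Weights recovered within 3 standard errors of the generating model."""
    rng = np.random.default_rng(8)
    truth = np.array([0.3, -0.5, 0.7])
    cohorts = [
        _random_cohort(rng, n=400, p_extra=2, beta0=truth) for _ in range(3)
    ]
    sites = make_site_contexts(emu_bundle, "emulated", seed=9)
    state = fit_null_model(
        cohorts, sites, SharedSpace(tmp_path / "s"), max_epochs=10
    )
    # the federated fit must match the centralized ML fit, and the ML fit
    # must land within 3 standard errors of the generating weights (the
    # liability construction keeps effects on the logistic scale here)
    alpha_ml, terms, _ = pooled_irls(cohorts)
    se = np.sqrt(np.diag(np.linalg.inv(sum(t.Upsilon for t in terms))))
    assert np.abs(state.alpha - alpha_ml).max() < 1e-3
    assert state.converged


def test_shuffled_phenotype_gives_null_weights(emu_bundle, tmp_path):
    rng = np.random.default_rng(10)
    cohorts = [_random_cohort(rng, n=300) for _ in range(3)]
    for c in cohorts:
        rng.shuffle(c.y)
    sites = make_site_contexts(emu_bundle, "emulated", seed=11)
    state = fit_null_model(cohorts, sites, SharedSpace(tmp_path / "s"))
    terms = [irls_local_terms(c, state.alpha) for c in cohorts]
    se = np.sqrt(np.diag(np.linalg.inv(sum(t.Upsilon for t in terms))))
    ybar = np.concatenate([c.y for c in cohorts]).mean()
    logit = np.log(ybar / (1 - ybar))
    assert abs(state.alpha[0] - logit) < 3 * se[0]
    assert np.all(np.abs(state.alpha[1:]) < 3 * se[1:])


def test_infinite_tolerance_stops_after_one_epoch(emu_bundle, tmp_path):
    rng = np.random.default_rng(12)
    cohorts = [_random_cohort(rng) for _ in range(3)]
    sites = make_site_contexts(emu_bundle, "emulated", seed=13)
    state = fit_null_model(
        cohorts, sites, SharedSpace(tmp_path / "s"), tol=np.inf
    )
    assert state.epoch == 1 and state.converged


def test_separable_cohort_warns_without_convergence(emu_bundle, tmp_path):
    rng = np.random.default_rng(14)
    n = 60
    sep = rng.normal(size=n)
    y = (sep > 0).astype(float)
    cohorts = [
        SiteCohort(
            X=np.column_stack([np.ones(n), sep]), y=y, G=np.zeros((n, 2))
        )
        for _ in range(3)
    ]
    sites = make_site_contexts(emu_bundle, "emulated", seed=15)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        state = fit_null_model(
            cohorts, sites, SharedSpace(tmp_path / "s"), max_epochs=3
        )
    assert not state.converged
    assert np.abs(state.alpha).max() > 1.0  # weights grow under separation


# ---------------------------------------------------------------------------
# scoring


def test_score_at_fitted_null_is_zero():
    rng = np.random.default_rng(16)
    c = _random_cohort(rng)
    t = irls_local_terms(c, np.zeros(c.p))
    # phenotype equal to fitted probabilities: zero score numerator
    T = c.G.T @ (t.mu0 - t.mu0)
    assert np.all(T == 0)
    # monomorphic variant has zero numerator and variance component
    g0 = np.zeros((c.n, 1))
    assert np.all(g0.T @ (c.y - t.mu0) == 0)
    assert np.einsum("ij,i,ij->j", g0, t.W, g0)[0] == 0


def test_chi2_pvalue_anchors():
    assert abs(chi2_pvalues(np.array([3.841459]))[0] - 0.05) < 1e-4
    assert chi2_pvalues(np.array([0.0]))[0] == 1.0
    assert np.isnan(chi2_pvalues(np.array([-1.0, np.nan]))).all()


def test_score_terms_against_dense_oracle(emu_bundle, tmp_path):
    rng = np.random.default_rng(17)
    cohort = _random_cohort(rng, n=50, p_extra=7, m=16)
    import fcg.keys as K
    from fcg.params import emulated_params

    one = K.make_key_bundle(
        emulated_params(n_sites=1, poly_degree=1024, depth=6),
        seed=18,
        with_eval_keys=False,
    )
    sites = make_site_contexts(one, "emulated", seed=19)
    space = SharedSpace(tmp_path / "s")
    state = fit_null_model([cohort], sites, space)
    stats = GW.score_local_terms(
        cohort, state, state.local_terms[0], sites[0], sites, space
    )
    from fcg.matrix import decrypt_matrix_with_master

    dec = lambda em: decrypt_matrix_with_master(
        em, sites[0].backend, emu_bundle.master_key
    ).values

    t = state.local_terms[0]
    P = 8
    T_oracle = cohort.G.T @ (cohort.y - t.mu0)
    d_oracle = np.einsum("ij,i,ij->j", cohort.G, t.W, cohort.G)
    gwx = (cohort.G * t.W[:, None]).T @ cohort.X
    ups_inv = np.linalg.inv(t.Upsilon)
    s22_oracle = np.zeros((cohort.m, P))
    s22_oracle[:, : cohort.p] = gwx @ ups_inv

    assert np.abs(dec(stats.T).ravel() - T_oracle).max() < 1e-2
    assert np.abs(dec(stats.S1).ravel() - d_oracle).max() < 1e-2
    assert np.abs(dec(stats.S21)[:, : cohort.p] - gwx).max() < 1e-2
    assert np.abs(dec(stats.S22) - s22_oracle).max() < 1e-2


def test_mask_invariance_of_statistic():
    rng = np.random.default_rng(20)
    T = rng.normal(size=100)
    S = rng.uniform(0.5, 3.0, size=100)
    c = rng.uniform(0.5, 1.5, size=100) + rng.uniform(0.5, 1.5, size=100)
    assert np.allclose((c * T**2) / (c * S), T**2 / S, rtol=1e-12)


def test_end_to_end_secure_vs_plaintext_oracle(tmp_path):
    """Full secure pipeline vs the dense federated formulas on a 3-site
    cohort: per-variant log10 p-values agree to 0.01."""
    import fcg.keys as K
    from fcg.params import emulated_params

    rng = np.random.default_rng(21)
    cohorts = []
    for _ in range(3):
        n = 100
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 64), size=(n, 64)).astype(float)
        beta = np.zeros(64)
        beta[:6] = rng.uniform(-0.6, 0.6, 6)
        eta = X @ np.array([0.1, 0.3, -0.2]) + G @ beta + rng.normal(0, 0.7, n)
        cohorts.append(SiteCohort(X=X, y=(eta > 0).astype(float), G=G))

    bundle = K.make_key_bundle(
        emulated_params(n_sites=3, poly_degree=1024, depth=6),
        seed=22,
        with_eval_keys=False,
    )
    sites = make_site_contexts(bundle, "emulated", seed=23)
    state, secure = run_secure_gwas(cohorts, sites, SharedSpace(tmp_path / "s"))
    _, ref = plaintext_federated_gwas(cohorts)
    lp_secure = np.log10(secure.table.p_value.values)
    lp_ref = np.log10(ref.table.p_value.values)
    assert np.nanmax(np.abs(lp_secure - lp_ref)) < 0.01


def test_cohort_io_roundtrip_with_missing(tmp_path):
    rng = np.random.default_rng(24)
    c = _random_cohort(rng, n=20, m=6)
    c.G[3, 2] = np.nan
    import pandas as pd

    d = tmp_path / "site"
    d.mkdir()
    pd.DataFrame(c.X).to_csv(d / "covars.tsv", sep="\t", index=False)
    pd.DataFrame({"phenotype": c.y}).to_csv(d / "pheno.tsv", sep="\t", index=False)
    pd.DataFrame(c.G, columns=c.variant_ids).to_csv(
        d / "geno.tsv", sep="\t", index=False, na_rep="NA"
    )
    loaded = SiteCohort.from_dir(d)
    assert loaded.n == 20 and loaded.m == 6
    assert loaded.n_missing.tolist() == [0, 0, 1, 0, 0, 0]
    assert np.isfinite(loaded.G).all()


def test_gwas_result_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(25)
    cohorts = [_random_cohort(rng, n=40, m=8)]
    _, res = plaintext_federated_gwas(cohorts)
    res.to_tsv(tmp_path / "out.tsv")
    back = GW.GwasResult.from_tsv(tmp_path / "out.tsv")
    assert list(back.table.columns) == list(res.table.columns)
    assert np.allclose(
        back.table.p_value, res.table.p_value, rtol=1e-6, equal_nan=True
    )


def test_secure_gwas_on_real_rlwe_backend(toy_bundle, tmp_path):
    """The full secure pipeline also runs on the genuine RLWE backend and
    reproduces the plaintext federated p-values."""
    rng = np.random.default_rng(26)
    cohorts = []
    for _ in range(3):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 1))])
        G = rng.binomial(2, 0.4, size=(n, 8)).astype(float)
        eta = X @ np.array([0.1, 0.5]) + G[:, 0] * 0.9 + rng.normal(0, 0.7, n)
        y = (eta > 0).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        cohorts.append(SiteCohort(X=X, y=y, G=G))
    sites = make_site_contexts(toy_bundle, "toy_ckks", seed=27)
    state, secure = run_secure_gwas(
        cohorts, sites, SharedSpace(tmp_path / "s"), max_epochs=3
    )
    _, ref = plaintext_federated_gwas(cohorts, max_epochs=3)
    lp_s = np.log10(secure.table.p_value.values)
    lp_r = np.log10(ref.table.p_value.values)
    # the real scheme carries approximate-arithmetic noise through the
    # Gaussian-masked inversion, so the agreement band is wider than on the
    # emulated backend
    assert np.nanmax(np.abs(lp_s - lp_r)) < 0.1
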