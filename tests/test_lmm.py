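"""Mixed-model engine: REML against closed forms and dual implementations."""

import numpy as np
import pytest

import frostgs as fg
from frostgs.lmm import compare_aic


def balanced_oneway(seed, g=8, r=4, s2g=4.0, s2e=1.0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(s2g), g)
    y = np.repeat(u, r) + rng.normal(0, np.sqrt(s2e), g * r)
    Z = np.kron(np.eye(g), np.ones((r, 1)))
    return y, Z, g, r


@pytest.mark.parametrize("seed", [1, 2, 3, 4])
def test_balanced_oneway_matches_anova(seed):
    """REML on a balanced one-way layout equals the ANOVA moment estimator."""
    y, Z, g, r = balanced_oneway(seed)
    fit = fg.fit_reml(fg.MixedModelSpec(y, np.ones((g * r, 1)), [fg.RandomTerm("g", Z)]))
    ym = y.reshape(g, r)
    msb = r * np.var(ym.mean(1), ddof=1)
    msw = ym.var(1, ddof=1).mean()
    anova = (msb - msw) / r
    assert anova > 0, "instance must have an interior optimum"
    assert fit.vc.variances["g"] == pytest.approx(anova, abs=1e-6)
    assert fit.vc.residual == pytest.approx(msw, abs=1e-6)


def test_noise_free_response_hits_zero_boundary():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    beta = np.array([2.0, -1.5])
    y = X @ beta
    Z = np.kron(np.eye(10), np.ones((3, 1)))
    fit = fg.fit_reml(fg.MixedModelSpec(y, X, [fg.RandomTerm("g", Z)]))
    assert fit.vc.variances["g"] == 0.0
    assert fit.vc.residual == 0.0
    assert "g" in fit.vc.boundary
    np.testing.assert_allclose(fit.beta, beta, atol=1e-10)


def test_spectral_equals_general_optimizer_single_kernel():
    """Two independent REML routes agree on a 40-line kernel model."""
    rng = np.random.default_rng(7)
    n = 40
    A = rng.normal(size=(n, 25))
    K = A @ A.T / 25
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    y = L @ rng.normal(size=n) * 1.3 + rng.normal(0, 0.8, n)
    spec = fg.MixedModelSpec(y, np.ones((n, 1)), [fg.RandomTerm("g", np.eye(n), K)])
    fast = fg.fit_reml(spec)
    slow = fg.fit_reml(spec, options={"force_general": True})
    assert fast.vc.variances["g"] == pytest.approx(slow.vc.variances["g"], rel=1e-5, abs=1e-6)
    assert fast.vc.residual == pytest.approx(slow.vc.residual, rel=1e-5, abs=1e-6)
    assert fast.vc.loglik == pytest.approx(slow.vc.loglik, abs=1e-6)


def test_mme_determinant_form_equals_dense_likelihood():
    """Identity-kernel fast path and dense fallback give the same optimum."""
    rng = np.random.default_rng(3)
    g, r = 12, 3
    y = np.repeat(rng.normal(0, 1.5, g), r) + np.tile(rng.normal(0, 0.7, r), g)[: g * r] + rng.normal(0, 1, g * r)
    Zg = np.kron(np.eye(g), np.ones((r, 1)))
    Zb = np.tile(np.eye(r), (g, 1))
    spec = fg.MixedModelSpec(y, np.ones((g * r, 1)), [fg.RandomTerm("g", Zg), fg.RandomTerm("b", Zb)])
    mme = fg.fit_reml(spec)
    dense = fg.fit_reml(spec, options={"force_dense": True})
    assert mme.vc.loglik == pytest.approx(dense.vc.loglik, abs=1e-6)
    for k in ("g", "b"):
        assert mme.vc.variances[k] == pytest.approx(dense.vc.variances[k], rel=1e-4, abs=1e-7)


def test_solve_mme_matches_direct_gls_oracle():
    """Henderson solution equals the dense closed form on a 30x200 instance."""
    rng = np.random.default_rng(11)
    n, q = 30, 200
    Z = rng.normal(size=(n, q)) / np.sqrt(q)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    vc = fg.VarianceComponents({"u": 1.7}, residual=0.6, loglik=0.0, aic=0.0, converged=True)
    spec = fg.MixedModelSpec(y, X, [fg.RandomTerm("u", Z)])
    fit = fg.solve_mme(spec, vc)
    V = 1.7 * Z @ Z.T + 0.6 * np.eye(n)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = 1.7 * Z.T @ Vi @ (y - X @ beta)
    np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
    np.testing.assert_allclose(fit.blups["u"], u, atol=1e-8)
    # idempotence
    fit2 = fg.solve_mme(spec, vc)
    np.testing.assert_array_equal(fit.blups["u"], fit2.blups["u"])


def test_scalar_shrinkage_closed_form():
    """K = I, intercept-only: BLUP_i = (y_i - ybar) s2g / (s2g + s2r)."""
    rng = np.random.default_rng(5)
    y = rng.normal(size=20)
    spec = fg.MixedModelSpec(y, np.ones((20, 1)), [fg.RandomTerm("g", np.eye(20))])
    vc = fg.VarianceComponents({"g": 2.0}, residual=3.0, loglik=0.0, aic=0.0, converged=True)
    fit = fg.solve_mme(spec, vc)
    np.testing.assert_allclose(fit.blups["g"], (y - y.mean()) * 2.0 / 5.0, atol=1e-10)


def test_infinite_shrinkage_sends_blups_to_zero():
    rng = np.random.default_rng(6)
    y = rng.normal(size=15)
    spec = fg.MixedModelSpec(y, np.ones((15, 1)), [fg.RandomTerm("g", np.eye(15))])
    vc = fg.VarianceComponents({"g": 1e-12}, residual=1.0, loglik=0.0, aic=0.0, converged=True)
    fit = fg.solve_mme(spec, vc)
    assert np.abs(fit.blups["g"]).max() < 1e-10


def test_solve_mme_reproduces_fit_reml_solutions():
    y, Z, g, r = balanced_oneway(9)
    spec = fg.MixedModelSpec(y, np.ones((g * r, 1)), [fg.RandomTerm("g", Z)])
    fit = fg.fit_reml(spec)
    again = fg.solve_mme(spec, fit.vc)
    np.testing.assert_allclose(fit.beta, again.beta, atol=1e-8)
    np.testing.assert_allclose(fit.blups["g"], again.blups["g"], atol=1e-8)


def test_centered_kernel_blups_sum_to_zero():
    """With a row-centered kernel (GRM-like), BLUPs are centered too."""
    rng = np.random.default_rng(14)
    n = 25
    W = rng.normal(size=(n, 60))
    W -= W.mean(0)
    K = W @ W.T / 60
    y = rng.normal(size=n)
    fit = fg.fit_reml(fg.MixedModelSpec(y, np.ones((n, 1)), [fg.RandomTerm("g", np.eye(n), K)]))
    assert abs(fit.blups["g"].sum()) < 1e-8


def test_aic_identical_fits_and_mixed_fixed_designs():
    y, Z, g, r = balanced_oneway(2)
    spec = fg.MixedModelSpec(y, np.ones((g * r, 1)), [fg.RandomTerm("g", Z)])
    f1, f2 = fg.fit_reml(spec), fg.fit_reml(spec)
    assert fg.aic(f1) == fg.aic(f2)
    other = fg.MixedModelSpec(
        y, np.column_stack([np.ones(g * r), np.arange(g * r)]), [fg.RandomTerm("g", Z)]
    )
    f3 = fg.fit_reml(other)
    with pytest.raises(ValueError, match="identical fixed designs"):
        compare_aic(f1, f3)


def test_aic_penalty_under_null_and_power_under_signal():
    """A spurious random term rarely improves AIC; a real one usually wins."""
    null_ok = signal_ok = 0
    n_seeds = 50
    g, r = 10, 3
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        Zg = np.kron(np.eye(g), np.ones((r, 1)))
        Zb = np.tile(np.eye(r), (g, 1))
        base = np.repeat(rng.normal(0, 1.0, g), r)
        y_null = base + rng.normal(0, 1.0, g * r)
        y_sig = base + np.tile(rng.normal(0, 1.5, r), g) + rng.normal(0, 1.0, g * r)
        X = np.ones((g * r, 1))
        with np.errstate(all="ignore"):
            f_small = fg.fit_reml(fg.MixedModelSpec(y_null, X, [fg.RandomTerm("g", Zg)]))
            f_big = fg.fit_reml(
                fg.MixedModelSpec(y_null, X, [fg.RandomTerm("g", Zg), fg.RandomTerm("b", Zb)])
            )
            null_ok += fg.aic(f_big) >= fg.aic(f_small) - 1e-6
            f_s2 = fg.fit_reml(fg.MixedModelSpec(y_sig, X, [fg.RandomTerm("g", Zg)]))
            f_b2 = fg.fit_reml(
                fg.MixedModelSpec(y_sig, X, [fg.RandomTerm("g", Zg), fg.RandomTerm("b", Zb)])
            )
            signal_ok += fg.aic(f_b2) < fg.aic(f_s2)
    assert null_ok >= n_seeds // 2 + 1
    assert signal_ok >= 45


def test_row_reorder_invariance():
    y, Z, g, r = balanced_oneway(8)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(y))
    f1 = fg.fit_reml(fg.MixedModelSpec(y, np.ones((len(y), 1)), [fg.RandomTerm("g", Z)]))
    f2 = fg.fit_reml(fg.MixedModelSpec(y[perm], np.ones((len(y), 1)), [fg.RandomTerm("g", Z[perm])]))
    assert f1.vc.variances["g"] == pytest.approx(f2.vc.variances["g"], rel=1e-6)
    assert f1.vc.residual == pytest.approx(f2.vc.residual, rel=1e-6)


def test_response_scale_equivariance():
    """Doubling y multiplies variances by 4, leaving ratio-type h2 unchanged."""
    y, Z, g, r = balanced_oneway(4)
    X = np.ones((len(y), 1))
    f1 = fg.fit_reml(fg.MixedModelSpec(y, X, [fg.RandomTerm("g", Z)]))
    f2 = fg.fit_reml(fg.MixedModelSpec(2 * y, X, [fg.RandomTerm("g", Z)]))
    assert f2.vc.variances["g"] == pytest.approx(4 * f1.vc.variances["g"], rel=1e-5)
    assert f2.vc.residual == pytest.approx(4 * f1.vc.residual, rel=1e-5)
    h1 = f1.vc.variances["g"] / (f1.vc.variances["g"] + f1.vc.residual)
    h2 = f2.vc.variances["g"] / (f2.vc.variances["g"] + f2.vc.residual)
    assert h1 == pytest.approx(h2, rel=1e-5)


def test_error_paths():
    rng = np.random.default_rng(1)
    y = rng.normal(size=12)
    Z = np.kron(np.eye(4), np.ones((3, 1)))
    bad_K = np.diag([1.0, 1.0, 1.0, -1.0])
    with pytest.raises(ValueError, match="positive semidefinite"):
        fg.fit_reml(fg.MixedModelSpec(y, np.ones((12, 1)), [fg.RandomTerm("g", Z, bad_K)]))
    X = np.column_stack([np.ones(12), np.ones(12)])
    with pytest.raises(ValueError, match="aliased columns.*x1"):
        fg.fit_reml(
            fg.MixedModelSpec(y, X, [fg.RandomTerm("g", Z)], fixed_names=["x0", "x1"])
        )
    with pytest.raises(ValueError, match="residual degrees"):
        fg.fit_reml(fg.MixedModelSpec(y[:3], np.eye(3)[:, :2], [fg.RandomTerm("g", Z[:3])]))
    with pytest.raises(ValueError, match="positive"):
        fg.solve_mme(
            fg.MixedModelSpec(np.zeros(4), np.ones((4, 1)), [fg.RandomTerm("g", np.eye(4))]),
            fg.VarianceComponents({"g": 1.0}, residual=0.0, loglik=0, aic=0, converged=True),
        )
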