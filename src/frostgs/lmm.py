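"""Linear mixed model engine: REML variance components, Henderson's equations, AIC.

This module is the shared numerical core for the phenotypic stage-1/stage-2
models, GBLUP/WBLUP genomic prediction, the kinship-corrected association scan
and ridge-regression BLUP.  All of those are instances of

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, K_k s2_k),   e ~ N(0, I s2_r)

with known design matrices and covariance kernels.  Three REML evaluation
strategies are used depending on model shape:

* a spectral (eigendecomposition) profiled likelihood for models with a single
  random term -- the hot path for GBLUP, the GWAS null model and RR-BLUP;
* a Henderson mixed-model-equation determinant form when every kernel is the
  identity (stage-1 field/frost models with several small variance components);
* a dense-V fallback for anything else.

All three compute the same restricted log-likelihood (up to the shared
(n-p)/2*log(2*pi) constant, which is included in the reported value) and are
cross-checked against each other in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "RandomTerm",
    "MixedModelSpec",
    "VarianceComponents",
    "FitResult",
    "fit_reml",
    "solve_mme",
    "aic",
    "compare_aic",
    "NonConvergenceWarning",
]

_LOG2PI = math.log(2.0 * math.pi)


class NonConvergenceWarning(UserWarning):
    """Raised as a warning when the REML optimizer fails to converge."""


@dataclass
class RandomTerm:
    """One random effect: design matrix ``Z`` (n x q) and covariance kernel ``K``.

    ``K is None`` means the identity (i.i.d. levels).  ``K`` must be symmetric
    positive semidefinite.
    """

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ValueError(f"random term {self.name!r}: Z must be 2-D")
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            q = self.Z.shape[1]
            if self.K.shape != (q, q):
                raise ValueError(
                    f"random term {self.name!r}: kernel shape {self.K.shape} "
                    f"does not match Z columns ({q})"
                )

    def cov_contribution(self) -> np.ndarray:
        """n x n covariance contribution Z K Z' (at unit variance)."""
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class MixedModelSpec:
    """Response, fixed design and random terms of one mixed model."""

    y: np.ndarray
    X: np.ndarray
    random_terms: list[RandomTerm]
    fixed_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of observations")
        for term in self.random_terms:
            if term.Z.shape[0] != self.y.shape[0]:
                raise ValueError(
                    f"random term {term.name!r} has {term.Z.shape[0]} rows, "
                    f"expected {self.y.shape[0]}"
                )
        if self.fixed_names is None:
            self.fixed_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def fixed_design_key(self) -> tuple:
        """Hashable fingerprint of the fixed part, for AIC comparability checks."""
        import hashlib

        h = hashlib.sha1(np.ascontiguousarray(self.X).tobytes()).hexdigest()
        return (self.X.shape, h)


@dataclass
class VarianceComponents:
    """REML variance component estimates for one fit."""

    variances: dict[str, float]
    residual: float
    loglik: float
    aic: float
    converged: bool
    boundary: list[str] = field(default_factory=list)
    n_params: int = 0

    def as_dict(self) -> dict[str, float]:
        d = dict(self.variances)
        d["residual"] = self.residual
        return d


@dataclass
class FitResult:
    """Variance components, GLS fixed effects (BLUEs) and BLUPs of one fit."""

    vc: VarianceComponents
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list[str]
    blups: dict[str, np.ndarray]
    fixed_design_key: tuple
    n_obs: int

    @property
    def converged(self) -> bool:
        return self.vc.converged


# ---------------------------------------------------------------------------
# validation helpers


def _check_kernels(spec: MixedModelSpec) -> None:
    for term in spec.random_terms:
        if term.K is None:
            continue
        K = term.K
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError(f"kernel of random term {term.name!r} is not symmetric")
        w = linalg.eigvalsh(K)
        if w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError(
                f"kernel of random term {term.name!r} is not positive semidefinite "
                f"(min eigenvalue {w[0]:.3g})"
            )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming aliased columns if X is column-rank deficient."""
    if X.shape[1] == 0:
        raise ValueError("fixed design has no columns")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(
            "fixed design is singular; aliased columns: " + ", ".join(map(str, aliased))
        )


# ---------------------------------------------------------------------------
# restricted likelihood evaluations


def _neg2_reml_dense(y, X, Hs, s2, s2r):
    n = y.shape[0]
    V = s2r * np.eye(n)
    for H, s in zip(Hs, s2):
        V += s * H
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, None
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ Vi_X
    XtViy = X.T @ Vi_y
    try:
        cx, lowx = linalg.cho_factor(XtViX, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, None
    logdet_x = 2.0 * np.sum(np.log(np.diag(cx)))
    beta = linalg.cho_solve((cx, lowx), XtViy, check_finite=False)
    yPy = float(y @ Vi_y - XtViy @ beta)
    return logdet_v + logdet_x + yPy, (V, Vi_y, Vi_X, XtViX, beta)


def _mme_precompute(spec: MixedModelSpec):
    W = np.hstack([spec.X] + [t.Z for t in spec.random_terms])
    return W.T @ W, W.T @ spec.y, float(spec.y @ spec.y)


def _neg2_reml_mme(spec, WtW, Wty, yty, s2, s2r):
    """Determinant form of -2 log RL for identity-kernel terms.

    Uses log|V| + log|X'V^-1 X| = log|R| + log|G| + log|C| with C the MME
    coefficient matrix; exact for any mix of fixed effects and i.i.d. random
    terms, at cost O((p + sum q_k)^3) instead of O(n^3).
    """
    n, p = spec.n, spec.p
    qs = [t.Z.shape[1] for t in spec.random_terms]
    C = WtW / s2r
    off = p
    log_g = 0.0
    for q, s in zip(qs, s2):
        idx = slice(off, off + q)
        C[idx, idx] = C[idx, idx] + np.eye(q) / s
        log_g += q * math.log(s)
        off += q
    try:
        c, low = linalg.cho_factor(C, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, None
    logdet_c = 2.0 * np.sum(np.log(np.diag(c)))
    b = linalg.cho_solve((c, low), Wty / s2r, check_finite=False)
    yPy = (yty - float(Wty @ b)) / s2r
    return n * math.log(s2r) + log_g + logdet_c + yPy, b


# ---------------------------------------------------------------------------
# fitting


def _finalize(spec, Hs, s2, s2r, neg2, converged, options):
    """Build FitResult from components via the dense GLS/MME closed form."""
    n, p = spec.n, spec.p
    crit, parts = _neg2_reml_dense(spec.y, spec.X, Hs, s2, s2r)
    if parts is None:
        raise linalg.LinAlgError("covariance matrix singular at the REML optimum")
    V, Vi_y, Vi_X, XtViX, beta = parts
    beta_cov = linalg.inv(XtViX)
    resid_vec = spec.y - spec.X @ beta
    c, low = linalg.cho_factor(V, check_finite=False)
    Vi_r = linalg.cho_solve((c, low), resid_vec, check_finite=False)
    blups = {}
    for term, s in zip(spec.random_terms, s2):
        ZtVir = term.Z.T @ Vi_r
        u = s * (ZtVir if term.K is None else term.K @ ZtVir)
        blups[term.name] = u
    scale = max(float(np.var(spec.y)), np.finfo(float).tiny)
    boundary = [
        t.name for t, s in zip(spec.random_terms, s2) if s <= options["floor"] * scale * 10
    ]
    if s2r <= options["floor"] * scale * 10:
        boundary.append("residual")
    k = len(s2) + 1
    loglik = -0.5 * (crit + (n - p) * _LOG2PI)
    vc = VarianceComponents(
        variances={t.name: float(s) for t, s in zip(spec.random_terms, s2)},
        residual=float(s2r),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        converged=converged,
        boundary=boundary,
        n_params=k,
    )
    return FitResult(
        vc=vc,
        beta=beta,
        beta_cov=beta_cov,
        fixed_names=list(spec.fixed_names),
        blups=blups,
        fixed_design_key=spec.fixed_design_key(),
        n_obs=n,
    )


def _fit_spectral(spec: MixedModelSpec, options) -> FitResult:
    """Profiled REML over the ratio gamma = s2_g / s2_r for one random term."""
    y, X = spec.y, spec.X
    n, p = spec.n, spec.p
    H = spec.random_terms[0].cov_contribution()
    lam, U = linalg.eigh(H)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def profile(log_gamma):
        g = math.exp(log_gamma)
        d = g * lam + 1.0
        w = 1.0 / d
        XtW = Xt * w[:, None]
        A = Xt.T @ XtW
        try:
            ca, lowa = linalg.cho_factor(A, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, None, None
        b = linalg.cho_solve((ca, lowa), XtW.T @ yt, check_finite=False)
        r = yt - Xt @ b
        rss_w = float(np.sum(w * r * r))
        if rss_w <= 0:
            return np.inf, None, None
        s2r = rss_w / (n - p)
        logdet_a = 2.0 * np.sum(np.log(np.diag(ca)))
        crit = (
            np.sum(np.log(d))
            + (n - p) * math.log(s2r)
            + logdet_a
            + (n - p)
        )
        return crit, s2r, g

    lo, hi = options["log_gamma_bounds"]
    res = optimize.minimize_scalar(
        lambda lg: profile(lg)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    crit, s2r, g = profile(res.x)
    converged = bool(res.success) and np.isfinite(crit)
    if not converged:
        warnings.warn("spectral REML did not converge", NonConvergenceWarning)
    s2 = [g * s2r]
    return _finalize(spec, [H], s2, s2r, crit, converged, options)


def _fit_general(spec: MixedModelSpec, options) -> FitResult:
    """Profiled REML over the variance ratios lambda_k = s2_k / s2_r.

    The residual scale has a closed form given the ratios, so the search runs
    in k dimensions on the log-ratio scale (Nelder-Mead; the likelihood is
    smooth but the ratio boundaries at 0 make gradient methods fragile).
    """
    y, X = spec.y, spec.X
    n, p = spec.n, spec.p
    Hs = [t.cov_contribution() for t in spec.random_terms]
    k = len(Hs)
    identity_only = all(t.K is None for t in spec.random_terms) and not options.get(
        "force_dense", False
    )
    if identity_only:
        WtW, Wty, yty = _mme_precompute(spec)
        qs = [t.Z.shape[1] for t in spec.random_terms]

        def profile(log_lam):
            lam = np.exp(np.clip(log_lam, -30.0, 30.0))
            C = WtW.copy()
            off = p
            log_g = 0.0
            for q, lv in zip(qs, lam):
                idx = slice(off, off + q)
                C[idx, idx] = C[idx, idx] + np.eye(q) / lv
                log_g += q * math.log(lv)
                off += q
            try:
                c, low = linalg.cho_factor(C, check_finite=False)
            except linalg.LinAlgError:
                return np.inf, None
            logdet_c = 2.0 * np.sum(np.log(np.diag(c)))
            b = linalg.cho_solve((c, low), Wty, check_finite=False)
            ypy_t = yty - float(Wty @ b)
            if ypy_t <= 0:
                return np.inf, None
            s2r = ypy_t / (n - p)
            crit = log_g + logdet_c + (n - p) * math.log(s2r) + (n - p)
            return crit, s2r

    else:

        def profile(log_lam):
            lam = np.exp(np.clip(log_lam, -30.0, 30.0))
            Vt = np.eye(n)
            for H, lv in zip(Hs, lam):
                Vt += lv * H
            try:
                c, low = linalg.cho_factor(Vt, check_finite=False)
            except linalg.LinAlgError:
                return np.inf, None
            logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
            Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
            Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
            A = X.T @ Vi_X
            try:
                ca, lowa = linalg.cho_factor(A, check_finite=False)
            except linalg.LinAlgError:
                return np.inf, None
            logdet_a = 2.0 * np.sum(np.log(np.diag(ca)))
            Xty = X.T @ Vi_y
            beta = linalg.cho_solve((ca, lowa), Xty, check_finite=False)
            ypy_t = float(y @ Vi_y - Xty @ beta)
            if ypy_t <= 0:
                return np.inf, None
            s2r = ypy_t / (n - p)
            crit = logdet_v + logdet_a + (n - p) * math.log(s2r) + (n - p)
            return crit, s2r

    def neg2(theta):
        return profile(theta)[0]

    starts = [
        np.zeros(k),
        np.full(k, math.log(0.1)),
        np.full(k, math.log(5.0)),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg2,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": options["maxiter"] * max(k, 1) * 5,
                "maxfev": options["maxiter"] * max(k, 1) * 10,
                "fatol": options["tol"],
                "xatol": 1e-8,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        if np.isfinite(res.fun) and res.success:
            break
    # NM can exhaust iterations while creeping along a flat boundary
    # direction; accept if the final simplex is numerically collapsed
    spread = np.inf
    if hasattr(best, "final_simplex"):
        fvals = best.final_simplex[1]
        spread = float(np.max(fvals) - np.min(fvals))
    converged = np.isfinite(best.fun) and (bool(best.success) or spread < 1e-6)
    if not converged:
        warnings.warn("REML optimizer did not converge", NonConvergenceWarning)
    crit, s2r = profile(best.x)
    lam = np.exp(np.clip(best.x, -30.0, 30.0))
    s2 = list(lam * s2r)
    return _finalize(spec, Hs, s2, s2r, best.fun, converged, options)


_DEFAULT_OPTIONS = {
    "maxiter": 200,
    "tol": 1e-9,
    "floor": 1e-8,
    "log_gamma_bounds": (-18.0, 18.0),
}


def fit_reml(spec: MixedModelSpec, options: dict | None = None) -> FitResult:
    """Restricted maximum likelihood fit of a mixed model.

    Returns variance components, GLS fixed-effect estimates with their
    covariance matrix, and BLUPs of every random term evaluated at the REML
    optimum.  Models with exactly one random term take the spectral fast path;
    models whose kernels are all identity use the Henderson-MME determinant
    form; everything else the dense fallback.

    Raises ``ValueError`` for non-PSD kernels or a singular fixed design
    (naming the aliased columns); non-convergence is flagged on the result and
    warned about, never silent.
    """
    opts = dict(_DEFAULT_OPTIONS)
    if options:
        opts.update(options)
    _check_kernels(spec)
    _check_full_rank(spec.X, spec.fixed_names)
    n, p = spec.n, spec.p
    if n - p < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")
    if not spec.random_terms:
        raise ValueError("at least one random term is required")

    # noise-free short circuit: the likelihood has no interior optimum
    beta_ols, rss, *_ = np.linalg.lstsq(spec.X, spec.y, rcond=None)
    rss = float(rss[0]) if np.size(rss) else float(
        np.sum((spec.y - spec.X @ beta_ols) ** 2)
    )
    scale = max(float(np.var(spec.y)), 1.0)
    if rss / n < 1e-14 * scale:
        k = len(spec.random_terms) + 1
        vc = VarianceComponents(
            variances={t.name: 0.0 for t in spec.random_terms},
            residual=0.0,
            loglik=math.inf,
            aic=-math.inf,
            converged=True,
            boundary=[t.name for t in spec.random_terms] + ["residual"],
            n_params=k,
        )
        return FitResult(
            vc=vc,
            beta=beta_ols,
            beta_cov=np.zeros((p, p)),
            fixed_names=list(spec.fixed_names),
            blups={t.name: np.zeros(t.Z.shape[1]) for t in spec.random_terms},
            fixed_design_key=spec.fixed_design_key(),
            n_obs=n,
        )

    if len(spec.random_terms) == 1 and not opts.get("force_general", False):
        return _fit_spectral(spec, opts)
    return _fit_general(spec, opts)


def solve_mme(spec: MixedModelSpec, vc: VarianceComponents) -> FitResult:
    """Solve the mixed-model equations at fixed variance components.

    Equivalent to Henderson's equations, computed through the GLS closed form
    b = (X'V^-1 X)^-1 X'V^-1 y and u_k = s2_k K_k Z_k' V^-1 (y - X b); exact
    and idempotent given the same inputs.
    """
    _check_kernels(spec)
    _check_full_rank(spec.X, spec.fixed_names)
    s2 = [vc.variances[t.name] for t in spec.random_terms]
    if any(s < 0 for s in s2) or vc.residual <= 0:
        raise ValueError("variance components must be positive (residual) and nonnegative")
    Hs = [t.cov_contribution() for t in spec.random_terms]
    opts = dict(_DEFAULT_OPTIONS)
    try:
        return _finalize(spec, Hs, s2, vc.residual, None, True, opts)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(f"singular mixed-model coefficient matrix: {exc}")


def aic(fit: FitResult) -> float:
    """Akaike information criterion of a converged REML fit.

    -2 log RL + 2 * (number of estimated variance parameters).  Comparable
    only between fits sharing the identical fixed design; use
    :func:`compare_aic` to enforce that.
    """
    if not fit.converged:
        raise ValueError("AIC undefined for a non-converged fit")
    return fit.vc.aic


def compare_aic(*fits: FitResult) -> int:
    """Index of the AIC-best fit; errors if fixed designs differ."""
    keys = {f.fixed_design_key for f in fits}
    if len(keys) > 1:
        raise ValueError(
            "AIC comparison requires identical fixed designs across models"
        )
    scores = [aic(f) for f in fits]
    return int(np.argmin(scores))
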