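"""Two-stage phenotypic analysis: within-trial and across-trial BLUEs and h2.

Stage 1 analyzes each trial with a mixed model; the line effect is first
fitted as random to estimate the genetic variance sigma2_G and then as fixed
to obtain adjusted line means (BLUEs).  Entry-mean heritability follows the
mean-variance-of-a-difference form

    h2 = sigma2_G / (sigma2_G + MVD / 2)

with MVD the mean variance of a difference between line BLUEs, computed from
the fixed-fit covariance matrix.  Field trials are screened over a small
candidate set of nuisance-effect models (block, block+row, block+column,
block+row+column, all random with i.i.d. residuals) selected by AIC; trials
with h2 <= 0.3 are flagged as too noisy for downstream prediction.  Stage 2
pools per-trial BLUEs with trial as a fixed effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import FitResult, MixedModelSpec, RandomTerm, compare_aic, fit_reml

__all__ = [
    "HeritabilityEstimate",
    "fit_frost_model",
    "fit_trial_model",
    "across_trial_model",
    "trait_correlations",
    "mvd_from_cov",
    "DEFAULT_CANDIDATES",
]

DEFAULT_CANDIDATES = [
    ("block",),
    ("block", "row"),
    ("block", "column"),
    ("block", "row", "column"),
]


@dataclass
class HeritabilityEstimate:
    """Entry-mean heritability with its ingredients."""

    h2: float
    sigma2_g: float
    mvd: float
    components: dict = field(default_factory=dict)
    flagged_low: bool = False
    trial: str | None = None

    @staticmethod
    def from_parts(sigma2_g: float, mvd: float, components=None, trial=None,
                   low_threshold: float = 0.3) -> "HeritabilityEstimate":
        denom = sigma2_g + 0.5 * mvd
        h2 = sigma2_g / denom if denom > 0 else 0.0
        h2 = min(h2, 1.0 - 1e-12)
        return HeritabilityEstimate(
            h2=h2,
            sigma2_g=sigma2_g,
            mvd=mvd,
            components=dict(components or {}),
            flagged_low=h2 <= low_threshold,
            trial=trial,
        )


def mvd_from_cov(C: np.ndarray) -> float:
    """Mean of var(BLUE_i - BLUE_j) over all unordered line pairs."""
    m = C.shape[0]
    if m < 2:
        return 0.0
    v = np.diag(C)
    total = C.sum()
    s = v.sum()
    pair_sum = (m - 1) * s - (total - s)
    return float(pair_sum / (m * (m - 1) / 2.0))


def _indicator(values: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(values))
    lookup = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), [lookup[v] for v in values]] = 1.0
    return Z, levels


def _drop_unobserved(pheno: pd.DataFrame) -> pd.DataFrame:
    bad = pheno["value"].isna()
    if bad.any():
        lost = sorted(set(pheno.loc[bad, "line"]) - set(pheno.loc[~bad, "line"]))
        if lost:
            warnings.warn(f"lines with no observed plots excluded: {lost}")
        pheno = pheno.loc[~bad]
    return pheno


def _two_pass(pheno: pd.DataFrame, nuisance: tuple[str, ...], trial: str | None):
    """Random-genotype fit for sigma2_G, then fixed-genotype fit for BLUEs/MVD."""
    y = pheno["value"].to_numpy(dtype=float)
    Zg, lines = _indicator(pheno["line"])
    nuis_terms = []
    for factor in nuisance:
        if factor not in pheno.columns or pheno[factor].isna().any():
            raise ValueError(f"design table lacks complete {factor!r} labels")
        Z, _ = _indicator(pheno[factor])
        nuis_terms.append(RandomTerm(factor, Z))

    random_fit = fit_reml(
        MixedModelSpec(
            y=y,
            X=np.ones((len(y), 1)),
            random_terms=[RandomTerm("line", Zg)] + nuis_terms,
            fixed_names=["intercept"],
        )
    )
    sigma2_g = random_fit.vc.variances["line"]

    fixed_fit = fit_reml(
        MixedModelSpec(
            y=y,
            X=Zg,
            random_terms=[RandomTerm(t.name, t.Z) for t in nuis_terms],
            fixed_names=list(lines),
        )
    )
    blues = pd.DataFrame(
        {
            "line": lines,
            "trait": pheno["trait"].iloc[0],
            "blue": fixed_fit.beta,
            "se": np.sqrt(np.diag(fixed_fit.beta_cov)),
        }
    )
    blues.attrs["trial"] = trial
    mvd = mvd_from_cov(fixed_fit.beta_cov)
    components = dict(random_fit.vc.as_dict())
    h2 = HeritabilityEstimate.from_parts(sigma2_g, mvd, components, trial)
    return blues, h2, random_fit, fixed_fit


def fit_frost_model(pheno: pd.DataFrame):
    """Analyze the complete-block frost experiment: BLUEs and heritability.

    Model: observation = grand mean + line + random block + residual, with
    the line effect random in the first pass (genetic variance) and fixed in
    the second (BLUEs and their pairwise difference variances).
    """
    pheno = _drop_unobserved(pheno)
    if pheno["block"].nunique() < 2:
        raise ValueError("frost analysis needs at least 2 blocks")
    trial = pheno["trial"].iloc[0] if "trial" in pheno else None
    blues, h2, *_ = _two_pass(pheno, ("block",), trial)
    return blues, h2


def fit_trial_model(pheno: pd.DataFrame, candidate_models: list | None = None):
    """Stage-1 field-trial analysis with AIC selection of nuisance effects.

    Each candidate is a tuple of random nuisance factors; the genotype-random
    fits (identical fixed parts) are compared by AIC, then the two-pass BLUE
    scheme is run under the winning model.  Returns (BLUEs, heritability,
    chosen model); the heritability carries the h2 <= 0.3 exclusion flag.
    """
    if candidate_models is None:
        candidate_models = list(DEFAULT_CANDIDATES)
    if not candidate_models:
        raise ValueError("empty candidate model list")
    pheno = _drop_unobserved(pheno)
    trial = pheno["trial"].iloc[0] if "trial" in pheno else None

    y = pheno["value"].to_numpy(dtype=float)
    Zg, _ = _indicator(pheno["line"])
    fits: list[FitResult] = []
    for cand in candidate_models:
        terms = [RandomTerm("line", Zg)]
        for factor in cand:
            if factor not in pheno.columns or pheno[factor].isna().any():
                raise ValueError(f"candidate {cand} requires complete {factor!r} labels")
            Z, _ = _indicator(pheno[factor])
            terms.append(RandomTerm(factor, Z))
        fits.append(
            fit_reml(
                MixedModelSpec(
                    y=y, X=np.ones((len(y), 1)), random_terms=terms,
                    fixed_names=["intercept"],
                )
            )
        )
    winner = compare_aic(*fits)
    chosen = tuple(candidate_models[winner])
    blues, h2, *_ = _two_pass(pheno, chosen, trial)
    if h2.flagged_low:
        warnings.warn(
            f"trial {trial!r}: heritability {h2.h2:.2f} <= 0.3, flagged for exclusion"
        )
    return blues, h2, chosen


def _connected(blues_by_trial: list[pd.DataFrame]) -> bool:
    parent: dict = {}

    def find(a):
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for t, tab in enumerate(blues_by_trial):
        tnode = ("trial", t)
        for ln in tab["line"]:
            ra, rb = find(tnode), find(("line", ln))
            if ra != rb:
                parent[ra] = rb
    roots = {find(("trial", t)) for t in range(len(blues_by_trial))}
    return len(roots) == 1


def across_trial_model(blues_by_trial: list[pd.DataFrame]):
    """Stage-2 pooled analysis of per-trial BLUEs with trial as fixed effect.

    The random effect of the stage-2 model absorbs both trial-by-line
    interaction and the stage-1 estimation error into a single pooled
    variance.  With a single input trial the BLUEs pass through unchanged.
    """
    if len(blues_by_trial) == 1:
        warnings.warn("single trial supplied; across-trial analysis is a pass-through")
        tab = blues_by_trial[0].copy()
        return tab, HeritabilityEstimate(np.nan, np.nan, np.nan, trial="across")
    shared = set(blues_by_trial[0]["line"])
    for tab in blues_by_trial[1:]:
        shared &= set(tab["line"])
    if len(shared) < 2:
        raise ValueError("trials share fewer than 2 lines")
    if not _connected(blues_by_trial):
        raise ValueError("disconnected trial/line structure")

    stacked = pd.concat(
        [tab.assign(trial_id=i) for i, tab in enumerate(blues_by_trial)],
        ignore_index=True,
    )
    y = stacked["blue"].to_numpy(dtype=float)
    Zg, lines = _indicator(stacked["line"])
    n_tr = len(blues_by_trial)
    # sum-to-zero trial contrasts keep the line coefficients interpretable as
    # adjusted means averaged over trials
    T = np.zeros((len(stacked), n_tr - 1))
    for j in range(n_tr - 1):
        T[stacked["trial_id"] == j, j] = 1.0
        T[stacked["trial_id"] == n_tr - 1, j] = -1.0

    random_fit = fit_reml(
        MixedModelSpec(
            y=y,
            X=np.hstack([np.ones((len(y), 1)), T]),
            random_terms=[RandomTerm("line", Zg)],
            fixed_names=["intercept"] + [f"trial{j}" for j in range(n_tr - 1)],
        )
    )
    sigma2_g = random_fit.vc.variances["line"]
    sigma2_e = random_fit.vc.residual

    # fixed-genotype pass: only the pooled residual remains random, so this
    # is ordinary least squares with covariance sigma2_e (X'X)^-1
    X = np.hstack([Zg, T])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    if dof < 1:
        raise ValueError("across-trial model has no residual degrees of freedom")
    s2e_fixed = float(resid @ resid) / dof
    cov = s2e_fixed * np.linalg.inv(XtX)
    m = len(lines)
    C = cov[:m, :m]
    blues = pd.DataFrame(
        {
            "line": lines,
            "trait": stacked["trait"].iloc[0],
            "blue": beta[:m],
            "se": np.sqrt(np.diag(C)),
        }
    )
    blues.attrs["trial"] = "across"
    h2 = HeritabilityEstimate.from_parts(
        sigma2_g, mvd_from_cov(C), random_fit.vc.as_dict(), "across"
    )
    return blues, h2


def trait_correlations(blues_a: pd.DataFrame, blues_others, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlations of one trait's BLUEs with a set of other traits.

    ``blues_others`` maps trait names to BLUE tables; correlations use lines
    shared with ``blues_a`` and carry a two-sided significance flag at
    ``alpha``.
    """
    from scipy import stats

    if isinstance(blues_others, pd.DataFrame):
        blues_others = {blues_others["trait"].iloc[0]: blues_others}
    rows = []
    a = blues_a.set_index("line")["blue"]
    for name, tab in blues_others.items():
        b = tab.set_index("line")["blue"]
        shared = a.index.intersection(b.index)
        if len(shared) < 3:
            raise ValueError(f"trait {name!r}: fewer than 3 shared lines")
        r, p = stats.pearsonr(a.loc[shared], b.loc[shared])
        rows.append(
            {"trait": name, "r": float(r), "p_value": float(p),
             "n": len(shared), "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows)
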