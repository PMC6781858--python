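"""Genomic and marker-assisted prediction plus the kinship-corrected scan.

Models (all fitted by REML through :mod:`frostgs.lmm`):

* GBLUP -- y = 1 mu + Z_G u_G + r with u_G ~ N(0, K s2_G); validation lines
  are predicted jointly through the full relationship matrix, i.e. their
  breeding values are BLUPs propagated via the kinship between validation and
  training lines (exact under the model, zero for an unrelated line).
* WBLUP -- GBLUP plus the Fr-A2 CNV haploblock as a fixed effect, upweighting
  the major locus relative to the genome-wide shrinkage.
* RR-BLUP -- ridge regression of (a subset of) marker codes with a common
  marker-effect variance; the workhorse for marker-assisted prediction with
  preselected marker sets.
* GWAS -- per-marker fixed-effect Wald tests with the polygenic kinship term;
  variance components are estimated once on the null model and reused for
  every marker (the usual population-parameters-previously-determined
  approximation that makes 100-fold cross-validated scans tractable).
* rho_G -- share of genetic variance attributed to a locus, measured as the
  relative drop in the REML genetic variance when the locus enters the model
  as a fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .geno import GenotypeMatrix, Haploblock
from .lmm import MixedModelSpec, RandomTerm, fit_reml

__all__ = [
    "VarianceExplained",
    "gblup_predict",
    "wblup_predict",
    "rrblup_predict",
    "gwas_scan",
    "variance_explained",
]


@dataclass
class VarianceExplained:
    locus: str
    rho_g: float
    sigma2_g_base: float
    sigma2_g_locus_fixed: float


def _gebv_table(values: pd.Series, model: str, trait, train_lines) -> pd.DataFrame:
    if not np.all(np.isfinite(values.to_numpy(dtype=float))):
        raise ValueError("non-finite predictions")
    out = pd.DataFrame(
        {"line": values.index, "trait": trait, "model": model, "value": values.to_numpy()}
    )
    out.attrs["training_lines"] = list(train_lines)
    return out


def _train_arrays(train_blues: pd.DataFrame, K: pd.DataFrame, validation_lines):
    tb = train_blues.dropna(subset=["blue"])
    train_lines = list(tb["line"])
    missing = [ln for ln in train_lines if ln not in K.index]
    if missing:
        raise KeyError(f"training lines absent from kinship matrix: {missing[:5]}")
    missing = [ln for ln in validation_lines if ln not in K.index]
    if missing:
        raise KeyError(f"validation lines absent from kinship matrix: {missing[:5]}")
    y = tb["blue"].to_numpy(dtype=float)
    idx = K.index.get_indexer(train_lines)
    Z = np.zeros((len(train_lines), K.shape[0]))
    Z[np.arange(len(train_lines)), idx] = 1.0
    return y, Z, train_lines, tb


def _kernel_fit(y: np.ndarray, X: np.ndarray, Z: np.ndarray, K: pd.DataFrame,
                fixed_names: list[str]):
    spec = MixedModelSpec(
        y=y, X=X, random_terms=[RandomTerm("genomic", Z, np.asarray(K, dtype=float))],
        fixed_names=fixed_names,
    )
    fit = fit_reml(spec)
    u = pd.Series(fit.blups["genomic"], index=K.index)
    return fit, u


def gblup_predict(
    train_blues: pd.DataFrame,
    K: pd.DataFrame,
    validation_lines,
    trait: str | None = None,
    model_tag: str = "GS",
) -> pd.DataFrame:
    """Genomic BLUP of validation lines from training BLUEs and kinship K.

    Returned values are on the centered breeding-value scale (a validation
    line unrelated to every training line predicts exactly 0).
    """
    y, Z, train_lines, tb = _train_arrays(train_blues, K, validation_lines)
    trait = trait or (tb["trait"].iloc[0] if "trait" in tb else None)
    fit, u = _kernel_fit(y, np.ones((len(y), 1)), Z, K, ["intercept"])
    return _gebv_table(u.loc[list(validation_lines)], model_tag, trait, train_lines)


def wblup_predict(
    train_blues: pd.DataFrame,
    K: pd.DataFrame,
    haploblock: Haploblock,
    validation_lines,
    trait: str | None = None,
    model_tag: str = "wGS",
) -> pd.DataFrame:
    """Weighted GBLUP: the CNV haploblock enters as a fixed effect.

    Validation predictions combine the estimated haploblock effect with the
    kinship-propagated polygenic breeding value.  Raises if the haploblock is
    monomorphic across the training lines (the fixed effect would be aliased
    with the intercept rather than silently degrading to GBLUP).
    """
    y, Z, train_lines, tb = _train_arrays(train_blues, K, validation_lines)
    trait = trait or (tb["trait"].iloc[0] if "trait" in tb else None)
    m_train = haploblock.codes_for(train_lines)
    if np.ptp(m_train) == 0:
        raise ValueError(
            f"haploblock {haploblock.name!r} is monomorphic in the training set; "
            "its fixed effect is inestimable"
        )
    X = np.column_stack([np.ones(len(y)), m_train])
    fit, u = _kernel_fit(y, X, Z, K, ["intercept", haploblock.name])
    m_val = haploblock.codes_for(validation_lines)
    pred = pd.Series(
        fit.beta[0] + m_val * fit.beta[1] + u.loc[list(validation_lines)].to_numpy(),
        index=list(validation_lines),
    )
    return _gebv_table(pred, model_tag, trait, train_lines)


def rrblup_predict(
    train_blues: pd.DataFrame,
    markers,
    validation_lines,
    center_freqs: pd.Series | None = None,
    trait: str | None = None,
    model_tag: str = "MAS",
):
    """Ridge-regression BLUP of shrunken marker effects; returns (GEBVs, effects).

    ``markers`` is a GenotypeMatrix (or codes DataFrame) covering training and
    validation lines with no missing calls.  Codes are centered with the +1
    allele frequencies of the training lines unless ``center_freqs`` supplies
    a frozen reference (e.g. the full-panel frequencies used for the GRM).
    Collinear or duplicated marker columns need no special casing: the common
    shrinkage variance keeps the system well-posed.  In the zero marker
    variance limit every prediction collapses to the training intercept.
    """
    codes = markers.codes if isinstance(markers, GenotypeMatrix) else markers
    if codes.shape[1] < 1:
        raise ValueError("at least one marker is required")
    tb = train_blues.dropna(subset=["blue"])
    train_lines = list(tb["line"])
    for ln in list(train_lines) + list(validation_lines):
        if ln not in codes.index:
            raise KeyError(f"line {ln!r} lacks marker data")
    if codes.loc[list(train_lines) + list(validation_lines)].isna().to_numpy().any():
        raise ValueError("marker subset contains missing calls; impute first")
    trait = trait or (tb["trait"].iloc[0] if "trait" in tb else None)
    y = tb["blue"].to_numpy(dtype=float)

    if center_freqs is None:
        p = (codes.loc[train_lines].mean(axis=0) + 1.0) / 2.0
    else:
        p = center_freqs.loc[codes.columns]
    center = 2.0 * p.to_numpy() - 1.0
    Wt = codes.loc[train_lines].to_numpy() - center
    Wv = codes.loc[list(validation_lines)].to_numpy() - center

    spec = MixedModelSpec(
        y=y,
        X=np.ones((len(y), 1)),
        random_terms=[RandomTerm("markers", Wt)],
        fixed_names=["intercept"],
    )
    fit = fit_reml(spec)
    effects = pd.Series(fit.blups["markers"], index=codes.columns, name="effect")
    pred = pd.Series(fit.beta[0] + Wv @ effects.to_numpy(), index=list(validation_lines))
    table = _gebv_table(pred, model_tag, trait, train_lines)
    table.attrs["intercept"] = float(fit.beta[0])
    return table, effects


def gwas_scan(train_blues: pd.DataFrame, geno: GenotypeMatrix, K: pd.DataFrame) -> pd.DataFrame:
    """Kinship-corrected association scan over all markers.

    Fits the polygenic null model once by REML, then tests each marker as a
    fixed effect by a Wald test at those variance components.  Monomorphic
    markers get p = 1 with a flag.
    """
    tb = train_blues.dropna(subset=["blue"])
    train_lines = list(tb["line"])
    for ln in train_lines:
        if ln not in geno.lines or ln not in K.index:
            raise KeyError(f"training line {ln!r} not covered by genotypes/kinship")
    y = tb["blue"].to_numpy(dtype=float)
    n = len(y)
    Ktt = K.loc[train_lines, train_lines].to_numpy()
    spec = MixedModelSpec(
        y=y, X=np.ones((n, 1)),
        random_terms=[RandomTerm("genomic", np.eye(n), Ktt)],
        fixed_names=["intercept"],
    )
    null_fit = fit_reml(spec)
    s2g = null_fit.vc.variances["genomic"]
    s2r = null_fit.vc.residual

    lam, U = linalg.eigh(Ktt)
    lam = np.clip(lam, 0.0, None)
    w = 1.0 / (s2g * lam + s2r)
    yt = U.T @ y
    M = geno.codes.loc[train_lines].to_numpy()
    if np.isnan(M).any():
        raise ValueError("genotypes contain missing calls; impute before the scan")
    mono = M.std(axis=0) == 0.0
    Mt = U.T @ M
    one_t = U.T @ np.ones(n)

    a11 = float(np.sum(w * one_t * one_t))
    a12 = (w * one_t) @ Mt
    a22 = np.einsum("i,ij,ij->j", w, Mt, Mt)
    b1 = float(np.sum(w * one_t * yt))
    b2 = (w * yt) @ Mt
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        var_beta = a11 / det
        se = np.sqrt(var_beta)
        stat = beta**2 / var_beta
    pvals = stats.chi2.sf(stat, df=1)
    beta[mono] = 0.0
    se[mono] = np.nan
    stat[mono] = 0.0
    pvals[mono] = 1.0
    out = pd.DataFrame(
        {
            "marker": geno.markers,
            "chrom": geno.marker_map["chrom"].to_numpy(),
            "pos": geno.marker_map["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "stat": stat,
            "p_value": np.clip(pvals, np.finfo(float).tiny, 1.0),
            "flag": np.where(mono, "monomorphic", "ok"),
        }
    )
    out.attrs["variance_components"] = {"genomic": s2g, "residual": s2r}
    return out


def variance_explained(
    train_blues: pd.DataFrame,
    K: pd.DataFrame,
    locus,
    name: str | None = None,
) -> VarianceExplained:
    """Proportion of genetic variance rho_G attributed to one locus.

    Two REML fits sharing all random terms: the base GBLUP model and the same
    model with the locus (haploblock or single-marker codes) as a fixed
    effect.  rho_G = max(0, 1 - s2_G(locus fixed) / s2_G(base)).
    """
    tb = train_blues.dropna(subset=["blue"])
    train_lines = list(tb["line"])
    y = tb["blue"].to_numpy(dtype=float)
    n = len(y)
    Ktt = K.loc[train_lines, train_lines].to_numpy()
    if isinstance(locus, Haploblock):
        codes = locus.codes_for(train_lines)
        name = name or locus.name
    else:
        codes = pd.Series(locus).loc[train_lines].to_numpy(dtype=float)
        name = name or getattr(locus, "name", "locus")

    base = fit_reml(
        MixedModelSpec(
            y=y, X=np.ones((n, 1)),
            random_terms=[RandomTerm("genomic", np.eye(n), Ktt)],
            fixed_names=["intercept"],
        )
    )
    s2_base = base.vc.variances["genomic"]
    if s2_base <= 1e-10 * max(np.var(y), 1e-12):
        raise ValueError("base genetic variance is ~0; rho_G undefined")
    fixed = fit_reml(
        MixedModelSpec(
            y=y, X=np.column_stack([np.ones(n), codes]),
            random_terms=[RandomTerm("genomic", np.eye(n), Ktt)],
            fixed_names=["intercept", str(name)],
        )
    )
    s2_fixed = fixed.vc.variances["genomic"]
    rho = max(0.0, 1.0 - s2_fixed / s2_base)
    return VarianceExplained(str(name), rho, s2_base, s2_fixed)
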