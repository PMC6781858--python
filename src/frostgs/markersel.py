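"""Marker pre-selection for marker-assisted prediction.

Two routes reduce a genome-wide scan to a small panel suitable for targeted
genotyping (KASP assays, custom arrays, targeted GBS):

* chromosome-wise: take the 12 most significant markers per chromosome, run a
  forward stepwise regression per chromosome keeping 1-6 of them, pool the
  survivors (one to six per chromosome, i.e. 21-126 genome-wide) and reduce
  the pool with a second stepwise stage to at most 21 markers;
* genome-wide: stepwise regression straight from the 126 most significant
  markers down to at most 21.

The stepwise criterion is the AIC of the ordinary least-squares fit of the
training BLUEs on the selected marker codes, with forward selection stopping
when AIC no longer improves or the size cap is reached.  A seeded random
sampler provides the baseline panels.  All three routes are pure functions of
their inputs and record a full audit trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix

__all__ = [
    "MarkerSubset",
    "select_chromosome_wise",
    "select_genome_wide",
    "sample_random_markers",
]


@dataclass
class MarkerSubset:
    markers: list[str]
    route: str
    audit: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.markers)


def _rank_markers(gwas: pd.DataFrame) -> pd.DataFrame:
    """Sort by significance; ties by larger |effect|, then map order."""
    g = gwas.reset_index(drop=True).copy()
    g["_order"] = np.arange(len(g))
    g["_abs_beta"] = -g["beta"].abs()
    return g.sort_values(["p_value", "_abs_beta", "_order"], kind="mergesort")


def _ols_aic(rss: float, n: int, k: int) -> float:
    # k = number of mean parameters (intercept + markers); the +2 for the
    # variance cancels in comparisons but is kept for interpretability
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2.0 * (k + 1)


def _forward_stepwise(y, codes: pd.DataFrame, candidates, max_terms, min_terms,
                      audit, stage):
    """Greedy forward selection on OLS AIC via an orthonormal basis update."""
    n = len(y)
    yv = np.asarray(y, dtype=float)
    Q = np.ones((n, 1)) / math.sqrt(n)
    r_y = yv - Q @ (Q.T @ yv)
    rss = float(r_y @ r_y)
    current_aic = _ols_aic(rss, n, 1)
    selected: list[str] = []
    remaining = list(candidates)
    while remaining and len(selected) < max_terms:
        best = None
        for m in remaining:
            c = codes[m].to_numpy(dtype=float)
            c_perp = c - Q @ (Q.T @ c)
            norm2 = float(c_perp @ c_perp)
            if norm2 <= 1e-10 * max(float(c @ c), 1.0):
                continue  # aliased with current model
            gain = float(c_perp @ r_y) ** 2 / norm2
            cand_aic = _ols_aic(rss - gain, n, len(selected) + 2)
            if best is None or cand_aic < best[0]:
                best = (cand_aic, m, c_perp / math.sqrt(norm2), gain)
        if best is None:
            break
        cand_aic, m, q_new, gain = best
        improves = cand_aic < current_aic - 1e-12
        if not improves and len(selected) >= min_terms:
            break
        selected.append(m)
        remaining.remove(m)
        Q = np.hstack([Q, q_new[:, None]])
        rss -= gain
        r_y = r_y - q_new * float(q_new @ r_y)
        audit.append(
            {"stage": stage, "step": len(selected), "marker": m,
             "aic": cand_aic, "improved": bool(improves)}
        )
        current_aic = cand_aic
    return selected


def _training_codes(train_blues: pd.DataFrame, geno: GenotypeMatrix):
    tb = train_blues.dropna(subset=["blue"])
    lines = list(tb["line"])
    codes = geno.codes.loc[lines]
    if codes.isna().to_numpy().any():
        raise ValueError("marker selection requires imputed genotypes")
    return tb["blue"].to_numpy(dtype=float), codes


def select_chromosome_wise(
    gwas: pd.DataFrame,
    train_blues: pd.DataFrame,
    geno: GenotypeMatrix,
    per_chrom_top: int = 12,
    per_chrom_max: int = 6,
    final_cap: int = 21,
) -> MarkerSubset:
    """Two-stage chromosome-wise marker selection.

    Stage 1 keeps 1-``per_chrom_max`` markers per chromosome out of each
    chromosome's ``per_chrom_top`` most significant ones; stage 2 reduces the
    pooled set to at most ``final_cap`` markers.  Designed to spread the final
    panel across the whole genome, matching the polygenic architecture of
    winter-hardiness traits.
    """
    y, codes = _training_codes(train_blues, geno)
    if final_cap > len(y) - 2:
        raise ValueError("final_cap exceeds training size - 2; OLS not identifiable")
    ranked = _rank_markers(gwas)
    audit: list[dict] = []
    pooled: list[str] = []
    for chrom, grp in ranked.groupby("chrom", sort=True):
        cands = list(grp["marker"].iloc[:per_chrom_top])
        audit.append({"stage": f"chrom{chrom}_candidates", "markers": list(cands)})
        kept = _forward_stepwise(
            y, codes, cands, max_terms=per_chrom_max, min_terms=1,
            audit=audit, stage=f"chrom{chrom}",
        )
        pooled.extend(kept)
    audit.append({"stage": "pooled", "markers": list(pooled)})
    final = _forward_stepwise(
        y, codes, pooled, max_terms=final_cap, min_terms=1,
        audit=audit, stage="final",
    )
    return MarkerSubset(final, "chromosome-wise", audit)


def select_genome_wide(
    gwas: pd.DataFrame,
    train_blues: pd.DataFrame,
    geno: GenotypeMatrix,
    top: int = 126,
    final_cap: int = 21,
) -> MarkerSubset:
    """Single-stage selection from the ``top`` most significant markers."""
    y, codes = _training_codes(train_blues, geno)
    if final_cap > len(y) - 2:
        raise ValueError("final_cap exceeds training size - 2; OLS not identifiable")
    ranked = _rank_markers(gwas)
    cands = list(ranked["marker"].iloc[:top])
    audit = [{"stage": "candidates", "markers": list(cands)}]
    final = _forward_stepwise(
        y, codes, cands, max_terms=final_cap, min_terms=1, audit=audit, stage="final"
    )
    return MarkerSubset(final, "genome-wide", audit)


def sample_random_markers(geno: GenotypeMatrix, n: int, seed: int = 0) -> MarkerSubset:
    """Uniform seeded sample of ``n`` markers without replacement."""
    markers = list(geno.markers)
    if n > len(markers):
        raise ValueError(f"requested {n} of {len(markers)} markers")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(markers), size=n, replace=False).tolist())
    picked = [markers[i] for i in chosen]
    return MarkerSubset(picked, "random", [{"stage": "random", "markers": picked, "seed": seed}])
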