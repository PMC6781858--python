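"""Desired-gains genomic selection index over two predicted traits.

Predicted winter-hardiness and frost-tolerance values of the candidate lines
are combined as

    Index_i = X_WINT,i * b_WINT + X_FROST,i * b_FROST

with weights b solving G b = a, where G is the 2x2 variance-covariance matrix
of the predicted values and a the desired-gains vector.  The default targets
a gain of one standard deviation of predicted performance per trait,
a = (sigma_WINT, sigma_FROST), which keeps both weights positive regardless
of how different the two trait scales are (a percent scale next to a 1-9
score); gains proportional to the raw variances would flip the sign of the
smaller-scale trait's weight as soon as the prediction covariance exceeds its
variance.  Both traits are scored lower-is-better, so no sign flips are
needed with the default orientation; mixed directions must be declared
explicitly and are resolved by negating the second trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IndexWeights", "compute_index_weights", "compute_index_values"]


@dataclass
class IndexWeights:
    b: np.ndarray
    G: np.ndarray
    a: np.ndarray
    traits: tuple[str, str]
    directions: tuple[str, str]


def _merge(gebv_wint: pd.DataFrame, gebv_frost: pd.DataFrame) -> pd.DataFrame:
    a = gebv_wint.set_index("line")["value"]
    b = gebv_frost.set_index("line")["value"]
    shared = a.index.intersection(b.index)
    only = set(a.index).symmetric_difference(b.index)
    if only:
        warnings.warn(f"{len(only)} lines present for only one trait excluded from the index")
    return pd.DataFrame({"wint": a.loc[shared], "frost": b.loc[shared]})


def compute_index_weights(
    gebv_wint: pd.DataFrame,
    gebv_frost: pd.DataFrame,
    desired_gains="default",
    directions: tuple[str, str] = ("lower", "lower"),
) -> IndexWeights:
    """Solve G b = a for the index weights.

    G is estimated from the predicted values of the shared candidate lines
    (the validation/selection set by default, matching how single-trait
    predictions are combined downstream).  ``desired_gains='default'`` uses
    a = sqrt(diag(G)), one standard deviation of predicted performance per
    trait.
    """
    if any(d not in ("lower", "higher") for d in directions):
        raise ValueError("directions must be 'lower' or 'higher' per trait")
    both = _merge(gebv_wint, gebv_frost)
    if len(both) < 3:
        raise ValueError("fewer than 3 shared candidate lines")
    vals = both.to_numpy(dtype=float)
    if directions[0] != directions[1]:
        vals = vals.copy()
        vals[:, 1] = -vals[:, 1]
    G = np.cov(vals, rowvar=False)
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite predicted values")
    det = float(np.linalg.det(G))
    scale = float(G[0, 0] * G[1, 1])
    if det <= 1e-12 * max(scale, 1e-300):
        raise ValueError(
            "prediction covariance matrix is singular (perfectly correlated "
            "predictions); restrict to one trait or decorrelate the models"
        )
    if isinstance(desired_gains, str) and desired_gains == "default":
        a = np.sqrt(np.diag(G))
    else:
        a = np.asarray(desired_gains, dtype=float)
        if a.shape != (2,):
            raise ValueError("desired gains must be a length-2 vector")
    b = np.linalg.solve(G, a)
    return IndexWeights(b=b, G=G, a=a, traits=("winter", "frost"), directions=tuple(directions))


def compute_index_values(
    weights: IndexWeights,
    gebv_wint: pd.DataFrame,
    gebv_frost: pd.DataFrame,
) -> pd.DataFrame:
    """Per-line index values from the fitted weights; model tag ``index``."""
    both = _merge(gebv_wint, gebv_frost)
    if both.empty:
        raise ValueError("no shared lines between the two GEBV tables")
    vals = both.to_numpy(dtype=float)
    if weights.directions[0] != weights.directions[1]:
        vals = vals.copy()
        vals[:, 1] = -vals[:, 1]
    idx = vals @ weights.b
    return pd.DataFrame(
        {"line": both.index, "trait": "index", "model": "index", "value": idx}
    )
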