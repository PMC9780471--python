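"""Asset-based wealth index: first principal component of household assets.

The classic survey construction (Filmer–Pritchett, as used by the DHS):
standardise each binary asset-ownership indicator by its sample mean and
standard deviation, take the first principal component as the wealth
score, and cut the scores into quintiles, quintile 1 being the poorest.
The component is sign-oriented so that owning more assets increases the
score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["compute_wealth_scores", "assign_quintiles", "wealth_quintiles"]


def compute_wealth_scores(assets: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First-principal-component wealth score per subject.

    Parameters
    ----------
    assets : (n_subjects, n_assets) array or DataFrame of {0, 1}
        Household asset-ownership indicators. Constant columns carry no
        information and are dropped with a warning; at least two
        non-constant columns are required.
    """
    mat = np.asarray(assets, dtype=float)
    if mat.ndim != 2:
        raise ValueError("asset matrix must be 2-dimensional")
    if not np.isin(mat, (0.0, 1.0)).all():
        raise ValueError("asset indicators must be binary 0/1")
    sd = mat.std(axis=0, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant asset column(s)",
            stacklevel=2,
        )
    if keep.sum() < 2:
        raise ValueError("need at least two non-constant asset columns")
    z = (mat[:, keep] - mat[:, keep].mean(axis=0)) / sd[keep]
    scores = PCA(n_components=1, svd_solver="full").fit_transform(z).ravel()
    # orient: more assets => higher score
    if np.corrcoef(scores, mat[:, keep].sum(axis=1))[0, 1] < 0:
        scores = -scores
    return scores


def assign_quintiles(scores: np.ndarray) -> np.ndarray:
    """Quintile labels 1 (poorest) .. 5 (wealthiest).

    Cuts at the 20/40/60/80th percentiles; scores tied with a boundary go
    to the lower (poorer) quintile, deterministically.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 5:
        raise ValueError("need at least 5 subjects for quintiles")
    cuts = np.quantile(scores, [0.2, 0.4, 0.6, 0.8])
    if np.allclose(scores, scores[0]):
        warnings.warn("degenerate score distribution: all scores equal", stacklevel=2)
        return np.ones(scores.size, dtype=int)
    # score <= cut  ->  lower quintile
    return (1 + np.searchsorted(cuts, scores, side="left")).astype(int)


def wealth_quintiles(assets: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Convenience: scores and quintiles in one frame."""
    scores = compute_wealth_scores(assets)
    return pd.DataFrame(
        {"wealth_score": scores, "wealth_quintile": assign_quintiles(scores)}
    )
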