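"""Association statistics between EEG indices and drug concentration.

Somers' D (asymmetric, y dependent on x), its rescaling to the
prediction probability P_K = 1 - (1 - |D|)/2 with SE(P_K) = SE(D)/2,
and Pearson/Spearman correlations. P_K measures how well an index
predicts ordinal anesthetic state: 0.5 is chance, 1 is perfect.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["somers_d", "pk_statistic", "pearson", "spearman"]


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def somers_d(x, y) -> tuple[float, float]:
    """Somers' D_yx with a jackknife standard error.

    D = (concordant - discordant) / (pairs not tied on x) over all
    unordered pairs — the asymmetric convention conditioning on the
    independent variable x. The SE is the leave-one-observation-out
    jackknife, computed in O(n^2) from per-observation pair counts.
    """
    x, y = _paired(x, y)
    n = len(x)
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    # per-row counts; each unordered pair appears in two rows
    c_i = (prod > 0).sum(axis=1).astype(float)
    d_i = (prod < 0).sum(axis=1).astype(float)
    t_i = (sx != 0).sum(axis=1).astype(float)
    C2, D2, T2 = c_i.sum(), d_i.sum(), t_i.sum()
    if T2 == 0:
        raise ValueError("Somers' D undefined: all x values tied")
    d = (C2 - D2) / T2
    # leave-one-out: removing obs i removes exactly its row's pairs
    t_loo = T2 - 2 * t_i
    with np.errstate(invalid="ignore", divide="ignore"):
        d_loo = np.where(t_loo > 0, (C2 - 2 * c_i - (D2 - 2 * d_i)) / t_loo, d)
    se = float(np.sqrt((n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)))
    return float(d), se


def pk_statistic(x, y) -> tuple[float, float]:
    """Prediction probability P_K = 1 - (1 - |D|)/2, SE = SE(D)/2."""
    d, se = somers_d(x, y)
    return 1.0 - (1.0 - abs(d)) / 2.0, se / 2.0


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p value."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 observations for a p value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation (midranks for ties) with two-sided p value."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 observations for a p value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")
    r = sps.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)
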