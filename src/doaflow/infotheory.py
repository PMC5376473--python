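"""Gaussian information measures between channel groups.

All quantities reduce to log-determinants of covariance matrices under
the Gaussian assumption: the Shannon entropy of a k-variate Gaussian
with covariance S is H = (1/2) ln((2 pi e)^k |S|), mutual information
is H(X) + H(Y) - H(X,Y), and transfer entropy from a source group B
into a target group A with lag tau samples is

    T(B -> A) = H(A_next, A_now) - H(A_now)
                - H(A_next, A_now, B_now) + H(A_now, B_now)

where A_next are the target samples tau steps ahead of A_now/B_now.
The embedding uses dimension 1 and delay 1 (one lagged vector per
group); tau is the prediction lag in samples. Everything is in nats.

Covariances are maximum-likelihood (divide by N) on per-window
mean-removed data; log-determinants use a Cholesky factorization with
a small diagonal ridge added only if the factorization fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import EEGRecording
from .windows import Window

__all__ = [
    "EmbeddedBlocks",
    "gaussian_entropy",
    "embed",
    "mutual_information",
    "transfer_entropy",
    "lagged_covariance",
    "te_from_lagged_cov",
]

_LN_2PIE = float(np.log(2.0 * np.pi * np.e))
#: negative-TE magnitudes below this are treated as numerical zero
CLIP_TOL = 1e-12


def _logdet(cov: np.ndarray) -> float:
    """Log-determinant via Cholesky; tiny ridge retry on failure."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eps = 1e-10 * float(np.mean(np.diag(cov)))
        if eps <= 0:
            raise ValueError("degenerate covariance (non-positive diagonal)")
        try:
            chol = np.linalg.cholesky(cov + eps * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            raise ValueError("covariance not positive definite after ridge")
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def gaussian_entropy(cov: np.ndarray, k: int | None = None) -> float:
    """Entropy (nats) of a Gaussian with the given covariance.

    ``k`` defaults to the matrix dimension and is validated against it.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if k is None:
        k = cov.shape[0]
    if cov.shape != (k, k):
        raise ValueError(f"expected {k}x{k} covariance, got {cov.shape}")
    return 0.5 * (k * _LN_2PIE + _logdet(cov))


def _check_groups(a: Sequence[str], b: Sequence[str]) -> None:
    if len(a) == 0 or len(b) == 0:
        raise ValueError("channel groups must be non-empty")
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("channel groups must not contain duplicates")
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"channel groups must be disjoint, share {sorted(overlap)}")


def _window_data(rec: EEGRecording, window: Window | None) -> np.ndarray:
    if window is None:
        return rec.data
    return rec.data[window.start_idx : window.end_idx]


@dataclass
class EmbeddedBlocks:
    """Time-aligned sample blocks for the TE entropy terms.

    Rows t = 0..N-tau-1: ``A_next[t]`` holds the target channels at
    sample t+tau, ``A_now[t]`` and ``B_now[t]`` the target and source
    channels at sample t. Values are per-window mean-removed.
    """

    A_next: np.ndarray
    A_now: np.ndarray
    B_now: np.ndarray
    tau: int


def embed(
    rec: EEGRecording,
    target: Sequence[str],
    source: Sequence[str],
    window: Window | None = None,
    tau: int = 2,
) -> EmbeddedBlocks:
    """Build the lag-aligned blocks for ``transfer_entropy``."""
    _check_groups(target, source)
    data = _window_data(rec, window)
    if not 0 < tau < data.shape[0]:
        raise ValueError(f"lag tau={tau} must be in (0, window length)")
    data = data - data.mean(axis=0)
    a = rec.channel_index(target)
    b = rec.channel_index(source)
    return EmbeddedBlocks(
        A_next=data[tau:, a], A_now=data[:-tau, a], B_now=data[:-tau, b], tau=tau
    )


def _sample_cov(columns: np.ndarray, unbiased: bool = False) -> np.ndarray:
    n = columns.shape[0]
    denom = n - 1 if unbiased else n
    centered = columns - columns.mean(axis=0)
    return centered.T @ centered / denom


def mutual_information(
    rec: EEGRecording,
    x: Sequence[str],
    y: Sequence[str],
    window: Window | None = None,
    unbiased: bool = False,
) -> float:
    """Gaussian mutual information H(X) + H(Y) - H(X,Y), in nats."""
    _check_groups(x, y)
    data = _window_data(rec, window)
    data = data - data.mean(axis=0)
    xi = rec.channel_index(x)
    yi = rec.channel_index(y)
    joint = _sample_cov(data[:, np.concatenate([xi, yi])], unbiased)
    nx = len(xi)
    mi = 0.5 * (
        _logdet(joint[:nx, :nx]) + _logdet(joint[nx:, nx:]) - _logdet(joint)
    )
    return max(mi, 0.0) if mi > -CLIP_TOL else _warn_negative(mi)


def lagged_covariance(
    data: np.ndarray, tau: int, unbiased: bool = False
) -> np.ndarray:
    """2n x 2n ML covariance of the stacked vector [x_{t+tau}, x_t].

    One pass over the window's samples; every entropy term of every
    bipartition's TE is the log-determinant of a sub-block of this
    matrix, which is what makes the full bipartition scan cheap.
    """
    data = np.asarray(data, dtype=float)
    if not 0 < tau < data.shape[0]:
        raise ValueError(f"lag tau={tau} must be in (0, n_samples)")
    data = data - data.mean(axis=0)
    stacked = np.hstack([data[tau:], data[:-tau]])
    return _sample_cov(stacked, unbiased)


def te_from_lagged_cov(
    cov2n: np.ndarray,
    n_channels: int,
    target_idx: Sequence[int],
    source_idx: Sequence[int],
) -> float:
    """TE (nats) of one bipartition from the pooled lagged covariance.

    ``target_idx``/``source_idx`` index channels 0..n-1; in ``cov2n``
    channel i appears at row i ("next", time t+tau) and row n+i
    ("now", time t). The (2 pi e) factors of the four entropy terms
    cancel, leaving half the alternating sum of log-determinants.
    """
    a = np.asarray(target_idx, dtype=int)
    b = np.asarray(source_idx, dtype=int)
    an = a + n_channels
    bn = b + n_channels
    idx_aa = np.concatenate([a, an])
    idx_full = np.concatenate([a, an, bn])
    idx_ab = np.concatenate([an, bn])
    te = 0.5 * (
        _logdet(cov2n[np.ix_(idx_aa, idx_aa)])
        - _logdet(cov2n[np.ix_(an, an)])
        - _logdet(cov2n[np.ix_(idx_full, idx_full)])
        + _logdet(cov2n[np.ix_(idx_ab, idx_ab)])
    )
    if te >= 0:
        return te
    if te > -CLIP_TOL:
        return 0.0
    return _warn_negative(te)


def _warn_negative(value: float) -> float:
    warnings.warn(
        f"information measure numerically negative ({value:.3e}); clipped to 0",
        RuntimeWarning,
        stacklevel=3,
    )
    return 0.0


def transfer_entropy(
    rec: EEGRecording,
    target: Sequence[str],
    source: Sequence[str],
    window: Window | None = None,
    tau: int = 2,
    unbiased: bool = False,
) -> float:
    """Transfer entropy (nats) from ``source`` into ``target``.

    Computed over the given window (whole recording if None) with a
    prediction lag of ``tau`` samples.
    """
    _check_groups(target, source)
    data = _window_data(rec, window)
    names = list(target) + list(source)
    cols = rec.channel_index(names)
    cov2n = lagged_covariance(data[:, cols], tau, unbiased)
    n = len(names)
    return te_from_lagged_cov(
        cov2n, n, list(range(len(target))), list(range(len(target), n))
    )
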