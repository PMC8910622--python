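"""Nonlinear features: Higuchi fractal dimension (N1), non-stationary index
(N2), and sample entropy (N3).

Higuchi FD estimates the fractal dimension from mean curve lengths at lags
k = 1…⌊N/20⌋: a smooth line gives 1, white noise approaches 2.  NSI is the
standard deviation of segment-wise means with ⌊0.15·N⌋ segments, a measure of
local-mean drift.  Sample entropy SampEn(m, r, N) is −ln of the ratio of
(m+1)- to m-length template-match counts at Chebyshev tolerance r = 0.2·SD.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

from .flags import flag


def higuchi_fd(epoch: np.ndarray, k_max: int | None = None) -> float:
    """Higuchi fractal dimension over lags k = 1…k_max (default ⌊N/20⌋).

    For each lag k and offset m the normalised curve length is
    H_m(k) = (N−1) · Σ_n |X(m+nk) − X(m+(n−1)k)| / (n_mk · k²) with
    n_mk = ⌊(N−m)/k⌋; FD is the least-squares slope of ln H̄(k) against
    −ln k, computed with the closed-form slope estimator.  A constant epoch
    (all curve lengths zero) returns a flagged 0.
    """
    x = np.asarray(epoch, dtype=float)
    n = x.size
    if k_max is None:
        k_max = n // 20
    if k_max < 2:
        raise ValueError(f"epoch too short for Higuchi FD (k_max={k_max})")
    offsets = np.arange(n)
    h_bar = np.empty(k_max)
    for k in range(1, k_max + 1):
        d = np.abs(x[k:] - x[:-k])  # d[i] belongs to offset m = i%k + 1
        sums = np.bincount(offsets[: n - k] % k, weights=d, minlength=k)
        m = np.arange(1, k + 1)
        n_mk = (n - m) // k
        h_bar[k - 1] = np.mean(sums * (n - 1) / (n_mk * k * k))
    if np.any(h_bar <= 0):
        flag("degenerate epoch: Higuchi FD set to 0")
        return 0.0
    ln_k = np.log(np.arange(1, k_max + 1))
    ln_h = np.log(h_bar)
    a = ln_k - ln_k.mean()  # = mu_k + ln k with mu_k = -mean(ln k)
    b = ln_h.mean() - ln_h  # = mu_H - ln Hbar(k)
    return float(np.sum(b * a) / np.sum(a * a))


def nsi(epoch: np.ndarray, fraction: float = 0.15) -> float:
    """Non-stationary index: population SD of segment means.

    The epoch is split into m = ⌊fraction·N⌋ contiguous segments, as equal as
    possible (the first N mod m segments get one extra sample).
    """
    x = np.asarray(epoch, dtype=float)
    n = x.size
    m = int(fraction * n)
    if m < 2:
        raise ValueError(f"epoch too short for NSI (m={m})")
    q, r = divmod(n, m)
    lengths = np.full(m, q)
    lengths[:r] += 1
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    means = np.add.reduceat(x, bounds[:-1]) / lengths
    return float(means.std())


def sample_entropy(epoch: np.ndarray, m: int = 2, r_coeff: float = 0.2) -> float:
    """SampEn(m, r, N) with Chebyshev distance and r = r_coeff · SD(epoch).

    B counts ordered template pairs i ≠ j (templates of length m) within
    tolerance r; A counts the same for length m+1.  Both use the first N−m
    templates so the ratio is a proper conditional match probability.
    Self-matches are excluded.  Returns NaN (flagged) when the epoch is
    constant or when no template pair matches at either length.
    """
    x = np.asarray(epoch, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"epoch too short for SampEn (N={n}, m={m})")
    s = x.std()
    if s == 0:
        flag("zero-variance epoch: SampEn undefined (NaN)")
        return float("nan")
    r = r_coeff * s
    n_templates = n - m
    xm = sliding_window_view(x, m)[:n_templates]
    xm1 = sliding_window_view(x, m + 1)  # exactly n - m rows
    tree_m = cKDTree(xm)
    tree_m1 = cKDTree(xm1)
    # count_neighbors counts ordered pairs including self-pairs
    b = tree_m.count_neighbors(tree_m, r, p=np.inf) - n_templates
    a = tree_m1.count_neighbors(tree_m1, r, p=np.inf) - n_templates
    if a == 0 or b == 0:
        flag("no template matches: SampEn undefined (NaN)")
        return float("nan")
    return float(-np.log(a / b))


def nonlinear_features(
    epoch: np.ndarray,
    sampen_m: int = 2,
    sampen_r: float = 0.2,
    nsi_fraction: float = 0.15,
    k_max: int | None = None,
) -> dict:
    """The three nonlinear features of one epoch, keyed N1, N2, N3."""
    return {
        "N1": higuchi_fd(epoch, k_max=k_max),
        "N2": nsi(epoch, fraction=nsi_fraction),
        "N3": sample_entropy(epoch, m=sampen_m, r_coeff=sampen_r),
    }
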