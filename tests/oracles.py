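"""Independent brute-force oracles used to cross-check the feature code.

Everything here is written as plain loops (or a direct two-sided DFT), with
no reliance on the implementation under test.
"""

import cmath
import math

import numpy as np


def mean_oracle(x):
    total = 0.0
    for v in x:
        total += v
    return total / len(x)


def moments_oracle(x):
    """(mean, variance, sd, skewness, excess kurtosis) by explicit loops,
    population-normalised central moments."""
    n = len(x)
    mu = mean_oracle(x)
    m2 = m3 = m4 = 0.0
    for v in x:
        d = v - mu
        m2 += d * d
        m3 += d**3
        m4 += d**4
    m2, m3, m4 = m2 / n, m3 / n, m4 / n
    sd = math.sqrt(m2)
    skew = m3 / sd**3 if sd > 0 else 0.0
    kurt = m4 / sd**4 - 3.0 if sd > 0 else 0.0
    return mu, m2, sd, skew, kurt


def zcr_oracle(x):
    mu = mean_oracle(x)
    c = [v - mu for v in x]
    n_z = 0
    for i in range(len(c) - 1):
        if c[i] * c[i + 1] < 0:
            n_z += 1
    return n_z / (len(c) - 1)


def diff_oracle(x):
    """(AFDN, ASDN) by explicit loops."""
    n = len(x)
    _, _, sd, _, _ = moments_oracle(x)
    if sd == 0:
        return 0.0, 0.0
    d1 = sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / (n - 1)
    d2 = sum(abs(x[i + 2] - x[i]) for i in range(n - 2)) / (n - 2)
    return d1 / sd, d2 / sd


def hjorth_oracle(x):
    """(activity, mobility, complexity) from loop-computed SDs of the signal,
    its first difference, and the difference of the difference."""
    d1 = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    d2 = [d1[i + 1] - d1[i] for i in range(len(d1) - 1)]
    _, var, s, _, _ = moments_oracle(x)
    _, _, sd, _, _ = moments_oracle(d1)
    _, _, sdd, _, _ = moments_oracle(d2)
    return var, sd / s, (sdd / sd) / (sd / s)


def nsi_oracle(x, fraction=0.15):
    """Population SD of segment means, hand-built segmentation."""
    n = len(x)
    m = int(fraction * n)
    q, r = n // m, n % m
    means, start = [], 0
    for k in range(m):
        length = q + 1 if k < r else q
        seg = x[start : start + length]
        means.append(sum(seg) / length)
        start += length
    mu = sum(means) / m
    return math.sqrt(sum((v - mu) ** 2 for v in means) / m)


def sampen_oracle(x, m=2, r_coeff=0.2):
    """SampEn by O(N^2) double loop over the first N-m templates."""
    n = len(x)
    _, _, sd, _, _ = moments_oracle(x)
    r = r_coeff * sd
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def dft_oracle(x, nfft):
    """Direct two-sided DFT (O(N·nfft) triple-product sum)."""
    n = len(x)
    out = []
    for k in range(nfft):
        acc = 0j
        for t in range(n):
            acc += x[t] * cmath.exp(-2j * cmath.pi * k * t / nfft)
        out.append(acc)
    return out


def band_power_oracle(x, lo, hi, nfft, fs):
    """Band power from the two-sided DFT: sum of |F[k]/nfft|^2 over the
    one-sided bins k with lo <= k*fs/nfft < hi."""
    F = dft_oracle(list(x), nfft)
    total = 0.0
    for k in range(nfft // 2 + 1):
        f = k * fs / nfft
        if lo <= f < hi:
            total += abs(F[k] / nfft) ** 2
    return total


def confusion_oracle(y_true, y_pred, stages):
    idx = {s: i for i, s in enumerate(stages)}
    m = np.zeros((len(stages), len(stages)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return m
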