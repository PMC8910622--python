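"""Time-domain features T1–T15 of a single 30-s epoch.

All moments are central and population-normalised (divide by N); kurtosis is
excess kurtosis (Gaussian = 0).  The zero-crossing rate is computed on the
mean-removed epoch, counting strict sign changes of adjacent samples.  The
first-order difference is X(n+1)−X(n); the second-order difference is the
two-sample gap X(n+2)−X(n), as conventional for the normalised difference
descriptors.  Hjorth activity/mobility/complexity follow the standard
variance-ratio definitions.
"""

from __future__ import annotations

import numpy as np

from .flags import flag


def basic_stats(epoch: np.ndarray) -> dict:
    """T1 peak-to-peak amplitude, T2 mean, T3 variance, T4 SD, T5 median,
    T6 skewness, T7 excess kurtosis, T8 max, T9 min.

    Zero-variance epochs report skewness and kurtosis as 0 (flagged).
    """
    x = np.asarray(epoch, dtype=float)
    if x.size < 2:
        raise ValueError("epoch must have at least 2 samples")
    mean = x.mean()
    c = x - mean
    var = np.mean(c**2)
    sd = np.sqrt(var)
    if sd > 0:
        skew = np.mean(c**3) / sd**3
        kurt = np.mean(c**4) / sd**4 - 3.0
    else:
        flag("zero-variance epoch: skewness/kurtosis set to 0")
        skew = kurt = 0.0
    return {
        "T1": float(x.max() - x.min()),
        "T2": float(mean),
        "T3": float(var),
        "T4": float(sd),
        "T5": float(np.median(x)),
        "T6": float(skew),
        "T7": float(kurt),
        "T8": float(x.max()),
        "T9": float(x.min()),
    }


def zero_crossing_rate(epoch: np.ndarray) -> float:
    """T10: fraction of adjacent sample pairs that strictly change sign,
    after mean removal: N_Z / (N − 1).  Exact zeros do not count."""
    x = np.asarray(epoch, dtype=float)
    if x.size < 2:
        raise ValueError("epoch must have at least 2 samples")
    c = x - x.mean()
    n_z = int(np.sum(c[:-1] * c[1:] < 0))
    return n_z / (x.size - 1)


def diff_features(epoch: np.ndarray) -> dict:
    """T11 (AFDN) and T12 (ASDN): mean absolute first/second difference,
    normalised by the epoch SD.

    T11 = mean|X(n+1)−X(n)| / s over N−1 terms;
    T12 = mean|X(n+2)−X(n)| / s over N−2 terms.
    Zero-SD epochs report flagged zeros.
    """
    x = np.asarray(epoch, dtype=float)
    if x.size < 3:
        raise ValueError("epoch must have at least 3 samples")
    s = x.std()
    if s == 0:
        flag("zero-variance epoch: AFDN/ASDN set to 0")
        return {"T11": 0.0, "T12": 0.0}
    d1 = np.mean(np.abs(x[1:] - x[:-1]))
    d2 = np.mean(np.abs(x[2:] - x[:-2]))
    return {"T11": float(d1 / s), "T12": float(d2 / s)}


def hjorth(epoch: np.ndarray) -> dict:
    """T13 Activity, T14 Mobility, T15 Complexity.

    Activity = s²; Mobility = sd/s with sd the SD of the first-difference
    sequence; Complexity = Mobility of the first difference divided by
    Mobility of the signal, i.e. (sdd/sd)/(sd/s).
    """
    x = np.asarray(epoch, dtype=float)
    if x.size < 3:
        raise ValueError("epoch must have at least 3 samples")
    s = x.std()
    if s == 0:
        flag("zero-variance epoch: Hjorth parameters set to 0")
        return {"T13": 0.0, "T14": 0.0, "T15": 0.0}
    d = np.diff(x)
    sd = d.std()
    activity = s**2
    mobility = sd / s
    if sd == 0:
        flag("constant-slope epoch: Hjorth complexity set to 0")
        complexity = 0.0
    else:
        sdd = np.diff(d).std()
        complexity = (sdd / sd) / (sd / s)
    return {"T13": float(activity), "T14": float(mobility), "T15": float(complexity)}


def time_features(epoch: np.ndarray) -> dict:
    """All fifteen time-domain features of one epoch, keyed T1…T15."""
    out = basic_stats(epoch)
    out["T10"] = zero_crossing_rate(epoch)
    out.update(diff_features(epoch))
    out.update(hjorth(epoch))
    return {f"T{i}": out[f"T{i}"] for i in range(1, 16)}
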