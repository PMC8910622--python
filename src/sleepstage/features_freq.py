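"""Frequency-domain features F1–F39: band powers, power ratios, and spectral
moments (mean power frequency and frequency variance).

The spectrum is the plain one-sided periodogram of the raw epoch
(rectangular window, no zero padding by default): power[k] = |DFT(x)[k]/nfft|²
for bins 0…nfft/2.  No one-sided doubling is applied; every exported feature
is either a ratio or a power-weighted moment, so the convention cancels.

The seven-band scheme keeps the low-delta/high-delta overlap as published:
low δ [0.5,2), high δ [1.2,4), θ [4,8), α [8,13), low β [13,20),
high β [20,30), γ [30,45) Hz, all half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flags import flag


def _default_bands() -> dict:
    return {
        "low_delta": (0.5, 2.0),
        "high_delta": (1.2, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "low_beta": (13.0, 20.0),
        "high_beta": (20.0, 30.0),
        "gamma": (30.0, 45.0),
    }


@dataclass(frozen=True)
class BandScheme:
    """Seven half-open frequency bands in Hz plus the total-power range."""

    bands: dict = field(default_factory=_default_bands)
    total: tuple = (0.5, 45.0)

    def validate(self, fs: float) -> None:
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi < fs / 2):
                raise ValueError(f"band {name} [{lo},{hi}) outside (0, {fs / 2})")


@dataclass
class PowerSpectrum:
    """One-sided periodogram: frequencies (Hz) and per-bin power."""

    freqs: np.ndarray
    power: np.ndarray
    nfft: int

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.freqs >= lo) & (self.freqs < hi)


@dataclass
class BandPowers:
    """E1 total (0.5–45 Hz); E2–E8 the seven bands; E9 = E2+…+E8."""

    E1: float
    E2: float
    E3: float
    E4: float
    E5: float
    E6: float
    E7: float
    E8: float

    @property
    def E9(self) -> float:
        return self.E2 + self.E3 + self.E4 + self.E5 + self.E6 + self.E7 + self.E8

    def __getitem__(self, key: str) -> float:
        return getattr(self, key)


def power_spectrum(epoch: np.ndarray, nfft: int | None = None, fs: float = 100.0) -> PowerSpectrum:
    """One-sided periodogram |DFT(x)/nfft|² of an epoch."""
    x = np.asarray(epoch, dtype=float)
    if nfft is None:
        nfft = x.size
    if nfft < x.size:
        raise ValueError(f"nfft ({nfft}) must be >= epoch length ({x.size})")
    spec = np.fft.rfft(x, n=nfft)
    power = np.abs(spec / nfft) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PowerSpectrum(freqs=freqs, power=power, nfft=nfft)


def band_powers(ps: PowerSpectrum, scheme: BandScheme | None = None) -> BandPowers:
    """Sum periodogram bins into the seven bands and the 0.5–45 Hz total."""
    scheme = scheme or BandScheme()
    if ps.freqs[-1] < scheme.total[1]:
        raise ValueError("spectrum does not cover the 0.5-45 Hz analysis range")
    e = {}
    for i, name in enumerate(scheme.bands, start=2):
        lo, hi = scheme.bands[name]
        e[f"E{i}"] = float(ps.power[ps.band_mask(lo, hi)].sum())
    e1 = float(ps.power[ps.band_mask(*scheme.total)].sum())
    return BandPowers(E1=e1, **e)


# The 25 band-power expressions, as tabulated for this feature set.
_RATIOS = {
    "F1": lambda E: (E.E1, 1.0),
    "F2": lambda E: (E.E2 + E.E3, 1.0),
    "F3": lambda E: (E.E4, 1.0),
    "F4": lambda E: (E.E5, 1.0),
    "F5": lambda E: (E.E6 + E.E7, 1.0),
    "F6": lambda E: (E.E8, 1.0),
    "F7": lambda E: (E.E2, E.E1),
    "F8": lambda E: (E.E3, E.E1),
    "F9": lambda E: (E.E4, E.E1),
    "F10": lambda E: (E.E5, E.E1),
    "F11": lambda E: (E.E6 + E.E7, E.E1),
    "F12": lambda E: (E.E8, E.E1),
    "F13": lambda E: (E.E4 + E.E5, E.E1),
    "F14": lambda E: (E.E5, E.E6 + E.E7),
    "F15": lambda E: (E.E4 + E.E5, E.E5 + E.E6 + E.E7),
    "F16": lambda E: (E.E4, E.E6 + E.E7),
    "F17": lambda E: (E.E3, E.E4 + E.E5),
    "F18": lambda E: (E.E4, E.E3 + E.E5),
    "F19": lambda E: (E.E5, E.E3 + E.E4),
    "F20": lambda E: (E.E2, E.E3 + E.E9),
    "F21": lambda E: (E.E5, E.E9),
    "F22": lambda E: (E.E6 + E.E7, E.E9),
    "F23": lambda E: (E.E5, E.E4),
    "F24": lambda E: (E.E2 + E.E3, E.E4),
    "F25": lambda E: (E.E2 + E.E6, E.E9),
}


def ratio_features(E: BandPowers) -> dict:
    """F1–F25: absolute band powers and the tabulated band-power ratios.

    A zero denominator yields a flagged 0 for that feature.
    """
    out = {}
    for name, expr in _RATIOS.items():
        num, den = expr(E)
        if den == 0:
            flag(f"{name}: zero denominator, feature set to 0")
            out[name] = 0.0
        else:
            out[name] = float(num / den)
    return out


# Frequency ranges for the spectral-moment features: full range, then the
# physiological bands with beta taken as the combined 13-30 Hz interval.
_MOMENT_BANDS = [
    ("full", None),
    ("low_delta", "low_delta"),
    ("high_delta", "high_delta"),
    ("theta", "theta"),
    ("alpha", "alpha"),
    ("beta", (13.0, 30.0)),
    ("gamma", "gamma"),
]


def mpf_fv_features(ps: PowerSpectrum, scheme: BandScheme | None = None) -> dict:
    """F26–F32 mean power frequency (MPF), F33–F39 frequency variance (FV).

    MPF over a bin set S is the power-weighted mean frequency
    Σ f·P(f) / Σ P(f); FV is the power-weighted variance about it.
    F26/F33 use the full 0.5–45 Hz range; the rest the individual bands
    (beta combined 13–30 Hz).  An empty or zero-power band yields flagged 0s.
    """
    scheme = scheme or BandScheme()
    mpf, fv = [], []
    for name, band in _MOMENT_BANDS:
        if band is None:
            lo, hi = scheme.total
        elif isinstance(band, tuple):
            lo, hi = band
        else:
            lo, hi = scheme.bands[band]
        mask = ps.band_mask(lo, hi)
        p = ps.power[mask]
        f = ps.freqs[mask]
        tot = p.sum()
        if tot == 0:
            flag(f"MPF/FV {name}: zero band power, features set to 0")
            mpf.append(0.0)
            fv.append(0.0)
        else:
            mu = float(np.sum(f * p) / tot)
            mpf.append(mu)
            fv.append(float(np.sum((f - mu) ** 2 * p) / tot))
    out = {f"F{26 + i}": v for i, v in enumerate(mpf)}
    out.update({f"F{33 + i}": v for i, v in enumerate(fv)})
    return out


def freq_features(
    epoch: np.ndarray,
    fs: float = 100.0,
    nfft: int | None = None,
    scheme: BandScheme | None = None,
) -> dict:
    """All 39 frequency-domain features of one epoch, keyed F1…F39."""
    scheme = scheme or BandScheme()
    ps = power_spectrum(epoch, nfft=nfft, fs=fs)
    E = band_powers(ps, scheme)
    out = ratio_features(E)
    out.update(mpf_fv_features(ps, scheme))
    return {f"F{i}": out[f"F{i}"] for i in range(1, 40)}
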