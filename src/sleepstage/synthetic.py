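"""Seeded generator of stage-conditioned synthetic EEG epochs.

Each stage is emulated as a sum of band-limited Gaussian noise components
with stage-specific gains, reproducing the gross spectral physiology used by
human scorers: alpha-dominant wake, theta-dominant N1, spindle- and
K-complex-bearing N2, high-amplitude delta N3, and low-voltage mixed-
frequency REM with a stronger beta share than N1.  Band-limited noise is
realised by FIR band-pass filtering white noise with the preprocessing
module's filter designs.

This is not a physiologically faithful PSG simulator — it has no EOG/EMG,
artifacts, stage transitions or inter-subject variability — but it gives the
feature extractor and classifiers a spectrally realistic, fully seeded test
bed with a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as _signal

from .preprocess import FilterSpec, design_bandpass
from .reference import CLASS_COUNTS
from .signal_io import STAGES, EpochedRecording

#: Generation bands (Hz): the canonical EEG rhythms.
GEN_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


def _default_gains() -> dict:
    # Relative RMS contribution of each rhythm, per stage.
    return {
        "W": {"delta": 0.30, "theta": 0.25, "alpha": 1.00, "beta": 0.45, "gamma": 0.10},
        "N1": {"delta": 0.45, "theta": 1.00, "alpha": 0.25, "beta": 0.20, "gamma": 0.05},
        "N2": {"delta": 0.80, "theta": 0.70, "alpha": 0.20, "beta": 0.15, "gamma": 0.05},
        "N3": {"delta": 2.20, "theta": 0.35, "alpha": 0.12, "beta": 0.08, "gamma": 0.03},
        "REM": {"delta": 0.35, "theta": 0.80, "alpha": 0.15, "beta": 0.55, "gamma": 0.08},
    }


def _default_amplitude() -> dict:
    # Overall amplitude scale per stage, µV of RMS per unit gain.
    return {"W": 20.0, "N1": 25.0, "N2": 35.0, "N3": 60.0, "REM": 16.0}


@dataclass
class SyntheticRecipe:
    """Per-stage band gains, amplitude scales and N2 event rates."""

    band_gains: dict = field(default_factory=_default_gains)
    amplitude: dict = field(default_factory=_default_amplitude)
    spindle_rate: float = 4.0  # expected spindle bursts per N2 epoch
    spindle_freq: float = 13.0  # Hz, within the 12-14 Hz sigma range
    kcomplex_rate: float = 1.0  # expected K-complexes per N2 epoch
    noise_floor: float = 0.10  # broadband white component, relative RMS
    hard: bool = False  # narrow the REM/N1 spectral gap (qualitative demos)

    def validate(self) -> None:
        for stage in STAGES:
            gains = self.band_gains[stage]
            if any(g < 0 for g in gains.values()):
                raise ValueError(f"negative band gain for stage {stage}")
            if not any(g > 0 for g in gains.values()):
                raise ValueError(f"stage {stage} has no positive band gain")

    def effective_gains(self, stage: str) -> dict:
        gains = dict(self.band_gains[stage])
        if self.hard and stage in ("N1", "REM"):
            # pull the two low-voltage mixed-frequency stages together
            other = "REM" if stage == "N1" else "N1"
            for band in gains:
                gains[band] = 0.5 * (gains[band] + self.band_gains[other][band])
        return gains


@lru_cache(maxsize=32)
def _band_coeffs(lo: float, hi: float, fs: float, n_taps: int = 401) -> np.ndarray:
    return design_bandpass(fs, FilterSpec(low_hz=lo, high_hz=hi, n_taps=n_taps))


def _band_noise(rng: np.random.Generator, band: tuple, fs: float, n: int) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise of length n."""
    coeffs = _band_coeffs(band[0], band[1], fs)
    x = _signal.filtfilt(coeffs, [1.0], rng.standard_normal(n))
    rms = x.std()
    return x / rms if rms > 0 else x


def generate_epoch(
    stage: str,
    recipe: SyntheticRecipe | None = None,
    seed: int = 0,
    fs: float = 100.0,
    n_samples: int = 3000,
) -> np.ndarray:
    """One synthetic 30-s epoch (µV) for the given stage, seeded."""
    recipe = recipe or SyntheticRecipe()
    recipe.validate()
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    gains = recipe.effective_gains(stage)
    x = recipe.noise_floor * rng.standard_normal(n_samples)
    for band, gain in gains.items():
        if gain > 0:
            x = x + gain * _band_noise(rng, GEN_BANDS[band], fs, n_samples)
    if stage == "N2":
        x = x + _n2_events(rng, recipe, fs, n_samples)
    return recipe.amplitude[stage] * x


def _n2_events(
    rng: np.random.Generator, recipe: SyntheticRecipe, fs: float, n: int
) -> np.ndarray:
    """Sleep spindles (sigma-band bursts) and K-complexes for N2 epochs."""
    x = np.zeros(n)
    dur = int(1.0 * fs)  # 1-s spindle
    t = np.arange(dur) / fs
    envelope = np.hanning(dur)
    for _ in range(rng.poisson(recipe.spindle_rate)):
        start = rng.integers(0, n - dur)
        phase = rng.uniform(0, 2 * np.pi)
        x[start : start + dur] += 1.2 * envelope * np.sin(
            2 * np.pi * recipe.spindle_freq * t + phase
        )
    kdur = int(0.8 * fs)  # biphasic ~0.8-s transient
    tk = np.linspace(-2.5, 2.5, kdur)
    kshape = -tk * np.exp(-(tk**2))  # sharp negative then slower positive wave
    kshape /= np.abs(kshape).max()
    for _ in range(rng.poisson(recipe.kcomplex_rate)):
        start = rng.integers(0, n - kdur)
        x[start : start + kdur] += 2.5 * kshape
    return x


def generate_dataset(
    counts: dict | None = None,
    recipe: SyntheticRecipe | None = None,
    seed: int = 0,
    fs: float = 100.0,
    n_samples: int = 3000,
) -> EpochedRecording:
    """A labelled synthetic dataset; default counts are the benchmark's
    balanced per-stage totals (9696 epochs).

    Every epoch gets an independent seed derived from the master seed, so
    datasets are reproducible and epochs are mutually independent.
    """
    counts = counts if counts is not None else dict(CLASS_COUNTS)
    recipe = recipe or SyntheticRecipe()
    master = np.random.default_rng(seed)
    total = int(sum(counts.values()))
    epoch_seeds = master.integers(0, 2**31, size=total)
    rows, labels = [], []
    i = 0
    for stage in STAGES:
        for _ in range(int(counts.get(stage, 0))):
            rows.append(
                generate_epoch(stage, recipe, seed=int(epoch_seeds[i]), fs=fs, n_samples=n_samples)
            )
            labels.append(stage)
            i += 1
    epochs = np.array(rows) if rows else np.empty((0, n_samples))
    return EpochedRecording(epochs=epochs, fs=fs, labels=np.array(labels, dtype=object))
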