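"""Assembly of the full 57-feature vector per epoch.

The feature table is a pandas DataFrame with the 57 named feature columns
(T1…T15, F1…F39, N1…N3) plus a ``stage`` label column — the package's
interchange format, written/read as CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features_freq import BandScheme, freq_features
from .features_nonlinear import nonlinear_features
from .features_time import time_features
from .signal_io import EpochedRecording

#: Canonical column order of the 57 features.
FEATURE_NAMES = (
    [f"T{i}" for i in range(1, 16)]
    + [f"F{i}" for i in range(1, 40)]
    + ["N1", "N2", "N3"]
)

#: Name of the label column in feature tables.
LABEL_COLUMN = "stage"


def extract_epoch(
    epoch: np.ndarray,
    fs: float = 100.0,
    nfft: int | None = None,
    scheme: BandScheme | None = None,
    sampen_m: int = 2,
    sampen_r: float = 0.2,
    nsi_fraction: float = 0.15,
) -> dict:
    """All 57 features of a single epoch as an ordered dict."""
    out = time_features(epoch)
    out.update(freq_features(epoch, fs=fs, nfft=nfft, scheme=scheme))
    out.update(
        nonlinear_features(
            epoch, sampen_m=sampen_m, sampen_r=sampen_r, nsi_fraction=nsi_fraction
        )
    )
    return {name: out[name] for name in FEATURE_NAMES}


def extract_features(er: EpochedRecording, **kwargs) -> pd.DataFrame:
    """Extract the 57 features of every epoch.

    Returns a DataFrame with one row per epoch, the 57 feature columns in
    canonical order, and a trailing ``stage`` column.  Keyword arguments are
    forwarded to :func:`extract_epoch`.
    """
    rows = [extract_epoch(e, **kwargs) for e in er.epochs]
    table = pd.DataFrame(rows, columns=FEATURE_NAMES)
    table[LABEL_COLUMN] = er.labels
    return table


def split_table(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (features, labels)."""
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"feature table has no {LABEL_COLUMN!r} column")
    return table.drop(columns=[LABEL_COLUMN]), table[LABEL_COLUMN].to_numpy()
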