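"""Published reference values for the Fpz-Cz single-channel staging benchmark.

These are the printed numbers from the study this package's pipeline
reproduces on the Expanded Sleep-EDF corpus: the balanced per-stage epoch
counts, the tree-model weight coefficients of the 57 features, and the
per-stage results table of the all-feature SVM configuration.  They serve as
fixed inputs for metric-arithmetic checks and for exercising the feature
screening on a realistic importance profile — the pipeline itself recomputes
all such quantities from data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Balanced per-stage epoch counts of the benchmark dataset (total 9696).
CLASS_COUNTS = {"W": 2029, "N1": 2029, "N2": 2029, "N3": 1671, "REM": 1938}

#: Published tree-model weight coefficients of the 57 features.
FEATURE_WEIGHTS = {
    "T1": 0.0030, "T2": 0.0006, "T3": 0.0051, "T4": 0.0122, "T5": 0.0111,
    "T6": 0.0513, "T7": 0.0201, "T8": 0.0015, "T9": 0.0066, "T10": 0.0086,
    "T11": 0.0013, "T12": 0.0049, "T13": 0.0101, "T14": 0.0048, "T15": 0.0050,
    "F1": 0.0148, "F2": 0.1049, "F3": 0.0056, "F4": 0.0125, "F5": 0.0394,
    "F6": 0.1459, "F7": 0.0038, "F8": 0.0281, "F9": 0.0457, "F10": 0.0038,
    "F11": 0.0106, "F12": 0.2043, "F13": 0.0024, "F14": 0.0142, "F15": 0.0124,
    "F16": 0.0110, "F17": 0.0105, "F18": 0.0104, "F19": 0.0540, "F20": 0.0008,
    "F21": 0.0031, "F22": 0.0301, "F23": 0.0077, "F24": 0.0012, "F25": 0.0053,
    "F26": 0.0011, "F27": 0.0028, "F28": 0.0007, "F29": 0.0011, "F30": 0.0013,
    "F31": 0.0007, "F32": 0.0006, "F33": 0.0007, "F34": 0.0037, "F35": 0.0014,
    "F36": 0.0006, "F37": 0.0010, "F38": 0.0005, "F39": 0.0006,
    "N1": 0.0045, "N2": 0.0470, "N3": 0.0032,
}

#: Published per-stage results of the all-feature SVM configuration:
#: (training samples, test samples, correctly staged test samples,
#:  precision, recall, f1) per stage.
SVM_STAGE_TABLE = pd.DataFrame(
    {
        "train": [1326, 1601, 1639, 1547, 1643],
        "test": [345, 428, 390, 391, 386],
        "correct": [321, 336, 255, 316, 360],
        "precision": [0.8992, 0.8276, 0.7143, 0.7215, 0.9424],
        "recall": [0.9304, 0.7850, 0.6538, 0.8082, 0.9326],
        "f1": [0.9145, 0.8058, 0.6827, 0.7624, 0.9375],
    },
    index=pd.Index(["N3", "N2", "N1", "REM", "W"], name="stage"),
)


def benchmark_labels() -> np.ndarray:
    """Stage-label vector with the benchmark per-stage counts (length 9696)."""
    return np.concatenate(
        [np.full(n, stage, dtype=object) for stage, n in CLASS_COUNTS.items()]
    )
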