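"""EDF signal / hypnogram I/O, stage-label mapping, epoching and class balancing.

Signals are kept in microvolts at their native sampling rate (100 Hz for the
Fpz-Cz recordings this package targets).  Hypnograms may come either from
EDF+ annotation files or from a plain-text TSV fallback with columns
``onset_s<TAB>duration_s<TAB>label``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

#: The five AASM sleep stages, in canonical display order.
STAGES = ("W", "N1", "N2", "N3", "REM")

#: Sentinel returned by :func:`map_labels` for epochs that must be discarded.
DROP = "drop"


class ChannelNotFoundError(KeyError):
    """Requested channel is absent from the EDF header."""


class HypnogramError(ValueError):
    """Malformed or inconsistent hypnogram annotations."""


@dataclass
class RawRecording:
    """A single-channel recording in microvolts."""

    samples: np.ndarray
    fs: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class EpochedRecording:
    """Fixed-length epochs with one stage label per epoch.

    ``epochs`` is an (n_epochs, N) array with N = round(30 * fs) samples per
    row; ``labels`` holds one of :data:`STAGES` per row.
    """

    epochs: np.ndarray
    fs: float
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epochs.size == 0:
            self.epochs = self.epochs.reshape(0, int(round(30 * self.fs)))
        if self.epochs.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must equal the number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def class_counts(self) -> dict:
        return {s: int(np.sum(self.labels == s)) for s in STAGES}


# ---------------------------------------------------------------------------
# EDF reading (via mne) and a minimal EDF writer for synthetic output
# ---------------------------------------------------------------------------

def read_edf_signal(path: str | os.PathLike, channel: str) -> RawRecording:
    """Read one channel of an EDF/EDF+ file.

    Returns the samples in microvolts together with the header sampling rate.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ChannelNotFoundError
        If ``channel`` is not among the EDF signal labels.
    ValueError
        If the file is not a parseable EDF/EDF+ file.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    except FileNotFoundError:
        raise
    except Exception as exc:  # mne raises a mix of ValueError/RuntimeError
        raise ValueError(f"could not parse EDF file {path!r}: {exc}") from exc
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in EDF ({', '.join(raw.ch_names)})"
        )
    raw = raw.pick([channel])
    raw.load_data(verbose="error")
    data = raw.get_data()[0] * 1e6  # mne returns volts
    return RawRecording(samples=data, fs=float(raw.info["sfreq"]), channel=channel)


def write_edf_signal(path: str | os.PathLike, rec: RawRecording) -> None:
    """Write a single-channel recording as a 16-bit EDF file.

    Uses 1-second data records; a trailing partial second is zero-padded.
    Physical range is taken from the data (µV).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    x = rec.samples
    n_rec = int(np.ceil(x.size / spr))
    padded = np.zeros(n_rec * spr)
    padded[: x.size] = x

    pmin, pmax = float(padded.min()), float(padded.max())
    if pmax - pmin < 1e-9:
        pmin, pmax = pmin - 1.0, pmax + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin) / scale + dmin).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate X X X X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 + 256), 8),  # header bytes: fixed + one signal
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),  # record duration, seconds
            f("1", 4),  # number of signals
        ]
    )
    sig = b"".join(
        [
            f(rec.channel or "EEG", 16),
            f("", 80),
            f("uV", 8),
            f(f"{pmin:.8g}", 8),
            f(f"{pmax:.8g}", 8),
            f(str(dmin), 8),
            f(str(dmax), 8),
            f("", 80),
            f(str(spr), 8),
            f("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | os.PathLike) -> list[tuple[float, float, str]]:
    """Read stage annotations as ``(onset_s, duration_s, raw_label)`` tuples.

    EDF+ annotation files are read through mne; any other extension is parsed
    as the TSV fallback (``onset_s<TAB>duration_s<TAB>label``, ``#`` comments
    allowed).  Intervals are returned sorted by onset and must not overlap.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(str(path))[1].lower()
    out: list[tuple[float, float, str]] = []
    if ext == ".edf":
        import mne

        ann = mne.read_annotations(str(path))
        for onset, duration, desc in zip(ann.onset, ann.duration, ann.description):
            out.append((float(onset), float(duration), str(desc)))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise HypnogramError(
                        f"{path}:{lineno}: expected 3 tab-separated fields"
                    )
                try:
                    onset, duration = float(parts[0]), float(parts[1])
                except ValueError as exc:
                    raise HypnogramError(f"{path}:{lineno}: {exc}") from exc
                out.append((onset, duration, parts[2]))
    out.sort(key=lambda t: t[0])
    for (o1, d1, _), (o2, _, _) in zip(out, out[1:]):
        if o1 + d1 > o2 + 1e-9:
            raise HypnogramError(f"overlapping intervals at onset {o2} s")
    return out


_LABEL_MAP = {
    "w": "W",
    "1": "N1",
    "2": "N2",
    "3": "N3",
    "4": "N3",  # R&K stages 3 and 4 merge into AASM N3
    "r": "REM",
    "rem": "REM",
    "n1": "N1",
    "n2": "N2",
    "n3": "N3",
    "m": DROP,
    "?": DROP,
}


def map_labels(raw_label: str) -> str:
    """Map a Sleep-EDF style annotation to an AASM stage or :data:`DROP`.

    Handles both the verbose vocabulary ("Sleep stage W", "Sleep stage 4",
    "Movement time", "Sleep stage ?") and bare tokens ("W", "4", "R", "M").
    """
    token = raw_label.strip().lower()
    if token.startswith("sleep stage"):
        token = token[len("sleep stage"):].strip()
    elif token in ("movement time", "movement"):
        token = "m"
    if token in _LABEL_MAP:
        return _LABEL_MAP[token]
    raise ValueError(f"unknown hypnogram label {raw_label!r}")


def make_epochs(
    rec: RawRecording,
    intervals: list[tuple[float, float, str]],
    epoch_s: float = 30.0,
) -> EpochedRecording:
    """Cut consecutive non-overlapping 30-s epochs aligned to the recording start.

    Each epoch takes the stage of the single labelled interval that fully
    contains it.  Epochs that straddle an interval boundary, fall in a
    drop-labelled interval (movement / unscored), or extend past the last
    interval are discarded, as is a trailing partial window.
    """
    n_per = int(round(epoch_s * rec.fs))
    if abs(n_per - epoch_s * rec.fs) > 1e-6:
        raise ValueError("epoch length must be an integer number of samples")
    mapped = [(o, d, map_labels(lab)) for o, d, lab in intervals]
    n_epochs_max = rec.samples.size // n_per
    rows, labels = [], []
    for i in range(n_epochs_max):
        t0, t1 = i * epoch_s, (i + 1) * epoch_s
        stage = None
        for onset, duration, lab in mapped:
            if onset <= t0 + 1e-9 and t1 <= onset + duration + 1e-9:
                stage = lab
                break
        if stage is None or stage == DROP:
            continue
        rows.append(rec.samples[i * n_per : (i + 1) * n_per])
        labels.append(stage)
    epochs = np.array(rows) if rows else np.empty((0, n_per))
    return EpochedRecording(epochs=epochs, fs=rec.fs, labels=np.array(labels, dtype=object))


def balance_classes(
    er: EpochedRecording, counts: dict, seed: int = 0
) -> EpochedRecording:
    """Undersample each stage to the requested count, without replacement.

    The selection within each stage and the final epoch order are both
    deterministic functions of ``seed``.
    """
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for stage, want in counts.items():
        idx = np.flatnonzero(er.labels == stage)
        if want > idx.size:
            raise ValueError(
                f"stage {stage}: requested {want} epochs but only {idx.size} available"
            )
        keep.append(rng.choice(idx, size=int(want), replace=False))
    sel = np.concatenate(keep) if keep else np.array([], dtype=int)
    sel = rng.permutation(sel)
    return EpochedRecording(epochs=er.epochs[sel], fs=er.fs, labels=er.labels[sel])
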