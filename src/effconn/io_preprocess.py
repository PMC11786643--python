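"""Reading, cleaning and windowing of multichannel EEG/ECG recordings.

The processing order is fixed: band-pass filter, downsample, common-average
re-reference, then segmentation into fixed-length windows whose stationarity
is assessed with a two-half variance-ratio F-test.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal as sps
import scipy.stats as sst

from . import _edf
from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

EMOTIONS = ("happiness", "disgust", "fear", "sadness")

#: labels starting with any of these prefixes are tagged ECG
_ECG_PREFIXES = ("EXG", "ECG", "EKG")

#: standard 10-20 EEG electrode names (upper-cased), the full montage used here
_EEG_1020 = {
    "FP1", "FP2", "AF3", "AF4", "F3", "F4", "F7", "F8", "FZ",
    "FC1", "FC2", "FC5", "FC6", "C3", "C4", "CZ", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "P3", "P4", "P7", "P8", "PZ",
    "PO3", "PO4", "O1", "O2", "OZ",
}


def infer_kind(label: str, strict: bool = False) -> str:
    """Channel kind from its label: EXG*/ECG*/EKG* -> ECG, 10-20 names -> EEG.

    Non-strict mode (the default, used by programmatic constructors) tags any
    other label EEG; strict mode (file readers without explicit kind
    metadata) raises so silent misclassification cannot happen.
    """
    up = label.upper()
    if up.startswith(_ECG_PREFIXES):
        return "ECG"
    if not strict or up in _EEG_1020:
        return "EEG"
    raise ValidationError(
        f"cannot infer channel kind for label {label!r}; pass a kind override"
    )


@dataclass
class MultichannelRecording:
    """A labeled, uniformly sampled signal matrix (channels x samples)."""

    samples: np.ndarray
    fs: float
    labels: list[str]
    kinds: list[str]
    emotion: str | None = None
    subject_id: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (channels x samples) matrix")
        m = self.samples.shape[0]
        if not (m == len(self.labels) == len(self.kinds)):
            raise ValidationError(
                f"channel count mismatch: {m} rows, {len(self.labels)} labels, "
                f"{len(self.kinds)} kinds"
            )
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        bad = set(self.kinds) - {"EEG", "ECG"}
        if bad:
            raise ValidationError(f"unknown channel kinds: {sorted(bad)}")
        if self.emotion is not None and self.emotion not in EMOTIONS:
            raise ValidationError(f"unknown emotion {self.emotion!r}; expected one of {EMOTIONS}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def is_canonical_montage(self) -> bool:
        """True for the full 32 EEG + 3 ECG montage."""
        return self.kinds.count("EEG") == 32 and self.kinds.count("ECG") == 3


@dataclass
class WindowSegment:
    """A fixed-length slice of a recording, carrying parent metadata."""

    samples: np.ndarray
    fs: float
    start_s: float
    labels: list[str]
    kinds: list[str]
    stationary: bool | None = None
    emotion: str | None = None
    subject_id: str | None = None
    stationarity_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


# ---------------------------------------------------------------------------
# readers / writers

_MAGIC = "# multichannel-recording v1"


def write_matrix(path: str | os.PathLike, rec: MultichannelRecording) -> None:
    """Write the plain-text matrix format (header comments + one row per channel)."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"# fs: {rec.fs!r}\n")
        fh.write("# labels: " + ",".join(rec.labels) + "\n")
        fh.write("# kinds: " + ",".join(rec.kinds) + "\n")
        if rec.emotion is not None:
            fh.write(f"# emotion: {rec.emotion}\n")
        if rec.subject_id is not None:
            fh.write(f"# subject: {rec.subject_id}\n")
        np.savetxt(fh, rec.samples, fmt="%.10g")


def _read_matrix(path: str | os.PathLike) -> MultichannelRecording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().strip()
        if first != _MAGIC:
            raise FormatError(f"{path}: not a multichannel-recording matrix file")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    if "fs" not in meta:
        raise FormatError(f"{path}: missing fs metadata")
    if "labels" not in meta:
        raise FormatError(f"{path}: missing labels metadata")
    labels = [s.strip() for s in meta["labels"].split(",")]
    if "kinds" in meta:
        kinds = [s.strip() for s in meta["kinds"].split(",")]
    else:
        kinds = [infer_kind(lab, strict=True) for lab in labels]
    return MultichannelRecording(
        samples=data,
        fs=float(meta["fs"]),
        labels=labels,
        kinds=kinds,
        emotion=meta.get("emotion"),
        subject_id=meta.get("subject"),
    )


def read_recording(
    path: str | os.PathLike,
    format: str | None = None,
    kind_overrides: dict[str, str] | None = None,
) -> MultichannelRecording:
    """Read a recording from BDF, EDF or the plain matrix format.

    Parameters
    ----------
    path:
        Input file. When ``format`` is None it is inferred from the suffix
        (``.bdf``, ``.edf``, anything else -> matrix).
    kind_overrides:
        Optional mapping label -> {"EEG","ECG"} overriding the prefix-based
        kind inference for non-standard channel names.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read recording: {path} does not exist")
    if format is None:
        format = {".bdf": "bdf", ".edf": "edf"}.get(path.suffix.lower(), "matrix")
    if format not in ("bdf", "edf", "matrix"):
        raise ValidationError(f"unknown format {format!r}")

    if format == "matrix":
        rec = _read_matrix(path)
        if kind_overrides:
            rec = replace(
                rec, kinds=[kind_overrides.get(lab, k) for lab, k in zip(rec.labels, rec.kinds)]
            )
    else:
        raw = _edf.read_edf(path)
        overrides = kind_overrides or {}
        kinds = [
            overrides.get(lab) or infer_kind(lab, strict=True) for lab in raw.labels
        ]
        rec = MultichannelRecording(
            samples=raw.samples, fs=raw.fs, labels=raw.labels, kinds=kinds
        )
    if rec.n_channels < 2:
        raise ValidationError(f"{path}: need at least 2 channels, got {rec.n_channels}")
    log.info(
        "read %s: %d channels (%d EEG / %d ECG), fs=%g Hz, %d samples",
        path, rec.n_channels, rec.kinds.count("EEG"), rec.kinds.count("ECG"),
        rec.fs, rec.n_samples,
    )
    return rec


def write_recording(path: str | os.PathLike, rec: MultichannelRecording,
                    format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".bdf": "bdf", ".edf": "edf"}.get(path.suffix.lower(), "matrix")
    if format == "matrix":
        write_matrix(path, rec)
    elif format in ("bdf", "edf"):
        _edf.write_edf(path, rec.samples, rec.fs, rec.labels, bdf=(format == "bdf"))
    else:
        raise ValidationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# cleaning

def bandpass_filter(
    rec: MultichannelRecording,
    lo: float = 0.5,
    hi: float = 45.0,
    order: int = 4,
    notch_hz: float | None = None,
) -> MultichannelRecording:
    """Zero-phase Butterworth band-pass; optional mains notch."""
    nyq = rec.fs / 2.0
    if not (0 <= lo < hi):
        raise ValidationError(f"need 0 <= lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValidationError(f"hi={hi} Hz must be below Nyquist {nyq} Hz")
    if lo > 0:
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    else:
        sos = sps.butter(order, hi, btype="lowpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.samples, axis=1)
    if notch_hz is not None:
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return replace(rec, samples=out)


def downsample(rec: MultichannelRecording, target_fs: float) -> MultichannelRecording:
    """Integer-factor decimation with internal anti-alias filtering."""
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValidationError(
            f"target_fs={target_fs} does not divide fs={rec.fs} (ratio {ratio:g})"
        )
    if q == 1:
        return replace(rec)
    out = sps.decimate(rec.samples, q, axis=1, ftype="fir", zero_phase=True)
    return replace(rec, samples=out, fs=float(target_fs))


def rereference_common_average(rec: MultichannelRecording) -> MultichannelRecording:
    """Subtract the per-sample mean over EEG channels from every EEG channel."""
    eeg = np.array([k == "EEG" for k in rec.kinds])
    if not eeg.any():
        raise ValidationError("no EEG channels to re-reference")
    out = rec.samples.copy()
    out[eeg] -= rec.samples[eeg].mean(axis=0, keepdims=True)
    return replace(rec, samples=out)


# ---------------------------------------------------------------------------
# windowing

def segment_windows(
    rec: MultichannelRecording,
    window_ms: int = 5000,
    overlap: float = 0.5,
    stationarity_alpha: float | None = 0.05,
) -> list[WindowSegment]:
    """Tile the recording with fixed windows; trailing partial window dropped.

    When ``stationarity_alpha`` is not None and windows are long enough, each
    segment's ``stationary`` flag is filled by :func:`variance_ratio_stationarity`.
    """
    if not (0 <= overlap < 1):
        raise ValidationError(f"overlap must be in [0, 1), got {overlap}")
    n_win = int(round(window_ms / 1000.0 * rec.fs))
    hop = int(round(n_win * (1.0 - overlap)))
    if hop < 1:
        raise ValidationError("hop is zero; decrease overlap")
    if rec.n_samples < n_win:
        log.warning(
            "recording of %d samples shorter than one %d-sample window; no windows",
            rec.n_samples, n_win,
        )
        return []
    count = (rec.n_samples - n_win) // hop + 1
    windows = []
    for w in range(count):
        s = w * hop
        seg = WindowSegment(
            samples=rec.samples[:, s : s + n_win].copy(),
            fs=rec.fs,
            start_s=s / rec.fs,
            labels=list(rec.labels),
            kinds=list(rec.kinds),
            emotion=rec.emotion,
            subject_id=rec.subject_id,
        )
        if stationarity_alpha is not None and n_win >= 64:
            flag, table = variance_ratio_stationarity(seg, alpha=stationarity_alpha)
            seg.stationary = flag
            seg.stationarity_table = table
        windows.append(seg)
    return windows


def variance_ratio_stationarity(
    win: WindowSegment,
    alpha: float = 0.05,
    channel_pass_frac: float = 0.90,
) -> tuple[bool, pd.DataFrame]:
    """Two-half variance-ratio F-test per channel.

    Each channel's window is split into two equal halves; the ratio of the
    larger to the smaller half variance is referred to an F(n/2-1, n/2-1)
    distribution two-sidedly. The window is flagged stationary when at least
    ``channel_pass_frac`` of channels pass at ``alpha``.
    """
    n = win.n_samples
    if n < 64:
        raise ValidationError(f"window too short for stationarity test ({n} < 64 samples)")
    half = n // 2
    a = win.samples[:, :half]
    b = win.samples[:, half : 2 * half]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    rows = []
    for i, lab in enumerate(win.labels):
        if va[i] <= 0 or vb[i] <= 0:
            rows.append((lab, np.inf, 0.0, False, "degenerate signal (zero variance)"))
            continue
        ratio = max(va[i], vb[i]) / min(va[i], vb[i])
        p = min(1.0, 2.0 * sst.f.sf(ratio, half - 1, half - 1))
        rows.append((lab, ratio, p, p > alpha, ""))
    table = pd.DataFrame(rows, columns=["channel", "ratio", "p_value", "pass", "note"])
    stationary = bool(table["pass"].mean() >= channel_pass_frac)
    return stationary, table


def preprocess(
    rec: MultichannelRecording,
    band: tuple[float, float] = (0.5, 45.0),
    target_fs: float | None = 128.0,
    window_ms: int = 5000,
    overlap: float = 0.5,
    drop_nonstationary: bool = False,
    notch_hz: float | None = None,
) -> list[WindowSegment]:
    """Full preprocessing chain: filter -> downsample -> re-reference -> segment."""
    rec = bandpass_filter(rec, *band, notch_hz=notch_hz)
    if target_fs is not None and target_fs != rec.fs:
        rec = downsample(rec, target_fs)
    rec = rereference_common_average(rec)
    windows = segment_windows(rec, window_ms=window_ms, overlap=overlap)
    n_total = len(windows)
    if drop_nonstationary:
        windows = [w for w in windows if w.stationary is not False]
    n_stat = sum(1 for w in windows if w.stationary)
    log.info(
        "preprocessed %s: %d windows (%d stationary, drop_nonstationary=%s)",
        rec.subject_id or "<recording>", n_total, n_stat, drop_nonstationary,
    )
    return windows
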