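"""Minimal EDF/BDF (European Data Format / BioSemi Data Format) reader and writer.

Implements the fixed-width ASCII header plus 16-bit (EDF) or 24-bit (BDF)
little-endian integer sample records. Only the subset needed to round-trip
multichannel recordings is supported: equal sampling rate across signals and
contiguous data records.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import FormatError

_HDR = 256  # bytes in the fixed part of the header


@dataclass
class _RawEdf:
    labels: list[str]
    fs: float
    samples: np.ndarray  # (n_channels, n_samples) physical units


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def _num(raw: bytes, start: int, length: int, what: str) -> float:
    text = _field(raw, start, length)
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable {what} field: {text!r}") from exc


def read_edf(path: str | os.PathLike) -> _RawEdf:
    """Read an EDF or BDF file; the variant is detected from the version field."""
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise FormatError(f"{path}: truncated header")
        is_bdf = head[0] == 0xFF and head[1:8].strip() == b"BIOSEMI"
        n_records = int(_num(head, 236, 8, "record count"))
        record_dur = _num(head, 244, 8, "record duration")
        ns = int(_num(head, 252, 4, "signal count"))
        if ns < 1:
            raise FormatError(f"{path}: no signals")
        sig = fh.read(ns * 256)
        if len(sig) < ns * 256:
            raise FormatError(f"{path}: truncated signal header")

        def col(offset: int, width: int) -> list[str]:
            return [_field(sig, offset * ns + i * width, width) for i in range(ns)]

        # per-signal blocks: label 0, transducer 16, dimension 96, phys_min 104,
        # phys_max 112, dig_min 120, dig_max 128, prefilter 136, spr 216
        labels = col(0, 16)
        phys_min = np.array([float(v) for v in col(104, 8)])
        phys_max = np.array([float(v) for v in col(112, 8)])
        dig_min = np.array([float(v) for v in col(120, 8)])
        dig_max = np.array([float(v) for v in col(128, 8)])
        spr = np.array([int(float(v)) for v in col(216, 8)])
        if record_dur <= 0:
            raise FormatError(f"{path}: non-positive record duration (missing fs)")
        if len(set(spr.tolist())) != 1:
            raise FormatError(f"{path}: per-signal sampling rates differ")
        fs = spr[0] / record_dur

        bps = 3 if is_bdf else 2
        payload = fh.read(n_records * int(spr.sum()) * bps)
        need = n_records * int(spr.sum()) * bps
        if len(payload) < need:
            raise FormatError(f"{path}: truncated data records")

    if is_bdf:
        b = np.frombuffer(payload, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
        ints = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
        ints = np.where(ints >= 1 << 23, ints - (1 << 24), ints)
    else:
        ints = np.frombuffer(payload, dtype="<i2").astype(np.int32)

    n = spr[0]
    ints = ints.reshape(n_records, ns, n)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    phys = (ints - dig_min[None, :, None]) * gain[None, :, None] + phys_min[None, :, None]
    samples = np.concatenate([phys[r] for r in range(n_records)], axis=1)
    return _RawEdf(labels=labels, fs=float(fs), samples=samples)


def _pad(text: str, width: int) -> bytes:
    out = text[:width].ljust(width)
    return out.encode("ascii")


def write_edf(
    path: str | os.PathLike,
    samples: np.ndarray,
    fs: float,
    labels: list[str],
    bdf: bool = False,
) -> None:
    """Write one data record holding the full signal per channel."""
    samples = np.asarray(samples, dtype=float)
    ns, n = samples.shape
    bits = 23 if bdf else 15
    dig_max = (1 << bits) - 1
    dig_min = -(1 << bits)

    phys_min = samples.min(axis=1)
    phys_max = samples.max(axis=1)
    flat = phys_max - phys_min < 1e-30
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    with open(path, "wb") as fh:
        if bdf:
            fh.write(b"\xffBIOSEMI")
        else:
            fh.write(_pad("0", 8))
        fh.write(_pad("effconn", 80))
        fh.write(_pad("effconn", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(_HDR + ns * 256), 8))
        fh.write(_pad("24BIT" if bdf else "EDF", 44))
        fh.write(_pad("1", 8))
        fh.write(_pad(repr(n / fs)[:8], 8))
        fh.write(_pad(str(ns), 4))

        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in labels:
            fh.write(_pad("", 80))
        for _ in labels:
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        fh.write(_pad(str(dig_min), 8) * ns)
        fh.write(_pad(str(dig_max), 8) * ns)
        for _ in labels:
            fh.write(_pad("", 80))
        fh.write(_pad(str(n), 8) * ns)
        fh.write(_pad("", 32) * ns)

        # re-read the header strings so quantization matches what a reader sees
        pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
        pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
        gain = (dig_max - dig_min) / (pmax - pmin)
        dig = np.rint((samples - pmin[:, None]) * gain[:, None] + dig_min)
        dig = np.clip(dig, dig_min, dig_max).astype(np.int32)

        if bdf:
            u = (dig & 0xFFFFFF).astype(np.uint32)
            b = np.empty((ns, n, 3), dtype=np.uint8)
            b[..., 0] = u & 0xFF
            b[..., 1] = (u >> 8) & 0xFF
            b[..., 2] = (u >> 16) & 0xFF
            fh.write(b.tobytes())
        else:
            fh.write(dig.astype("<i2").tobytes())
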