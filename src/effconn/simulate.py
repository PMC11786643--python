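"""Synthetic ground-truth MVAR systems and 4-class EEG/ECG-like datasets.

EEG-like channels are resonant AR(2) oscillators (default 10 Hz, pole radius
0.9 at 128 Hz); the three ECG-like channels share a slow quasi-periodic
driver (1.1 Hz). Class-dependent directed EEG<->ECG coupling profiles create
separable connectivity signatures:

* happiness — bidirectional coupling between EXG3 and most EEG channels
* disgust   — bidirectional coupling between EXG2 and most EEG channels
* fear      — (near) zero EEG<->ECG coupling
* sadness   — Fp1/Fp2 hubs feeding all other channels

Every emitted system is rescaled to spectral radius < 0.98, so downstream
MVAR fitting is always well-posed. All randomness flows from a single root
seed via numpy's seed-sequence spawning.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mvar
from .errors import ValidationError
from .imaging import CANONICAL_35
from .io_preprocess import EMOTIONS, MultichannelRecording, infer_kind

_MAX_RADIUS = 0.98


@dataclass
class SyntheticSpec:
    n_channels: int = 35
    fs: float = 128.0
    trial_s: float = 30.0
    trials_per_class: int = 40
    coupling: float = 0.4
    eeg_f0: float = 10.0  # Hz, alpha-band oscillators
    eeg_pole: float = 0.9
    ecg_f0: float = 1.1
    ecg_pole: float = 0.95
    noise_scale: float = 1.0
    seed: int = 0
    class_profiles: dict[str, list[tuple[int, int, float]]] | None = None
    labels: list[str] = field(default_factory=lambda: list(CANONICAL_35))


def _ar2_coeffs(f0: float, radius: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients with a complex pole pair at frequency f0, given radius."""
    theta = 2 * np.pi * f0 / fs
    return 2 * radius * np.cos(theta), -(radius**2)


def rescale_to_stable(A: np.ndarray, max_radius: float = _MAX_RADIUS) -> np.ndarray:
    """Shrink coefficients so the companion spectral radius drops below max_radius.

    Scaling A[r] by s**r scales every companion eigenvalue by exactly s.
    """
    A = np.asarray(A, dtype=float)
    rho = float(np.abs(np.linalg.eigvals(mvar.companion_matrix(A))).max())
    if rho < max_radius:
        return A
    s = (max_radius * 0.999) / rho
    out = A * (s ** np.arange(1, A.shape[0] + 1))[:, None, None]
    rho2 = float(np.abs(np.linalg.eigvals(mvar.companion_matrix(out))).max())
    if rho2 >= 1.0:
        raise ValidationError(f"system not stabilizable (radius {rho2:.4f} after rescaling)")
    return out


def generate_mvar_system(
    A: np.ndarray,
    seed: int | np.random.Generator = 0,
    n_samples: int = 10_000,
    fs: float = 128.0,
    sigma: np.ndarray | None = None,
    labels: list[str] | None = None,
    kinds: list[str] | None = None,
    emotion: str | None = None,
    subject_id: str | None = None,
) -> tuple[np.ndarray, MultichannelRecording]:
    """Simulate a (rescaled-to-stable) MVAR system; returns (A_used, recording).

    A burn-in of 10*P samples is discarded, so the returned series is
    (approximately) a draw from the stationary distribution.
    """
    A = rescale_to_stable(np.asarray(A, dtype=float))
    P, m, _ = A.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = mvar.simulate_var(A, n_samples, rng, sigma=sigma, burn_in=10 * P)
    if labels is None:
        labels = [f"ch{i}" for i in range(m)]
    if kinds is None:
        kinds = [infer_kind(lab) for lab in labels]
    rec = MultichannelRecording(
        samples=x, fs=fs, labels=labels, kinds=kinds,
        emotion=emotion, subject_id=subject_id,
    )
    return A, rec


FIVE_NODE_EDGES = [(0, 1), (0, 2), (1, 3), (3, 4)]  # source -> target, 0-based


def fixture_5node(
    seed: int = 0, n_samples: int = 10_000, fs: float = 128.0,
    strength: float = 0.4, pole_radius: float = 0.45,
) -> tuple[list[tuple[int, int]], np.ndarray, MultichannelRecording]:
    """Canonical 5-channel truth fixture with edge set {1->2, 1->3, 2->4, 4->5}
    (1-based), i.e. FIVE_NODE_EDGES 0-based. Returns (edges, A_true, recording).

    The node pole radius is deliberately moderate (0.45): sharp resonances
    amplify cascaded (indirect) influence in DTF and pairwise GC until it
    beats weak direct edges, which would defeat the fixture's purpose as a
    directionality-recovery benchmark.
    """
    m, P = 5, 2
    A = np.zeros((P, m, m))
    f0s = [7.0, 9.0, 11.0, 13.0, 15.0]
    for i in range(m):
        a1, a2 = _ar2_coeffs(f0s[i], pole_radius, fs)
        A[0, i, i] = a1
        A[1, i, i] = a2
    for src, dst in FIVE_NODE_EDGES:
        A[0, dst, src] = strength
    A_used, rec = generate_mvar_system(A, seed=seed, n_samples=n_samples, fs=fs)
    return list(FIVE_NODE_EDGES), A_used, rec


def _default_profiles(labels: list[str], coupling: float) -> dict[str, list[tuple[int, int, float]]]:
    """Directed (source, target, weight) edge lists per emotion class."""
    idx = {lab: i for i, lab in enumerate(labels)}
    eeg = [i for i, lab in enumerate(labels) if infer_kind(lab) == "EEG"]
    exg2, exg3 = idx["EXG2"], idx["EXG3"]
    fp1, fp2 = idx["Fp1"], idx["Fp2"]

    # bidirectional ECG<->EEG hubs over a 12-channel EEG subset: per-edge
    # weights must clear the DTF estimation noise floor, so fewer, stronger
    # edges beat many diluted ones (row normalization washes those out)
    hub = eeg[::3][:12]
    w = coupling * 0.5
    happiness = [(e, exg3, w) for e in hub] + [(exg3, e, w) for e in hub]
    disgust = [(e, exg2, w) for e in hub] + [(exg2, e, w) for e in hub]
    fear: list[tuple[int, int, float]] = []
    sadness = [
        (src, t, w)
        for src in (fp1, fp2)
        for t in range(len(labels))
        if t != src
    ]
    return {
        "happiness": happiness,
        "disgust": disgust,
        "fear": fear,
        "sadness": sadness,
    }


def build_class_system(spec: SyntheticSpec, emotion: str) -> np.ndarray:
    """Coefficient matrices (P=2) for one emotion class, rescaled to stability."""
    labels = spec.labels
    m = len(labels)
    if m != spec.n_channels:
        raise ValidationError("labels length does not match n_channels")
    A = np.zeros((2, m, m))
    ecg_rows = [i for i, lab in enumerate(labels) if infer_kind(lab) == "ECG"]
    for i in range(m):
        if i in ecg_rows:
            a1, a2 = _ar2_coeffs(spec.ecg_f0, spec.ecg_pole, spec.fs)
        else:
            a1, a2 = _ar2_coeffs(spec.eeg_f0, spec.eeg_pole, spec.fs)
        A[0, i, i] = a1
        A[1, i, i] = a2
    # shared slow driver: EXG1 feeds EXG2 and EXG3
    for other in ecg_rows[1:]:
        A[0, other, ecg_rows[0]] = 0.3
    profiles = spec.class_profiles or _default_profiles(labels, spec.coupling)
    if emotion not in profiles:
        raise ValidationError(f"no profile for emotion {emotion!r}")
    for src, dst, w in profiles[emotion]:
        if not (0 <= src < m and 0 <= dst < m):
            raise ValidationError(f"profile edge ({src}, {dst}) out of range")
        A[0, dst, src] += w
    return rescale_to_stable(A)


def generate_emotion_dataset(spec: SyntheticSpec | None = None) -> list[MultichannelRecording]:
    """Per class, simulate `trials_per_class` labeled recordings of `trial_s` seconds."""
    spec = spec or SyntheticSpec()
    n = int(round(spec.trial_s * spec.fs))
    kinds = [infer_kind(lab) for lab in spec.labels]
    root = np.random.SeedSequence(spec.seed)
    out: list[MultichannelRecording] = []
    for c, emotion in enumerate(EMOTIONS):
        A = build_class_system(spec, emotion)
        streams = root.spawn(spec.trials_per_class)
        for t, ss in enumerate(streams):
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=ss.spawn_key + (c,)))
            x = mvar.simulate_var(A, n, rng, burn_in=20 * A.shape[0])
            out.append(
                MultichannelRecording(
                    samples=x * spec.noise_scale, fs=spec.fs,
                    labels=list(spec.labels), kinds=list(kinds),
                    emotion=emotion, subject_id=f"sim{t:03d}",
                )
            )
    return out
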