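import numpy as np
import pytest

from effconn.io_preprocess import MultichannelRecording, WindowSegment


def make_window(samples: np.ndarray, fs: float = 128.0,
                labels: list[str] | None = None,
                kinds: list[str] | None = None, **kw) -> WindowSegment:
    samples = np.asarray(samples, dtype=float)
    m = samples.shape[0]
    labels = labels or [f"ch{i}" for i in range(m)]
    kinds = kinds or ["EEG"] * m
    return WindowSegment(samples=samples, fs=fs, start_s=0.0,
                         labels=labels, kinds=kinds, **kw)


def make_recording(samples: np.ndarray, fs: float = 128.0,
                   labels: list[str] | None = None,
                   kinds: list[str] | None = None, **kw) -> MultichannelRecording:
    samples = np.asarray(samples, dtype=float)
    m = samples.shape[0]
    labels = labels or [f"ch{i}" for i in range(m)]
    kinds = kinds or ["EEG"] * m
    return MultichannelRecording(samples=samples, fs=fs, labels=labels,
                                 kinds=kinds, **kw)


@pytest.fixture
def bivar_var1_model():
    """The hand-checked bivariate VAR(1): A1 = [[0.5, 0], [0.4, 0.5]]."""
    from effconn.mvar import MVARModel

    A = np.array([[[0.5, 0.0], [0.4, 0.5]]])
    return MVARModel(order=1, A=A, sigma=np.eye(2), fs=128.0, labels=["x", "y"])


@pytest.fixture(scope="session")
def canonical_recording():
    """One stable 35-channel synthetic recording (fear class: no cross coupling)."""
    from effconn import simulate

    spec = simulate.SyntheticSpec(trials_per_class=1, trial_s=20.0, seed=42)
    A = simulate.build_class_system(spec, "fear")
    _, rec = simulate.generate_mvar_system(
        A, seed=42, n_samples=int(20 * spec.fs), fs=spec.fs,
        labels=spec.labels, emotion="fear", subject_id="sess",
    )
    return rec
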