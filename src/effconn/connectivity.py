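"""Directed-connectivity estimators: Granger causality (GC), partial directed
coherence (PDC) and directed transfer function (DTF).

PDC and DTF come from a single joint MVAR fit per window: the spectral
coefficient matrix Abar(f) = I - sum_r A[r] exp(-i 2 pi (f/fs) r) and its
inverse, the transfer matrix H(f). PDC is the column-normalized magnitude of
Abar, DTF the row-normalized magnitude of H. GC is the classical bivariate
log residual-variance ratio, computed per band on band-pass filtered windows.

Matrix orientation everywhere: entry (i, j) is coupling from source channel j
to target channel i (rows = target/sink, columns = source).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal as sps

from . import mvar
from .errors import ValidationError
from .io_preprocess import WindowSegment

log = logging.getLogger(__name__)

ORIENTATION_NOTE = "rows = target (sink), columns = source"


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0 <= self.f_lo < self.f_hi):
            raise ValidationError(f"bad band edges: [{self.f_lo}, {self.f_hi})")


#: canonical EEG analysis bands (Hz); edges configurable via custom BandDefinitions
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}


def default_freq_grid(f_max: float = 45.0, df: float = 0.25) -> np.ndarray:
    return np.arange(df, f_max + df / 2, df)


@dataclass
class SpectralTransfer:
    """Per-frequency spectral coefficient matrices Abar(f) and H(f) = Abar(f)^-1."""

    freqs: np.ndarray  # (F,)
    Abar: np.ndarray  # (F, m, m) complex
    H: np.ndarray  # (F, m, m) complex

    @property
    def n_channels(self) -> int:
        return self.Abar.shape[1]


@dataclass
class ConnectivityMatrix:
    """A band-aggregated m x m directed-coupling matrix."""

    method: str  # GC | PDC | DTF
    band: str
    values: np.ndarray  # (m, m), non-negative
    labels: list[str]
    kinds: list[str]
    orientation: str = ORIENTATION_NOTE
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityConfig:
    order: int = 10
    f_max: float = 45.0
    freq_resolution: float = 0.25
    pdc_squared: bool = False
    diagnostics: str = "stability"  # none | stability | full
    filter_order: int = 4


def spectral_coefficients(model: mvar.MVARModel, freqs: np.ndarray) -> SpectralTransfer:
    """Evaluate Abar(f) = I - sum_r A[r] e^{-i 2 pi (f/fs) r} and H = Abar^-1."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValidationError("empty frequency grid")
    if freqs.min() < 0 or freqs.max() > model.fs / 2:
        raise ValidationError(
            f"frequencies must lie in [0, fs/2] = [0, {model.fs / 2}], "
            f"got [{freqs.min()}, {freqs.max()}]"
        )
    P, m, _ = model.A.shape
    r = np.arange(1, P + 1)
    # phase[f, r] = exp(-i 2 pi (f/fs) r)
    phase = np.exp(-2j * np.pi * np.outer(freqs / model.fs, r))
    Abar = np.eye(m)[None] - np.einsum("fr,rij->fij", phase, model.A)
    try:
        H = np.linalg.inv(Abar)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"Abar(f) singular on the grid: {exc}") from exc
    # determinant magnitude is scale-dependent at large m; check invertibility
    # through the actual inverse residual instead
    resid = np.abs(Abar @ H - np.eye(m)[None]).max(axis=(1, 2))
    if (resid > 1e-6).any():
        f_bad = freqs[int(np.argmax(resid))]
        raise ValidationError(
            f"Abar(f) numerically singular at f={f_bad:g} Hz "
            f"(near-unit-root model; inverse residual {resid.max():.2e})"
        )
    return SpectralTransfer(freqs=freqs, Abar=Abar, H=H)


def pdc(st: SpectralTransfer, squared: bool = False) -> np.ndarray:
    """Partial directed coherence: column-normalized |Abar(f)|, shape (F, m, m)."""
    mag = np.abs(st.Abar)
    col_norm = np.sqrt((mag**2).sum(axis=1, keepdims=True))  # (F, 1, m)
    if np.any(col_norm == 0):
        raise ValidationError("zero column norm in Abar (degenerate model)")
    out = mag / col_norm
    return out**2 if squared else out


def dtf(st: SpectralTransfer, squared: bool = False) -> np.ndarray:
    """Directed transfer function: row-normalized |H(f)|, shape (F, m, m)."""
    mag = np.abs(st.H)
    row_norm = np.sqrt((mag**2).sum(axis=2, keepdims=True))  # (F, m, 1)
    if np.any(row_norm == 0):
        raise ValidationError("zero row norm in H (degenerate model)")
    out = mag / row_norm
    return out**2 if squared else out


def _ar_resid_var(x: np.ndarray, order: int) -> float:
    """ML residual variance of a univariate AR(order) OLS fit."""
    n = x.size
    Y = x[order:]
    Z = np.empty((order, n - order))
    for r in range(order):
        Z[r] = x[order - r - 1 : n - r - 1]
    coef, _, _, _ = np.linalg.lstsq(Z.T, Y, rcond=None)
    resid = Y - coef @ Z
    return float(resid @ resid / (n - order))


def _var2_resid_var(x: np.ndarray, y: np.ndarray, order: int) -> float:
    """ML residual variance of x's equation in a bivariate VAR(order)."""
    n = x.size
    Y = x[order:]
    Z = np.empty((2 * order, n - order))
    for r in range(order):
        Z[2 * r] = x[order - r - 1 : n - r - 1]
        Z[2 * r + 1] = y[order - r - 1 : n - r - 1]
    coef, _, _, _ = np.linalg.lstsq(Z.T, Y, rcond=None)
    resid = Y - coef @ Z
    return float(resid @ resid / (n - order))


def granger_pairwise(
    win: WindowSegment,
    order: int = 10,
    band: BandDefinition | None = None,
    filter_order: int = 4,
) -> np.ndarray:
    """Pairwise time-domain Granger causality matrix.

    Entry (i, j) = GC_{j -> i} = ln(V_restricted(i) / V_full(i|i,j)), clipped
    at 0; diagonal fixed to 0. When ``band`` is given the window is zero-phase
    band-pass filtered to that band first (this is the per-band GC variant;
    note that narrow-band filtering can bias GC).
    """
    x = np.asarray(win.samples, dtype=float)
    if band is not None:
        hi = min(band.f_hi, win.fs / 2 * 0.999)
        sos = sps.butter(filter_order, [band.f_lo, hi], btype="bandpass",
                         fs=win.fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    m, n = x.shape
    if n <= 2 * order + order:
        raise ValidationError(f"window too short for pairwise GC at order {order}")
    restricted = np.array([_ar_resid_var(x[i], order) for i in range(m)])
    gc = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            try:
                v_full = _var2_resid_var(x[i], x[j], order)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ValidationError(f"GC fit failed for pair ({win.labels[i]}, "
                                      f"{win.labels[j]}): {exc}") from exc
            if v_full <= 0:
                raise ValidationError(
                    f"degenerate full-model variance for pair ({win.labels[i]}, {win.labels[j]})"
                )
            gc[i, j] = max(0.0, np.log(restricted[i] / v_full))
    return gc


def band_average(
    stack: np.ndarray,
    band: BandDefinition,
    freqs: np.ndarray,
    method: str = "",
    labels: list[str] | None = None,
    kinds: list[str] | None = None,
    meta: dict | None = None,
) -> ConnectivityMatrix:
    """Arithmetic mean of per-frequency matrices over f_lo <= f < f_hi."""
    freqs = np.asarray(freqs)
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    if not mask.any():
        raise ValidationError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}) does not overlap the "
            f"frequency grid [{freqs.min()}, {freqs.max()}]"
        )
    values = np.asarray(stack)[mask].mean(axis=0)
    m = values.shape[0]
    return ConnectivityMatrix(
        method=method,
        band=band.name,
        values=values,
        labels=labels or [f"ch{i}" for i in range(m)],
        kinds=kinds or ["EEG"] * m,
        meta=meta or {},
    )


def window_connectivity(
    win: WindowSegment,
    method: str,
    bands: list[BandDefinition] | None = None,
    config: ConnectivityConfig | None = None,
) -> list[ConnectivityMatrix]:
    """Per-band connectivity matrices for one window.

    PDC/DTF: one joint MVAR fit, spectral transfer on the configured grid,
    then band averaging. GC: pairwise time-domain GC per band with band-pass
    pre-filtering. Windows whose joint fit is unstable are skipped (empty
    list) with a log message.
    """
    method = method.upper()
    if method not in ("GC", "PDC", "DTF"):
        raise ValidationError(f"unknown method {method!r}")
    config = config or ConnectivityConfig()
    if bands is None:
        bands = list(BANDS.values())
    if win.n_channels < 2:
        raise ValidationError("need at least 2 channels")
    if not (win.kinds.count("EEG") == 32 and win.kinds.count("ECG") == 3):
        log.warning(
            "non-canonical montage (%d channels, expected 32 EEG + 3 ECG); proceeding",
            win.n_channels,
        )

    base_meta = {
        "start_s": win.start_s,
        "emotion": win.emotion,
        "subject_id": win.subject_id,
        "order": config.order,
        "stationary": win.stationary,
    }

    if method == "GC":
        out = []
        for band in bands:
            gc = granger_pairwise(win, order=config.order, band=band,
                                  filter_order=config.filter_order)
            out.append(
                ConnectivityMatrix(
                    method="GC", band=band.name, values=gc,
                    labels=list(win.labels), kinds=list(win.kinds),
                    meta=dict(base_meta),
                )
            )
        return out

    model = mvar.fit_mvar(win, order=config.order)
    if config.diagnostics == "full":
        rep = mvar.validate(model, win)
    elif config.diagnostics == "stability":
        rep = mvar.check_stability(model)
        model.diagnostics = rep
    else:
        rep = None
    if rep is not None and not rep.stable:
        log.warning(
            "window at %.2f s: unstable MVAR fit (spectral radius %.4f); skipped",
            win.start_s, rep.spectral_radius,
        )
        return []

    f_max = min(config.f_max, max(b.f_hi for b in bands), win.fs / 2 * 0.999)
    # full lattice from df to f_max, then restricted to the requested bands'
    # span; grid points coincide with the full-grid computation, so band
    # averages are unchanged
    freqs = np.arange(config.freq_resolution, f_max + config.freq_resolution / 2,
                      config.freq_resolution)
    f_lo = min(b.f_lo for b in bands)
    freqs = freqs[freqs >= f_lo - config.freq_resolution]
    st = spectral_coefficients(model, freqs)
    stack = pdc(st, squared=config.pdc_squared) if method == "PDC" else dtf(st)
    if rep is not None:
        base_meta["diagnostics"] = rep.as_dict()
    return [
        band_average(stack, band, freqs, method=method,
                     labels=list(win.labels), kinds=list(win.kinds),
                     meta=dict(base_meta))
        for band in bands
    ]


def save_connectivity(path, matrices: list[ConnectivityMatrix]) -> None:
    """Serialize matrices to .npz with labels, method, band and orientation note."""
    arrays = {}
    for k, cm in enumerate(matrices):
        arrays[f"values_{k}"] = cm.values
        arrays[f"meta_{k}"] = np.array(
            [cm.method, cm.band, ",".join(cm.labels), ",".join(cm.kinds),
             cm.orientation, str(cm.meta.get("emotion")), str(cm.meta.get("subject_id"))]
        )
    arrays["count"] = np.array([len(matrices)])
    np.savez(path, **arrays)


def load_connectivity(path) -> list[ConnectivityMatrix]:
    data = np.load(path, allow_pickle=False)
    out = []
    for k in range(int(data["count"][0])):
        meta = data[f"meta_{k}"]
        emotion = None if str(meta[5]) == "None" else str(meta[5])
        subject = None if str(meta[6]) == "None" else str(meta[6])
        out.append(
            ConnectivityMatrix(
                method=str(meta[0]), band=str(meta[1]),
                values=data[f"values_{k}"],
                labels=str(meta[2]).split(","), kinds=str(meta[3]).split(","),
                orientation=str(meta[4]),
                meta={"emotion": emotion, "subject_id": subject},
            )
        )
    return out
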