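"""Multivariate autoregressive (MVAR) model fitting, order selection and
validation.

The fit is ordinary least squares on the lag-stacked regression; the residual
covariance uses the degrees-of-freedom corrected denominator n_eff - m*P.
Validation covers companion-matrix stability, Ljung-Box residual whiteness and
a correlation-structure consistency score.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import acorr_ljungbox

from .errors import SingularFitError, ValidationError
from .io_preprocess import WindowSegment

log = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    stable: bool
    spectral_radius: float
    whiteness_p: float | None = None
    consistency_pct: float | None = None

    def as_dict(self) -> dict:
        return {
            "stable": self.stable,
            "spectral_radius": self.spectral_radius,
            "whiteness_p": self.whiteness_p,
            "consistency_pct": self.consistency_pct,
        }


@dataclass
class MVARModel:
    """Order-P coefficient matrices plus residual covariance.

    ``A[r][i][j]`` is the influence of channel j at lag r+1 on channel i.
    """

    order: int
    A: np.ndarray  # (P, m, m)
    sigma: np.ndarray  # (m, m)
    fs: float
    labels: list[str] = field(default_factory=list)
    diagnostics: StabilityReport | None = None

    @property
    def n_channels(self) -> int:
        return self.A.shape[1]


def _lag_matrices(x: np.ndarray, order: int, offset: int | None = None):
    """Build response Y (m, n_eff) and lag-stacked regressor Z (m*order, n_eff).

    ``offset`` fixes the first predicted sample index so different orders can
    be compared on the same effective span.
    """
    m, n = x.shape
    t0 = order if offset is None else offset
    if t0 < order:
        raise ValidationError("offset smaller than order")
    n_eff = n - t0
    Y = x[:, t0:]
    Z = np.empty((m * order, n_eff))
    for r in range(order):
        Z[r * m : (r + 1) * m] = x[:, t0 - r - 1 : n - r - 1]
    return Y, Z, n_eff


def _identify_bad_channels(x: np.ndarray, labels: list[str]) -> list[str]:
    bad = []
    var = x.var(axis=1)
    for i, lab in enumerate(labels):
        if var[i] <= 1e-300:
            bad.append(lab)
    # duplicated channels make the regression rank deficient too
    for i in range(x.shape[0]):
        for j in range(i + 1, x.shape[0]):
            if np.array_equal(x[i], x[j]):
                bad.extend([labels[i], labels[j]])
    return sorted(set(bad))


def _ols_fit(x: np.ndarray, order: int, labels: list[str], offset: int | None = None):
    """Core OLS VAR fit on a demeaned (m, n) array. Returns (A, sigma_dfc, sigma_ml, n_eff)."""
    m, n = x.shape
    Y, Z, n_eff = _lag_matrices(x, order, offset)
    if n_eff <= m * order + order:
        raise ValidationError(
            f"window too short for order {order}: {n} samples, {m} channels"
        )
    # numpy's gelsd with rcond=None truncates the tiny singular values that a
    # common-average reference introduces, giving the bounded minimum-norm
    # solution (scipy's lstsq default cond does not)
    coef, _, rank, _ = np.linalg.lstsq(Z.T, Y.T, rcond=None)
    if rank < m * order:
        bad = _identify_bad_channels(x, labels)
        if bad:
            raise SingularFitError(
                f"rank-deficient regressor (rank {rank} < {m * order}); "
                f"offending channels: {', '.join(bad)}",
                channels=bad,
            )
        # benign deficiency, e.g. the exact linear dependence introduced by
        # common-average re-referencing: keep the minimum-norm OLS solution
        log.debug("rank-deficient regressor (rank %d < %d) without degenerate "
                  "channels; using minimum-norm solution", rank, m * order)
    B = coef.T  # (m, m*order)
    resid = Y - B @ Z
    dof = n_eff - m * order
    sigma = resid @ resid.T / dof
    sigma_ml = resid @ resid.T / n_eff
    A = B.reshape(m, order, m).transpose(1, 0, 2)
    return A, sigma, sigma_ml, n_eff, resid


def fit_mvar(win: WindowSegment, order: int = 10) -> MVARModel:
    """Fit an order-P MVAR model by multivariate least squares.

    The per-channel window mean is removed before fitting. Residual covariance
    uses denominator n_eff - m*P. Deterministic for fixed input.
    """
    if order < 1:
        raise ValidationError(f"order must be >= 1, got {order}")
    x = np.asarray(win.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("window contains non-finite samples")
    x = x - x.mean(axis=1, keepdims=True)
    A, sigma, _, _, _ = _ols_fit(x, order, win.labels)
    sigma = (sigma + sigma.T) / 2.0
    return MVARModel(order=order, A=A, sigma=sigma, fs=win.fs, labels=list(win.labels))


def residuals(model: MVARModel, win: WindowSegment) -> np.ndarray:
    """Residuals of the model on the window it was fitted to, shape (m, n - P)."""
    x = np.asarray(win.samples, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    Y, Z, _ = _lag_matrices(x, model.order)
    B = model.A.transpose(1, 0, 2).reshape(model.n_channels, -1)
    return Y - B @ Z


def select_order_aic(win: WindowSegment, max_order: int = 20) -> tuple[int, pd.DataFrame]:
    """AIC order selection: n_eff * ln det(Sigma_ML) + 2 m^2 P, common sample span."""
    if max_order < 1:
        raise ValidationError("max_order must be >= 1")
    x = np.asarray(win.samples, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    m = x.shape[0]
    rows = []
    errors = []
    for p in range(1, max_order + 1):
        try:
            _, _, sigma_ml, n_eff, _ = _ols_fit(x, p, win.labels, offset=max_order)
            sign, logdet = np.linalg.slogdet(sigma_ml)
            if sign <= 0:
                raise ValidationError(f"degenerate residual covariance at order {p}")
            aic = n_eff * logdet + 2.0 * m * m * p
            rows.append((p, aic))
        except (ValidationError, SingularFitError) as exc:
            errors.append((p, exc))
    if not rows:
        raise ValidationError(f"all orders failed: {errors}")
    curve = pd.DataFrame(rows, columns=["order", "aic"])
    best = int(curve.loc[curve["aic"].idxmin(), "order"])
    return best, curve


def companion_matrix(A: np.ndarray) -> np.ndarray:
    """Stack the P lag matrices into the (mP x mP) companion form."""
    P, m, _ = A.shape
    C = np.zeros((m * P, m * P))
    C[:m] = A.transpose(1, 0, 2).reshape(m, m * P)
    if P > 1:
        C[m:, :-m] = np.eye(m * (P - 1))
    return C


def check_stability(model: MVARModel) -> StabilityReport:
    """Stable iff the companion matrix spectral radius is strictly below 1."""
    rho = float(np.abs(np.linalg.eigvals(companion_matrix(model.A))).max())
    return StabilityReport(stable=rho < 1.0, spectral_radius=rho)


def check_whiteness(model: MVARModel, win: WindowSegment, lags: int = 20) -> pd.DataFrame:
    """Per-channel Ljung-Box portmanteau test on the fit residuals."""
    if lags >= win.n_samples:
        raise ValidationError(f"lags={lags} must be below window length {win.n_samples}")
    res = residuals(model, win)
    rows = []
    for i, lab in enumerate(win.labels):
        lb = acorr_ljungbox(res[i], lags=[lags])
        rows.append((lab, float(lb["lb_stat"].iloc[0]), float(lb["lb_pvalue"].iloc[0])))
    return pd.DataFrame(rows, columns=["channel", "lb_stat", "p_value"])


def simulate_var(
    A: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    sigma: np.ndarray | None = None,
    burn_in: int | None = None,
) -> np.ndarray:
    """Simulate x(n) = sum_r A[r] x(n-r) + e(n) with Gaussian innovations."""
    A = np.asarray(A, dtype=float)
    P, m, _ = A.shape
    if burn_in is None:
        burn_in = 10 * P
    total = n_samples + burn_in
    if sigma is None:
        e = rng.standard_normal((total, m))
    else:
        # eigen-based square root tolerates singular covariances (which arise
        # after common-average re-referencing)
        w, V = np.linalg.eigh(np.asarray(sigma, dtype=float))
        L = V * np.sqrt(np.clip(w, 0.0, None))
        e = rng.standard_normal((total, m)) @ L.T
    x = np.zeros((total, m))
    x[:P] = e[:P]
    for t in range(P, total):
        acc = e[t].copy()
        for r in range(P):
            acc += A[r] @ x[t - r - 1]
        x[t] = acc
    return x[burn_in:].T.copy()


def _stacked_correlation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Auto/cross-correlation matrices at lags 0..max_lag, stacked along axis 0."""
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1)
    sd[sd == 0] = 1.0
    xn = xc / sd[:, None]
    out = np.empty((max_lag + 1, m, m))
    for lag in range(max_lag + 1):
        out[lag] = xn[:, lag:] @ xn[:, : n - lag if lag else n].T / (n - lag)
    return out


def check_consistency(model: MVARModel, win: WindowSegment, seed: int = 0) -> float:
    """Percent match between data and model-simulated correlation structure.

    consistency = 100 * (1 - ||R_data - R_sim||_F / ||R_data||_F), clipped at 0,
    with R the stacked auto/cross-correlations up to lag P.
    """
    rep = check_stability(model)
    if not rep.stable:
        raise ValidationError(
            f"model unstable (spectral radius {rep.spectral_radius:.4f}); cannot simulate"
        )
    rng = np.random.default_rng(seed)
    sim = simulate_var(model.A, win.n_samples, rng, sigma=model.sigma)
    r_data = _stacked_correlation(np.asarray(win.samples, dtype=float), model.order)
    r_sim = _stacked_correlation(sim, model.order)
    denom = np.linalg.norm(r_data)
    if denom == 0:
        raise ValidationError("degenerate window: zero correlation structure")
    pct = 100.0 * (1.0 - np.linalg.norm(r_data - r_sim) / denom)
    return float(max(0.0, pct))


def validate(model: MVARModel, win: WindowSegment, lags: int = 20,
             seed: int = 0) -> StabilityReport:
    """Run all three diagnostics and attach the combined report to the model."""
    rep = check_stability(model)
    if rep.stable:
        wt = check_whiteness(model, win, lags=min(lags, win.n_samples - 1))
        rep.whiteness_p = float(wt["p_value"].min())
        rep.consistency_pct = check_consistency(model, win, seed=seed)
    model.diagnostics = rep
    return rep
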