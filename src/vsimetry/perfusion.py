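"""Perfusion and diffusion quantification: ADC, leakage-corrected CBV, rCBV.

ADC comes from an ordinary least-squares fit of log DWI signal against
b-value (monoexponential decay), reported in um^2/ms (1e-3 mm^2/s).

Relative CBV is the trapezoidal integral of the bolus-induced dR2*(t)
curve after contrast-leakage correction, normalized so that the mean over
a contralateral normal-appearing-white-matter (NAWM) mask equals 1.

Leakage correction follows the Boxerman family of linear models: each
voxel curve is regressed against a whole-brain (non-leaky) reference
curve R(t) plus leakage terms,

    dR2*_meas(t) = K1 * R(t) - K2 * L(t),
    L(t) = integral_0^t R(tau) * exp(-k_back * (t - tau)) dtau,

where k_back = 0 gives the classic unidirectional (efflux-only) form and
k_back > 0 lets tracer return to the vasculature (bidirectional).  The
corrected curve adds the fitted leakage term back:
dR2*_corr(t) = dR2*_meas(t) + K2 * L(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DEFAULT_B_VALUES",
    "MonoexponentialAdc",
    "fit_adc",
    "LeakageResult",
    "leakage_correct",
    "compute_cbv",
    "normalize_cbv",
]

#: Diffusion weightings (s/mm^2) of the reference protocol.
DEFAULT_B_VALUES = (0.0, 500.0, 1000.0)

# 1 um^2/ms == 1e-3 mm^2/s; b [s/mm^2] * ADC [um^2/ms] * this factor is unitless
_B_ADC_UNIT = 1e-3


class MonoexponentialAdc(BaseEstimator, TransformerMixin):
    """OLS log-linear ADC estimator, sklearn-transformer style.

    ``transform`` maps DWI signal rows ``(n_samples, n_b)`` to an ADC
    column ``(n_samples, 1)`` in um^2/ms.  Rows containing non-positive
    signals are NaN.

    Parameters
    ----------
    b_values : sequence of floats, s/mm^2
        Must contain at least two distinct non-negative values.
    """

    def __init__(self, b_values=DEFAULT_B_VALUES):
        self.b_values = b_values

    def fit(self, X=None, y=None) -> "MonoexponentialAdc":
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least 2 b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.unique(b).size < 2:
            raise ValueError("b-values must not all be equal")
        self.b_values_ = b
        # precomputed OLS slope weights: slope = w @ ln(S)
        bc = b - b.mean()
        self._slope_weights_ = bc / np.sum(bc**2)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "b_values_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.b_values_.size:
            raise ValueError(
                f"expected (n_samples, {self.b_values_.size}) signals, got {X.shape}"
            )
        out = np.full((X.shape[0], 1), np.nan)
        valid = np.all(X > 0, axis=1) & np.all(np.isfinite(X), axis=1)
        if valid.any():
            slope = np.log(X[valid]) @ self._slope_weights_  # d lnS / db, mm^2/s scale
            out[valid, 0] = -slope / _B_ADC_UNIT  # -> um^2/ms
        return out


def fit_adc(dwi, b_values=DEFAULT_B_VALUES) -> np.ndarray:
    """ADC map (um^2/ms) from a ``(n_b,) + grid`` DWI stack.

    Voxels with any non-positive signal are NaN (masked).
    """
    dwi = np.asarray(dwi, dtype=float)
    est = MonoexponentialAdc(b_values=b_values).fit()
    if dwi.shape[0] != est.b_values_.size:
        raise ValueError(
            f"stack has {dwi.shape[0]} volumes for {est.b_values_.size} b-values"
        )
    grid = dwi.shape[1:]
    rows = dwi.reshape(dwi.shape[0], -1).T
    return est.transform(rows).reshape(grid)


@dataclass
class LeakageResult:
    """Leakage-corrected curves and per-voxel model coefficients."""

    corrected: np.ndarray      # same shape as input (T, ...)
    k1: np.ndarray             # vascular scaling per voxel
    k2: np.ndarray             # leakage amplitude per voxel (a.u.)
    k_back: np.ndarray         # backflux rate per voxel (1/s); 0 if unidirectional
    mode: str = "bidirectional"


def _leakage_kernel(reference: np.ndarray, time_axis: np.ndarray,
                    k_back: float) -> np.ndarray:
    """L(t) = int_0^t R(tau) exp(-k_back (t - tau)) dtau on the sample grid."""
    if k_back == 0.0:
        return cumulative_trapezoid(reference, time_axis, initial=0.0)
    damped = reference * np.exp(k_back * time_axis)
    integ = cumulative_trapezoid(damped, time_axis, initial=0.0)
    return integ * np.exp(-k_back * time_axis)


def leakage_correct(d_r2star_t, reference_curve, mode: str = "bidirectional",
                    time_axis=None,
                    k_back_grid=(0.0, 0.002, 0.005, 0.01, 0.02, 0.05)) -> LeakageResult:
    """Remove contrast-leakage contamination from dR2*(t) curves.

    Parameters
    ----------
    d_r2star_t : ndarray, shape (T,) or (T,) + grid
        Baseline-subtracted dR2* time courses (ms^-1).
    reference_curve : ndarray, shape (T,)
        Mean dR2*(t) over a designated non-leaky mask.
    mode : {'none', 'unidirectional', 'bidirectional'}
        'none' returns the input unchanged; 'unidirectional' uses the
        efflux-only integral term; 'bidirectional' additionally searches a
        small grid of backflux rates k_back per voxel.
    time_axis : seconds, defaults to unit spacing.

    Returns
    -------
    LeakageResult; K2 ~ 0 for voxels without leakage.
    """
    curves = np.asarray(d_r2star_t, dtype=float)
    ref = np.asarray(reference_curve, dtype=float)
    if ref.ndim != 1 or ref.shape[0] != curves.shape[0]:
        raise ValueError("reference curve must be 1-D and match the time axis")
    if mode not in ("none", "unidirectional", "bidirectional"):
        raise ValueError(f"unknown leakage mode {mode!r}")

    shape = curves.shape
    flat = np.nan_to_num(curves.reshape(shape[0], -1))
    n_vox = flat.shape[1]

    if mode == "none":
        zeros = np.zeros(n_vox).reshape(shape[1:] if len(shape) > 1 else ())
        return LeakageResult(corrected=curves.copy(), k1=np.ones_like(zeros),
                             k2=zeros, k_back=np.zeros_like(zeros), mode=mode)

    if time_axis is None:
        time_axis = np.arange(shape[0], dtype=float)
    time_axis = np.asarray(time_axis, dtype=float)
    if not np.all(np.isfinite(ref)):
        raise ValueError("reference curve contains non-finite values")
    if np.allclose(ref, 0):
        raise ValueError("degenerate (all-zero) reference curve")

    grid = (0.0,) if mode == "unidirectional" else tuple(k_back_grid)
    best_sse = np.full(n_vox, np.inf)
    best = {"k1": np.zeros(n_vox), "k2": np.zeros(n_vox),
            "kb": np.zeros(n_vox), "corr": np.empty_like(flat)}
    for kb in grid:
        L = _leakage_kernel(ref, time_axis, kb)
        design = np.column_stack([ref, -L])          # meas = K1*ref - K2*L
        coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
        resid = flat - design @ coef
        sse = np.sum(resid**2, axis=0)
        better = sse < best_sse - 1e-15
        if np.any(better):
            best_sse[better] = sse[better]
            best["k1"][better] = coef[0, better]
            best["k2"][better] = coef[1, better]
            best["kb"][better] = kb
            best["corr"][:, better] = flat[:, better] + coef[1, better] * L[:, None]
    corrected = best["corr"].reshape(shape)
    corrected = np.where(np.isfinite(curves), corrected, np.nan)
    out_shape = shape[1:] if len(shape) > 1 else ()
    return LeakageResult(
        corrected=corrected,
        k1=best["k1"].reshape(out_shape),
        k2=best["k2"].reshape(out_shape),
        k_back=best["kb"].reshape(out_shape),
        mode=mode,
    )


def compute_cbv(corrected_curve, time_axis, integration_window=None) -> np.ndarray:
    """Trapezoidal integral of dR2*(t) over the integration window (raw CBV, a.u.).

    ``integration_window`` is a (start, stop) index pair, stop exclusive;
    default integrates the full series.  Scalar per voxel; works on (T,) or
    (T,) + grid arrays.
    """
    curve = np.asarray(corrected_curve, dtype=float)
    time_axis = np.asarray(time_axis, dtype=float)
    if time_axis.shape[0] != curve.shape[0]:
        raise ValueError("time axis length must match the curve")
    if integration_window is None:
        integration_window = (0, curve.shape[0])
    i0, i1 = int(integration_window[0]), int(integration_window[1])
    if not (0 <= i0 < i1 <= curve.shape[0]) or i1 - i0 < 2:
        raise ValueError(f"integration window {integration_window} too short")
    return np.trapezoid(curve[i0:i1], time_axis[i0:i1], axis=0)


def normalize_cbv(cbv_raw, nawm_mask) -> np.ndarray:
    """rCBV = raw CBV / mean over the NAWM mask (NAWM mean becomes 1)."""
    cbv = np.asarray(cbv_raw, dtype=float)
    mask = np.asarray(nawm_mask, dtype=bool)
    if mask.shape != cbv.shape:
        raise ValueError("NAWM mask must match the CBV grid")
    if not mask.any():
        raise ValueError("empty NAWM mask")
    ref = np.nanmean(cbv[mask])
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"non-positive NAWM mean CBV ({ref}); cannot normalize")
    return cbv / ref
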