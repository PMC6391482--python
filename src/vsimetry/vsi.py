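"""Vessel size index from combined gradient-echo / spin-echo DSC contrast.

The Kiselev-family model estimates the average vessel caliber per voxel as

    VSI [um] = k * sqrt(rCBV * ADC) * dR2*_max / dR2_max^{3/2}

with ADC in um^2/ms and both relaxation-rate peaks in ms^-1, so the
expression is dimensionally a length in micrometres
((um^2/ms)^{1/2} * ms^{1/2} = um).  The gradient-echo peak dR2* is
sensitive to vessels of all sizes while the spin-echo peak dR2 is
capillary-weighted; their ratio therefore grows with vessel caliber.

The proportionality constant ``k`` (default 0.867) has not been
exhaustively validated against tissue, so it is an explicit parameter.
The exponent grouping is dR2* divided by (dR2)^{3/2} — the alternative
reading (dR2*/dR2)^{3/2} is dimensionally inconsistent here and is not
offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["DEFAULT_VSI_CONSTANT", "VsiMap", "VesselSizeIndex", "compute_vsi"]

DEFAULT_VSI_CONSTANT = 0.867


@dataclass
class VsiMap:
    """Vessel size index volume (um) with its validity mask."""

    vsi: np.ndarray
    valid: np.ndarray
    constant_k: float = DEFAULT_VSI_CONSTANT


class VesselSizeIndex(BaseEstimator, TransformerMixin):
    """sklearn-style transformer computing VSI from feature rows.

    ``transform`` takes rows ``[rcbv, adc, d_r2star_max, d_r2_max]`` of
    shape ``(n_samples, 4)`` and returns a ``(n_samples, 1)`` VSI column
    in um.  Rows are NaN where the model is undefined: dR2 peak <= 0,
    negative rCBV*ADC product, or negative dR2* peak.  A zero rCBV (or
    zero ADC or zero dR2*) gives a valid VSI of 0.
    """

    def __init__(self, constant_k: float = DEFAULT_VSI_CONSTANT):
        self.constant_k = constant_k

    def fit(self, X=None, y=None) -> "VesselSizeIndex":
        if not np.isfinite(self.constant_k) or self.constant_k <= 0:
            raise ValueError("constant_k must be a positive finite number")
        self.constant_k_ = float(self.constant_k)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "constant_k_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError(f"expected (n_samples, 4) features, got {X.shape}")
        rcbv, adc, dr2s, dr2 = X.T
        product = rcbv * adc
        valid = (
            np.isfinite(product) & np.isfinite(dr2s) & np.isfinite(dr2)
            & (product >= 0) & (dr2s >= 0) & (dr2 > 0)
        )
        out = np.full((X.shape[0], 1), np.nan)
        with np.errstate(invalid="ignore"):
            out[valid, 0] = (
                self.constant_k_ * np.sqrt(product[valid])
                * dr2s[valid] / dr2[valid] ** 1.5
            )
        return out


def compute_vsi(rcbv, adc, d_r2star_max, d_r2_max,
                constant_k: float = DEFAULT_VSI_CONSTANT) -> VsiMap:
    """Voxelwise VSI map from co-registered rCBV, ADC and peak-rate maps.

    All inputs must share one grid (broadcast is not attempted: a shape
    mismatch is a registration error and raises).  Returns a `VsiMap`
    whose ``vsi`` is NaN where invalid.
    """
    arrays = [np.asarray(a, dtype=float) for a in (rcbv, adc, d_r2star_max, d_r2_max)]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays[1:]):
        raise ValueError(
            "grid mismatch: " + ", ".join(str(a.shape) for a in arrays)
        )
    X = np.column_stack([a.reshape(-1) for a in arrays])
    col = VesselSizeIndex(constant_k=constant_k).fit().transform(X)[:, 0]
    vsi = col.reshape(shape)
    return VsiMap(vsi=vsi, valid=np.isfinite(vsi), constant_k=float(constant_k))
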