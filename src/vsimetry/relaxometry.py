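"""Four-echo SAGE-EPI relaxometry.

A spin-and-gradient-echo (SAGE) EPI shot acquires two gradient echoes
(TE1, TE2) before the refocusing pulse, an asymmetric spin echo (TE3) and
the spin echo itself (TE4).  For a monoexponential signal model the log
signals are linear in the unknowns ``A = [ln S0, ln delta, R2*, R2]``,
where ``delta`` absorbs the residual signal offset between the pre- and
post-refocusing echo trains caused by imperfectly matched slice profiles:

    ln S1 = ln S0            - TE1 * R2*
    ln S2 = ln S0            - TE2 * R2*
    ln S3 = ln S0 - ln delta - (TE4 - TE3) * R2* - (2*TE3 - TE4) * R2
    ln S4 = ln S0 - ln delta                     - TE4 * R2

The 4x4 system is exactly determined, so per-voxel, per-timepoint
inversion is a single matrix solve — no iterative fitting.  All rates are
expressed in ms^-1 and echo times in ms; with ADC in um^2/ms these units
make the vessel size index come out directly in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DEFAULT_ECHO_TIMES",
    "EchoTimes",
    "SageFit",
    "SageSeriesFit",
    "RelaxogramSeries",
    "design_matrix",
    "SageInverter",
    "fit_sage_voxel",
    "fit_sage_series",
    "detect_bolus_arrival",
    "default_baseline_window",
    "delta_curves",
]

#: Echo times (ms) of the reference SAGE-EPI acquisition: two gradient
#: echoes, the asymmetric spin echo, and the spin echo.
DEFAULT_ECHO_TIMES = (14.0, 34.1, 58.0, 92.4)

# fitted delta outside this band is physically suspicious (slice-profile
# mismatch should be a small multiplicative residual)
DELTA_QC_RANGE = (0.8, 1.5)


@dataclass(frozen=True)
class EchoTimes:
    """The four SAGE echo times in ms.

    ``te3`` is the asymmetric spin echo and must fall after the
    refocusing-symmetric midpoint, i.e. ``te3 > te4 / 2``, so that the
    ``TE4 - 2*TE3`` design coefficient is negative (as it is for the
    reference 14.0/34.1/58.0/92.4 ms protocol).
    """

    te1: float
    te2: float
    te3: float
    te4: float

    def __post_init__(self) -> None:
        tes = (self.te1, self.te2, self.te3, self.te4)
        if not all(np.isfinite(tes)):
            raise ValueError("echo times must be finite")
        if not (0 < self.te1 < self.te2 < self.te3 < self.te4):
            raise ValueError(
                f"echo times must satisfy 0 < TE1 < TE2 < TE3 < TE4, got {tes}"
            )
        if not self.te3 > self.te4 / 2:
            raise ValueError(
                "asymmetric spin echo must satisfy TE3 > TE4/2 "
                f"(got TE3={self.te3}, TE4={self.te4})"
            )

    @classmethod
    def from_sequence(cls, tes) -> "EchoTimes":
        if isinstance(tes, EchoTimes):
            return tes
        tes = tuple(float(t) for t in tes)
        if len(tes) != 4:
            raise ValueError(f"exactly 4 echo times required, got {len(tes)}")
        return cls(*tes)

    def as_array(self) -> np.ndarray:
        return np.array([self.te1, self.te2, self.te3, self.te4])


@dataclass(frozen=True)
class SageFit:
    """Per-voxel SAGE parameters: S0 (a.u.), delta (unitless), rates in ms^-1."""

    s0: float
    delta: float
    r2star: float
    r2: float

    @property
    def delta_in_range(self) -> bool:
        return DELTA_QC_RANGE[0] <= self.delta <= DELTA_QC_RANGE[1]


def design_matrix(tes) -> np.ndarray:
    """Coefficient matrix ``Y`` mapping ``[ln S0, ln delta, R2*, R2]`` to log signals.

    Rows (one per echo)::

        [1,  0, -TE1,          0         ]
        [1,  0, -TE2,          0         ]
        [1, -1, -TE4 + TE3,    TE4 - 2*TE3]
        [1, -1,  0,           -TE4       ]
    """
    t = EchoTimes.from_sequence(tes)
    Y = np.array(
        [
            [1.0, 0.0, -t.te1, 0.0],
            [1.0, 0.0, -t.te2, 0.0],
            [1.0, -1.0, -t.te4 + t.te3, t.te4 - 2.0 * t.te3],
            [1.0, -1.0, 0.0, -t.te4],
        ]
    )
    # structurally invertible for any valid EchoTimes; guard regardless
    if abs(np.linalg.det(Y)) < 1e-12:
        raise np.linalg.LinAlgError("singular SAGE design matrix")
    return Y


class SageInverter(BaseEstimator, TransformerMixin):
    """Exact per-sample inversion of the four-echo SAGE signal model.

    A stateless sklearn-style transformer: ``fit`` precomputes the design
    matrix and its inverse from the echo times, ``transform`` maps signal
    rows to parameter rows.

    Parameters
    ----------
    echo_times : sequence of 4 floats, ms
        TE1 < TE2 < TE3 (asymmetric spin echo) < TE4 (spin echo).

    Attributes
    ----------
    echo_times_ : EchoTimes
    design_matrix_ : (4, 4) ndarray
    inverse_design_ : (4, 4) ndarray

    Examples
    --------
    >>> inv = SageInverter().fit()
    >>> params = inv.transform(signals)   # signals: (n_samples, 4) -> (n_samples, 4)

    Output columns are ``[s0, delta, r2star, r2]``; rows with any
    non-positive signal are returned as NaN (masked, not raised).
    """

    def __init__(self, echo_times=DEFAULT_ECHO_TIMES):
        self.echo_times = echo_times

    def fit(self, X=None, y=None) -> "SageInverter":
        self.echo_times_ = EchoTimes.from_sequence(self.echo_times)
        self.design_matrix_ = design_matrix(self.echo_times_)
        self.inverse_design_ = np.linalg.inv(self.design_matrix_)
        return self

    def transform(self, X) -> np.ndarray:
        """Invert signal rows ``(n, 4)`` to ``[s0, delta, r2star, r2]`` rows."""
        if not hasattr(self, "inverse_design_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError(f"expected (n_samples, 4) signal array, got {X.shape}")
        valid = np.all(X > 0, axis=1) & np.all(np.isfinite(X), axis=1)
        out = np.full((X.shape[0], 4), np.nan)
        if valid.any():
            lnS = np.log(X[valid])
            A = lnS @ self.inverse_design_.T  # rows: [lnS0, ln delta, R2*, R2]
            out[valid, 0] = np.exp(A[:, 0])
            out[valid, 1] = np.exp(A[:, 1])
            out[valid, 2] = A[:, 2]
            out[valid, 3] = A[:, 3]
        return out

    def forward(self, s0, delta, r2star, r2) -> np.ndarray:
        """Forward model: broadcastable parameters -> signals, shape (..., 4)."""
        if not hasattr(self, "design_matrix_"):
            self.fit()
        s0, delta, r2star, r2 = np.broadcast_arrays(
            *(np.asarray(a, dtype=float) for a in (s0, delta, r2star, r2))
        )
        A = np.stack([np.log(s0), np.log(delta), r2star, r2], axis=-1)
        return np.exp(A @ self.design_matrix_.T)


def fit_sage_voxel(signals, tes=DEFAULT_ECHO_TIMES) -> SageFit:
    """Fit one voxel's four echo signals; raises on non-positive signals."""
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (4,):
        raise ValueError("fit_sage_voxel expects exactly 4 signals")
    if np.any(signals <= 0):
        raise ValueError("all 4 signals must be positive (log-linear inversion)")
    row = SageInverter(echo_times=tes).fit().transform(signals[None, :])[0]
    return SageFit(s0=row[0], delta=row[1], r2star=row[2], r2=row[3])


@dataclass
class SageSeriesFit:
    """Per-voxel SAGE parameters over time.

    All arrays are shaped ``(n_timepoints,) + grid_shape``; voxels outside
    the mask or with non-positive signals are NaN.
    """

    s0: np.ndarray
    delta: np.ndarray
    r2star: np.ndarray
    r2: np.ndarray
    mask: np.ndarray
    invalid_fraction: float
    #: max percent variation of fitted delta over time (median across voxels);
    #: diagnostic for slice-profile stability, no hard threshold.
    delta_variation_pct: float = float("nan")


def fit_sage_series(stack, tes=DEFAULT_ECHO_TIMES, mask=None) -> SageSeriesFit:
    """Invert a ``(4, n_timepoints) + grid`` SAGE stack voxel by voxel.

    Parameters
    ----------
    stack : ndarray, shape (4, T, ...)
        Echo-major signal stack (echo, time, spatial...).
    mask : boolean ndarray matching the spatial grid, optional.

    Returns
    -------
    SageSeriesFit with NaN outside the mask / at invalid voxels, the
    invalid-fit fraction among in-mask samples, and a delta-stability
    diagnostic.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 2 or stack.shape[0] != 4:
        raise ValueError(f"expected stack shaped (4, T, ...), got {stack.shape}")
    n_t = stack.shape[1]
    grid = stack.shape[2:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid}")

    inv = SageInverter(echo_times=tes).fit()
    # (4, T, V) -> (T*V, 4) for the masked voxels
    flat = stack.reshape(4, n_t, -1)[:, :, mask.reshape(-1)]
    n_vox = flat.shape[2]
    rows = np.moveaxis(flat, 0, -1).reshape(n_t * n_vox, 4)
    params = inv.transform(rows).reshape(n_t, n_vox, 4)

    out = {k: np.full((n_t,) + grid, np.nan) for k in ("s0", "delta", "r2star", "r2")}
    flat_idx = np.flatnonzero(mask.reshape(-1))
    for i, key in enumerate(("s0", "delta", "r2star", "r2")):
        out[key].reshape(n_t, -1)[:, flat_idx] = params[:, :, i]

    n_samples = n_t * n_vox
    invalid = int(np.isnan(params[:, :, 0]).sum())
    invalid_fraction = invalid / n_samples if n_samples else 0.0

    delta_var = float("nan")
    if n_vox:
        d = params[:, :, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dmean = np.nanmean(d, axis=0)
            spread = np.nanmax(d, axis=0) - np.nanmin(d, axis=0)
            pct = 100.0 * spread / dmean
            if np.isfinite(pct).any():
                delta_var = float(np.nanmedian(pct))

    return SageSeriesFit(
        s0=out["s0"], delta=out["delta"], r2star=out["r2star"], r2=out["r2"],
        mask=mask, invalid_fraction=invalid_fraction, delta_variation_pct=delta_var,
    )


@dataclass
class RelaxogramSeries:
    """Baseline-referenced relaxation-rate dynamics.

    ``d_r2star_t`` / ``d_r2_t`` are R2*(t) and R2(t) minus their means over
    the pre-bolus baseline window.  Peak maps are the post-baseline maxima
    of the (optionally smoothed) delta curves; voxels whose peaks are not
    positive are NaN in the peak maps and False in ``valid_peaks`` rather
    than clipped to zero, so they cannot masquerade as zero-caliber tissue.
    """

    r2star_t: np.ndarray
    r2_t: np.ndarray
    baseline_window: tuple
    d_r2star_t: np.ndarray = field(repr=False, default=None)
    d_r2_t: np.ndarray = field(repr=False, default=None)
    d_r2star_max: np.ndarray = None
    d_r2_max: np.ndarray = None
    valid_peaks: np.ndarray = None


def _moving_average3(curve: np.ndarray) -> np.ndarray:
    """3-point moving average along axis 0, edges kept unsmoothed."""
    out = curve.copy()
    if curve.shape[0] >= 3:
        out[1:-1] = (curve[:-2] + curve[1:-1] + curve[2:]) / 3.0
    return out


def detect_bolus_arrival(curve: np.ndarray, n_baseline_guess: int = 10,
                         threshold_sd: float = 5.0) -> int:
    """First timepoint where a mean delta-curve exceeds ``threshold_sd`` baseline SDs.

    Standard DSC arrival detection: a provisional baseline over the first
    ``n_baseline_guess`` samples defines mean and SD; arrival is the first
    later sample exceeding mean + threshold_sd * SD.  Returns the last index
    if nothing crosses (no bolus).
    """
    curve = np.asarray(curve, dtype=float)
    n0 = min(n_baseline_guess, max(3, curve.shape[0] // 4))
    base = curve[:n0]
    mu, sd = float(np.nanmean(base)), float(np.nanstd(base))
    sd = max(sd, 1e-12)
    above = np.flatnonzero(curve[n0:] > mu + threshold_sd * sd)
    return int(n0 + above[0]) if above.size else int(curve.shape[0] - 1)


def default_baseline_window(arrival_index: int, start: int = 5, gap: int = 3) -> tuple:
    """Default pre-bolus window: timepoints ``start`` .. ``arrival - gap`` (exclusive stop)."""
    stop = arrival_index - gap + 1
    if stop - start < 3:
        raise ValueError(
            f"cannot form a >=3-point baseline window before arrival at {arrival_index}"
        )
    return (start, stop)


def delta_curves(series: SageSeriesFit, baseline_window=None, smooth: bool = True,
                 arrival_threshold_sd: float = 5.0) -> RelaxogramSeries:
    """Baseline-subtract R2*(t), R2(t) and extract bolus peak maps.

    Parameters
    ----------
    series : SageSeriesFit
    baseline_window : (start, stop) timepoint indices (stop exclusive), or None
        to auto-detect: window from timepoint 5 to three samples before the
        detected bolus arrival.
    smooth : apply a 3-point moving average before peak extraction.

    Raises
    ------
    ValueError if the window is shorter than 3 samples or overlaps the bolus
    (the in-window curve exceeding ``arrival_threshold_sd`` baseline SDs).
    """
    r2s, r2 = series.r2star, series.r2
    n_t = r2s.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_curve = np.nanmean(r2s.reshape(n_t, -1), axis=1)
    mean_curve = np.where(np.isfinite(mean_curve), mean_curve, 0.0)

    if baseline_window is None:
        arrival = detect_bolus_arrival(mean_curve, threshold_sd=arrival_threshold_sd)
        baseline_window = default_baseline_window(arrival)
    start, stop = int(baseline_window[0]), int(baseline_window[1])
    if not (0 <= start < stop <= n_t):
        raise ValueError(f"baseline window {baseline_window} outside series of {n_t}")
    if stop - start < 3:
        raise ValueError("baseline window must span at least 3 timepoints")

    arrival = detect_bolus_arrival(mean_curve, threshold_sd=arrival_threshold_sd)
    crossing_found = arrival < n_t - 1
    if crossing_found and stop > arrival + 1:
        warnings.warn("baseline window overlaps the bolus", stacklevel=2)
        raise ValueError(
            f"baseline window {baseline_window} extends past the detected bolus "
            f"arrival at timepoint {arrival}; choose an earlier window"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d_r2s = r2s - np.nanmean(r2s[start:stop], axis=0)
        d_r2 = r2 - np.nanmean(r2[start:stop], axis=0)

    sm_s = _moving_average3(d_r2s) if smooth else d_r2s
    sm_2 = _moving_average3(d_r2) if smooth else d_r2
    post = slice(stop, n_t) if stop < n_t else slice(0, n_t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        peak_s = np.nanmax(sm_s[post], axis=0)
        peak_2 = np.nanmax(sm_2[post], axis=0)

    valid = np.isfinite(peak_s) & np.isfinite(peak_2) & (peak_s >= 0) & (peak_2 >= 0)
    peak_s = np.where(valid, peak_s, np.nan)
    peak_2 = np.where(valid, peak_2, np.nan)

    return RelaxogramSeries(
        r2star_t=r2s, r2_t=r2, baseline_window=(start, stop),
        d_r2star_t=d_r2s, d_r2_t=d_r2,
        d_r2star_max=peak_s, d_r2_max=peak_2, valid_peaks=valid,
    )
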