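"""Digital phantoms: SAGE-EPI DSC time series and multi-b DWI with ground truth.

The phantom is a labeled 3-D grid (tumor / normal-appearing white matter /
background).  Each tissue class carries baseline relaxation rates, proton
signal S0, the slice-profile factor delta, true ADC, bolus peak effects
(peak dR2* for gradient echo, peak dR2 for spin echo) and an optional
leakage rate.  The forward model is exactly the four-echo SAGE log-linear
signal model with time-varying rates

    R2*(t) = R2*_0 + peak_dR2* . b(t) - leakage_rate . int_0^t b,
    R2(t)  = R2_0  + peak_dR2  . b(t),

where ``b`` is the unit-peak bolus curve — so the dR2*/dR2 ratio, and
hence the ground-truth vessel size index, is constant per class.  Noise
is additive Gaussian per echo (a documented simplification of Rician
magnitude noise; at the simulated SNR the log-domain inversion is
unaffected by the distinction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ..relaxometry import DEFAULT_ECHO_TIMES, SageInverter
from ..vsi import DEFAULT_VSI_CONSTANT
from .bolus import BolusModel, gamma_variate_bolus

__all__ = ["TissueClass", "PhantomSpec", "GroundTruth", "SimulatedSage",
           "default_phantom", "simulate_sage_dataset", "simulate_dwi"]


@dataclass(frozen=True)
class TissueClass:
    """Per-class ground-truth parameters (rates ms^-1, ADC um^2/ms)."""

    baseline_r2star: float
    baseline_r2: float
    s0: float
    delta: float
    adc: float
    peak_dr2star: float = 0.0
    peak_dr2: float = 0.0
    leakage_rate: float = 0.0   # ms^-1 per second of accumulated bolus exposure

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1 (slice-profile residual)")
        if min(self.baseline_r2star, self.baseline_r2, self.s0, self.adc) <= 0:
            raise ValueError("rates, S0 and ADC must be positive")
        if self.peak_dr2star < self.peak_dr2:
            raise ValueError("gradient-echo effect must be >= spin-echo effect "
                             "(peak_dr2star >= peak_dr2)")
        if min(self.peak_dr2star, self.peak_dr2) < 0 or self.leakage_rate < 0:
            raise ValueError("peaks and leakage rate must be non-negative")

    def true_vsi(self, rcbv: float, constant_k: float = DEFAULT_VSI_CONSTANT) -> float:
        """Class ground-truth VSI (um) given the class's true rCBV ratio."""
        if self.peak_dr2 <= 0:
            return float("nan")
        return constant_k * np.sqrt(rcbv * self.adc) * \
            self.peak_dr2star / self.peak_dr2 ** 1.5


#: Defaults anchored at in-vivo scale: tumor ADC 1.30 um^2/ms and a 2x NAWM
#: blood-volume signal (true rCBV 2), NAWM normalized to rCBV 1.
DEFAULT_CLASSES = {
    "background": TissueClass(baseline_r2star=0.005, baseline_r2=0.004, s0=60.0,
                              delta=1.0, adc=3.0),
    "nawm": TissueClass(baseline_r2star=0.020, baseline_r2=0.012, s0=1000.0,
                        delta=1.05, adc=0.80, peak_dr2star=0.05, peak_dr2=0.04),
    "tumor": TissueClass(baseline_r2star=0.022, baseline_r2=0.013, s0=1100.0,
                         delta=1.05, adc=1.30, peak_dr2star=0.10, peak_dr2=0.05),
}
LABEL_CODES = {"background": 0, "nawm": 1, "tumor": 2}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + per-class parameters + noise for the digital phantom."""

    grid_shape: tuple = (32, 32, 8)
    voxel_size_mm: tuple = (1.875, 1.875, 5.0)
    classes: dict = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    noise_sigma: float = 0.0       # additive Gaussian, signal a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        missing = set(LABEL_CODES) - set(self.classes)
        if missing:
            raise ValueError(f"missing tissue classes: {sorted(missing)}")

    def label_volume(self) -> np.ndarray:
        """Default geometry: background shell, NAWM left, tumor sphere right."""
        nx, ny, nz = self.grid_shape
        labels = np.zeros(self.grid_shape, dtype=np.int8)
        labels[2:-2, 2:-2, 1:-1] = LABEL_CODES["nawm"]
        cx, cy, cz = int(nx * 0.68), ny // 2, nz // 2
        rx = max(nx // 6, 2)
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        sphere = ((ii - cx) / rx) ** 2 + ((jj - cy) / rx) ** 2 + \
                 ((kk - cz) / max(nz // 4, 1)) ** 2 <= 1.0
        labels[sphere & (labels > 0)] = LABEL_CODES["tumor"]
        return labels

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def class_map(self, name_to_value) -> np.ndarray:
        """Per-voxel map from a per-class scalar function."""
        labels = self.label_volume()
        out = np.zeros(self.grid_shape, dtype=float)
        for name, code in LABEL_CODES.items():
            out[labels == code] = name_to_value(self.classes[name])
        return out


def default_phantom(**overrides) -> PhantomSpec:
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


@dataclass
class GroundTruth:
    """Everything the simulator knew, for oracle-style downstream checks."""

    labels: np.ndarray
    s0: np.ndarray
    delta: np.ndarray
    r2star0: np.ndarray
    r20: np.ndarray
    adc: np.ndarray
    peak_dr2star: np.ndarray
    peak_dr2: np.ndarray
    leakage_rate: np.ndarray
    bolus_curve: np.ndarray          # unit-peak b(t)
    time_axis_s: np.ndarray
    d_r2star_t: np.ndarray           # (T,) + grid, leakage included
    d_r2_t: np.ndarray
    cbv_true: np.ndarray             # integral of peak * b(t), leakage-free
    echo_times: tuple
    classes: dict


@dataclass
class SimulatedSage:
    signal: np.ndarray               # (4, T) + grid
    truth: GroundTruth
    tr_ms: float


def simulate_sage_dataset(phantom: PhantomSpec, bolus: BolusModel | None = None,
                          echo_times=DEFAULT_ECHO_TIMES, tr_ms: float = 2000.0,
                          n_timepoints: int = 90) -> SimulatedSage:
    """Forward-model a 4-echo SAGE DSC acquisition over the phantom.

    Returns the (4, T) + grid signal stack and the full ground-truth
    bundle.  With ``noise_sigma = 0`` and no bolus the signals are
    time-constant per echo.
    """
    if bolus is None:
        bolus = BolusModel()
    inv = SageInverter(echo_times=echo_times).fit()
    t_s = np.arange(n_timepoints, dtype=float) * (tr_ms / 1000.0)
    b = gamma_variate_bolus(t_s, bolus)
    b_cum = cumulative_trapezoid(b, t_s, initial=0.0)

    maps = {name: phantom.class_map(lambda c, k=name: getattr(c, k))
            for name in ("s0", "delta", "adc", "leakage_rate")}
    maps["r2star0"] = phantom.class_map(lambda c: c.baseline_r2star)
    maps["r20"] = phantom.class_map(lambda c: c.baseline_r2)
    maps["peak_dr2star"] = phantom.class_map(lambda c: c.peak_dr2star)
    maps["peak_dr2"] = phantom.class_map(lambda c: c.peak_dr2)

    shape_t = (n_timepoints,) + phantom.grid_shape
    d_r2s = maps["peak_dr2star"][None] * b.reshape(-1, *([1] * len(phantom.grid_shape)))
    d_r2s = d_r2s - maps["leakage_rate"][None] * \
        b_cum.reshape(-1, *([1] * len(phantom.grid_shape)))
    d_r2 = maps["peak_dr2"][None] * b.reshape(-1, *([1] * len(phantom.grid_shape)))

    r2star_t = maps["r2star0"][None] + d_r2s
    r2_t = maps["r20"][None] + d_r2
    sig = inv.forward(
        np.broadcast_to(maps["s0"], shape_t),
        np.broadcast_to(maps["delta"], shape_t),
        r2star_t, r2_t,
    )                                           # (T,) + grid + (4,)
    signal = np.moveaxis(sig, -1, 0)            # (4, T) + grid
    if phantom.noise_sigma > 0:
        rng = np.random.default_rng(phantom.seed)
        signal = signal + rng.normal(0.0, phantom.noise_sigma, signal.shape)

    truth = GroundTruth(
        labels=phantom.label_volume(), s0=maps["s0"], delta=maps["delta"],
        r2star0=maps["r2star0"], r20=maps["r20"], adc=maps["adc"],
        peak_dr2star=maps["peak_dr2star"], peak_dr2=maps["peak_dr2"],
        leakage_rate=maps["leakage_rate"], bolus_curve=b, time_axis_s=t_s,
        d_r2star_t=d_r2s, d_r2_t=d_r2,
        cbv_true=maps["peak_dr2star"] * np.trapezoid(b, t_s),
        echo_times=tuple(inv.echo_times_.as_array()), classes=dict(phantom.classes),
    )
    return SimulatedSage(signal=signal, truth=truth, tr_ms=tr_ms)


def simulate_dwi(adc_map, s0_map, b_values=(0.0, 500.0, 1000.0),
                 noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Monoexponential DWI stack ``(n_b,) + grid``: S(b) = S0 exp(-b ADC).

    ADC in um^2/ms, b in s/mm^2 (the product is scaled by 1e-3 to be
    dimensionless).  b-values must be non-negative and include b = 0.
    """
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if not np.any(b == 0):
        raise ValueError("b-values must include b = 0")
    adc = np.asarray(adc_map, dtype=float)
    s0 = np.asarray(s0_map, dtype=float)
    stack = s0[None] * np.exp(-b.reshape(-1, *([1] * adc.ndim)) * adc[None] * 1e-3)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sigma, stack.shape)
    return stack
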