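"""Latent-variable cohorts of paired MRI / histology biopsy targets.

Draws per-target (rCBV, vessel density) and (VSI_MRI, VSI_histology)
pairs from bivariate normal models with requested correlations, at the
scale of an in-vivo high-grade-glioma validation cohort (26 targets;
rCBV ~ 1.4, density ~ 40 /mm^2, calibers ~ 13 um).  Used to test that the
statistics stage recovers known population correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..stats import TargetRecord

__all__ = ["CohortModel", "make_paired_cohort"]


@dataclass(frozen=True)
class CohortModel:
    """Population model for the paired cohort (means/SDs at in-vivo scale)."""

    rho_density: float = 0.42     # corr(rCBV, density)
    rho_caliber: float = 0.49     # corr(VSI_MRI, VSI_histo)
    rcbv_mean: float = 1.39
    rcbv_sd: float = 0.55
    density_mean: float = 40.6    # /mm^2
    density_sd: float = 18.0
    vsi_mri_mean: float = 13.67   # um
    vsi_mri_sd: float = 2.3
    vsi_histo_mean: float = 12.60 # um
    vsi_histo_sd: float = 2.0
    adc_mean: float = 1.30        # um^2/ms
    adc_sd: float = 0.35
    grade_iv_fraction: float = 10 / 26

    def __post_init__(self) -> None:
        if abs(self.rho_density) > 1 or abs(self.rho_caliber) > 1:
            raise ValueError("|rho| must be <= 1")


def _bivariate(rng, n, rho):
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal(n)
    return z1, z2


def make_paired_cohort(n_targets: int = 26, model: CohortModel | None = None,
                       seed: int = 0, **model_overrides):
    """Generate ``n_targets`` paired TargetRecords plus the latent truth.

    Returns ``(records, truth)`` where ``truth`` holds the latent
    standard-normal draws and the model, for oracle-style checks.
    Values are floored at small positive numbers (physical quantities);
    at the default means this truncation is negligible.
    """
    if n_targets < 3:
        raise ValueError("need at least 3 targets")
    if model is None:
        model = CohortModel(**model_overrides)
    elif model_overrides:
        raise ValueError("pass either a model or overrides, not both")
    rng = np.random.default_rng(seed)

    zr, zd = _bivariate(rng, n_targets, model.rho_density)
    zm, zh = _bivariate(rng, n_targets, model.rho_caliber)
    rcbv = np.maximum(model.rcbv_mean + model.rcbv_sd * zr, 0.05)
    density = np.maximum(model.density_mean + model.density_sd * zd, 1.0)
    vsi_mri = np.maximum(model.vsi_mri_mean + model.vsi_mri_sd * zm, 1.0)
    vsi_histo = np.maximum(model.vsi_histo_mean + model.vsi_histo_sd * zh, 1.0)
    adc = np.maximum(model.adc_mean + model.adc_sd * rng.standard_normal(n_targets), 0.2)

    n_iv = int(round(model.grade_iv_fraction * n_targets))
    grades = np.array(["III"] * (n_targets - n_iv) + ["IV"] * n_iv)
    rng.shuffle(grades)

    records = [
        TargetRecord(
            target_id=f"T{i:02d}", grade=str(grades[i]),
            rcbv=float(rcbv[i]), adc=float(adc[i]), vsi_mri=float(vsi_mri[i]),
            density=float(density[i]), vsi_histo=float(vsi_histo[i]),
            vessel_count=float(np.round(density[i] * 2.2)),
        )
        for i in range(n_targets)
    ]
    truth = {"model": model, "z": {"rcbv": zr, "density": zd,
                                   "vsi_mri": zm, "vsi_histo": zh}}
    return records, truth
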