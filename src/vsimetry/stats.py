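"""Per-target extraction and MRI-vs-histology agreement statistics.

Biopsy targets are 5-mm-radius spheres in scanner coordinates; the MRI
summary of a map over a target is the median across all voxels whose
centers fall inside the sphere.  Agreement between per-target MRI values
(rCBV, VSI) and histology morphometry (vessel density, cylinder-model
caliber) is assessed with Pearson correlation, Bland–Altman limits of
agreement, Mann–Whitney grade comparisons, Shapiro–Wilk normality checks
and a Student's t-test on the paired caliber difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TargetRecord",
    "BlandAltman",
    "AgreementReport",
    "extract_target",
    "bland_altman",
    "correlate",
    "group_compare",
    "paired_t",
    "build_report",
]


@dataclass
class TargetRecord:
    """Paired MRI and histology measurements for one biopsy target."""

    target_id: str
    grade: str                      # WHO grade, "III" or "IV"
    rcbv: float = float("nan")      # median over the target sphere
    adc: float = float("nan")       # um^2/ms
    vsi_mri: float = float("nan")   # um
    density: float = float("nan")   # vessels / mm^2
    vsi_histo: float = float("nan") # um
    vessel_count: float = float("nan")
    center_mm: tuple | None = None
    radius_mm: float = 5.0


def extract_target(volume, affine, center_mm, radius_mm: float = 5.0,
                   mask=None, statistic: str = "median"):
    """Summarize a map over a spherical target.

    Sphere membership is by voxel-center Euclidean distance in the
    scanner frame given by the NIfTI-style ``affine``.  NaN voxels and
    voxels outside ``mask`` are excluded.

    Returns
    -------
    (value, n_voxels); raises if the sphere contains no valid voxel.
    """
    volume = np.asarray(volume, dtype=float)
    affine = np.asarray(affine, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in volume.shape], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
    inside = np.linalg.norm(xyz - center, axis=1) <= radius_mm
    values = volume.reshape(-1)[inside]
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool).reshape(-1)[inside]]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError(f"no valid voxels inside target at {tuple(center)}")
    stat = np.median if statistic == "median" else np.mean
    return float(stat(values)), int(values.size)


@dataclass
class BlandAltman:
    """Mean difference and ±1.96 SD limits of agreement (sample SD, n−1)."""

    mean_difference: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


def bland_altman(x, y) -> BlandAltman:
    """Bland–Altman agreement of paired measurements; differences are x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(mean_difference=mean, loa_low=mean - 1.96 * sd,
                       loa_high=mean + 1.96 * sd, sd=sd, n=int(d.size))


def correlate(x, y):
    """Pearson product-moment correlation with its two-sided t-distribution p.

    Requires n >= 3 and non-degenerate variance in both variables.
    Returns ``(r, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def group_compare(values, grades):
    """Two-group comparison across WHO grades.

    Mann–Whitney U (exact for small untied samples, normal approximation
    with tie correction otherwise) plus Shapiro–Wilk normality per group
    (NaN for groups of < 3).

    Returns a dict with keys ``u``, ``p``, ``groups``, ``shapiro``.
    """
    values = np.asarray(values, dtype=float)
    grades = np.asarray(grades)
    names = [g for g in pd.unique(grades)]
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    a = values[grades == names[0]]
    b = values[grades == names[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    shapiro = {}
    for name, grp in zip(names, (a, b)):
        if grp.size >= 3 and np.std(grp) > 0:
            w = sps.shapiro(grp)
            shapiro[str(name)] = {"w": float(w.statistic), "p": float(w.pvalue)}
        else:
            shapiro[str(name)] = {"w": float("nan"), "p": float("nan")}
    return {"u": float(res.statistic), "p": float(res.pvalue),
            "groups": [str(n) for n in names], "shapiro": shapiro}


def paired_t(x, y, paired: bool = True):
    """Student's t-test on the difference of two measurement series.

    Paired by default (the per-target design); ``paired=False`` gives the
    two-sample variant.  A zero-variance, zero-mean difference returns
    p = 1.0; zero variance with a non-zero mean returns p = 0.0 (both are
    degenerate limits where the t statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test needs equal-length arrays")
        d = x - y
        if np.std(d, ddof=0) == 0:
            return (0.0, 1.0) if np.allclose(d, 0) else (float("inf"), 0.0)
        res = sps.ttest_rel(x, y)
    else:
        res = sps.ttest_ind(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AgreementReport:
    """Cohort-level agreement statistics (the validation-figure numbers)."""

    n_targets: int
    bland_altman: BlandAltman
    pearson: dict = field(default_factory=dict)     # pair name -> {r, p}
    grade_tests: dict = field(default_factory=dict) # variable -> mannwhitney dict
    t_statistic: float = float("nan")
    t_p: float = float("nan")
    excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


_PAIRS = {
    "rcbv_vs_density": ("rcbv", "density"),
    "rcbv_vs_caliber": ("rcbv", "vsi_histo"),
    "vsi_mri_vs_density": ("vsi_mri", "density"),
    "vsi_mri_vs_caliber": ("vsi_mri", "vsi_histo"),
}
_GRADE_VARS = ("rcbv", "adc", "vsi_mri", "density", "vsi_histo")


def build_report(cohort) -> tuple:
    """Assemble the full agreement report for a cohort of targets.

    The Bland–Altman difference is taken as VSI_histology − VSI_MRI, so a
    negative mean difference means MRI overestimates caliber.  Targets
    with missing required fields are excluded and listed in
    ``report.excluded``.

    Returns ``(AgreementReport, DataFrame)`` with one tidy row per target.
    """
    records = list(cohort)
    if len(records) < 3:
        raise ValueError("need at least 3 targets for agreement statistics")
    rows, excluded = [], []
    for rec in records:
        row = {k: getattr(rec, k) for k in
               ("target_id", "grade", "rcbv", "adc", "vsi_mri",
                "density", "vsi_histo", "vessel_count")}
        needed = [row[k] for k in ("rcbv", "vsi_mri", "density", "vsi_histo")]
        if not np.all(np.isfinite(needed)):
            excluded.append(rec.target_id)
            continue
        rows.append(row)
    if len(rows) < 3:
        raise ValueError("fewer than 3 complete targets after exclusions")
    df = pd.DataFrame(rows)

    ba = bland_altman(df["vsi_histo"].to_numpy(), df["vsi_mri"].to_numpy())
    pearson = {}
    for name, (xk, yk) in _PAIRS.items():
        try:
            r, p = correlate(df[xk].to_numpy(), df[yk].to_numpy())
        except ValueError:  # degenerate (zero-variance) cohort: flag, don't crash
            r, p = float("nan"), float("nan")
        pearson[name] = {"r": r, "p": p}
    grade_tests = {}
    if df["grade"].nunique() == 2:
        for var in _GRADE_VARS:
            vals = df[var].to_numpy()
            if np.all(np.isfinite(vals)):
                grade_tests[var] = group_compare(vals, df["grade"].to_numpy())
    t_stat, t_p = paired_t(df["vsi_histo"].to_numpy(), df["vsi_mri"].to_numpy())
    report = AgreementReport(
        n_targets=len(df), bland_altman=ba, pearson=pearson,
        grade_tests=grade_tests, t_statistic=t_stat, t_p=t_p, excluded=excluded,
    )
    return report, df
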