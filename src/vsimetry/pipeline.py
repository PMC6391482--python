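"""End-to-end orchestration: simulate -> relax -> perfuse -> vsi -> histo -> validate.

Each stage writes its outputs plus a ``manifest.json`` (parameters, seed,
package version, timestamp, SHA-256 of every input and output file).
Before a stage consumes an upstream file it re-hashes it against the
producing stage's manifest; a mismatch raises `ProvenanceError` — runs
are auditable and, under a fixed seed, bit-reproducible.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__, io
from .histology import analyze_slide
from .perfusion import compute_cbv, fit_adc, leakage_correct, normalize_cbv
from .relaxometry import delta_curves, fit_sage_series
from .stats import TargetRecord, build_report, extract_target
from .synthetic import (
    BolusModel,
    PhantomSpec,
    SlideSpec,
    render_slide,
    simulate_dwi,
    simulate_sage_dataset,
)
from .vsi import compute_vsi

__all__ = ["RunConfig", "ProvenanceError", "run", "demo_config_path", "load_config"]

STAGE_ORDER = ("simulate", "relax", "perfuse", "vsi", "histo", "validate")


class ProvenanceError(RuntimeError):
    """An upstream artifact does not match the hash its producer recorded."""


class SimulateConfig(BaseModel):
    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size_mm: tuple[float, float, float] = (1.875, 1.875, 5.0)
    n_timepoints: int = 90
    tr_ms: float = 2000.0
    echo_times: tuple[float, float, float, float] = (14.0, 34.1, 58.0, 92.4)
    noise_sigma: float = 0.0
    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0)
    dwi_noise_sigma: float = 0.0
    n_targets: int = 4
    target_radius_mm: float = 5.0
    slide_shape: tuple[int, int] = (384, 384)
    slide_um_per_px: float = 2.0
    vessels_per_slide: int = 30


class RelaxConfig(BaseModel):
    smooth: bool = True
    baseline_window: Optional[tuple[int, int]] = None
    mask_rel_threshold: float = 0.2  # fit voxels with mean signal above this fraction of the bright-signal level


class PerfuseConfig(BaseModel):
    leak_mode: str = "bidirectional"

    @field_validator("leak_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("none", "unidirectional", "bidirectional"):
            raise ValueError(f"invalid leak mode {v!r}")
        return v


class VsiConfig(BaseModel):
    constant_k: float = 0.867


class HistoConfig(BaseModel):
    n_rois: int = 3
    roi_size: int = 160
    roi_mode: str = "random"


class ValidateConfig(BaseModel):
    statistic: str = "median"


class RunConfig(BaseModel):
    """Validated YAML schema of a pipeline run."""

    stages: list[str] = Field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    relax: RelaxConfig = Field(default_factory=RelaxConfig)
    perfuse: PerfuseConfig = Field(default_factory=PerfuseConfig)
    vsi: VsiConfig = Field(default_factory=VsiConfig)
    histo: HistoConfig = Field(default_factory=HistoConfig)
    validate_: ValidateConfig = Field(default_factory=ValidateConfig, alias="validate")

    model_config = {"populate_by_name": True}

    @field_validator("stages")
    @classmethod
    def _ordered(cls, v):
        idx = [STAGE_ORDER.index(s) for s in v]  # raises on unknown stage
        if idx != sorted(idx):
            raise ValueError(f"stages must follow dependency order {STAGE_ORDER}")
        return v


def load_config(path) -> RunConfig:
    return RunConfig.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def demo_config_path() -> Path:
    """Bundled demo configuration (small phantom, all stages, < 1 min)."""
    return Path(__file__).parent / "data" / "demo.yaml"


def _write_manifest(stage_dir: Path, stage: str, params: dict, seed: int,
                    inputs: dict, outputs: list) -> None:
    io.write_json(
        {
            "stage": stage,
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "seed": seed,
            "parameters": params,
            "inputs": inputs,
            "outputs": {p.name: io.sha256_file(p) for p in outputs},
        },
        stage_dir / "manifest.json",
    )


def _check_inputs(run_dir: Path, deps: dict) -> dict:
    """Verify upstream hashes; returns {relative path: sha256} of inputs used."""
    used = {}
    for stage, names in deps.items():
        manifest_path = run_dir / stage / "manifest.json"
        if not manifest_path.exists():
            raise ProvenanceError(f"missing upstream stage '{stage}' (no manifest)")
        recorded = io.read_json(manifest_path)["outputs"]
        for name in names:
            path = run_dir / stage / name
            if not path.exists():
                raise ProvenanceError(f"missing upstream artifact {stage}/{name}")
            current = io.sha256_file(path)
            if name in recorded and recorded[name] != current:
                raise ProvenanceError(
                    f"hash mismatch for {stage}/{name}: file was modified after "
                    f"its producing stage wrote it"
                )
            used[f"{stage}/{name}"] = current
    return used


def _stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    c = cfg.simulate
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    phantom = PhantomSpec(grid_shape=tuple(c.grid_shape),
                          voxel_size_mm=tuple(c.voxel_size_mm),
                          noise_sigma=c.noise_sigma, seed=cfg.seed)
    sim = simulate_sage_dataset(phantom, BolusModel(), echo_times=c.echo_times,
                                tr_ms=c.tr_ms, n_timepoints=c.n_timepoints)
    affine = phantom.affine
    outputs = []
    for e in range(4):
        # NIfTI convention: spatial axes first, time last
        vol = np.moveaxis(sim.signal[e], 0, -1)
        outputs.append(io.save_nifti(vol, affine, out / f"echo{e + 1}.nii.gz"))
    truth = sim.truth
    outputs.append(io.save_nifti(truth.labels.astype(float), affine,
                                 out / "labels.nii.gz"))
    outputs.append(io.save_nifti((truth.labels == 1).astype(float), affine,
                                 out / "nawm_mask.nii.gz"))
    dwi = simulate_dwi(truth.adc, truth.s0, b_values=c.b_values,
                       noise_sigma=c.dwi_noise_sigma, seed=cfg.seed + 1)
    outputs.append(io.save_nifti(np.moveaxis(dwi, 0, -1), affine,
                                 out / "dwi.nii.gz"))
    outputs.append(io.write_bvals(c.b_values, out / "dwi.bval"))

    rng = np.random.default_rng(cfg.seed + 2)
    # keep target spheres inside the tumor: erode the mask by the target
    # radius (in-plane) so the 5-mm median is not diluted by NAWM
    from scipy import ndimage as ndi
    erode_vox = max(int(np.ceil(c.target_radius_mm / min(c.voxel_size_mm[:2]))) - 1, 1)
    inplane = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)[:, :, None]
    core = ndi.binary_erosion((truth.labels == 2), structure=inplane,
                              iterations=erode_vox)
    tumor_ijk = np.argwhere(core if core.sum() >= c.n_targets else truth.labels == 2)
    if tumor_ijk.shape[0] < c.n_targets:
        raise ValueError("phantom tumor too small for requested target count")
    picks = tumor_ijk[rng.choice(tumor_ijk.shape[0], c.n_targets, replace=False)]
    centers = picks @ affine[:3, :3].T + affine[:3, 3]
    targets = pd.DataFrame({
        "target_id": [f"T{i:02d}" for i in range(c.n_targets)],
        "x_mm": centers[:, 0], "y_mm": centers[:, 1], "z_mm": centers[:, 2],
        "radius_mm": c.target_radius_mm,
        "grade": ["III" if i % 2 == 0 else "IV" for i in range(c.n_targets)],
    })
    tpath = out / "targets.csv"
    targets.to_csv(tpath, index=False)
    outputs.append(tpath)

    # per-target slides whose true caliber scatters around the tumor-class VSI
    tumor_rcbv = (sim.truth.classes["tumor"].peak_dr2star
                  / sim.truth.classes["nawm"].peak_dr2star)
    class_vsi = sim.truth.classes["tumor"].true_vsi(tumor_rcbv)
    for i in range(c.n_targets):
        caliber = float(rng.normal(class_vsi, 1.5))
        radii = np.clip(rng.normal(caliber, 2.0, size=c.vessels_per_slide), 3.0, 22.0)
        spec = SlideSpec(image_shape=tuple(c.slide_shape),
                         um_per_px=c.slide_um_per_px,
                         vessel_radii=tuple(radii), seed=cfg.seed + 10 + i)
        rgb, slide_truth = render_slide(spec)
        outputs.append(io.write_slide(rgb, c.slide_um_per_px,
                                      out / f"slide_T{i:02d}.tif", truth=slide_truth))
        outputs.append(out / f"slide_T{i:02d}.tif.json")

    outputs.append(io.write_json(
        {"time_axis_s": truth.time_axis_s, "echo_times": truth.echo_times,
         "tr_ms": c.tr_ms,
         "class_cbv_true": {k: float(v.peak_dr2star) for k, v in truth.classes.items()}},
        out / "truth_summary.json"))
    _write_manifest(out, "simulate", c.model_dump(), cfg.seed, {}, outputs)


def _stage_relax(cfg: RunConfig, run_dir: Path) -> None:
    c = cfg.relax
    deps = {"simulate": [f"echo{e}.nii.gz" for e in (1, 2, 3, 4)]}
    used = _check_inputs(run_dir, deps)
    out = run_dir / "relax"
    out.mkdir(exist_ok=True)
    echoes, affine = [], None
    for e in (1, 2, 3, 4):
        vol, affine = io.load_nifti(run_dir / "simulate" / f"echo{e}.nii.gz")
        echoes.append(np.moveaxis(vol, -1, 0))      # (T,) + grid
    stack = np.stack(echoes, axis=0)                # (4, T) + grid
    tes = cfg.simulate.echo_times
    mean_sig = stack.mean(axis=(0, 1))
    mask = mean_sig > c.mask_rel_threshold * np.percentile(mean_sig, 99)
    series = fit_sage_series(stack, tes=tes, mask=mask)
    relax = delta_curves(series, baseline_window=c.baseline_window, smooth=c.smooth)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        delta_mean = np.nanmean(series.delta, axis=0)
        s0_mean = np.nanmean(series.s0, axis=0)
    outputs = [
        io.save_nifti(relax.d_r2star_max, affine, out / "dr2star_max.nii.gz"),
        io.save_nifti(relax.d_r2_max, affine, out / "dr2_max.nii.gz"),
        io.save_nifti(np.moveaxis(relax.d_r2star_t, 0, -1), affine,
                      out / "dr2star_t.nii.gz"),
        io.save_nifti(delta_mean, affine, out / "delta.nii.gz"),
        io.save_nifti(s0_mean, affine, out / "s0.nii.gz"),
        io.save_nifti(mask.astype(float), affine, out / "fit_mask.nii.gz"),
        io.write_json({"invalid_fraction": series.invalid_fraction,
                       "delta_variation_pct": series.delta_variation_pct,
                       "baseline_window": list(relax.baseline_window)},
                      out / "qc.json"),
    ]
    _write_manifest(out, "relax", c.model_dump(), cfg.seed, used, outputs)


def _stage_perfuse(cfg: RunConfig, run_dir: Path) -> None:
    c = cfg.perfuse
    deps = {"simulate": ["dwi.nii.gz", "dwi.bval", "nawm_mask.nii.gz",
                         "truth_summary.json"],
            "relax": ["dr2star_t.nii.gz"]}
    used = _check_inputs(run_dir, deps)
    out = run_dir / "perfuse"
    out.mkdir(exist_ok=True)
    d_r2s, affine = io.load_nifti(run_dir / "relax" / "dr2star_t.nii.gz")
    d_r2s = np.moveaxis(d_r2s, -1, 0)
    nawm, _ = io.load_nifti(run_dir / "simulate" / "nawm_mask.nii.gz")
    nawm = nawm > 0.5
    t_s = np.asarray(io.read_json(run_dir / "simulate" / "truth_summary.json")
                     ["time_axis_s"])
    ref = np.nanmean(d_r2s[:, nawm], axis=1)
    leak = leakage_correct(d_r2s, ref, mode=c.leak_mode, time_axis=t_s)
    cbv = compute_cbv(np.nan_to_num(leak.corrected), t_s)
    cbv = np.where(np.isfinite(d_r2s).all(axis=0), cbv, np.nan)
    rcbv = normalize_cbv(cbv, nawm)
    dwi, _ = io.load_nifti(run_dir / "simulate" / "dwi.nii.gz")
    bvals = io.read_bvals(run_dir / "simulate" / "dwi.bval")
    adc = fit_adc(np.moveaxis(dwi, -1, 0), bvals)
    outputs = [
        io.save_nifti(cbv, affine, out / "cbv.nii.gz"),
        io.save_nifti(rcbv, affine, out / "rcbv.nii.gz"),
        io.save_nifti(adc, affine, out / "adc.nii.gz"),
        io.save_nifti(np.asarray(leak.k2, dtype=float), affine, out / "k2.nii.gz"),
    ]
    _write_manifest(out, "perfuse", c.model_dump(), cfg.seed, used, outputs)


def _stage_vsi(cfg: RunConfig, run_dir: Path) -> None:
    c = cfg.vsi
    deps = {"perfuse": ["rcbv.nii.gz", "adc.nii.gz"],
            "relax": ["dr2star_max.nii.gz", "dr2_max.nii.gz"]}
    used = _check_inputs(run_dir, deps)
    out = run_dir / "vsi"
    out.mkdir(exist_ok=True)
    rcbv, affine = io.load_nifti(run_dir / "perfuse" / "rcbv.nii.gz")
    adc, _ = io.load_nifti(run_dir / "perfuse" / "adc.nii.gz")
    dr2s, _ = io.load_nifti(run_dir / "relax" / "dr2star_max.nii.gz")
    dr2, _ = io.load_nifti(run_dir / "relax" / "dr2_max.nii.gz")
    vmap = compute_vsi(rcbv, adc, dr2s, dr2, constant_k=c.constant_k)
    outputs = [
        io.save_nifti(vmap.vsi, affine, out / "vsi.nii.gz"),
        io.save_nifti(vmap.valid.astype(float), affine, out / "vsi_valid.nii.gz"),
    ]
    _write_manifest(out, "vsi", c.model_dump(), cfg.seed, used, outputs)


def _stage_histo(cfg: RunConfig, run_dir: Path) -> None:
    c = cfg.histo
    n = cfg.simulate.n_targets
    deps = {"simulate": [f"slide_T{i:02d}.tif" for i in range(n)]}
    used = _check_inputs(run_dir, deps)
    out = run_dir / "histo"
    out.mkdir(exist_ok=True)
    rows = []
    for i in range(n):
        rgb, sidecar = io.read_slide(run_dir / "simulate" / f"slide_T{i:02d}.tif")
        res = analyze_slide(rgb, um_per_px=sidecar["um_per_px"], n_rois=c.n_rois,
                            roi_size=c.roi_size, seed=cfg.seed + 20 + i,
                            roi_mode=c.roi_mode)
        rows.append({"target_id": f"T{i:02d}", "vessel_count": res.vessel_count,
                     "density": res.density, "vsi_histo": res.vsi_histo})
    path = out / "histo_targets.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_manifest(out, "histo", c.model_dump(), cfg.seed, used, [path])


def _stage_validate(cfg: RunConfig, run_dir: Path) -> None:
    c = cfg.validate_
    deps = {"simulate": ["targets.csv"],
            "perfuse": ["rcbv.nii.gz", "adc.nii.gz"],
            "vsi": ["vsi.nii.gz"],
            "histo": ["histo_targets.csv"]}
    used = _check_inputs(run_dir, deps)
    out = run_dir / "validate"
    out.mkdir(exist_ok=True)
    targets = pd.read_csv(run_dir / "simulate" / "targets.csv")
    histo = pd.read_csv(run_dir / "histo" / "histo_targets.csv").set_index("target_id")
    maps = {}
    affine = None
    for name, path in (("rcbv", "perfuse/rcbv.nii.gz"), ("adc", "perfuse/adc.nii.gz"),
                       ("vsi_mri", "vsi/vsi.nii.gz")):
        maps[name], affine = io.load_nifti(run_dir / path)
    records = []
    for _, row in targets.iterrows():
        center = (row.x_mm, row.y_mm, row.z_mm)
        rec = TargetRecord(target_id=row.target_id, grade=str(row.grade),
                           center_mm=center, radius_mm=float(row.radius_mm))
        for name in maps:
            value, _count = extract_target(maps[name], affine, center,
                                           radius_mm=float(row.radius_mm),
                                           statistic=c.statistic)
            setattr(rec, name, value)
        h = histo.loc[row.target_id]
        rec.density, rec.vsi_histo = float(h.density), float(h.vsi_histo)
        rec.vessel_count = float(h.vessel_count)
        records.append(rec)
    report, df = build_report(records)
    csv_path = out / "targets_report.csv"
    df.to_csv(csv_path, index=False)
    outputs = [csv_path, io.write_json(report.to_dict(), out / "report.json")]
    outputs += _agreement_plots(df, out)
    _write_manifest(out, "validate", c.model_dump(), cfg.seed, used, outputs)


def _agreement_plots(df: pd.DataFrame, out: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = df["vsi_histo"] - df["vsi_mri"]
    mean = d.mean()
    sd = d.std(ddof=1)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter((df["vsi_histo"] + df["vsi_mri"]) / 2, d)
    for y, style in ((mean, "-"), (mean - 1.96 * sd, "--"), (mean + 1.96 * sd, "--")):
        ax.axhline(y, ls=style, color="k", lw=0.8)
    ax.set_xlabel("mean VSI (um)")
    ax.set_ylabel("histology - MRI (um)")
    ba = out / "bland_altman.png"
    fig.tight_layout(); fig.savefig(ba, dpi=100); plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    axes[0].scatter(df["rcbv"], df["density"])
    axes[0].set_xlabel("rCBV"); axes[0].set_ylabel("density (/mm$^2$)")
    axes[1].scatter(df["vsi_mri"], df["vsi_histo"])
    axes[1].set_xlabel("VSI MRI (um)"); axes[1].set_ylabel("VSI histo (um)")
    sc = out / "scatter.png"
    fig.tight_layout(); fig.savefig(sc, dpi=100); plt.close(fig)
    return [ba, sc]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "relax": _stage_relax,
    "perfuse": _stage_perfuse,
    "vsi": _stage_vsi,
    "histo": _stage_histo,
    "validate": _stage_validate,
}


def run(config: RunConfig | str | Path, out_dir) -> Path:
    """Execute the configured stages into ``out_dir``; returns the run dir."""
    if not isinstance(config, RunConfig):
        config = load_config(config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for stage in config.stages:
        _STAGE_FUNCS[stage](config, run_dir)
    io.write_json({"stages": config.stages, "seed": config.seed,
                   "version": __version__}, run_dir / "run_manifest.json")
    return run_dir
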