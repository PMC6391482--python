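"""Synthetic endothelial-stained slide renderer with per-vessel ground truth.

Slides reproduce the three-hue structure of a chromogen-stained section:
reddish-brown vessel walls (endothelium) drawn as rings around paler
lumens, blue-violet nuclei blobs, and a lightly tinted background.
Vessels are circular cross-sections (cylinders cut perpendicular to the
axis); oblique elliptical sections are available behind a flag but off by
default — the randomly-oriented-cylinder correction is exercised in the
caliber formula, not pictorially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color, draw

from ..histology import vessel_size_index

__all__ = ["SlideSpec", "VesselTruth", "PackingError", "render_slide"]


class PackingError(RuntimeError):
    """Requested vessels cannot be placed without violating the packing bound."""


@dataclass(frozen=True)
class SlideSpec:
    """Geometry and staining parameters of one rendered slide.

    ``vessel_radii`` lists the true radius (um) of every vessel to draw;
    if ``vessel_count_target`` exceeds its length, radii are resampled
    from the list with replacement (seeded).  HSV triples control the
    three stain classes.
    """

    image_shape: tuple = (512, 512)
    um_per_px: float = 2.0
    vessel_radii: tuple = (4.0, 5.0, 6.0, 8.0, 10.0)
    vessel_count_target: int | None = None
    lumen_fraction: float = 0.6          # lumen radius / vessel radius
    stain_hue_vessel: tuple = (0.02, 0.75, 0.55)
    stain_hue_nuclei: tuple = (0.65, 0.60, 0.50)
    stain_hue_background: tuple = (0.08, 0.08, 0.95)
    nuclei_density: float = 150.0        # per mm^2
    seed: int = 0
    allow_overlap: bool = False
    min_gap_px: float = 4.0
    oblique_sections: bool = False
    max_eccentricity_angle_deg: float = 60.0
    color_jitter: float = 0.015          # per-pixel value noise, seeded

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if any(r <= 0 for r in self.vessel_radii):
            raise ValueError("vessel radii must be positive")
        if not (0 <= self.lumen_fraction < 1):
            raise ValueError("lumen_fraction must be in [0, 1)")

    @property
    def n_vessels(self) -> int:
        if self.vessel_count_target is None:
            return len(self.vessel_radii)
        return int(self.vessel_count_target)

    @property
    def field_area_mm2(self) -> float:
        h, w = self.image_shape
        return h * w * self.um_per_px**2 / 1e6


@dataclass
class VesselTruth:
    """Exact per-vessel geometry of a rendered slide."""

    centers_px: np.ndarray               # (n, 2) row, col
    radii_um: np.ndarray                 # (n,)
    areas_um2: np.ndarray                # (n,) pi r^2 (true, not rasterized)
    field_area_mm2: float

    @property
    def count(self) -> int:
        return int(self.radii_um.size)

    @property
    def density(self) -> float:
        """True vessel density, N/mm^2."""
        return self.count / self.field_area_mm2

    @property
    def vsi_histo(self) -> float:
        """Cylinder-model caliber recomputed from the true radii (um)."""
        return vessel_size_index(self.radii_um) if self.count else float("nan")


def _place_vessels(spec: SlideSpec, radii_px: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_shape
    # conservative packing bound: disks plus gaps must fit in the field
    need = np.sum(np.pi * (radii_px + spec.min_gap_px) ** 2)
    if not spec.allow_overlap and need > 0.55 * h * w:
        raise PackingError(
            f"{radii_px.size} vessels need ~{need:.0f} px^2 of {h * w} available"
        )
    centers = np.empty((0, 2))
    placed_r = np.empty(0)
    for r in radii_px:
        for attempt in range(20000):
            c = rng.uniform([r + 1, r + 1], [h - r - 1, w - r - 1])
            if spec.allow_overlap or centers.size == 0 or np.all(
                np.linalg.norm(centers - c, axis=1) >= placed_r + r + spec.min_gap_px
            ):
                centers = np.vstack([centers, c])
                placed_r = np.append(placed_r, r)
                break
        else:
            raise PackingError(f"could not place vessel of radius {r:.1f} px")
    return centers


def render_slide(spec: SlideSpec) -> tuple:
    """Render one slide; returns ``(rgb uint8 image, VesselTruth)``.

    Placement is rejection-sampled without overlap (unless
    ``allow_overlap``); an impossible packing raises `PackingError`
    rather than silently truncating the vessel list.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape

    radii_um = np.asarray(spec.vessel_radii, dtype=float)
    n = spec.n_vessels
    if n == 0:
        radii_um = np.empty(0)
    elif n <= radii_um.size:
        radii_um = radii_um[:n]
    else:
        radii_um = rng.choice(radii_um, size=n, replace=True)
    radii_px = radii_um / spec.um_per_px

    hsv = np.empty((h, w, 3), dtype=float)
    hsv[:] = spec.stain_hue_background

    # nuclei first so vessel rings paint over them cleanly
    n_nuclei = rng.poisson(spec.nuclei_density * spec.field_area_mm2)
    nucleus_r = max(1.5, 3.0 / spec.um_per_px)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rr, cc = draw.disk((cy, cx), nucleus_r, shape=(h, w))
        hsv[rr, cc] = spec.stain_hue_nuclei

    centers = _place_vessels(spec, radii_px, rng) if n else np.empty((0, 2))
    lumen_hsv = (spec.stain_hue_background[0], 0.04, 0.97)
    for (cy, cx), r in zip(centers, radii_px):
        if spec.oblique_sections:
            angle = np.deg2rad(rng.uniform(0, spec.max_eccentricity_angle_deg))
            rr, cc = draw.ellipse(cy, cx, r / max(np.cos(angle), 1e-3), r,
                                  shape=(h, w), rotation=rng.uniform(0, np.pi))
        else:
            rr, cc = draw.disk((cy, cx), r, shape=(h, w))
        hsv[rr, cc] = spec.stain_hue_vessel
        lumen_r = spec.lumen_fraction * r
        if lumen_r >= 1.0 and not spec.oblique_sections:
            rr, cc = draw.disk((cy, cx), lumen_r, shape=(h, w))
            hsv[rr, cc] = lumen_hsv

    if spec.color_jitter > 0:
        hsv[..., 2] = np.clip(
            hsv[..., 2] + rng.normal(0, spec.color_jitter, (h, w)), 0, 1)
        hsv[..., 1] = np.clip(
            hsv[..., 1] + rng.normal(0, spec.color_jitter, (h, w)), 0, 1)
    rgb = (color.hsv2rgb(hsv) * 255).round().astype(np.uint8)

    truth = VesselTruth(
        centers_px=centers, radii_um=radii_um,
        areas_um2=np.pi * radii_um**2, field_area_mm2=spec.field_area_mm2,
    )
    return rgb, truth
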