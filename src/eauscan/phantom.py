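"""Synthetic endoanal-ultrasound (EAUS) phantom generator.

Real EAUS frames from a 360-degree radial transducer show a central solid
disc (the transducer artifact), concentric echo layers of the rectal wall
alternating bright and dark, multiplicative speckle, occasional colored
on-screen annotation marks, and a metadata band at the frame edge. A rectal
tumor appears as a hypoechoic (darker) sector that disrupts the layered
pattern. This module emulates exactly those features, with ground-truth
masks attached, so that the preprocessing chain and the classifier can be
exercised and audited without access to clinical images.

The speckle model is first-order: per-pixel multiplicative gamma noise with
mean 1 applied to a noiseless layer template. No point-spread-function
convolution or depth attenuation is modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .workbench import ImageRecord, save_image, write_manifest

DEFAULT_LAYER_INTENSITIES = (170.0, 60.0, 150.0, 70.0, 120.0)


@dataclass
class LesionSpec:
    """A hypoechoic sector lesion disrupting the wall's echo layers."""

    angular_position: float = 40.0  # degrees, center of the sector
    angular_width: float = 70.0  # degrees
    radial_span: tuple[float, float] = (0.35, 0.85)  # fractions of field_radius
    intensity_drop: float = 0.55  # fraction in (0, 1]; higher = darker
    boundary_roughness: float = 0.08  # angular jitter amplitude (dimensionless)

    def validate(self) -> None:
        if not (0 < self.angular_width <= 180):
            raise ValueError(f"angular_width must be in (0, 180], got {self.angular_width}")
        if not (0 < self.intensity_drop <= 1):
            raise ValueError(f"intensity_drop must be in (0, 1], got {self.intensity_drop}")
        lo, hi = self.radial_span
        if not (0 <= lo < hi <= 1):
            raise ValueError(f"radial_span must satisfy 0 <= inner < outer <= 1, got {self.radial_span}")


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic EAUS frame."""

    width: int = 797
    height: int = 657
    center: tuple[float, float] | None = None  # (x, y); derived from geometry when None
    field_radius: float = 260.0
    circle_radius: float = 50.0
    n_layers: int = 5
    layer_intensities: tuple[float, ...] = DEFAULT_LAYER_INTENSITIES
    speckle_shape: float = 12.0  # gamma shape; larger = smoother
    lesion: LesionSpec | None = None
    marks: int = 0
    metadata_margin: int = 50
    seed: int = 0
    background: float = 3.0
    circle_intensity: float = 160.0
    circle_gap: float = 4.0  # dark ring (px) separating the transducer disc from the wall echoes

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        cy = self.metadata_margin + (self.height - self.metadata_margin) / 2
        return (self.width / 2, cy)

    def validate(self) -> None:
        if len(self.layer_intensities) != self.n_layers:
            raise ValueError(
                f"layer_intensities length {len(self.layer_intensities)} != n_layers {self.n_layers}"
            )
        if not (self.circle_radius < self.field_radius):
            raise ValueError("circle_radius must be smaller than field_radius")
        limit = min(self.width, self.height) / 2 - self.metadata_margin
        if self.field_radius > limit:
            raise ValueError(
                f"field_radius {self.field_radius} exceeds frame limit {limit} "
                f"(min(width,height)/2 - metadata_margin)"
            )
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.lesion is not None:
            self.lesion.validate()


def _polar_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = spec.resolved_center()
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    rr = np.hypot(xx - cx, yy - cy)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    return rr, theta


def _lesion_mask(spec: PhantomSpec, rr: np.ndarray, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    les = spec.lesion
    assert les is not None
    r_in = les.radial_span[0] * spec.field_radius
    r_out = les.radial_span[1] * spec.field_radius
    # ragged angular boundary: jitter the sector half-width with radius
    d_theta = (theta - les.angular_position + 180.0) % 360.0 - 180.0
    half = les.angular_width / 2.0
    if les.boundary_roughness > 0:
        wobble = rng.standard_normal(64)
        idx = np.clip(((rr - r_in) / max(r_out - r_in, 1e-9) * 63).astype(int), 0, 63)
        half = half * (1.0 + les.boundary_roughness * wobble[idx])
    mask = (np.abs(d_theta) <= half) & (rr >= max(r_in, spec.circle_radius)) & (rr <= r_out)
    return mask


def _draw_marks(rgb: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw saturated green/yellow caliper crosses; returns the colored-pixel mask."""
    h, w = rgb.shape[:2]
    cx, cy = spec.resolved_center()
    mark_mask = np.zeros((h, w), dtype=bool)
    colors = [(40, 255, 40), (255, 230, 30)]  # green, yellow
    # calipers annotate tissue: keep strokes clear of the probe halo and edge
    min_rad = spec.circle_radius + spec.circle_gap + 12
    max_rad = max(min_rad + 1, spec.field_radius - 10)
    for i in range(spec.marks):
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(min_rad, max_rad)
        mx = int(cx + rad * math.cos(ang))
        my = int(cy + rad * math.sin(ang))
        arm = int(rng.integers(3, 10))  # 3-9 px strokes
        color = colors[i % len(colors)]
        for dy, dx in [(0, 0)] + [(d, 0) for d in range(-arm, arm + 1)] + [(0, d) for d in range(-arm, arm + 1)]:
            y, x = my + dy, mx + dx
            if 0 <= y < h and 0 <= x < w:
                rgb[y, x] = color
                mark_mask[y, x] = True
    return mark_mask


def _draw_metadata(gray: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Dark metadata band at the top of the frame with bright glyph-like dashes."""
    m = spec.metadata_margin
    if m <= 0:
        return
    gray[:m, :] = 1.0
    n_glyphs = 14
    for _ in range(n_glyphs):
        gy = int(rng.integers(2, max(3, m - 4)))
        gx = int(rng.integers(4, spec.width - 24))
        glen = int(rng.integers(6, 20))
        gray[gy : gy + 2, gx : gx + glen] = 230.0


def generate_phantom(spec: PhantomSpec) -> ImageRecord:
    """Render one synthetic EAUS frame; deterministic for a fixed spec (incl. seed).

    The record's label is ``abnormal`` iff a lesion is present; ground-truth
    masks (``lesion``, ``field``, ``disc``, ``marks``) are attached.
    """
    spec.validate()
    # independent sub-streams so that e.g. adding a lesion leaves the speckle
    # realization unchanged for the same seed (paired comparisons)
    rng_lesion = np.random.default_rng([spec.seed, 1])
    rng_speckle = np.random.default_rng([spec.seed, 2])
    rng_meta = np.random.default_rng([spec.seed, 3])
    rng_marks = np.random.default_rng([spec.seed, 4])
    rr, theta = _polar_grids(spec)

    template = np.full((spec.height, spec.width), spec.background, dtype=float)
    field_mask = rr <= spec.field_radius
    disc_mask = rr <= spec.circle_radius

    # concentric wall layers between the transducer's dark halo and the field edge
    inner = spec.circle_radius + spec.circle_gap
    edges = np.linspace(inner, spec.field_radius, spec.n_layers + 1)
    for i, intensity in enumerate(spec.layer_intensities):
        ring = (rr > edges[i]) & (rr <= edges[i + 1])
        template[ring] = intensity
    template[(rr > spec.circle_radius) & (rr <= inner)] = 2.0  # anechoic probe halo
    template[disc_mask] = spec.circle_intensity

    lesion_mask = np.zeros_like(field_mask)
    if spec.lesion is not None:
        lesion_mask = _lesion_mask(spec, rr, theta, rng_lesion)
        template[lesion_mask] *= 1.0 - spec.lesion.intensity_drop

    # first-order multiplicative speckle (mean-1 gamma), field only
    speckle = rng_speckle.gamma(
        shape=spec.speckle_shape, scale=1.0 / spec.speckle_shape, size=template.shape
    )
    gray = np.where(field_mask, template * speckle, template)

    _draw_metadata(gray, spec, rng_meta)
    gray = np.clip(gray, 0, 255)

    rgb = np.repeat(gray[:, :, None], 3, axis=2).astype(np.uint8)
    mark_mask = _draw_marks(rgb, spec, rng_marks) if spec.marks > 0 else np.zeros_like(field_mask)

    label = "abnormal" if spec.lesion is not None else "normal"
    return ImageRecord(
        id=f"phantom-{spec.seed}",
        label=label,
        patient_id="",
        pixels=rgb,
        masks={"lesion": lesion_mask, "field": field_mask, "disc": disc_mask, "marks": mark_mask},
    )


def _jittered_spec(base: PhantomSpec, seed: int, with_lesion: bool, rng: np.random.Generator) -> PhantomSpec:
    """Per-image jitter of geometry and intensity around the base spec."""
    scale = rng.uniform(0.92, 1.08)
    intensities = tuple(
        float(np.clip(v * rng.uniform(0.9, 1.1), 5, 250)) for v in base.layer_intensities
    )
    lesion = None
    if with_lesion:
        les = base.lesion if base.lesion is not None else LesionSpec()
        lesion = replace(
            les,
            angular_position=float(rng.uniform(0, 360)),
            angular_width=float(np.clip(les.angular_width * rng.uniform(0.8, 1.2), 10, 180)),
            intensity_drop=float(np.clip(les.intensity_drop * rng.uniform(0.9, 1.1), 0.05, 1.0)),
        )
    return replace(
        base,
        field_radius=base.field_radius * scale,
        circle_radius=base.circle_radius * scale,
        layer_intensities=intensities,
        lesion=lesion,
        seed=seed,
    )


@dataclass
class PhantomDataset:
    records: list[ImageRecord]
    manifest: "object" = None  # pandas DataFrame, set in generate_dataset

    def write(self, out_dir: str | Path, save_masks: bool = False) -> Path:
        """Write PNGs and manifest.csv; returns the manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in self.records:
            rec.path = out_dir / f"{rec.id}.png"
            save_image(rec.path, rec.pixels)
            if save_masks and "lesion" in rec.masks:
                save_image(out_dir / f"{rec.id}_lesion_mask.png", rec.masks["lesion"] * 255)
        manifest_path = out_dir / "manifest.csv"
        write_manifest(self.records, manifest_path)
        return manifest_path


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    n_patients: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> PhantomDataset:
    """Generate a labeled phantom dataset with round-robin patient assignment.

    Classes are interleaved before patient assignment so that patients carry
    a mix of normal and abnormal frames, as in a clinical archive.
    """
    import pandas as pd  # local: keep module import light

    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("image counts must be non-negative")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    flags = [False] * n_normal + [True] * n_abnormal
    records: list[ImageRecord] = []
    for i, with_lesion in enumerate(flags):
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = _jittered_spec(base, child_seed, with_lesion, rng)
        rec = generate_phantom(spec)
        rec.id = f"img{i:04d}"
        rec.patient_id = f"P{i % n_patients:03d}"
        records.append(rec)
    manifest = pd.DataFrame(
        {
            "image_path": [f"{r.id}.png" for r in records],
            "label": [r.label for r in records],
            "patient_id": [r.patient_id for r in records],
        }
    )
    return PhantomDataset(records=records, manifest=manifest)
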