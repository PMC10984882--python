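"""Image enhancement chain for annotated EAUS frames.

Stages, in order: colored-annotation mask -> grayscale -> diffusion
inpainting -> binarize (threshold 8, strict greater-than) -> crop to the
largest connected component's bounding box -> small-spot removal ->
transducer-circle detection and mask-out -> structuring-element radius
selection by contrast improvement ratio (CIR) -> top-hat/bottom-hat
contrast enhancement. All stages are deterministic.

Local contrast is Weber-like, computed per pixel against the mean of its
window neighbors (center excluded, windows clipped at the image border):

    c(x, y) = |p - a| / (p + a)

and the CIR between an original image and its enhanced version over a
region R is

    CIR = sum_R (c - c_enh)^2 / sum_R c^2 .

The structuring-element radius for the top-hat/bottom-hat step is swept
over increasing disk radii and the radius maximizing the CIR is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger("eauscan")


@dataclass
class PreprocessParams:
    color_delta_threshold: float = 20.0
    binarize_threshold: float = 8.0
    connectivity: int = 8  # pixel connectivity for labeling: 4 or 8
    min_spot_area: int = 50
    circle_search: str = "largest-filled-component"
    se_shape: str = "disk"
    se_radii_sweep: tuple[int, ...] = tuple(range(1, 16))
    cir_window: int = 3
    cir_rel_tol: float = 1e-3
    clip_range: tuple[float, float] = (0.0, 255.0)
    circle_fill_ratio: float = 0.85
    circle_center_frac: float = 0.25  # max centroid offset from ROI center, as frac of ROI size

    def validate(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.cir_window < 3 or self.cir_window % 2 == 0:
            raise ValueError("cir_window must be odd and >= 3")
        radii = list(self.se_radii_sweep)
        if radii != sorted(set(radii)) or not radii:
            raise ValueError("se_radii_sweep must be nonempty and strictly increasing")
        if self.se_shape != "disk":
            raise ValueError("only disk structuring elements are supported")


@dataclass
class PreprocessResult:
    enhanced: np.ndarray
    trace: dict[str, np.ndarray] = field(default_factory=dict)
    chosen_se_radius: int = 0
    cir_value: float = 0.0
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)
    circle: Optional[tuple[float, float, float]] = None


class PipelineStageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


def _skimage_connectivity(connectivity: int) -> int:
    return 1 if connectivity == 4 else 2


def detect_color_marks(image: np.ndarray, color_delta_threshold: float = 20.0) -> np.ndarray:
    """Mask of saturated (colored) pixels: max-channel minus min-channel above threshold."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise TypeError(f"expected a 3-channel RGB image, got shape {image.shape}")
    img = image.astype(float)
    spread = img.max(axis=2) - img.min(axis=2)
    return spread > color_delta_threshold


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Channel-mean grayscale in [0, 255] float; identity on 2-D input."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    return image.mean(axis=2)


def inpaint(gray: np.ndarray, mask: np.ndarray, tol: float = 0.5, max_iter: int = 10000) -> np.ndarray:
    """Fill masked pixels by iterative 4-neighbor mean diffusion.

    Iterates Jacobi updates on the masked pixels only (boundary values
    clamped to the surrounding image) until the largest per-pixel change
    drops below ``tol`` gray levels, i.e. an approximate harmonic fill.
    """
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        return gray.copy()
    if mask.all():
        raise ValueError("mask covers the entire image; nothing to diffuse from")
    out = gray.copy()
    out[mask] = gray[~mask].mean()  # neutral initialization
    kernel = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    ones = np.ones_like(out)
    counts = ndimage.convolve(ones, kernel, mode="constant", cval=0.0)
    for _ in range(max_iter):
        neighbor_sum = ndimage.convolve(out, kernel, mode="constant", cval=0.0)
        new_vals = neighbor_sum[mask] / counts[mask]
        delta = np.abs(new_vals - out[mask]).max()
        out[mask] = new_vals
        if delta < tol:
            break
    return np.clip(out, 0.0, 255.0)


def binarize(gray: np.ndarray, threshold: float = 8.0) -> np.ndarray:
    """Strict greater-than threshold: a pixel at exactly the threshold is background."""
    return np.asarray(gray, dtype=float) > threshold


def largest_bbox(binary: np.ndarray, connectivity: int = 8) -> tuple[int, int, int, int]:
    """Bounding box (row0, col0, row1, col1; half-open) of the largest component.

    Area ties are broken by the smallest (row0, col0) lexicographically.
    """
    binary = np.asarray(binary, dtype=bool)
    labels = measure.label(binary, connectivity=_skimage_connectivity(connectivity))
    props = measure.regionprops(labels)
    if not props:
        raise ValueError("no foreground pixels: cannot determine a bounding box")
    best = max(props, key=lambda p: (p.area, -p.bbox[0], -p.bbox[1]))
    r0, c0, r1, c1 = best.bbox
    return (int(r0), int(c0), int(r1), int(c1))


def remove_small_spots(binary: np.ndarray, min_spot_area: int = 50, connectivity: int = 8) -> np.ndarray:
    """Drop connected components with area strictly below ``min_spot_area``."""
    binary = np.asarray(binary, dtype=bool)
    labels = measure.label(binary, connectivity=_skimage_connectivity(connectivity))
    areas = np.bincount(labels.ravel())
    keep = areas >= min_spot_area
    keep[0] = False
    return keep[labels]


def find_solid_circle(
    binary: np.ndarray, params: PreprocessParams | None = None
) -> tuple[Optional[tuple[float, float, float]], np.ndarray]:
    """Locate the transducer disc: the largest near-center filled circular component.

    A component qualifies when it is filled (hole-free, Euler number 1), its
    fill ratio area / (pi r^2) is at least ``circle_fill_ratio`` with r taken
    as half the mean bounding-box side, and its centroid lies within
    ``circle_center_frac`` of the ROI size from the ROI center. Returns
    ((cx, cy, r), disc mask) or (None, empty mask) when nothing qualifies
    (e.g. thin rings, or the echo-field annulus around the transducer).
    """
    params = params or PreprocessParams()
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    labels = measure.label(binary, connectivity=_skimage_connectivity(params.connectivity))
    center = np.array([h / 2, w / 2])
    max_offset = params.circle_center_frac * min(h, w)
    best = None
    for p in measure.regionprops(labels):
        r0, c0, r1, c1 = p.bbox
        r_est = ((r1 - r0) + (c1 - c0)) / 4.0
        if r_est <= 0 or p.euler_number != 1:
            continue
        fill_ratio = p.area / (np.pi * r_est**2)
        offset = np.linalg.norm(np.array(p.centroid) - center)
        if fill_ratio >= params.circle_fill_ratio and offset <= max_offset:
            if best is None or p.area > best[0]:
                best = (p.area, p.centroid, r_est)
    if best is None:
        return None, np.zeros_like(binary)
    _, (cy, cx), r = best
    yy, xx = np.mgrid[0:h, 0:w]
    disc = np.hypot(xx - cx, yy - cy) <= r
    return (float(cx), float(cy), float(r)), disc


def local_contrast(gray: np.ndarray, window: int = 3) -> np.ndarray:
    """Weber-like local contrast |p - a| / (p + a), a = mean of window neighbors.

    Windows are clipped at the image border (the neighbor mean runs over the
    pixels actually present); pixels where p + a = 0 get contrast 0.
    """
    gray = np.asarray(gray, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    kernel = np.ones((window, window))
    total = ndimage.convolve(gray, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(gray), kernel, mode="constant", cval=0.0)
    neigh_mean = (total - gray) / (counts - 1)
    denom = gray + neigh_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(gray - neigh_mean) / denom
    c[denom == 0] = 0.0
    return c


def cir(
    original: np.ndarray,
    enhanced: np.ndarray,
    window: int = 3,
    roi_mask: np.ndarray | None = None,
) -> float:
    """Contrast improvement ratio between an original image and its enhancement."""
    c_orig = local_contrast(original, window)
    c_enh = local_contrast(enhanced, window)
    if roi_mask is None:
        roi_mask = np.ones_like(c_orig, dtype=bool)
    denom = float((c_orig[roi_mask] ** 2).sum())
    if denom == 0:
        raise ValueError("original image has identically zero local contrast; CIR undefined")
    num = float(((c_orig[roi_mask] - c_enh[roi_mask]) ** 2).sum())
    return num / denom


def tophat_bothat_enhance(
    gray: np.ndarray, se_radius: int, clip_range: tuple[float, float] = (0.0, 255.0)
) -> np.ndarray:
    """Add the white top-hat and subtract the black bottom-hat (disk SE), then clip.

    Bright detail smaller than the structuring element is amplified and dark
    detail deepened, which raises local contrast on speckled tissue.
    """
    gray = np.asarray(gray, dtype=float)
    se = morphology.disk(se_radius)
    th = morphology.white_tophat(gray, se)
    bh = morphology.black_tophat(gray, se)
    return np.clip(gray + th - bh, clip_range[0], clip_range[1])


def select_se_radius(
    gray: np.ndarray, params: PreprocessParams | None = None, roi_mask: np.ndarray | None = None
) -> tuple[int, float]:
    """Sweep disk radii, scoring each by CIR; return (best radius, its CIR).

    With ``cir_rel_tol > 0`` the sweep stops early once the relative CIR
    improvement over the running best has stayed below the tolerance for two
    consecutive radii; a non-positive tolerance forces an exhaustive sweep.
    Ties prefer the smallest radius.
    """
    params = params or PreprocessParams()
    params.validate()
    best_r: int | None = None
    best_cir = 0.0
    stall = 0
    for r in params.se_radii_sweep:
        enhanced = tophat_bothat_enhance(gray, r, params.clip_range)
        value = cir(gray, enhanced, params.cir_window, roi_mask)
        if best_r is None:
            best_r, best_cir = r, value
            continue
        improvement = (value - best_cir) / best_cir if best_cir > 0 else (np.inf if value > best_cir else 0.0)
        if value > best_cir:
            best_r, best_cir = r, value
        if params.cir_rel_tol > 0:
            stall = stall + 1 if improvement < params.cir_rel_tol else 0
            if stall >= 2:
                break
    assert best_r is not None
    return int(best_r), float(best_cir)


def preprocess_pipeline(image: np.ndarray, params: PreprocessParams | None = None) -> PreprocessResult:
    """Run the full enhancement chain on one frame; see the module docstring.

    Accepts an RGB or grayscale array in [0, 255]. Every intermediate stage
    is recorded in the result's trace for auditability.
    """
    params = params or PreprocessParams()
    params.validate()
    image = np.asarray(image)
    trace: dict[str, np.ndarray] = {}

    def run(stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    if image.ndim == 3:
        mark_mask = run("mark_mask", detect_color_marks, image, params.color_delta_threshold)
    else:
        mark_mask = np.zeros(image.shape[:2], dtype=bool)
    trace["mark_mask"] = mark_mask

    gray = to_grayscale(image)
    inpainted = run("inpaint", inpaint, gray, mark_mask)
    trace["inpainted"] = inpainted

    binary = run("binarize", binarize, inpainted, params.binarize_threshold)
    trace["binary"] = binary

    box = run("largest_bbox", largest_bbox, binary, params.connectivity)
    r0, c0, r1, c1 = box
    roi_gray = inpainted[r0:r1, c0:c1]
    roi_binary = binary[r0:r1, c0:c1]
    trace["bbox"] = roi_gray

    despotted = run("remove_small_spots", remove_small_spots, roi_binary, params.min_spot_area, params.connectivity)
    trace["despotted"] = despotted

    circle, disc_mask = run("find_solid_circle", find_solid_circle, despotted, params)
    if circle is None:
        log.info("no solid circle found; proceeding without transducer masking")
    trace["circle_mask"] = disc_mask

    masked_roi = roi_gray.copy()
    masked_roi[disc_mask] = 0.0

    best_r, _ = run("select_se_radius", select_se_radius, masked_roi, params)
    enhanced = run("tophat_bothat_enhance", tophat_bothat_enhance, masked_roi, best_r, params.clip_range)
    trace["enhanced"] = enhanced
    cir_value = run("cir", cir, masked_roi, enhanced, params.cir_window)

    return PreprocessResult(
        enhanced=enhanced,
        trace=trace,
        chosen_se_radius=best_r,
        cir_value=float(cir_value),
        bbox=box,
        circle=circle,
    )


class UltrasoundPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer over the enhancement chain.

    ``transform`` maps a list of raw frames to their enhanced grayscale
    ROIs (shapes vary with the detected bounding box); ``fit`` is a no-op
    kept for pipeline compatibility. The per-image stage traces of the
    last ``transform`` call are kept in ``last_results_``.
    """

    def __init__(self, params: PreprocessParams | None = None):
        self.params = params

    def _params(self) -> PreprocessParams:
        return self.params if self.params is not None else PreprocessParams()

    def fit(self, X=None, y=None):
        self._params().validate()
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> list[np.ndarray]:
        params = self._params()
        self.last_results_ = [preprocess_pipeline(np.asarray(img), params) for img in X]
        return [r.enhanced for r in self.last_results_]
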