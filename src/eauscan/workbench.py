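"""Dataset plumbing: image records, manifests, anonymization crops, run configuration.

Pixel coordinates are 0-based and half-open everywhere in this package:
a box ``(row0, col0, row1, col1)`` selects ``pixels[row0:row1, col0:col1]``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("eauscan")

LABELS = ("normal", "abnormal")


@dataclass
class ImageRecord:
    """One ultrasound frame with its label and patient id.

    ``pixels`` is a 2-D (grayscale) or (H, W, 3) RGB uint8-range array in
    [0, 255]. ``masks`` optionally carries ground-truth boolean masks
    (synthetic data only): ``lesion``, ``field``, ``disc``, ``marks``.
    """

    id: str
    label: str
    patient_id: str
    pixels: np.ndarray | None = None
    path: Path | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def load(self) -> np.ndarray:
        """Return pixels, reading from ``path`` on first access if needed."""
        if self.pixels is None:
            if self.path is None:
                raise ValueError(f"record {self.id}: no pixels and no path")
            self.pixels = np.asarray(iio.imread(self.path))
        return self.pixels


def read_manifest(csv_path: str | Path, *, require_files: bool = True) -> list[ImageRecord]:
    """Read a manifest CSV (columns image_path, label, patient_id) into records.

    Record ids are the image-path stems; duplicate ids, unknown labels and
    (optionally) missing files are rejected with the offending row named.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype=str)
    required = {"image_path", "label", "patient_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {csv_path}: missing columns {sorted(required - set(df.columns))}")
    records: list[ImageRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        path = Path(str(row.image_path))
        if not path.is_absolute():
            path = csv_path.parent / path
        rid = path.stem
        if row.label not in LABELS:
            raise ValueError(f"manifest row {i}: unknown label {row.label!r}")
        if rid in seen:
            raise ValueError(f"manifest row {i}: duplicate image id {rid!r}")
        if require_files and not path.exists():
            raise FileNotFoundError(f"manifest row {i}: missing file {path}")
        seen.add(rid)
        records.append(ImageRecord(id=rid, label=str(row.label), patient_id=str(row.patient_id), path=path))
    return records


def write_manifest(records: list[ImageRecord], csv_path: str | Path) -> None:
    """Write a manifest CSV; image paths are stored relative to the CSV when possible."""
    csv_path = Path(csv_path)

    def rel(p: Path) -> str:
        try:
            return str(p.relative_to(csv_path.parent.resolve()))
        except ValueError:
            try:
                return str(p.relative_to(csv_path.parent))
            except ValueError:
                return str(p)

    df = pd.DataFrame(
        {
            "image_path": [rel(Path(r.path)) for r in records],
            "label": [r.label for r in records],
            "patient_id": [r.patient_id for r in records],
        }
    )
    df.to_csv(csv_path, index=False)


def anonymize_crop(image: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Crop ``image`` to the half-open box (row0, col0, row1, col1).

    Used to cut away on-screen metadata (patient name, device settings)
    before any image leaves the acquisition workstation.
    """
    r0, c0, r1, c1 = box
    h, w = image.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"crop box {box} exceeds image bounds {h}x{w}")
    return image[r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# Run configuration

_KNOWN_SECTIONS = {"phantom", "preprocess", "model", "train", "evaluate", "paths", "anonymize_crop"}


@dataclass
class RunConfig:
    """Validated container for a pipeline run's configuration sections."""

    sections: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
        unknown = set(data) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(sections=data)

    def get(self, section: str, default: Any = None) -> Any:
        return self.sections.get(section, default)

    def hash(self) -> str:
        payload = json.dumps(self.sections, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_repro_block(out_dir: str | Path, config: RunConfig | None, seed: int | None) -> Path:
    """Write a reproducibility block (config hash, seed, versions) to ``out_dir``."""
    import numpy, scipy, skimage, sklearn  # noqa: PLC0415

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block = {
        "config_hash": config.hash() if config is not None else None,
        "seed": seed,
        "python": sys.version.split()[0],
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path = out_dir / "reproducibility.json"
    path.write_text(json.dumps(block, indent=2))
    return path


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    arr = np.clip(np.asarray(pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def records_to_arrays(records: list[ImageRecord]) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Split records into (pixel list, binary labels, patient ids).

    Labels are encoded 1 = abnormal (positive class), 0 = normal.
    """
    X = [r.load() for r in records]
    y = np.array([1 if r.label == "abnormal" else 0 for r in records])
    groups = np.array([r.patient_id for r in records])
    return X, y, groups
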