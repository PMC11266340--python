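"""File I/O: detector images, stacks, run configuration, dataset catalog.

Detector images are stored either as whitespace-delimited plain-text
matrices (row-major, one detector row per line) or as single-page
32-bit float TIFF.  Reconstruction stacks go to multi-page TIFF with a
CSV sidecar table (z, side_px, min, max).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import CameraGeometry
from .simulate import DetectorImage
from .stacks import ImageStack

__all__ = [
    "read_detector_image",
    "write_detector_image",
    "write_stack",
    "RunConfig",
    "load_config",
    "save_config",
    "DATASET_DISTANCES_MM",
    "load_dataset",
    "fetch_dataset",
]

#: Source-to-mask distances of the measured reference dataset:
#: 12-20 mm in 2 mm steps, then 25-100 mm in 5 mm steps (21 positions).
DATASET_DISTANCES_MM = tuple(range(12, 21, 2)) + tuple(range(25, 101, 5))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "tiff" if path.suffix.lower() in (".tif", ".tiff") else "text"


def read_detector_image(path, fmt: str | None = None,
                        meta: dict | None = None) -> DetectorImage:
    """Read a detector image from a text matrix or a TIFF file."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "tiff":
        pixels = np.asarray(tifffile.imread(path), dtype=float)
    elif fmt == "text":
        try:
            pixels = np.loadtxt(path, dtype=float)
        except ValueError as exc:
            raise ValueError(f"malformed text matrix in {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(
            f"{path}: detector image must be square, got {pixels.shape}"
        )
    if np.any(pixels < 0):
        i, j = map(int, np.argwhere(pixels < 0)[0])
        raise ValueError(
            f"{path}: negative pixel at row {i}, column {j}"
        )
    info = {"provenance": "file", "path": str(path), "format": fmt}
    info.update(meta or {})
    return DetectorImage(pixels=pixels, meta=info)


def write_detector_image(path, image: DetectorImage | np.ndarray,
                         fmt: str | None = None) -> Path:
    """Write a detector image as a text matrix or 32-bit float TIFF."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    pixels = image.pixels if isinstance(image, DetectorImage) else np.asarray(image)
    if fmt == "tiff":
        tifffile.imwrite(path, pixels.astype(np.float32))
    elif fmt == "text":
        np.savetxt(path, pixels, fmt="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_stack(path, stack: ImageStack) -> tuple[Path, Path]:
    """Write a stack as multi-page TIFF plus a CSV sidecar table."""
    path = Path(path)
    sides = {s.side_px for s in stack.slices}
    if len(sides) == 1:
        tifffile.imwrite(path, stack.as_array().astype(np.float32),
                         photometric="minisblack")
    else:  # mixed sizes: one page per slice shape
        with tifffile.TiffWriter(path) as tif:
            for s in stack.slices:
                tif.write(s.pixels.astype(np.float32),
                          photometric="minisblack")
    table = pd.DataFrame({
        "z_mm": stack.z_values,
        "side_px": [s.side_px for s in stack.slices],
        "min": [float(s.pixels.min()) for s in stack.slices],
        "max": [float(s.pixels.max()) for s in stack.slices],
    })
    sidecar = path.with_suffix(".csv")
    table.to_csv(sidecar, index=False)
    return path, sidecar


# ---------------------------------------------------------------------------
# run configuration

_KNOWN_SECTIONS = {"geometry", "reconstruction", "assessment", "io", "seed"}


@dataclass
class RunConfig:
    """Validated run configuration (geometry + method + assessment + seed)."""

    geometry: CameraGeometry = field(default_factory=CameraGeometry)
    reconstruction: dict = field(default_factory=dict)
    assessment: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "reconstruction": dict(self.reconstruction),
            "assessment": dict(self.assessment),
            "io": dict(self.io),
            "seed": self.seed,
        }


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown sections or keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    geometry = CameraGeometry.from_dict(raw.get("geometry", {}) or {})
    return RunConfig(
        geometry=geometry,
        reconstruction=raw.get("reconstruction", {}) or {},
        assessment=raw.get("assessment", {}) or {},
        io=raw.get("io", {}) or {},
        seed=raw.get("seed"),
    )


def save_config(path, config: RunConfig) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# measured-dataset catalog

_DIST_RE = re.compile(r"(\d+)\s*mm", re.IGNORECASE)


def _parse_distance(name: str) -> int | None:
    m = _DIST_RE.search(name)
    if m:
        return int(m.group(1))
    digits = re.findall(r"\d+", name)
    for d in digits:
        if int(d) in DATASET_DISTANCES_MM:
            return int(d)
    return None


def load_dataset(directory, manifest: dict | None = None) -> dict:
    """Catalog a local copy of the measured 21-image dataset.

    Files are discovered by parsing the source-to-mask distance from the
    filename (e.g. ``..._30mm...``); ``manifest`` maps distances (mm) to
    filenames explicitly and overrides discovery.  Returns a dict
    ``{distance_mm: DetectorImage}`` and raises listing the absent
    distances when the catalog is incomplete.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(
            f"dataset directory {directory} does not exist; download the "
            "deposited measurement archive or point to a local copy"
        )
    catalog: dict[int, DetectorImage] = {}
    if manifest:
        items = [(int(k), directory / v) for k, v in manifest.items()]
    else:
        items = []
        for f in sorted(directory.iterdir()):
            if f.suffix.lower() not in (".txt", ".tif", ".tiff", ".dat"):
                continue
            dist = _parse_distance(f.name)
            if dist is not None:
                items.append((dist, f))
    for dist, f in items:
        catalog[dist] = read_detector_image(f, meta={"distance_mm": dist})
    missing = sorted(set(DATASET_DISTANCES_MM) - set(catalog))
    if missing:
        raise FileNotFoundError(
            f"dataset incomplete in {directory}: missing distances {missing} mm"
        )
    return dict(sorted(catalog.items()))


def fetch_dataset(url_or_path, dest=None) -> dict:
    """Fetch the measured dataset from a local path or (if reachable) a URL."""
    p = Path(str(url_or_path))
    if p.exists():
        return load_dataset(p)
    if str(url_or_path).startswith(("http://", "https://")):
        raise ConnectionError(
            f"cannot download {url_or_path}: no network access in this "
            "environment; provide a local copy of the dataset instead"
        )
    raise FileNotFoundError(f"dataset source {url_or_path} not found")
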