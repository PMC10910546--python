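"""Thumbnail and diagnostic-image generation (the "images" service).

Micrographs get a downsampled thumbnail plus a 2-D power-spectrum image;
volumes get their central z-slice and xy/xz projections. Everything is
written as 8-bit contrast-stretched PNG for display in the session report.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image

from .types import StageResult

__all__ = ["to_uint8", "make_micrograph_images", "make_volume_images", "make_images"]

_THUMB_MAX = 256


def to_uint8(image: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Contrast-stretch to 8 bit between the given intensity percentiles."""
    lo, hi = np.percentile(image, [p_low, p_high])
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.uint8)
    return (np.clip((image - lo) / (hi - lo), 0.0, 1.0) * 255).astype(np.uint8)


def _save(image: np.ndarray, path: Path) -> str:
    arr = to_uint8(image)
    if max(arr.shape) > _THUMB_MAX:
        step = int(np.ceil(max(arr.shape) / _THUMB_MAX))
        arr = arr[::step, ::step]
    Image.fromarray(arr).save(path)
    return str(path)


def make_micrograph_images(image: np.ndarray, out_dir: Path, stem: str) -> list[str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    thumb = _save(image, out_dir / f"{stem}_thumb.png")
    ps = np.abs(np.fft.fftshift(np.fft.fft2(image - image.mean())))
    spectrum = _save(np.log1p(ps), out_dir / f"{stem}_powerspec.png")
    return [thumb, spectrum]


def make_volume_images(voxels: np.ndarray, out_dir: Path, stem: str) -> list[str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    central = _save(voxels[voxels.shape[0] // 2], out_dir / f"{stem}_central_slice.png")
    proj_xy = _save(voxels.mean(axis=0), out_dir / f"{stem}_proj_xy.png")
    proj_xz = _save(voxels.mean(axis=1), out_dir / f"{stem}_proj_xz.png")
    return [central, proj_xy, proj_xz]


def make_images(artifact_path: str, kind: str, out_dir: str | Path,
                stem: str | None = None) -> StageResult:
    """Produce display images for a stored micrograph or volume artifact."""
    from ..io_mrc import read_mrc  # local import: keeps this module importable alone

    out_dir = Path(out_dir)
    if stem is None:
        stem = Path(artifact_path).stem
    if not os.path.exists(artifact_path):
        return StageResult.failure("images", artifact_path, "missing_artifact",
                                   error_class="transient")
    try:
        data, _ = read_mrc(artifact_path)
    except Exception:
        return StageResult.failure("images", artifact_path, "unreadable_artifact")
    if kind == "volume" and data.ndim == 3:
        paths = make_volume_images(data, out_dir, stem)
    else:
        if data.ndim == 3:  # stored single-section stacks
            data = data[0]
        paths = make_micrograph_images(data, out_dir, stem)
    return StageResult(stage="images", input_key=artifact_path,
                       metrics={"n_images": len(paths)}, artifact_paths=paths)
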