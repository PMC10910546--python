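"""Typed containers passed between processing stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

__all__ = ["MovieStack", "Micrograph", "CtfResult", "TomogramVolume", "StageResult"]


@dataclass
class MovieStack:
    """A multi-frame exposure for a single tilt (``frames``: n × H × W)."""

    frames: np.ndarray
    pixel_size: float  # Angstrom / px
    tilt_angle: float  # degrees
    series_id: str = ""
    path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, H, W) stack with n_frames >= 1")
        if min(self.frames.shape[1:]) < 16:
            raise ValueError("frame dimensions must be >= 16 px")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class Micrograph:
    """A motion-corrected sum with its per-frame drift trace (px)."""

    image: np.ndarray
    pixel_size: float
    drift_trace: list[tuple[float, float]]  # per-frame (dx, dy), first = (0, 0)
    total_drift: float
    tilt_angle: float = 0.0


@dataclass
class CtfResult:
    defocus: float  # micrometres, underfocus positive
    fit_score: float  # correlation coefficient in [-1, 1]
    power_spectrum_1d: np.ndarray
    low_confidence: bool = False


@dataclass
class TomogramVolume:
    """Reconstructed volume, (Z, Y, X) with z along the beam at zero tilt."""

    voxels: np.ndarray
    voxel_size: float
    alignment_shifts: list[tuple[float, float]]
    denoised: bool = False


@dataclass
class StageResult:
    """Uniform stage output: metrics + artifacts + fields forwarded downstream.

    A failed stage is data, not control flow: ``success=False`` with an
    ``error`` classification in ``metrics`` (``error_class`` is
    ``transient`` or ``permanent``); the service layer decides whether to
    retry or dead-letter.
    """

    stage: str
    input_key: str
    metrics: dict[str, Any] = field(default_factory=dict)
    artifact_paths: list[str] = field(default_factory=list)
    success: bool = True
    #: JSON-serializable fields merged into downstream message parameters
    forward: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def failure(cls, stage: str, input_key: str, error: str,
                error_class: str = "permanent", **extra: Any) -> "StageResult":
        m = {"error": error, "error_class": error_class}
        m.update(extra)
        return cls(stage=stage, input_key=input_key, metrics=m, success=False)
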