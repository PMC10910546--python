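"""Message-facing stage runners.

Each service worker runs one of these: a thin adapter that takes the
JSON-serializable message parameters, loads artifacts from disk, calls the
numeric stage, writes output artifacts, and returns a
:class:`~tiltpipe.stages.types.StageResult` whose ``forward`` fields become
downstream message parameters.

Failure classification follows one rule: missing or unreadable files are
*transient* (retry — the filesystem may be recovering), while validation
failures such as blank input or too few tilts are *permanent*
(dead-letter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np

from ..io_mrc import read_mrc, write_mrc
from .ctf import estimate_ctf
from .images import make_images
from .motion import motion_correct
from .recon import align_and_reconstruct, denoise
from .types import Micrograph, MovieStack, StageResult

__all__ = ["StageContext", "STAGE_RUNNERS", "get_runner"]


@dataclass
class StageContext:
    """Shared per-pipeline state handed to every stage runner."""

    work_dir: Path
    optics: dict[str, float]
    ctf_search: dict[str, float]
    #: motion-correction shift search half-window, px; must cover the worst
    #: cumulative drift over a movie
    max_shift: int = 16
    outcome_store: Any = None  # results.OutcomeStore, set by the pipeline
    dispatcher: Any = None  # recipes.Dispatcher, set by the pipeline

    def subdir(self, name: str) -> Path:
        d = self.work_dir / name
        d.mkdir(parents=True, exist_ok=True)
        return d


def _read_or_none(path: str) -> tuple[np.ndarray, float] | None:
    try:
        return read_mrc(path)
    except (FileNotFoundError, OSError, RuntimeError, ValueError):
        return None


def run_motioncorr(params: dict, ctx: StageContext) -> StageResult:
    movie_id = params.get("movie_id", "")
    path = params.get("movie_path", "")
    loaded = _read_or_none(path)
    if loaded is None:
        return StageResult.failure("motioncorr", movie_id, "missing_input",
                                   error_class="transient", path=path)
    data, voxel = loaded
    if data.ndim == 2:
        data = data[None]
    movie = MovieStack(frames=data, pixel_size=voxel,
                       tilt_angle=float(params.get("tilt_angle", 0.0)),
                       series_id=params.get("series_id", ""), path=path)
    mic, result = motion_correct(movie, max_shift=ctx.max_shift)
    result.input_key = movie_id
    if mic is None:
        return result
    out = ctx.subdir("micrographs") / f"{movie_id}_mc.mrc"
    write_mrc(out, mic.image, mic.pixel_size)
    result.artifact_paths = [str(out)]
    result.forward = {"micrograph_path": str(out), "artifact_path": str(out)}
    return result


def run_ctffind(params: dict, ctx: StageContext) -> StageResult:
    movie_id = params.get("movie_id", "")
    path = params.get("micrograph_path", "")
    loaded = _read_or_none(path)
    if loaded is None:
        return StageResult.failure("ctffind", movie_id, "missing_input",
                                   error_class="transient", path=path)
    data, voxel = loaded
    mic = Micrograph(image=data, pixel_size=voxel, drift_trace=[(0.0, 0.0)],
                     total_drift=0.0)
    _, result = estimate_ctf(mic, ctx.optics, ctx.ctf_search)
    result.input_key = movie_id
    return result


def run_tomo_align_recon(params: dict, ctx: StageContext) -> StageResult:
    series_id = params.get("series_id", "")
    tilt_specs = params.get("tilts", [])
    mics: list[Micrograph] = []
    angles: list[float] = []
    for t in sorted(tilt_specs, key=lambda t: float(t.get("tilt_angle", 0.0))):
        loaded = _read_or_none(t.get("micrograph_path", ""))
        if loaded is None:
            return StageResult.failure("tomo_align_recon", series_id, "missing_input",
                                       error_class="transient",
                                       path=t.get("micrograph_path", ""))
        data, voxel = loaded
        mics.append(Micrograph(image=data, pixel_size=voxel, drift_trace=[(0.0, 0.0)],
                               total_drift=0.0, tilt_angle=float(t.get("tilt_angle", 0.0))))
        angles.append(float(t.get("tilt_angle", 0.0)))
    tomo, result = align_and_reconstruct(mics, angles,
                                         thickness=int(params.get("thickness", 64)))
    result.input_key = series_id
    if tomo is None:
        return result
    out = ctx.subdir("tomograms") / f"{series_id}_tomo.mrc"
    write_mrc(out, tomo.voxels, tomo.voxel_size)
    result.artifact_paths = [str(out)]
    result.forward = {"tomogram_path": str(out), "artifact_path": str(out)}
    return result


def run_denoise(params: dict, ctx: StageContext) -> StageResult:
    series_id = params.get("series_id", "")
    path = params.get("tomogram_path", "")
    loaded = _read_or_none(path)
    if loaded is None:
        return StageResult.failure("denoise", series_id, "missing_input",
                                   error_class="transient", path=path)
    data, voxel = loaded
    from .types import TomogramVolume

    vol = TomogramVolume(voxels=data, voxel_size=voxel, alignment_shifts=[])
    out_vol, result = denoise(vol, strength=float(params.get("strength", 1.0)))
    result.input_key = series_id
    out = ctx.subdir("tomograms") / f"{series_id}_denoised.mrc"
    write_mrc(out, out_vol.voxels, out_vol.voxel_size)
    result.artifact_paths = [str(out)]
    result.forward = {"denoised_path": str(out), "artifact_path": str(out)}
    return result


def run_images(params: dict, ctx: StageContext) -> StageResult:
    artifact = (params.get("artifact_path") or params.get("denoised_path")
                or params.get("tomogram_path") or params.get("micrograph_path") or "")
    kind = params.get("kind", "micrograph")
    result = make_images(artifact, kind, ctx.subdir("images"))
    result.input_key = params.get("movie_id") or params.get("series_id", "")
    return result


def run_ispyb(params: dict, ctx: StageContext) -> StageResult:
    """LIMS connector: persist one outcome record (idempotent insert)."""
    if ctx.outcome_store is None:
        return StageResult.failure("ispyb", "", "store_unavailable",
                                   error_class="transient")
    try:
        record_id = ctx.outcome_store.record_outcome(params)
    except ValueError as exc:
        return StageResult.failure("ispyb", str(params.get("idempotency_key", "")),
                                   f"malformed_record:{exc}")
    return StageResult(stage="ispyb", input_key=str(params.get("idempotency_key", "")),
                       metrics={"record_id": record_id})


def run_dispatch(params: dict, ctx: StageContext) -> StageResult:
    """Workflow-triggering service: turn a processing request into the entry message."""
    from ..recipes import ProcessingRequest

    if ctx.dispatcher is None:
        return StageResult.failure("dispatch", "", "dispatcher_unavailable",
                                   error_class="transient")
    request = ProcessingRequest(
        recipe=params.get("recipe", ""),
        parameters=params.get("parameters", {}),
        session=params.get("session", ""),
        idempotency_key=params.get("idempotency_key", ""),
    )
    msg_id = ctx.dispatcher.dispatch(request)
    if msg_id is None:
        return StageResult.failure("dispatch", request.idempotency_key,
                                   "request_rejected")
    return StageResult(stage="dispatch", input_key=request.idempotency_key,
                       metrics={"entry_message": msg_id})


STAGE_RUNNERS: dict[str, Callable[[dict, StageContext], StageResult]] = {
    "motioncorr": run_motioncorr,
    "ctffind": run_ctffind,
    "tomo_align_recon": run_tomo_align_recon,
    "denoise": run_denoise,
    "images": run_images,
    "ispyb": run_ispyb,
    "dispatch": run_dispatch,
}


def get_runner(stage: str) -> Callable[[dict, StageContext], StageResult]:
    try:
        return STAGE_RUNNERS[stage]
    except KeyError:
        raise KeyError(f"no runner registered for stage {stage!r}") from None
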