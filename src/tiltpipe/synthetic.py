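"""Synthetic acquisition: phantoms, tilted noisy movies, schedules, replay.

Everything the pipeline consumes is generated here with known ground
truth, standing in for the microscope and detector: sphere phantoms,
parallel-beam tilt projections with per-frame drift, optional CTF blur and
Gaussian noise, mdoc-like metadata sidecars, and acquisition schedules
replayed onto a fake detector filesystem. Each dataset's manifest records
every generation parameter (drift, defocus, seeds), so every processing
stage can be scored against the truth without external data.

Default desk-scale geometry: 64×64 px frames, 8 frames per movie, 11 tilts
from −50° to +50° in 10° steps, 3 series — small enough that a complete
end-to-end run takes minutes on a single CPU while exercising every code
path the full-scale system has.

The projector shares the reconstruction module's geometry: tilt axis along
image y, detector coordinate ``u = x*cos(theta) - z*sin(theta)`` in centred
volume coordinates. Frame drift is cyclic (``np.roll``), matching the
wrap-around boundary model of the motion-correction stage.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
from scipy import ndimage

from . import mdoc
from .io_mrc import write_mrc
from .stages.ctf import apply_ctf
from .stages.recon import project_volume
from .stages.types import Micrograph, MovieStack

__all__ = [
    "Phantom", "ScheduleEvent", "AcquisitionSchedule",
    "make_phantom", "project_volume", "project_movie", "make_ctf_micrograph",
    "build_schedule", "replay",
]

DEFAULT_PIXEL_SIZE = 4.0  # Angstrom / px


@dataclass
class Phantom:
    """Ground-truth specimen: random non-overlapping spheres in a volume."""

    voxels: np.ndarray  # (Z, Y, X), float32, densities >= 0
    spheres: list[tuple[tuple[float, float, float], float, float]]  # (center zyx, r, density)
    seed: int


@dataclass
class ScheduleEvent:
    time: float  # seconds from session start
    series_id: str
    tilt_index: int
    angle: float  # degrees
    kind: str  # "movie" | "series_end"


@dataclass
class AcquisitionSchedule:
    pattern: str  # "sequential" | "beam_shift"
    events: list[ScheduleEvent] = field(default_factory=list)

    def series_ids(self) -> list[str]:
        seen: list[str] = []
        for e in self.events:
            if e.series_id not in seen:
                seen.append(e.series_id)
        return seen


def make_phantom(dims: tuple[int, int, int] = (64, 64, 64), n_spheres: int = 5,
                 seed: int = 0) -> Phantom:
    """Random sphere phantom; reproducible from ``seed``.

    Spheres are placed by rejection sampling to avoid overlap; if a sphere
    cannot be placed within a bounded number of retries the phantom is
    returned with fewer spheres and a warning.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = dims
    vol = np.zeros(dims, dtype=np.float32)
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    placed: list[tuple[tuple[float, float, float], float, float]] = []
    max_tries = 200
    for _ in range(n_spheres):
        for _try in range(max_tries):
            r = float(rng.uniform(0.06, 0.14) * min(dims))
            c = tuple(float(rng.uniform(r + 1, d - r - 1)) for d in dims)
            if all(np.sqrt(sum((a - b) ** 2 for a, b in zip(c, pc))) > r + pr + 1
                   for pc, pr, _ in placed):
                density = float(rng.uniform(0.5, 1.5))
                mask = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r ** 2
                vol[mask] += density
                placed.append((c, r, density))
                break
        else:
            warnings.warn(f"could only place {len(placed)} of {n_spheres} spheres")
            break
    return Phantom(voxels=vol, spheres=placed, seed=seed)


def project_movie(
    phantom: Phantom,
    angle_deg: float,
    n_frames: int = 8,
    drift_per_frame: tuple[int, int] = (1, 0),
    defocus_um: Optional[float] = None,
    noise_sigma: float = 1.0,
    seed: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    optics: Optional[dict] = None,
) -> tuple[MovieStack, dict]:
    """Simulate one movie: projection + cumulative drift + optional CTF + noise.

    Per-frame integer drift ``(dx, dy)`` px accumulates from frame to frame
    (frame i carries shift ``i*(dx, dy)``, applied cyclically). When
    ``defocus_um`` is given the projection is CTF-filtered in Fourier space
    before framing. Returns the movie plus the ground-truth record needed
    to score recovery: cumulative shifts, defocus, angle.
    """
    if abs(angle_deg) >= 90:
        raise ValueError("tilt angle must satisfy |angle| < 90 degrees")
    rng = np.random.default_rng(seed)
    base = project_volume(phantom.voxels, angle_deg)
    if defocus_um is not None:
        o = optics or {}
        base = apply_ctf(base, pixel_size, defocus_um,
                         voltage_kv=o.get("voltage_kv", 300.0),
                         cs_mm=o.get("cs_mm", 2.7),
                         amplitude_contrast=o.get("amplitude_contrast", 0.1))
    dx, dy = int(drift_per_frame[0]), int(drift_per_frame[1])
    frames = np.empty((n_frames,) + base.shape, dtype=np.float32)
    shifts: list[tuple[int, int]] = []
    for i in range(n_frames):
        sx, sy = i * dx, i * dy
        frame = np.roll(base, (sy, sx), axis=(0, 1))
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=base.shape)
        frames[i] = frame
        shifts.append((sx, sy))
    movie = MovieStack(frames=frames, pixel_size=pixel_size, tilt_angle=angle_deg)
    truth = {"shifts": shifts, "defocus_um": defocus_um, "angle": angle_deg,
             "noise_sigma": noise_sigma, "seed": seed}
    return movie, truth


def make_ctf_micrograph(size: int = 256, defocus_um: float = 2.0,
                        pixel_size: float = 2.0, seed: int = 0,
                        optics: Optional[dict] = None) -> Micrograph:
    """White-noise micrograph filtered by the CTF at a known defocus.

    The power spectrum of such an image is proportional to the squared
    CTF, which is exactly the observable the estimator fits — the
    generation defocus is the recovery oracle.
    """
    rng = np.random.default_rng(seed)
    o = optics or {}
    noise = rng.normal(0.0, 1.0, size=(size, size)).astype(np.float32)
    image = apply_ctf(noise, pixel_size, defocus_um,
                      voltage_kv=o.get("voltage_kv", 300.0),
                      cs_mm=o.get("cs_mm", 2.7),
                      amplitude_contrast=o.get("amplitude_contrast", 0.1))
    return Micrograph(image=image, pixel_size=pixel_size,
                      drift_trace=[(0.0, 0.0)], total_drift=0.0)


def build_schedule(
    pattern: str = "sequential",
    n_series: int = 3,
    n_tilts: int = 11,
    angle_range: tuple[float, float] = (-50.0, 50.0),
    burst_size: int = 1,
    inter_event_gap: float = 1.0,
    series_prefix: str = "Pos",
) -> AcquisitionSchedule:
    """Build a movie-arrival schedule.

    ``sequential``: each series' movies are contiguous in time, with its
    completion marker following immediately — reconstruction of one series
    can overlap acquisition of the next. ``beam_shift``: the schedule is
    angle-major across groups of ``burst_size`` series (all series of a
    group are exposed at one stage tilt before the angle advances), so a
    whole group finishes within ``burst_size`` gaps — the burst load the
    reconstruction autoscaler must absorb.
    """
    if n_series < 1 or n_tilts < 1:
        raise ValueError("n_series and n_tilts must be >= 1")
    if pattern not in ("sequential", "beam_shift"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if burst_size > n_series:
        warnings.warn(f"burst_size {burst_size} > n_series {n_series}; clamping")
        burst_size = n_series
    angles = (np.linspace(angle_range[0], angle_range[1], n_tilts)
              if n_tilts > 1 else np.array([0.5 * sum(angle_range)]))
    ids = [f"{series_prefix}{i + 1}" for i in range(n_series)]
    events: list[ScheduleEvent] = []
    t = 0.0
    if pattern == "sequential":
        for sid in ids:
            for i, a in enumerate(angles):
                events.append(ScheduleEvent(t, sid, i, float(a), "movie"))
                t += inter_event_gap
            events.append(ScheduleEvent(t, sid, n_tilts, 0.0, "series_end"))
    else:
        for g in range(0, n_series, burst_size):
            group = ids[g:g + burst_size]
            for i, a in enumerate(angles):
                for sid in group:
                    events.append(ScheduleEvent(t, sid, i, float(a), "movie"))
                    if i == n_tilts - 1:
                        events.append(ScheduleEvent(t, sid, n_tilts, 0.0, "series_end"))
                    t += inter_event_gap
    return AcquisitionSchedule(pattern=pattern, events=events)


def replay(
    schedule: AcquisitionSchedule,
    detector_root: str | Path,
    seed: int = 0,
    time_scale: float = 0.0,
    phantom_dims: tuple[int, int, int] = (64, 64, 64),
    n_spheres: int = 5,
    n_frames: int = 8,
    max_drift: int = 2,
    noise_sigma: float = 1.0,
    with_ctf: bool = False,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    optics: Optional[dict] = None,
) -> dict:
    """Write a schedule's movies and sidecars onto a fake detector tree.

    One phantom per series (reproducible from derived seeds); one MRC movie
    per event plus an appended mdoc block; a series-end event appends the
    ``ExpectedTilts`` completion line. ``time_scale`` scales the schedule's
    wall-clock gaps (0 writes everything at once — stress mode). Returns
    the manifest (also written as ``manifest.json``) carrying every
    ground-truth parameter keyed by movie id.
    """
    root = Path(detector_root)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    series_ids = schedule.series_ids()
    phantom_seeds = {sid: int(rng.integers(0, 2**31 - 1)) for sid in series_ids}
    defoci = {sid: float(rng.uniform(1.0, 3.0)) if with_ctf else None
              for sid in series_ids}
    phantoms = {sid: make_phantom(phantom_dims, n_spheres, phantom_seeds[sid])
                for sid in series_ids}
    manifest: dict[str, Any] = {
        "seed": seed,
        "pattern": schedule.pattern,
        "pixel_size": pixel_size,
        "series": {sid: {"phantom_seed": phantom_seeds[sid],
                         "phantom_dims": list(phantom_dims),
                         "n_spheres": n_spheres,
                         "defocus_um": defoci[sid],
                         "n_tilts": 0} for sid in series_ids},
        "movies": {},
    }
    sidecar_started: set[str] = set()
    prev_time = schedule.events[0].time if schedule.events else 0.0
    for ev in schedule.events:
        if time_scale > 0 and ev.time > prev_time:
            time.sleep((ev.time - prev_time) * time_scale)
        prev_time = ev.time
        sidecar = root / f"{ev.series_id}.mdoc"
        if ev.series_id not in sidecar_started:
            mdoc.write_header(sidecar, ev.series_id, PixelSpacing=pixel_size)
            sidecar_started.add(ev.series_id)
        if ev.kind == "series_end":
            mdoc.append_series_end(sidecar, manifest["series"][ev.series_id]["n_tilts"])
            continue
        movie_id = f"{ev.series_id}_{ev.tilt_index:03d}_{ev.angle:+.1f}"
        drift = (int(rng.integers(-max_drift, max_drift + 1)),
                 int(rng.integers(-max_drift, max_drift + 1)))
        movie_seed = int(rng.integers(0, 2**31 - 1))
        movie, truth = project_movie(
            phantoms[ev.series_id], ev.angle, n_frames=n_frames,
            drift_per_frame=drift, defocus_um=defoci[ev.series_id],
            noise_sigma=noise_sigma, seed=movie_seed, pixel_size=pixel_size,
            optics=optics)
        path = root / f"{movie_id}.mrc"
        write_mrc(path, movie.frames, pixel_size)
        mdoc.append_tilt(sidecar, ev.tilt_index, ev.angle, path.name)
        manifest["series"][ev.series_id]["n_tilts"] += 1
        manifest["movies"][movie_id] = {
            "series_id": ev.series_id, "tilt_index": ev.tilt_index,
            "angle": ev.angle, "path": str(path),
            "drift_per_frame": list(drift), **truth,
            "shifts": [list(s) for s in truth["shifts"]],
        }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
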