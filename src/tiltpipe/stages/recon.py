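"""Tilt-series alignment, weighted back-projection and tomogram denoising.

Geometry convention (shared with the synthetic projector, which imports
:func:`project_volume` from here): the tilt axis lies along image y;
volumes are (Z, Y, X) with z along the beam at zero tilt and all rotations
about the y axis. A projection at tilt angle theta maps centred volume
coordinates (z, x) onto the centred detector coordinate
``u = x*cos(theta) - z*sin(theta)``; y passes through unchanged. Angles are
degrees everywhere in the interface.

Alignment is translational, by projection matching: each raw tilt image is
cross-correlated against the reprojection of the current reconstruction at
its own angle, and the reconstruction is repeated with the refined shifts.
Correlating adjacent tilts directly would confuse genuine stage shifts
with the parallax of off-plane content (features at height z move by
``z*d(sin theta)`` between tilts even in a perfectly aligned series);
matching against the model's own reprojection cancels that term, and an
already-aligned series is a fixed point of the iteration. Estimated
shifts below 0.25 px are snapped to zero.

Reconstruction is ramp-filtered (weighted) back-projection; denoising is
an isotropic Gaussian filter, the desk-scale stand-in for a trained
denoising model.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .motion import correlation_shift
from .types import Micrograph, StageResult, TomogramVolume

__all__ = ["align_and_reconstruct", "denoise", "ramp_filter", "project_volume"]

_SHIFT_DEADBAND = 0.25  # px; snap smaller alignment shifts to zero


def project_volume(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Parallel-beam projection of a (Z, Y, X) volume about the y tilt axis.

    Returns a (Y, X) image of line integrals along the beam direction
    tilted by ``angle_deg`` in the x-z plane (linear interpolation,
    zero-padded outside the volume).
    """
    nz, ny, nx = vol.shape
    th = np.deg2rad(angle_deg)
    n_t = int(np.ceil(np.sqrt(2.0) * max(nz, nx))) + 1
    u = np.arange(nx) - (nx - 1) / 2.0
    t = np.arange(n_t) - (n_t - 1) / 2.0
    x = (nx - 1) / 2.0 + u[None, :] * np.cos(th) + t[:, None] * np.sin(th)  # (T, U)
    z = (nz - 1) / 2.0 + t[:, None] * np.cos(th) - u[None, :] * np.sin(th)
    coords = [
        np.broadcast_to(z[:, None, :], (n_t, ny, nx)),
        np.broadcast_to(np.arange(ny)[None, :, None], (n_t, ny, nx)),
        np.broadcast_to(x[:, None, :], (n_t, ny, nx)),
    ]
    samples = ndimage.map_coordinates(vol, coords, order=1, mode="constant", cval=0.0)
    return samples.sum(axis=0).astype(np.float32)


def ramp_filter(image: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply the |f| ramp weighting along one axis (Fourier multiplication)."""
    n = image.shape[axis]
    freqs = np.abs(np.fft.rfftfreq(n))
    spec = np.fft.rfft(image, axis=axis)
    shape = [1] * image.ndim
    shape[axis] = len(freqs)
    return np.fft.irfft(spec * freqs.reshape(shape), n=n, axis=axis)


def _backproject(filtered: np.ndarray, angle_deg: float, vol: np.ndarray) -> None:
    """Accumulate one ramp-filtered projection (Y, X) into vol (Z, Y, X)."""
    nz, ny, nx = vol.shape
    th = np.deg2rad(angle_deg)
    zz = np.arange(nz) - (nz - 1) / 2.0
    xx = np.arange(nx) - (nx - 1) / 2.0
    u = xx[None, :] * np.cos(th) - zz[:, None] * np.sin(th) + (filtered.shape[1] - 1) / 2.0
    flo = np.floor(u).astype(np.int64)
    w = u - flo
    w0 = (1.0 - w) * ((flo >= 0) & (flo < filtered.shape[1]))
    w1 = w * ((flo + 1 >= 0) & (flo + 1 < filtered.shape[1]))
    c0 = np.clip(flo, 0, filtered.shape[1] - 1)
    c1 = np.clip(flo + 1, 0, filtered.shape[1] - 1)
    contrib = filtered[:, c0] * w0[None] + filtered[:, c1] * w1[None]  # (Y, Z, X)
    vol += contrib.transpose(1, 0, 2)


def _wbp(images: list[np.ndarray], angles: list[float],
         shifts: list[tuple[float, float]], thickness: int) -> np.ndarray:
    ny, nx = images[0].shape
    vol = np.zeros((int(thickness), ny, nx), dtype=np.float64)
    for img, angle, (dx, dy) in zip(images, angles, shifts):
        aligned = ndimage.shift(img, (-dy, -dx), order=1, mode="grid-wrap") \
            if (dx or dy) else img
        _backproject(ramp_filter(aligned, axis=1), angle, vol)
    vol *= np.pi / (2.0 * len(images))
    return vol


def align_and_reconstruct(
    tilts: list[Micrograph],
    angles: list[float],
    thickness: int = 64,
    max_shift: int = 8,
    n_iter: int = 2,
) -> tuple[TomogramVolume | None, StageResult]:
    """Align a tilt series by projection matching and reconstruct by WBP.

    ``angles`` must be strictly monotone and match ``tilts`` in length; at
    least 3 tilts are required for a meaningful reconstruction.
    Deterministic for fixed inputs.
    """
    if len(tilts) != len(angles):
        return None, StageResult.failure("tomo_align_recon", "", "mismatched_lengths")
    if len(tilts) < 3:
        return None, StageResult.failure("tomo_align_recon", "", "insufficient_tilts")
    diffs = np.diff(np.asarray(angles, dtype=float))
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        return None, StageResult.failure("tomo_align_recon", "", "angles_not_monotone")

    images = [np.asarray(t.image, dtype=np.float64) for t in tilts]
    shifts: list[tuple[float, float]] = [(0.0, 0.0)] * len(images)
    for _ in range(max(0, n_iter)):
        vol = _wbp(images, angles, shifts, thickness)
        new_shifts: list[tuple[float, float]] = []
        for img, angle in zip(images, angles):
            reproj = project_volume(vol, angle).astype(np.float64)
            dx, dy = correlation_shift(reproj, img, max_shift)
            if abs(dx) < _SHIFT_DEADBAND:
                dx = 0.0
            if abs(dy) < _SHIFT_DEADBAND:
                dy = 0.0
            new_shifts.append((dx, dy))
        if np.allclose(new_shifts, shifts, atol=0.1):
            shifts = new_shifts
            break
        shifts = new_shifts
    vol = _wbp(images, angles, shifts, thickness)

    tomo = TomogramVolume(
        voxels=vol.astype(np.float32),
        voxel_size=tilts[0].pixel_size,
        alignment_shifts=[(float(dx), float(dy)) for dx, dy in shifts],
    )
    central = vol[vol.shape[0] // 2]
    result = StageResult(
        stage="tomo_align_recon", input_key="",
        metrics={
            "n_tilts": len(tilts),
            "alignment_shifts": [list(s) for s in tomo.alignment_shifts],
            "central_slice": {"mean": float(central.mean()), "std": float(central.std()),
                              "min": float(central.min()), "max": float(central.max())},
        },
    )
    return tomo, result


def denoise(vol: TomogramVolume, strength: float = 1.0) -> tuple[TomogramVolume, StageResult]:
    """Gaussian smoothing of a tomogram; strength is sigma in voxels.

    Strength 0 is the identity; variance never increases.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    voxels = np.asarray(vol.voxels, dtype=np.float32)
    out = ndimage.gaussian_filter(voxels, sigma=strength) if strength > 0 else voxels.copy()
    denoised = TomogramVolume(voxels=out, voxel_size=vol.voxel_size,
                              alignment_shifts=list(vol.alignment_shifts), denoised=True)
    result = StageResult(
        stage="denoise", input_key="",
        metrics={"strength": float(strength),
                 "variance_before": float(voxels.var()),
                 "variance_after": float(out.var())},
    )
    return denoised, result
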