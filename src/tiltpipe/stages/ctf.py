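"""Defocus estimation from a micrograph's radially averaged power spectrum.

The microscope's contrast transfer function modulates image contrast with
an oscillation (Thon rings) whose ring spacing is set chiefly by defocus.
The estimator computes the rotationally averaged power spectrum, removes
the smooth background with a high-pass (the profile minus its heavily
smoothed self), and grid-searches defocus for the best Pearson correlation
between the residual oscillation and the modelled squared CTF. The fit is
1-D (radial) only; astigmatism is out of scope.

Conventions: defocus in micrometres, underfocus positive; spatial
frequency k in 1/Angstrom; phase chi(k) = pi*lambda*dz*k^2 -
(pi/2)*Cs*lambda^3*k^4 + phase(amplitude contrast), CTF = -sin(chi).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import CtfResult, Micrograph, StageResult

__all__ = ["electron_wavelength", "ctf_1d", "radial_power_spectrum",
           "apply_ctf", "estimate_ctf"]

_MIN_SIZE = 32


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom (300 kV -> ~0.0197 A)."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_1d(k: np.ndarray, defocus_um: float, voltage_kv: float, cs_mm: float,
           amplitude_contrast: float) -> np.ndarray:
    """CTF amplitude at spatial frequencies ``k`` (1/Angstrom)."""
    lam = electron_wavelength(voltage_kv)
    dz = defocus_um * 1e4  # A, underfocus positive
    cs = cs_mm * 1e7  # A
    phase_shift = np.arcsin(np.clip(amplitude_contrast, 0.0, 1.0))
    chi = np.pi * lam * dz * k**2 - 0.5 * np.pi * cs * lam**3 * k**4 + phase_shift
    return -np.sin(chi)


def apply_ctf(image: np.ndarray, pixel_size: float, defocus_um: float,
              voltage_kv: float = 300.0, cs_mm: float = 2.7,
              amplitude_contrast: float = 0.1) -> np.ndarray:
    """Filter an image by the 2-D (astigmatism-free) CTF in Fourier space."""
    h, w = image.shape
    ky = np.fft.fftfreq(h, d=pixel_size)
    kx = np.fft.rfftfreq(w, d=pixel_size)
    k = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    filt = ctf_1d(k, defocus_um, voltage_kv, cs_mm, amplitude_contrast)
    return np.fft.irfft2(np.fft.rfft2(image) * filt, s=image.shape).astype(np.float32)


def radial_power_spectrum(image: np.ndarray, pixel_size: float,
                          n_bins: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally averaged power spectrum; returns (k centres, power)."""
    h, w = image.shape
    ps = np.abs(np.fft.fftshift(np.fft.fft2(image - image.mean()))) ** 2
    ky = np.fft.fftshift(np.fft.fftfreq(h, d=pixel_size))
    kx = np.fft.fftshift(np.fft.fftfreq(w, d=pixel_size))
    k = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    nyquist = 0.5 / pixel_size
    if n_bins is None:
        n_bins = min(h, w) // 2
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    idx = np.clip(np.digitize(k.ravel(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=ps.ravel(), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    profile = sums / np.maximum(counts, 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, profile


def _oscillation(profile: np.ndarray, smooth_bins: float = 6.0) -> np.ndarray:
    """High-pass a radial profile: subtract its heavily smoothed self."""
    return profile - ndimage.gaussian_filter1d(profile, smooth_bins, mode="nearest")


def estimate_ctf(
    mic: Micrograph,
    optics: dict,
    search: dict,
    fit_band: tuple[float, float] | None = None,
) -> tuple[CtfResult | None, StageResult]:
    """Grid-search the defocus best explaining the micrograph's Thon rings.

    ``optics`` carries voltage_kv, cs_mm, amplitude_contrast; ``search``
    carries defocus_min_um, defocus_max_um, step_um. ``fit_band`` restricts
    the fitted frequency range (1/Angstrom); the default skips the lowest
    12% of Nyquist, where the background dominates, and the top 12%, where
    ring spacing approaches the bin width. Deterministic for fixed input.
    """
    lo, hi, step = (float(search["defocus_min_um"]), float(search["defocus_max_um"]),
                    float(search["step_um"]))
    if not (lo < hi and step > 0):
        raise ValueError("invalid defocus search range")
    image = np.asarray(mic.image, dtype=np.float64)
    if min(image.shape) < _MIN_SIZE:
        return None, StageResult.failure("ctffind", "", "image_too_small")

    k, profile = radial_power_spectrum(image, mic.pixel_size)
    nyquist = 0.5 / mic.pixel_size
    if fit_band is None:
        fit_band = (0.12 * nyquist, 0.88 * nyquist)
    band = (k >= fit_band[0]) & (k <= fit_band[1])
    data = _oscillation(profile)[band]
    data_std = float(np.std(data))

    grid = np.arange(lo, hi + 0.5 * step, step)
    best_dz, best_score = grid[0], -np.inf
    if data_std > 0:
        for dz in grid:
            model = _oscillation(ctf_1d(k, dz, **{
                "voltage_kv": optics["voltage_kv"], "cs_mm": optics["cs_mm"],
                "amplitude_contrast": optics["amplitude_contrast"]}) ** 2)[band]
            ms = float(np.std(model))
            if ms == 0:
                continue
            score = float(np.mean((data - data.mean()) * (model - model.mean()))
                          / (data_std * ms))
            if score > best_score:
                best_dz, best_score = float(dz), score
    else:
        best_score = 0.0  # constant image: no oscillation to fit

    low_confidence = best_score < 0.1
    ctf = CtfResult(defocus=float(best_dz), fit_score=float(max(best_score, 0.0) if
                                                           np.isfinite(best_score) else 0.0),
                    power_spectrum_1d=profile, low_confidence=low_confidence)
    result = StageResult(
        stage="ctffind", input_key="",
        metrics={"defocus": ctf.defocus, "fit_score": ctf.fit_score,
                 "low_confidence": low_confidence},
    )
    return ctf, result
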