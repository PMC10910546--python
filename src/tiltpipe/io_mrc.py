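"""MRC volume/image I/O backed by gemmi's CCP4/MRC map support.

Everything the pipeline writes to disk (movies, micrographs, tomograms) is
MRC mode 2 (float32). Arrays are kept in the package's native index order:
2-D images are (y, x), movie stacks are (frame, y, x) and volumes are
(z, y, x). gemmi's numpy view of a map grid is (x, y, z)-ordered, so data
are transposed on the way in and out; the voxel size is carried in the map
unit cell.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np

__all__ = ["read_mrc", "write_mrc"]


def write_mrc(path: str | os.PathLike, data: np.ndarray, voxel_size: float = 1.0) -> str:
    """Write a 2-D or 3-D float array as an MRC (mode 2) map.

    2-D input is stored as a single-section volume. ``voxel_size`` is in
    Angstrom per pixel, isotropic.
    """
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D data, got {arr.ndim}-D")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    nz, ny, nx = arr.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.array(grid, copy=False)[:] = arr.T
    grid.unit_cell = gemmi.UnitCell(
        nx * voxel_size, ny * voxel_size, nz * voxel_size, 90.0, 90.0, 90.0
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(os.fspath(path))
    return os.fspath(path)


def read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read an MRC map; returns ``(data, voxel_size)``.

    Data come back (z, y, x)-ordered; a single-section map is squeezed to
    a 2-D (y, x) image.
    """
    m = gemmi.read_ccp4_map(os.fspath(path))
    arr = np.array(m.grid, copy=True).T.astype(np.float32)
    voxel = m.grid.unit_cell.a / m.grid.nu if m.grid.nu else 1.0
    if arr.shape[0] == 1:
        arr = arr[0]
    return arr, float(voxel)
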