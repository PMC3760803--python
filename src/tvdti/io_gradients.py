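"""Volume and gradient-table I/O.

Defines the grid and coordinate conventions used throughout the package:
voxel indices are 0-based, world coordinates in mm are ``index * voxel_size``
(no affine/rotation support -- everything downstream is grid-local), and
diffusion volumes are stored x-y-z with the gradient direction on the last
axis, matching the NIfTI 4D layout.

Gradient tables are FSL-dialect ``.bval``/``.bvec`` text files (bvec: 3 rows
by M columns). Volumes with b below :data:`B0_THRESHOLD` are treated as
unweighted and averaged into the b=0 reference image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "B0_THRESHOLD",
    "MIN_DIRECTIONS",
    "GradientScheme",
    "VolumeGrid",
    "DWISeries",
    "GradientTableError",
    "InsufficientDirectionsError",
    "default_scheme",
    "read_dwi",
    "read_volume",
    "write_volume",
    "write_gradient_table",
]

#: b-values below this (s/mm^2) count as unweighted; tolerates vendor "b=0"
#: volumes that carry a small residual weighting.
B0_THRESHOLD = 50.0

#: A symmetric tensor has six independent elements; fewer encoding
#: directions cannot determine it.
MIN_DIRECTIONS = 6


class GradientTableError(ValueError):
    """Malformed or inconsistent gradient table."""


class InsufficientDirectionsError(ValueError):
    """Fewer diffusion-encoding directions than the method requires."""


def _normalize_directions(directions: np.ndarray) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.ndim != 2 or directions.shape[1] != 3:
        raise GradientTableError(
            f"directions must be (N, 3), got {directions.shape}"
        )
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms < 1e-12):
        raise GradientTableError("zero-norm diffusion encoding direction")
    # scale only rows that need it, so normalization is exactly idempotent
    out = directions.copy()
    off = np.abs(norms - 1.0) > 1e-12
    out[off] /= norms[off, None]
    return out


@dataclass(frozen=True)
class GradientScheme:
    """Single-shell diffusion encoding: one b-value plus N unit directions.

    Parameters
    ----------
    bvalue : float
        Diffusion weighting in s/mm^2.
    directions : (N, 3) array
        Encoding directions; normalized to unit length on construction
        (normalization is idempotent).
    """

    bvalue: float
    directions: np.ndarray

    def __post_init__(self) -> None:
        if self.bvalue <= 0:
            raise GradientTableError("bvalue must be positive")
        object.__setattr__(
            self, "directions", _normalize_directions(self.directions)
        )

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class VolumeGrid:
    """Regular voxel grid: shape in voxels and voxel size in mm.

    Anisotropic voxels are permitted (the reference configuration is
    1 x 1 x 2.5 mm^3). World mm coordinates are ``index * voxel_size``;
    the center of voxel (i, j, k) is at ``(index + 0.5) * voxel_size``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {shape}")
        if len(voxel_size) != 3 or any(v <= 0 for v in voxel_size):
            raise ValueError(f"voxel size must be 3 positive floats, got {voxel_size}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths of the grid bounding box (mm)."""
        return np.asarray(self.shape, float) * np.asarray(self.voxel_size, float)

    @property
    def diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.extent_mm))


@dataclass
class DWISeries:
    """A b=0 reference volume plus N diffusion-weighted volumes.

    ``dwi`` is shaped ``grid.shape + (N,)`` with the direction on the last
    axis, ordered like ``scheme.directions``.
    """

    s0: np.ndarray
    dwi: np.ndarray
    grid: VolumeGrid
    scheme: GradientScheme

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.dwi = np.asarray(self.dwi, dtype=float)
        if self.s0.shape != self.grid.shape:
            raise ValueError(
                f"s0 shape {self.s0.shape} != grid shape {self.grid.shape}"
            )
        expected = self.grid.shape + (self.scheme.n_directions,)
        if self.dwi.shape != expected:
            raise ValueError(f"dwi shape {self.dwi.shape} != {expected}")


def default_scheme(n_directions: int = 12, bvalue: float = 1000.0) -> GradientScheme:
    """Well-spread single-shell scheme (Fibonacci hemisphere lattice).

    The reference configuration is 12 directions at b = 1000 s/mm^2. The
    resulting design matrix has full rank 6 for any ``n_directions >= 6``
    of this lattice.
    """
    k = np.arange(n_directions)
    z = (k + 0.5) / n_directions
    r = np.sqrt(1.0 - z**2)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    directions = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return GradientScheme(bvalue=bvalue, directions=directions)


def _load_table(path: str | Path) -> np.ndarray:
    try:
        return np.loadtxt(path, dtype=float, ndmin=2)
    except Exception as exc:  # noqa: BLE001 - normalize to a format error
        raise GradientTableError(f"cannot parse gradient table {path}: {exc}") from exc


def read_dwi(
    path_volume: str | Path,
    path_bval: str | Path,
    path_bvec: str | Path,
) -> DWISeries:
    """Read a 4D NIfTI volume with its FSL-style bval/bvec gradient table.

    Volumes with b < 50 s/mm^2 are averaged into ``s0``; the remaining
    volumes populate ``dwi`` with their (normalized) directions. The grid is
    taken from the NIfTI header voxel dimensions.
    """
    img = nib.load(str(path_volume))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise GradientTableError(
            f"expected a 4D volume, got shape {data.shape}"
        )
    bvals = _load_table(path_bval).ravel()
    bvecs = _load_table(path_bvec)
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != 3:
        raise GradientTableError(
            f"bvec must have 3 rows (FSL dialect), got shape {bvecs.shape}"
        )
    n_vol = data.shape[3]
    if bvals.size != n_vol or bvecs.shape[1] != n_vol:
        raise GradientTableError(
            f"volume count {n_vol} does not match gradient table "
            f"({bvals.size} bvals, {bvecs.shape[1]} bvec columns)"
        )

    low = bvals < B0_THRESHOLD
    if not np.any(low):
        raise GradientTableError("no b=0 volume (all b >= 50 s/mm^2)")
    n_dwi = int(np.count_nonzero(~low))
    if n_dwi < MIN_DIRECTIONS:
        raise InsufficientDirectionsError(
            f"{n_dwi} diffusion-weighted volumes; at least "
            f"{MIN_DIRECTIONS} directions are required"
        )
    b_shell = bvals[~low]
    b_mean = float(b_shell.mean())
    if (b_shell.max() - b_shell.min()) > 0.05 * b_mean:
        raise GradientTableError(
            "multi-shell acquisitions are not supported "
            f"(b ranges {b_shell.min():g}..{b_shell.max():g})"
        )

    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(shape=data.shape[:3], voxel_size=tuple(float(z) for z in zooms))
    s0 = data[..., low].mean(axis=3)
    scheme = GradientScheme(bvalue=b_mean, directions=bvecs[:, ~low].T)
    return DWISeries(s0=s0, dwi=data[..., ~low], grid=grid, scheme=scheme)


def _affine(grid: VolumeGrid) -> np.ndarray:
    return np.diag([*grid.voxel_size, 1.0])


def write_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    """Write a 3D or 4D array as NIfTI-1 with the grid's voxel sizes.

    Data is stored as float64, so a write/read round trip preserves values
    bit-exactly.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim not in (3, 4) or data.shape[:3] != grid.shape:
        raise ValueError(
            f"data shape {data.shape} inconsistent with grid {grid.shape}"
        )
    img = nib.Nifti1Image(data, _affine(grid))
    zooms = grid.voxel_size + ((1.0,) if data.ndim == 4 else ())
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a NIfTI volume, returning the data array and its grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected 3D or 4D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(shape=data.shape[:3], voxel_size=tuple(float(z) for z in zooms))
    return data, grid


def write_gradient_table(
    scheme: GradientScheme,
    path_bval: str | Path,
    path_bvec: str | Path,
    n_b0: int = 1,
) -> None:
    """Write an FSL-dialect bval/bvec pair with ``n_b0`` leading b=0 columns."""
    if n_b0 < 0:
        raise ValueError("n_b0 must be >= 0")
    bvals = np.concatenate([np.zeros(n_b0), np.full(scheme.n_directions, scheme.bvalue)])
    bvecs = np.hstack([np.zeros((3, n_b0)), scheme.directions.T])
    np.savetxt(path_bval, bvals[None, :], fmt="%.6g")
    np.savetxt(path_bvec, bvecs, fmt="%.9f")
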