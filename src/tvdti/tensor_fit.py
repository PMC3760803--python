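"""Diffusion tensor estimation and tensor-space noise projection.

The forward model is the Stejskal--Tanner equation
``S_i = S0 * exp(-b * g_i^T D g_i)``. Taking logs linearizes it:
``y_i = ln(S0 / S_i) / b = B_i . d`` where ``B`` is the encoding design
matrix and ``d`` the six-vector of independent tensor elements. The linear
least-squares (LLS) solution is ``d = (B^T B)^{-1} B^T y``.

The same pseudoinverse projects a DWI-space noise series into tensor space:
to first order, noise ``eps_i`` on a denoised signal ``S_hat_i`` perturbs the
log-linearization by ``-eps_i / (b * S_hat_i)``, so the induced tensor-element
perturbation is ``d_eps = pinv(B) @ (-eps / (b * S_hat))``. This "noise
tensor" carries the spatial noise distribution per tensor element and feeds
the spatially varying regularization.

Tensor element channels are ordered (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
project-wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_gradients import (
    MIN_DIRECTIONS,
    DWISeries,
    GradientScheme,
    InsufficientDirectionsError,
    VolumeGrid,
)

__all__ = [
    "TENSOR_CHANNELS",
    "CHANNEL_WEIGHTS",
    "TensorField",
    "NoiseTensorField",
    "DesignMatrix",
    "DegenerateSchemeError",
    "tensor_to_matrix",
    "matrix_to_tensor",
    "design_matrix",
    "fit_tensor",
    "fit_noise_tensor",
    "enforce_psd",
    "eigensystem",
    "fa_md_maps",
]

#: Fixed project-wide channel order for the six independent elements of the
#: symmetric diffusion tensor.
TENSOR_CHANNELS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

#: Multiplicity of each channel in the full symmetric 3x3 matrix; the
#: Frobenius norm of D is ``sqrt(sum(CHANNEL_WEIGHTS * d**2))``.
CHANNEL_WEIGHTS = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

#: Signals below this fraction of S0 are floored before the log transform.
SIGNAL_FLOOR = 1e-6


class DegenerateSchemeError(ValueError):
    """Encoding directions do not span the six tensor degrees of freedom."""


@dataclass
class TensorField:
    """Six-channel symmetric tensor per voxel, units mm^2/s.

    ``elements`` is shaped ``grid.shape + (6,)`` in :data:`TENSOR_CHANNELS`
    order. ``mask`` (optional) flags voxels where the fit was valid.
    """

    elements: np.ndarray
    grid: VolumeGrid
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        expected = self.grid.shape + (6,)
        if self.elements.shape != expected:
            raise ValueError(
                f"elements shape {self.elements.shape} != {expected}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid")


class NoiseTensorField(TensorField):
    """Per-voxel noise contribution to each tensor element (mm^2/s)."""


_IDX = np.array([[0, 3, 4], [3, 1, 5], [4, 5, 2]])


def tensor_to_matrix(elements: np.ndarray) -> np.ndarray:
    """(..., 6) channel vectors -> (..., 3, 3) symmetric matrices."""
    return np.asarray(elements)[..., _IDX]


def matrix_to_tensor(matrices: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) channel vectors."""
    m = np.asarray(matrices)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


@dataclass(frozen=True)
class DesignMatrix:
    """Encoding gradient design matrix with its cached pseudoinverse.

    Row i is ``(gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)`` for unit
    direction g_i, so that ``B @ d = g^T D g`` per direction.
    """

    B: np.ndarray
    pinv: np.ndarray

    @property
    def n_directions(self) -> int:
        return self.B.shape[0]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.B))


def design_matrix(scheme: GradientScheme) -> DesignMatrix:
    g = scheme.directions
    B = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    if np.linalg.matrix_rank(B) < 6:
        raise DegenerateSchemeError(
            f"design matrix rank {np.linalg.matrix_rank(B)} < 6; "
            "directions do not span tensor space"
        )
    return DesignMatrix(B=B, pinv=np.linalg.pinv(B))


def fit_tensor(dwi: DWISeries) -> TensorField:
    """Per-voxel LLS tensor fit ``d = pinv(B) @ ln(S0/S_i)/b``.

    Voxels with ``s0 <= 0`` get a zero tensor and are excluded from the
    returned mask. Signals are floored at ``SIGNAL_FLOOR * s0`` before the
    log to avoid infinities.
    """
    if dwi.scheme.n_directions < MIN_DIRECTIONS:
        raise InsufficientDirectionsError(
            f"tensor fit needs >= {MIN_DIRECTIONS} directions, "
            f"got {dwi.scheme.n_directions}"
        )
    dm = design_matrix(dwi.scheme)
    b = dwi.scheme.bvalue
    mask = dwi.s0 > 0
    s0 = np.where(mask, dwi.s0, 1.0)
    floor = SIGNAL_FLOOR * s0[..., None]
    signals = np.maximum(dwi.dwi, floor)
    y = np.log(s0[..., None] / signals) / b
    d = y @ dm.pinv.T
    d[~mask] = 0.0
    return TensorField(elements=d, grid=dwi.grid, mask=mask)


def fit_noise_tensor(noise: np.ndarray, denoised: DWISeries) -> NoiseTensorField:
    """Project a DWI-space noise series into tensor space.

    ``noise`` has the same layout as ``denoised.dwi``. The per-voxel
    first-order perturbation of the log-linearization by additive noise is
    ``y_eps_i = -eps_i / (b * S_hat_i)``; applying the cached pseudoinverse
    gives the noise tensor. Voxels where any ``S_hat_i`` falls below
    ``SIGNAL_FLOOR * s0`` are masked out (zero noise tensor, mask False).
    """
    noise = np.asarray(noise, dtype=float)
    if noise.shape != denoised.dwi.shape:
        raise ValueError(
            f"noise shape {noise.shape} != dwi shape {denoised.dwi.shape}"
        )
    dm = design_matrix(denoised.scheme)
    b = denoised.scheme.bvalue
    s0_ok = denoised.s0 > 0
    floor = SIGNAL_FLOOR * np.where(s0_ok, denoised.s0, 1.0)[..., None]
    valid = s0_ok & np.all(denoised.dwi > floor, axis=-1)
    s_hat = np.where(denoised.dwi > floor, denoised.dwi, 1.0)
    y = -noise / (b * s_hat)
    d = y @ dm.pinv.T
    d[~valid] = 0.0
    return NoiseTensorField(elements=d, grid=denoised.grid, mask=valid)


def enforce_psd(tensors: TensorField) -> TensorField:
    """Clamp negative eigenvalues to zero, keeping eigenvectors.

    The diffusion tensor is physically positive (semi)definite; noise or
    regularization can violate that, and the repair replaces negative
    eigenvalues with zero. Voxels that are already PSD are passed through
    bit-identically; the operation is idempotent.
    """
    elements = tensors.elements.copy()
    mats = tensor_to_matrix(elements.reshape(-1, 6))
    evals = np.linalg.eigvalsh(mats)
    # rounding-scale tolerance keeps the repair idempotent: recomposition
    # itself perturbs eigenvalues by ~eps * scale
    scale = np.abs(evals).max(axis=1)
    bad = evals[:, 0] < -1e-13 * scale
    if np.any(bad):
        w, v = np.linalg.eigh(mats[bad])
        w = np.maximum(w, 0.0)
        repaired = np.einsum("...ij,...j,...kj->...ik", v, w, v)
        flat = elements.reshape(-1, 6)
        flat[bad] = matrix_to_tensor(repaired)
    return TensorField(
        elements=elements, grid=tensors.grid,
        mask=None if tensors.mask is None else tensors.mask.copy(),
    )


def eigensystem(tensors: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors per voxel.

    Returns ``(evals, evecs)`` shaped ``grid + (3,)`` and ``grid + (3, 3)``;
    ``evecs[..., :, k]`` is the eigenvector of ``evals[..., k]``, so the
    principal direction is ``evecs[..., :, 2]``.
    """
    return np.linalg.eigh(tensor_to_matrix(tensors.elements))


def fa_md_maps(tensors: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """Fractional anisotropy (dimensionless, [0, 1]) and mean diffusivity.

    FA = sqrt(3/2 * sum((l - MD)^2) / sum(l^2)) from the eigenvalues l;
    zero where the tensor vanishes.
    """
    evals = np.linalg.eigvalsh(tensor_to_matrix(tensors.elements))
    md = evals.mean(axis=-1)
    num = ((evals - md[..., None]) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0), md
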