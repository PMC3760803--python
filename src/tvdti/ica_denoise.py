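"""ICA-based separation of signal and noise in diffusion-weighted slices.

Each axial slice of an N-direction DWI series is treated as N observed
mixtures of N statistically independent spatial source maps. Blind source
separation (FastICA) recovers the sources; a data-driven spatial statistic
then labels each component as *signal* (tissue microstructure / directed
diffusion -- spatially structured) or *noise* (spatially white). Zeroing
the noise components and inverting the mixing yields a denoised series; the
complement yields a matched noise series used for the tensor-space noise
projection.

For data that follow the tensor model, six components carry signal
regardless of the number of encoding directions -- a symmetric tensor has
six independent elements -- so with 12 directions one expects six signal
and six noise components. The classifier does not hard-code that split:
it scores each component's lag-1 spatial autocorrelation, keeping the
six-signal outcome a testable prediction. Classification is a function of
component content only, never of component order (any permutation can be
applied to the basic ICA model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io_gradients import DWISeries

__all__ = [
    "SIGNAL",
    "NOISE",
    "AUTOCORR_THRESHOLD",
    "MIN_ICA_DIRECTIONS",
    "ICADecomposition",
    "DecompositionError",
    "decompose_slice",
    "spatial_autocorrelation",
    "classify_components",
    "reconstruct",
    "denoise_series",
]

SIGNAL = "signal"
NOISE = "noise"

#: Lag-1 spatial autocorrelation above which a component counts as signal.
#: Noise components are spatially white (autocorrelation near zero); tissue
#: and diffusion components are smooth (autocorrelation near one).
AUTOCORR_THRESHOLD = 0.2

#: Six components carry the tensor degrees of freedom, so at least one more
#: direction is needed for a noise subspace to exist.
MIN_ICA_DIRECTIONS = 7


class DecompositionError(ValueError):
    """The slice stack cannot be decomposed (e.g. rank deficiency)."""


@dataclass
class ICADecomposition:
    """One slice's ICA factorization: ``stack = mixing @ components + mean``.

    ``components`` holds N variance-normalized spatial maps (rows, flattened
    pixels); ``mixing`` is the N x N matrix mapping components to the
    observed direction images; ``mean`` is the per-direction-image mean
    removed before unmixing. ``labels[k]`` tags component k as signal or
    noise once classified.
    """

    components: np.ndarray
    mixing: np.ndarray
    mean: np.ndarray
    map_shape: tuple[int, int]
    slice_index: int = 0
    labels: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def component_map(self, k: int) -> np.ndarray:
        return self.components[k].reshape(self.map_shape)

    def reconstruction(self) -> np.ndarray:
        """All components mixed back: reproduces the input stack."""
        flat = self.mixing @ self.components + self.mean[:, None]
        return flat.reshape((self.n_components, *self.map_shape))


def decompose_slice(stack: np.ndarray, seed: int = 0) -> ICADecomposition:
    """FastICA on one slice's N direction images.

    ``stack`` is (N, ny, nx). Requires N >= 7 (six tensor degrees of
    freedom plus a noise subspace). Deterministic given ``seed``; the
    component order is arbitrary and handled downstream by
    :func:`classify_components`.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"stack must be (N, ny, nx), got {stack.shape}")
    n = stack.shape[0]
    if n < MIN_ICA_DIRECTIONS:
        raise DecompositionError(
            f"{n} direction images; blind separation of the six-dimensional "
            f"tensor subspace needs at least {MIN_ICA_DIRECTIONS}"
        )
    X = stack.reshape(n, -1)
    centered = X - X.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(centered)
    if rank < n:
        raise DecompositionError(
            f"slice stack is rank deficient (rank {rank} < {n}); "
            "direction images are linearly dependent"
        )
    ica = FastICA(
        n_components=n,
        random_state=int(seed) % (2**31 - 1),
        whiten="unit-variance",
        max_iter=800,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        # Rotations inside an i.i.d. Gaussian noise subspace are
        # indeterminate; FastICA flags that as non-convergence although the
        # factorization (and hence reconstruction) is unaffected.
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(X.T)  # (pixels, N)
    components = sources.T
    mixing = ica.mixing_.copy()
    # Variance-normalize components; carry the scale in the mixing matrix.
    stds = components.std(axis=1)
    stds[stds == 0] = 1.0
    components /= stds[:, None]
    mixing *= stds[None, :]
    return ICADecomposition(
        components=components,
        mixing=mixing,
        mean=ica.mean_.copy(),
        map_shape=stack.shape[1:],
    )


def spatial_autocorrelation(map2d: np.ndarray) -> float:
    """Mean of the lag-1 Pearson autocorrelations along the two image axes."""
    m = np.asarray(map2d, dtype=float)
    m = m - m.mean()
    acs = []
    for a, b in ((m[1:, :], m[:-1, :]), (m[:, 1:], m[:, :-1])):
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        acs.append(float((a * b).sum() / denom) if denom > 0 else 0.0)
    return float(np.mean(acs))


def classify_components(dec: ICADecomposition) -> ICADecomposition:
    """Label each component signal or noise by spatial structure.

    Deterministic given the decomposition; independent of component order.
    """
    labels = [
        SIGNAL if spatial_autocorrelation(dec.component_map(k)) > AUTOCORR_THRESHOLD
        else NOISE
        for k in range(dec.n_components)
    ]
    return replace(dec, labels=labels)


def reconstruct(dec: ICADecomposition, keep: str | list[str]) -> np.ndarray:
    """Mix back only the components whose label is in ``keep``.

    The removed mean image belongs to the signal share, so
    ``reconstruct(dec, SIGNAL) + reconstruct(dec, NOISE)`` reproduces the
    full reconstruction (equal to the input stack up to numerical error).
    """
    if dec.labels is None:
        raise ValueError("labels not assigned; run classify_components first")
    keep_set = {keep} if isinstance(keep, str) else set(keep)
    mask = np.array([lab in keep_set for lab in dec.labels], dtype=bool)
    flat = dec.mixing[:, mask] @ dec.components[mask]
    if SIGNAL in keep_set:
        flat = flat + dec.mean[:, None]
    return flat.reshape((dec.n_components, *dec.map_shape))


def denoise_series(
    dwi: DWISeries, seed: int = 0
) -> tuple[DWISeries, np.ndarray]:
    """Slice-wise decompose -> classify -> reconstruct over a DWI series.

    Returns the denoised series ``S_hat`` and the matched noise series
    ``eps = dwi - S_hat`` (exact completeness by construction). The b=0
    image is passed through untouched, and slices with no content are left
    unchanged with zero noise.
    """
    denoised = dwi.dwi.copy()
    eps = np.zeros_like(dwi.dwi)
    nz = dwi.grid.shape[2]
    for z in range(nz):
        stack = np.moveaxis(dwi.dwi[:, :, z, :], -1, 0)
        if np.abs(stack).max() == 0.0:
            continue
        dec = decompose_slice(stack, seed=(int(seed) + 977 * z) % (2**31 - 1))
        dec = classify_components(dec)
        dec.slice_index = z
        s_hat = reconstruct(dec, SIGNAL)
        denoised[:, :, z, :] = np.moveaxis(s_hat, 0, -1)
        eps[:, :, z, :] = dwi.dwi[:, :, z, :] - denoised[:, :, z, :]
    out = DWISeries(
        s0=dwi.s0.copy(), dwi=denoised, grid=dwi.grid, scheme=dwi.scheme
    )
    return out, eps
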