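"""Dual TV solver, automatic regularization update, tensor-slice contracts."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tvdti.phantom import (
    add_tensor_noise,
    make_noise_tensor_field,
    reference_noise_model,
)
from tvdti.tensor_fit import CHANNEL_WEIGHTS, NoiseTensorField, TensorField
from tvdti.tv_regularize import (
    TVSolveOptions,
    _chambolle_iterate,
    _div,
    _grad,
    chambolle_scalar,
    local_variance_tensor,
    regularize_tensor_field,
    regularize_tensor_slice,
    tv_norm_tensor,
)

QUICK = TVSolveOptions(polish_iterations=2000)


def projected_gradient_rof(f, lam, iterations=60_000):
    """Independent ROF minimizer: plain projected gradient on the dual with
    explicit per-pixel re-projection (no semi-implicit normalization)."""
    fc = f[None]
    p = np.zeros((1, 2) + f.shape)
    step = 0.9 / (8.0 * lam)
    for _ in range(iterations):
        u = fc + lam * _div(p)
        p = p + step * _grad(u)
        mag = np.sqrt((p**2).sum(axis=(0, 1), keepdims=True))
        p = p / np.maximum(1.0, mag)
    return fc[0] + lam * _div(p)[0]


def piecewise_constant_image(shape=(32, 32), sigma=0.1, seed=0):
    rng = np.random.default_rng(seed)
    f0 = np.zeros(shape)
    f0[8:24, 10:26] = 1.0
    return f0, f0 + sigma * rng.standard_normal(shape)


def test_grad_div_adjoint():
    rng = np.random.default_rng(0)
    u = rng.standard_normal((3, 11, 7))
    p = rng.standard_normal((3, 2, 11, 7))
    assert abs((_grad(u) * p).sum() + (u * _div(p)).sum()) < 1e-12


# ----------------------------------------------------------------- variance

def test_variance_constant_field_is_zero():
    field = np.full((10, 12, 2, 6), 3.3)
    var = local_variance_tensor(field, window=5)
    np.testing.assert_allclose(var.elements, 0.0, atol=1e-20)


def test_variance_iid_gaussian_matches_sigma_squared():
    """An i.i.d. sigma = 2 field gives a variance map whose mean is within
    5% of 4 over >= 10^4 voxels."""
    rng = np.random.default_rng(1)
    field = 2.0 * rng.standard_normal((110, 110, 1, 6))
    var = local_variance_tensor(field, window=5)
    assert abs(var.elements.mean() / 4.0 - 1) < 0.05


def test_variance_interior_matches_brute_force_window():
    """An interior 5x5 window agrees with np.var over the same 25 values."""
    rng = np.random.default_rng(2)
    field = rng.standard_normal((12, 12, 1, 6))
    var = local_variance_tensor(field, window=5)
    i, j, c = 6, 5, 3
    brute = np.var(field[i - 2:i + 3, j - 2:j + 3, 0, c], ddof=1)
    assert var.elements[i, j, 0, c] == pytest.approx(brute, rel=1e-10)


def test_variance_window_validation():
    field = np.zeros((6, 6, 1, 6))
    with pytest.raises(ValueError):
        local_variance_tensor(field, window=4)
    with pytest.raises(ValueError):
        local_variance_tensor(field, window=7)


# ------------------------------------------------------------------ TV norm

def test_tv_norm_constant_and_single_channel():
    assert tv_norm_tensor(np.full((8, 8, 6), 2.0)) == 0.0
    rng = np.random.default_rng(3)
    img = rng.standard_normal((10, 10))
    gx = np.diff(img, axis=0)
    gy = np.diff(img, axis=1)
    scalar_tv = np.sqrt(
        np.pad(gx, ((0, 1), (0, 0)))**2 + np.pad(gy, ((0, 0), (0, 1)))**2
    ).sum()
    assert tv_norm_tensor(img[..., None]) == pytest.approx(scalar_tv, rel=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_tv_norm_one_homogeneous(c):
    rng = np.random.default_rng(4)
    a = rng.standard_normal((6, 6, 6))
    assert tv_norm_tensor(c * a) == pytest.approx(
        abs(c) * tv_norm_tensor(a), rel=1e-9, abs=1e-9
    )


# ------------------------------------------------------------- scalar ROF

def test_chambolle_sigma_zero_and_constant_input():
    rng = np.random.default_rng(5)
    f = rng.standard_normal((16, 16))
    np.testing.assert_array_equal(chambolle_scalar(f, 0.0, QUICK), f)
    const = np.full((16, 16), 3.0)
    np.testing.assert_allclose(chambolle_scalar(const, 0.5, QUICK), const,
                               atol=1e-12)


def test_chambolle_matches_projected_gradient_oracle():
    """The automatic-lambda solver agrees with an independently coded
    projected-gradient ROF minimizer at the same lambda to < 1e-3 of the
    image range."""
    f0, f = piecewise_constant_image(sigma=0.1, seed=0)
    u, info = chambolle_scalar(f, 0.1, return_info=True)
    oracle = projected_gradient_rof(f, info["lam"])
    assert np.abs(u - oracle).max() < 1e-3 * (f.max() - f.min())


def test_chambolle_discrepancy_principle():
    """Converged residual norm equals sigma*sqrt(N) within 2% on
    homogeneous-noise input."""
    _, f = piecewise_constant_image(sigma=0.15, seed=6)
    u, info = chambolle_scalar(f, 0.15, return_info=True)
    target = 0.15 * np.sqrt(f.size)
    assert abs(np.linalg.norm(u - f) - target) <= 0.02 * target


def test_chambolle_dual_energy_monotone():
    """With tau <= 1/8 the dual objective is non-increasing across inner
    iterations."""
    _, f = piecewise_constant_image(sigma=0.1, seed=7)
    lam = np.full((1,) + f.shape, 0.2)
    _, _, energies = _chambolle_iterate(
        f[None], lam, tau=0.125, n_iter=200, track_energy=True
    )
    diffs = np.diff(energies)
    assert np.all(diffs <= 1e-10 * max(1.0, abs(energies[0])))


def test_chambolle_insensitive_to_lambda_initialization():
    """The converged residual varies < 3% across a 10x range of the
    initial regularization scale."""
    _, f = piecewise_constant_image(sigma=0.1, seed=8)
    residuals = []
    for scale in (0.316, 1.0, 3.16):
        _, info = chambolle_scalar(f, 0.1, QUICK, lambda0_scale=scale,
                                   return_info=True)
        residuals.append(info["residual"])
    assert (max(residuals) - min(residuals)) / np.mean(residuals) < 0.03


def test_chambolle_tau_validation():
    with pytest.raises(ValueError):
        TVSolveOptions(tau=0.2)
    with pytest.raises(ValueError):
        TVSolveOptions(window_size=4)


# -------------------------------------------------------- tensor slices

@pytest.fixture(scope="module")
def noisy_phantom_slice(ref_phantom):
    tensors, labels = ref_phantom
    noise = make_noise_tensor_field(tensors.grid, reference_noise_model(seed=11))
    noisy = add_tensor_noise(tensors, noise)
    var = local_variance_tensor(noise, window=5)
    z = 10
    return (
        tensors.elements[:, :, z, :],
        noisy.elements[:, :, z, :],
        var.elements[:, :, z, :],
        labels[:, :, z],
    )


def test_slice_zero_variance_is_identity():
    rng = np.random.default_rng(9)
    arr = rng.standard_normal((20, 20, 6))
    out = regularize_tensor_slice(arr, np.zeros_like(arr), QUICK)
    np.testing.assert_allclose(out, arr, atol=1e-8)


def test_slice_reduces_rmse_every_channel(noisy_phantom_slice):
    """On a noisy phantom slice the per-element RMSE to ground truth drops
    for every channel."""
    truth, noisy, var, _ = noisy_phantom_slice
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = regularize_tensor_slice(noisy, var, TVSolveOptions())
    for c in range(6):
        before = np.sqrt(((noisy[..., c] - truth[..., c]) ** 2).mean())
        after = np.sqrt(((out[..., c] - truth[..., c]) ** 2).mean())
        assert after < before


def test_slice_local_residual_matches_noise_std(noisy_phantom_slice):
    """In interior homogeneous regions the local residual RMS matches the
    local noise std within 10%."""
    truth, noisy, var, labels = noisy_phantom_slice
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = regularize_tensor_slice(noisy, var, TVSolveOptions())
    res = out - noisy
    # homogeneous interior: background voxels away from edges and bundles
    from scipy import ndimage

    interior = ndimage.binary_erosion(labels == 0, iterations=6)
    interior[:8] = interior[-8:] = False
    interior[:, :8] = interior[:, -8:] = False
    w = CHANNEL_WEIGHTS  # noqa: F841  (channel scaling cancels in the ratio)
    rms = np.sqrt((res[interior] ** 2).mean(axis=0))
    sig = np.sqrt(var[interior].mean(axis=0))
    assert np.all(np.abs(rms / sig - 1.0) < 0.10)


def test_slice_regularization_tensor_lower_in_noisy_center(noisy_phantom_slice):
    """With centrally boosted noise the converged regularization tensor is
    lower (stronger smoothing) in the center than at the periphery."""
    truth, noisy, var, labels = noisy_phantom_slice
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, info = regularize_tensor_slice(
            noisy, var, TVSolveOptions(), return_info=True
        )
    lam_fid = info["regularization_tensor"]
    ny, nx = lam_fid.shape[:2]
    cy, cx = ny // 2, nx // 2
    center = lam_fid[cy - 8:cy + 8, cx - 8:cx + 8]
    border = np.concatenate(
        [lam_fid[:6].ravel(), lam_fid[-6:].ravel(),
         lam_fid[:, :6].ravel(), lam_fid[:, -6:].ravel()]
    )
    center = center[np.isfinite(center)]
    border = border[np.isfinite(border)]
    assert np.median(center) < np.median(border)


def test_field_zero_noise_is_identity(ref_phantom):
    tensors, _ = ref_phantom
    zero = NoiseTensorField(np.zeros_like(tensors.elements), tensors.grid)
    out = regularize_tensor_field(tensors, zero, QUICK)
    np.testing.assert_allclose(out.elements, tensors.elements, atol=1e-10)


def test_field_slice_independence(ref_phantom):
    """Regularization is strictly per axial slice: permuting the slices and
    regularizing gives the permuted result."""
    tensors, _ = ref_phantom
    sub = TensorField(tensors.elements[:, :, :4, :].copy(), _subgrid(tensors, 4))
    noise = make_noise_tensor_field(sub.grid, reference_noise_model(seed=12))
    noisy = add_tensor_noise(sub, noise)
    perm = [2, 0, 3, 1]
    noisy_p = TensorField(noisy.elements[:, :, perm, :].copy(), sub.grid)
    noise_p = NoiseTensorField(noise.elements[:, :, perm, :].copy(), sub.grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = regularize_tensor_field(noisy, noise, QUICK)
        b = regularize_tensor_field(noisy_p, noise_p, QUICK)
    np.testing.assert_array_equal(b.elements, a.elements[:, :, perm, :])


def _subgrid(tensors, nz):
    from tvdti.io_gradients import VolumeGrid

    return VolumeGrid(tensors.grid.shape[:2] + (nz,), tensors.grid.voxel_size)


def test_monotone_coupling_doubled_variance_smooths_no_less(noisy_phantom_slice):
    """Doubling the variance tensor never decreases the amount of
    smoothing (L2 distance from the input is non-decreasing)."""
    _, noisy, var, _ = noisy_phantom_slice
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u1 = regularize_tensor_slice(noisy, var, QUICK)
        u2 = regularize_tensor_slice(noisy, 2.0 * var, QUICK)
    d1 = np.linalg.norm(u1 - noisy)
    d2 = np.linalg.norm(u2 - noisy)
    assert d2 >= d1


def test_edge_preservation_two_level_slice():
    """On a two-level piecewise-constant slice the mean absolute gradient
    across the true edge is kept >= 80% of the noise-free edge step while
    the flat-region variance drops by >= 5x."""
    rng = np.random.default_rng(13)
    ny = nx = 40
    truth = np.zeros((ny, nx, 6))
    truth[:, nx // 2:, :3] = 1.0e-3
    truth[..., :3] += 0.7e-3
    sigma = 1.0e-4
    noisy = truth + sigma * rng.standard_normal(truth.shape)
    var = np.full_like(truth, sigma**2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = regularize_tensor_slice(noisy, var, TVSolveOptions())
    edge_jump = np.abs(
        out[:, nx // 2, 0] - out[:, nx // 2 - 1, 0]
    ).mean()
    assert edge_jump >= 0.8 * 1.0e-3
    flat = out[5:-5, 5:nx // 2 - 5, 0]
    assert flat.var() <= noisy[5:-5, 5:nx // 2 - 5, 0].var() / 5.0


def test_decoupled_mode_runs_and_differs(noisy_phantom_slice):
    """Channel-decoupled TV is available for ablation and produces a valid
    (different) solution."""
    truth, noisy, var, _ = noisy_phantom_slice
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coupled = regularize_tensor_slice(noisy, var, QUICK)
        decoupled = regularize_tensor_slice(
            noisy, var, TVSolveOptions(coupled=False, polish_iterations=2000)
        )
    assert np.abs(coupled - decoupled).max() > 0
    before = np.sqrt(((noisy - truth) ** 2).mean())
    assert np.sqrt(((decoupled - truth) ** 2).mean()) < before
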