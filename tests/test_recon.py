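import dataclasses

import numpy as np
import pytest

from irute.gating import reject_fraction_mask
from irute.phantom import make_phantom
from irute.recon import (
    GriddingParams,
    KSpaceData,
    adjoint_nufft,
    apply_motion_shift,
    dft_forward,
    dual_echo_subtract,
    forward_nufft,
    grid_adjoint,
    iterative_dcf,
    psf,
    reconstruct,
    synthesize_kspace,
)
from irute.sequence import SequenceParams
from irute.trajectory import radial_trajectory_2d


def soft_disk(n, radius=None):
    """Disk test image with a one-pixel partial-volume edge."""
    radius = radius or n / 3.2
    x = np.arange(n) - n // 2
    r = np.hypot(*np.meshgrid(x, x, indexing="ij"))
    return np.clip(radius + 0.5 - r, 0.0, 1.0)


def conjugate_phase_sum(k_points, values, n):
    x = np.arange(n) - n // 2
    X, Y = np.meshgrid(x, x, indexing="ij")
    out = np.zeros((n, n), dtype=complex)
    for (kx, ky), v in zip(k_points, values):
        out += v * np.exp(2j * np.pi * (kx * X + ky * Y) / n)
    return out


def direct_dft_sum(image, k_points):
    n = image.shape[0]
    x = np.arange(n) - n // 2
    X, Y = np.meshgrid(x, x, indexing="ij")
    out = np.empty(len(k_points), dtype=complex)
    for j, (kx, ky) in enumerate(k_points):
        out[j] = np.sum(image * np.exp(-2j * np.pi * (kx * X + ky * Y) / n))
    return out


class TestGriddingParams:
    def test_beatty_beta_and_literal_beta(self):
        auto = GriddingParams()
        assert auto.beta_value == pytest.approx(6.4861, abs=1e-3)
        lit = GriddingParams(beta=1.9)
        assert lit.beta_value == 1.9

    @pytest.mark.parametrize(
        "kwargs", [{"kernel_width": 1.0}, {"oversampling": 1.0}, {"beta": -1.0}]
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            GriddingParams(**kwargs)

    def test_grid_size_even(self):
        assert GriddingParams().grid_size(220) == 440
        assert GriddingParams(oversampling=1.5).grid_size(33) % 2 == 0


class TestForwardOracle:
    def test_dc_sample_is_image_sum(self, gp):
        img = soft_disk(32)
        val = forward_nufft(img, np.zeros((1, 2)), gp)[0]
        assert val == pytest.approx(img.sum(), rel=1e-2)

    def test_point_source_flat_spectrum(self, gp):
        n = 32
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        traj = radial_trajectory_2d(n, segment_size=7)
        s = forward_nufft(img, traj.k_coords().reshape(-1, 2), gp)
        # flat to within the W=3 kernel interpolation accuracy (~1.5%)
        assert np.abs(np.abs(s) - 1.0).max() < 2e-2

    def test_forward_matches_direct_dft(self, gp):
        """Gridding forward vs brute-force DFT sum on a 32x32 disk."""
        img = soft_disk(32)
        traj = radial_trajectory_2d(32, segment_size=7)
        pts = traj.k_coords().reshape(-1, 2)
        s_grid = forward_nufft(img, pts, gp)
        s_direct = direct_dft_sum(img, pts)
        scale = np.abs(s_direct).max()
        assert np.abs(s_grid - s_direct).max() / scale < 1e-2
        # a wider kernel drives the interpolation error below 1e-3
        s_wide = forward_nufft(img, pts, GriddingParams(kernel_width=4.0))
        assert np.abs(s_wide - s_direct).max() / scale < 1e-3

    def test_package_dft_path_matches_independent_sum(self):
        img = soft_disk(24)
        pts = np.array([[0.0, 0.0], [3.0, -2.5], [11.5, 7.0], [-12.0, 0.5]])
        np.testing.assert_allclose(
            dft_forward(img, pts), direct_dft_sum(img, pts), rtol=1e-10
        )


class TestAdjointOracle:
    def test_adjoint_matches_conjugate_phase_sum(self, gp, rng):
        traj = radial_trajectory_2d(16, segment_size=5)
        pts = traj.k_coords().reshape(-1, 2)
        vals = rng.normal(size=len(pts)) + 1j * rng.normal(size=len(pts))
        adj = adjoint_nufft(pts, vals, 16, gp)
        oracle = conjugate_phase_sum(pts, vals, 16)
        assert np.abs(adj - oracle).max() / np.abs(oracle).max() < 1e-2

    def test_linearity(self, gp, rng):
        pts = radial_trajectory_2d(16, segment_size=5).k_coords().reshape(-1, 2)
        x = rng.normal(size=len(pts)) + 1j * rng.normal(size=len(pts))
        y = rng.normal(size=len(pts)) + 1j * rng.normal(size=len(pts))
        a, b = 2.5, -1.0 + 0.5j
        lhs = adjoint_nufft(pts, a * x + b * y, 16, gp)
        rhs = a * adjoint_nufft(pts, x, 16, gp) + b * adjoint_nufft(pts, y, 16, gp)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9 * np.abs(rhs).max())

    def test_zero_data_gives_zero_image(self, gp):
        pts = radial_trajectory_2d(16, segment_size=5).k_coords().reshape(-1, 2)
        img = adjoint_nufft(pts, np.zeros(len(pts), complex), 16, gp)
        assert np.abs(img).max() == 0.0


class TestIterativeDcf:
    def test_single_dc_sample_converges_to_constant(self, gp):
        traj = radial_trajectory_2d(16, n_spokes=1, segment_size=1)
        traj = dataclasses.replace(traj, k_radii=np.zeros(1))
        w = iterative_dcf(traj, gp=gp)
        assert w.shape == (1, 1)
        assert w[0, 0] > 0
        np.testing.assert_allclose(w / w.max(), 1.0)

    def test_ramp_like_weights(self, gp):
        """Converged weights grow linearly with |k| away from the center
        (ramp filter); the outermost half-cell sample carries half weight."""
        traj = radial_trajectory_2d(64, n_spokes=692, segment_size=21)
        w = iterative_dcf(traj, gp=gp)
        kr = traj.k_radii
        interior = (kr > 2) & (kr < kr.max())
        prof = w[0]
        r = np.corrcoef(kr[interior], prof[interior])[0, 1]
        assert r > 0.99
        assert np.all(np.diff(prof[interior]) > 0)  # monotone increase
        # boundary sample covers a half cell
        assert prof[-1] < prof[-2]

    def test_weighting_flatness(self, gp):
        traj = radial_trajectory_2d(64, n_spokes=692, segment_size=21)
        w = iterative_dcf(traj, gp=gp, n_iter=20)
        from irute.recon import _gather, _scatter, _to_grid_units

        grid = gp.grid_size(64)
        pts = _to_grid_units(traj.k_coords().reshape(-1, 2), grid, gp)
        d = _gather(pts, _scatter(pts, w.ravel(), grid, gp), gp)
        kr = np.hypot(*traj.k_coords().reshape(-1, 2).T)
        assert np.abs(d[kr > 2] - 1.0).max() < 0.05

    def test_strictly_positive_and_zero_on_rejected(self, gp):
        traj = radial_trajectory_2d(32, segment_size=7)
        accept = reject_fraction_mask(traj.n_spokes, 0.2)
        w = iterative_dcf(traj, accept, gp)
        assert np.all(w[accept] > 0)
        assert np.all(w[~accept] == 0)

    def test_empty_acceptance_raises(self, gp):
        traj = radial_trajectory_2d(32, segment_size=7)
        with pytest.raises(ValueError):
            iterative_dcf(traj, np.zeros(traj.n_spokes, bool), gp)


class TestRoundTrip:
    def test_disk_round_trip_nrmse(self, gp):
        """Forward-model + DCF + adjoint recovers a fully sampled disk."""
        n = 32
        img = soft_disk(n)
        traj = radial_trajectory_2d(n, segment_size=7)
        pts = traj.k_coords().reshape(-1, 2)
        s = dft_forward(img, pts).reshape(traj.n_spokes, -1)
        w = iterative_dcf(traj, gp=gp)
        rec = adjoint_nufft(pts, (s * w).ravel(), n, gp)
        rec *= gp.kernel_area ** 4 / (gp.oversampling ** 2 * n ** 2)
        nrmse = np.linalg.norm(rec - img) / np.linalg.norm(img)
        assert nrmse < 0.05


@pytest.fixture(scope="module")
def setup():
    params = dataclasses.replace(SequenceParams(), matrix=32, fov=32.0,
                                 spokes_per_segment=7)
    ph = make_phantom(size=32, seed=2, n_lesions=0)
    traj = radial_trajectory_2d(32, segment_size=7)
    return ph, params, traj


class TestSynthesizeKspace:

    def test_gridding_matches_exact_dft_path(self, setup, gp):
        ph, params, traj = setup
        exact = synthesize_kspace(ph, params, traj, method="dft")
        approx = synthesize_kspace(ph, params, traj, gp=gp, method="gridding")
        scale = np.abs(exact.samples).max()
        assert np.abs(exact.samples - approx.samples).max() / scale < 1e-2

    def test_dc_sample_equals_composite_image_sum(self, setup):
        ph, params, traj = setup
        kdata = synthesize_kspace(ph, params, traj, method="dft")
        from irute.sequence import echo_weighted_images

        imgs = echo_weighted_images(ph, params)
        for spoke in (0, 10):
            pos = spoke % params.spokes_per_segment
            for e in (0, 1):
                assert kdata.samples[spoke, 0, e] == pytest.approx(
                    imgs[pos, e].sum(), rel=1e-9
                )

    def test_matrix_mismatch_rejected(self, setup):
        ph, params, _ = setup
        bad_traj = radial_trajectory_2d(64, segment_size=7)
        with pytest.raises(ValueError):
            synthesize_kspace(ph, params, bad_traj)

    def test_motion_phase_shift_matches_shifted_object(self, setup, gp):
        """Phase-modulating all spokes equals imaging a rolled phantom
        (the rolled-over rows are empty background, so the circular and
        linear shifts coincide)."""
        from irute.phantom import LabelPhantom

        ph, params, traj = setup
        kdata = synthesize_kspace(ph, params, traj, method="dft")
        shift = np.tile([2.0, 0.0], (traj.n_spokes, 1))
        moved = apply_motion_shift(kdata, shift)
        ph_shifted = LabelPhantom(
            labels=np.roll(ph.labels, 2, axis=0), classes=ph.classes,
            pixel_size=ph.pixel_size,
        )
        expect = synthesize_kspace(ph_shifted, params, traj, method="dft")
        scale = np.abs(expect.samples).max()
        assert np.abs(moved.samples - expect.samples).max() / scale < 1e-9


class TestReconstructAndSubtract:
    def test_identical_echoes_cancel(self):
        img = soft_disk(16)
        assert np.abs(dual_echo_subtract(img, img)).max() == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dual_echo_subtract(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_pure_long_t2_phantom_cancels(self, gp):
        """Dual-echo subtraction of a pure long-T2* object is bounded by the
        exponential decay between the echoes (< 2% of echo 1)."""
        from irute.phantom import LabelPhantom, default_tissue_table

        n = 32
        labels = np.where(soft_disk(n) > 0.5, 1, 0).astype(np.int16)  # CSF disk
        ph = LabelPhantom(labels=labels, classes=default_tissue_table())
        params = dataclasses.replace(SequenceParams(), matrix=n, fov=float(n),
                                     spokes_per_segment=7)
        traj = radial_trajectory_2d(n, segment_size=7)
        kdata = synthesize_kspace(ph, params, traj, method="dft")
        out = reconstruct(kdata, gp=gp)
        e1 = np.abs(out["echo1"])
        assert np.abs(out["myelin"]).mean() < 0.02 * e1.mean()

    def test_myelin_survives_subtraction(self, gp):
        """An ultrashort-T2* object keeps its echo-1 signal: the echo-2
        attenuation exp(-TE2/T2*) ~ exp(-15) makes subtraction ~ echo 1."""
        from irute.phantom import LabelPhantom, default_tissue_table

        n = 32
        labels = np.where(soft_disk(n) > 0.5, 4, 0).astype(np.int16)  # myelin
        ph = LabelPhantom(labels=labels, classes=default_tissue_table())
        params = dataclasses.replace(SequenceParams(), matrix=n, fov=float(n),
                                     spokes_per_segment=7)
        traj = radial_trajectory_2d(n, segment_size=7)
        kdata = synthesize_kspace(ph, params, traj, method="dft")
        out = reconstruct(kdata, gp=gp)
        e1 = np.abs(out["echo1"])
        np.testing.assert_allclose(out["myelin"], e1, atol=1e-6 * e1.max())

    def test_grid_adjoint_requires_accepted_spokes(self, gp):
        params = dataclasses.replace(SequenceParams(), matrix=32, fov=32.0,
                                     spokes_per_segment=7)
        ph = make_phantom(size=32, seed=2, n_lesions=0)
        traj = radial_trajectory_2d(32, segment_size=7)
        kdata = synthesize_kspace(ph, params, traj, method="dft")
        kdata.accept[:] = False
        with pytest.raises(ValueError):
            grid_adjoint(kdata, np.ones((traj.n_spokes, traj.samples_per_spoke)), gp)


class TestPsf:
    def test_full_sampling_peaks_at_center(self, gp):
        traj = radial_trajectory_2d(64, segment_size=21)
        p = psf(traj, gp=gp)
        assert p[32, 32] == pytest.approx(1.0)
        assert np.unravel_index(np.argmax(p), p.shape) == (32, 32)

    def test_rotation_equivariance(self, gp):
        """Rotating every spoke by 90 degrees rotates the PSF identically
        (odd matrix so the rotation center is a pixel)."""
        traj = radial_trajectory_2d(33, n_spokes=100, segment_size=10)
        rot = dataclasses.replace(
            traj, directions=traj.directions @ np.array([[0.0, 1.0], [-1.0, 0.0]])
        )
        accept = reject_fraction_mask(100, 0.2)
        p1 = psf(traj, accept, gp=gp)
        p2 = psf(rot, accept, gp=gp)
        err = min(
            np.abs(np.rot90(p1, k) - p2).max() for k in (1, 3)
        )
        assert err < 1e-6
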