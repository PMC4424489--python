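"""Analytic sinograms, the scan simulator and artefact injection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tomopipe as tp
from tomopipe.framework import TomoError
from tomopipe.synthetic import _ellipse_projection


def quadrature_line_integral(phantom, theta_deg, t, n_samples=100_000):
    """Numeric oracle, independent of the chord-length formula: sample each
    ellipse's implicit quadratic along the ray and locate the entry/exit
    crossings by linear interpolation between samples.  The quadratic is
    smooth, so the refined crossings are accurate far beyond the sampling
    step; the integral is rho times the in-ellipse path length."""
    th = np.deg2rad(theta_deg)
    # Ray direction is (-sin, cos); a point on the ray is t*(cos, sin).
    half = 2.0  # generous half-length; phantoms live in |x|,|y| < 1
    s = np.linspace(-half, half, n_samples)
    x = t * np.cos(th) - s * np.sin(th)
    y = t * np.sin(th) + s * np.cos(th)
    total = 0.0
    for e in phantom.ellipses:
        ca, sa = np.cos(np.deg2rad(e.phi_deg)), np.sin(np.deg2rad(e.phi_deg))
        u = (ca * (x - e.centre[0]) + sa * (y - e.centre[1])) / e.semi_axes[0]
        v = (-sa * (x - e.centre[0]) + ca * (y - e.centre[1])) / e.semi_axes[1]
        f = u * u + v * v - 1.0  # negative inside the ellipse
        sign_change = np.nonzero(np.signbit(f[1:]) != np.signbit(f[:-1]))[0]
        crossings = [
            s[i] - f[i] * (s[i + 1] - s[i]) / (f[i + 1] - f[i]) for i in sign_change
        ]
        for s_in, s_out in zip(crossings[::2], crossings[1::2]):
            total += e.rho * (s_out - s_in)
    return total


class TestAnalyticSinogram:
    def test_unit_disc_central_chord_is_diameter(self):
        ph = tp.Phantom([tp.Ellipse((0, 0), (1, 1), 0, 1.0)], field_of_view=2.0)
        # 5 detectors, spacing 0.6: offsets -1.2, -0.6, 0, 0.6, 1.2
        sino = tp.analytic_sinogram(ph, [0.0], 5, 0.6)
        np.testing.assert_allclose(sino[0], [0.0, 1.6, 2.0, 1.6, 0.0], atol=1e-12)

    def test_rotated_ellipse_matches_quadrature(self):
        ph = tp.Phantom([tp.Ellipse((0.1, -0.05), (0.7, 0.3), 30.0, 1.3)])
        for theta, t in [(17.0, 0.2), (63.0, -0.41), (120.0, 0.05)]:
            exact = _ellipse_projection(
                ph.ellipses[0], np.array(np.deg2rad(theta)), np.array(t)
            )
            brute = quadrature_line_integral(ph, theta, t)
            assert abs(float(exact) - brute) < 1e-6

    def test_radon_linearity_of_two_ellipse_phantom(self):
        e1 = tp.Ellipse((0.1, 0.0), (0.2, 0.3), 10.0, 1.0)
        e2 = tp.Ellipse((-0.2, 0.1), (0.15, 0.1), -20.0, 0.5)
        ang = np.linspace(0, 180, 13, endpoint=False)
        both = tp.analytic_sinogram(tp.Phantom([e1, e2]), ang, 64, 1 / 64)
        s1 = tp.analytic_sinogram(tp.Phantom([e1]), ang, 64, 1 / 64)
        s2 = tp.analytic_sinogram(tp.Phantom([e2]), ang, 64, 1 / 64)
        np.testing.assert_array_equal(both, s1 + s2)

    def test_mass_conservation_across_angles(self, shepp):
        # Point-sampled chords form a midpoint rule whose sqrt-edge error
        # decays as h^(3/2); 8192 bins brings it below 1e-6.
        n = 8192
        ang = np.array([0.0, 33.0, 90.0, 141.0])
        sino = tp.analytic_sinogram(shepp, ang, n, 1.0 / n)
        masses = sino.sum(axis=1) / n
        np.testing.assert_allclose(masses, shepp.total_mass(), atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        x0=st.floats(-0.2, 0.2),
        y0=st.floats(-0.2, 0.2),
        a=st.floats(0.05, 0.4),
        b=st.floats(0.05, 0.4),
        phi=st.floats(0, 180),
        theta=st.floats(0, 360),
    )
    def test_single_ellipse_projection_mass(self, x0, y0, a, b, phi, theta):
        """Any single projection integrates to the ellipse mass pi*a*b*rho."""
        ph = tp.Phantom([tp.Ellipse((x0, y0), (a, b), phi, 1.0)])
        n = 4096
        sino = tp.analytic_sinogram(ph, [theta], n, 2.0 / n)
        assert abs(sino[0].sum() * 2.0 / n - np.pi * a * b) < 1e-4


class TestSimulateScan:
    def test_empty_phantom_frames_equal_flats(self):
        empty = tp.Phantom([], field_of_view=1.0)
        scan = tp.ScanConfig(n_angles=4, n_det=32, n_rows=4, noise_on=False)
        block, flats, darks, _ = tp.simulate_scan(empty, scan)
        for frame in block.values:
            np.testing.assert_array_equal(frame, flats[0])

    def test_parallel_beam_flip_symmetry_at_180(self, offcentre):
        """With no artefacts, the horizontally flipped 180-degree frame
        equals the 0-degree frame exactly."""
        scan = tp.ScanConfig(
            n_angles=8, n_det=64, n_rows=4, noise_on=False, include_final_180=True
        )
        block, _, _, _ = tp.simulate_scan(offcentre, scan)
        assert block.angles_deg[-1] == 180.0
        np.testing.assert_allclose(
            block.values[-1][:, ::-1], block.values[0], atol=1e-12
        )

    def test_ideal_correction_recovers_analytic_sinogram(self, shepp, noiseless_scan):
        block, flats, darks, truth = noiseless_scan
        fbar, dbar = flats.mean(axis=0), darks.mean(axis=0)
        trans = (block.values - dbar) / (fbar - dbar)
        sino = -np.log(trans[:, 1, :])
        ref = tp.analytic_sinogram(
            shepp, block.angles_deg, 64, truth["det_spacing"]
        )
        np.testing.assert_allclose(sino, ref, atol=1e-10)

    def test_poisson_dark_frames_have_expected_mean(self, offcentre):
        scan = tp.ScanConfig(
            n_angles=1, n_det=64, n_rows=8, noise_on=True, i0=1e3,
            n_darks=100, dark_level=20.0, seed=7,
        )
        _, _, darks, _ = tp.simulate_scan(offcentre, scan)
        se = np.sqrt(20.0 / darks.size)
        assert abs(darks.mean() - 20.0) < 3 * se

    def test_tilt_with_single_row_warns(self, offcentre):
        scan = tp.ScanConfig(n_angles=2, n_det=32, n_rows=1, noise_on=False)
        with pytest.warns(UserWarning, match="unobservable"):
            tp.simulate_scan(offcentre, scan, tp.ArtefactConfig(tilt_deg=0.1))


class TestInjectArtefacts:
    def test_all_off_config_is_identity(self, noiseless_scan):
        frames = noiseless_scan[0].values
        out, truth = tp.inject_artefacts(frames, tp.ArtefactConfig(), seed=1)
        np.testing.assert_array_equal(out, frames)
        assert truth["zinger_pixels"] == []

    def test_dead_pixel_constant_across_frames(self, noiseless_scan):
        frames = noiseless_scan[0].values
        art = tp.ArtefactConfig(dead_pixels=((2, 10),), dead_value=7.0)
        out, _ = tp.inject_artefacts(frames, art, seed=1)
        assert np.all(out[:, 2, 10] == 7.0)

    def test_dead_pixel_out_of_range_rejected(self, noiseless_scan):
        frames = noiseless_scan[0].values
        with pytest.raises(TomoError, match="outside frame"):
            tp.inject_artefacts(
                frames, tp.ArtefactConfig(dead_pixels=((99, 0),)), seed=1
            )

    def test_jitter_shifts_recorded_and_deterministic(self, noiseless_scan):
        frames = noiseless_scan[0].values
        art = tp.ArtefactConfig(jitter_px=3.0)
        out1, t1 = tp.inject_artefacts(frames, art, seed=9)
        out2, t2 = tp.inject_artefacts(frames, art, seed=9)
        np.testing.assert_array_equal(out1, out2)
        assert t1["jitter_px"] == t2["jitter_px"]
        assert np.all(np.abs(t1["jitter_px"]) <= 3.0)

    def test_injected_jitter_shifts_com_by_recorded_amount(self):
        """The hysteresis shifts stored in the truth record move each
        frame's centre of mass by exactly the recorded amount (linear
        interpolation preserves mass and first moment on supported rows)."""
        x = np.arange(128)
        row = np.exp(-0.5 * ((x - 63.5) / 8.0) ** 2)
        frames = np.broadcast_to(row, (12, 4, 128)).copy()
        out, truth = tp.inject_artefacts(
            frames, tp.ArtefactConfig(jitter_px=3.0), seed=11
        )
        jitter = np.asarray(truth["jitter_px"])
        from tomopipe.sinogram import centre_of_mass_rows

        com0 = centre_of_mass_rows(frames[:, 0, :])
        com1 = centre_of_mass_rows(out[:, 0, :])
        np.testing.assert_allclose(com1 - com0, jitter, atol=1e-8)

    def test_simulated_jitter_recoverable_from_true_params(self, offcentre):
        """Jitter injected in ray geometry by the simulator matches the
        stored truth to within the point-sampling error of the sinogram."""
        scan = tp.ScanConfig(
            n_angles=16, n_det=128, n_rows=1, noise_on=False,
            include_final_180=False, seed=11,
        )
        block, flats, darks, truth = tp.simulate_scan(
            offcentre, scan, tp.ArtefactConfig(jitter_px=3.0)
        )
        jitter = np.asarray(truth["jitter_px"])
        trans = (block.values - darks.mean(0)) / (flats.mean(0) - darks.mean(0))
        sino = -np.log(trans[:, 0, :])
        ref = tp.analytic_sinogram(offcentre, block.angles_deg, 128, truth["det_spacing"])
        from tomopipe.sinogram import centre_of_mass_rows

        np.testing.assert_allclose(
            centre_of_mass_rows(sino) - centre_of_mass_rows(ref), jitter, atol=0.1
        )
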