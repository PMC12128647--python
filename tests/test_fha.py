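"""FHA tests: polar transform, trigonometric regression, moments, averaging.

Independent oracles: analytic shapes (disk, ellipse), numpy's FFT for the
equal-angle regression, direct-summation moment formulas, and numerical
Fourier integrals of the ellipse's polar radius.
"""
import numpy as np
import pytest
import scipy.integrate

from spermshape import fha, segment
from conftest import circle_polygon, ellipse_polygon


def _ellipse_radius(a, b, theta):
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


class TestToPolar:
    def test_unit_circle_radii(self):
        prof = fha.to_polar(circle_polygon(1.0, 360))
        assert np.allclose(prof.r, 1.0, atol=1e-3)

    def test_translation_invariance(self):
        p1 = fha.to_polar(circle_polygon(2.0, 256))
        p2 = fha.to_polar(circle_polygon(2.0, 256, center=(13.7, -4.2)))
        assert np.allclose(p1.r, p2.r, atol=1e-9)

    def test_ellipse_axis_radii(self):
        prof = fha.to_polar(ellipse_polygon(4.5, 2.0, 1440))
        assert prof.r[0] == pytest.approx(4.5, abs=1e-3)
        assert prof.r[len(prof.r) // 4] == pytest.approx(2.0, abs=1e-3)

    def test_non_star_shape_raises(self):
        # thin 300-degree horseshoe: centroid falls in the open middle
        t = np.linspace(-2.6, 2.6, 200)
        outer = np.column_stack([5 * np.cos(t), 5 * np.sin(t)])
        inner = np.column_stack([4.3 * np.cos(t[::-1]), 4.3 * np.sin(t[::-1])])
        horseshoe = np.vstack([outer, inner])
        with pytest.raises(fha.NonStarShapeError):
            fha.to_polar(horseshoe)

    def test_multi_crossing_uses_farthest_and_flags(self):
        # crescent: centroid inside, but rays toward the horns cross the
        # boundary three times -> farthest crossing used, profile flagged
        import shapely.geometry as sg

        disk = sg.Point(0, 0).buffer(2.0, quad_segs=90)
        bite = sg.Point(1.7, 0).buffer(1.3, quad_segs=90)
        poly = np.array(disk.difference(bite).exterior.coords)[:-1]
        prof = fha.to_polar(poly, 256)
        assert prof.non_star
        assert np.all(prof.r > 0)


class TestFitFourier:
    def test_circle_constant_term_only(self):
        h = fha.fit_fourier(fha.to_polar(circle_polygon(2.85, 720)))
        assert h.amplitudes[0] == pytest.approx(2.85, abs=1e-3)
        assert np.all(h.amplitudes[1:] < 1e-3)

    def test_centered_ellipse_even_harmonics(self):
        theta = np.arange(256) * (2 * np.pi / 256)
        prof = fha.PolarProfile(np.zeros(2), theta, _ellipse_radius(4.5, 2.0, theta))
        h = fha.fit_fourier(prof)
        amp = h.amplitudes
        assert amp[1] < 1e-6 and amp[3] < 1e-6 and amp[5] < 1e-6
        assert amp[2] > amp[4] > 0
        # oracle: numerical Fourier integrals of the polar radius
        for k in (2, 4):
            ak = (
                scipy.integrate.quad(
                    lambda t: _ellipse_radius(4.5, 2.0, t) * np.cos(k * t), 0, 2 * np.pi,
                    limit=200,
                )[0]
                / np.pi
            )
            assert amp[k] == pytest.approx(abs(ak), rel=1e-4)

    def test_ols_equals_dft_on_equal_angles(self):
        rng = np.random.default_rng(8)
        theta = np.arange(256) * (2 * np.pi / 256)
        r = 3.0 + sum(
            rng.normal(0, 0.2) * np.cos(k * theta) + rng.normal(0, 0.2) * np.sin(k * theta)
            for k in range(1, 6)
        ) + 0.05 * np.cos(11 * theta)
        h = fha.fit_fourier(fha.PolarProfile(np.zeros(2), theta, r))
        F = np.fft.rfft(r) / len(r)
        c0 = F[0].real
        a = 2 * F[1:6].real
        b = -2 * F[1:6].imag
        assert h.c0 == pytest.approx(c0, abs=1e-9)
        assert np.allclose(h.a, a, atol=1e-9)
        assert np.allclose(h.b, b, atol=1e-9)

    def test_insufficient_samples_rejected(self):
        theta = np.arange(9) * (2 * np.pi / 9)
        prof = fha.PolarProfile(np.zeros(2), theta, np.full(9, 2.0))
        with pytest.raises(ValueError, match="samples"):
            fha.fit_fourier(prof, max_harmonic=5)

    def test_truncation_monotonicity(self):
        prof = fha.to_polar(ellipse_polygon(4.0, 2.2, 720), n_samples=128)
        resid = [fha.fit_fourier(prof, max_harmonic=K).residual_rms for K in range(1, 6)]
        assert all(r1 >= r2 - 1e-12 for r1, r2 in zip(resid, resid[1:]))


class TestInvariances:
    def test_amplitudes_rotation_invariant_exact_path(self, sampled_shapes):
        h = sampled_shapes[0]
        for ang in (0.3, 1.1, 2.9):
            hr = h.rotated(ang)
            fit = fha.fit_fourier(hr.sample_profile(128))
            assert np.allclose(fit.amplitudes, h.amplitudes, atol=1e-12)

    def test_amplitudes_rotation_invariant_polygon_path(self, sampled_shapes):
        h = sampled_shapes[1]
        base = fha.harmonics_from_trace(h.to_polygon(2048)).amplitudes
        rot = fha.harmonics_from_trace(h.rotated(1.234).to_polygon(2048)).amplitudes
        assert np.allclose(base, rot, atol=1e-4)

    def test_exact_linear_scaling(self, sampled_shapes):
        poly = sampled_shapes[2].to_polygon(720)
        a1 = fha.harmonics_from_trace(poly).amplitudes
        a2 = fha.harmonics_from_trace(poly * 3.5).amplitudes
        assert np.allclose(a2, 3.5 * a1, rtol=1e-12)


class TestSummarizeRam:
    def test_identical_nuclei_degenerate(self, sampled_shapes):
        s = fha.summarize_ram([sampled_shapes[0]] * 5, ram_id="r1")
        assert s.degenerate
        assert s.features["ha2_var"] == 0.0
        assert s.features["ha2_skew"] == 0.0

    def test_hand_computed_moments(self):
        hs = [fha.HarmonicSet(c0=1.0, a=[0, v, 0, 0, 0], b=np.zeros(5)) for v in (0.8, 0.9, 1.0)]
        s = fha.summarize_ram(hs)
        assert s.features["ha2_mean"] == pytest.approx(0.9)
        assert s.features["ha2_var"] == pytest.approx(0.01)

    def test_moments_match_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(3.0, 0.2, size=100)
        hs = [fha.HarmonicSet(c0=v, a=np.zeros(5), b=np.zeros(5)) for v in x]
        s = fha.summarize_ram(hs)
        n = len(x)
        m = x.mean()
        m2 = ((x - m) ** 2).sum() / n
        m3 = ((x - m) ** 3).sum() / n
        m4 = ((x - m) ** 4).sum() / n
        skew = np.sqrt(n * (n - 1)) / (n - 2) * m3 / m2**1.5
        kurt = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * (m4 / m2**2 - 3) + 6)
        assert s.features["ha0_mean"] == pytest.approx(m, rel=1e-12)
        assert s.features["ha0_var"] == pytest.approx(x.var(ddof=1), rel=1e-12)
        assert s.features["ha0_skew"] == pytest.approx(skew, rel=1e-10)
        assert s.features["ha0_kurt"] == pytest.approx(kurt, rel=1e-10)

    def test_too_few_nuclei(self, sampled_shapes):
        with pytest.raises(ValueError):
            fha.summarize_ram(sampled_shapes[:1])


class TestAverageShape:
    def test_identical_circles(self):
        circles = [circle_polygon(2.0, 360)] * 5
        with pytest.warns(UserWarning, match="circular"):
            avg = fha.average_shape(circles)
        assert np.allclose(avg.sd_r, 0.0, atol=1e-9)
        assert np.allclose(avg.mean_r, 2.0, atol=1e-3)

    def test_alignment_idempotent_under_rotation(self, sampled_shapes):
        poly = sampled_shapes[3].to_polygon(720)
        ang = 0.87
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = poly @ R.T
        avg_pair = fha.average_shape([poly, rotated])
        avg_self = fha.average_shape([poly, poly])
        assert np.allclose(avg_pair.mean_r, avg_self.mean_r, atol=1e-6)
        assert np.allclose(avg_pair.sd_r, 0.0, atol=1e-6)

    def test_average_consistent_with_cohort_mean_ha0(self, sampled_shapes):
        polys = [h.to_polygon(720) for h in sampled_shapes]
        avg = fha.average_shape(polys)
        mean_ha0 = np.mean([h.amplitudes[0] for h in sampled_shapes])
        avg_ha0 = avg.mean_r.mean()
        assert avg_ha0 == pytest.approx(mean_ha0, rel=0.02)

    def test_needs_at_least_two(self):
        with pytest.raises(ValueError):
            fha.average_shape([circle_polygon(1.0)])


class TestPipelineRecovery:
    def test_render_segment_fha_recovers_ha0_ha2(self, sampled_shapes):
        """Full image pipeline recovers true HA0/HA2 to < 0.05 μm."""
        from spermshape import synth

        err0, err2 = [], []
        for i, h in enumerate(sampled_shapes):
            img, _ = synth.render_nucleus(h, rng_seed=900 + i)
            _, traces = segment.segment_image(img, 0.11)
            assert len(traces) == 1
            fit = fha.harmonics_from_trace(traces[0], radial_offset_um=0.055)
            err0.append(abs(fit.amplitudes[0] - h.amplitudes[0]))
            err2.append(abs(fit.amplitudes[2] - h.amplitudes[2]))
        assert np.mean(err0) < 0.05
        assert np.mean(err2) < 0.05
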