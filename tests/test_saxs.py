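"""Tests of the SAXS analytics against closed-form and simulation oracles."""

import numpy as np
import pytest

from coopbind import saxs, synth
from coopbind.saxs import (
    FrameSelectionError,
    GuinierError,
    ScatteringCurve,
    SecSaxsSeries,
    buffer_subtract,
    chi_square,
    correlation_volume_mw,
    dimensionless_kratky,
    guinier_fit,
    optimal_scale,
    pair_distribution,
    select_stable_frames,
)

SPHERE_R = 30.0


def sphere_curve(scale=1e4, qmax=0.35, n=300, rel_sigma=0.01):
    q = np.linspace(0.005, qmax, n)
    x = q * SPHERE_R
    I = scale * (3 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
    return ScatteringCurve(q, I, rel_sigma * np.abs(I) + scale * 1e-9)


def gaussian_curve(Rg=20.0, I0=100.0, qmax=0.5, n=500):
    q = np.linspace(0.002, qmax, n)
    I = I0 * np.exp(-(q**2) * Rg**2 / 3)
    return ScatteringCurve(q, I, 0.01 * I)


class TestBufferSubtract:
    def test_zero_buffer_is_identity(self):
        s = gaussian_curve()
        b = ScatteringCurve(s.q, np.zeros_like(s.I), 0 * s.I + 1e-9)
        out = buffer_subtract(s, b)
        assert out.I == pytest.approx(s.I)

    def test_self_subtraction_is_zero_with_finite_sigma(self):
        s = gaussian_curve()
        out = buffer_subtract(s, s)
        assert np.all(out.I == 0)
        assert np.all(np.isfinite(out.sigma)) and np.all(out.sigma > 0)

    def test_sigma_combines_in_quadrature(self):
        s = gaussian_curve()
        b = ScatteringCurve(s.q, 0.1 * s.I, 0.02 * s.I)
        out = buffer_subtract(s, b)
        assert out.sigma == pytest.approx(np.sqrt(s.sigma**2 + b.sigma**2))

    def test_mismatched_grids_rejected(self):
        s = gaussian_curve()
        b = gaussian_curve(qmax=0.4, n=123)
        with pytest.raises(ValueError, match="grid"):
            buffer_subtract(s, b)


class TestGuinier:
    def test_gaussian_curve_recovered_exactly(self):
        g = guinier_fit(gaussian_curve(Rg=20.0, I0=100.0))
        assert g.Rg == pytest.approx(20.0, rel=1e-6)
        assert g.I0 == pytest.approx(100.0, rel=1e-6)

    def test_sphere_rg_within_one_percent(self):
        g = guinier_fit(sphere_curve())
        assert g.Rg == pytest.approx(np.sqrt(3 / 5) * SPHERE_R, rel=0.01)

    def test_truncated_curve_fails(self):
        c = gaussian_curve()
        short = ScatteringCurve(c.q[:3], c.I[:3], c.sigma[:3])
        with pytest.raises(GuinierError):
            guinier_fit(short)

    def test_rising_low_q_fails(self):
        q = np.linspace(0.005, 0.1, 50)
        c = ScatteringCurve(q, 1.0 + 10 * q**2, np.full(50, 0.01))
        with pytest.raises(GuinierError, match="slope"):
            guinier_fit(c)

    def test_debye_chain_matches_exact_coordinate_rg(self):
        for model in (
            synth.BeadModel.open_chain(16),
            synth.BeadModel.looped_chain(16),
        ):
            curve = synth.gen_saxs(model, noise=False)
            g = guinier_fit(curve)
            assert g.Rg == pytest.approx(model.exact_rg(), rel=0.02)


class TestKratky:
    def test_zero_at_low_q(self):
        c = gaussian_curve()
        k = dimensionless_kratky(c, guinier_fit(c))
        assert k["kratky"][0] == pytest.approx(0.0, abs=2e-3)

    def test_gaussian_peak_at_sqrt3(self):
        c = gaussian_curve()
        k = dimensionless_kratky(c, guinier_fit(c))
        imax = int(np.argmax(k["kratky"]))
        assert k["qrg"][imax] == pytest.approx(np.sqrt(3), abs=0.02)
        assert k["kratky"][imax] == pytest.approx(3 / np.e, rel=0.005)

    def test_extended_chain_exceeds_globular_plateau(self):
        model = synth.BeadModel.open_chain(16)
        curve = synth.gen_saxs(model, noise=False)
        g = guinier_fit(curve)
        k = dimensionless_kratky(curve, g)
        high = k["kratky"][(k["qrg"] > 2.5) & (k["qrg"] < 6.0)]
        assert np.max(high) > 3 / np.e


class TestCorrelationVolume:
    def test_intensity_rescaling_leaves_vc_unchanged(self):
        c = gaussian_curve()
        g = guinier_fit(c)
        vc1, _ = correlation_volume_mw(c, g)
        c5 = ScatteringCurve(c.q, 5 * c.I, 5 * c.sigma)
        g5 = guinier_fit(c5)
        vc5, _ = correlation_volume_mw(c5, g5)
        assert vc5 == pytest.approx(vc1, rel=1e-9)

    def test_gaussian_closed_form(self):
        Rg = 20.0
        c = gaussian_curve(Rg=Rg)
        g = guinier_fit(c)
        vc, _ = correlation_volume_mw(c, g)
        assert vc == pytest.approx(2 * Rg**2 / 3, rel=0.01)

    def test_mw_positive_and_grows_with_size(self):
        mws = []
        for Rg in (15.0, 30.0):
            c = gaussian_curve(Rg=Rg)
            _, mw = correlation_volume_mw(c, guinier_fit(c))
            mws.append(mw)
        assert mws[0] > 0
        assert mws[1] > mws[0]

    def test_unknown_calibration_rejected(self):
        c = gaussian_curve()
        with pytest.raises(ValueError, match="calibration"):
            correlation_volume_mw(c, guinier_fit(c), calibration="dna")


class TestScaleAndChi2:
    def test_identical_curves_scale_one_chi2_zero(self):
        c = sphere_curve()
        assert optimal_scale(c, c) == pytest.approx(1.0, rel=1e-12)
        assert chi_square(c, c).chi2 == pytest.approx(0.0, abs=1e-20)

    def test_scaled_theor_recovered(self):
        c = sphere_curve()
        t = ScatteringCurve(c.q, c.I / 5, c.sigma)
        assert optimal_scale(c, t) == pytest.approx(5.0, rel=1e-12)
        assert chi_square(c, t).chi2 == pytest.approx(0.0, abs=1e-18)

    def test_scale_minimises_chi2_against_grid_search(self):
        rng = np.random.default_rng(3)
        c = sphere_curve()
        t = ScatteringCurve(c.q, c.I * (1 + 0.05 * rng.standard_normal(c.n_points)), c.sigma)
        c_opt = optimal_scale(c, t)
        chi_opt = chi_square(c, t, scale=c_opt).chi2
        for trial in np.linspace(0.5 * c_opt, 1.5 * c_opt, 201):
            assert chi_opt <= chi_square(c, t, scale=trial).chi2 + 1e-12

    def test_one_sigma_offset_with_unit_scale(self):
        c = sphere_curve()
        t = ScatteringCurve(c.q, c.I - c.sigma, c.sigma)
        out = chi_square(c, t, scale=1.0)
        assert out.chi2 == pytest.approx(c.n_points / (c.n_points - 1), rel=1e-12)

    def test_chi2_invariant_to_theor_rescaling(self):
        rng = np.random.default_rng(4)
        c = sphere_curve()
        t_I = c.I * (1 + 0.03 * rng.standard_normal(c.n_points))
        chi_a = chi_square(c, ScatteringCurve(c.q, t_I, c.sigma)).chi2
        chi_b = chi_square(c, ScatteringCurve(c.q, 7.3 * t_I, c.sigma)).chi2
        assert chi_a == pytest.approx(chi_b, rel=1e-10)

    def test_all_zero_theor_rejected(self):
        c = sphere_curve()
        t = ScatteringCurve(c.q, np.zeros_like(c.I), c.sigma)
        with pytest.raises(ValueError, match="zero"):
            optimal_scale(c, t)

    def test_mismatched_grids_rejected(self):
        c = sphere_curve()
        t = sphere_curve(qmax=0.3, n=200)
        with pytest.raises(ValueError, match="grid"):
            chi_square(c, t)


class TestPairDistribution:
    def test_sphere_dmax_and_shape(self):
        """Dmax of a solid sphere within 10% of 2R; p(r) matches the
        Monte-Carlo distance distribution of uniform points in a sphere."""
        pr = pair_distribution(sphere_curve())
        assert pr.dmax == pytest.approx(2 * SPHERE_R, rel=0.10)
        assert np.all(pr.p >= -1e-12)
        assert pr.p[0] == 0.0 and pr.p[-1] == 0.0
        # Monte-Carlo oracle for the sphere distance distribution
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((4000, 3))
        radii = rng.uniform(0, 1, 4000) ** (1 / 3)
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * radii[:, None] * SPHERE_R
        d = np.linalg.norm(pts[:2000, None] - pts[None, 2000:], axis=-1).ravel()
        hist, edges = np.histogram(d, bins=25, range=(0, 2 * SPHERE_R), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p_interp = np.interp(centers, pr.r, pr.p)
        p_interp /= np.trapezoid(p_interp, centers)
        assert np.corrcoef(hist, p_interp)[0, 1] > 0.99

    def test_pr_rg_consistent_with_guinier(self):
        c = sphere_curve()
        g = guinier_fit(c)
        pr = pair_distribution(c, guinier=g)
        assert pr.rg() == pytest.approx(g.Rg, rel=0.03)

    def test_back_transform_quality_on_noiseless_data(self):
        pr = pair_distribution(sphere_curve())
        assert pr.back_chi2 <= 1.5

    def test_fixed_dmax_respected(self):
        pr = pair_distribution(sphere_curve(), dmax=70.0)
        assert pr.dmax == 70.0
        assert pr.r[-1] == pytest.approx(70.0)

    def test_loop_closure_compacts_dmax(self):
        """Loop-closed chains report smaller Dmax than open chains of the
        same bead count, mirroring the compaction readout."""
        for n in (8, 16):
            open_pr = pair_distribution(
                synth.gen_saxs(synth.BeadModel.open_chain(n), snr=100, seed=1)
            )
            loop_pr = pair_distribution(
                synth.gen_saxs(synth.BeadModel.looped_chain(n), snr=100, seed=1)
            )
            assert loop_pr.dmax < open_pr.dmax


class TestFrameSelection:
    def _frame(self, Rg, seed=0, scale=100.0):
        q = np.linspace(0.005, 0.3, 150)
        I = scale * np.exp(-(q**2) * Rg**2 / 3)
        rng = np.random.default_rng(seed)
        sigma = 0.01 * I + 1e-6
        return ScatteringCurve(q, I + rng.normal(0, sigma), sigma)

    def test_identical_frames_all_selected(self):
        frames = [self._frame(20.0, seed=0)] * 6
        series = SecSaxsSeries(frames=frames)
        avg, mask = select_stable_frames(series)
        assert mask.all()
        assert avg.I == pytest.approx(frames[0].I)

    def test_single_frame_returned(self):
        series = SecSaxsSeries(frames=[self._frame(20.0)])
        avg, mask = select_stable_frames(series)
        assert mask.tolist() == [True]

    def test_plateau_frames_selected(self):
        """Rg drifts at the elution edges; only the stable plateau enters
        the average."""
        rgs = [30.0, 26.0, 23.0, 20.0, 20.1, 19.9, 20.0, 20.2, 24.0, 28.0]
        series = SecSaxsSeries(frames=[self._frame(r, seed=i) for i, r in enumerate(rgs)])
        avg, mask = select_stable_frames(series, rg_tolerance=0.05)
        assert mask.tolist() == [False, False, False, True, True, True, True, True, False, False]

    def test_averaging_reduces_sigma(self):
        frames = [self._frame(20.0, seed=i) for i in range(5)]
        series = SecSaxsSeries(frames=frames)
        avg, mask = select_stable_frames(series)
        min_sigma = np.min(np.stack([f.sigma for f in frames]), axis=0)
        assert np.all(avg.sigma <= min_sigma + 1e-15)

    def test_unstable_series_fails(self):
        rgs = [10.0, 20.0, 35.0, 55.0, 80.0]
        series = SecSaxsSeries(frames=[self._frame(r, seed=i) for i, r in enumerate(rgs)])
        with pytest.raises(FrameSelectionError):
            select_stable_frames(series, rg_tolerance=0.01)
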