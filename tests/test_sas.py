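"""Curve I/O, SEC reduction, Guinier, Kratky, P(r) inversion, Fischer MW."""

import numpy as np
import pytest

from flexsas.sas import (
    FrameSeries,
    GuinierError,
    SasError,
    ScatteringCurve,
    fischer_mw,
    guinier,
    ift_pr,
    kratky_dimensionless,
    pr_forward,
    pr_robustness_scan,
    read_curve,
    sec_reduce,
    write_curve,
)
from flexsas.synthetic import (
    PhantomSpec,
    debye_coil_intensity,
    guinier_intensity,
    make_phantom,
    make_sec_series,
    sphere_intensity,
    sphere_pr,
)


def _curve(q, i, rel_sigma=0.01):
    return ScatteringCurve(q, i, rel_sigma * np.abs(i))


class TestCurveIO:
    def test_sigma_scale_halves(self, tmp_path):
        p = tmp_path / "c.dat"
        p.write_text("# q I 2sig\n0.01 10.0 0.4\n0.02 9.0 0.4\n")
        c = read_curve(p, sigma_scale=2.0)
        assert np.allclose(c.sigma, [0.2, 0.2])

    def test_round_trip(self, tmp_path):
        q = np.linspace(0.01, 0.3, 40)
        c = _curve(q, np.exp(-q * 10))
        path = tmp_path / "c.dat"
        write_curve(c, path)
        c2 = read_curve(path)
        assert np.allclose(c2.q, c.q) and np.allclose(c2.i, c.i)
        assert np.allclose(c2.sigma, c.sigma)

    def test_two_column_file_rejected(self, tmp_path):
        p = tmp_path / "c.dat"
        p.write_text("0.01 10.0\n0.02 9.0\n")
        with pytest.raises(SasError, match="column"):
            read_curve(p)

    def test_nonpositive_sigma_dropped(self, tmp_path):
        p = tmp_path / "c.dat"
        p.write_text("0.01 10 0.1\n0.02 9 0.0\n0.03 8 0.1\n")
        c = read_curve(p)
        assert len(c) == 2 and c.metadata["n_dropped_sigma"] == 1

    def test_validation(self):
        with pytest.raises(SasError):
            ScatteringCurve(np.array([0.2, 0.1]), np.ones(2), np.ones(2))
        with pytest.raises(SasError):
            ScatteringCurve(np.array([0.1, 0.2]), np.ones(2),
                            np.array([1.0, 0.0]))


class TestSecReduce:
    def test_zero_buffer_identity(self):
        q = np.linspace(0.01, 0.3, 50)
        i = np.exp(-((q * 30) ** 2) / 3)
        sample = ScatteringCurve(q, i, 0.01 * i)
        buffer = ScatteringCurve(q, np.zeros_like(q) + 1e-9, 1e-6 * np.ones_like(q))
        series = FrameSeries(frames=[buffer, sample, sample])
        out = sec_reduce(series, [0], [1, 2])
        assert np.allclose(out.i, i, atol=1e-8)

    def test_sample_equals_buffer_gives_zero(self):
        q = np.linspace(0.01, 0.3, 50)
        i = np.full_like(q, 3.0)
        frames = [ScatteringCurve(q, i, 0.1 * i) for _ in range(4)]
        out = sec_reduce(FrameSeries(frames=frames), [0, 1], [2, 3])
        assert np.all(np.abs(out.i) <= 3 * out.sigma)

    def test_overlapping_sets_rejected(self):
        q = np.linspace(0.01, 0.2, 10)
        frames = [ScatteringCurve(q, np.ones(10), np.ones(10)) for _ in range(3)]
        with pytest.raises(SasError):
            sec_reduce(FrameSeries(frames=frames), [0, 1], [1, 2])

    def test_synthetic_series_recovers_rg(self):
        spec = PhantomSpec(kind="guinier", rg=40.0, i0=5.0, noise_a=0.005,
                           q_grid=np.linspace(0.005, 0.1, 120), seed=3)
        conc = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 2.0, 1.0, 0.0, 0.0])
        series, truth = make_sec_series(conc, spec, buffer_level=0.05, seed=4)
        out = sec_reduce(series, [0, 1, 2, 7, 8], [3, 4, 5, 6])
        fit = guinier(out)
        assert fit.rg == pytest.approx(40.0, rel=0.02)


class TestGuinier:
    def test_exact_recovery(self):
        q = np.linspace(0.004, 0.05, 60)
        i = 100.0 * np.exp(-(q * 50.0) ** 2 / 3.0)
        fit = guinier(_curve(q, i))
        assert fit.rg == pytest.approx(50.0, rel=1e-9)
        assert fit.i0 == pytest.approx(100.0, rel=1e-9)
        assert fit.qrg_max <= 1.1 + 1e-9

    def test_scaling_invariance(self):
        q = np.linspace(0.004, 0.05, 60)
        i = np.exp(-(q * 50.0) ** 2 / 3.0)
        f1 = guinier(_curve(q, i))
        f2 = guinier(_curve(q, 10.0 * i))
        assert f2.rg == pytest.approx(f1.rg)
        assert f2.i0 == pytest.approx(10.0 * f1.i0)

    def test_sphere_rg(self):
        q = np.linspace(0.003, 0.2, 400)
        i = sphere_intensity(q, 30.0)
        fit = guinier(_curve(q, i))
        assert fit.rg == pytest.approx(np.sqrt(3.0 / 5.0) * 30.0, rel=0.02)

    def test_explicit_point_range(self):
        q = np.linspace(0.004, 0.05, 60)
        i = np.exp(-(q * 50.0) ** 2 / 3.0)
        fit = guinier(_curve(q, i), point_range=(3, 12))
        assert fit.point_range == (3, 12)
        assert fit.n_points == 10

    def test_positive_slope_error(self):
        q = np.linspace(0.01, 0.1, 30)
        i = np.exp(+(q * 20.0) ** 2)
        with pytest.raises(GuinierError, match="slope"):
            guinier(_curve(q, i))


class TestKratky:
    def test_guinier_peak_at_sqrt3(self):
        q = np.linspace(0.0005, 0.12, 4000)
        i = guinier_intensity(q, 50.0)
        fit = guinier(_curve(q, i))
        k = kratky_dimensionless(_curve(q, i), fit)
        assert k["peak_qrg"] == pytest.approx(np.sqrt(3.0), rel=0.005)
        assert k["peak_value"] == pytest.approx(3.0 / np.e, rel=0.005)

    def test_coil_plateau_at_two(self):
        q = np.linspace(0.001, 2.0, 3000)
        i = debye_coil_intensity(q, 30.0)
        fit = guinier(_curve(q.copy()[:200], i[:200]))
        k = kratky_dimensionless(_curve(q, i), fit)
        tail = k["value"][k["qrg"] > 40]
        assert np.allclose(tail, 2.0, rtol=0.1)

    def test_zero_limit(self):
        q = np.linspace(0.001, 0.1, 100)
        i = guinier_intensity(q, 50.0)
        fit = guinier(_curve(q, i))
        k = kratky_dimensionless(_curve(q, i), fit)
        # transform vanishes quadratically at low q
        assert k["value"][0] == pytest.approx((q[0] * fit.rg) ** 2, rel=0.01)
        assert k["value"][0] < 0.01


class TestIftPr:
    def test_sphere_recovery(self):
        q = np.linspace(0.005, 0.35, 300)
        c = _curve(q, sphere_intensity(q, 40.0), rel_sigma=0.005)
        pr = ift_pr(c, dmax=80.0)
        ref = sphere_pr(pr.r_grid, 40.0)
        assert np.max(np.abs(pr.p / pr.p.max() - ref)) < 0.02
        assert pr.rg_pr == pytest.approx(np.sqrt(3.0 / 5.0) * 40.0, rel=0.01)

    def test_i0_matches_forward_limit(self):
        q = np.linspace(0.005, 0.35, 300)
        c = _curve(q, sphere_intensity(q, 40.0, i0=7.5), rel_sigma=0.005)
        pr = ift_pr(c, dmax=80.0)
        fwd0 = pr_forward(pr, np.array([1e-6]))[0]
        assert pr.i0_pr == pytest.approx(fwd0, rel=0.01)
        assert pr.i0_pr == pytest.approx(7.5, rel=0.02)

    def test_round_trip_smooth_unimodal(self):
        r = np.linspace(0.0, 100.0, 201)
        p = np.sin(np.pi * r / 100.0) ** 2 * np.exp(-r / 60.0)
        p[0] = p[-1] = 0.0
        q = np.linspace(0.005, 0.4, 300)
        from flexsas.synthetic import pr_to_intensity

        i = pr_to_intensity(r, p, q)
        pr = ift_pr(_curve(q, i, rel_sigma=0.005), dmax=100.0)
        assert np.max(np.abs(pr.p - np.interp(pr.r_grid, r, p))) < 0.03 * p.max()

    def test_wrong_dmax_raises_chi2(self):
        q = np.linspace(0.01, 0.35, 300)
        c = _curve(q, sphere_intensity(q, 40.0), rel_sigma=0.005)
        good = ift_pr(c, dmax=80.0)
        with pytest.warns(UserWarning):
            bad = ift_pr(c, dmax=40.0)
        assert bad.fit_chi2 >= 5.0 * good.fit_chi2

    def test_endpoints_zero(self):
        q = np.linspace(0.005, 0.35, 200)
        pr = ift_pr(_curve(q, sphere_intensity(q, 30.0)), dmax=60.0)
        assert pr.p[0] == 0.0 and pr.p[-1] == 0.0

    def test_qmin_warning(self):
        q = np.linspace(0.05, 0.35, 100)
        with pytest.warns(UserWarning, match="Dmax"):
            ift_pr(_curve(q, sphere_intensity(q, 40.0)), dmax=80.0, alpha=1.0)


class TestRobustnessScan:
    @staticmethod
    def _bimodal_curve(seed=4):
        r = np.linspace(0.0, 340.0, 341)
        main = np.exp(-0.5 * ((r - 70.0) / 30.0) ** 2)
        sat = 0.10 * np.exp(-0.5 * ((r - 250.0) / 20.0) ** 2)
        p = (main + sat) * (r / 50.0) * np.exp(-r / 200.0)
        p[0] = p[-1] = 0.0
        spec = PhantomSpec(kind="pr_custom", pr_table=(r, p), i0=1.0,
                           noise_a=0.01, seed=seed,
                           q_grid=np.linspace(0.008, 0.25, 300))
        return make_phantom(spec)[0]

    def test_satellite_persists(self):
        curve = self._bimodal_curve()
        a0 = ift_pr(curve, 340.0).alpha
        scan = pr_robustness_scan(curve, [306.0, 340.0, 374.0],
                                  [a0 / 3, a0, 3 * a0],
                                  feature_window=(220.0, 300.0))
        assert scan["persistence_fraction"] >= 0.9

    def test_sphere_never_flags(self):
        q = np.linspace(0.008, 0.25, 300)
        curve, _ = make_phantom(PhantomSpec(kind="sphere", radius=40.0,
                                            noise_a=0.01, seed=5, q_grid=q))
        a0 = ift_pr(curve, 80.0).alpha
        scan = pr_robustness_scan(curve, [72.0, 80.0, 88.0],
                                  [a0 / 3, a0, 3 * a0],
                                  feature_window=(40.0, 76.0))
        assert scan["persistence_fraction"] == 0.0

    def test_empty_grid_rejected(self):
        curve = self._bimodal_curve()
        with pytest.raises(SasError):
            pr_robustness_scan(curve, [340.0], [], feature_window=(200, 300))


class TestFischerMw:
    def test_sphere_volume(self):
        q = np.linspace(0.003, 0.35, 600)
        c = _curve(q, sphere_intensity(q, 30.0), rel_sigma=0.002)
        fit = guinier(c)
        out = fischer_mw(c, fit)
        true_v = 4.0 / 3.0 * np.pi * 30.0 ** 3
        assert out["volume"] == pytest.approx(true_v, rel=0.10)

    def test_scale_invariant_mw(self):
        q = np.linspace(0.003, 0.35, 600)
        i = sphere_intensity(q, 30.0)
        m1 = fischer_mw(_curve(q, i), guinier(_curve(q, i)))
        c10 = _curve(q, 10 * i)
        m2 = fischer_mw(c10, guinier(c10))
        assert m2["mw_kda"] == pytest.approx(m1["mw_kda"], rel=1e-6)

    def test_short_curve_rejected(self):
        q = np.linspace(0.003, 0.1, 100)
        c = _curve(q, sphere_intensity(q, 30.0))
        with pytest.raises(SasError):
            fischer_mw(c, guinier(c), qmax_cut=0.3)
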