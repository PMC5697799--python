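import logging

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miefield.exceptions import GeometryError, ValidationError
from miefield.incident import OpticalConfig, focused_field
from miefield.materials import MaterialSpectrum
from miefield.scatter import (
    Scene,
    Sphere,
    aperture_samples,
    icosphere,
    mc_sphere_field,
    planewave_sphere_field,
    sample_scatter_domain,
    scatter_domain,
    scattering_coefficients,
    surface_field,
    total_field,
)
from miefield.sphmath import aperture_coeffs, legendre_sequence, spherical_bessel_family, spherical_jn_all

LAM = 2.5
K = 2 * np.pi / LAM
ZHAT = np.array([0.0, 0.0, 1.0])


class TestScatteringCoefficients:
    def test_null_scatterer_B_vanishes(self):
        co = scattering_coefficients(1.0, 1.0, LAM)
        assert np.max(np.abs(co.B)) < 1e-12

    def test_null_scatterer_A_is_incident_expansion(self):
        co = scattering_coefficients(1.0, 1.0, LAM)
        l = np.arange(co.N_l + 1)
        np.testing.assert_allclose(co.A, (2 * l + 1) * 1j**l, atol=1e-12)

    def test_coefficient_decay(self):
        for ka in (1.0, 5.0, 15.0):
            for n in (1.5, 1.5 + 0.1j, 2.4):
                co = scattering_coefficients(ka / K, n, LAM)
                assert np.abs(co.B[-1]) < 1e-6 * np.max(np.abs(co.B))

    def test_absorbing_index_required_nonnegative(self):
        with pytest.raises(ValidationError):
            scattering_coefficients(1.0, 1.5 - 0.1j, LAM)

    def test_bad_geometry(self):
        with pytest.raises(ValidationError):
            scattering_coefficients(-1.0, 1.5, LAM)


class TestPlanewaveSphereField:
    @pytest.fixture
    def setup(self):
        a, n = 1.0, 1.5 + 0.01j
        return Sphere([0.0, 0.0, 0.0], a), scattering_coefficients(a, n, LAM)

    def test_centered_sphere_has_unit_phase(self, setup):
        sphere, co = setup
        pts = np.array([[0.0, 0.0, 2.0]])
        # moving the focal point does not change the field when c is scaled to 0
        v1 = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts)
        sphere2 = Sphere([1.0, 0.0, 0.0], sphere.radius)
        v2 = planewave_sphere_field(sphere2, co, ZHAT, [1.0, 0.0, 0.0],
                                    pts + np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(v1, v2, rtol=1e-12)

    def test_translation_phase_parallel(self, setup, surface_directions):
        sphere, co = setup
        pts = 1.7 * surface_directions
        delta = 0.731
        shifted = Sphere(sphere.center + delta * ZHAT, sphere.radius)
        v0 = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts)
        v1 = planewave_sphere_field(shifted, co, ZHAT, [0, 0, 0],
                                    pts + delta * ZHAT)
        np.testing.assert_allclose(v1, np.exp(1j * K * delta) * v0, atol=1e-10)

    def test_translation_phase_perpendicular(self, setup, surface_directions):
        # offsets perpendicular to the propagation direction leave the
        # phase factor unchanged
        sphere, co = setup
        pts = 1.7 * surface_directions
        delta = np.array([0.62, -0.41, 0.0])
        shifted = Sphere(sphere.center + delta, sphere.radius)
        v0 = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts)
        v1 = planewave_sphere_field(shifted, co, ZHAT, [0, 0, 0], pts + delta)
        np.testing.assert_allclose(v1, v0, atol=1e-10)

    def test_boundary_continuity(self, setup, surface_directions):
        sphere, co = setup
        pts = sphere.radius * surface_directions
        es = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts, branch="external")
        ei = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts, branch="internal")
        einc = np.exp(1j * K * (pts @ ZHAT))
        mismatch = np.max(np.abs(ei - (einc + es))) / np.max(np.abs(ei))
        assert mismatch < 1e-6

    def test_center_point_is_regular(self, setup):
        sphere, co = setup
        val = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], [sphere.center])[0]
        assert np.isfinite(val)
        assert val == pytest.approx(co.A[0], rel=1e-12)  # j_0(0) P_0 = 1

    def test_arbitrary_precision_oracle(self, setup):
        # independent high-order series with mpmath special functions
        sphere, co = setup
        mp.mp.dps = 40
        n = co.n
        x = mp.mpf(K) * sphere.radius
        z = mp.mpc(n) * x

        def jl(l, zz):
            zz = mp.mpc(zz)
            return mp.sqrt(mp.pi / (2 * zz)) * mp.besselj(l + mp.mpf(1) / 2, zz)

        def h1(l, zz):
            zz = mp.mpc(zz)
            return mp.sqrt(mp.pi / (2 * zz)) * (
                mp.besselj(l + mp.mpf(1) / 2, zz) + 1j * mp.bessely(l + mp.mpf(1) / 2, zz))

        def deriv(f, l, zz):
            return f(1, zz) * (-1) if l == 0 else f(l - 1, zz) - (l + 1) / mp.mpc(zz) * f(l, zz)

        pts = np.array([[0.5, 0.2, 1.3], [0.0, 0.9, -0.8], [1.6, 0.0, 0.2]])
        ours = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts)
        for p, got in zip(pts, ours):
            r = mp.sqrt(sum(mp.mpf(float(c)) ** 2 for c in p))
            ct = mp.mpf(float(p[2])) / r
            total = mp.mpc(0)
            for l in range(co.N_l + 1):
                num = jl(l, x) * deriv(jl, l, z) * n - jl(l, z) * deriv(jl, l, x)
                den = jl(l, z) * deriv(h1, l, x) - h1(l, x) * deriv(jl, l, z) * n
                B = (2 * l + 1) * 1j**l * num / den
                total += B * h1(l, mp.mpf(K) * r) * mp.legendre(l, ct)
            ref = complex(total)
            assert abs(got - ref) < 1e-10 * abs(ref)


class TestScatterDomain:
    @pytest.fixture
    def domain_setup(self):
        a, n = 1.0, 1.5 + 0.02j
        sphere = Sphere([0.0, 0.0, 0.0], a)
        co = scattering_coefficients(a, n, LAM)
        dom = scatter_domain(sphere, co, fov=10.0, resolution=256, r_theta=1000)
        return sphere, co, dom

    def test_node_equality(self, domain_setup):
        sphere, co, dom = domain_setup
        for i, j in [(40, 100), (200, 700), (5, 10)]:
            d, ct = dom.d_axis[i], dom.costheta_axis[j]
            p = [d * np.sqrt(1 - ct**2), 0.0, d * ct]
            direct = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], [p])[0]
            assert sample_scatter_domain(dom, d, ct)[0] == pytest.approx(direct, rel=1e-10)

    def test_random_probe_interpolation(self, domain_setup, rng):
        sphere, co, dom = domain_setup
        d = rng.uniform(1.2, 4.8, 100)
        ct = rng.uniform(-1, 1, 100)
        pts = np.stack([d * np.sqrt(1 - ct**2), np.zeros(100), d * ct], axis=1)
        direct = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts)
        via = sample_scatter_domain(dom, d, ct)
        assert np.max(np.abs(via - direct)) / np.max(np.abs(direct)) < 1e-3

    def test_continuity_at_surface(self, domain_setup, surface_directions):
        sphere, co, _ = domain_setup
        pts = sphere.radius * surface_directions
        es = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts, branch="external")
        ei = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts, branch="internal")
        einc = np.exp(1j * K * pts[:, 2])
        assert np.max(np.abs(ei - (einc + es))) / np.max(np.abs(ei)) < 1e-6

    def test_aliasing_does_not_improve_accuracy(self, domain_setup, rng):
        sphere, co, _ = domain_setup
        errs = {}
        for r_theta in (2 * co.N_l, co.N_l):
            dom = scatter_domain(sphere, co, fov=10.0, resolution=256,
                                 r_theta=r_theta)
            d = rng.uniform(3.5, 4.9, 200)
            ct = rng.uniform(-1, 1, 200)
            pts = np.stack([d * np.sqrt(1 - ct**2), np.zeros(200), d * ct], axis=1)
            direct = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], pts)
            via = sample_scatter_domain(dom, d, ct)
            errs[r_theta] = np.max(np.abs(via - direct))
        assert errs[2 * co.N_l] < errs[co.N_l]

    def test_below_nyquist_warns(self, domain_setup, caplog):
        sphere, co, _ = domain_setup
        with caplog.at_level(logging.WARNING):
            scatter_domain(sphere, co, fov=10.0, resolution=32, r_theta=co.N_l)
        assert any("Nyquist" in r.message for r in caplog.records)

    def test_clamp_warning(self, domain_setup, caplog):
        _, _, dom = domain_setup
        with caplog.at_level(logging.WARNING):
            sample_scatter_domain(dom, 99.0, 0.5)
        assert any("clamping" in r.message for r in caplog.records)


class TestApertureSamples:
    def test_degenerate_cap(self):
        s = aperture_samples(0.0, 1e-7, 50, seed=1)
        np.testing.assert_allclose(s.directions[:, 2], 1.0, atol=1e-9)

    def test_mean_z_matches_uniform_expectation(self):
        alpha2 = np.arcsin(0.8)
        s = aperture_samples(0.0, alpha2, 100000, seed=3)
        expect = (1 + np.cos(alpha2)) / 2
        se = np.sqrt((1 - np.cos(alpha2)) ** 2 / 12 / s.M)
        assert abs(s.directions[:, 2].mean() - expect) < 3 * se

    def test_seed_reproducibility(self):
        a = aperture_samples(0.1, 0.9, 777, seed=42)
        b = aperture_samples(0.1, 0.9, 777, seed=42)
        np.testing.assert_array_equal(a.directions, b.directions)

    @settings(max_examples=25, deadline=None)
    @given(m=st.integers(1, 400), seed=st.integers(0, 2**31),
           a1=st.floats(0.0, 0.5), width=st.floats(0.01, 1.0))
    def test_all_directions_in_cap(self, m, seed, a1, width):
        a2 = a1 + width
        s = aperture_samples(a1, a2, m, seed)
        theta = np.arccos(np.clip(s.directions[:, 2], -1, 1))
        assert np.all(theta >= a1 - 1e-9)
        assert np.all(theta <= a2 + 1e-9)
        np.testing.assert_allclose(np.linalg.norm(s.directions, axis=1), 1.0,
                                   rtol=1e-12)

    def test_validation(self):
        with pytest.raises(ValidationError):
            aperture_samples(0.5, 0.2, 10, 0)
        with pytest.raises(ValidationError):
            aperture_samples(0.0, 0.5, 0, 0)


class Fig7Setup:
    """3 um particle, lam = 2.5 um, 0.8 NA condenser."""

    config = OpticalConfig.from_na(LAM, 0.0, 0.8)
    sphere = Sphere([0.0, 0.0, 0.0], 1.5)
    coeffs = scattering_coefficients(1.5, 1.4 + 0.05j, LAM)

    @classmethod
    def mc(cls, m, seed, pts, **kw):
        s = aperture_samples(cls.config.alpha1, cls.config.alpha2, m, seed)
        return mc_sphere_field(cls.sphere, cls.coeffs, s, cls.config, pts, **kw)


class TestMonteCarloField:
    def test_closed_form_limit_for_centered_sphere(self):
        # Aperture integration of the Legendre term has a closed form when
        # c = 0: E_s = 2 pi E0 sum_l B_l c_l / (2l+1) h1_l(kr) P_l(cos t)
        cfg, sphere, co = Fig7Setup.config, Fig7Setup.sphere, Fig7Setup.coeffs
        pts = np.array([[0.0, 0.0, 2.0], [1.5, 0.5, 0.5], [0.0, 2.2, 0.1]])
        mc = Fig7Setup.mc(10000, 7, pts, branch="external")
        l = np.arange(co.N_l + 1)
        w = co.B * aperture_coeffs(co.N_l, cfg.alpha1, cfg.alpha2) / (2 * l + 1)
        r = np.linalg.norm(pts, axis=1)
        ct = pts[:, 2] / r
        h1 = spherical_bessel_family(co.N_l, K * r).h1
        P = legendre_sequence(co.N_l, ct)
        closed = 2 * np.pi * cfg.E0 * (w @ (h1 * P))
        # error normalized by the peak magnitude over the probe set
        assert np.max(np.abs(mc - closed)) / np.max(np.abs(closed)) < 0.005

    def test_standard_error_scaling(self):
        probe = np.array([[0.4, 0.3, 0.6]])
        ms = [25, 100, 400, 1600]
        stds = []
        for m in ms:
            vals = np.array([abs(Fig7Setup.mc(m, 1000 + s, probe)[0])
                             for s in range(60)])
            stds.append(vals.std(ddof=1))
        slope = np.polyfit(np.log(ms), np.log(stds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_unbiased_estimator(self):
        probe = np.array([[0.4, 0.3, 0.6]])
        vals = np.array([Fig7Setup.mc(25, 2000 + s, probe)[0] for s in range(200)])
        ref = Fig7Setup.mc(10000, 55, probe)[0]
        se_mean = vals.std(ddof=1) / np.sqrt(len(vals))
        se_ref = vals.std(ddof=1) / np.sqrt(10000 / 25)
        assert abs(vals.mean() - ref) < 3 * np.hypot(se_mean, se_ref)

    def test_centered_sphere_rotational_symmetry(self):
        # centered sphere: rotationally symmetric up to MC noise, which
        # shrinks with M
        phis = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        th = np.pi / 3
        a = Fig7Setup.sphere.radius
        ring = np.stack([a * np.sin(th) * np.cos(phis),
                         a * np.sin(th) * np.sin(phis),
                         np.full(16, a * np.cos(th))], axis=1)
        spreads = []
        for m in (400, 6400):
            v = np.abs(Fig7Setup.mc(m, 9, ring))
            spreads.append((v.max() - v.min()) / v.mean())
        assert spreads[1] < spreads[0]
        assert spreads[1] < 0.15

    def test_mismatched_aperture_warns(self, caplog):
        other = OpticalConfig.from_na(LAM, 0.0, 0.5)
        s = aperture_samples(other.alpha1, other.alpha2, 16, 0)
        with caplog.at_level(logging.WARNING):
            mc_sphere_field(Fig7Setup.sphere, Fig7Setup.coeffs, s,
                            Fig7Setup.config, [[0.0, 0.0, 2.0]])
        assert any("differs" in r.message for r in caplog.records)


class TestTotalField:
    def test_no_spheres_is_focused_field(self, lens_config):
        scene = Scene([], lens_config)
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, -0.5]])
        np.testing.assert_allclose(total_field(scene, pts),
                                   focused_field(lens_config, pts), rtol=1e-12)

    def test_null_scatterer_matches_incident(self):
        cfg = OpticalConfig.from_na(LAM, 0.0, 0.8)
        mat = MaterialSpectrum.constant(1.0 + 0.0j)
        samp = aperture_samples(cfg.alpha1, cfg.alpha2, 4000, 3)
        scene = Scene([Sphere([0.0, 0.0, 0.0], 1.0, mat)], cfg, samp)
        pts = np.array([[0.0, 0.0, 0.0], [0.3, 0.2, 0.1], [0.5, -0.4, 0.6],
                        [2.0, 1.0, 0.5]])
        tf = total_field(scene, pts)
        ff = focused_field(cfg, pts)
        assert np.max(np.abs(tf - ff) / np.abs(ff)) < 0.02

    def test_overlapping_point_raises(self, lens_config):
        mat = MaterialSpectrum.constant(1.5)
        samp = aperture_samples(lens_config.alpha1, lens_config.alpha2, 16, 0)
        scene = Scene([Sphere([0.0, 0.0, 0.0], 1.0, mat),
                       Sphere([0.5, 0.0, 0.0], 1.0, mat)], lens_config, samp)
        with pytest.raises(GeometryError):
            total_field(scene, [[0.25, 0.0, 0.0]])

    def test_overlap_warns_at_scene_build(self, lens_config, caplog):
        mat = MaterialSpectrum.constant(1.5)
        with caplog.at_level(logging.WARNING):
            Scene([Sphere([0.0, 0.0, 0.0], 1.0, mat),
                   Sphere([0.5, 0.0, 0.0], 1.0, mat)], lens_config)
        assert any("overlap" in r.message for r in caplog.records)

    def test_missing_sampling_raises(self, lens_config):
        mat = MaterialSpectrum.constant(1.5)
        scene = Scene([Sphere([0.0, 0.0, 0.0], 1.0, mat)], lens_config)
        with pytest.raises(ValidationError):
            total_field(scene, [[3.0, 0.0, 0.0]])

    def test_three_sphere_row_center_dominates(self):
        # three 2 um diameter spheres separated by 2 um of vacuum, 0.2 NA
        cfg = OpticalConfig.from_na(LAM, 0.0, 0.2)
        mat = MaterialSpectrum.constant(1.49 + 0.01j)
        samp = aperture_samples(cfg.alpha1, cfg.alpha2, 400, 5)
        spheres = [Sphere([-4.0, 0, 0], 1.0, mat), Sphere([0.0, 0, 0], 1.0, mat),
                   Sphere([4.0, 0, 0], 1.0, mat)]
        scene = Scene(spheres, cfg, samp)
        mags = [surface_field(s, scene, 162).magnitude.mean() for s in spheres]
        assert mags[1] > mags[0]
        assert mags[1] > mags[2]


class TestSurfaceField:
    def test_icosphere_counts(self):
        for level, count in [(0, 12), (1, 42), (2, 162), (3, 642)]:
            verts, faces = icosphere(level)
            assert verts.shape == (count, 3)
            assert faces.shape == (20 * 4**level, 3)
            np.testing.assert_allclose(np.linalg.norm(verts, axis=1), 1.0,
                                       rtol=1e-12)

    def test_invalid_vertex_count(self, single_sphere_scene):
        with pytest.raises(ValidationError):
            surface_field(single_sphere_scene.spheres[0], single_sphere_scene, 100)

    def test_planewave_constant_on_theta_rings(self):
        # Eq-symmetry: a centered sphere under one plane wave depends only
        # on (r, cos theta)
        a = 1.0
        co = scattering_coefficients(a, 1.5 + 0.02j, LAM)
        sphere = Sphere([0.0, 0.0, 0.0], a)
        phis = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        th = 0.9
        ring = np.stack([a * np.sin(th) * np.cos(phis),
                         a * np.sin(th) * np.sin(phis),
                         np.full(16, a * np.cos(th))], axis=1)
        vals = planewave_sphere_field(sphere, co, ZHAT, [0, 0, 0], ring)
        np.testing.assert_allclose(vals, vals[0], rtol=1e-10)

    def test_internal_external_consistency_at_surface(self):
        # MC internal minus MC external must equal the MC estimate of the
        # incident wave (per-sample identity at r = a)
        cfg, sphere, co = Fig7Setup.config, Fig7Setup.sphere, Fig7Setup.coeffs
        samp = aperture_samples(cfg.alpha1, cfg.alpha2, 200, 13)
        verts, _ = icosphere(2)
        pts = sphere.radius * verts[:40]
        ei = mc_sphere_field(sphere, co, samp, cfg, pts, branch="internal")
        es = mc_sphere_field(sphere, co, samp, cfg, pts, branch="external")
        pref = 2 * np.pi * cfg.E0 * (np.cos(cfg.alpha1) - np.cos(cfg.alpha2)) / samp.M
        einc = pref * np.exp(1j * cfg.k * (samp.directions @ pts.T)).sum(axis=0)
        assert np.max(np.abs(ei - (einc + es))) / np.max(np.abs(ei)) < 1e-6

    def test_off_focus_sphere_gains_phi_dependence(self):
        cfg, co = Fig7Setup.config, Fig7Setup.coeffs
        a = Fig7Setup.sphere.radius
        phis = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        th = np.pi / 3
        ring = np.stack([a * np.sin(th) * np.cos(phis),
                         a * np.sin(th) * np.sin(phis),
                         np.full(16, a * np.cos(th))], axis=1)
        centered = np.abs(Fig7Setup.mc(6400, 9, ring))
        off_sphere = Sphere([2.0, 0.0, 0.0], a)
        samp = aperture_samples(cfg.alpha1, cfg.alpha2, 6400, 9)
        off = np.abs(mc_sphere_field(off_sphere, co, samp, cfg,
                                     ring + np.array([2.0, 0.0, 0.0])))
        spread_c = (centered.max() - centered.min()) / centered.mean()
        spread_o = (off.max() - off.min()) / off.mean()
        assert spread_o > 5 * spread_c

    def test_ply_export(self, tmp_path, single_sphere_scene):
        mesh = surface_field(single_sphere_scene.spheres[0],
                             single_sphere_scene, 42)
        path = tmp_path / "sphere.ply"
        mesh.write_ply(path)
        text = path.read_text().splitlines()
        assert text[0] == "ply"
        assert f"element vertex {mesh.positions.shape[0]}" in text
        assert f"element face {mesh.faces.shape[0]}" in text
        body = text[text.index("end_header") + 1:]
        assert len(body) == mesh.positions.shape[0] + mesh.faces.shape[0]
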