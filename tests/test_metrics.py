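"""Mode counting, curvature bias, Gaussian curvature, power-law fits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shellgrow.fixtures import make_analytic_sphere_patch, make_sinusoidal_edge
from shellgrow.metrics import (
    EdgeProfile,
    count_modes,
    curvature_bias,
    fit_power_law,
    gaussian_curvature,
    quads_from_structured,
)


class TestCountModes:
    def test_five_full_waves(self):
        prof = make_sinusoidal_edge(10.0, 5, 1.0)
        assert count_modes(prof).n == 5

    def test_flat_profile_counts_zero(self):
        prof = make_sinusoidal_edge(10.0, 5, 0.0)
        m = count_modes(prof)
        assert m.n == 0 and m.n_all == 0

    def test_localized_envelope_distinguishes_thresholds(self):
        # three central crests above 10% of the peak; all seven present
        prof = make_sinusoidal_edge(10.0, 7, 1.0, envelope="gaussian",
                                    envelope_sigma_fraction=0.095)
        m = count_modes(prof, threshold_fraction=0.1)
        assert m.n == 3
        assert m.n_all == 7

    @given(st.floats(0.01, 100.0), st.integers(1, 12))
    def test_scale_invariance(self, scale, n_waves):
        prof = make_sinusoidal_edge(10.0, n_waves, 1.0, n_samples=max(64, 6 * n_waves))
        scaled = EdgeProfile(xi2=prof.xi2, w=scale * prof.w)
        assert count_modes(prof).n == count_modes(scaled).n == n_waves

    def test_sign_symmetry(self):
        prof = make_sinusoidal_edge(10.0, 6, 1.0, envelope="gaussian")
        flipped = EdgeProfile(xi2=prof.xi2, w=-prof.w)
        m1, m2 = count_modes(prof), count_modes(flipped)
        assert (m1.n, m1.n_all) == (m2.n, m2.n_all)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            count_modes(make_sinusoidal_edge(10.0, 2, 1.0), threshold_fraction=1.5)
        with pytest.raises(ValueError):
            count_modes(EdgeProfile(xi2=np.arange(4.0), w=np.zeros(4)))


class TestCurvatureBias:
    def test_straight_reference_balanced(self):
        prof = make_sinusoidal_edge(10.0, 5, 1.0)
        ratio, rep = curvature_bias(prof, np.zeros(len(prof.w)))
        assert rep["flag"] == "straight_reference"
        assert 0.9 <= ratio <= 1.1

    def test_equal_crests_give_unit_ratio(self):
        prof = make_sinusoidal_edge(10.0, 4, 1.0)
        kap = np.full(len(prof.w), -0.05)  # compatible with +w crests
        ratio, _ = curvature_bias(prof, kap)
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_suppressed_incompatible_crests(self):
        prof = make_sinusoidal_edge(10.0, 4, 1.0)
        w = prof.w.copy()
        w[w < 0] *= 0.3  # suppress troughs
        biased = EdgeProfile(xi2=prof.xi2, w=w)
        kap = np.full(len(w), 0.05)  # troughs (w<0) are the compatible family
        ratio, rep = curvature_bias(biased, kap)
        assert ratio == pytest.approx(0.3, abs=1e-6)
        kap_neg = -kap
        ratio2, _ = curvature_bias(biased, kap_neg)
        assert ratio2 == pytest.approx(1 / 0.3, abs=1e-4)

    def test_zero_deflection_flagged(self):
        prof = make_sinusoidal_edge(10.0, 3, 0.0)
        ratio, rep = curvature_bias(prof, np.zeros(len(prof.w)))
        assert ratio == 1.0
        assert rep["flag"] == "zero_deflection"


class TestGaussianCurvature:
    def test_sphere_patch_constant_curvature(self):
        R = 10.0
        grid = make_analytic_sphere_patch(R, 64, 64)
        verts, quads = quads_from_structured(grid)
        K = gaussian_curvature(verts, quads)
        K = K[np.isfinite(K)]
        assert np.median(K) == pytest.approx(1.0 / R**2, rel=0.05)

    def test_refinement_improves_sphere_estimate(self):
        R = 10.0
        errs = []
        for n in (16, 32, 64):
            grid = make_analytic_sphere_patch(R, n, n)
            verts, quads = quads_from_structured(grid)
            K = gaussian_curvature(verts, quads)
            K = K[np.isfinite(K)]
            errs.append(abs(np.median(K) - 1.0 / R**2))
        assert errs[2] < errs[1] < errs[0] * 1.05

    def test_plane_is_flat(self):
        x, y = np.meshgrid(np.linspace(0, 1, 12), np.linspace(0, 2, 12), indexing="ij")
        grid = np.stack([x, y, 0 * x + 0.3 * x + 0.1 * y], axis=-1)  # tilted plane
        verts, quads = quads_from_structured(grid)
        K = gaussian_curvature(verts, quads)
        assert np.nanmax(np.abs(K)) < 1e-10

    def test_monkey_saddle_negative(self):
        x, y = np.meshgrid(np.linspace(-1, 1, 40), np.linspace(-1, 1, 40), indexing="ij")
        grid = np.stack([x, y, x**3 - 3 * x * y**2], axis=-1)
        verts, quads = quads_from_structured(grid)
        K = gaussian_curvature(verts, quads).reshape(40, 40)
        interior = K[5:-5, 5:-5]
        away = np.abs(x[5:-5, 5:-5]) + np.abs(y[5:-5, 5:-5]) > 0.4
        assert np.all(interior[away] < 0)

    def test_gauss_bonnet_on_closed_sphere(self):
        # cube-sphere quad mesh: total curvature = 4 pi (Euler characteristic 2)
        n = 12
        faces = []
        verts = []
        lin = np.linspace(-1, 1, n)
        for axis in range(3):
            for sgn in (-1.0, 1.0):
                a, b = np.meshgrid(lin, lin, indexing="ij")
                pts = np.zeros((n, n, 3))
                pts[..., axis] = sgn
                pts[..., (axis + 1) % 3] = a
                pts[..., (axis + 2) % 3] = sgn * b  # keep outward orientation
                pts /= np.linalg.norm(pts, axis=-1, keepdims=True)
                base = len(verts)
                verts.extend(pts.reshape(-1, 3))
                for i in range(n - 1):
                    for j in range(n - 1):
                        faces.append([base + i * n + j, base + (i + 1) * n + j,
                                      base + (i + 1) * n + j + 1, base + i * n + j + 1])
        verts = np.asarray(verts)
        # merge duplicate cube-edge vertices
        key = np.round(verts, 9)
        _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
        verts_u = verts[idx]
        faces_u = inv[np.asarray(faces)]
        K = gaussian_curvature(verts_u, faces_u)
        assert np.all(np.isfinite(K))  # closed surface: no boundary vertices
        # angle deficits sum exactly to 2 pi chi; with the mixed-area weights
        # the integral estimate stays within 2%
        areas = np.zeros(len(verts_u))
        tris = np.vstack([faces_u[:, [0, 1, 2]], faces_u[:, [0, 2, 3]]])
        for c in range(3):
            aa = verts_u[tris[:, c]]
            bb = verts_u[tris[:, (c + 1) % 3]]
            cc = verts_u[tris[:, (c + 2) % 3]]
            tri_area = 0.5 * np.linalg.norm(np.cross(bb - aa, cc - aa), axis=1)
            np.add.at(areas, tris[:, c], tri_area / 3.0)
        total = np.sum(K * areas)
        assert total == pytest.approx(4 * np.pi, rel=0.02)

    def test_degenerate_face_rejected(self):
        verts = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            gaussian_curvature(verts, np.array([[0, 1, 2, 3]]))


class TestFitPowerLaw:
    def test_exact_inverse_law(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        a, b, r2 = fit_power_law(x, 1.0 / x)
        assert a == pytest.approx(-1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_quadratic_monte_carlo(self):
        rng = np.random.default_rng(11)
        exps = []
        for _ in range(50):
            x = np.linspace(1, 10, 20)
            y = 3 * x**2 * np.exp(0.01 * rng.standard_normal(20))
            a, _, _ = fit_power_law(x, y)
            exps.append(a)
        assert np.mean(exps) == pytest.approx(2.0, abs=0.05)
        assert np.max(np.abs(np.array(exps) - 2.0)) < 0.05

    def test_degenerate_x_finite(self):
        a, b, r2 = fit_power_law([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isfinite(a) and np.isfinite(b)
        assert r2 < 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])
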