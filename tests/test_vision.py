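"""Spectra, cone catches, polynomial camera mapping and JND formulas."""

import numpy as np
import pytest

from mimicspec.vision import (ConeCatch, Spectrum, WeberFractions,
                              apply_camera_to_cone, chromatic_jnd,
                              cone_catch_from_spectrum, fit_camera_to_cone,
                              flat_illuminant, gaussian_receptor,
                              interpolate_spectrum, luminance_jnd,
                              pairwise_chromatic_jnd, weber_from_abundances,
                              ReceptorSet, builtin_receptor_set)


class TestInterpolation:
    def test_same_grid_unchanged(self):
        grid = np.arange(400.0, 501.0)
        s = Spectrum(grid, np.linspace(0.1, 0.5, grid.size))
        out = interpolate_spectrum(s, grid)
        np.testing.assert_allclose(out.value, s.value, atol=1e-15)

    def test_linear_midpoint(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.2, 0.4]))
        out = interpolate_spectrum(s, np.array([400.0, 450.0, 500.0]))
        assert out.value[1] == pytest.approx(0.3, abs=1e-15)

    def test_matches_piecewise_linear_oracle(self, rng):
        wl = np.sort(rng.uniform(350, 650, 10))
        wl[0], wl[-1] = 350.0, 650.0
        v = rng.uniform(0, 1, 10)
        s = Spectrum(wl, v)
        queries = rng.uniform(350, 650, 20)
        out = interpolate_spectrum(s, np.sort(queries))
        for q, got in zip(np.sort(queries), out.value):
            j = np.searchsorted(wl, q) - 1
            j = min(max(j, 0), wl.size - 2)
            frac = (q - wl[j]) / (wl[j + 1] - wl[j])
            assert got == pytest.approx(v[j] + frac * (v[j + 1] - v[j]),
                                        abs=1e-12)

    def test_extrapolation_refused(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.2, 0.4]))
        with pytest.raises(ValueError, match="beyond"):
            interpolate_spectrum(s, np.array([390.0, 450.0]))


class TestConeCatch:
    def test_white_reflector_gives_unit_catches(self, trichrom, illuminant):
        cc = cone_catch_from_spectrum(Spectrum.flat(1.0), illuminant,
                                      trichrom)
        np.testing.assert_allclose(cc.q, 1.0, atol=1e-12)

    def test_grey_reflector_gives_flat_catches(self, trichrom, illuminant):
        cc = cone_catch_from_spectrum(Spectrum.flat(0.4), illuminant,
                                      trichrom)
        np.testing.assert_allclose(cc.q, 0.4, atol=1e-12)

    def test_matches_trapezoid_quadrature_oracle(self, rng, trichrom,
                                                 illuminant):
        grid = np.arange(300.0, 701.0)
        for _ in range(5):
            refl = Spectrum(grid, rng.uniform(0.05, 0.9, grid.size))
            cc = cone_catch_from_spectrum(refl, illuminant, trichrom)
            for i, name in enumerate(trichrom.names):
                s = trichrom.sensitivities[name].value
                num = np.trapezoid(refl.value * 1.0 * s, grid)
                den = np.trapezoid(1.0 * s, grid)
                assert cc.q[i] == pytest.approx(num / den, abs=1e-9)

    def test_linear_in_reflectance_before_von_kries(self, rng, trichrom,
                                                    illuminant):
        grid = np.arange(300.0, 701.0)
        r1 = rng.uniform(0.0, 0.5, grid.size)
        r2 = rng.uniform(0.0, 0.5, grid.size)
        a, b = 0.3, 0.6
        combo = cone_catch_from_spectrum(
            Spectrum(grid, a * r1 + b * r2), illuminant, trichrom)
        c1 = cone_catch_from_spectrum(Spectrum(grid, r1), illuminant,
                                      trichrom)
        c2 = cone_catch_from_spectrum(Spectrum(grid, r2), illuminant,
                                      trichrom)
        # von Kries divides by a reflectance-independent constant, so
        # linearity survives normalization
        np.testing.assert_allclose(combo.q, a * c1.q + b * c2.q, atol=1e-9)

    def test_no_overlap_is_degenerate(self):
        rs = ReceptorSet(
            names=("A", "B"),
            sensitivities={"A": gaussian_receptor(350, 10, 300, 420),
                           "B": gaussian_receptor(400, 10, 300, 420)},
            abundances={"A": 1.0, "B": 1.0}, weber_reference=("A", 0.05))
        refl = Spectrum.flat(0.5, 500, 700)
        with pytest.raises(ValueError, match="overlap"):
            cone_catch_from_spectrum(refl, flat_illuminant(500, 700), rs)


class TestChromaticJND:
    def test_identical_stimuli_zero(self, weber3):
        a = ConeCatch(np.array([0.2, 0.3, 0.4]), ("SWS", "MWS", "LWS"))
        assert chromatic_jnd(a, a, weber3) == 0.0

    def test_matches_hand_coded_trichromat_formula(self, rng, weber3):
        names = ("SWS", "MWS", "LWS")
        e1, e2, e3 = weber3.e
        for _ in range(20):
            qa = rng.uniform(0.05, 1.0, 3)
            qb = rng.uniform(0.05, 1.0, 3)
            f = np.log(qa) - np.log(qb)
            num = (e1 ** 2 * (f[2] - f[1]) ** 2
                   + e2 ** 2 * (f[2] - f[0]) ** 2
                   + e3 ** 2 * (f[1] - f[0]) ** 2)
            den = ((e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2)
            expect = np.sqrt(num / den)
            got = chromatic_jnd(ConeCatch(qa, names), ConeCatch(qb, names),
                                weber3)
            assert got == pytest.approx(expect, abs=1e-12)

    def test_matches_hand_coded_tetrachromat_formula(self, rng, tetra_uvs):
        w = tetra_uvs.weber_fractions()
        names = tetra_uvs.chromatic_names
        e = w.e
        qa = rng.uniform(0.05, 1.0, 4)
        qb = rng.uniform(0.05, 1.0, 4)
        f = np.log(qa) - np.log(qb)
        num = 0.0
        import itertools
        for (i, j) in itertools.combinations(range(4), 2):
            k, l = [m for m in range(4) if m not in (i, j)]
            num += (e[i] * e[j]) ** 2 * (f[k] - f[l]) ** 2
        den = sum((e[i] * e[j] * e[k]) ** 2
                  for i, j, k in itertools.combinations(range(4), 3))
        got = chromatic_jnd(ConeCatch(qa, names), ConeCatch(qb, names), w)
        assert got == pytest.approx(np.sqrt(num / den), abs=1e-12)

    def test_intensity_invariance(self, rng, weber3):
        names = ("SWS", "MWS", "LWS")
        qa = rng.uniform(0.05, 1.0, 3)
        for c in (0.1, 1.0, 7.3):
            assert chromatic_jnd(ConeCatch(qa, names),
                                 ConeCatch(c * qa, names),
                                 weber3) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng, weber3):
        names = ("SWS", "MWS", "LWS")
        for _ in range(20):
            a = ConeCatch(rng.uniform(0.05, 1.0, 3), names)
            b = ConeCatch(rng.uniform(0.05, 1.0, 3), names)
            assert chromatic_jnd(a, b, weber3) == pytest.approx(
                chromatic_jnd(b, a, weber3), abs=1e-12)

    def test_receptor_mismatch_rejected(self, weber3):
        a = ConeCatch(np.array([0.2, 0.3, 0.4]), ("SWS", "MWS", "LWS"))
        b = ConeCatch(np.array([0.2, 0.3, 0.4]), ("X", "Y", "Z"))
        with pytest.raises(ValueError, match="mismatch"):
            chromatic_jnd(a, b, weber3)

    def test_pairwise_matrix_matches_scalar_loop(self, rng, weber3):
        names = ("SWS", "MWS", "LWS")
        q = rng.uniform(0.05, 1.0, (15, 3))
        mat = pairwise_chromatic_jnd(np.log(q), weber3)
        for i in range(15):
            for j in range(15):
                expect = chromatic_jnd(ConeCatch(q[i], names),
                                       ConeCatch(q[j], names), weber3)
                # the Gram-identity path loses ~sqrt(eps) precision near 0
                assert mat[i, j] == pytest.approx(expect, abs=1e-6)


class TestLuminanceJND:
    def test_equal_catches_zero(self):
        assert luminance_jnd(0.3, 0.3) == 0.0

    def test_log_ratio_closed_form(self):
        assert luminance_jnd(1.0, np.exp(0.05), 0.05) == pytest.approx(
            1.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(100):
            qa, qb = rng.uniform(0.01, 1.0, 2)
            assert luminance_jnd(qa, qb) == pytest.approx(
                luminance_jnd(qb, qa), abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            luminance_jnd(0.0, 0.4)


class TestWeberScaling:
    def test_equal_abundances_equal_webers(self):
        w = weber_from_abundances({"A": 2.0, "B": 2.0, "C": 2.0},
                                  ("A", 0.05))
        np.testing.assert_allclose(w.e, 0.05)

    def test_sqrt_abundance_scaling(self):
        w = weber_from_abundances({"A": 1.0, "B": 4.0}, ("B", 0.05))
        np.testing.assert_allclose(w.e, [0.10, 0.05], atol=1e-15)

    def test_formula_on_random_abundances(self, rng):
        ab = {f"r{i}": float(rng.uniform(0.1, 3.0)) for i in range(4)}
        ref = ("r2", 0.06)
        w = weber_from_abundances(ab, ref)
        for i, name in enumerate(ab):
            expect = 0.06 * np.sqrt(ab["r2"] / ab[name])
            assert w.e[i] == pytest.approx(expect, abs=1e-12)

    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError):
            weber_from_abundances({"A": 0.0, "B": 1.0}, ("B", 0.05))


class TestCameraMapping:
    def test_exact_degree2_model_recovered(self, rng):
        X = rng.uniform(0.05, 1.0, (100, 3))
        D = np.column_stack([np.ones(100), X[:, 0], X[:, 1], X[:, 2],
                             X[:, 0] * X[:, 1], X[:, 0] ** 2])
        coef = rng.uniform(-0.5, 0.5, (6, 3))
        Y = D @ coef + 0.5
        m = fit_camera_to_cone(X, Y, degree=2)
        pred = apply_camera_to_cone(m, X)
        np.testing.assert_allclose(pred, np.maximum(Y, 1e-6), atol=1e-8)
        np.testing.assert_allclose(m.fit_r2, 1.0, atol=1e-8)

    def test_matched_sensitivities_give_identity_map(self, rng, trichrom,
                                                     illuminant):
        # camera channels == cone classes: the degree-1 map is the identity
        grid = np.arange(300.0, 701.0)
        spectra = [Spectrum(grid, np.clip(
            sum(a * np.exp(-0.5 * ((grid - c) / sd) ** 2)
                for a, c, sd in zip(rng.uniform(0.2, 0.8, 3),
                                    rng.uniform(350, 650, 3),
                                    rng.uniform(30, 120, 3))), 0.001, 1.4))
            for _ in range(60)]
        catches = np.array([cone_catch_from_spectrum(
            s, illuminant, trichrom, include_double_cone=False).q
            for s in spectra])
        m = fit_camera_to_cone(catches, catches, degree=1)
        coef = m.coefficients
        np.testing.assert_allclose(coef[0], 0.0, atol=1e-6)
        np.testing.assert_allclose(coef[1:], np.eye(3), atol=1e-6)

    def test_heldout_r2_on_natural_spectra(self, rng, trichrom, illuminant):
        grid = np.arange(300.0, 701.0)
        camera = ReceptorSet(
            names=("cR", "cG", "cB"),
            sensitivities={"cR": gaussian_receptor(600, 50),
                           "cG": gaussian_receptor(530, 50),
                           "cB": gaussian_receptor(460, 50)},
            abundances={"cR": 1, "cG": 1, "cB": 1},
            weber_reference=("cR", 0.05))

        def batch(n):
            cams, cones = [], []
            for _ in range(n):
                n_g = rng.integers(1, 4)
                v = np.zeros(grid.size)
                for _ in range(n_g):
                    v += (rng.uniform(0.1, 0.6)
                          * np.exp(-0.5 * ((grid - rng.uniform(320, 680))
                                           / rng.uniform(40, 150)) ** 2))
                s = Spectrum(grid, np.clip(v + 0.02, 0.001, 1.4))
                cams.append(cone_catch_from_spectrum(
                    s, illuminant, camera, include_double_cone=False).q)
                cones.append(cone_catch_from_spectrum(
                    s, illuminant, trichrom, include_double_cone=False).q)
            return np.array(cams), np.array(cones)

        Xtr, Ytr = batch(200)
        Xte, Yte = batch(60)
        m = fit_camera_to_cone(Xtr, Ytr, degree=2)
        pred = apply_camera_to_cone(m, Xte)
        for j in range(3):
            ss_res = np.sum((Yte[:, j] - pred[:, j]) ** 2)
            ss_tot = np.sum((Yte[:, j] - Yte[:, j].mean()) ** 2)
            assert 1 - ss_res / ss_tot >= 0.95

    def test_batch_equals_per_pixel_loop(self, rng):
        X = rng.uniform(0.05, 1.0, (90, 3))
        Y = rng.uniform(0.05, 1.0, (90, 3))
        m = fit_camera_to_cone(X, Y, degree=2)
        px = rng.uniform(0.05, 1.0, (25, 3))
        batch = apply_camera_to_cone(m, px)
        loop = np.vstack([apply_camera_to_cone(m, px[i:i + 1])
                          for i in range(25)])
        np.testing.assert_allclose(batch, loop, rtol=1e-12)

    def test_too_few_training_spectra_rejected(self, rng):
        X = rng.uniform(0.1, 1.0, (10, 3))
        with pytest.raises(ValueError, match="training spectra"):
            fit_camera_to_cone(X, X, degree=2)

    def test_channel_mismatch_rejected(self, rng):
        X = rng.uniform(0.1, 1.0, (40, 3))
        m = fit_camera_to_cone(X, X, degree=1)
        with pytest.raises(ValueError, match="channels"):
            apply_camera_to_cone(m, rng.uniform(0.1, 1.0, (5, 2)))


class TestDichromatReduction:
    def test_general_formula_reduces_to_closed_form(self, rng):
        w = WeberFractions(np.array([0.05, 0.08]), ("A", "B"))
        for _ in range(30):
            qa = rng.uniform(0.05, 1.0, 2)
            qb = rng.uniform(0.05, 1.0, 2)
            f = np.log(qa) - np.log(qb)
            expect = abs(f[0] - f[1]) / np.sqrt(0.05 ** 2 + 0.08 ** 2)
            got = chromatic_jnd(ConeCatch(qa, ("A", "B")),
                                ConeCatch(qb, ("A", "B")), w)
            assert got == pytest.approx(expect, abs=1e-12)


def test_builtin_sets_are_well_formed():
    for name in ("trichrom_skins", "tetra_uvs", "tetra_vs"):
        rs = builtin_receptor_set(name)
        w = rs.weber_fractions()
        assert np.all((w.e > 0) & (w.e < 1))
        assert rs.double_cone == "DBL"
    with pytest.raises(ValueError):
        builtin_receptor_set("nope")
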