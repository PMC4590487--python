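"""Abundant colour, luminance histograms, granularity spectra and tables."""

import numpy as np
import pytest

from mimicspec.plumage import (ConeCatchPatch, LuminanceHistogram,
                               PatternSpectrum, SpecimenSet, abundant_colour,
                               build_comparison_table, l_diff,
                               luminance_histogram, pattern_energy,
                               region_luminance_jnd, s_diff)
from mimicspec.vision import ConeCatch, chromatic_jnd

NAMES = ("SWS", "MWS", "LWS")


def _patch(catches, lum=None, region="back"):
    catches = np.atleast_2d(catches)
    if lum is None:
        lum = np.full(catches.shape[0], 0.4)
    return ConeCatchPatch(region=region, catches=catches, luminance=lum,
                          receptor_names=NAMES)


class TestAbundantColour:
    def test_uniform_patch_returns_that_colour(self, weber3):
        q = np.tile([0.2, 0.4, 0.6], (30, 1))
        got = abundant_colour(_patch(q), weber3)
        np.testing.assert_allclose(got.q, [0.2, 0.4, 0.6])

    def test_majority_cluster_wins(self, rng, weber3):
        # 60 pixels in a tight chromatic cluster, 40 far away
        base = np.array([0.3, 0.4, 0.5])
        far = base * np.exp(np.array([0.5, 0.0, -0.5]))  # ~10 JND off
        cluster = base * np.exp(rng.normal(0, 0.005, (60, 3)))
        outliers = far * np.exp(rng.normal(0, 0.005, (40, 3)))
        q = np.vstack([cluster, outliers])
        got = abundant_colour(_patch(q), weber3)
        d = chromatic_jnd(got, ConeCatch(base, NAMES), weber3)
        assert d < 2.0  # winner belongs to the big cluster

    def test_matches_double_loop_oracle(self, rng, weber3):
        q = np.exp(rng.normal(np.log(0.3), 0.06, (50, 3)))
        got = abundant_colour(_patch(q), weber3)
        # independent O(n^2) count with per-pair scalar JND calls
        counts = np.zeros(50, dtype=int)
        for i in range(50):
            for j in range(50):
                if i == j:
                    continue
                d = chromatic_jnd(ConeCatch(q[i], NAMES),
                                  ConeCatch(q[j], NAMES), weber3)
                if d < 2.0:
                    counts[i] += 1
        best = int(np.argmax(counts))
        np.testing.assert_allclose(got.q, q[best])

    def test_empty_patch_rejected(self, weber3):
        with pytest.raises(ValueError):
            abundant_colour(_patch(np.empty((0, 3))), weber3)


class TestLuminanceHistogram:
    def test_constant_patch_fills_one_bin(self):
        h = luminance_histogram(_patch(np.tile([0.3, 0.3, 0.3], (10, 1)),
                                       lum=np.full(10, 0.5)))
        assert h.proportions.max() == 1.0
        assert (h.proportions > 0).sum() == 1

    def test_extremes_fall_in_first_and_last_bins(self):
        lum = np.array([0.01, 0.99, 0.01, 0.99])
        h = luminance_histogram(_patch(np.tile([0.3] * 3, (4, 1)), lum=lum))
        assert h.proportions[0] == 0.5
        assert h.proportions[-1] == 0.5

    def test_matches_binning_oracle(self, rng):
        lum = rng.uniform(0, 1, 300)
        h = luminance_histogram(_patch(np.tile([0.3] * 3, (300, 1)),
                                       lum=lum))
        oracle = np.zeros(32)
        for v in lum:
            b = min(int(v * 32), 31)
            oracle[b] += 1
        np.testing.assert_allclose(h.proportions, oracle / 300, atol=1e-12)

    def test_values_above_one_are_clipped(self):
        lum = np.array([1.2, 1.5, 0.5])
        h = luminance_histogram(_patch(np.tile([0.3] * 3, (3, 1)), lum=lum))
        assert h.proportions[-1] == pytest.approx(2 / 3)


class TestLDiff:
    def _hist(self, p):
        return LuminanceHistogram(np.asarray(p, dtype=float))

    def test_identical_histograms_zero(self, rng):
        p = rng.dirichlet(np.ones(32))
        assert l_diff(self._hist(p), self._hist(p)) == 0.0

    def test_disjoint_histograms_hit_total_variation_bound(self):
        a = np.zeros(32)
        a[:16] = 1 / 16
        b = np.zeros(32)
        b[16:] = 1 / 16
        assert l_diff(self._hist(a), self._hist(b)) == pytest.approx(
            2.0, abs=1e-12)

    def test_matches_hand_summed_differences(self, rng):
        a = rng.dirichlet(np.ones(32))
        b = rng.dirichlet(np.ones(32))
        expect = sum(abs(x - y) for x, y in zip(a, b))
        assert l_diff(self._hist(a), self._hist(b)) == pytest.approx(
            expect, abs=1e-12)

    def test_pseudometric_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = (self._hist(rng.dirichlet(np.ones(32)))
                       for _ in range(3))
            assert l_diff(a, c) <= l_diff(a, b) + l_diff(b, c) + 1e-12


class TestPatternEnergy:
    def test_constant_image_has_zero_energy(self):
        ps = pattern_energy(np.full((32, 32), 0.7))
        np.testing.assert_allclose(ps.energy, 0.0, atol=1e-12)
        assert ps.scales.size == 33

    def test_sinusoid_peak_localized_to_its_wavelength_band(self):
        x = np.arange(64)
        img = 0.5 + 0.2 * np.sin(2 * np.pi * x[None, :] / 16.0)
        img = np.tile(img, (64, 1))
        ps = pattern_energy(img)
        k = int(np.argmax(ps.energy))
        # the winning scale's half-octave band must contain the 16-px
        # wavelength
        assert ps.scales[k] / np.sqrt(2) <= 16.0 <= ps.scales[k] * np.sqrt(2)

    def test_white_noise_has_energy_at_every_scale(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        ps = pattern_energy(img)
        assert np.all(ps.energy > 0)

    def test_dc_invariance(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        a = pattern_energy(img)
        b = pattern_energy(img + 5.0)
        np.testing.assert_allclose(a.energy, b.energy, atol=1e-10)

    def test_contrast_linearity(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        base = pattern_energy(img)
        for k in (-2.0, 0.5, 3.0):
            scaled = pattern_energy(k * img)
            np.testing.assert_allclose(scaled.energy, abs(k) * base.energy,
                                       rtol=1e-9, atol=1e-12)

    def test_masked_analysis_uses_in_mask_pixels(self, rng):
        img = rng.uniform(0, 1, (40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        ps = pattern_energy(img, mask=mask)
        assert ps.scales[-1] == pytest.approx(30.0)

    def test_too_small_image_rejected_with_feasible_range(self):
        with pytest.raises(ValueError, match="8"):
            pattern_energy(np.ones((5, 40)))

    def test_half_octave_bands_cover_every_frequency(self):
        # every non-DC lattice frequency of a 32x32 DFT falls inside at
        # least one scale's [s/sqrt2, s*sqrt2) annulus
        h = w = 32
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        rho = np.hypot(fy, fx)
        ps = pattern_energy(np.random.default_rng(0).uniform(0, 1, (h, w)))
        with np.errstate(divide="ignore"):
            lam = np.where(rho > 0, 1.0 / rho, np.inf)
        in_band = sum(((lam >= s / np.sqrt(2)) & (lam < s * np.sqrt(2))
                       & (rho > 0)).astype(int) for s in ps.scales)
        assert (in_band[rho > 0] >= 1).all()


class TestSDiff:
    def _spec(self, e):
        return PatternSpectrum(np.arange(2.0, 35.0), np.asarray(e))

    def test_identical_spectra_zero(self, rng):
        e = rng.uniform(0, 1, 33)
        assert s_diff(self._spec(e), self._spec(e)) == 0.0

    def test_single_scale_perturbation_is_additive(self, rng):
        e = rng.uniform(0, 1, 33)
        e2 = e.copy()
        e2[7] += 0.37
        assert s_diff(self._spec(e), self._spec(e2)) == pytest.approx(
            0.37, abs=1e-12)

    def test_matches_independent_summation(self, rng):
        a = rng.uniform(0, 1, 33)
        b = rng.uniform(0, 1, 33)
        expect = sum(abs(x - y) for x, y in zip(a, b))
        assert s_diff(self._spec(a), self._spec(b)) == pytest.approx(
            expect, abs=1e-12)

    def test_scale_grid_mismatch_rejected(self, rng):
        a = PatternSpectrum(np.arange(2.0, 35.0), rng.uniform(0, 1, 33))
        b = PatternSpectrum(np.arange(3.0, 36.0), rng.uniform(0, 1, 33))
        with pytest.raises(ValueError, match="scale"):
            s_diff(a, b)

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = (self._spec(rng.uniform(0, 1, 33)) for _ in range(3))
            assert s_diff(a, c) <= s_diff(a, b) + s_diff(b, c) + 1e-12


class TestRegionLuminance:
    def test_identical_patches_zero(self):
        p = _patch(np.tile([0.3] * 3, (5, 1)), lum=np.full(5, 0.4))
        assert region_luminance_jnd(p, p) == 0.0

    def test_mean_ratio_closed_form(self):
        a = _patch(np.tile([0.3] * 3, (5, 1)), lum=np.full(5, 0.4))
        b = _patch(np.tile([0.3] * 3, (5, 1)),
                   lum=np.full(5, 0.4 * np.exp(0.1)))
        assert region_luminance_jnd(a, b, 0.05) == pytest.approx(
            2.0, abs=1e-10)

    def test_matches_mean_then_formula(self, rng):
        la, lb = rng.uniform(0.1, 0.9, 40), rng.uniform(0.1, 0.9, 40)
        a = _patch(np.tile([0.3] * 3, (40, 1)), lum=la)
        b = _patch(np.tile([0.3] * 3, (40, 1)), lum=lb)
        expect = abs(np.log(la.mean() / lb.mean())) / 0.05
        assert region_luminance_jnd(a, b, 0.05) == pytest.approx(
            expect, abs=1e-12)


class TestComparisonTable:
    def _set(self, rng, name, group, n_spec=2, regions=("back", "wing")):
        patches = {}
        for i in range(n_spec):
            sid = f"{name}_{i}"
            patches[sid] = {}
            for r in regions:
                grid = 0.4 + rng.normal(0, 0.02, (12, 12))
                q = np.exp(rng.normal(np.log(0.3), 0.05, (144, 3)))
                patches[sid][r] = ConeCatchPatch(
                    region=r, catches=q, luminance=grid.ravel(),
                    receptor_names=NAMES, luminance_grid=grid)
        return SpecimenSet(name, group, patches)

    def test_cardinality(self, rng, weber3):
        focal = self._set(rng, "mimic", "focal_mimic")
        other = self._set(rng, "model", "Euplectes")
        res = build_comparison_table(focal, [other], weber3)
        assert len(res.records) == 2 * 2 * 2  # 2 focal x 2 other x 2 regions

    def test_self_comparison_diagonal_is_zero(self, rng, weber3):
        focal = self._set(rng, "mimic", "focal_mimic")
        res = build_comparison_table(focal, [focal], weber3)
        diag = res.records[res.records.focal_id == res.records.other_id]
        for col in ("colour_jnd", "luminance_jnd", "l_diff", "s_diff"):
            np.testing.assert_allclose(diag[col], 0.0, atol=1e-9)

    def test_missing_region_excluded_with_warning(self, rng, weber3):
        focal = self._set(rng, "mimic", "focal_mimic")
        other = self._set(rng, "model", "Euplectes")
        del other.patches["model_0"]["wing"]
        res = build_comparison_table(focal, [other], weber3)
        assert len(res.excluded) == 2  # both focal specimens hit the gap
        assert len(res.records) == 8 - 2

    def test_log_transform_column_present(self, rng, weber3):
        focal = self._set(rng, "mimic", "focal_mimic")
        other = self._set(rng, "model", "Euplectes")
        res = build_comparison_table(focal, [other], weber3)
        np.testing.assert_allclose(
            res.records["log_s_diff"],
            np.log(res.records["s_diff"] + 1e-8), atol=1e-12)
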