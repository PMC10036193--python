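"""Bilateral filter, Otsu threshold, edge indicator, gray band, evolution."""
import numpy as np
import pytest
from scipy import ndimage

from vertemtl import levelset as ls
from vertemtl.segnet import dice_coefficient


def brute_force_bilateral(img, sigma_s, sigma_r, radius):
    h, w = img.shape
    padded = np.pad(img, radius, mode="edge")
    out = np.zeros_like(img, dtype=np.float64)
    for y in range(h):
        for x in range(w):
            num = den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    v = padded[y + dy + radius, x + dx + radius]
                    wgt = (np.exp(-(dy * dy + dx * dx) / (2 * sigma_s ** 2))
                           * np.exp(-((img[y, x] - v) ** 2) / (2 * sigma_r ** 2)))
                    num += wgt * v
                    den += wgt
            out[y, x] = num / den
    return out


class TestBilateral:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 0.37)
        assert np.allclose(ls.bilateral_filter(img, 2.0, 0.1), img)

    def test_matches_brute_force(self, rng):
        img = rng.random((16, 16))
        mine = ls.bilateral_filter(img, 1.5, 0.2, radius=3)
        ref = brute_force_bilateral(img, 1.5, 0.2, radius=3)
        assert np.allclose(mine, ref, atol=1e-9)

    def test_large_sigma_r_is_gaussian_blur(self, rng):
        img = rng.random((20, 20))
        radius = 4
        mine = ls.bilateral_filter(img, 1.5, 1e6, radius=radius)
        # plain (truncated, normalized) Gaussian convolution oracle
        ax = np.arange(-radius, radius + 1)
        k1 = np.exp(-(ax ** 2) / (2 * 1.5 ** 2))
        k2 = np.outer(k1, k1)
        k2 /= k2.sum()
        padded = np.pad(img, radius, mode="edge")
        ref = np.zeros_like(img)
        for y in range(20):
            for x in range(20):
                ref[y, x] = (padded[y:y + 2 * radius + 1, x:x + 2 * radius + 1] * k2).sum()
        assert np.allclose(mine, ref, atol=1e-6)

    def test_bad_sigmas(self):
        with pytest.raises(ValueError):
            ls.bilateral_filter(np.zeros((4, 4)), -1.0, 0.1)


def exhaustive_otsu(img):
    """Oracle: scan every distinct value as the low-class upper bound."""
    vals = np.unique(img)
    best_t, best_v = None, -1.0
    flat = img.ravel().astype(np.float64)
    for t in vals[:-1]:
        lo = flat[flat <= t]
        hi = flat[flat > t]
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t, best_v


class TestOtsu:
    def test_two_delta_peaks(self):
        img = np.concatenate([np.full(50, 50.0), np.full(50, 200.0)])
        t = ls.adaptive_threshold(img.reshape(10, 10))
        assert 50.0 <= t < 200.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(32, 32)).astype(np.float64)
            t_mine, v_mine = ls.otsu_threshold(img)
            t_ref, v_ref = exhaustive_otsu(img)
            assert v_mine == pytest.approx(v_ref, rel=1e-9)
            assert t_mine == pytest.approx(t_ref)

    def test_label_swap_invariance(self, rng):
        img = rng.integers(0, 256, size=(16, 16)).astype(np.float64)
        t1, _ = ls.otsu_threshold(img)
        t2, _ = ls.otsu_threshold(255.0 - img)
        # swapping populations mirrors the threshold
        assert t1 == pytest.approx(255.0 - t2, abs=1.0 + 1e-9)

    def test_constant_image_degenerate(self):
        with pytest.raises(ValueError):
            ls.adaptive_threshold(np.full((8, 8), 3.0))


class TestEdgeIndicator:
    def test_constant_image_gives_one(self):
        g = ls.edge_indicator(np.full((16, 16), 0.5))
        assert np.allclose(g, 1.0)

    def test_lower_on_boundary_than_interior(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (xx - 32) ** 2 + (yy - 32) ** 2 <= 15 ** 2
        img = np.where(disc, 0.6, 0.2)
        g = ls.edge_indicator(img)
        r = np.hypot(xx - 32, yy - 32)
        band = np.abs(r - 15) <= 2
        interior = r <= 8
        assert g[band].mean() < g[interior].mean()

    def test_values_in_unit_interval(self, rng):
        g = ls.edge_indicator(rng.random((24, 24)))
        assert g.min() > 0.0 and g.max() <= 1.0


class TestGrayConstraint:
    def _state(self, phi):
        return ls.LevelSetState(phi=phi, i_low=0.3, i_high=0.7)

    def test_in_range_inside_contour_is_minus_gamma(self):
        img = np.full((4, 4), 0.5)
        state = self._state(np.full((4, 4), 1e9))  # H(phi) = 1
        q = ls.gray_constraint(img, state, gamma_q=2.0)
        assert np.allclose(q, -2.0)

    def test_out_of_range_is_plus_gamma_regardless_of_phi(self):
        img = np.full((4, 4), 0.9)
        for phi in (np.full((4, 4), 1e9), np.full((4, 4), -1e9)):
            q = ls.gray_constraint(img, self._state(phi), gamma_q=2.0)
            assert np.allclose(q, 2.0)

    def test_gamma_zero_disables(self, rng):
        img = rng.random((6, 6))
        q = ls.gray_constraint(img, self._state(rng.normal(size=(6, 6))), 0.0)
        assert np.allclose(q, 0.0)


def _disc(size=96, r=22, cx=48, cy=48, fg=0.55, bg=0.22):
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return np.where(mask, fg, bg).astype(np.float64), mask


class TestEvolve:
    def test_zero_iterations_returns_prior(self, rng):
        img, mask = _disc()
        prior = ndimage.binary_dilation(mask, iterations=2)
        refined, trace = ls.evolve(img, prior, ls.LevelSetParams(n_iter=0))
        assert np.array_equal(refined, prior)
        assert len(trace) == 0

    def test_region_means_converge_to_two_levels(self):
        img, mask = _disc()
        prior = ndimage.binary_dilation(mask, iterations=3)
        _, trace = ls.evolve(img, prior, ls.LevelSetParams(n_iter=120))
        c1, c2 = trace.iloc[-1]["c1"], trace.iloc[-1]["c2"]
        assert abs(c1 - 0.55) < 1.0 / 255.0
        assert abs(c2 - 0.22) < 1.0 / 255.0

    def test_recovers_eroded_prior(self):
        img, mask = _disc()
        prior = ndimage.binary_erosion(mask, iterations=3)
        refined, trace = ls.evolve(img, prior, ls.LevelSetParams(n_iter=150))
        assert dice_coefficient(refined, mask) > dice_coefficient(prior, mask)
        e = trace["energy"].to_numpy()
        assert np.all(np.diff(e) <= 1e-3 * np.abs(e[:-1]))

    def test_translation_equivariance(self):
        img, mask = _disc(cx=44, cy=42)
        prior = ndimage.binary_dilation(mask, iterations=2)
        params = ls.LevelSetParams(n_iter=60)
        ref, _ = ls.evolve(img, prior, params)
        img_s = np.roll(img, (5, 7), axis=(0, 1))
        prior_s = np.roll(prior, (5, 7), axis=(0, 1))
        out_s, _ = ls.evolve(img_s, prior_s, params)
        back = np.roll(out_s, (-5, -7), axis=(0, 1))
        b = 20  # exclude the border where padding breaks the symmetry
        assert np.array_equal(back[b:-b, b:-b], ref[b:-b, b:-b])

    def test_empty_prior_raises(self):
        img, _ = _disc()
        with pytest.raises(ValueError):
            ls.evolve(img, np.zeros_like(img, dtype=bool))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ls.LevelSetParams(dt=0.0).validate()
        with pytest.raises(ValueError):
            ls.LevelSetParams(mu=-1.0).validate()
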