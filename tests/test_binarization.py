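"""Adaptive/mean/prebinarized thresholding and density."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from ttquant import (ThresholdSettings, ValidationError, accept_prebinarized,
                     adaptive_binarize, compute_density, mean_binarize)
from ttquant.phantom import PhantomSpec, generate_phantom

VOX = (1.0, 1.0, 1.0)  # 1 µm pixels: window_um == window in px


def _settings(**kw):
    base = dict(window_um=5.0, sensitivity=1.0, min_object=0, noise_floor_k=0.0)
    base.update(kw)
    return ThresholdSettings(**base)


def _brute_force_masked_stats(img, dom, window):
    """Independent oracle: loop over pixels, window statistics over domain pixels."""
    h = window // 2
    mu = np.full(img.shape, np.nan)
    sd = np.full(img.shape, np.nan)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            ys, ye = max(0, y - h), min(img.shape[0], y + h + 1)
            xs, xe = max(0, x - h), min(img.shape[1], x + h + 1)
            # constant-padded window as in the implementation's uniform filter
            w_img = np.zeros((window, window))
            w_dom = np.zeros((window, window), dtype=bool)
            w_img[ys - y + h : ye - y + h, xs - x + h : xe - x + h] = img[ys:ye, xs:xe]
            w_dom[ys - y + h : ye - y + h, xs - x + h : xe - x + h] = dom[ys:ye, xs:xe]
            vals = w_img[w_dom]
            if vals.size:
                mu[y, x] = vals.mean()
                sd[y, x] = vals.std()
    return mu, sd


class TestAdaptive:
    def test_constant_cytosol_empty(self):
        img = np.full((20, 20), 50.0)
        dom = np.ones((20, 20), dtype=bool)
        sm = adaptive_binarize(img, dom, _settings(), VOX)
        assert sm.mask.sum() == 0
        assert any("zero-variance" in f for f in sm.flags)

    def test_bright_line_matches_brute_force_rule(self):
        img = np.full((21, 21), 10.0)
        img[:, 10] = 200.0  # one bright 1-px vertical line
        dom = np.ones_like(img, dtype=bool)
        sm = adaptive_binarize(img, dom, _settings(), VOX)
        mu, sd = _brute_force_masked_stats(img, dom, 5)
        expected = dom & (img > mu + 1.0 * sd)
        assert np.array_equal(sm.mask[0], expected)
        # the line itself is detected, nothing else
        assert np.array_equal(np.unique(np.nonzero(sm.mask[0])[1]), [10])

    def test_affine_intensity_invariance_exact(self, default_phantom):
        ph = default_phantom
        dom = ph.interior_mask
        s = ThresholdSettings()
        a = adaptive_binarize(ph.image, dom, s, ph.spec.voxel_size)
        b = adaptive_binarize(0.5 * ph.image + 17.0, dom, s, ph.spec.voxel_size)
        assert np.array_equal(a.mask, b.mask)

    def test_monotone_in_sensitivity(self, default_phantom):
        ph = default_phantom
        dom = ph.interior_mask
        masks = [
            adaptive_binarize(
                ph.image, dom,
                ThresholdSettings(sensitivity=s, min_object=0),
                ph.spec.voxel_size,
            ).mask
            for s in (0.5, 1.0, 2.0)
        ]
        assert np.all(masks[1] <= masks[0])
        assert np.all(masks[2] <= masks[1])

    def test_window_larger_than_cytosol(self):
        img = np.random.default_rng(0).uniform(0, 10, (30, 30))
        dom = np.zeros((30, 30), dtype=bool)
        dom[12:18, 12:18] = True
        with pytest.raises(ValidationError, match="window"):
            adaptive_binarize(img, dom, _settings(window_um=21), VOX)

    def test_mask_restricted_to_domain(self, default_phantom):
        ph = default_phantom
        sm = adaptive_binarize(ph.image, ph.interior_mask, ThresholdSettings(),
                               ph.spec.voxel_size)
        assert not np.any(sm.mask & ~sm.domain)

    def test_abundance_unbiased_over_dropout_sweep(self):
        """Same noise seed, dropout-only sweep: detection error has no trend."""
        drops = [(0, 0), (0.2, 0.2), (0.4, 0.4), (0.6, 0.6), (0.8, 0.8),
                 (1, 1), (0, 1), (1, 0), (0.5, 1), (1, 0.5)]
        errs, truths = [], []
        for pt, pl in drops:
            ph = generate_phantom(PhantomSpec(seed=42, p_drop_t=pt, p_drop_l=pl))
            sm = adaptive_binarize(ph.image, ph.interior_mask, ThresholdSettings(),
                                   ph.spec.voxel_size)
            truths.append(ph.truth["density_total"])
            errs.append(compute_density(sm) - ph.truth["density_total"])
        assert max(abs(e) for e in errs) < 0.01
        if len(set(errs)) > 1:  # constant error = perfectly trend-free
            assert abs(spearmanr(truths, errs).statistic) < 0.3


class TestMean:
    def test_constant_image_empty(self):
        img = np.full((10, 10), 7.0)
        dom = np.ones_like(img, dtype=bool)
        sm = mean_binarize(img, dom, _settings(mode="mean", k_mean=1.0))
        assert sm.mask.sum() == 0

    def test_half_bright_half_dark(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        dom = np.ones_like(img, dtype=bool)
        sm = mean_binarize(img, dom, _settings(mode="mean", k_mean=1.0))
        assert np.array_equal(sm.mask[0], img > 50)

    def test_hand_computed_grid(self):
        # 8x8 with values 0..63: mean = 31.5; k=1.2 -> threshold 37.8 -> 38..63
        img = np.arange(64, dtype=float).reshape(8, 8)
        dom = np.ones_like(img, dtype=bool)
        sm = mean_binarize(img, dom, _settings(mode="mean", k_mean=1.2))
        assert sm.mask.sum() == 64 - 38
        assert np.array_equal(sm.mask[0], img >= 38)

    def test_nonpositive_k_rejected(self):
        img = np.ones((4, 4))
        with pytest.raises(ValidationError):
            mean_binarize(img, np.ones_like(img, dtype=bool),
                          _settings(mode="mean", k_mean=0.0))


class TestPrebinarized:
    @pytest.mark.parametrize("hi", [255, 1])
    def test_two_valued_image(self, hi):
        img = np.zeros((10, 10))
        img[3:6, 3:6] = hi
        dom = np.zeros_like(img, dtype=bool)
        dom[:5] = True
        sm = accept_prebinarized(img, dom)
        assert np.array_equal(sm.mask[0], (img == hi) & dom)

    def test_three_valued_rejected(self):
        img = np.zeros((6, 6))
        img[0, 0], img[1, 1] = 100, 200
        with pytest.raises(ValidationError, match="not binary"):
            accept_prebinarized(img, np.ones_like(img, dtype=bool))


class TestDensity:
    def test_empty_and_full(self):
        dom = np.ones((5, 5), dtype=bool)
        sm = accept_prebinarized(np.zeros((5, 5)), dom)
        assert compute_density(sm) == 0.0
        sm = accept_prebinarized(np.ones((5, 5)), dom)
        assert compute_density(sm) == 1.0

    def test_truth_mask_reproduces_phantom_density(self, noiseless_phantom):
        """Pixel-counting definition: structure pixels / cell area."""
        ph = noiseless_phantom
        union = ph.transverse_mask | ph.longitudinal_mask
        sm = accept_prebinarized(union.astype(np.uint8), ph.interior_mask)
        assert compute_density(sm) == pytest.approx(ph.truth["density_total"])
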