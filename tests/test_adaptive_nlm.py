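"""Non-local means, the MCMC block search and the adaptive denoiser."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrfseg import evaluation as ev
from mrfseg.adaptive_nlm import (
    DenoiseConfig,
    SearchFailureError,
    acceptance_prob,
    denoise,
    estimate_noise_sigma,
    gaussian_patch_kernel,
    mcmc_block_search,
    nlm_filter,
    nlm_weights,
    optimal_block_size,
    patch_distance,
    propose_location,
    similarity_phi,
)
from mrfseg.synthetic_data import make_blob_phantom, render_and_noise


def tiled_image(tile_size=6, reps=6, crop=32, seed=8):
    tile = np.random.default_rng(seed).uniform(0, 255, (tile_size, tile_size))
    return np.tile(tile, (reps, reps))[:crop, :crop]


class TestPatchDistance:
    def test_identical_patches_zero(self, rng):
        p = rng.uniform(0, 255, (5, 5))
        assert patch_distance(p, p) == 0.0

    def test_single_center_difference(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        delta = 7.0
        b[1, 1] = delta
        g = gaussian_patch_kernel(3, 3 / 4.0)
        assert patch_distance(a, b) == pytest.approx(g[1, 1] * delta**2, abs=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.uniform(0, 255, (2, 5, 5))
        assert patch_distance(a, b) == pytest.approx(patch_distance(b, a), rel=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            patch_distance(np.zeros((3, 3)), np.zeros((5, 5)))


class TestNlmWeights:
    def test_identical_candidates_uniform(self):
        img = np.full((16, 16), 90.0)
        cands = [(4, 4), (8, 8), (10, 3)]
        wf = nlm_weights((8, 8), cands, img, DenoiseConfig(sigma=10.0))
        assert wf.weights == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_weights_sum_to_one(self, rng):
        img = rng.uniform(0, 255, (20, 20))
        cands = [(int(r), int(c)) for r, c in rng.integers(0, 20, (10, 2))]
        wf = nlm_weights((10, 10), cands, img, DenoiseConfig(sigma=10.0))
        assert wf.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(wf.weights >= 0)

    def test_self_candidate_dominates(self, rng):
        img = rng.uniform(0, 255, (20, 20))
        cands = [(10, 10), (3, 3), (15, 6), (7, 14)]
        wf = nlm_weights((10, 10), cands, img, DenoiseConfig(sigma=10.0))
        assert np.argmax(wf.weights) == 0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            nlm_weights((0, 0), [], np.zeros((8, 8)), DenoiseConfig(sigma=10.0))


class TestNlmFilter:
    def test_constant_image_fixed_point(self):
        img = np.full((24, 24), 77.0)
        out = nlm_filter(img, DenoiseConfig(sigma=10.0))
        assert out == pytest.approx(img, abs=1e-9)

    def test_output_within_input_hull(self, rng):
        img = rng.uniform(30, 200, (32, 32))
        out = nlm_filter(img, DenoiseConfig(sigma=20.0))
        assert out.min() >= img.min() - 1e-9
        assert out.max() <= img.max() + 1e-9

    def test_matches_pointwise_weights_in_interior(self, rng):
        # the shifted-window implementation must agree with the definitional
        # per-pixel weight computation away from the border
        img = rng.uniform(0, 255, (30, 30))
        cfg = DenoiseConfig(sigma=15.0, search_radius=4)
        out = nlm_filter(img, cfg)
        x = (15, 15)
        cands = [
            (x[0] + di, x[1] + dj)
            for di in range(-4, 5)
            for dj in range(-4, 5)
        ]
        wf = nlm_weights(x, cands, img, cfg)
        expected = sum(w * img[y] for w, y in zip(wf.weights, cands))
        assert out[x] == pytest.approx(expected, abs=1e-9)

    def test_denoises_phantom(self):
        labels = make_blob_phantom(96, 96, 2, n_blobs=5, radius_range=(8, 16), seed=2)
        ph = render_and_noise(labels, [60.0, 180.0], sigma=25.0, seed=3)
        out = nlm_filter(ph.noisy_clipped, DenoiseConfig(sigma=25.0))
        assert ev.psnr(ph.clean, out) > ev.psnr(ph.clean, ph.noisy_clipped)


class TestProposeLocation:
    def test_degenerate_std_stays_put(self):
        rng = np.random.default_rng(0)
        assert propose_location((5, 7), 1e-12, rng, (20, 20)) == (5, 7)

    def test_always_in_lattice(self, rng):
        for _ in range(500):
            r, c = propose_location((0, 19), 8.0, rng, (20, 20))
            assert 0 <= r < 20 and 0 <= c < 20

    def test_displacement_mean_is_zero(self):
        rng = np.random.default_rng(3)
        n = 10_000
        sigma_s = 2.0
        moves = np.array(
            [propose_location((50, 50), sigma_s, rng, (101, 101)) for _ in range(n)]
        ) - 50.0
        se = sigma_s / np.sqrt(n)
        assert np.all(np.abs(moves.mean(axis=0)) < 3 * se + 0.05)


class TestSimilarityPhi:
    def test_identical_is_one(self, rng):
        p = rng.uniform(0, 255, (5, 5))
        assert similarity_phi(p, p, C=100.0) == 1.0

    def test_single_pixel_difference(self):
        a = np.zeros((3, 3))
        b = a.copy()
        b[0, 2] = 4.0
        assert similarity_phi(b, a, C=50.0) == pytest.approx(np.exp(-16.0 / 50.0))

    def test_symmetric_and_bounded(self, rng):
        a, b = rng.uniform(0, 255, (2, 5, 5))
        phi = similarity_phi(a, b, C=1000.0)
        assert phi == similarity_phi(b, a, C=1000.0)
        assert 0.0 < phi <= 1.0

    def test_invalid_constant_rejected(self):
        with pytest.raises(ValueError):
            similarity_phi(np.zeros((3, 3)), np.zeros((3, 3)), C=0.0)


class TestAcceptanceProb:
    @pytest.mark.parametrize(
        "cand,prev,expected", [(0.9, 0.3, 1.0), (0.2, 0.4, 0.5), (0.37, 0.37, 1.0)]
    )
    def test_ratio_rule(self, cand, prev, expected):
        assert acceptance_prob(cand, prev) == pytest.approx(expected)

    def test_invalid_previous_rejected(self):
        with pytest.raises(ValueError):
            acceptance_prob(0.5, 0.0)


class TestBlockSearch:
    def test_periodic_texture_members_are_exact_repeats(self):
        img = tiled_image()
        cfg = DenoiseConfig(sigma=20.0, N=8, chain_len=2000, sigma_s=8.0)
        bs = mcmc_block_search((12, 12), 5, img, cfg, np.random.default_rng(1), sigma=20.0)
        assert np.all(bs.phis == 1.0)

    def test_constant_image_zero_variance(self):
        img = np.full((32, 32), 100.0)
        cfg = DenoiseConfig(sigma=10.0)
        bs = mcmc_block_search((16, 16), 7, img, cfg, np.random.default_rng(2), sigma=10.0)
        assert bs.variance == 0.0
        assert np.allclose(bs.mean_block, 100.0)

    def test_member_contract(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        cfg = DenoiseConfig(sigma=40.0, N=10)
        bs = mcmc_block_search((16, 16), 5, img, cfg, np.random.default_rng(3), sigma=40.0)
        assert len(bs.members) <= 10
        assert len(set(bs.members)) == len(bs.members)
        assert bs.members[0] == (16, 16)
        assert np.allclose(bs.mean_block, bs.blocks.mean(axis=0))

    def test_two_texture_concentration(self):
        # the chain's stationary law is the similarity phi, so members must
        # concentrate in the half of the image sharing the query's texture
        tile = np.random.default_rng(1).uniform(0, 255, (8, 8))
        left = np.tile(tile, (8, 4))
        right = np.random.default_rng(2).uniform(0, 255, (64, 32))
        img = np.hstack([left, right])
        cfg = DenoiseConfig(sigma=20.0, N=16, chain_len=2000, sigma_s=10.0)
        bs = mcmc_block_search((32, 12), 7, img, cfg, np.random.default_rng(5), sigma=20.0)
        frac = np.mean([c < 32 for _, c in bs.members])
        assert frac >= 0.8

    def test_search_failure_on_stuck_chain(self):
        # strong unique 2-D ramp: every block is unique, and at tiny C no
        # proposal is ever accepted
        img = np.arange(256, dtype=float).reshape(16, 16) * 100.0
        cfg = DenoiseConfig(sigma=0.01, chain_len=50, N=2, sigma_s=3.0)
        with pytest.raises(SearchFailureError):
            mcmc_block_search((8, 8), 5, img, cfg, np.random.default_rng(0), sigma=0.01)


class TestOptimalBlockSize:
    def test_constant_image_chooses_largest(self):
        img = np.full((32, 32), 128.0)
        d, bs = optimal_block_size((16, 16), img, DenoiseConfig(sigma=15.0),
                                   np.random.default_rng(2))
        assert d == 9
        assert bs.size == 9

    def test_paper_threshold_value(self):
        cfg = DenoiseConfig(sigma=15.0, threshold_mode="paper")
        assert cfg.size_threshold(15.0) == pytest.approx(1.0 / 225.0)

    def test_fallback_when_no_size_passes(self, rng):
        # with the literal 1/sigma^2 threshold any noisy image fails every
        # candidate size, triggering the smallest-size fallback
        img = rng.normal(128, 25, (48, 48))
        cfg = DenoiseConfig(sigma=25.0, threshold_mode="paper")
        d, _ = optimal_block_size((24, 24), img, cfg, np.random.default_rng(4))
        assert d == 3


class TestDenoise:
    def test_constant_image_identity(self):
        img = np.full((32, 32), 150.0)
        out = denoise(img, DenoiseConfig(sigma=10.0, seed=1))
        assert out == pytest.approx(img, abs=1e-9)

    def test_deterministic_replay(self):
        labels = make_blob_phantom(48, 48, 2, n_blobs=3, radius_range=(6, 10), seed=6)
        ph = render_and_noise(labels, [60.0, 180.0], sigma=25.0, seed=7)
        cfg = DenoiseConfig(sigma=25.0, seed=9)
        out1 = denoise(ph.noisy_clipped, cfg)
        out2 = denoise(ph.noisy_clipped, cfg)
        assert np.array_equal(out1, out2)

    def test_improves_psnr_and_ssim(self):
        labels = make_blob_phantom(64, 64, 2, n_blobs=4, radius_range=(7, 12), seed=8)
        ph = render_and_noise(labels, [60.0, 180.0], sigma=25.0, seed=9)
        out = denoise(ph.noisy_clipped, DenoiseConfig(sigma=25.0, seed=10))
        assert ev.psnr(ph.clean, out) > ev.psnr(ph.clean, ph.noisy_clipped) + 2.0
        assert ev.ssim(ph.clean, out) > ev.ssim(ph.clean, ph.noisy_clipped)
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_rgb_input_rejected(self):
        with pytest.raises(ValueError):
            denoise(np.zeros((8, 8, 3)), DenoiseConfig(sigma=10.0))


class TestEstimateNoiseSigma:
    def test_constant_image_near_zero(self):
        assert estimate_noise_sigma(np.full((16, 16), 42.0)) < 0.5

    def test_recovers_noise_std(self):
        noise = np.random.default_rng(0).normal(128.0, 25.0, (256, 256))
        assert estimate_noise_sigma(noise) == pytest.approx(25.0, rel=0.10)

    def test_offset_invariant(self, rng):
        img = rng.normal(100.0, 10.0, (64, 64))
        assert estimate_noise_sigma(img) == pytest.approx(
            estimate_noise_sigma(img + 55.0), abs=1e-9
        )

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.zeros((4, 4)))
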