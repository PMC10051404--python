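import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchrefine.grid import PatchGrid, PatchIndex, crop, make_grid
from patchrefine.uncertainty import (
    UNCERTAINTY_MAX,
    PatchScores,
    SelectionConfig,
    patch_scores,
    pixel_uncertainty,
    sample_training_patch,
    select_patches,
)


class TestPixelUncertainty:
    @pytest.mark.parametrize("variant", ["paper", "full_entropy"])
    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_saturated_probabilities_have_zero_uncertainty(self, p, variant):
        assert pixel_uncertainty(p, variant) == 0.0

    def test_half(self):
        assert pixel_uncertainty(0.5, "paper") == pytest.approx(0.5)
        assert pixel_uncertainty(0.5, "full_entropy") == pytest.approx(1.0)

    def test_paper_variant_argmax_grid_oracle(self):
        # independent dense grid search over p
        ps = np.linspace(0.0, 1.0, 200_001)
        u = pixel_uncertainty(ps, "paper")
        k = int(np.argmax(u))
        assert ps[k] == pytest.approx(1.0 / math.e, abs=1e-4)
        assert u[k] == pytest.approx(math.log2(math.e) / math.e, abs=1e-8)
        assert UNCERTAINTY_MAX["paper"] == pytest.approx(u[k], abs=1e-8)

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                pixel_uncertainty(bad)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            pixel_uncertainty(0.5, "mc_dropout")

    @settings(max_examples=50, deadline=None)
    @given(p=st.floats(0.0, 1.0))
    def test_full_entropy_symmetry(self, p):
        assert pixel_uncertainty(p) == pytest.approx(pixel_uncertainty(1.0 - p), abs=1e-12)

    def test_paper_variant_asymmetry(self):
        # documents the variant difference: u(p) != u(1-p) away from {0, 0.5, 1}
        for p in (0.1, 0.3, 0.8):
            assert pixel_uncertainty(p, "paper") != pytest.approx(
                pixel_uncertainty(1.0 - p, "paper"), abs=1e-6
            )

    @settings(max_examples=50, deadline=None)
    @given(p=st.floats(0.0, 1.0), variant=st.sampled_from(["paper", "full_entropy"]))
    def test_nonnegative_and_bounded(self, p, variant):
        u = pixel_uncertainty(p, variant)
        assert 0.0 <= u <= UNCERTAINTY_MAX[variant] + 1e-12


class TestPatchScores:
    def test_all_zero_probabilities(self):
        g = make_grid(8, 8, 4)
        s = patch_scores(np.zeros((8, 8)), g)
        np.testing.assert_array_equal(s.scores, np.zeros((2, 2)))

    def test_hand_computed_mean(self):
        # per-pixel oracle: (0 + 0 + 0.5 + 0.5) / 4
        g = make_grid(2, 2, 1)
        p = np.array([[1.0, 1.0], [0.5, 0.5]])
        s = patch_scores(p, g, "paper")
        assert s.scores[0, 0] == pytest.approx(0.25)

    @pytest.mark.parametrize("n_patches", [4, 16])
    @pytest.mark.parametrize("variant", ["paper", "full_entropy"])
    def test_brute_force_oracle_equivalence(self, n_patches, variant, rng):
        p = rng.random((64, 64))
        g = make_grid(64, 64, n_patches)
        s = patch_scores(p, g, variant)
        for idx in g.indices():
            block = crop(p, g, idx)
            naive = np.mean([pixel_uncertainty(float(v), variant) for v in block.ravel()])
            assert s.scores[idx.i, idx.j] == pytest.approx(naive, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            patch_scores(np.zeros((7, 8)), make_grid(8, 8, 4))


def _scores_from_normalized(values, variant="full_entropy"):
    vals = np.asarray(values, dtype=float) * UNCERTAINTY_MAX[variant]
    grid = PatchGrid(1, vals.size, 1, vals.size, 1, 1)
    return PatchScores(grid=grid, scores=vals.reshape(1, -1), variant=variant)


class TestSelectPatches:
    def test_threshold_zero_selects_all(self, rng):
        s = _scores_from_normalized(rng.random(6))
        assert select_patches(s, 0.0) == {PatchIndex(0, j) for j in range(6)}

    def test_threshold_one_empty_when_unsaturated(self):
        s = _scores_from_normalized([0.2, 0.99, 0.5])
        assert select_patches(s, 1.0) == set()

    def test_direct_enumeration(self):
        s = _scores_from_normalized([0.1, 0.3, 0.6])
        assert select_patches(s, 0.25) == {PatchIndex(0, 1), PatchIndex(0, 2)}

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        t1=st.floats(0.0, 1.0),
        t2=st.floats(0.0, 1.0),
    )
    def test_threshold_monotonicity(self, values, t1, t2):
        lo, hi = sorted((t1, t2))
        s = _scores_from_normalized(values)
        assert select_patches(s, hi) <= select_patches(s, lo)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            select_patches(_scores_from_normalized([0.5]), 1.5)


class TestSampling:
    def test_degenerate_weights(self):
        s = _scores_from_normalized([0.0, 0.0, 1.0])
        cfg = SelectionConfig(strategy="weighted", seed=0)
        rng = np.random.default_rng(0)
        assert all(
            sample_training_patch(s, cfg, rng) == PatchIndex(0, 2) for _ in range(20)
        )

    def test_highest_row_major_tie_break(self):
        s = _scores_from_normalized([0.9, 0.9, 0.2])
        cfg = SelectionConfig(strategy="highest")
        assert sample_training_patch(s, cfg, np.random.default_rng(0)) == PatchIndex(0, 0)

    def test_weighted_frequencies_binomial_oracle(self):
        s = _scores_from_normalized([0.25, 0.75])
        cfg = SelectionConfig(strategy="weighted", seed=0)
        rng = np.random.default_rng(cfg.seed)
        n = 10_000
        hits = sum(sample_training_patch(s, cfg, rng).j for _ in range(n))
        freq = hits / n
        sigma = math.sqrt(0.75 * 0.25 / n)
        assert abs(freq - 0.75) <= 3 * sigma

    def test_weighted_uniform_fallback_on_zero_scores(self):
        s = _scores_from_normalized([0.0, 0.0, 0.0])
        cfg = SelectionConfig(strategy="weighted", seed=0)
        rng = np.random.default_rng(1)
        seen = {sample_training_patch(s, cfg, rng).j for _ in range(200)}
        assert seen == {0, 1, 2}

    def test_determinism_same_seed(self, rng):
        s = _scores_from_normalized(rng.random(9))
        cfg = SelectionConfig(strategy="weighted", seed=42)
        seq1 = [sample_training_patch(s, cfg, np.random.default_rng(cfg.seed)) for _ in range(1)]
        r1 = np.random.default_rng(cfg.seed)
        r2 = np.random.default_rng(cfg.seed)
        seq1 = [sample_training_patch(s, cfg, r1) for _ in range(50)]
        seq2 = [sample_training_patch(s, cfg, r2) for _ in range(50)]
        assert seq1 == seq2

    def test_random_uniform_coverage(self):
        s = _scores_from_normalized([0.9, 0.1])
        cfg = SelectionConfig(strategy="random", seed=0)
        rng = np.random.default_rng(3)
        n = 10_000
        freq = sum(sample_training_patch(s, cfg, rng).j for _ in range(n)) / n
        assert abs(freq - 0.5) <= 3 * math.sqrt(0.25 / n)


class TestSelectionConfig:
    def test_rejects_unknown_strategy(self):
        with pytest.raises(ValueError):
            SelectionConfig(strategy="rl")

    def test_rejects_out_of_range_threshold(self):
        with pytest.raises(ValueError):
            SelectionConfig(threshold=2.0)
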