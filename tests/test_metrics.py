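"""Spatial frequency, average gradient, and classification reporting."""

import numpy as np
import pytest

from camfuse import average_gradient, classification_report, spatial_frequency


def sf_brute(x, scale):
    x = x * scale
    m, n = x.shape
    rf = cf = 0.0
    for i in range(m):
        for j in range(1, n):
            rf += (x[i, j] - x[i, j - 1]) ** 2
    for i in range(1, m):
        for j in range(n):
            cf += (x[i, j] - x[i - 1, j]) ** 2
    return np.sqrt(rf / (m * n) + cf / (m * n))


def ag_brute(x, scale):
    x = x * scale
    m, n = x.shape
    total = 0.0
    for i in range(m - 1):
        for j in range(n - 1):
            dx = x[i, j + 1] - x[i, j]
            dy = x[i + 1, j] - x[i, j]
            total += np.sqrt((dx**2 + dy**2) / 2.0)
    return total / ((m - 1) * (n - 1))


class TestClosedForms:
    def test_constant_image_is_zero(self):
        img = np.full((6, 9), 0.37)
        assert spatial_frequency(img, 1.0) == 0.0
        assert average_gradient(img, 1.0) == 0.0

    def test_checkerboard(self):
        cb = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert spatial_frequency(cb, 1.0) == pytest.approx(1.0)
        assert average_gradient(cb, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 9, 17])
    def test_linear_ramp_closed_form(self, n):
        ramp = np.tile(np.linspace(0.0, 1.0, n), (n, 1))
        assert average_gradient(ramp, 1.0) == pytest.approx(
            np.sqrt(0.5) / (n - 1), rel=1e-12
        )

    def test_scale_homogeneity_and_shift_invariance(self, rng):
        img = rng.uniform(size=(8, 8))
        assert spatial_frequency(img, 510.0) == pytest.approx(
            2 * spatial_frequency(img, 255.0)
        )
        assert average_gradient(img, 510.0) == pytest.approx(
            2 * average_gradient(img, 255.0)
        )
        shifted = img + 0.21
        assert spatial_frequency(shifted, 1.0) == pytest.approx(
            spatial_frequency(img, 1.0)
        )
        assert average_gradient(shifted, 1.0) == pytest.approx(
            average_gradient(img, 1.0)
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_brute_force_double_loop_agreement(self, seed):
        img = np.random.default_rng(seed).uniform(size=(7, 11))
        assert spatial_frequency(img, 255.0) == pytest.approx(
            sf_brute(img, 255.0), abs=1e-9
        )
        assert average_gradient(img, 255.0) == pytest.approx(
            ag_brute(img, 255.0), abs=1e-9
        )

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError):
            spatial_frequency(np.ones((1, 1)))
        with pytest.raises(ValueError):
            average_gradient(np.ones((1, 5)))


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = [0, 0, 1, 1, 2, 2]
        rep = classification_report(y, y)
        assert (rep.f1, rep.recall, rep.precision, rep.accuracy) == (
            100.0, 100.0, 100.0, 100.0,
        )

    def test_symmetric_two_class_confusion(self):
        # confusion [[3,1],[1,3]]
        y_true = [0] * 4 + [1] * 4
        y_pred = [0, 0, 0, 1, 1, 1, 1, 0]
        rep = classification_report(y_true, y_pred)
        assert rep.accuracy == 75.0 and rep.f1 == 75.0
        np.testing.assert_array_equal(rep.confusion, [[3, 1], [1, 3]])

    def test_single_predicted_class_macro_recall(self):
        y_true = [0, 0, 1, 1]
        y_pred = [0, 0, 0, 0]
        rep = classification_report(y_true, y_pred)
        assert rep.recall == 50.0  # (100% + 0%) / 2

    def test_accuracy_equals_trace_over_sum(self, rng):
        y_true = rng.integers(0, 3, size=60)
        y_pred = rng.integers(0, 3, size=60)
        rep = classification_report(y_true, y_pred)
        assert rep.accuracy == pytest.approx(
            round(100 * np.trace(rep.confusion) / rep.confusion.sum(), 1)
        )

    def test_length_mismatch_and_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_report([0, 1], [0])
        with pytest.raises(ValueError):
            classification_report([1, 1, 1], [0, 1, 1])


class TestFusionTextureDirection:
    def test_attention_selection_preserves_more_texture_than_averaging(
        self, rng
    ):
        """Paired over >= 50 complementary-view fixtures, attention-selection
        fusion keeps more textural information (SF and AG) than plain
        averaging of the three view maps."""
        from scipy import stats

        from camfuse import FusionConfig, SyntheticSpec, fuse_maps, generate_dataset
        from camfuse.synthetic import VIEWS

        ds = generate_dataset(SyntheticSpec(n_classes=3, per_class=20, seed=0))
        cfg = FusionConfig()
        sf_wins = ag_wins = sf_ties = ag_ties = 0
        n = len(ds.images)
        for i in range(n):
            maps = [ds.view_maps[v][i] for v in VIEWS]
            fused = fuse_maps(maps, cfg, mode="map").values
            avg = np.mean([m.values for m in maps], axis=0)
            avg = (avg - avg.min()) / (avg.max() - avg.min())
            d_sf = spatial_frequency(fused, 1.0) - spatial_frequency(avg, 1.0)
            d_ag = average_gradient(fused, 255.0) - average_gradient(avg, 255.0)
            sf_wins += d_sf > 0; sf_ties += d_sf == 0
            ag_wins += d_ag > 0; ag_ties += d_ag == 0
        assert n >= 50
        for wins, ties in ((sf_wins, sf_ties), (ag_wins, ag_ties)):
            p = stats.binomtest(wins, n - ties, 0.5, alternative="greater").pvalue
            assert p < 0.05
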