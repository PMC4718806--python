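"""FSC, resolution estimation and noise-substitution mask correction."""

import numpy as np
import pytest

from cryofocus import VolumeGrid
from cryofocus.masks import SoftMask, make_soft_mask
from cryofocus.validation import (
    FSCCurve,
    compute_fsc,
    fsc_noise_substitution,
    resolution_at,
    run_report,
    split_half_sets,
)


def _noise_volume(seed, box=64, pixel_size=1.0):
    rng = np.random.default_rng(seed)
    return VolumeGrid(rng.standard_normal((box, box, box)), pixel_size)


class TestComputeFsc:
    def test_self_correlation_is_one(self, smooth_volume):
        curve = compute_fsc(smooth_volume, smooth_volume)
        populated = curve.counts > 0
        assert np.allclose(curve.values[populated], 1.0, atol=1e-12)

    def test_negated_map_gives_minus_one(self, smooth_volume):
        neg = VolumeGrid(-smooth_volume.data, smooth_volume.pixel_size)
        curve = compute_fsc(smooth_volume, neg)
        assert np.allclose(curve.values[curve.counts > 0], -1.0, atol=1e-12)

    def test_independent_noise_decorrelates(self):
        means = []
        for seed in range(10):
            c = compute_fsc(_noise_volume(2 * seed), _noise_volume(2 * seed + 1))
            means.append(c.values[1:].mean())
        assert -0.05 < float(np.mean(means)) < 0.05

    def test_symmetric_in_arguments(self):
        a, b = _noise_volume(1), _noise_volume(2)
        ab = compute_fsc(a, b)
        ba = compute_fsc(b, a)
        assert np.array_equal(ab.values, ba.values)

    def test_invariant_under_global_scaling(self, smooth_volume):
        other = _noise_volume(3, box=32)
        base = compute_fsc(smooth_volume, other)
        scaled = compute_fsc(
            VolumeGrid(5.0 * smooth_volume.data, 1.0),
            VolumeGrid(5.0 * other.data, 1.0),
        )
        assert np.allclose(base.values, scaled.values, atol=1e-12)

    def test_grid_mismatch_rejected(self, smooth_volume):
        with pytest.raises(ValueError, match="mismatch"):
            compute_fsc(smooth_volume, _noise_volume(0, box=16))


class TestResolutionAt:
    def test_never_crossing_returns_nyquist_flagged(self):
        freqs = np.arange(17) / 32.0
        curve = FSCCurve(freqs, np.ones(17), np.ones(17))
        res, crossed = resolution_at(curve)
        assert not crossed
        assert res == pytest.approx(1.0 / freqs[-1])

    def test_step_curve_interpolates_crossing(self):
        freqs = np.arange(17) / 32.0
        values = np.where(np.arange(17) <= 8, 1.0, 0.0)
        curve = FSCCurve(freqs, values, np.ones(17))
        res, crossed = resolution_at(curve, threshold=0.143)
        # linear segment from (freqs[8], 1.0) to (freqs[9], 0.0)
        f_cross = freqs[8] + (1.0 - 0.143) * (freqs[9] - freqs[8])
        assert crossed
        assert res == pytest.approx(1.0 / f_cross)

    def test_starting_below_threshold_rejected(self):
        freqs = np.arange(5) / 8.0
        curve = FSCCurve(freqs, np.full(5, 0.1), np.ones(5))
        with pytest.raises(ValueError):
            resolution_at(curve)

    def test_resolution_degrades_with_noise(self, smooth_volume):
        # half-map pairs at increasing noise: reported resolution gets worse
        resolutions = []
        for sigma in (0.001, 0.01, 0.05):
            res_for_seeds = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                h1 = VolumeGrid(
                    smooth_volume.data + sigma * rng.standard_normal((32, 32, 32)), 1.0
                )
                h2 = VolumeGrid(
                    smooth_volume.data + sigma * rng.standard_normal((32, 32, 32)), 1.0
                )
                res, _ = resolution_at(compute_fsc(h1, h2), 0.143)
                res_for_seeds.append(res)
            resolutions.append(np.mean(res_for_seeds))
        assert resolutions[0] <= resolutions[1] <= resolutions[2]


class TestNoiseSubstitution:
    def _tight_mask(self, box=64):
        g = np.arange(box) - box // 2
        z, y, x = np.meshgrid(g, g, g, indexing="ij")
        blob = (x**2 + y**2 + z**2 <= 8**2).astype(float)
        return make_soft_mask(VolumeGrid(blob, 1.0), 0.5, 0, 3)

    @staticmethod
    def _half_maps(seed, box=64):
        # shared compact signal + independent noise: the regime where a tight
        # mask inflates high-shell FSC by leaking the shared low frequencies
        g = np.arange(box) - box // 2
        z, y, x = np.meshgrid(g, g, g, indexing="ij")
        signal = 30.0 * np.exp(-(x**2 + y**2 + z**2) / (2 * 4.0**2))
        rng = np.random.default_rng(seed)
        h1 = VolumeGrid(signal + rng.standard_normal((box,) * 3), 1.0)
        h2 = VolumeGrid(signal + rng.standard_normal((box,) * 3), 1.0)
        return h1, h2

    def test_allpass_mask_correction_is_small(self):
        ones = SoftMask(VolumeGrid(np.ones((64, 64, 64)), 1.0))
        h1, h2 = self._half_maps(7)
        plain = compute_fsc(h1, h2, ones)
        corrected = fsc_noise_substitution(h1, h2, ones, randomize_from=4.0)
        valid = ~corrected.flags
        diffs = corrected.values[valid] - plain.values[valid]
        assert np.mean(np.abs(diffs)) < 0.02
        assert np.max(np.abs(diffs)) < 0.1  # single-shell estimator noise

    def test_shells_before_randomization_untouched(self):
        mask = self._tight_mask()
        h1, h2 = self._half_maps(20)
        masked = compute_fsc(h1, h2, mask)
        corrected = fsc_noise_substitution(h1, h2, mask, randomize_from=8.0)
        shell0 = int(round(64 * 1.0 / 8.0))
        assert np.array_equal(corrected.values[: shell0 + 1], masked.values[: shell0 + 1])

    def test_tight_mask_inflation_removed(self):
        # in noise-dominated shells the masked FSC is inflated by the shared
        # signal leaking through the mask; the correction removes it.  A tiny
        # mask leaves few effective components per shell, so the check is on
        # seed-averaged means, not single shells.
        mask = self._tight_mask()
        unmasked_means, inflated, corrected_means = [], [], []
        for seed in range(20):
            h1, h2 = self._half_maps(100 + seed)
            high = np.arange(33) > 20  # far beyond the signal support
            unmasked_means.append(compute_fsc(h1, h2).values[high].mean())
            masked = compute_fsc(h1, h2, mask)
            inflated.append(masked.values[high].mean())
            corr = fsc_noise_substitution(h1, h2, mask, randomize_from=4.0, seed=seed)
            sel = high & ~corr.flags
            corrected_means.append(corr.values[sel].mean())
        assert abs(np.mean(unmasked_means)) < 0.01  # noise-only without mask
        assert np.mean(inflated) > 0.03  # the mask-induced inflation is real
        assert abs(np.mean(corrected_means)) < 0.02  # the correction removes it
        assert np.mean(corrected_means) < 0.5 * np.mean(inflated)

    def test_correction_never_adds_correlation(self):
        # removes, never adds: on average over noise-dominated shells the
        # corrected curve does not exceed the masked one
        mask = self._tight_mask()
        excess = []
        for seed in range(10):
            h1, h2 = self._half_maps(200 + seed)
            masked = compute_fsc(h1, h2, mask)
            corr = fsc_noise_substitution(h1, h2, mask, randomize_from=4.0, seed=seed)
            sel = (np.arange(33) > 16) & ~corr.flags
            excess.append(np.mean(corr.values[sel] - masked.values[sel]))
        assert np.mean(excess) <= 0.02


class TestHalfSetsAndReport:
    def test_split_is_balanced_and_deterministic(self):
        labels = split_half_sets(1001, seed=3)
        assert set(labels) == {1, 2}
        assert abs((labels == 1).sum() - (labels == 2).sum()) <= 1
        assert np.array_equal(labels, split_half_sets(1001, seed=3))

    def test_report_aggregates_fractions_and_accuracy(self):
        from cryofocus.classification import ClassModel, NoiseSpectrum

        refs = (VolumeGrid(np.zeros((8, 8, 8)), 1.0),) * 2
        model = ClassModel(refs, np.array([0.6, 0.4]), NoiseSpectrum(np.ones(4)))
        resp = np.tile([0.9, 0.1], (10, 1))
        history = [{"iteration": 1, "fractions": model.fractions,
                    "mean_log_evidence": -1.0}]
        rep = run_report(model, resp, history, truth_labels=[1] * 10)
        assert rep["class_counts"] == [10, 0]
        assert sum(rep["class_fractions"]) == pytest.approx(1.0)
        assert rep["accuracy"] == 1.0

    def test_empty_history_rejected(self):
        from cryofocus.classification import ClassModel, NoiseSpectrum

        refs = (VolumeGrid(np.zeros((8, 8, 8)), 1.0),)
        model = ClassModel(refs, np.array([1.0]), NoiseSpectrum(np.ones(4)))
        with pytest.raises(ValueError, match="empty"):
            run_report(model, np.ones((3, 1)), [])
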