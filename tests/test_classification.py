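"""Fixed-orientation EM classification: exactness, symmetry and determinism."""

import numpy as np
import pytest

from cryofocus import VolumeGrid
from cryofocus.classification import (
    ClassModel,
    NoiseSpectrum,
    _Engine,
    classify,
    e_step,
    init_classes,
    m_step,
    select_classes,
)
from cryofocus.masks import apply_mask
from cryofocus.simulation import score_classification


@pytest.fixture(scope="module")
def small_problem(subtracted_noisy):
    particles = subtracted_noisy["particles"].subset(range(0, 500, 5))
    from cryofocus.io_formats import ImageStack

    images = ImageStack(
        subtracted_noisy["images"].data[::5], subtracted_noisy["images"].pixel_size
    )
    return particles, images


class TestEStep:
    def test_single_class_gets_all_responsibility(self, small_problem, two_class_setup):
        particles, images = small_problem
        model = init_classes(particles, images, 1, seed=0, mask=two_class_setup["mask"])
        resp, log_ev, _ = e_step(model, particles, images)
        assert np.allclose(resp, 1.0)
        assert np.all(np.isfinite(log_ev))

    def test_duplicate_references_share_responsibility(
        self, small_problem, two_class_setup
    ):
        particles, images = small_problem
        eng = _Engine(particles, images)
        ref = init_classes(particles, images, 1, 0, two_class_setup["mask"],
                           _engine=eng).references[0]
        model = ClassModel(
            (ref, ref),
            np.array([0.5, 0.5]),
            NoiseSpectrum(np.ones(eng.n_shell)),
            two_class_setup["mask"],
            0,
            eng.smax,
        )
        resp, _, _ = e_step(model, particles, images, _engine=eng)
        assert np.allclose(resp, 0.5, atol=1e-9)

    def test_truthful_init_classifies_clean_data_perfectly(
        self, two_class_setup, clean_sim
    ):
        from cryofocus.subtraction import subtract_signal

        sim = clean_sim
        images, particles = subtract_signal(
            sim.particles, sim.images, two_class_setup["b"].volume
        )
        eng = _Engine(particles, images)
        mask = two_class_setup["mask"]
        rod = apply_mask(two_class_setup["a"].part_map("rod"), mask)
        empty = VolumeGrid(np.zeros_like(rod.data), rod.pixel_size)
        model = ClassModel(
            (rod, empty),
            np.array([0.5, 0.5]),
            NoiseSpectrum(np.full(eng.n_shell, 1e-6)),
            mask,
            0,
            eng.smax,
        )
        resp, _, _ = e_step(model, particles, images, _engine=eng)
        assert score_classification(resp, sim.labels) == 1.0


class TestInitAndMStep:
    def test_k1_reference_is_plain_reconstruction(self, small_problem):
        particles, images = small_problem
        eng = _Engine(particles, images)
        model = init_classes(particles, images, 1, seed=3, _engine=eng)
        direct = eng.reconstruct_class(np.ones(len(particles)))
        assert np.allclose(model.references[0].data, direct.data, atol=1e-12)

    def test_same_seed_reproducible(self, small_problem, two_class_setup):
        particles, images = small_problem
        m1 = init_classes(particles, images, 3, seed=7, mask=two_class_setup["mask"])
        m2 = init_classes(particles, images, 3, seed=7, mask=two_class_setup["mask"])
        assert np.array_equal(m1.fractions, m2.fractions)
        for a, b in zip(m1.references, m2.references):
            assert np.array_equal(a.data, b.data)

    def test_partition_matches_rng_replay(self, small_problem):
        particles, images = small_problem
        model = init_classes(particles, images, 2, seed=123)
        labels = np.random.default_rng(123).permutation(len(particles)) % 2
        expect = np.array([np.mean(labels == j) for j in range(2)])
        assert np.allclose(model.fractions, expect)

    def test_k_exceeding_n_rejected(self, small_problem):
        particles, images = small_problem
        with pytest.raises(ValueError, match="exceeds"):
            init_classes(particles, images, len(particles) + 1, seed=0)

    def test_hard_responsibilities_reproduce_group_reconstructions(
        self, small_problem
    ):
        particles, images = small_problem
        eng = _Engine(particles, images)
        model = init_classes(particles, images, 2, seed=5, _engine=eng)
        labels = np.random.default_rng(5).permutation(len(particles)) % 2
        resp = np.eye(2)[labels]
        new = m_step(model, particles, images, resp, _engine=eng)
        group0 = eng.reconstruct_class((labels == 0).astype(float))
        assert np.allclose(new.references[0].data, group0.data, atol=1e-12)

    def test_fractions_sum_to_one_after_update(self, small_problem, rng):
        particles, images = small_problem
        eng = _Engine(particles, images)
        model = init_classes(particles, images, 3, seed=1, _engine=eng)
        resp = rng.random((len(particles), 3))
        resp /= resp.sum(axis=1, keepdims=True)
        new = m_step(model, particles, images, resp, _engine=eng)
        assert new.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sigma2_recovers_known_noise_variance(self, two_class_setup):
        # pure-noise residuals of known flat spectrum: per-shell recovery < 5%
        from cryofocus.io_formats import ImageStack, ParticleRecord, ParticleSet
        from cryofocus.geometry import CTFParams

        # n large enough that the freshly fitted reference absorbs only a
        # small share of the noise it is estimated from
        rng = np.random.default_rng(8)
        n, box = 1000, 32
        power = 3.0  # per-component Fourier power => sigma2 = 1.5
        noise = rng.standard_normal((n, box, box)) * np.sqrt(power)
        records = tuple(
            ParticleRecord(
                image_ref=("n.mrcs", i + 1),
                rot=rng.uniform(-180, 180),
                tilt=rng.uniform(0, 180),
                psi=rng.uniform(-180, 180),
                ctf=CTFParams(),
            )
            for i in range(n)
        )
        particles = ParticleSet(records, pixel_size=1.0, box=box)
        images = ImageStack(noise, 1.0)
        eng = _Engine(particles, images)
        zero = VolumeGrid(np.zeros((box, box, box)), 1.0)
        model = ClassModel(
            (zero,), np.array([1.0]), NoiseSpectrum(np.ones(eng.n_shell)), None, 0,
            eng.smax,
        )
        new = m_step(model, particles, images, np.ones((n, 1)), _engine=eng)
        est = new.noise.sigma2[1:]
        assert np.all(np.abs(est / (power / 2.0) - 1.0) < 0.05)


class TestClassify:
    def test_clean_two_class_run_recovers_truth(self, two_class_setup, clean_sim):
        from cryofocus.subtraction import subtract_signal

        sim = clean_sim
        images, particles = subtract_signal(
            sim.particles, sim.images, two_class_setup["b"].volume
        )
        model, resp, history = classify(
            particles, images, 2, two_class_setup["mask"], n_iter=10, seed=5
        )
        assert score_classification(resp, sim.labels) == 1.0
        assert model.fractions == pytest.approx([0.5, 0.5], abs=0.01)

    def test_log_evidence_non_decreasing(
        self, two_class_setup, subtracted_noisy
    ):
        model, resp, history = classify(
            subtracted_noisy["particles"],
            subtracted_noisy["images"],
            2,
            two_class_setup["mask"],
            n_iter=12,
            seed=5,
        )
        for a, b in zip(history, history[1:]):
            if a["shell_limit"] != b["shell_limit"]:
                continue  # band switch: evidence values not comparable
            ea, eb = a["mean_log_evidence"], b["mean_log_evidence"]
            assert eb >= ea - 1e-6 * abs(ea)

    def test_label_permutation_symmetry(self, two_class_setup, noisy_sim):
        # different seeds permute classes but find the same partition; run at
        # half noise power so the partition itself is stable across runs
        from cryofocus.simulation import rescale_noise
        from cryofocus.subtraction import subtract_signal

        sim = rescale_noise(noisy_sim["sim"], 0.5)
        images, particles = subtract_signal(
            sim.particles, sim.images, two_class_setup["b"].volume
        )
        kw = dict(mask=two_class_setup["mask"], n_iter=8)
        _, r1, _ = classify(particles, images, 2, seed=21, **kw)
        _, r2, _ = classify(particles, images, 2, seed=22, **kw)
        a1, a2 = r1.argmax(axis=1), r2.argmax(axis=1)
        agree = max(np.mean(a1 == a2), np.mean(a1 == 1 - a2))
        assert agree > 0.9

    def test_deterministic_given_seed(self, small_problem, two_class_setup):
        particles, images = small_problem
        kw = dict(mask=two_class_setup["mask"], n_iter=3, seed=9)
        m1, r1, h1 = classify(particles, images, 2, **kw)
        m2, r2, h2 = classify(particles, images, 2, **kw)
        assert np.array_equal(r1, r2)
        assert h1[-1]["mean_log_evidence"] == h2[-1]["mean_log_evidence"]


class TestSelect:
    def test_zero_min_fraction_returns_all(self, small_problem, two_class_setup):
        particles, images = small_problem
        model, resp, _ = classify(
            particles, images, 2, two_class_setup["mask"], n_iter=3, seed=4
        )
        sel = select_classes(model, resp, min_fraction=0.0)
        assert len(sel) == 2

    def test_hard_assignment_partitions_particles(
        self, small_problem, two_class_setup
    ):
        particles, images = small_problem
        model, resp, _ = classify(
            particles, images, 2, two_class_setup["mask"], n_iter=3, seed=4
        )
        sel = select_classes(model, resp)
        allidx = np.concatenate([s["indices"] for s in sel])
        assert sorted(allidx) == list(range(len(particles)))

    def test_min_fraction_filters(self, small_problem, two_class_setup):
        particles, images = small_problem
        model, resp, _ = classify(
            particles, images, 2, two_class_setup["mask"], n_iter=3, seed=4
        )
        sel = select_classes(model, resp, min_fraction=1.01)
        assert sel == []
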