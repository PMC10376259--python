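import numpy as np
import pytest
from scipy.stats import ks_2samp

from facescreen.mesh import normalize_sequence
from facescreen.synthetic import (
    CohortConfig,
    Session,
    face_template,
    generate_appearance_sequence,
    generate_au_sequence,
    generate_cohort,
    generate_mesh_sequence,
    hog_descriptor_length,
    session_frame_count,
)


class TestConfigValidation:
    def test_defaults_match_recording_protocol(self):
        cfg = CohortConfig()
        assert cfg.frames_per_session == 18_000 == session_frame_count(10, 30)
        assert cfg.n_landmarks == 478
        assert cfg.n_au == 17
        assert cfg.n_appearance_dims == 4464 == hog_descriptor_length(12, 12, 31)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects_per_class": 0},
            {"sessions_per_subject_range": (3, 2)},
            {"sessions_per_subject_range": (0, 2)},
            {"frames_per_session": 0},
            {"au_var_scale": 0.0},
            {"noise_sd": -1.0},
            {"streams": ("au", "video")},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)


class TestAUGeneration:
    def test_values_within_scale(self):
        cfg = CohortConfig(frames_per_session=500, au_mean_shift=3.0, au_var_scale=4.0, seed=1)
        seq = generate_au_sequence("dementia", cfg, np.random.default_rng(0))
        assert seq.values.min() >= 0.0 and seq.values.max() <= 5.0
        assert seq.values.shape == (500, 17)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="class label"):
            generate_au_sequence("mci", CohortConfig(), np.random.default_rng(0))

    def test_null_config_classes_indistinguishable(self):
        # zero shift, unit variance scale: both labels draw from one process
        cfg = CohortConfig(frames_per_session=4000, au_mean_shift=0.0, au_var_scale=1.0)
        h = generate_au_sequence("healthy", cfg, np.random.default_rng(1))
        d = generate_au_sequence("dementia", cfg, np.random.default_rng(2))
        # thin to every 20th frame to de-autocorrelate before the KS test
        stat = ks_2samp(h.values[::20].ravel(), d.values[::20].ravel())
        assert stat.pvalue > 0.01

    def test_mean_shift_recovered_from_sample_statistics(self):
        # oracle: direct sample means over the generated arrays
        shift = np.zeros(17)
        shift[3] = 0.5
        cfg = CohortConfig(
            n_subjects_per_class=10,
            sessions_per_subject_range=(1, 1),
            frames_per_session=18_000,
            au_mean_shift=tuple(shift),
            seed=7,
        )
        cohort = generate_cohort(cfg)
        pooled = {
            label: np.vstack([s.au.values for s in cohort if s.label == label])
            for label in ("healthy", "dementia")
        }
        diff = pooled["dementia"].mean(axis=0) - pooled["healthy"].mean(axis=0)
        assert diff[3] == pytest.approx(0.5, abs=0.05)
        assert np.all(np.abs(np.delete(diff, 3)) < 0.05)

    def test_variance_scale_applied(self):
        cfg = CohortConfig(frames_per_session=8000, au_var_scale=4.0, seed=3)
        h = generate_au_sequence("healthy", cfg, np.random.default_rng(5))
        d = generate_au_sequence("dementia", cfg, np.random.default_rng(5))
        ratio = d.values.var(axis=0) / h.values.var(axis=0)
        assert np.median(ratio) == pytest.approx(4.0, rel=0.3)


class TestMeshGeneration:
    def test_degenerate_motion_reproduces_template(self):
        cfg = CohortConfig(
            frames_per_session=4, n_landmarks=30,
            mesh_motion_scale=(1e-30, 1e-30), noise_sd=0.0, seed=0,
        )
        seq = generate_mesh_sequence(
            "healthy", cfg, np.random.default_rng(0), transform=(2.0, np.array([1.0, 2.0, 3.0]))
        )
        expected = face_template(30) * 2.0 + np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(seq.coords[0], expected, atol=1e-12)
        np.testing.assert_allclose(seq.coords[3], expected, atol=1e-12)

    def test_visibility_defaults_to_one(self):
        cfg = CohortConfig(frames_per_session=2, n_landmarks=10)
        seq = generate_mesh_sequence("healthy", cfg, np.random.default_rng(0))
        assert np.array_equal(seq.visibility, np.ones((2, 10)))

    def test_transforms_cancel_after_normalization(self):
        # same motion substream, different cameras -> identical features
        cfg = CohortConfig(frames_per_session=6, n_landmarks=40, seed=0)
        a = generate_mesh_sequence(
            "healthy", cfg, np.random.default_rng(11), transform=(0.7, np.array([1.0, -4.0, 2.0]))
        )
        b = generate_mesh_sequence(
            "healthy", cfg, np.random.default_rng(11), transform=(1.9, np.array([-3.0, 0.5, 8.0]))
        )
        assert np.array_equal(normalize_sequence(a), normalize_sequence(b))

    def test_nonpositive_transform_scale_rejected(self):
        cfg = CohortConfig(frames_per_session=2, n_landmarks=5)
        with pytest.raises(ValueError, match="positive"):
            generate_mesh_sequence(
                "healthy", cfg, np.random.default_rng(0), transform=(0.0, np.zeros(3))
            )


class TestAppearanceGeneration:
    def test_values_nonnegative(self):
        cfg = CohortConfig(frames_per_session=50, n_appearance_dims=100, appearance_noise_sd=3.0)
        values = generate_appearance_sequence("healthy", cfg, np.random.default_rng(0))
        assert values.min() >= 0.0
        assert values.shape == (50, 100)

    def test_bias_offset_is_class_correlated(self):
        cfg = CohortConfig(
            frames_per_session=2000, n_appearance_dims=64,
            appearance_bias=1.5, appearance_bias_dims=8, appearance_signal=0.0,
        )
        h = generate_appearance_sequence("healthy", cfg, np.random.default_rng(1))
        d = generate_appearance_sequence("dementia", cfg, np.random.default_rng(2))
        diff = d.mean(axis=0) - h.mean(axis=0)
        assert np.all(diff[-8:] > 0.5)
        assert np.all(np.abs(diff[:-8]) < 0.3)


class TestCohort:
    def test_seeded_determinism_bit_identical(self):
        cfg = CohortConfig(
            n_subjects_per_class=3, sessions_per_subject_range=(1, 3),
            frames_per_session=64, seed=9,
        )
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert [s.session_id for s in a] == [s.session_id for s in b]
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.au.values, sb.au.values)

    def test_session_count_range(self):
        cfg = CohortConfig(
            n_subjects_per_class=10, sessions_per_subject_range=(1, 10),
            frames_per_session=8, seed=2,
        )
        cohort = generate_cohort(cfg)
        assert 20 <= len(cohort) <= 200
        for subject in cohort.subjects():
            assert 1 <= len(cohort.sessions_for(subject)) <= 10

    def test_single_label_per_subject(self, small_au_cohort):
        _, cohort = small_au_cohort
        for subject in cohort.subjects():
            labels = {s.label for s in cohort.sessions_for(subject)}
            assert len(labels) == 1

    def test_class_sizes_equal(self, small_au_cohort):
        _, cohort = small_au_cohort
        assert len(cohort.subjects("healthy")) == len(cohort.subjects("dementia")) == 4

    def test_adding_subjects_preserves_existing_data(self):
        base = CohortConfig(
            n_subjects_per_class=2, sessions_per_subject_range=(1, 2),
            frames_per_session=32, seed=4,
        )
        small = generate_cohort(base)
        import dataclasses

        big = generate_cohort(dataclasses.replace(base, n_subjects_per_class=4))
        by_id = {s.session_id: s for s in big}
        for s in small:
            assert np.array_equal(s.au.values, by_id[s.session_id].au.values)

    def test_conflicting_labels_rejected(self):
        au = generate_au_sequence(
            "healthy", CohortConfig(frames_per_session=8), np.random.default_rng(0)
        )
        from facescreen.synthetic import Cohort

        with pytest.raises(ValueError, match="two labels"):
            Cohort(
                (
                    Session("A", "A_s0", "healthy", au=au),
                    Session("A", "A_s1", "dementia", au=au),
                )
            )

    def test_mismatched_stream_lengths_rejected(self):
        cfg = CohortConfig(frames_per_session=8)
        au = generate_au_sequence("healthy", cfg, np.random.default_rng(0))
        appearance = np.zeros((9, 4))
        with pytest.raises(ValueError, match="frame count"):
            Session("A", "A_s0", "healthy", au=au, appearance=appearance)
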