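"""Protocol guarantees: leakage-free scaling, fold partitions, the
segment-level pipeline's exact counts, LOSO tiling, and the ablation
harness schema."""

import numpy as np
import pytest

from tanet.backbone import ModelConfig
from tanet.mca import AttentionConfig, MCAFusion
from tanet.protocol import (ABLATION_VARIANTS, InstrumentedScaler,
                            ablation_harness, binarize_scores, build_variant,
                            deap_build_segments, deap_time_extend, loso_split,
                            seed_standardize, stratified_split,
                            subject_cv_folds)
from tanet.training import TrainConfig

rng = np.random.default_rng(0)


class TestStandardisation:
    def test_train_statistics_become_zero_mean_unit_sd(self):
        train = rng.standard_normal((40, 5, 8, 10)) * 3 + 2
        val = rng.standard_normal((10, 5, 8, 10))
        tr, va, scaler = seed_standardize(train, val, "DE")
        for b in range(5):
            assert tr[:, b].mean() == pytest.approx(0.0, abs=1e-10)
            assert tr[:, b].std() == pytest.approx(1.0, abs=1e-10)
        assert scaler.was_fitted_on(train)
        assert not scaler.was_fitted_on(val)

    def test_validation_shift_leaves_train_scaling_unchanged(self):
        train = rng.standard_normal((30, 5, 4, 6))
        val = rng.standard_normal((8, 5, 4, 6))
        tr1, va1, s1 = seed_standardize(train, val, "DE")
        tr2, va2, s2 = seed_standardize(train, val + 100.0, "DE")
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(s1.mean_, s2.mean_)
        assert abs(va2.mean()) > abs(va1.mean())  # val stats do differ

    def test_psd_square_root_then_zscore_arithmetic(self):
        scaler = InstrumentedScaler(modality="PSD")
        scaler.mean_ = np.full((1, 1, 1, 1), 1.0)
        scaler.sd_ = np.full((1, 1, 1, 1), 0.5)
        out = scaler.transform(np.full((1, 1, 1, 1), 4.0))
        assert out.item() == pytest.approx(2.0)   # (sqrt(4) - 1) / 0.5

    def test_zero_variance_band_centred_only(self):
        train = rng.standard_normal((10, 2, 3, 4))
        train[:, 1] = 7.0
        _, _, scaler = seed_standardize(train, train.copy(), "DE")
        assert scaler.sd_.ravel()[1] == 1.0
        out = scaler.transform(train)
        np.testing.assert_allclose(out[:, 1], 0.0, atol=1e-12)


class TestSubjectFolds:
    def test_folds_partition_each_subject(self):
        labels = np.tile(np.repeat([0, 1, 2], 50), 3)
        subjects = np.repeat([0, 1, 2], 150)
        plans = subject_cv_folds(labels, subjects, k=5, seed=1)
        for sid, plan in plans.items():
            union = []
            for fold in range(5):
                tr, va = plan.split(fold)
                assert len(np.intersect1d(tr, va)) == 0
                union.append(va)
            union = np.sort(np.concatenate(union))
            np.testing.assert_array_equal(union, plan.indices)
            # stratification: each fold has ~10 of each class
            for fold in range(5):
                _, va = plan.split(fold)
                counts = np.bincount(labels[va], minlength=3)
                assert (np.abs(counts - 10) <= 1).all()

    def test_same_seed_same_plan(self):
        labels = np.repeat([0, 1, 2], 20)
        subjects = np.zeros(60, dtype=int)
        a = subject_cv_folds(labels, subjects, k=5, seed=3)
        b = subject_cv_folds(labels, subjects, k=5, seed=3)
        np.testing.assert_array_equal(a[0].fold_assignments,
                                      b[0].fold_assignments)

    def test_too_few_samples_per_class_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            subject_cv_folds(np.array([0, 0, 1, 1]), np.zeros(4), k=5)


class TestTimeExtension:
    def test_output_shape_60_steps(self):
        x = rng.standard_normal((3, 32, 5, 58, 4))
        assert deap_time_extend(x).shape == (3, 32, 5, 60)

    def test_constant_tensor_preserved(self):
        out = deap_time_extend(np.full((1, 32, 5, 58, 4), 1.5))
        np.testing.assert_allclose(out, 1.5)

    def test_appended_steps_equal_tail_mean(self):
        x = rng.standard_normal((2, 32, 5, 58, 4))
        out = deap_time_extend(x)
        collapsed = x.mean(axis=-1)
        tail = collapsed[..., -4:].mean(axis=-1)
        np.testing.assert_allclose(out[..., 58], tail)
        np.testing.assert_allclose(out[..., 59], tail)
        np.testing.assert_allclose(out[..., :58], collapsed)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            deap_time_extend(np.zeros((1, 32, 5, 60)))


@pytest.fixture(scope="module")
def deap_fusion():
    return MCAFusion(AttentionConfig(in_dim=60, bidirectional=True),
                     np.random.default_rng(0), layout="deap_like").eval()


class TestSegmentPipeline:
    def test_segment_counts_shapes_and_label_propagation(self, deap_fusion):
        n = 8
        de = rng.standard_normal((n, 32, 5, 60))
        psd = rng.standard_normal((n, 32, 5, 60))
        scores = np.linspace(1, 9, n)
        out = deap_build_segments(de, psd, scores, deap_fusion)
        assert out.segments.shape == (n * 20, 32, 5, 3)
        assert out.labels.shape == (n * 20,)
        assert (out.segments >= 0).all() and (out.segments <= 1).all()
        expected = binarize_scores(scores)
        for t in range(n):
            seg_labels = out.labels[out.provenance[:, 0] == t]
            assert (seg_labels == expected[t]).all()

    def test_provenance_is_bijection(self, deap_fusion):
        n = 5
        de = rng.standard_normal((n, 32, 5, 60))
        out = deap_build_segments(de, de.copy(), np.full(n, 6.0), deap_fusion)
        pairs = {tuple(row) for row in out.provenance}
        assert len(pairs) == n * 20
        assert pairs == {(t, w) for t in range(n) for w in range(20)}

    def test_binarisation_threshold_at_five(self):
        np.testing.assert_array_equal(
            binarize_scores(np.array([4.99, 5.0, 1.0, 9.0])), [0, 1, 0, 1])

    def test_degenerate_minmax_rejected(self, deap_fusion):
        de = np.zeros((2, 32, 5, 60))
        with pytest.raises(ValueError, match="min-max"):
            deap_build_segments(de, de, np.array([6.0, 6.0]), deap_fusion,
                                minmax=(1.0, 1.0))

    def test_leakage_safe_stats_override(self, deap_fusion):
        de = rng.standard_normal((4, 32, 5, 60))
        default = deap_build_segments(de, de.copy(), np.full(4, 6.0),
                                      deap_fusion)
        override = deap_build_segments(de, de.copy(), np.full(4, 6.0),
                                       deap_fusion,
                                       minmax=(default.scale_min - 1.0,
                                               default.scale_max + 1.0))
        assert override.scale_min == default.scale_min - 1.0
        assert not np.allclose(override.segments, default.segments)


class TestSplits:
    def test_stratified_nine_to_one_counts(self):
        labels = rng.integers(0, 2, 2560)
        tr, te = stratified_split(2560, labels, ratio=0.9, seed=0)
        assert len(tr) == 2304 and len(te) == 256
        assert len(np.intersect1d(tr, te)) == 0
        global_ratio = labels.mean()
        test_ratio = labels[te].mean()
        assert abs(test_ratio - global_ratio) <= 1.5 / len(te)

    def test_different_seeds_distinct_reproducible_partitions(self):
        labels = rng.integers(0, 2, 400)
        splits = [stratified_split(400, labels, seed=s) for s in range(10)]
        again = [stratified_split(400, labels, seed=s) for s in range(10)]
        for (a, _), (b, _) in zip(splits, again):
            np.testing.assert_array_equal(a, b)
        unique = {tuple(tr) for tr, _ in splits}
        assert len(unique) == 10

    def test_loso_test_sets_tile_subjects(self):
        subjects = np.repeat(np.arange(32), 3)
        splits = loso_split(subjects)
        assert len(splits) == 32
        all_test = np.sort(np.concatenate([te for _, _, te in splits]))
        np.testing.assert_array_equal(all_test, np.arange(len(subjects)))
        for sid, tr, te in splits:
            assert len(np.intersect1d(tr, te)) == 0
            assert (subjects[te] == sid).all()
            assert (subjects[tr] != sid).all()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            loso_split(np.zeros(10))


class TestAblation:
    def test_variant_construction_swaps_single_module(self, tiny_config):
        full = build_variant(tiny_config, "full", seed=0)
        no_mca = build_variant(tiny_config, "conformer+cbam", seed=0)
        no_cbam = build_variant(tiny_config, "conformer+mca", seed=0)
        no_conf = build_variant(tiny_config, "cbam+mca", seed=0)
        from tanet.nn import count_trainable_parameters as count
        assert count(no_mca) < count(full)
        assert count(no_cbam) < count(full)
        assert count(no_conf) < count(full)
        x = rng.standard_normal((2, 5, 8, 10))
        for m in (full, no_mca, no_cbam, no_conf):
            m.eval()
            assert m.forward(x, np.abs(x)).shape == (2, 3)

    def test_harness_schema_and_self_comparison(self, tiny_config,
                                                tiny_dataset):
        de, psd, y = tiny_dataset
        cfg = TrainConfig(epochs=1, batch_size=32, seed=0, lr=1e-3,
                          early_stop_patience=5)
        table, per_fold = ablation_harness(de, psd, y, tiny_config, cfg,
                                           k=2, seed=0)
        assert list(table.columns) == ["accuracy", "CI", "F1", "kappa", "p"]
        assert set(table.index) == set(ABLATION_VARIANTS)
        assert table.loc["full", "p"] == 1.0
        for variant in ABLATION_VARIANTS:
            assert len(per_fold[variant]) == 2

    def test_unknown_variant_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="variant"):
            build_variant(tiny_config, "nonsense")
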