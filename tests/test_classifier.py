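import dataclasses

import numpy as np
import pytest

from thermoprick.classifier import (
    DESK_CONV_PLAN,
    TABLE1_CONV_PLAN,
    AugmentConfig,
    ReactionClassifier,
    Sample,
    apply_normalization,
    augment_pair,
    build_classifier,
    denormalize,
    extract_roi,
    fit_norm_stats,
    trunk_output_size,
)


def make_sample(rng, size=16, label=0, patient="p0", age=30.0):
    idx = int(patient.lstrip("p") or 0)
    attrs = np.array([idx % 2, age, 60.0 + 3 * idx, 36.2 + 0.1 * (idx % 6)])
    return Sample(visible_roi=rng.random((size, size, 3)),
                  delta_roi=rng.standard_normal((size, size)) * 0.3,
                  attributes=attrs, label=label, patient_id=patient)


class _ScriptedRng:
    """Stand-in RNG emitting a scripted sequence of coin flips / draws."""

    def __init__(self, randoms, uniforms):
        self._randoms = list(randoms)
        self._uniforms = list(uniforms)

    def random(self):
        return self._randoms.pop(0)

    def uniform(self, low, high, size=None):
        v = self._uniforms.pop(0)
        return np.asarray(v) if size is not None else v


class TestExtractRoi:
    def test_interior_crop_is_exact(self, rng):
        img = rng.random((1024, 770, 3))
        roi = extract_roi(img, (500.0, 400.0), 300)
        np.testing.assert_array_equal(roi, img[350:650, 250:550])

    def test_border_center_zero_pads(self, rng):
        img = rng.random((1024, 770))
        roi = extract_roi(img, (20.0, 20.0), 300)
        assert roi.shape == (300, 300)
        # 150 - 20 = 130 rows/cols of padding at the top-left
        assert np.all(roi[:130, :] == 0) and np.all(roi[:, :130] == 0)
        np.testing.assert_array_equal(roi[130:, 130:], img[:170, :170])

    def test_center_outside_image_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_roi(rng.random((100, 100)), (150.0, 50.0), 32)


class TestNormalization:
    def test_stats_from_training_attributes(self, rng):
        samples = [make_sample(rng, age=20.0, patient="p0"),
                   make_sample(rng, age=60.0, patient="p1")]
        stats = fit_norm_stats(samples)
        assert stats.attr_min[1] == 20.0 and stats.attr_max[1] == 60.0

    def test_standardisation_identity_on_training_set(self, rng):
        samples = [make_sample(rng, patient=f"p{i}", age=20.0 + 5 * i)
                   for i in range(6)]
        stats = fit_norm_stats(samples)
        normed = [apply_normalization(s, stats) for s in samples]
        vis = np.stack([s.visible_roi for s in normed])
        assert np.allclose(vis.mean(axis=(0, 1, 2)), 0, atol=1e-6)
        assert np.allclose(vis.std(axis=(0, 1, 2)), 1, atol=1e-6)

    def test_attribute_endpoints_map_to_unit_interval(self, rng):
        samples = [make_sample(rng, age=20.0, patient="p0"),
                   make_sample(rng, age=60.0, patient="p1")]
        stats = fit_norm_stats(samples)
        lo = apply_normalization(samples[0], stats)
        hi = apply_normalization(samples[1], stats)
        assert lo.attributes[1] == pytest.approx(0.0)
        assert hi.attributes[1] == pytest.approx(1.0)
        # out-of-range test attribute exceeds 1: no clipping
        out = apply_normalization(make_sample(rng, age=80.0), stats)
        assert out.attributes[1] > 1.0

    def test_round_trip_inverse(self, rng):
        samples = [make_sample(rng, age=20.0, patient="p0"),
                   make_sample(rng, age=60.0, patient="p1")]
        stats = fit_norm_stats(samples)
        back = denormalize(apply_normalization(samples[0], stats), stats)
        np.testing.assert_allclose(back.visible_roi, samples[0].visible_roi,
                                   atol=1e-9)
        np.testing.assert_allclose(back.attributes, samples[0].attributes,
                                   atol=1e-9)

    def test_constant_channel_rejected(self, rng):
        samples = [make_sample(rng, patient=f"p{i}", age=20.0 + 10 * i)
                   for i in range(3)]
        flat = [dataclasses.replace(s, delta_roi=np.zeros_like(s.delta_roi))
                for s in samples]
        with pytest.raises(ValueError):
            fit_norm_stats(flat)


class TestAugmentPair:
    def test_all_skipped_is_identity(self, rng):
        sample = make_sample(rng)
        fake = _ScriptedRng(randoms=[0.9] * 5, uniforms=[])
        out = augment_pair(sample, AugmentConfig(), fake)
        np.testing.assert_array_equal(out.visible_roi, sample.visible_roi)
        np.testing.assert_array_equal(out.delta_roi, sample.delta_roi)

    def test_hflip_applies_to_both_modalities(self, rng):
        sample = make_sample(rng)
        fake = _ScriptedRng(randoms=[0.1, 0.9, 0.9, 0.9, 0.9], uniforms=[])
        out = augment_pair(sample, AugmentConfig(), fake)
        np.testing.assert_allclose(out.visible_roi,
                                   sample.visible_roi[:, ::-1], atol=1e-6)
        np.testing.assert_allclose(out.delta_roi,
                                   sample.delta_roi[:, ::-1], atol=1e-6)

    def test_integer_translation_is_exact_shift(self, rng):
        sample = make_sample(rng)
        fake = _ScriptedRng(randoms=[0.9, 0.9, 0.9, 0.1, 0.9],
                            uniforms=[(4.0, 0.0)])
        out = augment_pair(sample, AugmentConfig(), fake)
        # output pixel (r, c) shows input pixel (r-4, c)
        np.testing.assert_allclose(out.visible_roi[4:], sample.visible_roi[:-4],
                                   atol=1e-6)
        np.testing.assert_allclose(out.delta_roi[4:], sample.delta_roi[:-4],
                                   atol=1e-6)
        assert np.all(out.delta_roi[:4] == 0)

    def test_label_and_attributes_untouched(self, rng):
        sample = make_sample(rng, label=1)
        out = augment_pair(sample, AugmentConfig(), np.random.default_rng(0))
        assert out.label == 1
        np.testing.assert_array_equal(out.attributes, sample.attributes)

    def test_realised_transform_identical_across_channels(self, rng):
        # encode pixel coordinates as an image placed in both modalities:
        # any mismatch between the two realised transforms shows up as a
        # channel difference
        size = 24
        pattern = np.linspace(0, 1, size * size).reshape(size, size)
        sample = Sample(visible_roi=np.repeat(pattern[:, :, None], 3, axis=2),
                        delta_roi=pattern.copy(),
                        attributes=np.array([0, 30, 70, 36.6]),
                        label=0, patient_id="p")
        rng2 = np.random.default_rng(7)
        for _ in range(25):
            out = augment_pair(sample, AugmentConfig(), rng2)
            np.testing.assert_allclose(out.visible_roi[:, :, 0], out.delta_roi,
                                       atol=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(max_zoom=0.5)
        with pytest.raises(ValueError):
            AugmentConfig(p_each=1.5)


class TestArchitecture:
    def test_pooling_arithmetic_to_3x3(self):
        # 300 -> 149 -> 74 -> 36 -> 17 -> 8 -> 3 through six 3x3/2 pools
        assert trunk_output_size(300, TABLE1_CONV_PLAN) == 3

    def test_full_scale_flatten_dimension(self):
        model = build_classifier("both", roi_size=300, seed=0)
        assert model.flat_features == 256 * 3 * 3 == 2304
        assert model.fc1.weight.value.shape == (64, 2304 + 4)

    def test_input_channels_follow_mode(self):
        for mode, ch in [("both", 4), ("thermal_only", 1),
                         ("visible_only", 3)]:
            model = build_classifier(mode, roi_size=64,
                                     conv_plan=DESK_CONV_PLAN, seed=0)
            assert model.trunk.layers[0].in_channels == ch

    def test_channel_plan_is_respected(self):
        from thermoprick import nn

        model = build_classifier("both", roi_size=300, seed=0)
        convs = [l for l in model.trunk.layers if isinstance(l, nn.Conv2d)]
        assert [c.out_channels for c in convs] == \
            [c for c, _ in TABLE1_CONV_PLAN]
        pools = [l for l in model.trunk.layers if isinstance(l, nn.AvgPool2d)]
        assert len(pools) == sum(p for _, p in TABLE1_CONV_PLAN)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_classifier("infrared", roi_size=64)

    def test_forward_pass_shapes(self, rng):
        model = build_classifier("thermal_only", roi_size=32,
                                 conv_plan=((4, True), (8, True)), seed=0)
        x = rng.standard_normal((3, 1, 32, 32)).astype(np.float32)
        attrs = rng.random((3, 4))
        out = model.forward(x, attrs)
        assert out.shape == (3,)


class TestReactionClassifier:
    def small_cohort(self, rng, n_patients=6):
        samples = []
        for p in range(n_patients):
            for k in range(4):
                label = int(k % 2 == 0)
                s = make_sample(rng, size=16, label=label,
                                patient=f"p{p}", age=20.0 + p)
                # separable signal: positives get a warm delta blob
                if label:
                    s.delta_roi[4:12, 4:12] += 2.0
                samples.append(s)
        return samples

    def clf(self, **kw):
        kw.setdefault("conv_plan", ((4, True), (8, True)))
        kw.setdefault("max_epochs", 5)
        kw.setdefault("batch_size", 8)
        kw.setdefault("seed", 0)
        return ReactionClassifier(input_mode="thermal_only", **kw)

    def test_single_class_training_rejected(self, rng):
        samples = [make_sample(rng, label=0) for _ in range(6)]
        with pytest.raises(ValueError):
            self.clf().fit(samples)

    def test_predict_before_fit_rejected(self, rng):
        with pytest.raises(ValueError):
            self.clf().predict_proba([make_sample(rng)])

    def test_training_is_deterministic_given_seed(self, rng):
        samples = self.small_cohort(rng)
        m1 = self.clf(max_epochs=2).fit(samples)
        m2 = self.clf(max_epochs=2).fit(samples)
        np.testing.assert_array_equal(m1.model_.fc2.weight.value,
                                      m2.model_.fc2.weight.value)
        np.testing.assert_array_equal(m1.predict_proba(samples),
                                      m2.predict_proba(samples))

    def test_learns_separable_cohort(self, rng):
        samples = self.small_cohort(rng, n_patients=8)
        clf = self.clf(max_epochs=10).fit(samples)
        assert clf.loss_history_[-1] < 0.5 * clf.loss_history_[0]
        probs = clf.predict_proba(samples)
        y = np.array([s.label for s in samples])
        assert probs[y == 1].mean() > probs[y == 0].mean()
        assert np.all((probs >= 0) & (probs <= 1))

    def test_duplicate_sample_scores_identically(self, rng):
        samples = self.small_cohort(rng)
        clf = self.clf(max_epochs=2).fit(samples)
        p = clf.predict_proba([samples[0], samples[0]])
        assert p[0] == p[1]
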