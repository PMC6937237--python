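"""Augmentation, extractor contract, neuron sampling, concatenation, layer choice."""

import numpy as np
import pytest

from rgpipe import (
    AugmentedImage,
    FeatureExtractor,
    LesionImage,
    NeuronSample,
    RandomConvExtractor,
    augment,
    concat_sequences,
    extract,
    select_layer,
)
from rgpipe.cnn import CROP_SIZE, _center_view
from rgpipe.core import SEQUENCES


def lesion_image(pixels=None, seed=0):
    if pixels is None:
        pixels = np.random.default_rng(seed).normal(size=(243, 243))
    return LesionImage(pixels, "P0", "T2W", 0, (0, 1, 0, 1))


class TestAugment:
    def test_cardinality_and_center(self):
        views = augment(lesion_image())
        assert len(views) == 72
        offsets = {(v.transform[0], v.transform[1]) for v in views}
        assert len(offsets) == 9
        assert sum(v.is_center for v in views) == 1
        assert len({v.transform for v in views}) == 72
        assert all(v.pixels.shape == (227, 227) for v in views)

    def test_wrong_size_rejected(self):
        bad = lesion_image()
        bad.pixels = np.zeros((227, 227))
        with pytest.raises(ValueError):
            augment(bad)

    def test_constant_input_all_views_equal(self):
        views = augment(lesion_image(np.full((243, 243), 2.0)))
        assert len(views) == 72
        assert all(np.array_equal(v.pixels, views[0].pixels) for v in views)
        assert len({v.transform for v in views}) == 72

    def test_double_hflip_restores_crop(self):
        views = augment(lesion_image(seed=1))
        by_transform = {v.transform: v for v in views}
        for (dx, dy, rot, flip), v in by_transform.items():
            if flip:
                partner = by_transform[(dx, dy, rot, False)]
                assert np.array_equal(np.fliplr(v.pixels), partner.pixels)

    def test_center_view_is_central_crop(self):
        img = lesion_image(seed=2)
        center = next(v for v in augment(img) if v.is_center)
        assert np.array_equal(center.pixels, img.pixels[8:235, 8:235])
        assert np.array_equal(center.pixels, _center_view(img).pixels)


class TestRandomConvExtractor:
    def test_deterministic_and_seed_sensitive(self):
        img = np.random.default_rng(0).random((227, 227)).astype(np.float32)
        a = extract(AugmentedImage(img, (0, 0, 0, False)), RandomConvExtractor(5), "conv5")
        b = extract(AugmentedImage(img, (0, 0, 0, False)), RandomConvExtractor(5), "conv5")
        c = extract(AugmentedImage(img, (0, 0, 0, False)), RandomConvExtractor(6), "conv5")
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_zero_weights_give_zero_vector(self):
        ex = RandomConvExtractor(0)
        for name, (w, b) in ex._conv_w.items():
            ex._conv_w[name] = (np.zeros_like(w), np.zeros_like(b))
        img = np.random.default_rng(1).random((227, 227))
        assert np.all(extract(AugmentedImage(img, (0, 0, 0, False)), ex, "conv3") == 0)

    def test_first_layer_matches_explicit_convolution(self):
        """conv1 activation at a corner equals the direct 11x11x3 dot product."""
        ex = RandomConvExtractor(3)
        rng = np.random.default_rng(2)
        img2d = rng.random((227, 227))
        x = ex.prepare(img2d)
        acts = ex.activations(x)["conv1"].reshape(55, 55, 8)
        w, b = ex._conv_w["conv1"]
        for (i, j, f) in [(0, 0, 0), (3, 7, 5), (54, 54, 7)]:
            patch = x[4 * i : 4 * i + 11, 4 * j : 4 * j + 11, :]
            expect = float((patch * w[:, :, :, f]).sum() + b[f])
            assert acts[i, j, f] == pytest.approx(expect, rel=1e-5)

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError):
            extract(np.zeros((227, 227)), RandomConvExtractor(0), "conv9")


class TestNeuronSampleConcat:
    def test_sample_fixed_and_unique(self):
        a = NeuronSample.draw("conv5", 2704, 1000, seed=9)
        b = NeuronSample.draw("conv5", 2704, 1000, seed=9)
        assert np.array_equal(a.indices, b.indices)
        assert len(np.unique(a.indices)) == 1000
        assert a.indices.max() < 2704

    def test_concat_length_and_order(self):
        sample = NeuronSample("conv5", np.arange(1000), seed=0)
        per_seq = {s: np.full(2704, i, dtype=float) for i, s in enumerate(SEQUENCES)}
        out = concat_sequences(per_seq, sample)
        assert out.shape == (4000,)
        assert np.all(out[:1000] == 0) and np.all(out[3000:] == 3)
        # permuting input map order does not change output order
        reordered = dict(reversed(list(per_seq.items())))
        assert np.array_equal(concat_sequences(reordered, sample), out)

    def test_missing_sequence_rejected(self):
        sample = NeuronSample("conv5", np.arange(10), seed=0)
        with pytest.raises(ValueError):
            concat_sequences({"T1W": np.zeros(100)}, sample)

    def test_single_sequence_subsample_length(self):
        sample = NeuronSample("fc6", np.arange(64), seed=0)
        assert np.asarray(np.zeros(128))[sample.indices].shape == (64,)


class PlantedExtractor(FeatureExtractor):
    """Two layers: 'signal' carries image summary statistics, 'noise' is a
    deterministic pseudorandom function of the image, uninformative of role."""

    @property
    def layer_names(self):
        return ("signal", "noise")

    @property
    def layer_dims(self):
        return {"signal": 8, "noise": 8}

    def activations(self, image):
        m = float(image.mean())
        s = float(image.std())
        sig = np.array([m, s, m + s, m - s, m * 2, s * 2, m / 2, s / 2])
        h = np.random.default_rng(abs(hash(round(m, 6))) % 2**31)
        return {"signal": sig, "noise": h.normal(size=8)}


def test_select_layer_finds_planted_layer(small_cohort):
    from rgpipe.orchestrate import lesion_images_for

    _, cohort = small_cohort
    lesion, normal = {}, {}
    for rec in cohort:
        if rec.normal_voi is None:
            continue
        lesion[rec.patient_id] = lesion_images_for(rec)
        normal[rec.patient_id] = lesion_images_for(rec, rec.normal_voi)
    best, report = select_layer(
        lesion,
        normal,
        PlantedExtractor(),
        k_neurons=8,
        seed=0,
        outer_k=3,
        inner_k=2,
        cost_grid=(1.0,),
        use_augmentation=False,
    )
    assert best == "signal"
    assert set(report) == {"signal", "noise"}
    assert report["signal"]["mean_accuracy"] > report["noise"]["mean_accuracy"]
    for layer in report:
        assert {"mean_accuracy", "ci95_halfwidth", "mean_auprc"} <= set(report[layer])


def test_select_layer_single_layer_trivial(small_cohort):
    from rgpipe.orchestrate import lesion_images_for

    class OneLayer(PlantedExtractor):
        @property
        def layer_names(self):
            return ("signal",)

        @property
        def layer_dims(self):
            return {"signal": 8}

        def activations(self, image):
            return {"signal": super().activations(image)["signal"]}

    _, cohort = small_cohort
    lesion, normal = {}, {}
    for rec in cohort:
        if rec.normal_voi is None:
            continue
        lesion[rec.patient_id] = lesion_images_for(rec)
        normal[rec.patient_id] = lesion_images_for(rec, rec.normal_voi)
    best, _ = select_layer(
        lesion, normal, OneLayer(), k_neurons=8, seed=0, outer_k=2, inner_k=2,
        cost_grid=(1.0,), use_augmentation=False,
    )
    assert best == "signal"
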