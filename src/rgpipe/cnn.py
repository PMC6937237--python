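"""Convolutional texture features: augmentation, extraction, concatenation.

The 243x243 lesion image is augmented into 72 views (nine 227x227 crops at
shifts of 0/±8 pixels about the center, times four right-angle rotations,
times horizontal flip or not).  All views feed network training downstream;
scoring uses only the center view (no shift, rotation or flip).

Feature extraction is behind the :class:`FeatureExtractor` contract: any
deterministic network exposing per-layer activation vectors (ReLU and dropout
layers excluded) can back it.  The shipped backend is
:class:`RandomConvExtractor`, a fixed-seed random-weight convolutional stack
with an AlexNet-like topology (five conv layers, three fully connected).
Random convolutional projections preserve texture statistics well enough to
drive the layer-selection and classification mechanics, and they make every
analysis runnable without any network download; the extractor seed is part of
the experiment provenance.

Per layer, a fixed random subsample of neurons (default 1000) is drawn once
per analysis and reused for every patient and every train/test split; the
subsampled vectors of the four sequences are concatenated in fixed order
(T1W | T2W | GdT1W | FLAIR), giving 4000 features at the default sample size.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from itertools import product

import numpy as np

from .core import SEQUENCES, child_seed
from .preprocess import LESION_IMAGE_SIZE, LesionImage

CROP_SIZE = 227
CROP_SHIFTS = (-8, 0, 8)
ROTATIONS = (0, 90, 180, 270)


@dataclass
class AugmentedImage:
    """A 227x227 view of a lesion image with its transform provenance."""

    pixels: np.ndarray
    transform: tuple[int, int, int, bool]  # (dx, dy, rotation_deg, hflip)
    parent: LesionImage | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError("augmented image must be 227x227")

    @property
    def is_center(self) -> bool:
        return self.transform == (0, 0, 0, False)


def augment(image: LesionImage) -> list[AugmentedImage]:
    """All 72 augmented views of a lesion image, in a fixed order.

    Order: crop shifts (dx outer, dy inner, each -8/0/+8), then rotation
    (0/90/180/270 degrees counterclockwise), then horizontal flip (no/yes).
    Exactly one view (dx=dy=0, no rotation, no flip) is the center view.
    """
    px = image.pixels
    if px.shape != (LESION_IMAGE_SIZE, LESION_IMAGE_SIZE):
        raise ValueError("augment expects a 243x243 lesion image")
    base = (LESION_IMAGE_SIZE - CROP_SIZE) // 2  # 8
    out: list[AugmentedImage] = []
    for dx, dy in product(CROP_SHIFTS, CROP_SHIFTS):
        crop = px[base + dy : base + dy + CROP_SIZE, base + dx : base + dx + CROP_SIZE]
        for rot in ROTATIONS:
            rotated = np.rot90(crop, k=rot // 90)
            for flip in (False, True):
                view = np.fliplr(rotated) if flip else rotated
                out.append(AugmentedImage(np.ascontiguousarray(view), (dx, dy, rot, flip), image))
    return out


class FeatureExtractor(ABC):
    """Contract for a deterministic per-layer activation extractor.

    ``activations`` maps a 227x227x3 image to one flat real vector per
    exposed layer; exposed layers exclude ReLU and dropout.  Identical input
    must give identical activations.
    """

    @property
    @abstractmethod
    def layer_names(self) -> tuple[str, ...]: ...

    @property
    @abstractmethod
    def layer_dims(self) -> dict[str, int]: ...

    @abstractmethod
    def activations(self, image: np.ndarray) -> dict[str, np.ndarray]: ...

    def prepare(self, pixels2d: np.ndarray) -> np.ndarray:
        """Replicate a single-channel image to the 3 input channels."""
        px = np.asarray(pixels2d, dtype=np.float32)
        if px.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError("extractor input must be 227x227")
        return np.repeat(px[:, :, None], 3, axis=2)


def extract(
    image: AugmentedImage | np.ndarray, extractor: FeatureExtractor, layer: str
) -> np.ndarray:
    """Activation vector of one exposed layer for one augmented image."""
    if layer not in extractor.layer_names:
        raise ValueError(f"unknown layer {layer!r}")
    pixels = image.pixels if isinstance(image, AugmentedImage) else np.asarray(image)
    return extractor.activations(extractor.prepare(pixels))[layer]


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int):
    # x: (H, W, Cin); w: (kh*kw*Cin, Cout)
    kh, kw, cin, cout = w.shape
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(0, 1))
    windows = windows[::stride, ::stride]  # (oh, ow, Cin, kh, kw)
    oh, ow = windows.shape[:2]
    # reorder to (oh*ow, kh*kw*Cin) matching w layout (kh, kw, Cin)
    cols = windows.transpose(0, 1, 3, 4, 2).reshape(oh * ow, kh * kw * cin)
    out = cols @ w.reshape(kh * kw * cin, cout) + b
    return out.reshape(oh, ow, cout)


def _maxpool(x: np.ndarray, size: int = 3, stride: int = 2) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(x, (size, size), axis=(0, 1))
    return windows[::stride, ::stride].max(axis=(-2, -1))


class RandomConvExtractor(FeatureExtractor):
    """Fixed-seed random-weight convolutional stack with AlexNet-like topology.

    Five convolutional layers and three fully connected layers; exposed
    features are the pre-ReLU outputs of each layer, flattened.  Weights are
    He-initialized from a seeded generator, so the extractor is a pure
    deterministic function of (seed, input).
    """

    _ARCH = (  # name, kernel, stride, pad, channels, pool_after
        ("conv1", 11, 4, 0, 8, True),
        ("conv2", 5, 1, 2, 16, True),
        ("conv3", 3, 1, 1, 24, False),
        ("conv4", 3, 1, 1, 24, False),
        ("conv5", 3, 1, 1, 16, True),
    )
    _FC = (("fc6", 128), ("fc7", 128), ("fc8", 16))

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self._conv_w: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        cin = 3
        size = CROP_SIZE
        dims: dict[str, int] = {}
        for name, k, stride, pad, cout, pool in self._ARCH:
            fan_in = k * k * cin
            w = (rng.standard_normal((k, k, cin, cout)) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )
            b = np.zeros(cout, dtype=np.float32)
            self._conv_w[name] = (w, b)
            size = (size + 2 * pad - k) // stride + 1
            dims[name] = size * size * cout
            if pool:
                size = (size - 3) // 2 + 1
            cin = cout
        self._fc_w: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        fan_in = size * size * cin
        for name, width in self._FC:
            w = (rng.standard_normal((fan_in, width)) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )
            self._fc_w[name] = (w, np.zeros(width, dtype=np.float32))
            dims[name] = width
            fan_in = width
        self._dims = dims

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(self._dims)

    @property
    def layer_dims(self) -> dict[str, int]:
        return dict(self._dims)

    def activations(self, image: np.ndarray) -> dict[str, np.ndarray]:
        x = np.asarray(image, dtype=np.float32)
        if x.shape != (CROP_SIZE, CROP_SIZE, 3):
            raise ValueError("input must be 227x227x3")
        out: dict[str, np.ndarray] = {}
        for name, k, stride, pad, cout, pool in self._ARCH:
            w, b = self._conv_w[name]
            pre = _conv2d(x, w, b, stride, pad)
            out[name] = pre.ravel().astype(np.float64)
            x = np.maximum(pre, 0.0)
            if pool:
                x = _maxpool(x)
        v = x.ravel()
        for name, _ in self._FC:
            w, b = self._fc_w[name]
            pre = v @ w + b
            out[name] = pre.astype(np.float64)
            v = np.maximum(pre, 0.0)
        return out


@dataclass
class NeuronSample:
    """A fixed random subsample of neuron indices within one layer.

    Drawn once per analysis and reused for every patient and split, so the
    feature space is identical on both sides of any train/test division.
    """

    layer: str
    indices: np.ndarray
    seed: int

    @classmethod
    def draw(cls, layer: str, layer_dim: int, k: int, seed: int) -> "NeuronSample":
        rng = np.random.default_rng(child_seed(seed, f"neurons:{layer}"))
        k_eff = min(k, layer_dim)
        idx = np.sort(rng.choice(layer_dim, size=k_eff, replace=False))
        return cls(layer, idx, seed)


def concat_sequences(
    per_sequence: dict[str, np.ndarray], sample: NeuronSample
) -> np.ndarray:
    """Subsample each sequence's layer vector and concatenate in fixed order.

    Order is T1W | T2W | GdT1W | FLAIR; length is 4x the sample size (4000 at
    the default 1000 neurons per layer).  Input map order is irrelevant.
    """
    missing = [s for s in SEQUENCES if s not in per_sequence]
    if missing:
        raise ValueError(f"missing sequences: {missing}")
    parts = [np.asarray(per_sequence[s])[sample.indices] for s in SEQUENCES]
    return np.concatenate(parts)


def patient_cnn_matrix(
    lesion_images: dict[str, LesionImage],
    extractor: FeatureExtractor,
    layer: str,
    sample: NeuronSample,
    use_augmentation: bool = True,
) -> tuple[np.ndarray, int]:
    """Feature matrix (views x features) for one patient VOI.

    Row r concatenates, across the four sequences, the subsampled layer
    activations of augmented view r (the same transform applied to every
    sequence).  Returns the matrix and the row index of the center view.
    """
    per_seq_views: dict[str, list[np.ndarray]] = {}
    center_row = -1
    for seq in SEQUENCES:
        views = (
            augment(lesion_images[seq])
            if use_augmentation
            else [_center_view(lesion_images[seq])]
        )
        per_seq_views[seq] = [extract(v, extractor, layer) for v in views]
        if center_row < 0:
            center_row = next(i for i, v in enumerate(views) if v.is_center)
    n_views = len(per_seq_views[SEQUENCES[0]])
    rows = [
        concat_sequences({s: per_seq_views[s][r] for s in SEQUENCES}, sample)
        for r in range(n_views)
    ]
    return np.vstack(rows), center_row


def _center_view(image: LesionImage) -> AugmentedImage:
    base = (LESION_IMAGE_SIZE - CROP_SIZE) // 2
    crop = image.pixels[base : base + CROP_SIZE, base : base + CROP_SIZE]
    return AugmentedImage(np.ascontiguousarray(crop), (0, 0, 0, False), image)


def select_layer(
    lesion_images: dict[str, dict[str, LesionImage]],
    normal_images: dict[str, dict[str, LesionImage]],
    extractor: FeatureExtractor,
    k_neurons: int = 1000,
    seed: int = 0,
    outer_k: int = 10,
    inner_k: int = 5,
    cost_grid: np.ndarray | None = None,
    use_augmentation: bool = True,
) -> tuple[str, dict[str, dict[str, float]]]:
    """Pick the extractor layer that best separates lesion from normal tissue.

    For each exposed layer, runs the patient-grouped nested-CV lesion-vs-normal
    classification on subsampled features (each patient contributes one lesion
    and one mirrored-normal sample, kept in the same fold) and returns the
    layer with the highest mean balanced accuracy, plus a per-layer report of
    mean accuracy with 95% CI half-width and mean AUPRC.

    ``lesion_images`` / ``normal_images`` map patient id -> sequence ->
    lesion image; only patients present in both (valid mirrored VOI) are used.
    """
    from .classify import Sample, make_folds, nested_cv
    from .stats import ci95

    pids = sorted(set(lesion_images) & set(normal_images))
    if len(pids) < 2:
        raise ValueError("need at least two patients with valid normal VOIs")

    # One forward pass per image; cache subsampled activations per layer.
    samples_by_layer: dict[str, list] = {name: [] for name in extractor.layer_names}
    neuron = {
        name: NeuronSample.draw(name, extractor.layer_dims[name], k_neurons, seed)
        for name in extractor.layer_names
    }
    for pid in pids:
        for role, images in (("lesion", lesion_images[pid]), ("normal", normal_images[pid])):
            per_seq_all: dict[str, list[dict[str, np.ndarray]]] = {}
            center_row = -1
            for seq in SEQUENCES:
                views = (
                    augment(images[seq]) if use_augmentation else [_center_view(images[seq])]
                )
                per_seq_all[seq] = [
                    extractor.activations(extractor.prepare(v.pixels)) for v in views
                ]
                if center_row < 0:
                    center_row = next(i for i, v in enumerate(views) if v.is_center)
            n_views = len(per_seq_all[SEQUENCES[0]])
            for name in extractor.layer_names:
                rows = [
                    concat_sequences(
                        {s: per_seq_all[s][r][name] for s in SEQUENCES}, neuron[name]
                    )
                    for r in range(n_views)
                ]
                samples_by_layer[name].append(
                    Sample(f"{pid}:{role}", pid, role, np.vstack(rows), center_row)
                )

    plan = make_folds(pids, None, k=outer_k, seed=child_seed(seed, "layer-cv"),
                      stratified=False, inner_k=inner_k)
    report: dict[str, dict[str, float]] = {}
    best_layer, best_acc = "", -1.0
    for name in extractor.layer_names:
        res = nested_cv(samples_by_layer[name], plan, cost_grid=cost_grid)
        accs = [f.balanced_accuracy for f in res.per_fold]
        report[name] = {
            "mean_accuracy": res.mean_accuracy,
            "ci95_halfwidth": ci95(accs) if len(accs) > 1 else 0.0,
            "mean_auprc": float(np.mean([f.auprc for f in res.per_fold])),
        }
        if res.mean_accuracy > best_acc:
            best_layer, best_acc = name, res.mean_accuracy
    return best_layer, report
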