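"""Per-site reaction classification.

A *sample* is one allergen application site: a visible-spectrum ROI cut
from the post-application image, the matching crop of the delta thermal
image (same coordinates — the two modalities are pixel-correlated), four
patient attributes (sex, age, weight, body temperature) and a binary
reaction label.

The classifier is a convolutional network whose trunk follows a fixed
channel plan (3x3 convs, batch norm, LeakyReLU, 3x3/stride-2 average
pooling after flagged layers); the flattened features are concatenated
with the attributes and passed through a dense 64 -> LeakyReLU ->
Dropout(0.5) -> dense 1 head.  A single logit with sigmoid/BCE is used
(equivalent to a 2-way softmax with cross-entropy).  Optimisation is Adam
with decoupled weight decay 1e-4 at lr 0.001, early-stopped at a fixed
epoch budget.

Input spectra variants: ``both`` fuses visible + delta into a 4-channel
tensor; ``thermal_only`` uses the 1-channel delta; ``visible_only`` the
3-channel visible ROI.  Augmentation (flips, rotation <=45 deg, translation
<=4 px, zoom <=1.3, each with probability 0.5) applies the *identical*
realised geometric transform to both images of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .imaging import PatientRecord, Segment
from .registration import DeltaImage

#: (out_channels, pool_after) sequence of the full-scale trunk
TABLE1_CONV_PLAN: Tuple[Tuple[int, bool], ...] = (
    (32, True), (64, True), (64, False), (128, False), (128, True),
    (256, False), (256, True), (256, False), (256, True), (256, False),
    (256, True),
)

#: reduced trunk for desk-scale (64x64 ROI) experiments
DESK_CONV_PLAN: Tuple[Tuple[int, bool], ...] = (
    (16, True), (32, True), (32, False), (64, True), (64, True),
)

INPUT_CHANNELS = {"both": 4, "thermal_only": 1, "visible_only": 3}


@dataclass
class Sample:
    """One application site ready for classification."""

    visible_roi: np.ndarray          # (S, S, 3)
    delta_roi: np.ndarray            # (S, S) degC difference
    attributes: np.ndarray           # [sex01, age, weight, body_temperature]
    label: int
    patient_id: str
    site_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.visible_roi = np.asarray(self.visible_roi, dtype=np.float64)
        self.delta_roi = np.asarray(self.delta_roi, dtype=np.float64)
        self.attributes = np.asarray(self.attributes, dtype=np.float64)
        s = self.visible_roi.shape[0]
        if self.visible_roi.shape != (s, s, 3) or self.delta_roi.shape != (s, s):
            raise ValueError("ROIs must be square and share their size")
        if self.attributes.shape != (4,) or not np.all(np.isfinite(self.attributes)):
            raise ValueError("attributes must be a finite 4-vector")

    @property
    def roi_size(self) -> int:
        return self.visible_roi.shape[0]


@dataclass
class AugmentConfig:
    p_each: float = 0.5
    max_rotation_deg: float = 45.0
    max_translation_px: float = 4.0
    max_zoom: float = 1.3
    flips: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_each <= 1.0:
            raise ValueError("p_each must be in [0, 1]")
        if self.max_zoom < 1.0:
            raise ValueError("max_zoom must be >= 1")


@dataclass
class NormStats:
    """Normalisation statistics, fitted on training data only."""

    image_mean: np.ndarray  # (4,): visible RGB then delta
    image_std: np.ndarray   # (4,)
    attr_min: np.ndarray    # (4,)
    attr_max: np.ndarray    # (4,)
    train_patient_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if np.any(self.image_std <= 0):
            raise ValueError("zero-variance image channel")
        if np.any(self.attr_max <= self.attr_min):
            raise ValueError("degenerate attribute range")


# ---------------------------------------------------------------------------
# sample assembly
# ---------------------------------------------------------------------------

def extract_roi(image: np.ndarray, center: Tuple[float, float],
                size: int = 300) -> np.ndarray:
    """Square crop centred on *center*; out-of-bounds area is zero-padded.

    Raises if the center itself lies outside the image.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    cr, cc = center
    if not (0 <= cr < h and 0 <= cc < w):
        raise ValueError(f"ROI center {center} outside image {h}x{w}")
    r0 = int(round(cr)) - size // 2
    c0 = int(round(cc)) - size // 2
    out_shape = (size, size) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    sr0, sr1 = max(r0, 0), min(r0 + size, h)
    sc0, sc1 = max(c0, 0), min(c0 + size, w)
    if sr0 < sr1 and sc0 < sc1:
        out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return out


def encode_attributes(patient: PatientRecord) -> np.ndarray:
    """[sex as {0,1}, age, weight, body temperature]; height is not used."""
    return np.array([0.0 if patient.sex == "M" else 1.0,
                     patient.age, patient.weight, patient.body_temperature])


def samples_from_case(case, delta: DeltaImage,
                      segments: Optional[Sequence[Segment]] = None,
                      roi_size: int = 300,
                      max_match_distance: float = 40.0) -> List[Sample]:
    """Cut one Sample per segment of a synthetic case.

    Visible ROIs come from the post-series visible image; delta ROIs from
    the delta image at the same coordinates.  When *segments* is None the
    ground-truth annotations act as manual segmentation.  Detected segments
    are matched to the nearest annotated site (within
    *max_match_distance* px, post frame) to inherit its label.
    """
    attrs = encode_attributes(case.patient)
    ann_centers = case.true_transform.apply(
        np.array([a.injection_point for a in case.annotations]))
    post_vis = case.post.visible.pixels
    out: List[Sample] = []
    if segments is None:
        centers = ann_centers
        matched = list(range(len(case.annotations)))
    else:
        centers = [np.asarray(s.center, dtype=np.float64) for s in segments]
        matched = []
        for c in centers:
            d = np.linalg.norm(ann_centers - c, axis=1)
            matched.append(int(np.argmin(d)) if d.min() <= max_match_distance
                           else -1)
    for center, j in zip(centers, matched):
        if j < 0:
            continue
        out.append(Sample(
            visible_roi=extract_roi(post_vis, tuple(center), roi_size),
            delta_roi=extract_roi(delta.pixels, tuple(center), roi_size),
            attributes=attrs,
            label=int(case.labels[j]),
            patient_id=case.patient.patient_id,
            site_id=case.annotations[j].site_id,
        ))
    return out


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def fit_norm_stats(train_samples: Sequence[Sample]) -> NormStats:
    """Per-channel image mean/std and per-attribute min/max over the
    training set (and only the training set).

    A zero-variance image channel is an error.  An attribute that is
    constant across the training patients (possible in very small folds)
    carries no information; its range is widened to 1 so min-max rescaling
    maps it to a constant 0 instead of dividing by zero.
    """
    if len(train_samples) < 2:
        raise ValueError("need >=2 training samples")
    vis = np.stack([s.visible_roi for s in train_samples])
    dlt = np.stack([s.delta_roi for s in train_samples])
    mean = np.concatenate([vis.mean(axis=(0, 1, 2)), [dlt.mean()]])
    std = np.concatenate([vis.std(axis=(0, 1, 2)), [dlt.std()]])
    attrs = np.stack([s.attributes for s in train_samples])
    amin, amax = attrs.min(axis=0), attrs.max(axis=0)
    amax = np.where(amax > amin, amax, amin + 1.0)
    return NormStats(image_mean=mean, image_std=std,
                     attr_min=amin, attr_max=amax,
                     train_patient_ids=frozenset(s.patient_id
                                                 for s in train_samples))


def apply_normalization(sample: Sample, stats: NormStats) -> Sample:
    """Standardise image channels; min-max rescale attributes (no clipping,
    so out-of-range test values may fall outside [0, 1])."""
    vis = (sample.visible_roi - stats.image_mean[:3]) / stats.image_std[:3]
    dlt = (sample.delta_roi - stats.image_mean[3]) / stats.image_std[3]
    attrs = (sample.attributes - stats.attr_min) / (stats.attr_max - stats.attr_min)
    return replace(sample, visible_roi=vis, delta_roi=dlt, attributes=attrs,
                   normalized=True)


def denormalize(sample: Sample, stats: NormStats) -> Sample:
    vis = sample.visible_roi * stats.image_std[:3] + stats.image_mean[:3]
    dlt = sample.delta_roi * stats.image_std[3] + stats.image_mean[3]
    attrs = sample.attributes * (stats.attr_max - stats.attr_min) + stats.attr_min
    return replace(sample, visible_roi=vis, delta_roi=dlt, attributes=attrs,
                   normalized=False)


# ---------------------------------------------------------------------------
# paired augmentation
# ---------------------------------------------------------------------------

def _augment_matrix(size: int, hflip: bool, vflip: bool, angle_deg: float,
                    translation: Tuple[float, float], zoom: float) -> np.ndarray:
    """Output <- input affine map in (row, col) homogeneous coordinates.

    Flips, rotation and zoom act about the patch center; the translation is
    applied last: output pixel (r, c) shows input content from
    (r, c) - translation.
    """
    c = (size - 1) / 2.0

    def about_center(lin: np.ndarray) -> np.ndarray:
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = np.array([c, c]) - lin @ np.array([c, c])
        return m

    m = np.eye(3)
    if hflip:
        m = about_center(np.diag([1.0, -1.0])) @ m
    if vflip:
        m = about_center(np.diag([-1.0, 1.0])) @ m
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    m = about_center(rot) @ m
    m = about_center(zoom * np.eye(2)) @ m
    t = np.eye(3)
    t[:2, 2] = translation
    return t @ m


def _warp_channels(image: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(matrix)
    kwargs = dict(matrix=inv[:2, :2], offset=inv[:2, 2], order=1,
                  mode="constant", cval=0.0)
    if image.ndim == 2:
        return ndimage.affine_transform(image, **kwargs)
    return np.stack([ndimage.affine_transform(image[..., k], **kwargs)
                     for k in range(image.shape[2])], axis=-1)


def augment_pair(sample: Sample, config: AugmentConfig,
                 rng: np.random.Generator) -> Sample:
    """Randomly transform a sample, identically for both modalities.

    Each of {hflip, vflip, rotation, translation, zoom} is independently
    applied with probability ``p_each``; parameters are drawn uniformly.
    One realised transform chain is applied to the visible ROI and the
    delta ROI alike; attributes and label are untouched.
    """
    hflip = config.flips and rng.random() < config.p_each
    vflip = config.flips and rng.random() < config.p_each
    angle = (rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
             if rng.random() < config.p_each else 0.0)
    translation = (tuple(rng.uniform(-config.max_translation_px,
                                     config.max_translation_px, size=2))
                   if rng.random() < config.p_each else (0.0, 0.0))
    zoom = (rng.uniform(1.0, config.max_zoom)
            if rng.random() < config.p_each else 1.0)
    if not (hflip or vflip or angle or zoom != 1.0
            or translation != (0.0, 0.0)):
        return sample
    m = _augment_matrix(sample.roi_size, hflip, vflip, angle, translation, zoom)
    return replace(sample,
                   visible_roi=_warp_channels(sample.visible_roi, m),
                   delta_roi=_warp_channels(sample.delta_roi, m))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def trunk_output_size(roi_size: int,
                      conv_plan: Sequence[Tuple[int, bool]]) -> int:
    """Spatial side after the trunk: same-padded convs leave the size
    unchanged; each 3x3/stride-2 unpadded pool maps n -> floor((n-3)/2)+1."""
    s = roi_size
    for _, pool in conv_plan:
        if pool:
            s = nn.AvgPool2d.out_size(s)
    if s < 1:
        raise ValueError("ROI too small for this conv plan")
    return s


class ReactionCNN:
    """Convolutional trunk per the channel plan + attribute-fused dense head."""

    def __init__(self, in_channels: int, roi_size: int,
                 conv_plan: Sequence[Tuple[int, bool]] = TABLE1_CONV_PLAN,
                 dense_units: int = 64, leaky_slope: float = 0.01,
                 dropout: float = 0.5,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        layers: List[nn.Layer] = []
        c = in_channels
        for out_c, pool in conv_plan:
            layers += [nn.Conv2d(c, out_c, 3, rng=rng),
                       nn.BatchNorm2d(out_c),
                       nn.LeakyReLU(leaky_slope)]
            if pool:
                layers.append(nn.AvgPool2d(3, 2))
            c = out_c
        self.trunk = nn.Sequential(*layers)
        side = trunk_output_size(roi_size, conv_plan)
        self.flat_features = c * side * side
        self.fc1 = nn.Linear(self.flat_features + 4, dense_units, rng=rng)
        self.act = nn.LeakyReLU(leaky_slope)
        self.drop = nn.Dropout(dropout, rng=rng)
        self.fc2 = nn.Linear(dense_units, 1, rng=rng)
        self._trunk_shape: Optional[Tuple[int, ...]] = None

    def parameters(self) -> List[nn.Parameter]:
        return (self.trunk.parameters() + self.fc1.parameters()
                + self.fc2.parameters())

    def forward(self, x: np.ndarray, attrs: np.ndarray,
                train: bool = False) -> np.ndarray:
        feats = self.trunk.forward(x, train)
        self._trunk_shape = feats.shape
        flat = feats.reshape(feats.shape[0], -1)
        z = np.concatenate([flat, attrs.astype(np.float32)], axis=1)
        z = self.fc1.forward(z, train)
        z = self.act.forward(z, train)
        z = self.drop.forward(z, train)
        return self.fc2.forward(z, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc2.backward(dlogits[:, None])
        d = self.act.backward(self.drop.backward(d))
        d = self.fc1.backward(d)
        d_img = d[:, :self.flat_features].reshape(self._trunk_shape)
        self.trunk.backward(np.ascontiguousarray(d_img))


def build_classifier(input_mode: str = "both", roi_size: int = 300,
                     conv_plan: Sequence[Tuple[int, bool]] = TABLE1_CONV_PLAN,
                     seed: int = 0, **kwargs) -> ReactionCNN:
    if input_mode not in INPUT_CHANNELS:
        raise ValueError(f"unknown input_mode {input_mode!r}")
    return ReactionCNN(INPUT_CHANNELS[input_mode], roi_size, conv_plan,
                       rng=np.random.Generator(np.random.PCG64(seed)), **kwargs)


def _sample_tensor(samples: Sequence[Sample], input_mode: str) -> np.ndarray:
    def channels(s: Sample) -> np.ndarray:
        vis = s.visible_roi.transpose(2, 0, 1)
        dlt = s.delta_roi[None]
        if input_mode == "both":
            return np.concatenate([vis, dlt], axis=0)
        if input_mode == "thermal_only":
            return dlt
        if input_mode == "visible_only":
            return vis
        raise ValueError(f"unknown input_mode {input_mode!r}")
    return np.stack([channels(s) for s in samples]).astype(np.float32)


class ReactionClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style estimator around :class:`ReactionCNN`.

    ``fit`` takes raw (unnormalised) :class:`Sample` sequences: it fits
    :class:`NormStats` on them, trains with per-epoch paired augmentation,
    and stores ``model_``, ``norm_stats_`` and ``loss_history_``.
    ``predict_proba`` normalises incoming samples with the *stored* stats
    (no augmentation at inference).
    """

    def __init__(self, input_mode: str = "both",
                 conv_plan: Sequence[Tuple[int, bool]] = TABLE1_CONV_PLAN,
                 dense_units: int = 64, leaky_slope: float = 0.01,
                 dropout: float = 0.5, lr: float = 0.001,
                 weight_decay: float = 1e-4, max_epochs: int = 80,
                 batch_size: int = 32, augment: bool = True,
                 augment_config: Optional[AugmentConfig] = None,
                 seed: int = 0):
        self.input_mode = input_mode
        self.conv_plan = conv_plan
        self.dense_units = dense_units
        self.leaky_slope = leaky_slope
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.augment = augment
        self.augment_config = augment_config
        self.seed = seed

    def fit(self, samples: Sequence[Sample],
            labels: Optional[Sequence[int]] = None) -> "ReactionClassifier":
        if self.input_mode not in INPUT_CHANNELS:
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        samples = list(samples)
        y = np.array([s.label for s in samples] if labels is None else labels,
                     dtype=np.float32)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.norm_stats_ = fit_norm_stats(samples)
        normed = [apply_normalization(s, self.norm_stats_) for s in samples]
        roi = normed[0].roi_size
        rng = np.random.Generator(np.random.PCG64(self.seed))
        aug_rng = np.random.Generator(np.random.PCG64(self.seed + 1))
        self.model_ = ReactionCNN(INPUT_CHANNELS[self.input_mode], roi,
                                  self.conv_plan, self.dense_units,
                                  self.leaky_slope, self.dropout, rng=rng)
        self.model_.drop.rng = rng
        opt = nn.AdamW(self.model_.parameters(), lr=self.lr,
                       weight_decay=self.weight_decay)
        aug_cfg = self.augment_config or AugmentConfig()
        self.loss_history_ = []
        n = len(normed)
        self.classes_ = np.array([0, 1])
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                batch = [normed[i] for i in idx]
                if self.augment:
                    batch = [augment_pair(s, aug_cfg, aug_rng) for s in batch]
                x = _sample_tensor(batch, self.input_mode)
                attrs = np.stack([s.attributes for s in batch])
                logits = self.model_.forward(x, attrs, train=True)
                loss, dl = nn.bce_with_logits(logits, y[idx])
                opt.zero_grad()
                self.model_.backward(dl)
                opt.step()
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict_proba(self, samples: Sequence[Sample]) -> np.ndarray:
        """Reaction probability per sample (sigmoid of the single logit)."""
        if not hasattr(self, "model_"):
            raise ValueError("classifier is not fitted (no stored NormStats)")
        normed = [s if s.normalized else apply_normalization(s, self.norm_stats_)
                  for s in samples]
        probs = np.empty(len(normed))
        for start in range(0, len(normed), 64):
            batch = normed[start:start + 64]
            x = _sample_tensor(batch, self.input_mode)
            attrs = np.stack([s.attributes for s in batch])
            probs[start:start + len(batch)] = nn.sigmoid(
                self.model_.forward(x, attrs, train=False))
        return probs

    def predict(self, samples: Sequence[Sample]) -> np.ndarray:
        return (self.predict_proba(samples) >= 0.5).astype(int)
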