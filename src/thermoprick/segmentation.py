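"""Finding the eight allergen application sites on a forearm image.

The stages mirror how a prick-test reader has to work:

1. ground-truth masks are built from manual annotations (a filled disc per
   site, radius = distance from injection point to the highlighter mark);
2. a U-Net predicts a per-pixel marker probability map from the visible
   image (markers are drawn in ink and are invisible in thermal);
3. connected components of the thresholded map become candidate segments,
   filtered by bounding-box size and aspect ratio;
4. a grid-completion heuristic arranges the surviving segments into the
   2x4 application grid and synthesises any missing positions from the
   grid pitch, so that downstream marker matching always has eight
   correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure
from skimage.transform import resize
from sklearn.base import BaseEstimator

from . import nn
from .imaging import MarkerAnnotation, Provenance, Segment

NATIVE_HEIGHT = 770  # native acquisition size is 1024x770 (width x height)


class IncompleteGridError(ValueError):
    """Too few detected markers to anchor the application grid."""


@dataclass
class ContourFilter:
    """Bounding-box gate for candidate marker contours.

    ``bbox_side_range`` is expressed at the scale of the mask the filter is
    applied to.  The native-scale default derives from the observed marker
    bounding boxes (mean 85 px, min 60, max 104) widened by ~10%.
    """

    bbox_side_range: Tuple[float, float] = (54.0, 114.0)
    aspect_ratio_range: Tuple[float, float] = (0.6, 1.67)

    def __post_init__(self) -> None:
        lo, hi = self.bbox_side_range
        alo, ahi = self.aspect_ratio_range
        if not (0 < lo < hi and 0 < alo < ahi):
            raise ValueError("filter ranges must be positive and non-degenerate")

    def scaled(self, factor: float) -> "ContourFilter":
        """Rescale the side range (aspect ratio is scale-free)."""
        lo, hi = self.bbox_side_range
        return replace(self, bbox_side_range=(lo * factor, hi * factor))

    def accepts(self, height: float, width: float) -> bool:
        lo, hi = self.bbox_side_range
        alo, ahi = self.aspect_ratio_range
        return (lo <= height <= hi and lo <= width <= hi
                and alo <= width / height <= ahi)


@dataclass
class SegTrainConfig:
    """U-Net training recipe: Adam at its default rate, BCE loss, 30 epochs
    on images downscaled to 385x512 with pixels normalised to [0, 1]."""

    epochs: int = 30
    lr: float = 0.001
    train_size: Tuple[int, int] = (385, 512)  # (height, width)
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.train_size) < 1:
            raise ValueError("train_size must be positive")


# ---------------------------------------------------------------------------
# ground-truth masks
# ---------------------------------------------------------------------------

def annotations_to_mask(annotations: Sequence[MarkerAnnotation],
                        image_size: Tuple[int, int]) -> np.ndarray:
    """Binary mask with a filled disc per annotation.

    The disc radius is the distance from the injection point to the marker
    point; square (histamine) markers are rendered as circles too — a
    deliberate simplification, since exact highlighter shapes vary.
    Discs are clipped at the image borders.
    """
    h, w = image_size
    if h <= 0 or w <= 0:
        raise ValueError("image_size must be positive")
    mask = np.zeros((h, w), dtype=bool)
    for ann in annotations:
        r = ann.radius
        cr, cc = ann.injection_point
        r0, r1 = max(int(np.floor(cr - r)), 0), min(int(np.ceil(cr + r)) + 1, h)
        c0, c1 = max(int(np.floor(cc - r)), 0), min(int(np.ceil(cc + r)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                                 indexing="ij")
        mask[r0:r1, c0:c1] |= (rows - cr) ** 2 + (cols - cc) ** 2 <= r * r
    return mask


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

class UNet:
    """Encoder-decoder segmentation network with skip connections.

    Contracting path of double-conv blocks with 2x2 max pooling, expanding
    path of x2 nearest upsampling + 3x3 conv, channel-concatenated skips,
    and a final 1x1 convolution producing one logit per pixel (sigmoid
    applied outside).  ``base_channels=64, depth=4`` reproduces the classic
    layout; narrower/shallower variants are used at desk scale.  Inputs are
    reflect-padded to a multiple of ``2**depth`` and the output cropped
    back, so any image size is accepted.
    """

    def __init__(self, in_channels: int = 3, base_channels: int = 64,
                 depth: int = 4, batch_norm: bool = True,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.depth = depth
        self.batch_norm = batch_norm
        ch = [base_channels * (2 ** i) for i in range(depth + 1)]

        def block(c_in: int, c_out: int) -> nn.Sequential:
            layers: List[nn.Layer] = []
            for cin, cout in ((c_in, c_out), (c_out, c_out)):
                layers.append(nn.Conv2d(cin, cout, 3, rng=rng))
                if batch_norm:
                    layers.append(nn.BatchNorm2d(cout))
                layers.append(nn.ReLU())
            return nn.Sequential(*layers)

        self.enc = [block(in_channels if i == 0 else ch[i - 1], ch[i])
                    for i in range(depth)]
        self.pools = [nn.MaxPool2x2() for _ in range(depth)]
        self.bottleneck = block(ch[depth - 1], ch[depth])
        self.ups = [nn.Sequential(nn.Upsample2x(),
                                  nn.Conv2d(ch[i + 1], ch[i], 3, rng=rng))
                    for i in range(depth)]
        self.dec = [block(2 * ch[i], ch[i]) for i in range(depth)]
        self.final = nn.Conv2d(ch[0], 1, 1, rng=rng)
        self._ch = ch
        self._pad: Optional[Tuple[int, int]] = None

    def parameters(self) -> List[nn.Parameter]:
        params: List[nn.Parameter] = []
        for m in (*self.enc, self.bottleneck, *self.ups, *self.dec, self.final):
            params.extend(m.parameters())
        return params

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        m = 2 ** self.depth
        ph, pw = (-h) % m, (-w) % m
        self._pad = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for i in reversed(range(self.depth)):
            x = self.ups[i].forward(x, train)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[i].forward(x, train)
        x = self.final.forward(x, train)
        return x[:, :, :h, :w]

    def backward(self, dout: np.ndarray) -> None:
        ph, pw = self._pad
        if ph or pw:
            dout = np.pad(dout, ((0, 0), (0, 0), (0, ph), (0, pw)))
        d = self.final.backward(dout)
        dskips = []
        for i in range(self.depth):
            d = self.dec[i].backward(d)
            c = self._ch[i]
            dskips.append(d[:, :c])
            d = self.ups[i].backward(np.ascontiguousarray(d[:, c:]))
        d = self.bottleneck.backward(d)
        for i in reversed(range(self.depth)):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            d = self.enc[i].backward(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel marker probability, inference mode."""
        return nn.sigmoid(self.forward(x, train=False))


def build_unet(in_channels: int = 3, base_channels: int = 64, depth: int = 4,
               batch_norm: bool = True, seed: int = 0) -> UNet:
    """Construct the segmentation U-Net (classic widths by default)."""
    return UNet(in_channels=in_channels, base_channels=base_channels,
                depth=depth, batch_norm=batch_norm,
                rng=np.random.Generator(np.random.PCG64(seed)))


def _to_nchw(images: Sequence[np.ndarray], size: Tuple[int, int]) -> np.ndarray:
    out = np.empty((len(images), 3, *size), dtype=np.float32)
    for i, img in enumerate(images):
        img = np.asarray(img, dtype=np.float64)
        if img.max() > 1.0:  # 0-255 input
            img = img / img.max()
        if img.shape[:2] != size:
            img = resize(img, size, order=1, anti_aliasing=True)
        out[i] = img.transpose(2, 0, 1)
    return out


def _masks_to_tensor(masks: Sequence[np.ndarray], size: Tuple[int, int]) -> np.ndarray:
    out = np.empty((len(masks), 1, *size), dtype=np.float32)
    for i, m in enumerate(masks):
        m = np.asarray(m, dtype=np.float64)
        if m.shape != size:
            m = resize(m, size, order=0, anti_aliasing=False)
        out[i, 0] = m > 0.5
    return out


class UNetSegmenter(BaseEstimator):
    """Sklearn-style estimator wrapping U-Net training and segment extraction.

    ``fit(images, masks)`` trains on visible images (any size; internally
    resized to ``train_size``), ``predict_proba`` returns probability maps
    at ``train_size``, and ``predict`` returns filtered :class:`Segment`
    lists with coordinates rescaled to each input image's own frame.

    Parameters follow the training recipe: Adam at lr 0.001, binary
    cross-entropy, 30 epochs, inputs normalised to [0, 1].
    """

    def __init__(self, epochs: int = 30, lr: float = 0.001,
                 train_size: Tuple[int, int] = (385, 512),
                 base_channels: int = 64, depth: int = 4,
                 batch_norm: bool = True, batch_size: int = 2,
                 threshold: float = 0.5,
                 contour_filter: Optional[ContourFilter] = None,
                 seed: int = 0):
        self.epochs = epochs
        self.lr = lr
        self.train_size = train_size
        self.base_channels = base_channels
        self.depth = depth
        self.batch_norm = batch_norm
        self.batch_size = batch_size
        self.threshold = threshold
        self.contour_filter = contour_filter
        self.seed = seed

    def _filter_at_train_scale(self) -> ContourFilter:
        if self.contour_filter is not None:
            return self.contour_filter
        return ContourFilter().scaled(self.train_size[0] / NATIVE_HEIGHT)

    def fit(self, images: Sequence[np.ndarray], masks: Sequence[np.ndarray],
            ) -> "UNetSegmenter":
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if len(images) != len(masks) or len(images) == 0:
            raise ValueError("need equally many (>=1) images and masks")
        size = tuple(self.train_size)
        x = _to_nchw(images, size)
        y = _masks_to_tensor(masks, size)
        rng = np.random.Generator(np.random.PCG64(self.seed))
        self.model_ = UNet(3, self.base_channels, self.depth,
                           self.batch_norm, rng=rng)
        opt = nn.Adam(self.model_.parameters(), lr=self.lr)
        n = len(x)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.model_.forward(x[idx], train=True)
                loss, dl = nn.bce_with_logits(logits.ravel(), y[idx].ravel())
                opt.zero_grad()
                self.model_.backward(dl.reshape(logits.shape))
                opt.step()
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict_proba(self, images: Sequence[np.ndarray]) -> List[np.ndarray]:
        """Marker probability maps at ``train_size``, one per image."""
        size = tuple(self.train_size)
        x = _to_nchw(images, size)
        return [self.model_.predict(x[i:i + 1])[0, 0] for i in range(len(x))]

    def predict(self, images: Sequence[np.ndarray]) -> List[List[Segment]]:
        """Filtered segments per image, in each image's own pixel frame."""
        cf = self._filter_at_train_scale()
        out = []
        for img, prob in zip(images, self.predict_proba(images)):
            img = np.asarray(img)
            sr = img.shape[0] / self.train_size[0]
            sc = img.shape[1] / self.train_size[1]
            segs = extract_segments(prob, self.threshold, cf)
            out.append([_rescale_segment(s, sr, sc) for s in segs])
        return out


def _rescale_segment(s: Segment, sr: float, sc: float) -> Segment:
    r0, c0, h, w = s.bbox
    return Segment(center=(s.center[0] * sr, s.center[1] * sc),
                   bbox=(r0 * sr, c0 * sc, h * sr, w * sc),
                   grid_index=s.grid_index, provenance=s.provenance)


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

def extract_segments(prob_mask: np.ndarray, threshold: float = 0.5,
                     contour_filter: Optional[ContourFilter] = None,
                     ) -> List[Segment]:
    """Connected components of the thresholded map, gated by bbox size/shape.

    The filter must be expressed at the scale of *prob_mask*.  Segment
    centers are bounding-box centers; provenance is ``detected``.
    """
    cf = contour_filter or ContourFilter()
    binary = np.asarray(prob_mask) >= threshold
    labelled = measure.label(binary, connectivity=2)
    segments = []
    for region in measure.regionprops(labelled):
        r0, c0, r1, c1 = region.bbox  # half-open
        h, w = r1 - r0, c1 - c0
        if not cf.accepts(h, w):
            continue
        segments.append(Segment(center=((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0),
                                bbox=(float(r0), float(c0), float(h), float(w)),
                                provenance=Provenance.DETECTED))
    return segments


# ---------------------------------------------------------------------------
# grid completion
# ---------------------------------------------------------------------------

def complete_grid(segments: Sequence[Segment],
                  expected: Tuple[int, int] = (2, 4)) -> List[Segment]:
    """Arrange detected segments into the application grid and fill gaps.

    Detected segments are split into two lines by the midpoint of their row
    coordinates, then assigned grid positions by their offset from the
    right side along the grid's principal axis: the globally rightmost
    detected marker anchors position 0 for both lines (a single shared
    anchor survives the dropout of any one line's own rightmost marker).
    The grid pitch is the minimal-length displacement between consecutive
    positioned segments; missing positions are synthesised from a per-line
    least-squares fit of center against position, with the median detected
    bounding-box size and ``inferred`` provenance.

    Returns exactly ``n_lines * n_per_line`` segments, each with
    ``grid_index = (line, position)`` where position 0 is rightmost.
    Raises :class:`IncompleteGridError` for < 4 segments or a single line.
    """
    n_lines, n_per_line = expected
    if n_lines != 2:
        raise ValueError("grid completion assumes two lines")
    segments = list(segments)
    if len(segments) < 4:
        raise IncompleteGridError(f"need >=4 detected segments, got {len(segments)}")
    centers = np.array([s.center for s in segments], dtype=np.float64)

    split = (centers[:, 0].min() + centers[:, 0].max()) / 2.0
    line_idx = (centers[:, 0] > split).astype(int)
    if len(set(line_idx)) < 2:
        raise IncompleteGridError("all segments fall in a single line")

    # principal axis of the marker cloud ~ forearm direction
    centred = centers - centers.mean(axis=0)
    # remove the line offset so the axis follows the lines, not the diagonal
    for li in (0, 1):
        sel = line_idx == li
        centred[sel] -= centred[sel].mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if axis[1] < 0:
        axis = -axis

    s = centers @ axis  # coordinate along the forearm
    # minimal consecutive gap within a line = one grid pitch
    gaps = []
    for li in (0, 1):
        vals = np.sort(s[line_idx == li])
        gaps.extend(np.diff(vals))
    gaps = [g for g in gaps if g > 1e-6]
    if not gaps:
        raise IncompleteGridError("cannot estimate grid pitch")
    pitch = min(gaps)

    anchor = s.max()  # rightmost detected marker anchors position 0
    positions = np.rint((anchor - s) / pitch).astype(int)
    if positions.max() >= n_per_line or positions.min() < 0:
        raise IncompleteGridError("detected segments inconsistent with grid extent")

    assigned: dict[tuple[int, int], Segment] = {}
    for seg, li, pos in zip(segments, line_idx, positions):
        key = (int(li), int(pos))
        if key in assigned:
            raise IncompleteGridError(f"two segments claim grid position {key}")
        assigned[key] = Segment(center=seg.center, bbox=seg.bbox,
                                grid_index=key, provenance=seg.provenance)

    bboxes = np.array([s.bbox for s in segments])
    med_h, med_w = np.median(bboxes[:, 2]), np.median(bboxes[:, 3])

    # shared pitch vector: pooled least squares of center ~ a_line + pos * v
    # (pooling both lines stabilises extrapolation when a line keeps only
    # two jittered markers)
    num = np.zeros(2)
    den = 0.0
    line_data = {}
    for li in (0, 1):
        keys = [k for k in assigned if k[0] == li]
        pos = np.array([k[1] for k in keys], dtype=np.float64)
        pts = np.array([assigned[k].center for k in keys])
        line_data[li] = (pos, pts)
        if len(keys) >= 2:
            num += (pos - pos.mean()) @ (pts - pts.mean(axis=0))
            den += np.sum((pos - pos.mean()) ** 2)
    v = num / den
    fits = {}
    for li in (0, 1):
        pos, pts = line_data[li]
        fits[li] = (pts.mean(axis=0) - pos.mean() * v, v)

    out = []
    for li in range(n_lines):
        a, v = fits[li]
        for pos in range(n_per_line):
            key = (li, pos)
            if key in assigned:
                out.append(assigned[key])
                continue
            center = a + pos * v
            out.append(Segment(
                center=(float(center[0]), float(center[1])),
                bbox=(float(center[0] - med_h / 2), float(center[1] - med_w / 2),
                      float(med_h), float(med_w)),
                grid_index=key,
                provenance=Provenance.INFERRED,
            ))
    return out
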