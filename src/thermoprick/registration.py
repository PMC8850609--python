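"""Pre/post thermal alignment from marker correspondences, and delta images.

Two alignment techniques are provided, both driven purely by the eight
application-site markers found by segmentation:

* a projective homography estimated from the marker correspondences
  (normalised direct linear transform, least squares over all pairs), and
* a lower-degree-of-freedom "two lines" method: a least-squares line is
  fitted through each marker set, and a rotation + translation is computed
  that carries the pre-series line onto the post-series one.

The estimated transform warps the pre-reaction thermal image into the
post-reaction frame; subtracting it from the post image yields the *delta*
thermal image, which ideally contains only reaction-induced temperature
change.

Transforms use homogeneous coordinates in the package-wide ``(row, col)``
convention: ``[row', col', 1]^T ∝ M @ [row, col, 1]^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .imaging import Segment, ThermalImage


class TransformKind(str, Enum):
    HOMOGRAPHY = "homography"
    RIGID = "rigid"


class EstimationError(ValueError):
    """Too few or degenerate correspondences for transform estimation."""


class CorrespondenceError(ValueError):
    """Marker sets cannot be matched by grid index."""


@dataclass
class PlanarTransform:
    """3x3 homogeneous planar transform in (row, col) pixel coordinates."""

    matrix: np.ndarray
    kind: TransformKind = TransformKind.HOMOGRAPHY

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if isinstance(self.kind, str):
            self.kind = TransformKind(self.kind)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")
        if self.kind is TransformKind.RIGID:
            r = self.matrix[:2, :2]
            if not (np.allclose(r @ r.T, np.eye(2), atol=1e-6)
                    and np.linalg.det(r) > 0):
                raise ValueError("rigid transform requires a proper rotation block")

    @classmethod
    def identity(cls, kind: TransformKind = TransformKind.RIGID) -> "PlanarTransform":
        return cls(np.eye(3), kind)

    @classmethod
    def rigid(cls, angle_deg: float, translation: Tuple[float, float],
              center: Tuple[float, float] = (0.0, 0.0)) -> "PlanarTransform":
        """Rotation by *angle_deg* about *center* followed by *translation*.

        Angle is measured from the +row axis toward the +col axis.
        """
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        c = np.asarray(center, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64) + c - rot @ c
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = t
        return cls(m, TransformKind.RIGID)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (row, col) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        h = np.column_stack([pts, np.ones(len(pts))])
        out = h @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(np.linalg.inv(self.matrix), self.kind)

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the (polar-decomposed) linear part, degrees."""
        a = self.matrix[:2, :2]
        u, _, vt = np.linalg.svd(a)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        return float(np.rad2deg(np.arctan2(r[1, 0], r[0, 0])))


@dataclass
class DeltaImage:
    """Post-minus-aligned-pre temperature difference (°C, positive = warming)."""

    pixels: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.pixels.shape != self.valid_mask.shape:
            raise ValueError("pixels and valid_mask shapes differ")


def match_markers(pre_segments: Sequence[Segment],
                  post_segments: Sequence[Segment]) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Pair marker centers across series by equal grid index.

    Both inputs must carry complete grid indices (output of grid completion);
    correspondence by index is robust to the forearm moving between series,
    unlike nearest-neighbour matching.
    """

    def index_map(segments: Sequence[Segment]) -> dict:
        out = {}
        for s in segments:
            if s.grid_index is None:
                raise CorrespondenceError("segment without grid_index")
            if tuple(s.grid_index) in out:
                raise CorrespondenceError(f"duplicate grid_index {s.grid_index}")
            out[tuple(s.grid_index)] = np.asarray(s.center, dtype=np.float64)
        return out

    pre_map, post_map = index_map(pre_segments), index_map(post_segments)
    if set(pre_map) != set(post_map):
        raise CorrespondenceError("pre/post grid indices do not match")
    pairs = [(pre_map[k], post_map[k]) for k in sorted(pre_map)]
    if len(pairs) < 4:
        raise CorrespondenceError(f"need >=4 correspondences, got {len(pairs)}")
    return pairs


def estimate_homography(correspondences: Sequence[Tuple[np.ndarray, np.ndarray]],
                        ) -> Tuple[PlanarTransform, float]:
    """Least-squares homography (normalised DLT); returns (transform, residual RMS).

    The residual is the RMS reprojection error of the input correspondences.
    """
    if len(correspondences) < 4:
        raise EstimationError(f"need >=4 point pairs, got {len(correspondences)}")
    src = np.array([p for p, _ in correspondences], dtype=np.float64)
    dst = np.array([q for _, q in correspondences], dtype=np.float64)

    # collinearity guard: normalised DLT is degenerate for collinear points
    for pts in (src, dst):
        centred = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-6 * max(1.0, np.abs(pts).max())) < 2:
            raise EstimationError("degenerate (collinear) marker configuration")

    from skimage.transform import ProjectiveTransform

    # skimage works in (x, y) = (col, row); permute in and out
    tf = ProjectiveTransform.from_estimate(src[:, ::-1], dst[:, ::-1])
    if not tf:
        raise EstimationError("homography estimation failed")
    perm = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    matrix = perm @ tf.params @ perm
    transform = PlanarTransform(matrix, TransformKind.HOMOGRAPHY)
    residual = float(np.sqrt(np.mean(np.sum((transform.apply(src) - dst) ** 2, axis=1))))
    return transform, residual


def _fit_line(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares line through (n, 2) (row, col) points.

    Returns (point_on_line, unit_direction).  The fit minimises orthogonal
    (total-least-squares) distance: unlike row-on-col regression, the
    principal axis rotates exactly with the point set even when the markers
    scatter across two grid rows, so the recovered rotation is unbiased.
    Handles vertical lines with no special casing.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        raise EstimationError("need >=2 points to fit a line")
    centroid = points.mean(axis=0)
    centred = points - centroid
    if centred.std() < 1e-9:
        raise EstimationError("coincident points: line undefined")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    direction = direction / np.linalg.norm(direction)
    if direction[1] < 0 or (direction[1] == 0 and direction[0] < 0):
        direction = -direction
    return centroid, direction


def estimate_rigid_lines(pre_points: np.ndarray,
                         post_points: np.ndarray) -> PlanarTransform:
    """Rigid (rotation + translation) transform aligning two fitted marker lines.

    A least-squares line is fitted through each marker set.  The rotation is
    the angle between the two lines; the translation carries the projection
    of the pre centroid onto its line to the projection of the post centroid
    onto the post line.  The transformed pre line then coincides with the
    post line.
    """
    pre_points = np.atleast_2d(np.asarray(pre_points, dtype=np.float64))
    post_points = np.atleast_2d(np.asarray(post_points, dtype=np.float64))
    c_pre, d_pre = _fit_line(pre_points)
    c_post, d_post = _fit_line(post_points)
    if np.dot(d_pre, d_post) < 0:
        d_post = -d_post
    # with phi = atan2(row, col), rotating by the matrix in PlanarTransform
    # maps a direction's phi to phi - angle, hence the pre-minus-post order
    angle = np.arctan2(d_pre[0], d_pre[1]) - np.arctan2(d_post[0], d_post[1])
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    # centroids already lie on their least-squares lines (regression passes
    # through the mean), so they are their own projections
    t = c_post - rot @ c_pre
    m = np.eye(3)
    m[:2, :2] = rot
    m[:2, 2] = t
    return PlanarTransform(m, TransformKind.RIGID)


def warp_thermal(pre: ThermalImage, transform: PlanarTransform,
                 out_shape: Tuple[int, int] | None = None,
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Warp the pre image into the post frame (inverse mapping, bilinear).

    Returns ``(warped, valid_mask)``; output pixels whose pre-image falls
    outside the source are 0 with ``valid_mask`` False.
    """
    src = pre.pixels
    h, w = out_shape if out_shape is not None else src.shape
    inv = transform.inverse().matrix
    rows, cols = np.meshgrid(np.arange(h, dtype=np.float64),
                             np.arange(w, dtype=np.float64), indexing="ij")
    ones = np.ones_like(rows)
    denom = inv[2, 0] * rows + inv[2, 1] * cols + inv[2, 2]
    src_r = (inv[0, 0] * rows + inv[0, 1] * cols + inv[0, 2]) / denom
    src_c = (inv[1, 0] * rows + inv[1, 1] * cols + inv[1, 2]) / denom
    valid = ((src_r >= 0) & (src_r <= src.shape[0] - 1)
             & (src_c >= 0) & (src_c <= src.shape[1] - 1))
    warped = ndimage.map_coordinates(src, [src_r, src_c], order=1,
                                     mode="constant", cval=0.0)
    warped[~valid] = 0.0
    return warped, valid


def delta_image(post: ThermalImage, pre_aligned: np.ndarray,
                valid_mask: np.ndarray) -> DeltaImage:
    """Delta thermal image: post minus aligned pre where valid, 0 elsewhere."""
    pre_aligned = np.asarray(pre_aligned, dtype=np.float64)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if post.pixels.shape != pre_aligned.shape or post.pixels.shape != valid_mask.shape:
        raise ValueError("post, pre_aligned and valid_mask shapes must match")
    pixels = np.where(valid_mask, post.pixels - pre_aligned, 0.0)
    return DeltaImage(pixels=pixels, valid_mask=valid_mask)


def align_and_subtract(pre: ThermalImage, post: ThermalImage,
                       pre_segments: Sequence[Segment],
                       post_segments: Sequence[Segment],
                       method: str = "homography") -> Tuple[DeltaImage, PlanarTransform]:
    """Convenience: match markers, estimate transform, warp, subtract."""
    pairs = match_markers(pre_segments, post_segments)
    if method == "homography":
        transform, _ = estimate_homography(pairs)
    elif method in ("lines", "rigid"):
        src = np.array([p for p, _ in pairs])
        dst = np.array([q for _, q in pairs])
        transform = estimate_rigid_lines(src, dst)
    else:
        raise ValueError(f"unknown alignment method {method!r}")
    warped, valid = warp_thermal(pre, transform, out_shape=post.pixels.shape)
    return delta_image(post, warped, valid), transform
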