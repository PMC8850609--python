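"""Synthetic paired visible/thermal forearm scenes with full ground truth.

The generator emulates the statistical structure a prick-test reading
pipeline relies on, without attempting photorealism:

* a 2x4 grid of highlighter marks per forearm (7 circles + 1 square for the
  histamine control), with per-marker positional jitter;
* a pre series and a post series related by a small random rigid transform
  (the patient shifting/rotating the forearm between acquisitions);
* localised hyperthermic spots (isotropic Gaussian temperature bumps) at
  positive sites in the post thermal image, plus a low-contrast reddish
  hive in the post visible image;
* confounders: hair rendered as thin dark/cool curves, superficial vessels
  as faint warm ridges, a smooth baseline temperature gradient, and
  independent per-series Gaussian sensor noise;
* optionally "unreadable" markers drawn at strongly reduced contrast on
  both series (incomplete marking), to exercise grid completion.

Every scene element is rendered analytically at its (possibly transformed)
geometry, so the post image is an exact re-render of the moved scene rather
than an interpolated warp: ground-truth marker centers, the inter-series
transform and the hot-spot field are consistent with the pixels to machine
precision.  All randomness flows from ``(config.seed, patient_seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .imaging import (
    ImageBundle,
    MarkerAnnotation,
    MarkerShape,
    PatientRecord,
    Series,
    ThermalImage,
    VisibleImage,
    write_annotations,
    write_bundle,
)
from .registration import PlanarTransform, TransformKind

HISTAMINE_SITE = (0, 0)      # (line, column) of the square positive control
NEG_CONTROL_SITE = (1, 3)    # diluent-only site, never reacts

_SKIN_RGB = np.array([0.80, 0.62, 0.50])
_MARKER_RGB = np.array([0.20, 0.85, 0.25])  # highlighter green
_HAIR_RGB = np.array([0.22, 0.15, 0.10])


class ConfigurationError(ValueError):
    """Scene parameters are inconsistent (e.g. grid does not fit)."""


@dataclass
class SceneConfig:
    """Parameters of the synthetic study conditions.

    Defaults describe half-native-resolution scenes (385x512, i.e. the scale
    the U-Net trains at); marker radii are chosen so detected bounding boxes
    land in the 60-104 px native range (mean ~85) after doubling.
    """

    image_size: Tuple[int, int] = (385, 512)  # (height, width)
    grid: Tuple[int, int] = (2, 4)            # (n_lines, n_per_line)
    marker_radius_range: Tuple[float, float] = (19.0, 24.0)  # px at this scale
    inter_marker_spacing: float = 112.0       # px between neighbouring markers
    line_spacing: float = 112.0               # px between the two grid lines
    position_jitter: float = 4.0              # per-marker uniform jitter, px
    max_rotation_deg: float = 5.0             # pose change between series
    max_translation_px: float = 15.0
    hotspot_amplitude: float = 1.5            # degC added at a reacting site
    hotspot_sigma: float = 12.0               # px spread of the reaction bump
    hive_contrast: float = 0.25               # visible redness of a reaction
    baseline_temp: float = 33.0               # degC skin baseline
    noise_sd: float = 0.05                    # degC sensor noise per series
    hair_density: int = 10                    # hairs per forearm
    vessel_count: int = 3
    hair_cooling: float = 0.25                # degC dip under a hair
    vessel_warming: float = 0.35              # degC rise over a vessel
    prevalence: float = 0.3                   # P(reaction) at an allergen site
    marker_dropout: float = 0.0               # P(marker drawn almost invisibly)
    dropout_contrast: float = 0.12            # ink contrast of a dropped marker
    force_controls: bool = True               # histamine +, negative control -
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError("prevalence must be in [0, 1]")
        if not 0.0 <= self.marker_dropout < 1.0:
            raise ConfigurationError("marker_dropout must be in [0, 1)")
        if self.hotspot_amplitude <= 0:
            raise ConfigurationError("hotspot_amplitude must be positive")
        if min(self.hair_density, self.vessel_count) < 0:
            raise ConfigurationError("confounder counts must be >= 0")
        h, w = self.image_size
        n_lines, n_per_line = self.grid
        r_max = self.marker_radius_range[1] + self.position_jitter
        span_c = (n_per_line - 1) * self.inter_marker_spacing + 2 * r_max
        span_r = (n_lines - 1) * self.line_spacing + 2 * r_max
        margin = 2 * (self.max_translation_px + 4)
        if span_c + margin > w or span_r + margin > h:
            raise ConfigurationError(
                f"{n_lines}x{n_per_line} grid with spacing "
                f"{self.inter_marker_spacing} does not fit in {self.image_size}"
            )

    @property
    def n_sites(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class SyntheticCase:
    """One forearm: paired pre/post bundles plus complete ground truth."""

    patient: PatientRecord
    forearm: str  # "L" or "R"
    pre: ImageBundle
    post: ImageBundle
    annotations: List[MarkerAnnotation]
    true_transform: PlanarTransform  # pre -> post
    labels: List[int]                # aligned with annotations
    dropped_markers: Set[int]        # indices into annotations
    site_grid: List[Tuple[int, int]]  # (line, column-from-left) per annotation
    config: SceneConfig

    def hotspot_truth_field(self) -> np.ndarray:
        """Post-frame temperature field added by the reactions (degC)."""
        h, w = self.config.image_size
        out = np.zeros((h, w))
        centers = np.array([a.injection_point for a in self.annotations])
        centers = self.true_transform.apply(centers)
        for center, label in zip(centers, self.labels):
            if label:
                _add_gaussian_spot(out, center, self.config.hotspot_sigma,
                                   self.config.hotspot_amplitude)
        return out


# ---------------------------------------------------------------------------
# geometry sampling
# ---------------------------------------------------------------------------

def sample_grid_centers(config: SceneConfig, rng: np.random.Generator,
                        ) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Jittered 2x4 marker centers and their (line, column) indices.

    Columns are indexed left to right; segmentation's grid completion uses
    its own right-anchored indexing internally.
    """
    h, w = config.image_size
    n_lines, n_per_line = config.grid
    row0 = h / 2.0 - (n_lines - 1) * config.line_spacing / 2.0
    col0 = w / 2.0 - (n_per_line - 1) * config.inter_marker_spacing / 2.0
    centers, indices = [], []
    for line in range(n_lines):
        for pos in range(n_per_line):
            jitter = rng.uniform(-config.position_jitter,
                                 config.position_jitter, size=2)
            centers.append([row0 + line * config.line_spacing + jitter[0],
                            col0 + pos * config.inter_marker_spacing + jitter[1]])
            indices.append((line, pos))
    return np.array(centers), indices


def _sample_hairs(config: SceneConfig, rng: np.random.Generator) -> List[np.ndarray]:
    """Each hair is a polyline (n, 2) of (row, col) points."""
    h, w = config.image_size
    hairs = []
    for _ in range(config.hair_density):
        start = rng.uniform([0, 0], [h, w])
        angle = rng.uniform(0, 2 * np.pi)
        n_steps = rng.integers(8, 16)
        step = rng.uniform(3.0, 5.0)
        pts = [start]
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.25)
            pts.append(pts[-1] + step * np.array([np.sin(angle), np.cos(angle)]))
        hairs.append(np.array(pts))
    return hairs


def _sample_vessels(config: SceneConfig, rng: np.random.Generator) -> List[np.ndarray]:
    """Vessels run roughly along the forearm (image columns)."""
    h, w = config.image_size
    vessels = []
    for _ in range(config.vessel_count):
        row = rng.uniform(0.15 * h, 0.85 * h)
        n_knots = 6
        cols = np.linspace(-0.05 * w, 1.05 * w, n_knots)
        rows = row + np.cumsum(rng.normal(0.0, 6.0, n_knots))
        vessels.append(np.column_stack([rows, cols]))
    return vessels


# ---------------------------------------------------------------------------
# rendering primitives (all analytic in continuous coordinates)
# ---------------------------------------------------------------------------

def _window(shape: Tuple[int, int], pts: np.ndarray, pad: float):
    r0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
    r1 = min(int(np.ceil(pts[:, 0].max() + pad)) + 1, shape[0])
    c0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
    c1 = min(int(np.ceil(pts[:, 1].max() + pad)) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return None
    rows, cols = np.meshgrid(np.arange(r0, r1, dtype=np.float64),
                             np.arange(c0, c1, dtype=np.float64), indexing="ij")
    return (slice(r0, r1), slice(c0, c1)), rows, cols


def _add_gaussian_spot(field: np.ndarray, center: Sequence[float],
                       sigma: float, amplitude: float, support: float = 4.0) -> None:
    """Isotropic Gaussian bump, truncated (exact zero) beyond support*sigma."""
    win = _window(field.shape, np.atleast_2d(np.asarray(center)), support * sigma)
    if win is None:
        return
    sl, rows, cols = win
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    bump = amplitude * np.exp(-d2 / (2.0 * sigma * sigma))
    bump[d2 > (support * sigma) ** 2] = 0.0
    field[sl] += bump


def _segment_distance(rows: np.ndarray, cols: np.ndarray,
                      p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    length2 = float(d @ d)
    if length2 < 1e-12:
        return np.hypot(rows - p0[0], cols - p0[1])
    t = ((rows - p0[0]) * d[0] + (cols - p0[1]) * d[1]) / length2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rows - (p0[0] + t * d[0]), cols - (p0[1] + t * d[1]))


def _add_polyline(field: np.ndarray, pts: np.ndarray, sigma: float,
                  amplitude: float, support: float = 3.0) -> None:
    """Gaussian-profile ridge along a polyline (shared by hair and vessels)."""
    for p0, p1 in zip(pts[:-1], pts[1:]):
        win = _window(field.shape, np.array([p0, p1]), support * sigma)
        if win is None:
            continue
        sl, rows, cols = win
        d = _segment_distance(rows, cols, p0, p1)
        mask = d <= support * sigma
        field[sl][mask] += amplitude * np.exp(-d[mask] ** 2 / (2 * sigma * sigma))


def _blend_alpha(image: np.ndarray, sl, alpha: np.ndarray, color: np.ndarray) -> None:
    patch = image[sl]
    image[sl] = patch * (1.0 - alpha[..., None]) + color * alpha[..., None]


def _draw_ring(image: np.ndarray, center: np.ndarray, radius: float,
               contrast: float, thickness: float = 1.6) -> None:
    win = _window(image.shape[:2], np.atleast_2d(center), radius + 4 * thickness)
    if win is None:
        return
    sl, rows, cols = win
    d = np.hypot(rows - center[0], cols - center[1])
    alpha = contrast * np.exp(-((d - radius) ** 2) / (2 * thickness ** 2))
    _blend_alpha(image, sl, alpha, _MARKER_RGB)


def _draw_square_ring(image: np.ndarray, corners: np.ndarray,
                      contrast: float, thickness: float = 1.6) -> None:
    win = _window(image.shape[:2], corners, 4 * thickness)
    if win is None:
        return
    sl, rows, cols = win
    d = np.full(rows.shape, np.inf)
    for i in range(4):
        p0, p1 = corners[i], corners[(i + 1) % 4]
        d = np.minimum(d, _segment_distance(rows, cols, p0, p1))
    alpha = contrast * np.exp(-(d ** 2) / (2 * thickness ** 2))
    _blend_alpha(image, sl, alpha, _MARKER_RGB)


def _square_corners(center: np.ndarray, half_side: float) -> np.ndarray:
    return center + half_side * np.array(
        [[-1, -1], [-1, 1], [1, 1], [1, -1]], dtype=np.float64
    )


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _render_series(config: SceneConfig, scene: dict,
                   transform: Optional[PlanarTransform],
                   hot_labels: Optional[Sequence[int]],
                   noise_rng: Optional[np.random.Generator],
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Render one series; geometry is mapped through *transform* if given."""
    h, w = config.image_size

    def tf(pts: np.ndarray) -> np.ndarray:
        return transform.apply(pts) if transform is not None else np.atleast_2d(pts)

    # thermal baseline: plane in pre-frame coordinates (moves with the arm)
    rows, cols = np.meshgrid(np.arange(h, dtype=np.float64),
                             np.arange(w, dtype=np.float64), indexing="ij")
    if transform is not None:
        inv = transform.inverse().matrix
        denom = inv[2, 0] * rows + inv[2, 1] * cols + inv[2, 2]
        pre_r = (inv[0, 0] * rows + inv[0, 1] * cols + inv[0, 2]) / denom
        pre_c = (inv[1, 0] * rows + inv[1, 1] * cols + inv[1, 2]) / denom
    else:
        pre_r, pre_c = rows, cols
    gr, gc = scene["thermal_gradient"]
    thermal = config.baseline_temp + gr * (pre_r - h / 2) + gc * (pre_c - w / 2)

    visible = np.empty((h, w, 3))
    visible[...] = _SKIN_RGB * (1.0 + scene["tone_gradient"][0] * (pre_r - h / 2) / h
                                + scene["tone_gradient"][1] * (pre_c - w / 2) / w)[..., None]

    for vessel in scene["vessels"]:
        pts = tf(vessel)
        _add_polyline(thermal, pts, sigma=3.0, amplitude=config.vessel_warming)
        vis_shade = np.zeros((h, w))
        _add_polyline(vis_shade, pts, sigma=3.0, amplitude=0.05)
        visible[..., 0] -= vis_shade * 0.5
        visible[..., 2] += vis_shade * 0.3

    for hair in scene["hairs"]:
        pts = tf(hair)
        _add_polyline(thermal, pts, sigma=1.2, amplitude=-config.hair_cooling)
        hair_alpha = np.zeros((h, w))
        _add_polyline(hair_alpha, pts, sigma=0.9, amplitude=0.8)
        visible *= (1.0 - np.clip(hair_alpha, 0, 1))[..., None]
        visible += np.clip(hair_alpha, 0, 1)[..., None] * _HAIR_RGB

    centers = tf(scene["centers"])
    for i, (center, radius, shape) in enumerate(
            zip(centers, scene["radii"], scene["shapes"])):
        contrast = (config.dropout_contrast if i in scene["dropped"] else 0.95)
        if shape is MarkerShape.SQUARE:
            corners = tf(_square_corners(scene["centers"][i], radius))
            _draw_square_ring(visible, corners, contrast)
        else:
            _draw_ring(visible, center, radius, contrast)

    if hot_labels is not None:  # post series only
        for center, label in zip(centers, hot_labels):
            if not label:
                continue
            _add_gaussian_spot(thermal, center, config.hotspot_sigma,
                               config.hotspot_amplitude)
            hive = np.zeros((h, w))
            _add_gaussian_spot(hive, center, 0.6 * config.hotspot_sigma,
                               config.hive_contrast)
            visible[..., 0] += hive
            visible[..., 1] -= 0.5 * hive
            visible[..., 2] -= 0.5 * hive

    if noise_rng is not None and config.noise_sd > 0:
        thermal = thermal + noise_rng.normal(0.0, config.noise_sd, size=(h, w))
        visible = visible + noise_rng.normal(0.0, 0.01, size=(h, w, 3))

    return np.clip(visible, 0.0, 1.0), thermal


def _sample_patient(patient_seed: int, rng: np.random.Generator) -> PatientRecord:
    return PatientRecord(
        patient_id=f"P{patient_seed:04d}",
        sex="M" if rng.random() < 0.5 else "F",
        age=float(np.round(rng.uniform(18, 70), 1)),
        weight=float(np.round(rng.uniform(50, 100), 1)),
        height=float(np.round(rng.uniform(150, 195), 1)),
        body_temperature=float(np.round(rng.uniform(36.0, 37.2), 2)),
    )


def _site_name(line: int, pos: int, forearm: str) -> str:
    if (line, pos) == HISTAMINE_SITE:
        return "histamine"
    if (line, pos) == NEG_CONTROL_SITE:
        return "neg_control"
    return f"allergen_{forearm}_{line}{pos}"


def generate_case(config: SceneConfig, patient_seed: int,
                  patient: Optional[PatientRecord] = None,
                  forearm: str = "L") -> SyntheticCase:
    """Generate one forearm's paired pre/post bundles with ground truth.

    Deterministic given ``(config.seed, patient_seed, forearm)``.
    """
    ss = np.random.SeedSequence(
        [int(config.seed), int(patient_seed), 0 if forearm == "L" else 1]
    )
    rng = np.random.Generator(np.random.PCG64(ss))
    if patient is None:
        patient = _sample_patient(patient_seed, rng)

    centers, site_grid = sample_grid_centers(config, rng)
    n = config.n_sites
    radii = rng.uniform(*config.marker_radius_range, size=n)
    shapes = [MarkerShape.SQUARE if (line, pos) == HISTAMINE_SITE
              else MarkerShape.CIRCLE for line, pos in site_grid]

    labels = (rng.random(n) < config.prevalence).astype(int)
    if config.force_controls:
        for i, (line, pos) in enumerate(site_grid):
            if (line, pos) == HISTAMINE_SITE:
                labels[i] = 1
            elif (line, pos) == NEG_CONTROL_SITE:
                labels[i] = 0

    dropped = {i for i in range(n) if rng.random() < config.marker_dropout}

    angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    translation = rng.uniform(-config.max_translation_px,
                              config.max_translation_px, size=2)
    h, w = config.image_size
    true_transform = PlanarTransform.rigid(angle, tuple(translation),
                                           center=(h / 2.0, w / 2.0))

    scene = {
        "centers": centers,
        "radii": radii,
        "shapes": shapes,
        "dropped": dropped,
        "hairs": _sample_hairs(config, rng),
        "vessels": _sample_vessels(config, rng),
        "thermal_gradient": rng.uniform(-8e-4, 8e-4, size=2),
        "tone_gradient": rng.uniform(-0.05, 0.05, size=2),
    }

    pre_vis, pre_th = _render_series(config, scene, transform=None,
                                     hot_labels=None, noise_rng=rng)
    post_vis, post_th = _render_series(config, scene, transform=true_transform,
                                       hot_labels=labels, noise_rng=rng)

    annotations = [
        MarkerAnnotation(
            injection_point=(float(c[0]), float(c[1])),
            marker_point=(float(c[0]), float(c[1] + r)),
            shape=s,
            site_id=_site_name(line, pos, forearm),
        )
        for c, r, s, (line, pos) in zip(centers, radii, shapes, site_grid)
    ]

    return SyntheticCase(
        patient=patient,
        forearm=forearm,
        pre=ImageBundle(VisibleImage(pre_vis), ThermalImage(pre_th), Series.PRE),
        post=ImageBundle(VisibleImage(post_vis), ThermalImage(post_th), Series.POST),
        annotations=annotations,
        true_transform=true_transform,
        labels=[int(x) for x in labels],
        dropped_markers=dropped,
        site_grid=site_grid,
        config=config,
    )


def generate_cohort(config: SceneConfig, n_patients: int,
                    ) -> Tuple[List[SyntheticCase], pd.DataFrame]:
    """Generate two forearms per patient plus the long-format labels table.

    The labels table has one row per application site:
    ``patient_id, forearm, site_id, label``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cases: List[SyntheticCase] = []
    rows = []
    for p in range(n_patients):
        ss = np.random.SeedSequence([int(config.seed), int(p), 999])
        patient = _sample_patient(p, np.random.Generator(np.random.PCG64(ss)))
        for forearm in ("L", "R"):
            case = generate_case(config, p, patient=patient, forearm=forearm)
            cases.append(case)
            for ann, label in zip(case.annotations, case.labels):
                rows.append({"patient_id": patient.patient_id,
                             "forearm": forearm,
                             "site_id": ann.site_id,
                             "label": int(label)})
    return cases, pd.DataFrame(rows)


def write_cohort(directory: str | Path, cases: Sequence[SyntheticCase],
                 labels: pd.DataFrame) -> None:
    """Write the on-disk layout consumed by the CLI pipeline stages."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels.to_csv(directory / "labels.csv", index=False)
    transforms: Dict[str, list] = {}
    for case in cases:
        stem = f"{case.patient.patient_id}_{case.forearm}"
        write_bundle(directory, f"{stem}_pre", case.pre)
        write_bundle(directory, f"{stem}_post", case.post)
        write_annotations(directory / f"{stem}_annotations.json", case.annotations)
        transforms[stem] = case.true_transform.matrix.tolist()
    (directory / "transforms.json").write_text(json.dumps(transforms, indent=1))
    patients = pd.DataFrame([asdict(c.patient) for c in cases]).drop_duplicates()
    patients.to_csv(directory / "patients.csv", index=False)
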