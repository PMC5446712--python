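"""Synthetic vessels and map groups with known ground truth.

Two generators make every pipeline stage testable without animal data:

* :func:`make_vessel` renders a curved tubular vessel — an arch (circular
  arc) joined to a straight descending segment, emulating an aortic-arch
  geometry — with additive Gaussian noise and optional intensity hotspots
  ("lesions") at known medial arc-length positions.  It emits the sparse
  boundary points a user would mark manually (about one per 20 px of wall)
  together with dense ground truth: the true medial axis, the vessel mask
  and the lesion positions.

* :func:`make_map_groups` draws two groups of standardized maps from a
  Gaussian noise model, with a rectangular effect region of controlled
  amplitude added to group A — the test bed for error-rate calibration and
  power checks.

Noise is additive Gaussian throughout; the generators do not attempt a
physically realistic fluorescence model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .permtest import StudyDesign

__all__ = [
    "VesselSpec",
    "SyntheticVessel",
    "MapGroupSpec",
    "make_vessel",
    "make_map_groups",
    "default_section_arclengths",
]


@dataclass(frozen=True)
class VesselSpec:
    """Geometry and intensity model of a synthetic curved vessel.

    The centerline is a circular arc of radius ``arc_radius`` spanning
    ``arc_span`` radians (the arch), continued by a straight segment of
    ``straight_length`` pixels (the descending part).  ``half_width`` is a
    constant or a callable of medial arc length.  ``lesions`` are
    ``(arc_position, axial_sigma, relative_amplitude)`` triples added
    multiplicatively to the base intensity.
    """

    arc_radius: float = 110.0
    arc_span: float = math.pi
    straight_length: float = 150.0
    half_width: float = 16.0
    image_size: tuple[int, int] = (320, 360)  # rows, cols
    base_intensity: float = 100.0
    background_intensity: float = 5.0
    noise_sd: float = 2.0
    lesions: tuple[tuple[float, float, float], ...] = ()
    boundary_spacing: float = 20.0

    def half_width_at(self, s) -> np.ndarray:
        if callable(self.half_width):
            return np.asarray(self.half_width(np.asarray(s, dtype=float)), dtype=float)
        return np.full_like(np.asarray(s, dtype=float), float(self.half_width))

    @property
    def arc_length_total(self) -> float:
        return self.arc_radius * self.arc_span + self.straight_length


@dataclass(eq=False)
class SyntheticVessel:
    """Rendered vessel image plus all ground truth."""

    image: np.ndarray
    boundary_a: np.ndarray  # sparse marked points, outer wall
    boundary_b: np.ndarray  # sparse marked points, inner wall
    medial_axis: np.ndarray  # dense true centerline points
    medial_arclength: np.ndarray
    mask: np.ndarray
    lesion_truth: list
    spec: VesselSpec = field(repr=False, default=None)


def _centerline_geometry(spec: VesselSpec, s: np.ndarray):
    """Centerline points, tangents and inward normals at arc lengths ``s``."""
    s = np.asarray(s, dtype=float)
    rows, cols = spec.image_size
    margin = (
        float(np.max(spec.half_width_at(np.linspace(0, spec.arc_length_total, 64))))
        + 8.0
    )
    R = spec.arc_radius
    cx, cy = cols / 2.0, R + margin
    arc_len = R * spec.arc_span
    if arc_len <= 1e-12:
        # zero curvature: a vertical tube running down from the top margin
        px = np.full_like(s, cx)
        py = margin + s
        tangents = np.tile([0.0, 1.0], (len(s), 1))
        normals = np.tile([-1.0, 0.0], (len(s), 1))
        return np.stack([px, py], axis=-1), tangents, normals

    theta = math.pi - np.minimum(s, arc_len) / max(R, 1e-9)
    on_arc = s <= arc_len
    px = cx + R * np.cos(theta)
    py = cy - R * np.sin(theta)
    tx, ty = np.sin(theta), np.cos(theta)

    theta_e = math.pi - spec.arc_span
    ex = cx + R * math.cos(theta_e)
    ey = cy - R * math.sin(theta_e)
    dx, dy = math.sin(theta_e), math.cos(theta_e)
    u = s - arc_len
    px = np.where(on_arc, px, ex + u * dx)
    py = np.where(on_arc, py, ey + u * dy)
    tx = np.where(on_arc, tx, dx)
    ty = np.where(on_arc, ty, dy)

    # normal rotated +90 degrees from the tangent points toward the arc centre
    nx, ny = -ty, tx
    pts = np.stack([px, py], axis=-1)
    normals = np.stack([nx, ny], axis=-1)
    return pts, np.stack([tx, ty], axis=-1), normals


def default_section_arclengths(spec: VesselSpec) -> np.ndarray:
    """Anatomical section cuts: four equal arch quarters plus the straight part."""
    arc = spec.arc_radius * spec.arc_span
    return np.array(
        [0.0, arc / 4, arc / 2, 3 * arc / 4, arc, spec.arc_length_total]
    )


def make_vessel(spec: VesselSpec = VesselSpec(), seed: int = 0) -> SyntheticVessel:
    """Render a synthetic vessel with ground truth.

    Raises if the tube (centerline plus half width) leaves the image.
    """
    rows, cols = spec.image_size
    L = spec.arc_length_total
    ds = 0.25
    s_dense = np.arange(0.0, L + ds / 2, ds)
    s_dense[-1] = min(s_dense[-1], L)
    pts, _, normals = _centerline_geometry(spec, s_dense)
    hw = spec.half_width_at(s_dense)

    lo = (pts - (hw[:, None] + 1.0)).min(axis=0)
    hi = (pts + (hw[:, None] + 1.0)).max(axis=0)
    if lo[0] < 0 or lo[1] < 0 or hi[0] > cols - 1 or hi[1] > rows - 1:
        raise ValueError("tube exits image bounds; enlarge image or shrink vessel")

    tree = cKDTree(pts)
    yy, xx = np.mgrid[0:rows, 0:cols]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=-1).astype(float)
    dist, idx = tree.query(pix, workers=-1)
    s_near = s_dense[idx]
    inside = (dist <= hw[idx]) & (s_near > ds) & (s_near < L - ds)
    inside = inside.reshape(rows, cols)
    s_map = s_near.reshape(rows, cols)

    factor = np.ones((rows, cols))
    for s0, sig, amp in spec.lesions:
        if not 0 <= s0 <= L:
            raise ValueError("lesion position outside vessel extent")
        factor += amp * np.exp(-0.5 * ((s_map - s0) / max(sig, 1e-9)) ** 2)

    rng = np.random.default_rng(seed)
    image = np.full((rows, cols), spec.background_intensity, dtype=float)
    image[inside] = spec.base_intensity * factor[inside]
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)

    s_marks = np.arange(0.0, L, spec.boundary_spacing)
    if L - s_marks[-1] > 1e-9:
        s_marks = np.append(s_marks, L)
    mpts, _, mnormals = _centerline_geometry(spec, s_marks)
    mhw = spec.half_width_at(s_marks)
    boundary_a = mpts - mhw[:, None] * mnormals  # outer wall
    boundary_b = mpts + mhw[:, None] * mnormals  # inner wall

    return SyntheticVessel(
        image=image,
        boundary_a=boundary_a,
        boundary_b=boundary_b,
        medial_axis=pts,
        medial_arclength=s_dense,
        mask=inside,
        lesion_truth=[
            {"arc_position": float(s0), "axial_sigma": float(sig), "amplitude": float(amp)}
            for s0, sig, amp in spec.lesions
        ],
        spec=spec,
    )


@dataclass(frozen=True)
class MapGroupSpec:
    """Two groups of standardized maps with a controlled planted effect.

    Group B maps are ``base_intensity`` plus pixel-wise Gaussian noise;
    group A additionally carries ``effect_size`` inside the rectangular
    ``effect_region`` (half-open ``(r0, r1, c0, c1)``; defaults to the
    central quarter of the map).  In paired mode each pair shares a
    per-subject baseline offset of SD ``subject_sd``.
    """

    shape: tuple[int, int] = (400, 40)
    n_per_group: int = 5
    effect_region: tuple[int, int, int, int] | None = None
    effect_size: float = 1.0
    noise_sd: float = 1.0
    base_intensity: float = 1.0
    subject_sd: float = 0.0
    paired: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.effect_region is None:
            h, w = self.shape
            object.__setattr__(
                self, "effect_region", (h // 4, 3 * h // 4, w // 4, 3 * w // 4)
            )
        r0, r1, c0, c1 = self.effect_region
        if not (0 <= r0 < r1 <= self.shape[0] and 0 <= c0 < c1 <= self.shape[1]):
            raise ValueError("effect region must lie within the map shape")
        if self.n_per_group < 2:
            raise ValueError("need at least two maps per group")


def make_map_groups(spec: MapGroupSpec = MapGroupSpec()) -> StudyDesign:
    """Draw the two map groups of a study design from the spec's noise model."""
    rng = np.random.default_rng(spec.seed)
    r0, r1, c0, c1 = spec.effect_region
    effect = np.zeros(spec.shape)
    effect[r0:r1, c0:c1] = spec.effect_size

    group_a, group_b = [], []
    for i in range(spec.n_per_group):
        off_a = rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
        off_b = off_a if spec.paired else (
            rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
        )
        group_a.append(
            spec.base_intensity
            + off_a
            + effect
            + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        )
        group_b.append(
            spec.base_intensity + off_b + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        )
    return StudyDesign(group_a, group_b, paired=spec.paired)
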