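"""Unwarping, standardization and background normalization of vessel maps.

A curved vessel plus its orthogonal frame is converted into a rectangular
intensity map: image intensities are recorded along each orthogonal segment
into one row, rows are stretched according to the physical length of the
medial axis (length correction), anatomical sections are resampled to fixed
target lengths and every profile to a fixed width, the assembled map is
Gaussian-smoothed, and finally divided by the subject's mean background
intensity so that maps from different subjects are pixel-wise comparable.

Processing order: record rows -> length-correct -> per-section length rescale
-> width rescale -> smooth -> background-normalize.  Smoothing sits after
standardization and before normalization (normalization is a scalar division
and commutes with the linear resampling/smoothing steps); the applied order
is recorded in the map metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .geometry import OrthogonalFrame, SectionDefinition

__all__ = [
    "RawMap",
    "StandardizationSpec",
    "VesselMap",
    "BackgroundRegion",
    "record_rows",
    "length_correct",
    "standardize",
    "normalize_background",
    "positions_to_rows",
]

DEFAULT_SECTION_LENGTHS = (50, 50, 50, 50, 200)
DEFAULT_WIDTH = 40
DEFAULT_SIGMA = 3.0


@dataclass(eq=False)
class RawMap:
    """Unwarped intensity grid; one row per orthogonal segment (or per
    physical-length sample after length correction)."""

    values: np.ndarray
    row_positions: np.ndarray  # medial arc length (pixels) per row

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.row_positions = np.asarray(self.row_positions, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raw map values must be 2D")
        if len(self.row_positions) != self.values.shape[0]:
            raise ValueError("row_positions must have one entry per row")
        if np.any(np.diff(self.row_positions) < 0):
            raise ValueError("row_positions must be non-decreasing")


@dataclass(frozen=True)
class StandardizationSpec:
    """Target geometry of a standardized map.

    Defaults follow the five-section aortic layout: four 50-pixel sections
    across the arch (kept large relative to their physical size so the
    strongly bent arch is not under-represented) and one 200-pixel section
    for the descending portion, at a uniform 40-pixel width, smoothed with a
    Gaussian of sigma = 3 pixels.
    """

    section_lengths: tuple[int, ...] = DEFAULT_SECTION_LENGTHS
    width: int = DEFAULT_WIDTH
    smoothing_sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        if any(int(l) <= 0 for l in self.section_lengths):
            raise ValueError("section lengths must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing sigma must be >= 0")

    @property
    def total_length(self) -> int:
        return int(sum(self.section_lengths))


@dataclass(eq=False)
class VesselMap:
    """Standardized rectangular intensity map with normalization metadata."""

    values: np.ndarray
    section_offsets: np.ndarray
    normalization_factor: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.section_offsets = np.asarray(self.section_offsets, dtype=int)
        if self.normalization_factor <= 0:
            raise ValueError("normalization factor must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def section_rows(self, section: int) -> tuple[int, int]:
        """Half-open row range [r0, r1) of a section."""
        bounds = np.append(self.section_offsets, self.values.shape[0])
        if not 0 <= section < len(self.section_offsets):
            raise ValueError(f"no section {section}")
        return int(bounds[section]), int(bounds[section + 1])


@dataclass(frozen=True)
class BackgroundRegion:
    """Background reference region on a standardized map.

    Either a section index (e.g. the uninflamed reference artery section in
    the anatomical layout) or explicit row/column ranges, or both (ranges
    are then relative to the whole map and intersected with the section
    rows).  Ranges are half-open ``(start, stop)``.
    """

    section: int | None = None
    rows: tuple[int, int] | None = None
    cols: tuple[int, int] | None = None

    def resolve(self, vmap: VesselMap) -> tuple[slice, slice]:
        if self.section is None and self.rows is None and self.cols is None:
            raise ValueError("background region is empty: give a section or ranges")
        if self.section is not None:
            r0, r1 = vmap.section_rows(self.section)
            if self.rows is not None:
                r0, r1 = max(r0, self.rows[0]), min(r1, self.rows[1])
        elif self.rows is not None:
            r0, r1 = self.rows
        else:
            r0, r1 = 0, vmap.values.shape[0]
        c0, c1 = self.cols if self.cols is not None else (0, vmap.values.shape[1])
        if r1 <= r0 or c1 <= c0:
            raise ValueError("background region is empty")
        return slice(r0, r1), slice(c0, c1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def record_rows(
    image: np.ndarray, frame: OrthogonalFrame, samples_per_row: int = DEFAULT_WIDTH
) -> RawMap:
    """Sample the image along each orthogonal segment into one map row.

    Each segment is sampled at ``samples_per_row`` equidistant points (the
    midpoints of equal subdivisions, so the samples tile the profile) with
    bilinear interpolation.  Row order follows the frame's proximal->distal
    segment order; row positions are the cumulative medial-axis arc length.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if samples_per_row < 1:
        raise ValueError("samples_per_row must be >= 1")
    ea, eb = frame.endpoint_arrays()
    h, w = img.shape
    for pts in (ea, eb):
        if (
            pts[:, 0].min() < -1e-6
            or pts[:, 0].max() > w - 1 + 1e-6
            or pts[:, 1].min() < -1e-6
            or pts[:, 1].max() > h - 1 + 1e-6
        ):
            raise ValueError("orthogonal segment endpoint outside image bounds")
    frac = (np.arange(samples_per_row) + 0.5) / samples_per_row
    pts = ea[:, None, :] + frac[None, :, None] * (eb - ea)[:, None, :]
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])  # row=y, col=x
    vals = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    vals = vals.reshape(len(ea), samples_per_row)
    return RawMap(vals, frame.medial_axis.cumulative_length.copy())


def _cubic_interpolator(x: np.ndarray, y: np.ndarray, axis: int):
    """Natural cubic interpolant (linear for two samples); linear precision."""
    if len(x) == 2:
        slope = (np.take(y, 1, axis=axis) - np.take(y, 0, axis=axis)) / (x[1] - x[0])

        def f(xn):
            xn = np.asarray(xn, dtype=float)
            shp = [1] * y.ndim
            shp[axis] = len(xn)
            t = (xn - x[0]).reshape(shp)
            return np.expand_dims(np.take(y, 0, axis=axis), axis) + t * np.expand_dims(
                slope, axis
            )

        return f
    return CubicSpline(x, y, axis=axis, bc_type="natural")


def length_correct(raw: RawMap) -> RawMap:
    """Stretch rows according to the physical medial-axis length.

    Output row indices are proportional to arc length; the number of output
    rows equals the total medial length in pixels, rounded half-up.  Rows at
    duplicate positions are dropped (first kept) before cubic resampling.
    """
    pos = raw.row_positions
    uniq, idx = np.unique(pos, return_index=True)
    if len(uniq) < 2:
        raise ValueError("all rows lie at the same medial position")
    total = uniq[-1] - uniq[0]
    n_out = max(2, int(np.floor(total + 0.5)))
    targets = np.linspace(uniq[0], uniq[-1], n_out)
    interp = _cubic_interpolator(uniq, raw.values[idx], axis=0)
    return RawMap(interp(targets), targets)


def positions_to_rows(raw: RawMap, positions) -> np.ndarray:
    """Nearest row index of given medial arc-length positions."""
    rows = np.interp(positions, raw.row_positions, np.arange(len(raw.row_positions)))
    return np.round(rows).astype(int)


def standardize(
    raw: RawMap,
    sections: SectionDefinition,
    spec: StandardizationSpec = StandardizationSpec(),
) -> VesselMap:
    """Resample sections to target lengths, rows to target width, then smooth.

    ``sections.cut_indices`` index rows of ``raw`` (the first and last cut
    close the region; rows outside are discarded).  Each section is
    resampled independently with a natural cubic interpolant: section ``s``
    covers input rows ``[c_s, c_{s+1})`` — the final section includes its
    last row — so a map already at target geometry passes through unchanged.
    Gaussian smoothing (reflective borders) is applied to the assembled map.
    """
    cuts = sections.cut_indices
    sections.validate_for(raw.values.shape[0])
    if sections.section_count != len(spec.section_lengths):
        raise ValueError(
            f"{sections.section_count} sections defined but "
            f"{len(spec.section_lengths)} target lengths given"
        )
    blocks = []
    n_sec = sections.section_count
    for s in range(n_sec):
        c0, c1 = int(cuts[s]), int(cuts[s + 1])
        if c1 - c0 < 1:
            raise ValueError("section with fewer than 2 rows")
        block = raw.values[c0 : c1 + 1]
        n_rows = block.shape[0]
        length = int(spec.section_lengths[s])
        if s == n_sec - 1:
            # final section maps inclusively onto its target rows
            x_new = np.linspace(0.0, n_rows - 1.0, length)
        else:
            x_new = (c1 - c0) / length * np.arange(length)
        interp = _cubic_interpolator(np.arange(n_rows, dtype=float), block, axis=0)
        blocks.append(interp(x_new))
    grid = np.vstack(blocks)

    n_col = grid.shape[1]
    if n_col == 1:
        grid = np.repeat(grid, spec.width, axis=1)
    else:
        interp = _cubic_interpolator(np.arange(n_col, dtype=float), grid, axis=1)
        grid = interp(np.linspace(0.0, n_col - 1.0, spec.width))

    if spec.smoothing_sigma > 0:
        grid = ndimage.gaussian_filter(grid, spec.smoothing_sigma, mode="reflect")

    offsets = np.concatenate([[0], np.cumsum(spec.section_lengths)[:-1]])
    return VesselMap(
        grid,
        offsets,
        1.0,
        metadata={
            "section_lengths": list(spec.section_lengths),
            "width": int(spec.width),
            "smoothing_sigma": float(spec.smoothing_sigma),
            "processing_order": "sections->width->smooth->normalize",
        },
    )


def normalize_background(vmap: VesselMap, background: BackgroundRegion) -> VesselMap:
    """Divide the map by its mean intensity over the background region."""
    rs, cs = background.resolve(vmap)
    mean = float(vmap.values[rs, cs].mean())
    if mean <= 0:
        raise ValueError(
            f"background mean is {mean}; background region appears corrupt"
        )
    meta = dict(vmap.metadata)
    meta["background_region"] = {
        "section": background.section,
        "rows": background.rows,
        "cols": background.cols,
    }
    return VesselMap(vmap.values / mean, vmap.section_offsets.copy(), mean, meta)
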