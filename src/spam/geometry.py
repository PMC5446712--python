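"""Vessel boundary geometry.

Builds the unwarping scaffold for a curved vessel imaged in 2D: two boundary
curves are interpolated through user-marked wall points with natural cubic
splines under centripetal parameterization, densely sampled into polygonal
chains, and connected by nearest-neighbour cross-vessel ("orthogonal") line
segments.  A non-crossing subset of those segments — segments from the locally
longer boundary within each stretch between mutual nearest-neighbour pairs —
covers the whole vessel area; their midpoints form the medial axis used for
length measurement and unwarping.

Coordinates are continuous, 0-based, pixel-centre convention: ``x`` is the
image column, ``y`` the image row.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "BoundaryCurve",
    "PolygonalChain",
    "OrthogonalSegment",
    "OrthogonalFrame",
    "SectionDefinition",
    "fit_boundary_spline",
    "sample_chain",
    "nearest_neighbor_segments",
    "build_frame",
    "medial_centrality",
    "coverage_fraction",
    "chains_to_mask",
    "centripetal_knots",
]

DEFAULT_STEP = 0.1
"""Default chain sampling step in centripetal knot units.

Dense enough that the resulting orthogonal segments cover every pixel of the
vessel area for vessels at typical planar-imaging resolution (roughly two
samples per pixel of boundary length)."""


def centripetal_knots(points: np.ndarray) -> np.ndarray:
    """Knot vector with increments proportional to sqrt(chord length)."""
    pts = np.asarray(points, dtype=float)
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chords == 0.0):
        raise ValueError("consecutive boundary points must be distinct")
    return np.concatenate([[0.0], np.cumsum(np.sqrt(chords))])


@dataclass(eq=False)
class BoundaryCurve:
    """Interpolating natural cubic spline through ordered wall points.

    The curve passes through every control point exactly; the parameter is
    the centripetal knot value, strictly increasing along the control points.
    """

    control_points: np.ndarray
    knots: np.ndarray
    _spline: CubicSpline = field(repr=False)

    def __call__(self, t):
        """Evaluate the curve at parameter values ``t`` -> (..., 2) array."""
        return self._spline(t)

    @property
    def parameter_range(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])


@dataclass(eq=False)
class PolygonalChain:
    """Ordered point list approximating a curve, with cumulative arc length."""

    points: np.ndarray
    cumulative_length: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 1:
            raise ValueError("chain needs an (n, 2) point array with n >= 1")
        if self.cumulative_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.cumulative_length = np.concatenate([[0.0], np.cumsum(seg)])

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_length(self) -> float:
        return float(self.cumulative_length[-1])


@dataclass(eq=False)
class OrthogonalSegment:
    """Cross-vessel segment joining a point on each boundary chain.

    ``origin`` records which chain the segment emanates from ("A", "B", or
    "mutual" for mutually-nearest-neighbour pairs).
    """

    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    index_a: int
    index_b: int
    mutual: bool
    origin: str = "A"

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.endpoint_a) + np.asarray(self.endpoint_b))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.endpoint_b) - np.asarray(self.endpoint_a)))


@dataclass(eq=False)
class OrthogonalFrame:
    """Ordered non-crossing orthogonal segments plus the medial axis.

    ``segments`` run proximal -> distal; ``medial_axis`` holds exactly one
    point (the segment midpoint) per segment.  ``endpoint_a`` of every
    segment lies on ``chain_a``.
    """

    segments: list[OrthogonalSegment]
    medial_axis: PolygonalChain
    chain_a: PolygonalChain
    chain_b: PolygonalChain

    def __len__(self) -> int:
        return len(self.segments)

    def endpoint_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([s.endpoint_a for s in self.segments], dtype=float)
        b = np.array([s.endpoint_b for s in self.segments], dtype=float)
        return a, b

    def to_json(self) -> str:
        items = [
            {
                "endpoint_a": list(map(float, s.endpoint_a)),
                "endpoint_b": list(map(float, s.endpoint_b)),
                "index_a": int(s.index_a),
                "index_b": int(s.index_b),
                "mutual": bool(s.mutual),
                "origin": s.origin,
                "midpoint": list(map(float, s.midpoint)),
            }
            for s in self.segments
        ]
        return json.dumps(items)


@dataclass(eq=False)
class SectionDefinition:
    """Segment indices delimiting anatomical sections along a frame.

    ``cut_indices`` are indices into ``OrthogonalFrame.segments``; the first
    and last index close the region of interest (rows outside them are
    discarded).  Section ``s`` spans cut ``s`` .. cut ``s+1``.
    """

    cut_indices: np.ndarray

    def __post_init__(self):
        self.cut_indices = np.asarray(self.cut_indices, dtype=int)
        if self.cut_indices.ndim != 1 or len(self.cut_indices) < 2:
            raise ValueError("need at least two cut indices")
        if np.any(np.diff(self.cut_indices) <= 0):
            raise ValueError("cut indices must be strictly increasing")
        if self.cut_indices[0] < 0:
            raise ValueError("cut indices must be non-negative")

    @property
    def section_count(self) -> int:
        return len(self.cut_indices) - 1

    def validate_for(self, n_rows: int) -> None:
        if self.cut_indices[-1] >= n_rows:
            raise ValueError(
                f"cut index {self.cut_indices[-1]} out of range for {n_rows} rows"
            )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fit_boundary_spline(points) -> BoundaryCurve:
    """Interpolate ordered wall points with a natural cubic spline.

    Knot spacing follows the centripetal scheme (increments proportional to
    the square root of chord length), which avoids the overshoot of uniform
    parameterization on unevenly marked points.  Endpoint second derivatives
    are zero (natural boundary condition); the two-point case degenerates to
    the straight segment.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y coordinates")
    if len(pts) < 2:
        raise ValueError("at least two boundary points are required")
    if not np.all(np.isfinite(pts)):
        raise ValueError("boundary points must be finite")
    knots = centripetal_knots(pts)
    spline = CubicSpline(knots, pts, axis=0, bc_type="natural")
    return BoundaryCurve(control_points=pts, knots=knots, _spline=spline)


def sample_chain(curve: BoundaryCurve, step: float = DEFAULT_STEP) -> PolygonalChain:
    """Evaluate the curve at uniform parameter steps into a polygonal chain.

    Parameters run from the first knot to the last in increments of ``step``
    (centripetal knot units); the final knot is always included.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    t0, t1 = curve.parameter_range
    n = int(math.floor((t1 - t0) / step + 1e-12))
    ts = t0 + step * np.arange(n + 1)
    ts = np.minimum(ts, t1)
    if ts[-1] < t1 - 1e-12:
        ts = np.append(ts, t1)
    return PolygonalChain(np.asarray(curve(ts), dtype=float))


def _nearest_indices(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Index of the Euclidean-nearest target point for each source point.

    Brute force (lowest index wins on exact ties) below a size cutoff, kd-tree
    above it.
    """
    if len(src) * len(tgt) <= 4_000_000:
        return cdist(src, tgt).argmin(axis=1)
    return cKDTree(tgt).query(src)[1]


def nearest_neighbor_segments(
    source: PolygonalChain, target: PolygonalChain
) -> list[OrthogonalSegment]:
    """One segment per source point, to its nearest neighbour on ``target``.

    The ``mutual`` flag marks segments whose target point's own nearest
    source point is the originating point.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("chains must be non-empty")
    nn = _nearest_indices(source.points, target.points)
    back = _nearest_indices(target.points, source.points)
    segs = []
    for i in range(len(source)):
        j = int(nn[i])
        segs.append(
            OrthogonalSegment(
                endpoint_a=source.points[i].copy(),
                endpoint_b=target.points[j].copy(),
                index_a=i,
                index_b=j,
                mutual=bool(back[j] == i),
                origin="A",
            )
        )
    return segs


def _cross_z(o, a, b):
    """z-component of (a - o) x (b - o); broadcasts."""
    o = np.asarray(o, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - (
        a[..., 1] - o[..., 1]
    ) * (b[..., 0] - o[..., 0])


def segments_cross(p1, p2, q1, q2):
    """Strict interior crossing test; shared endpoints do not count.

    Broadcasts: q1/q2 may be (n, 2) arrays against a single p segment.
    """
    d1 = _cross_z(p1, p2, q1)
    d2 = _cross_z(p1, p2, q2)
    d3 = _cross_z(q1, q2, p1)
    d4 = _cross_z(q1, q2, p2)
    return (d1 * d2 < 0) & (d3 * d4 < 0)


def build_frame(chain_a: PolygonalChain, chain_b: PolygonalChain) -> OrthogonalFrame:
    """Combine the two directed nearest-neighbour sets into a non-crossing frame.

    Mutual nearest-neighbour pairs mark inflection points or straight
    portions; between consecutive mutual pairs the segments emanating from
    the locally longer boundary (the outside of the bend, measured by
    sub-chain arc length; ties keep chain A) are retained.  Maximal runs of
    mutual segments are kept verbatim.  Any residual crossing — possible
    with noisy manual points — is resolved greedily by dropping the later
    segment, with a warning.
    """
    A, B = chain_a.points, chain_b.points
    nA, nB = len(A), len(B)
    if nA < 2 or nB < 2:
        raise ValueError("frame construction requires chains of >= 2 points")
    # opposite orientation shows as crossing first-to-first / last-to-last connectors
    if bool(segments_cross(A[0], B[0], A[-1], B[-1])):
        raise ValueError(
            "boundary chains appear oppositely oriented "
            "(first-to-first and last-to-last connectors cross)"
        )

    nn_ab = _nearest_indices(A, B)
    nn_ba = _nearest_indices(B, A)
    mutual_i = np.where(nn_ba[nn_ab] == np.arange(nA))[0]

    # mutual pairs ordered along chain A; enforce monotone progress on B
    pairs: list[tuple[int, int]] = []
    last_j = -1
    for i in mutual_i:
        j = int(nn_ab[i])
        if j > last_j:
            pairs.append((int(i), j))
            last_j = j

    cum_a, cum_b = chain_a.cumulative_length, chain_b.cumulative_length
    ext = [(-1, -1)] + pairs + [(nA, nB)]

    items: list[tuple[str, int]] = []  # (origin, source index)
    for t in range(len(ext) - 1):
        (i0, j0), (i1, j1) = ext[t], ext[t + 1]
        la = cum_a[min(i1, nA - 1)] - cum_a[max(i0, 0)]
        lb = cum_b[min(j1, nB - 1)] - cum_b[max(j0, 0)]
        if la >= lb:
            items.extend(("A", i) for i in range(i0 + 1, min(i1, nA)))
        else:
            items.extend(("B", j) for j in range(j0 + 1, min(j1, nB)))
        if t + 1 < len(ext) - 1:  # the bounding mutual segment itself
            items.append(("M", i1))

    candidates: list[OrthogonalSegment] = []
    for origin, idx in items:
        if origin == "A" or origin == "M":
            i, j = idx, int(nn_ab[idx])
            candidates.append(
                OrthogonalSegment(
                    endpoint_a=A[i].copy(),
                    endpoint_b=B[j].copy(),
                    index_a=i,
                    index_b=j,
                    mutual=(origin == "M"),
                    origin="mutual" if origin == "M" else "A",
                )
            )
        else:
            j, i = idx, int(nn_ba[idx])
            candidates.append(
                OrthogonalSegment(
                    endpoint_a=A[i].copy(),
                    endpoint_b=B[j].copy(),
                    index_a=i,
                    index_b=j,
                    mutual=False,
                    origin="B",
                )
            )

    # greedy removal of residual crossings (later segment dropped)
    kept: list[OrthogonalSegment] = []
    kept_a = np.empty((0, 2))
    kept_b = np.empty((0, 2))
    dropped = 0
    for seg in candidates:
        if len(kept) and bool(
            segments_cross(seg.endpoint_a, seg.endpoint_b, kept_a, kept_b).any()
        ):
            dropped += 1
            continue
        kept.append(seg)
        kept_a = np.vstack([kept_a, seg.endpoint_a])
        kept_b = np.vstack([kept_b, seg.endpoint_b])
    if dropped:
        logger.warning("dropped %d residual crossing segments", dropped)

    if not kept:
        raise ValueError("no orthogonal segments survive selection")

    mids = np.array([s.midpoint for s in kept])
    return OrthogonalFrame(
        segments=kept,
        medial_axis=PolygonalChain(mids),
        chain_a=chain_a,
        chain_b=chain_b,
    )


def medial_centrality(frame: OrthogonalFrame) -> tuple[float, float]:
    """Mean and SD of |distance to wall A - distance to wall B| per axis point.

    For each medial-axis point, the nearest point on each boundary chain is
    found; the absolute difference of the two distances is zero when the
    axis point sits exactly midway between the walls.  Sub-pixel values
    indicate a well-centred medial axis.
    """
    mids = frame.medial_axis.points
    da = cKDTree(frame.chain_a.points).query(mids)[0]
    db = cKDTree(frame.chain_b.points).query(mids)[0]
    diffs = np.abs(da - db)
    return float(diffs.mean()), float(diffs.std())


def coverage_fraction(frame: OrthogonalFrame, vessel_mask: np.ndarray) -> float:
    """Fraction of vessel-mask pixels touched by rasterized frame segments."""
    mask = np.asarray(vessel_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("vessel mask is empty")
    hit = np.zeros_like(mask)
    h, w = mask.shape
    pts = []
    for seg in frame.segments:
        n = max(2, int(math.ceil(2.0 * seg.length)) + 1)
        frac = np.linspace(0.0, 1.0, n)[:, None]
        pts.append(seg.endpoint_a[None, :] + frac * (seg.endpoint_b - seg.endpoint_a)[None, :])
    all_pts = np.vstack(pts)
    cc = np.clip(np.round(all_pts[:, 0]).astype(int), 0, w - 1)
    rr = np.clip(np.round(all_pts[:, 1]).astype(int), 0, h - 1)
    hit[rr, cc] = True
    return float(hit[mask].sum() / mask.sum())


def chains_to_mask(
    chain_a: PolygonalChain, chain_b: PolygonalChain, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize the region enclosed between the two boundary chains."""
    from skimage.draw import polygon

    poly = np.vstack([chain_a.points, chain_b.points[::-1]])
    rr, cc = polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask
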