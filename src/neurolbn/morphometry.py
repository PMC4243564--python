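"""Axonal morphometry from SWC reconstructions.

Computes the 18 axonal predictor variables X1..X18 used for interneuron
classification:

* X1   2-D convex hull perimeter of the axon (depth axis projected out)
* X2   total axon length
* X3-5 axon length in radial shells <150, 150-300, >300 um from the soma
* X6-8 axon length inside / outside the soma's cortical layer + proportion
* X9-11 axon length inside / outside the soma's cortical column + proportion
* X12-15 planar distances from axonal centroids (all / above / below soma)
         to the soma centroid + proportion
* X16-18 axon length above / below the soma + proportion

Geometric conventions: the cortical layer is a horizontal band of the
looked-up thickness centered on the soma centroid; the cortical column is
an infinite vertical cylinder (default diameter 300 um) whose axis passes
through the soma.  Segments crossing a shell, band, cylinder or plane
boundary are split at the exact parametric crossing, which makes the
length decompositions conserve total axon length to machine precision.

Coordinates are in micrometers.  By default the SWC Y axis is the
pia-directed vertical and Z the depth into the slice (the projection axis
for X1); both are configurable per dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial._qhull import QhullError

__all__ = [
    "SwcPoint",
    "Reconstruction",
    "NeuronMetadata",
    "FeatureVector",
    "FEATURE_NAMES",
    "parse_swc",
    "write_swc",
    "soma_centroid",
    "estimate_layer_thickness",
    "convex_hull_perimeter_2d",
    "total_axon_length",
    "radial_shell_lengths",
    "laminar_lengths",
    "columnar_lengths",
    "centroid_distances",
    "vertical_lengths",
    "compute_features",
]

FEATURE_NAMES = tuple(f"X{i}" for i in range(1, 19))

STRUCT_SOMA = 1
STRUCT_AXON = 2
_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class SwcPoint:
    id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Reconstruction:
    """A typed 3-D tracing: a forest of sample points.

    Derived arrays: ``soma_points`` (coordinates of soma-typed samples),
    ``axon_points`` (coordinates of axon-typed samples), and the axon
    segment endpoint arrays ``seg_a``/``seg_b`` (parent -> child), one row
    per axonal segment.  A segment is counted when the child point is
    axon-typed and its parent is axon- or soma-typed (the soma attachment
    segment belongs to the axon).
    """

    points: tuple[SwcPoint, ...]

    def __post_init__(self) -> None:
        self.points = tuple(self.points)
        by_id = {}
        for p in self.points:
            if p.id in by_id:
                raise ValueError(f"duplicate SWC id {p.id}")
            by_id[p.id] = p
        for p in self.points:
            if p.parent != -1 and p.parent not in by_id:
                raise ValueError(f"point {p.id} has dangling parent {p.parent}")
            if not all(math.isfinite(c) for c in (p.x, p.y, p.z)):
                raise ValueError(f"point {p.id} has non-finite coordinates")
        self._by_id = by_id
        soma = [p.xyz for p in self.points if p.structure == STRUCT_SOMA]
        axon = [p.xyz for p in self.points if p.structure == STRUCT_AXON]
        self.soma_points = np.array(soma) if soma else np.empty((0, 3))
        self.axon_points = np.array(axon) if axon else np.empty((0, 3))
        seg_a, seg_b, seg_parent_id = [], [], []
        for p in self.points:
            if p.structure != STRUCT_AXON or p.parent == -1:
                continue
            q = by_id[p.parent]
            if q.structure in (STRUCT_AXON, STRUCT_SOMA):
                seg_a.append(q.xyz)
                seg_b.append(p.xyz)
                seg_parent_id.append(p.id)
        self.seg_a = np.array(seg_a) if seg_a else np.empty((0, 3))
        self.seg_b = np.array(seg_b) if seg_b else np.empty((0, 3))
        self._seg_child_ids = tuple(seg_parent_id)

    @property
    def n_axon_segments(self) -> int:
        return self.seg_a.shape[0]

    def require_axon_and_soma(self) -> None:
        if self.soma_points.shape[0] == 0:
            raise ValueError("reconstruction has no soma points")
        if self.n_axon_segments == 0:
            raise ValueError("reconstruction has no axon segments")


@dataclass
class NeuronMetadata:
    """Per-neuron context needed by the laminar/columnar features."""

    neuron_id: str
    thickness_lo_um: float
    thickness_hi_um: float
    column_diameter_um: float = 300.0
    vertical_axis: str = "y"
    depth_axis: str = "z"

    def __post_init__(self) -> None:
        if self.thickness_lo_um > self.thickness_hi_um:
            raise ValueError("thickness interval lo > hi")
        if self.thickness_lo_um < 0:
            raise ValueError("negative layer thickness bound")
        if self.column_diameter_um <= 0:
            raise ValueError("column diameter must be positive")
        if self.vertical_axis == self.depth_axis:
            raise ValueError("vertical and depth axes must differ")

    @property
    def layer_thickness_um(self) -> float:
        return estimate_layer_thickness((self.thickness_lo_um, self.thickness_hi_um))

    @property
    def vertical(self) -> int:
        return _AXES[self.vertical_axis]

    @property
    def depth(self) -> int:
        return _AXES[self.depth_axis]


@dataclass(frozen=True)
class FeatureVector:
    """The 18 predictors; lengths/distances in um, proportions in [0, 1]."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 18:
            raise ValueError("expected 18 features")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def parse_swc(path) -> Reconstruction:
    """Read a standard 7-column SWC file (# comments allowed)."""
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            try:
                pid, struct = int(fields[0]), int(fields[1])
                x, y, z, radius = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed SWC line") from None
            points.append(SwcPoint(pid, struct, x, y, z, radius, parent))
    if not points:
        raise ValueError(f"{path}: empty reconstruction")
    return Reconstruction(tuple(points))


def write_swc(recon: Reconstruction, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for p in recon.points:
            fh.write(
                f"{p.id} {p.structure} {p.x:.17g} {p.y:.17g} {p.z:.17g} "
                f"{p.radius:.17g} {p.parent}\n"
            )


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def soma_centroid(recon: Reconstruction) -> np.ndarray:
    """Unweighted mean of the soma sample points."""
    if recon.soma_points.shape[0] == 0:
        raise ValueError("reconstruction has no soma points")
    return recon.soma_points.mean(axis=0)


def estimate_layer_thickness(interval: tuple[float, float]) -> float:
    """Midpoint of a (lo, hi) layer-thickness interval, in um."""
    lo, hi = interval
    if lo < 0 or hi < 0:
        raise ValueError("negative thickness bound")
    if lo > hi:
        raise ValueError("interval lo > hi")
    return (lo + hi) / 2.0


def _segment_lengths(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(b - a, axis=1)


def _split_segment(t_breaks: Iterable[float]) -> list[tuple[float, float]]:
    """Partition [0, 1] at the given interior parameters."""
    ts = sorted(t for t in t_breaks if 1e-12 < t < 1 - 1e-12)
    bounds = [0.0, *ts, 1.0]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _quad_roots(qa: float, qb: float, qc: float) -> list[float]:
    """Real roots of qa t^2 + qb t + qc = 0 (qa may be ~0)."""
    if abs(qa) < 1e-30:
        return [] if abs(qb) < 1e-30 else [-qc / qb]
    disc = qb * qb - 4 * qa * qc
    if disc <= 0:
        return []
    s = math.sqrt(disc)
    return [(-qb - s) / (2 * qa), (-qb + s) / (2 * qa)]


# ---------------------------------------------------------------------------
# the 18 features
# ---------------------------------------------------------------------------

def convex_hull_perimeter_2d(recon: Reconstruction, depth_axis: int = 2) -> float:
    """X1: perimeter of the 2-D convex hull of projected axon points.

    Degenerate hulls (collinear points spanning length L) use the 2L
    convention; a single point gives 0.
    """
    pts = np.delete(recon.axon_points, depth_axis, axis=1)
    pts = np.unique(pts, axis=0)
    if pts.shape[0] == 0:
        raise ValueError("no axon points")
    if pts.shape[0] == 1:
        return 0.0
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
        return float(
            np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1).sum()
        )
    except QhullError:
        # collinear: hull degenerates to a segment traversed both ways
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        return float(2.0 * (proj.max() - proj.min()))


def total_axon_length(recon: Reconstruction) -> float:
    """X2: sum of 3-D Euclidean axon segment lengths."""
    if recon.n_axon_segments == 0:
        raise ValueError("no axon segments")
    return float(_segment_lengths(recon.seg_a, recon.seg_b).sum())


def _path_start_distances(recon: Reconstruction, center: np.ndarray) -> np.ndarray:
    """Arc-length distance from the soma to each segment's start point."""
    dist: dict[int, float] = {}
    by_id = recon._by_id
    lengths = _segment_lengths(recon.seg_a, recon.seg_b)
    starts = np.empty(recon.n_axon_segments)
    # children are listed after parents in well-formed files we produce;
    # iterate until all resolved to stay order-independent
    pending = list(range(recon.n_axon_segments))
    while pending:
        progressed = False
        rest = []
        for si in pending:
            child = by_id[recon._seg_child_ids[si]]
            parent = by_id[child.parent]
            if parent.structure != STRUCT_AXON:
                start = float(np.linalg.norm(parent.xyz - center))
                dist[child.id] = start + lengths[si]
                starts[si] = start
                progressed = True
            elif parent.id in dist:
                start = dist[parent.id]
                dist[child.id] = start + lengths[si]
                starts[si] = start
                progressed = True
            else:
                rest.append(si)
                continue
        pending = rest
        if pending and not progressed:
            raise ValueError("axon tree has unresolved parent ordering")
    return starts


def radial_shell_lengths(recon: Reconstruction, r1: float = 150.0,
                         r2: float = 300.0,
                         distance: str = "euclidean") -> tuple[float, float, float]:
    """X3, X4, X5: axon length by distance-to-soma shells [0,r1), [r1,r2), [r2,inf).

    ``distance`` is "euclidean" (3-D distance to the soma centroid;
    default) or "path" (arc length along the arbor from the soma).
    Segments are split exactly at the shell boundaries.
    """
    if r1 >= r2:
        raise ValueError("r1 must be < r2")
    recon.require_axon_and_soma()
    c = soma_centroid(recon)
    lengths = _segment_lengths(recon.seg_a, recon.seg_b)
    out = [0.0, 0.0, 0.0]
    if distance == "path":
        starts = _path_start_distances(recon, c)
        for i in range(recon.n_axon_segments):
            L = lengths[i]
            if L == 0:
                continue
            breaks = [(r - starts[i]) / L for r in (r1, r2)]
            for t0, t1 in _split_segment(breaks):
                dmid = starts[i] + 0.5 * (t0 + t1) * L
                shell = 0 if dmid < r1 else (1 if dmid < r2 else 2)
                out[shell] += (t1 - t0) * L
        return tuple(out)
    if distance != "euclidean":
        raise ValueError("distance must be 'euclidean' or 'path'")
    for i in range(recon.n_axon_segments):
        a, b = recon.seg_a[i], recon.seg_b[i]
        d = b - a
        L = lengths[i]
        if L == 0:
            continue
        breaks = []
        for r in (r1, r2):
            qa = float(d @ d)
            qb = 2.0 * float(d @ (a - c))
            qc = float((a - c) @ (a - c)) - r * r
            breaks.extend(_quad_roots(qa, qb, qc))
        for t0, t1 in _split_segment(breaks):
            mid = a + 0.5 * (t0 + t1) * d
            dmid = float(np.linalg.norm(mid - c))
            shell = 0 if dmid < r1 else (1 if dmid < r2 else 2)
            out[shell] += (t1 - t0) * L
    return tuple(out)


def laminar_lengths(recon: Reconstruction, thickness: float,
                    vertical_axis: int = 1) -> tuple[float, float, float]:
    """X6, X7, X8: axon length inside/outside the soma's layer band.

    The layer is the band |v - v_soma| <= thickness/2 on the vertical
    axis, the soma assumed equidistant from the layer's confines.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    recon.require_axon_and_soma()
    c = soma_centroid(recon)
    half = thickness / 2.0
    lo, hi = c[vertical_axis] - half, c[vertical_axis] + half
    lengths = _segment_lengths(recon.seg_a, recon.seg_b)
    inside = 0.0
    for i in range(recon.n_axon_segments):
        a, b = recon.seg_a[i], recon.seg_b[i]
        L = lengths[i]
        if L == 0:
            continue
        va, vb = a[vertical_axis], b[vertical_axis]
        dv = vb - va
        breaks = []
        if abs(dv) > 1e-30:
            breaks = [(lo - va) / dv, (hi - va) / dv]
        for t0, t1 in _split_segment(breaks):
            vmid = va + 0.5 * (t0 + t1) * dv
            if lo <= vmid <= hi:
                inside += (t1 - t0) * L
    total = float(lengths.sum())
    x6 = min(inside, total)  # guard float round-off in the split sums
    x7 = total - x6
    return x6, x7, x6 / total


def columnar_lengths(recon: Reconstruction, diameter: float = 300.0,
                     vertical_axis: int = 1) -> tuple[float, float, float]:
    """X9, X10, X11: axon length inside/outside the soma's cortical column.

    The column is an infinite vertical cylinder of the given diameter whose
    axis passes through the soma centroid.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    recon.require_axon_and_soma()
    c = soma_centroid(recon)
    lateral = [i for i in range(3) if i != vertical_axis]
    r = diameter / 2.0
    lengths = _segment_lengths(recon.seg_a, recon.seg_b)
    inside = 0.0
    for i in range(recon.n_axon_segments):
        a, b = recon.seg_a[i], recon.seg_b[i]
        L = lengths[i]
        if L == 0:
            continue
        a2 = a[lateral] - c[lateral]
        d2 = b[lateral] - a[lateral]
        qa = float(d2 @ d2)
        qb = 2.0 * float(d2 @ a2)
        qc = float(a2 @ a2) - r * r
        breaks = _quad_roots(qa, qb, qc)
        for t0, t1 in _split_segment(breaks):
            mid2 = a2 + 0.5 * (t0 + t1) * d2
            if float(mid2 @ mid2) <= r * r:
                inside += (t1 - t0) * L
    total = float(lengths.sum())
    x9 = min(inside, total)
    x10 = total - x9
    return x9, x10, x9 / total


def _plane_distance(p: np.ndarray, q: np.ndarray, depth_axis: int) -> float:
    return float(np.linalg.norm(np.delete(p - q, depth_axis)))


def centroid_distances(recon: Reconstruction, vertical_axis: int = 1,
                       depth_axis: int = 2) -> tuple[float, float, float, float]:
    """X12..X15: planar centroid-to-soma distances.

    Centroids are unweighted means of axon sample points; distances are
    measured in the (lateral, vertical) image plane, i.e. with the depth
    axis projected out.  Points exactly at soma height count as "above".
    An empty above/below subset contributes distance 0; the proportion
    X15 = X13/(X13+X14) is 0.5 when both distances vanish.
    """
    recon.require_axon_and_soma()
    c = soma_centroid(recon)
    pts = recon.axon_points
    x12 = _plane_distance(pts.mean(axis=0), c, depth_axis)
    above = pts[pts[:, vertical_axis] >= c[vertical_axis]]
    below = pts[pts[:, vertical_axis] < c[vertical_axis]]
    x13 = _plane_distance(above.mean(axis=0), c, depth_axis) if len(above) else 0.0
    x14 = _plane_distance(below.mean(axis=0), c, depth_axis) if len(below) else 0.0
    denom = x13 + x14
    x15 = x13 / denom if denom > 0 else 0.5
    return x12, x13, x14, x15


def vertical_lengths(recon: Reconstruction,
                     vertical_axis: int = 1) -> tuple[float, float, float]:
    """X16, X17, X18: axon length above/below the soma plane.

    Segments are split at the horizontal plane through the soma centroid;
    segments lying exactly in the plane count as "above" (half-open
    convention).
    """
    recon.require_axon_and_soma()
    c = soma_centroid(recon)
    cv = c[vertical_axis]
    lengths = _segment_lengths(recon.seg_a, recon.seg_b)
    above = 0.0
    for i in range(recon.n_axon_segments):
        a, b = recon.seg_a[i], recon.seg_b[i]
        L = lengths[i]
        if L == 0:
            continue
        va, vb = a[vertical_axis], b[vertical_axis]
        dv = vb - va
        breaks = [(cv - va) / dv] if abs(dv) > 1e-30 else []
        for t0, t1 in _split_segment(breaks):
            vmid = va + 0.5 * (t0 + t1) * dv
            if vmid >= cv:
                above += (t1 - t0) * L
    total = float(lengths.sum())
    x16 = min(above, total)
    x17 = total - x16
    x18 = x16 / total if total > 0 else 0.5
    return x16, x17, x18


def compute_features(recon: Reconstruction, meta: NeuronMetadata,
                     radial_distance: str = "euclidean") -> FeatureVector:
    """Assemble X1..X18 for one reconstruction under its metadata."""
    recon.require_axon_and_soma()
    x1 = convex_hull_perimeter_2d(recon, depth_axis=meta.depth)
    x2 = total_axon_length(recon)
    x3, x4, x5 = radial_shell_lengths(recon, distance=radial_distance)
    x6, x7, x8 = laminar_lengths(
        recon, meta.layer_thickness_um, vertical_axis=meta.vertical
    )
    x9, x10, x11 = columnar_lengths(
        recon, meta.column_diameter_um, vertical_axis=meta.vertical
    )
    x12, x13, x14, x15 = centroid_distances(
        recon, vertical_axis=meta.vertical, depth_axis=meta.depth
    )
    x16, x17, x18 = vertical_lengths(recon, vertical_axis=meta.vertical)
    return FeatureVector((
        x1, x2, x3, x4, x5, x6, x7, x8, x9, x10,
        x11, x12, x13, x14, x15, x16, x17, x18,
    ))
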