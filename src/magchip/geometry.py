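"""Micromagnet pattern geometry.

The transport substrate is a 100-nm permalloy film patterned into periodic
"drop"-shaped magnets: a wide circular head tapering to a narrower rounded
tip.  Consecutive drops along a track are separated by a gap ``G``; the tip
width is the neck ``N``.  Two dimensionless ratios govern whether a bead of
diameter ``d_P`` can be carried along the track by a rotating conical field:

* ``beta = d_P / G`` — the bead must be large enough (relative to the gap)
  to be handed from one drop tip to the next head;
* ``gamma = d_P / N`` — the bead must not be too large relative to the neck,
  or the tip region cannot hold it at the bead's flight height.

Coordinates are chip-plane micrometres, x right / y up, z normal to the
film.  Polygons are closed vertex loops in counter-clockwise order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShPolygon

from .errors import (
    EmptyPatternError,
    InvalidArgumentError,
    InvalidSpecError,
    UnsupportedStyleError,
)

BEND_STYLES = (
    "naive_obtuse",
    "multi_drop_corner",
    "corner_magnet_A",
    "corner_magnet_B",
    "inside_corner",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MagnetPattern:
    """A set of patterned thin-film magnets.

    Parameters
    ----------
    polygons
        List of ``(k, 2)`` float arrays, closed CCW vertex loops in um.
        The closing vertex is implicit (last != first).
    thickness
        Film thickness in um (default 0.1, i.e. 100 nm permalloy).
    label
        Free-text name of the pattern.
    labels
        Optional per-polygon labels (e.g. ``magnet1``/``magnet2``/``magnet3``
        around a bend corner).
    spine
        Optional ``(m, 2)`` polyline approximating the intended particle
        path; used to measure transport progress.
    metadata
        Construction metadata (gaps, period, style ...).
    """

    polygons: list
    thickness: float = 0.1
    label: str = ""
    labels: list = field(default_factory=list)
    spine: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.thickness <= 0:
            raise InvalidSpecError("film thickness must be positive")
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
                raise InvalidSpecError("each polygon needs >= 3 (x, y) vertices")
            if not _ShPolygon(p).is_valid:
                raise InvalidSpecError("polygon is self-intersecting")

    @property
    def n_magnets(self) -> int:
        return len(self.polygons)

    def shapely_polygons(self):
        return [_ShPolygon(p) for p in self.polygons]

    def bounding_box(self, pad: float = 0.0):
        """(xmin, ymin, xmax, ymax) over all vertices, padded by ``pad`` um."""
        if not self.polygons:
            raise EmptyPatternError("pattern has no polygons")
        pts = np.vstack(self.polygons)
        lo = pts.min(axis=0) - pad
        hi = pts.max(axis=0) + pad
        return lo[0], lo[1], hi[0], hi[1]

    def translated(self, dx: float, dy: float) -> "MagnetPattern":
        return MagnetPattern(
            [p + np.array([dx, dy]) for p in self.polygons],
            thickness=self.thickness,
            label=self.label,
            labels=list(self.labels),
            spine=None if self.spine is None else self.spine + np.array([dx, dy]),
            metadata=dict(self.metadata),
        )

    def consecutive_gaps(self):
        """Minimum surface-to-surface distance between consecutive magnets."""
        shp = self.shapely_polygons()
        return [shp[i].distance(shp[i + 1]) for i in range(len(shp) - 1)]


@dataclass(frozen=True)
class TrackSpec:
    """Parameters of a straight drop-shape track.

    The spatial period is ``drop_length + gap``; a phase-locked bead
    advances one period per field rotation.
    """

    drop_length: float = 30.0
    drop_width: float = 16.0
    neck: float = 15.0
    gap: float = 15.0
    n_units: int = 5
    orientation: tuple = (1.0, 0.0)

    def __post_init__(self):
        for name in ("drop_length", "drop_width", "neck", "gap"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive, got {getattr(self, name)}")
        if self.neck > self.drop_width:
            raise InvalidSpecError("neck width cannot exceed drop width")
        if self.neck >= 2 * self.drop_length:
            raise InvalidSpecError("neck too large for drop length")
        if self.n_units < 2:
            raise InvalidSpecError("a track needs n_units >= 2")
        n = np.hypot(*self.orientation)
        if not n > 0:
            raise InvalidSpecError("orientation must be a nonzero vector")

    @property
    def period(self) -> float:
        """Spatial period lambda = drop_length + gap, um."""
        return self.drop_length + self.gap

    @property
    def unit_vector(self) -> np.ndarray:
        v = np.asarray(self.orientation, dtype=float)
        return v / np.hypot(*v)


@dataclass(frozen=True)
class BendSpec:
    """Parameters of a track bend joining two straight arms.

    ``turn_angle`` is the change of travel direction in degrees (CCW).
    ``corner_params`` carries style-specific lengths; defaults are derived
    from the arm spec so that every inter-magnet gap along the particle path
    stays <= the arm gap — except for the deliberately flawed
    ``naive_obtuse`` style whose corner gaps are enlarged.
    """

    style: str = "corner_magnet_A"
    turn_angle: float = 90.0
    arm_spec: TrackSpec = field(default_factory=TrackSpec)
    corner_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.style not in BEND_STYLES:
            raise UnsupportedStyleError(
                f"unknown bend style {self.style!r}; choose one of {BEND_STYLES}"
            )
        if not (0.0 < self.turn_angle < 180.0):
            raise InvalidSpecError("turn_angle must lie in (0, 180) degrees")


@dataclass(frozen=True)
class DesignRatios:
    """The two dimensionless transport design ratios."""

    d_P: float
    G: float
    N: float
    beta: float
    gamma: float


# ---------------------------------------------------------------------------
# drop outline
# ---------------------------------------------------------------------------

def drop_outline(drop_length: float, drop_width: float, neck: float,
                 n_head: int = 37, n_tip: int = 17, n_tail: int = 14,
                 tail_radius_factor: float = 0.5) -> np.ndarray:
    """CCW outline of a single drop magnet in local coordinates.

    A teardrop: convex head circle (radius ``drop_width/2``, leftmost point
    at x=0) joined to a convex tip cap (radius ``neck/2``, rightmost point
    at x=``drop_length``) by *concave* fillet arcs of radius
    ``tail_radius_factor * drop_length``.  The alternation of boundary
    curvature sign (convex head/tip, concave tail) is what lets the energy
    well detach from one magnet and hand the bead to the next: on a fully
    convex island the well merely circulates and the bead orbits in place.
    """
    r1 = drop_width / 2.0
    r2 = neck / 2.0
    c1 = np.array([r1, 0.0])
    c2 = np.array([drop_length - r2, 0.0])
    d = c2[0] - c1[0]
    if d <= 0 or d <= abs(r1 - r2):
        raise InvalidSpecError("drop_length too short for the head/neck radii")
    rc = tail_radius_factor * drop_length
    # fillet circle tangent externally to head and tip circles, centre above
    # (upper tail) / below (lower tail) the axis
    ra, rb = rc + r1, rc + r2
    # intersection of circles |O-c1|=ra, |O-c2|=rb
    x = (d * d + ra * ra - rb * rb) / (2.0 * d)
    y2 = ra * ra - x * x
    if y2 <= 0:
        raise InvalidSpecError("tail fillet radius too small for this drop")
    y = math.sqrt(y2)
    o_u = c1 + np.array([x, y])      # upper fillet centre
    o_l = c1 + np.array([x, -y])     # lower fillet centre

    def ang(v):
        return math.atan2(v[1], v[0])

    # head arc: from upper tangency CCW through pi to lower tangency
    a1u = ang(o_u - c1)
    th = np.linspace(a1u, 2.0 * math.pi - a1u, n_head)
    head = c1 + r1 * np.stack([np.cos(th), np.sin(th)], axis=1)
    # lower fillet: clockwise (concave) from head tangency to tip tangency
    b1 = ang(c1 - o_l)
    b2 = ang(c2 - o_l)
    tb = np.linspace(b1, b2, n_tail + 2)[1:-1]
    tail_lo = o_l + rc * np.stack([np.cos(tb), np.sin(tb)], axis=1)
    # tip cap: CCW through 0
    a2u = ang(o_u - c2)
    tt = np.linspace(-a2u, a2u, n_tip)
    tip = c2 + r2 * np.stack([np.cos(tt), np.sin(tt)], axis=1)
    # upper fillet: concave back to the head
    ub = np.linspace(ang(c2 - o_u), ang(c1 - o_u), n_tail + 2)[1:-1]
    tail_up = o_u + rc * np.stack([np.cos(ub), np.sin(ub)], axis=1)
    return np.vstack([head, tail_lo, tip, tail_up])


def _rot(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def _transform(poly: np.ndarray, deg: float, offset) -> np.ndarray:
    return poly @ _rot(deg).T + np.asarray(offset, dtype=float)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_drop_track(spec: TrackSpec, thickness: float = 0.1) -> MagnetPattern:
    """Build a straight periodic drop-shape track.

    Drops point along ``spec.orientation``; drop ``k`` occupies arclength
    ``[k*period, k*period + drop_length]``, leaving a gap ``G`` between each
    tip and the next head.
    """
    base = drop_outline(spec.drop_length, spec.drop_width, spec.neck)
    u = spec.unit_vector
    ang = math.degrees(math.atan2(u[1], u[0]))
    polys = []
    for k in range(spec.n_units):
        polys.append(_transform(base, ang, u * (k * spec.period)))
    length = spec.n_units * spec.period
    spine = np.stack([-u * spec.gap, u * (length + spec.gap)])
    gap_centers = [k * spec.period + spec.drop_length + spec.gap / 2.0
                   for k in range(spec.n_units - 1)]
    return MagnetPattern(
        polys,
        thickness=thickness,
        label="straight_drop_track",
        labels=[f"drop{k}" for k in range(spec.n_units)],
        spine=spine,
        metadata={
            "period": spec.period,
            "gap": spec.gap,
            "neck": spec.neck,
            "drop_length": spec.drop_length,
            "drop_width": spec.drop_width,
            "gap_centers": gap_centers,
            "kind": "track",
        },
    )


def design_ratios(d_P: float, G: float, N: float) -> DesignRatios:
    """Compute beta = d_P/G and gamma = d_P/N (exact arithmetic)."""
    for name, v in (("d_P", d_P), ("G", G), ("N", N)):
        if not v > 0:
            raise InvalidArgumentError(f"{name} must be positive, got {v}")
    return DesignRatios(d_P=d_P, G=G, N=N, beta=d_P / G, gamma=d_P / N)


def rasterize(pattern: MagnetPattern, resolution: float, pad: float = 10.0):
    """Boolean occupancy grid of the film.

    Returns ``(grid, extent)`` where ``grid[j, i]`` is True when the centre
    of cell ``(i, j)`` lies inside any magnet polygon, and ``extent`` is
    ``(xmin, ymin, xmax, ymax)``.  The grid covers the pattern bounding box
    padded by ``pad`` um (>= 10 by default).
    """
    if not pattern.polygons:
        raise EmptyPatternError("cannot rasterize an empty pattern")
    if not resolution > 0:
        raise InvalidArgumentError("resolution must be positive")
    pad = max(pad, 10.0)
    xmin, ymin, xmax, ymax = pattern.bounding_box(pad=pad)
    xs = np.arange(xmin + resolution / 2.0, xmax, resolution)
    ys = np.arange(ymin + resolution / 2.0, ymax, resolution)
    XX, YY = np.meshgrid(xs, ys)
    grid = np.zeros(XX.shape, dtype=bool)
    for p in pattern.polygons:
        grid |= shapely.contains_xy(_ShPolygon(p), XX, YY)
    return grid, (xmin, ymin, xmax, ymax)


# ---------------------------------------------------------------------------
# bends
# ---------------------------------------------------------------------------

def _arm(spec: TrackSpec, ang_deg: float, origin, n_units: int, reverse=False):
    """Drop polygons of one straight arm; returns (polys, tip_point, head_point)."""
    base = drop_outline(spec.drop_length, spec.drop_width, spec.neck)
    u = _rot(ang_deg) @ np.array([1.0, 0.0])
    polys = [
        _transform(base, ang_deg, np.asarray(origin) + u * (k * spec.period))
        for k in range(n_units)
    ]
    return polys, u


def make_bend(spec: BendSpec, thickness: float = 0.1,
              n_arm_units: int = 3) -> MagnetPattern:
    """Join two straight track arms at ``turn_angle`` with a corner element.

    All styles except ``naive_obtuse`` keep every inter-magnet gap along the
    particle path <= the arm gap ``G`` so the design ratio ``beta`` is
    preserved through the corner.  ``naive_obtuse`` reproduces the flawed
    design in which the corner is formed by simply enlarging the tip-to-tip
    gaps (default 2 G), which blocks small beads.

    The three magnets around the corner are labelled ``magnet1`` (last arm-1
    drop), ``magnet2`` (corner element; for multi-drop corners the middle
    corner drop), ``magnet3`` (next magnet on the outgoing side).
    """
    arm = spec.arm_spec
    G, L, W, N = arm.gap, arm.drop_length, arm.drop_width, arm.neck
    turn = spec.turn_angle
    cp = dict(spec.corner_params)

    polys: list = []
    labels: list = []
    spine_pts: list = []

    # incoming arm along +x; its last tip ends at x = n*period - G
    p1, u1 = _arm(arm, 0.0, (0.0, 0.0), n_arm_units)
    tip1 = np.array([(n_arm_units - 1) * arm.period + L, 0.0])
    polys += p1
    labels += [f"arm1_{k}" for k in range(n_arm_units)]
    labels[-1] = "magnet1"
    spine_pts += [np.array([-G, 0.0]), tip1]

    u2 = _rot(turn) @ np.array([1.0, 0.0])

    def finish(corner_polys, corner_labels, arm2_head, path_spine_extra=()):
        """Add the corner and the outgoing arm starting with its head at arm2_head."""
        polys.extend(corner_polys)
        labels.extend(corner_labels)
        a2_origin = np.asarray(arm2_head, dtype=float)
        p2, _ = _arm(arm, turn, a2_origin, n_arm_units)
        polys.extend(p2)
        lab2 = [f"arm2_{k}" for k in range(n_arm_units)]
        if "magnet3" not in labels and "magnet3" not in corner_labels:
            lab2[0] = "magnet3"
        labels.extend(lab2)
        spine_pts.extend(path_spine_extra)
        spine_pts.append(a2_origin + u2 * (n_arm_units * arm.period + G))

    if spec.style == "naive_obtuse":
        # corner drop on the bisector at an ENLARGED tip-to-tip gap
        cg = cp.get("corner_gap", 2.0 * G)
        half = turn / 2.0
        c_origin = tip1 + _rot(half) @ np.array([cg, 0.0])
        base = drop_outline(L, W, N)
        corner = _transform(base, half, c_origin)
        c_tip = c_origin + _rot(half) @ np.array([L, 0.0])
        arm2_head = c_tip + u2 * cg
        finish([corner], ["magnet2"], arm2_head, [c_origin, c_tip])
        corner_gaps = [cg, cg]
    elif spec.style == "multi_drop_corner":
        # corner replaced by several small drops, each rotated a slight
        # angle with respect to the previous one, gaps kept at G
        k = int(cp.get("n_corner_drops", 3))
        scale = float(cp.get("corner_scale", 0.6))
        base = drop_outline(L * scale, W * scale, min(N * scale, W * scale))
        step = turn / (k + 1)
        prev_tip = tip1
        corner_polys, corner_labels = [], []
        extra = []
        for i in range(k):
            a = step * (i + 1)
            o = prev_tip + _rot(a) @ np.array([G, 0.0])
            corner_polys.append(_transform(base, a, o))
            corner_labels.append(f"corner_{i}")
            prev_tip = o + _rot(a) @ np.array([L * scale, 0.0])
            extra += [o, prev_tip]
        corner_labels[k // 2] = "magnet2"
        arm2_head = prev_tip + u2 * G
        finish(corner_polys, corner_labels, arm2_head, extra)
        corner_gaps = [G] * (k + 1)
    elif spec.style in ("corner_magnet_A", "corner_magnet_B", "inside_corner"):
        # single large drop-shaped magnet on the corner, oriented along the
        # outgoing arm so its tip hands the bead onward; sized so both path
        # gaps stay == G.  The corner magnet must itself be a teardrop: a
        # rotationally symmetric corner (disk) would trap the bead in orbit.
        if spec.style == "corner_magnet_A":
            sc_l, sc_w = cp.get("corner_scale_lw", (1.3, 1.0))
        elif spec.style == "corner_magnet_B":
            sc_l, sc_w = cp.get("corner_scale_lw", (1.6, 1.0))
        else:  # inside_corner: compact corner magnet hugging the inner side
            sc_l, sc_w = cp.get("corner_scale_lw", (1.0, 0.9))
        Lc, Wc = sc_l * L, sc_w * W
        Nc = min(N * sc_w, Wc)
        shape = drop_outline(Lc, Wc, Nc)
        corner0 = _transform(shape, turn, tip1)
        c0_sh = _ShPolygon(corner0)
        m1_sh = _ShPolygon(polys[-1])
        # slide the corner drop along the outgoing direction until its gap
        # to the last incoming drop is exactly G
        lo, hi = 0.0, 4.0 * arm.period
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            moved = _ShPolygon(corner0 + u2 * mid)
            if moved.distance(m1_sh) < G:
                lo = mid
            else:
                hi = mid
        corner = corner0 + u2 * hi
        c_sh = _ShPolygon(corner)
        c_origin = tip1 + u2 * hi
        c_tip = c_origin + u2 * Lc
        arm2_head = _place_arm2(c_sh, arm, u2, tip1, turn)
        finish([corner], ["magnet2"], arm2_head, [c_origin, c_tip])
        corner_gaps = [G, G]
    else:  # pragma: no cover - guarded by BendSpec
        raise UnsupportedStyleError(spec.style)

    pat = MagnetPattern(
        polys,
        thickness=thickness,
        label=f"bend_{spec.style}",
        labels=labels,
        spine=np.asarray(spine_pts),
        metadata={
            "style": spec.style,
            "turn_angle": turn,
            "gap": G,
            "neck": N,
            "period": arm.period,
            "corner_gaps": corner_gaps,
            "corner_gap_max": max(corner_gaps),
        },
    )
    pat.metadata["path_gap_max"] = _max_path_gap(pat)
    return pat


def _place_arm2(corner_shp, arm: TrackSpec, u2: np.ndarray,
                tip1: np.ndarray, turn: float) -> np.ndarray:
    """Slide arm 2 along its own axis until its first head clears the corner
    magnet by exactly the arm gap G (bisection on the offset)."""
    base = drop_outline(arm.drop_length, arm.drop_width, arm.neck)
    anchor = np.asarray(corner_shp.centroid.coords[0])

    def gap_at(s):
        head = anchor + u2 * s
        return _ShPolygon(_transform(base, turn, head)).distance(corner_shp)

    lo, hi = 0.0, 6.0 * arm.period
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap_at(mid) < arm.gap:
            lo = mid
        else:
            hi = mid
    return anchor + u2 * hi


def _max_path_gap(pattern: MagnetPattern) -> float:
    """Largest nearest-neighbour hop along the magnet sequence."""
    gaps = pattern.consecutive_gaps()
    return max(gaps) if gaps else 0.0


def make_disk_pattern(diameter: float = 20.0, n_disks: int = 1,
                      gap: float = 15.0, thickness: float = 0.1) -> MagnetPattern:
    """Row of circular disks — the rotationally symmetric geometry on which a
    conical field traps beads in closed orbits instead of transporting them."""
    if diameter <= 0 or gap <= 0 or n_disks < 1:
        raise InvalidSpecError("diameter/gap must be > 0, n_disks >= 1")
    r = diameter / 2.0
    th = np.linspace(0, 2 * math.pi, 72, endpoint=False)
    circ = r * np.stack([np.cos(th), np.sin(th)], axis=1)
    period = diameter + gap
    polys = [circ + np.array([r + k * period, 0.0]) for k in range(n_disks)]
    spine = np.array([[-gap, 0.0], [n_disks * period, 0.0]])
    return MagnetPattern(polys, thickness=thickness, label="disk_row",
                         labels=[f"disk{k}" for k in range(n_disks)],
                         spine=spine,
                         metadata={"period": period, "gap": gap, "kind": "disks"})
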