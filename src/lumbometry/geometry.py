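"""Lumbosacral radiographic parameters from named vertebral corner landmarks.

All coordinate, sign, and line conventions of the measurement live here.

Conventions
-----------
* Image pixel coordinates: ``x`` = column (increases to the right), ``y`` =
  row (increases downward), origin at the top-left corner.
* ``anterior_side`` names the image side toward the patient's anterior
  ("left" or "right"); it is supplied, never guessed from pixels.
* Endplate tangent lines are oriented toward the anterior side.  The
  *anterior elevation* of such a line is ``atan2(-dy, d . anterior_unit)`` —
  positive when the line rises toward the anterior side.
* LL and SHA are unsigned in [0, 90].  ISA is signed: positive when the disc
  space opens anteriorly (lordotic wedge).  PLS is signed: positive when the
  upper vertebra is displaced anteriorly (anterolisthesis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, NamedTuple

from .errors import DegenerateGeometryError, MissingKeypointError

#: The ten canonical landmarks used by the four parameters.
VOCABULARY = (
    "L1SA", "L1SP",
    "L4IA", "L4IP",
    "L5SA", "L5SP", "L5IA", "L5IP",
    "S1SA", "S1SP",
)

#: All corner names a KeyPointSet may carry (phantoms label every body corner).
EXTENDED_VOCABULARY = tuple(
    f"{body}{code}"
    for body in ("L1", "L2", "L3", "L4", "L5", "S1")
    for code in ("SA", "SP", "IA", "IP")
)

PARAMETER_NAMES = ("LL", "SHA", "ISA_L4L5", "ISA_L5S1", "PLS_L4L5", "PLS_L5S1")

#: Two undirected lines are treated as parallel when |sin(angle)| < this.
PARALLEL_TOL = 1e-9

AnteriorSide = Literal["left", "right"]
Segment = Literal["L4L5", "L5S1"]
Vertebra = Literal["L4", "L5", "S1"]


class Point2D(NamedTuple):
    """An (x=column, y=row) location in pixel coordinates."""

    x: float
    y: float


@dataclass(frozen=True)
class Line2D:
    """A 2D line given by an anchor point and a unit direction vector."""

    anchor: Point2D
    direction: tuple[float, float]

    def __post_init__(self):
        norm = math.hypot(*self.direction)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise DegenerateGeometryError(
                f"line direction must be a unit vector, got norm {norm!r}"
            )


@dataclass
class KeyPointSet:
    """Named 2D landmarks on a lateral lumbar radiograph.

    Parameters
    ----------
    points : mapping of landmark name to Point2D
        Names must come from :data:`EXTENDED_VOCABULARY`; measurements use
        the canonical ten of :data:`VOCABULARY`.
    pixel_spacing : (row_mm, col_mm) or None
        Physical size of one pixel; required only for mm-based metrics.
    anterior_side : {"left", "right"}
        Image side toward the patient's anterior.
    """

    points: dict[str, Point2D] = field(default_factory=dict)
    pixel_spacing: tuple[float, float] | None = None
    anterior_side: AnteriorSide = "left"

    def __post_init__(self):
        clean: dict[str, Point2D] = {}
        for name, pt in self.points.items():
            if name not in EXTENDED_VOCABULARY:
                raise ValueError(f"unknown landmark name {name!r}")
            pt = Point2D(float(pt[0]), float(pt[1]))
            if not (math.isfinite(pt.x) and math.isfinite(pt.y)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = pt
        self.points = clean
        if self.anterior_side not in ("left", "right"):
            raise ValueError(f"anterior_side must be 'left' or 'right'")
        if self.pixel_spacing is not None:
            r, c = self.pixel_spacing
            if r <= 0 or c <= 0:
                raise ValueError("pixel_spacing entries must be positive")
            self.pixel_spacing = (float(r), float(c))

    def __getitem__(self, name: str) -> Point2D:
        try:
            return self.points[name]
        except KeyError:
            raise MissingKeypointError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, names: Iterable[str]) -> None:
        for name in names:
            if name not in self.points:
                raise MissingKeypointError(name)


@dataclass(frozen=True)
class ParameterSet:
    """The six lumbosacral radiographic parameters.

    LL, SHA, ISA values are degrees; PLS values are percent.
    """

    LL: float
    SHA: float
    ISA_L4L5: float
    ISA_L5S1: float
    PLS_L4L5: float
    PLS_L5S1: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "ParameterSet":
        return cls(**{name: float(values[name]) for name in PARAMETER_NAMES})


def anterior_unit(anterior_side: AnteriorSide) -> tuple[float, float]:
    """Unit vector pointing toward the patient's anterior in image coords."""
    return (-1.0, 0.0) if anterior_side == "left" else (1.0, 0.0)


def endplate_line(a: Point2D, p: Point2D, anterior_side: AnteriorSide = "left") -> Line2D:
    """Tangent line of an endplate through its anterior and posterior vertices.

    The direction is normalized and oriented so its component toward
    ``anterior_side`` is >= 0.
    """
    dx, dy = p[0] - a[0], p[1] - a[1]
    norm = math.hypot(dx, dy)
    if norm < 1e-12:
        raise DegenerateGeometryError(f"endplate points coincide: {a!r}, {p!r}")
    dx, dy = dx / norm, dy / norm
    ax, _ = anterior_unit(anterior_side)
    if dx * ax < 0 or (dx * ax == 0 and dy > 0):
        dx, dy = -dx, -dy
    return Line2D(Point2D(*a), (dx, dy))


def angle_between_lines(l1: Line2D, l2: Line2D) -> float:
    """Unsigned acute angle in degrees between two undirected lines."""
    dot = l1.direction[0] * l2.direction[0] + l1.direction[1] * l2.direction[1]
    return math.degrees(math.acos(min(1.0, abs(dot))))


def _wrap_half(deg: float) -> float:
    """Wrap an undirected-line angle difference into (-90, 90]."""
    deg = (deg + 90.0) % 180.0 - 90.0
    return 90.0 if deg == -90.0 else deg


def _elevation(line: Line2D, anterior_side: AnteriorSide) -> float:
    """Anterior elevation (degrees) of a line oriented toward the anterior."""
    ax, _ = anterior_unit(anterior_side)
    dx, dy = line.direction
    return math.degrees(math.atan2(-dy, dx * ax))


def lumbar_lordosis(kps: KeyPointSet) -> float:
    """LL: angle between the L1 and S1 superior endplate tangents, [0, 90]."""
    kps.require(("L1SA", "L1SP", "S1SA", "S1SP"))
    l1 = endplate_line(kps["L1SA"], kps["L1SP"], kps.anterior_side)
    s1 = endplate_line(kps["S1SA"], kps["S1SP"], kps.anterior_side)
    return angle_between_lines(l1, s1)


def sacral_horizontal_angle(kps: KeyPointSet) -> float:
    """SHA: angle between the S1 superior endplate and the horizontal, [0, 90]."""
    kps.require(("S1SA", "S1SP"))
    s1 = endplate_line(kps["S1SA"], kps["S1SP"], kps.anterior_side)
    horizontal = Line2D(Point2D(0.0, 0.0), (1.0, 0.0))
    return angle_between_lines(s1, horizontal)


_SEGMENT_LANDMARKS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    # segment -> ((upper inferior endplate A, P), (lower superior endplate A, P))
    "L4L5": (("L4IA", "L4IP"), ("L5SA", "L5SP")),
    "L5S1": (("L5IA", "L5IP"), ("S1SA", "S1SP")),
}


def intervertebral_space_angle(kps: KeyPointSet, segment: Segment) -> float:
    """ISA: signed wedge angle of a disc space, positive when lordotic."""
    if segment not in _SEGMENT_LANDMARKS:
        raise ValueError(f"segment must be 'L4L5' or 'L5S1', got {segment!r}")
    (ua, up), (la, lp) = _SEGMENT_LANDMARKS[segment]
    kps.require((ua, up, la, lp))
    upper = endplate_line(kps[ua], kps[up], kps.anterior_side)
    lower = endplate_line(kps[la], kps[lp], kps.anterior_side)
    return _wrap_half(
        _elevation(upper, kps.anterior_side) - _elevation(lower, kps.anterior_side)
    )


def posterior_edge_line(kps: KeyPointSet, vertebra: Vertebra) -> Line2D:
    """Extension line of a vertebra's posterior edge.

    L5 uses its two posterior corners.  L4 has no annotated superior corner,
    so its posterior line runs through L4IP parallel to the L5 posterior
    edge.  S1 has no annotated inferior corner, so its posterior line runs
    through S1SP perpendicular to the S1 superior endplate.
    """
    if vertebra == "L5":
        kps.require(("L5SP", "L5IP"))
        sp, ip = kps["L5SP"], kps["L5IP"]
        dx, dy = ip.x - sp.x, ip.y - sp.y
        norm = math.hypot(dx, dy)
        if norm < 1e-12:
            raise DegenerateGeometryError("L5SP and L5IP coincide")
        return Line2D(sp, (dx / norm, dy / norm))
    if vertebra == "L4":
        kps.require(("L4IP",))
        ref = posterior_edge_line(kps, "L5")
        return Line2D(kps["L4IP"], ref.direction)
    if vertebra == "S1":
        kps.require(("S1SA", "S1SP"))
        plate = endplate_line(kps["S1SA"], kps["S1SP"], kps.anterior_side)
        dx, dy = plate.direction
        return Line2D(kps["S1SP"], (-dy, dx))
    raise ValueError(f"vertebra must be one of 'L4', 'L5', 'S1', got {vertebra!r}")


def _intersect(l1: Line2D, l2: Line2D) -> Point2D:
    """Intersection point of two lines; raises when (nearly) parallel."""
    (d1x, d1y), (d2x, d2y) = l1.direction, l2.direction
    denom = d1x * d2y - d1y * d2x  # = sin(angle) for unit directions
    if abs(denom) < PARALLEL_TOL:
        raise DegenerateGeometryError("lines are parallel: no unique intersection")
    ax, ay = l2.anchor.x - l1.anchor.x, l2.anchor.y - l1.anchor.y
    t = (ax * d2y - ay * d2x) / denom
    return Point2D(l1.anchor.x + t * d1x, l1.anchor.y + t * d1y)


_PLS_VERTEBRAE: dict[str, tuple[Vertebra, Vertebra, tuple[str, str]]] = {
    # segment -> (upper vertebra, lower vertebra, lower superior endplate (A, P))
    "L4L5": ("L4", "L5", ("L5SA", "L5SP")),
    "L5S1": ("L5", "S1", ("S1SA", "S1SP")),
}


def percent_spondylolisthesis(kps: KeyPointSet, segment: Segment) -> float:
    """PLS = N/M x 100 (signed; positive = anterolisthesis).

    N is the distance, measured along the lower vertebra's superior-endplate
    line, between that line's intersections with the posterior edge lines of
    the upper and lower vertebrae.  M is the distance from the lower
    vertebra's superior-anterior to superior-posterior landmark.
    """
    if segment not in _PLS_VERTEBRAE:
        raise ValueError(f"segment must be 'L4L5' or 'L5S1', got {segment!r}")
    upper_v, lower_v, (la, lp) = _PLS_VERTEBRAE[segment]
    kps.require((la, lp))
    plate = endplate_line(kps[la], kps[lp], kps.anterior_side)
    m = math.hypot(kps[lp].x - kps[la].x, kps[lp].y - kps[la].y)
    if m < 1e-9:
        raise DegenerateGeometryError("endplate reference span M is ~0")
    p_upper = _intersect(posterior_edge_line(kps, upper_v), plate)
    p_lower = _intersect(posterior_edge_line(kps, lower_v), plate)
    n_signed = (p_upper.x - p_lower.x) * plate.direction[0] + (
        p_upper.y - p_lower.y
    ) * plate.direction[1]
    return 100.0 * n_signed / m


def compute_all_parameters(kps: KeyPointSet) -> ParameterSet:
    """Evaluate all six parameters from a complete ten-landmark set."""
    kps.require(VOCABULARY)
    return ParameterSet(
        LL=lumbar_lordosis(kps),
        SHA=sacral_horizontal_angle(kps),
        ISA_L4L5=intervertebral_space_angle(kps, "L4L5"),
        ISA_L5S1=intervertebral_space_angle(kps, "L5S1"),
        PLS_L4L5=percent_spondylolisthesis(kps, "L4L5"),
        PLS_L5S1=percent_spondylolisthesis(kps, "L5S1"),
    )
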