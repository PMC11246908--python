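"""Named landmarks from a segmentation mask.

Pipeline: connected-region extraction -> anatomical identity assignment ->
Harris corner detection on each region's binary support -> non-maximum
suppression -> corner-to-landmark naming.  Anatomy-count mismatches abort
with explicit errors rather than being silently repaired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import AnatomyCountError, CornerShortageError, LabelingError
from .geometry import AnteriorSide, KeyPointSet, Point2D

#: 8-connectivity structuring element for component labelling.
_EIGHT = np.ones((3, 3), dtype=bool)

LUMBAR_LABEL, SACRUM_LABEL = 1, 2


@dataclass
class KeypointConfig:
    """Tunables of the corner-detection stage."""

    min_area: int = 50  # px; components below this are discarded
    opening_radius: int = 1  # 3-px-diameter morphological opening of supports
    presmooth_sigma: float = 1.0  # Gaussian on the support before gradients
    harris_sigma: float = 2.0  # structure-tensor smoothing scale
    harris_k: float = 0.05
    nms_radius: int = 5
    rel_threshold: float = 0.1  # of the region's max response
    abs_threshold: float = 1e-4  # rejects cornerless (smooth) regions
    max_candidates: int = 12  # strongest corners fed to the 4-subset search
    snap_radius: int = 2  # refine peaks onto the support's extreme pixel
    edge_refine: bool = True  # sub-pixel corner = intersection of edge fits
    pair_refine: bool = True  # joint endplate fit across each corner pair
    refine_radius: float = 8.0  # boundary window for the edge fits
    refine_exclude: float = 2.5  # rounded-tip pixels ignored by the fits


@dataclass
class VertebraRegion:
    """One connected component of a segmentation class."""

    support: np.ndarray  # boolean, full-frame
    klass: str  # "lumbar" | "sacrum"
    centroid: Point2D
    identity: str | None = None  # L1..L5 / S1 once assigned


@dataclass(frozen=True)
class CornerCandidate:
    location: Point2D
    response: float


def extract_regions(mask: np.ndarray,
                    config: KeypointConfig | None = None) -> list[VertebraRegion]:
    """8-connected components per class, area-filtered and row-sorted.

    Raises AnatomyCountError unless exactly 5 lumbar components and exactly
    1 sacrum component survive the minimum-area filter.
    """
    cfg = config or KeypointConfig()
    regions: list[VertebraRegion] = []
    counts = {}
    for label, klass in ((LUMBAR_LABEL, "lumbar"), (SACRUM_LABEL, "sacrum")):
        labelled, n = ndimage.label(mask == label, structure=_EIGHT)
        kept = []
        for i in range(1, n + 1):
            support = labelled == i
            if support.sum() < cfg.min_area:
                continue
            ys, xs = np.nonzero(support)
            kept.append(
                VertebraRegion(
                    support=support, klass=klass,
                    centroid=Point2D(float(xs.mean()), float(ys.mean())),
                )
            )
        counts[klass] = len(kept)
        regions.extend(kept)
    if counts["lumbar"] != 5 or counts["sacrum"] != 1:
        raise AnatomyCountError(
            f"expected 5 lumbar + 1 sacrum regions, found "
            f"{counts['lumbar']} lumbar + {counts['sacrum']} sacrum"
        )
    regions.sort(key=lambda r: (r.klass == "sacrum", r.centroid.y))
    return regions


def label_vertebrae(regions: list[VertebraRegion]) -> list[VertebraRegion]:
    """Assign L1..L5 by increasing centroid row; the sacrum becomes S1."""
    lumbar = sorted(
        (r for r in regions if r.klass == "lumbar"), key=lambda r: r.centroid.y
    )
    sacrum = [r for r in regions if r.klass == "sacrum"]
    if len(lumbar) != 5 or len(sacrum) != 1:
        raise AnatomyCountError(
            f"labelling requires 5 lumbar + 1 sacrum regions, got "
            f"{len(lumbar)} + {len(sacrum)}"
        )
    for name, region in zip(("L1", "L2", "L3", "L4", "L5"), lumbar):
        region.identity = name
    sacrum[0].identity = "S1"
    return lumbar + sacrum


def harris_response(patch: np.ndarray, sigma: float = 2.0,
                    k: float = 0.05, presmooth: float = 0.0) -> np.ndarray:
    """Harris corner response R = det(M) - k.trace(M)^2.

    M is the Gaussian-smoothed gradient structure tensor ("covariance
    matrix") of the patch; gradients are central differences, optionally on
    a pre-smoothed patch (suppresses raster staircase on curved outlines).
    """
    f = patch.astype(np.float64)
    if presmooth > 0:
        f = ndimage.gaussian_filter(f, presmooth)
    gy, gx = np.gradient(f)
    ixx = ndimage.gaussian_filter(gx * gx, sigma)
    iyy = ndimage.gaussian_filter(gy * gy, sigma)
    ixy = ndimage.gaussian_filter(gx * gy, sigma)
    det = ixx * iyy - ixy * ixy
    trace = ixx + iyy
    return det - k * trace * trace


def _boundary_arcs(support: np.ndarray, x: float, y: float,
                   cfg: KeypointConfig):
    """The two boundary-pixel arcs flanking a corner, with their TLS lines.

    Boundary pixels within ``refine_radius`` of (x, y) — excluding the
    possibly rounded tip itself — are split into two angular clusters, each
    fitted with a total-least-squares line.  Returns a list of
    ``(mean, direction, points)`` per arc, or None when degenerate.
    """
    eroded = ndimage.binary_erosion(support, structure=_EIGHT)
    bys, bxs = np.nonzero(support & ~eroded)
    dx, dy = bxs - x, bys - y
    r = np.hypot(dx, dy)
    near = (r <= cfg.refine_radius) & (r >= cfg.refine_exclude)
    if near.sum() < 6:
        return None
    ang = np.arctan2(dy[near], dx[near])
    order = np.argsort(ang)
    sorted_ang = ang[order]
    gaps = np.diff(np.concatenate([sorted_ang, [sorted_ang[0] + 2 * np.pi]]))
    lo, hi = sorted(np.argsort(gaps)[-2:])
    idx = np.arange(len(sorted_ang))
    arcs = (order[(idx > lo) & (idx <= hi)], order[(idx <= lo) | (idx > hi)])
    pts = np.column_stack([bxs[near], bys[near]]).astype(float)
    out = []
    for arc in arcs:
        if len(arc) < 3:
            return None
        cloud = pts[arc]
        mean = cloud.mean(axis=0)
        _, _, vt = np.linalg.svd(cloud - mean, full_matrices=False)
        out.append((mean, vt[0], cloud))
    return out


def _intersect_lines(p1, d1, p2, d2):
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 0.15:  # nearly collinear: unstable intersection
        return None
    t = ((p2[0] - p1[0]) * d2[1] - (p2[1] - p1[1]) * d2[0]) / denom
    return p1[0] + t * d1[0], p1[1] + t * d1[1]


def _edge_intersection_refine(support: np.ndarray, x: float, y: float,
                              cfg: KeypointConfig) -> tuple[float, float]:
    """Sub-pixel corner refinement: intersect fits of the two adjacent edges.

    Segmentation networks round off thin corners, biasing any peak-based
    detector inward; the two boundary edges away from the tip are unbiased,
    so their intersection recovers the true vertex.  The refinement is
    rejected (input returned) when the fits are degenerate or the corner
    would move more than 4 px.
    """
    arcs = _boundary_arcs(support, x, y, cfg)
    if arcs is None:
        return x, y
    hit = _intersect_lines(arcs[0][0], arcs[0][1], arcs[1][0], arcs[1][1])
    if hit is None or np.hypot(hit[0] - x, hit[1] - y) > 4.0:
        return x, y
    return float(hit[0]), float(hit[1])


def _endplate_pair_refine(support: np.ndarray, a: Point2D, p: Point2D,
                          cfg: KeypointConfig) -> tuple[Point2D, Point2D]:
    """Joint refinement of an endplate's two corners.

    The endplate edge is shared by both corners, so its direction is fitted
    once from the pooled boundary pixels of both corners' endplate-side
    arcs; each corner is then re-placed at the intersection of that common
    endplate line with its own off-endplate edge.  This suppresses the
    endplate-angle noise of independent per-corner fits.
    """
    ab = np.array([p.x - a.x, p.y - a.y])
    span = np.linalg.norm(ab)
    if span < 1e-6:
        return a, p
    ab /= span
    picked = []
    for corner in (a, p):
        arcs = _boundary_arcs(support, corner.x, corner.y, cfg)
        if arcs is None:
            return a, p
        aligned = max(arcs, key=lambda arc: abs(float(np.dot(arc[1], ab))))
        other = arcs[0] if aligned is arcs[1] else arcs[1]
        if abs(float(np.dot(aligned[1], ab))) < 0.9:
            return a, p  # neither arc follows the endplate: keep inputs
        picked.append((aligned, other))
    pooled = np.vstack([picked[0][0][2], picked[1][0][2]])
    mean = pooled.mean(axis=0)
    _, _, vt = np.linalg.svd(pooled - mean, full_matrices=False)
    plate_dir = vt[0]
    refined = []
    for corner, (_, other) in zip((a, p), picked):
        hit = _intersect_lines(mean, plate_dir, other[0], other[1])
        if hit is None or np.hypot(hit[0] - corner.x, hit[1] - corner.y) > 4.0:
            return a, p
        refined.append(Point2D(float(hit[0]), float(hit[1])))
    return refined[0], refined[1]


def detect_corners(region: VertebraRegion,
                   config: KeypointConfig | None = None) -> list[CornerCandidate]:
    """Thresholded local maxima of the Harris response after NMS.

    The region support is smoothed by a small morphological opening first so
    raster staircase pixels do not spawn spurious corners.  Raises
    CornerShortageError when fewer than 4 (lumbar) or 2 (sacrum) candidates
    survive.
    """
    cfg = config or KeypointConfig()
    support = region.support
    if cfg.opening_radius > 0:
        support = ndimage.binary_opening(
            support, structure=disk(cfg.opening_radius).astype(bool)
        )
    resp = harris_response(support, cfg.harris_sigma, cfg.harris_k,
                           presmooth=cfg.presmooth_sigma)
    peak = resp.max()
    threshold = max(cfg.rel_threshold * peak, cfg.abs_threshold)
    footprint = disk(cfg.nms_radius).astype(bool)
    local_max = resp == ndimage.maximum_filter(resp, footprint=footprint)
    ys, xs = np.nonzero(local_max & (resp > threshold))
    cy, cx = region.centroid.y, region.centroid.x
    sup_ys, sup_xs = np.nonzero(region.support)
    by_location: dict[tuple[float, float], float] = {}
    for y, x in zip(ys, xs):
        strength = float(resp[y, x])
        # Harris peaks of a binary corner sit 1-2 px inside the vertex;
        # snap each peak to the locally most extreme support pixel (max
        # distance from the region centroid) within a small window.
        fx, fy = float(x), float(y)
        if cfg.snap_radius > 0:
            near = (np.abs(sup_xs - x) <= cfg.snap_radius) & (
                np.abs(sup_ys - y) <= cfg.snap_radius
            )
            if near.any():
                dist2 = (sup_xs[near] - cx) ** 2 + (sup_ys[near] - cy) ** 2
                best = np.argmax(dist2)
                fx = float(sup_xs[near][best])
                fy = float(sup_ys[near][best])
        if cfg.edge_refine:
            fx, fy = _edge_intersection_refine(region.support, fx, fy, cfg)
        key = (fx, fy)
        by_location[key] = max(by_location.get(key, -np.inf), strength)
    # Snapping/refinement can pull two NMS peaks onto the same physical
    # corner; re-suppress within the NMS radius, keeping the strongest.
    candidates: list[CornerCandidate] = []
    for (x, y), r in sorted(by_location.items(), key=lambda kv: -kv[1]):
        if all(
            np.hypot(c.location.x - x, c.location.y - y) > cfg.nms_radius
            for c in candidates
        ):
            candidates.append(CornerCandidate(Point2D(x, y), r))
    needed = 2 if region.klass == "sacrum" else 4
    if len(candidates) < needed:
        raise CornerShortageError(region.identity or region.klass,
                                  len(candidates), needed)
    return candidates


def _quad_area(points: list[Point2D]) -> float:
    """Area of the convex hull of 4 points (shoelace on the hull ordering)."""
    cx = sum(p.x for p in points) / 4.0
    cy = sum(p.y for p in points) / 4.0
    ordered = sorted(points, key=lambda p: np.arctan2(p.y - cy, p.x - cx))
    area = 0.0
    for a, b in zip(ordered, ordered[1:] + ordered[:1]):
        area += a.x * b.y - b.x * a.y
    return abs(area) / 2.0


def _quad_refine(support: np.ndarray, corners: list[Point2D],
                 cfg: KeypointConfig) -> list[Point2D]:
    """Joint refinement of a body's four corners by fitting its four edges.

    ``corners`` are cyclically ordered around the quad.  Boundary pixels are
    assigned to the nearest edge (middle portion only, so rounded corners
    do not contaminate the fits), each edge gets a total-least-squares
    line, and the corners are re-placed at adjacent-edge intersections.
    Falls back to the inputs when any fit or intersection is unstable.
    """
    eroded = ndimage.binary_erosion(support, structure=_EIGHT)
    bys, bxs = np.nonzero(support & ~eroded)
    pts = np.column_stack([bxs, bys]).astype(float)
    lines = []
    for i in range(4):
        c1 = np.array(corners[i])
        c2 = np.array(corners[(i + 1) % 4])
        edge = c2 - c1
        length = np.linalg.norm(edge)
        if length < 4.0:
            return corners
        d = edge / length
        rel = pts - c1
        t = rel @ d / length
        perp = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
        sel = (t >= 0.12) & (t <= 0.88) & (perp <= 2.0)
        if sel.sum() < 5:
            return corners
        cloud = pts[sel]
        mean = cloud.mean(axis=0)
        _, _, vt = np.linalg.svd(cloud - mean, full_matrices=False)
        lines.append((mean, vt[0]))
    refined = []
    for i in range(4):
        prev_line = lines[(i - 1) % 4]
        hit = _intersect_lines(prev_line[0], prev_line[1],
                               lines[i][0], lines[i][1])
        if hit is None or np.hypot(hit[0] - corners[i].x,
                                   hit[1] - corners[i].y) > 4.0:
            return corners
        refined.append(Point2D(float(hit[0]), float(hit[1])))
    return refined


def assign_anatomical_labels(candidates: list[CornerCandidate],
                             region: VertebraRegion,
                             anterior_side: AnteriorSide,
                             config: KeypointConfig | None = None,
                             ) -> dict[str, Point2D]:
    """Name corner candidates for one region.

    Lumbar: the 4 candidates (among the strongest ``max_candidates``)
    maximising quadrilateral area become the body corners; the two with the
    smaller rows are the superior pair, and within each pair the point
    toward ``anterior_side`` is anterior.  Sacrum: the 2 smallest-row
    candidates become S1SA/S1SP.
    """
    cfg = config or KeypointConfig()
    if region.identity is None:
        raise LabelingError("region has no anatomical identity assigned")
    if region.klass == "sacrum":
        if len(candidates) < 2:
            raise CornerShortageError(region.identity, len(candidates), 2)
        top = sorted(candidates, key=lambda c: c.location.y)[:2]
        a, p = sorted(
            (c.location for c in top),
            key=lambda pt: pt.x if anterior_side == "left" else -pt.x,
        )
        if cfg.pair_refine:
            a, p = _endplate_pair_refine(region.support, a, p, cfg)
        return {f"{region.identity}SA": a, f"{region.identity}SP": p}

    if len(candidates) < 4:
        raise CornerShortageError(region.identity, len(candidates), 4)
    pool = candidates[: cfg.max_candidates]
    best = max(
        itertools.combinations(pool, 4),
        key=lambda quad: _quad_area([c.location for c in quad]),
    )
    pts = sorted((c.location for c in best), key=lambda pt: pt.y)
    if not pts[1].y < pts[2].y:
        raise LabelingError(
            f"{region.identity}: corner pairs are not separable by row"
        )
    superior, inferior = pts[:2], pts[2:]
    named: dict[str, Point2D] = {}
    for pair, sup in ((superior, "S"), (inferior, "I")):
        a, p = sorted(
            pair, key=lambda pt: pt.x if anterior_side == "left" else -pt.x
        )
        named[f"{sup}A"] = a
        named[f"{sup}P"] = p
    if cfg.pair_refine:
        order = ("SA", "SP", "IP", "IA")  # cyclic around the body
        refined = _quad_refine(
            region.support, [named[c] for c in order], cfg
        )
        named = dict(zip(order, refined))
    return {f"{region.identity}{code}": pt for code, pt in named.items()}


def infer_anterior_side(sacrum: VertebraRegion,
                        config: KeypointConfig | None = None) -> AnteriorSide:
    """Heuristic: the anterior is the side toward which the S1 superior
    endplate descends.  Overridable by passing anterior_side explicitly to
    :func:`mask_to_keypoints`."""
    candidates = detect_corners(sacrum, config)
    top = sorted(candidates, key=lambda c: c.location.y)[:2]
    lo, hi = sorted((c.location for c in top), key=lambda pt: pt.y)
    # ``hi`` (larger row) is the lower = anterior endplate corner.
    return "left" if hi.x < lo.x else "right"


def mask_to_keypoints(mask: np.ndarray,
                      anterior_side: AnteriorSide | None = None,
                      pixel_spacing: tuple[float, float] | None = None,
                      config: KeypointConfig | None = None) -> KeyPointSet:
    """Full pipeline: mask -> the ten named vocabulary landmarks."""
    cfg = config or KeypointConfig()
    regions = label_vertebrae(extract_regions(mask, cfg))
    if anterior_side is None:
        sacrum = next(r for r in regions if r.klass == "sacrum")
        anterior_side = infer_anterior_side(sacrum, cfg)
    wanted = {
        "L1": ("SA", "SP"),
        "L4": ("IA", "IP"),
        "L5": ("SA", "SP", "IA", "IP"),
        "S1": ("SA", "SP"),
    }
    points: dict[str, Point2D] = {}
    for region in regions:
        codes = wanted.get(region.identity or "")
        if not codes:
            continue
        named = assign_anatomical_labels(
            detect_corners(region, cfg), region, anterior_side, cfg
        )
        for code in codes:
            points[f"{region.identity}{code}"] = named[f"{region.identity}{code}"]
    return KeyPointSet(
        points=points, pixel_spacing=pixel_spacing, anterior_side=anterior_side
    )
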