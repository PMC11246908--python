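"""Synthetic lateral-lumbar-radiograph phantoms with analytic ground truth.

A phantom is five lumbar vertebral bodies plus a sacrum, drawn as bright
convex quadrilaterals on a noisy gradient background.  Corner landmarks are
solved *analytically* so that the geometry module applied to them reproduces
the generating parameter targets exactly (the closure contract); the raster
mask and image are rendered from those same corners afterwards.

Construction order (caudal to cranial): the S1 superior endplate elevation is
fixed by the SHA target; the ISA targets fix the two caudal disc wedges;
per-body wedges are small sampled constants; the residual angle needed to
meet the LL target is spread evenly over the three untargeted discs.  PLS is
imposed by translating the upper vertebra (and everything above it) along the
lower superior-endplate direction, to which the slip distance N responds
linearly and exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from . import geometry
from .errors import InfeasibleSpecError
from .geometry import KeyPointSet, ParameterSet, Point2D

#: Vertebral bodies from cranial to caudal.
BODIES = ("L1", "L2", "L3", "L4", "L5")

#: Label values in phantom masks.
LABEL_BACKGROUND, LABEL_LUMBAR, LABEL_SACRUM = 0, 1, 2

#: Hard bound on any lumbar endplate elevation; beyond this the corner pairs
#: of a body are no longer separable by image row.
MAX_ELEVATION_DEG = 35.0


@dataclass(frozen=True)
class PhantomSpec:
    """Fully resolved recipe for one phantom (all values already sampled)."""

    shape: tuple[int, int] = (256, 128)  # (rows, cols)
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # mm per px (row, col)
    ll: float = 49.77
    sha: float = 38.09
    isa_l4l5: float = 14.86
    isa_l5s1: float = 19.15
    pls_l4l5: float = 12.27
    pls_l5s1: float = 13.36
    body_width: float = 32.0
    body_height: float = 24.0
    disc_height: float = 9.0
    body_wedges: tuple[float, float, float, float, float] = (2.0,) * 5  # L1..L5
    sacrum_width: float = 40.0
    sacrum_height: float = 55.0
    sacrum_shear: float = 6.0
    base_point: tuple[float, float] = (72.0, 196.0)  # (x, y) of S1 endplate mid
    background_range: tuple[float, float] = (0.15, 0.30)
    lumbar_intensity: float = 0.85
    sacrum_intensity: float = 0.65
    blur_sigma: float = 1.0
    noise_sd: float = 0.04
    anterior_side: str = "left"
    seed: int = 0

    def targets(self) -> ParameterSet:
        return ParameterSet(
            LL=self.ll,
            SHA=self.sha,
            ISA_L4L5=self.isa_l4l5,
            ISA_L5S1=self.isa_l5s1,
            PLS_L4L5=self.pls_l4l5,
            PLS_L5S1=self.pls_l5s1,
        )


@dataclass
class PhantomSample:
    """A rendered phantom: image + mask + corner landmarks + ground truth."""

    image: np.ndarray  # float32 in [0, 1], shape = spec.shape
    mask: np.ndarray  # uint8 labels {0, 1, 2}, same shape
    keypoints: KeyPointSet  # all 4 corners of every body (superset of the 10)
    truth: ParameterSet
    spec: PhantomSpec


@dataclass(frozen=True)
class PopulationConfig:
    """Sampling distributions for phantom specs.

    Parameter targets default to the reference-standard means/SDs of the
    source cohort; they are drawn from truncated normals and re-drawn (up to
    ``max_attempts``) until the solved geometry is feasible.
    """

    ll: tuple[float, float] = (49.77, 7.82)
    sha: tuple[float, float] = (38.09, 6.85)
    isa_l4l5: tuple[float, float] = (14.86, 4.07)
    isa_l5s1: tuple[float, float] = (19.15, 8.07)
    pls_l4l5: tuple[float, float] = (12.27, 10.31)
    pls_l5s1: tuple[float, float] = (13.36, 9.25)
    bounds: dict = field(
        default_factory=lambda: {
            "ll": (20.0, 80.0),
            "sha": (15.0, 52.0),
            "isa_l4l5": (0.0, 30.0),
            "isa_l5s1": (0.0, 40.0),
            "pls_l4l5": (-15.0, 40.0),
            "pls_l5s1": (-15.0, 40.0),
        }
    )
    body_width: tuple[float, float] = (30.0, 34.0)  # uniform range
    body_height: tuple[float, float] = (22.0, 26.0)
    disc_height: tuple[float, float] = (8.0, 10.0)
    wedge: tuple[float, float] = (2.0, 0.5)  # normal, clipped to [0, 5]
    shape: tuple[int, int] = (256, 128)
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 0.04
    blur_sigma: float = 1.0
    anterior_side: str = "left"
    max_attempts: int = 100


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (exact, cheap at these widths)."""
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))  # pragma: no cover - pathological config


def sample_spec(population: PopulationConfig | None = None,
                rng: np.random.Generator | int | None = None) -> PhantomSpec:
    """Draw one feasible PhantomSpec from the population distributions."""
    pop = population or PopulationConfig()
    rng = np.random.default_rng(rng)
    for _ in range(pop.max_attempts):
        b = pop.bounds
        spec = PhantomSpec(
            shape=pop.shape,
            pixel_spacing=pop.pixel_spacing,
            ll=_truncnorm(rng, *pop.ll, *b["ll"]),
            sha=_truncnorm(rng, *pop.sha, *b["sha"]),
            isa_l4l5=_truncnorm(rng, *pop.isa_l4l5, *b["isa_l4l5"]),
            isa_l5s1=_truncnorm(rng, *pop.isa_l5s1, *b["isa_l5s1"]),
            pls_l4l5=_truncnorm(rng, *pop.pls_l4l5, *b["pls_l4l5"]),
            pls_l5s1=_truncnorm(rng, *pop.pls_l5s1, *b["pls_l5s1"]),
            body_width=float(rng.uniform(*pop.body_width)),
            body_height=float(rng.uniform(*pop.body_height)),
            disc_height=float(rng.uniform(*pop.disc_height)),
            body_wedges=tuple(
                float(np.clip(rng.normal(*pop.wedge), 0.0, 5.0)) for _ in range(5)
            ),
            noise_sd=pop.noise_sd,
            blur_sigma=pop.blur_sigma,
            anterior_side=pop.anterior_side,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            solve_keypoints(spec)
        except InfeasibleSpecError:
            continue
        return spec
    raise InfeasibleSpecError(
        f"no feasible spec after {pop.max_attempts} attempts"
    )


def _direction(phi_deg: float, ax: float) -> tuple[float, float]:
    """Unit vector along an endplate, oriented toward the anterior side.

    ``phi_deg`` is the anterior elevation: positive = rises toward anterior.
    """
    phi = math.radians(phi_deg)
    return (ax * math.cos(phi), -math.sin(phi))


def _up_normal(phi_deg: float, ax: float) -> tuple[float, float]:
    """Unit normal of an endplate pointing toward smaller rows (upward)."""
    dx, dy = _direction(phi_deg, ax)
    nx, ny = -dy, dx
    if ny > 0:
        nx, ny = -nx, -ny
    return nx, ny


def _elevations(spec: PhantomSpec) -> dict[str, float]:
    """Anterior elevation (deg) of every endplate, from the completion rule."""
    w1, w2, w3, w4, w5 = spec.body_wedges
    phi: dict[str, float] = {}
    phi["S1S"] = -spec.sha
    phi["L5I"] = spec.isa_l5s1 + phi["S1S"]
    phi["L5S"] = phi["L5I"] + w5
    phi["L4I"] = spec.isa_l4l5 + phi["L5S"]
    phi["L4S"] = phi["L4I"] + w4
    target_l1s = phi["S1S"] + spec.ll
    disc = (target_l1s - phi["L4S"] - (w1 + w2 + w3)) / 3.0
    phi["L3I"] = phi["L4S"] + disc
    phi["L3S"] = phi["L3I"] + w3
    phi["L2I"] = phi["L3S"] + disc
    phi["L2S"] = phi["L2I"] + w2
    phi["L1I"] = phi["L2S"] + disc
    phi["L1S"] = phi["L1I"] + w1
    return phi


def solve_keypoints(spec: PhantomSpec) -> KeyPointSet:
    """Analytically place every body corner so the targets close exactly.

    Raises InfeasibleSpecError when an endplate elevation exceeds the
    row-separability bound or a landmark leaves the frame.
    """
    ax = -1.0 if spec.anterior_side == "left" else 1.0
    phi = _elevations(spec)
    for name, val in phi.items():
        limit = 90.0 if name == "S1S" else MAX_ELEVATION_DEG
        if abs(val) > limit:
            raise InfeasibleSpecError(
                f"endplate {name} elevation {val:.1f} deg exceeds {limit} deg"
            )

    pts: dict[str, np.ndarray] = {}

    def place_endplate(prefix: str, mid: np.ndarray, phi_deg: float, width: float):
        d = np.array(_direction(phi_deg, ax))
        pts[prefix + "A"] = mid + 0.5 * width * d
        pts[prefix + "P"] = mid - 0.5 * width * d

    # Sacrum: superior endplate at the base point, body extends downward with
    # a posterior shear; inferior corners may be truncated by the frame.
    base = np.array(spec.base_point, dtype=float)
    place_endplate("S1S", base, phi["S1S"], spec.sacrum_width)
    down = -np.array(_up_normal(phi["S1S"], ax))
    shear = -spec.sacrum_shear * np.array(_direction(phi["S1S"], ax))
    pts["S1IA"] = pts["S1SA"] + spec.sacrum_height * down + shear
    pts["S1IP"] = pts["S1SP"] + spec.sacrum_height * down + shear

    # Lumbar bodies stacked caudal to cranial.  Wedged discs close toward one
    # end, so the perpendicular separation is raised until both endplate ends
    # keep a safety margin (prevents touching/merged raster regions).
    margin = 2.2
    mid_lower = base
    phi_lower = phi["S1S"]
    lower_width = spec.sacrum_width
    for body in reversed(BODIES):
        u_low = np.array(_up_normal(phi_lower, ax))
        d_low = np.array(_direction(phi_lower, ax))
        d_up = np.array(_direction(phi[body + "I"], ax))
        u_up = np.array(_up_normal(phi[body + "I"], ax))
        height = spec.disc_height
        for _ in range(6):
            mid_inf = mid_lower + height * u_low
            upper_ends = [mid_inf + s * 0.5 * spec.body_width * d_up
                          for s in (1.0, -1.0)]
            lower_ends = [mid_lower + s * 0.5 * lower_width * d_low
                          for s in (1.0, -1.0)]
            clearance = min(
                min(float(np.dot(p - mid_lower, u_low)) for p in upper_ends),
                min(-float(np.dot(p - mid_inf, u_up)) for p in lower_ends),
            )
            if clearance >= margin:
                break
            height += margin - clearance
        place_endplate(body + "I", mid_inf, phi[body + "I"], spec.body_width)
        mid_sup = mid_inf + spec.body_height * u_up
        place_endplate(body + "S", mid_sup, phi[body + "S"], spec.body_width)
        mid_lower = mid_sup
        phi_lower = phi[body + "S"]
        lower_width = spec.body_width

    def shift_above(lowest_body: str, delta: np.ndarray):
        idx = BODIES.index(lowest_body)
        for body in BODIES[: idx + 1]:
            for code in ("SA", "SP", "IA", "IP"):
                pts[body + code] = pts[body + code] + delta

    # Impose PLS by sliding the upper stack along the lower superior endplate.
    def current(name: str) -> Point2D:
        return Point2D(*pts[name])

    def kps_now() -> KeyPointSet:
        return KeyPointSet(
            points={k: current(k) for k in geometry.VOCABULARY},
            anterior_side=spec.anterior_side,
        )

    for segment, lowest, plate in (("L5S1", "L5", "S1S"), ("L4L5", "L4", "L5S")):
        n0 = geometry.percent_spondylolisthesis(kps_now(), segment)
        target = spec.pls_l5s1 if segment == "L5S1" else spec.pls_l4l5
        width = spec.sacrum_width if segment == "L5S1" else spec.body_width
        t = (target - n0) / 100.0 * width
        shift_above(lowest, t * np.array(_direction(phi[plate], ax)))

    rows, cols = spec.shape
    for body in BODIES:
        for code in ("SA", "SP", "IA", "IP"):
            x, y = pts[body + code]
            if not (1.0 <= x <= cols - 2.0 and 1.0 <= y <= rows - 2.0):
                raise InfeasibleSpecError(
                    f"landmark {body + code} at ({x:.1f}, {y:.1f}) leaves the frame"
                )
    for code in ("SA", "SP"):
        x, y = pts["S1" + code]
        if not (1.0 <= x <= cols - 2.0 and 1.0 <= y <= rows - 2.0):
            raise InfeasibleSpecError(f"landmark S1{code} leaves the frame")

    return KeyPointSet(
        points={name: Point2D(*xy) for name, xy in pts.items()},
        pixel_spacing=spec.pixel_spacing,
        anterior_side=spec.anterior_side,
    )


def _fill_quad(canvas: np.ndarray, corners: Sequence[Point2D], value: int):
    """Rasterise a convex quad (SA, SP, IP, IA order) including its vertices."""
    xs = np.array([p.x for p in corners])
    ys = np.array([p.y for p in corners])
    rr, cc = draw_polygon(ys, xs, shape=canvas.shape)
    canvas[rr, cc] = value
    rows, cols = canvas.shape
    vr = np.clip(np.rint(ys).astype(int), 0, rows - 1)
    vc = np.clip(np.rint(xs).astype(int), 0, cols - 1)
    inside = (np.rint(ys) >= 0) & (np.rint(ys) < rows) & \
             (np.rint(xs) >= 0) & (np.rint(xs) < cols)
    canvas[vr[inside], vc[inside]] = value


def render_mask(spec: PhantomSpec, kps: KeyPointSet) -> np.ndarray:
    """Crisp label map {0 bg, 1 lumbar, 2 sacrum} from solved corners."""
    mask = np.zeros(spec.shape, dtype=np.uint8)
    quad = lambda b: tuple(kps[b + c] for c in ("SA", "SP", "IP", "IA"))
    _fill_quad(mask, quad("S1"), LABEL_SACRUM)
    for body in BODIES:
        scratch = np.zeros(spec.shape, dtype=np.uint8)
        _fill_quad(scratch, quad(body), 1)
        if np.any(mask[scratch > 0]):
            raise InfeasibleSpecError(f"body {body} overlaps another structure")
        mask[scratch > 0] = LABEL_LUMBAR
    return mask


def render_phantom(spec: PhantomSpec,
                   rng: np.random.Generator | int | None = None) -> PhantomSample:
    """Render image + mask + keypoints for one spec.

    The mask is rendered before blur/noise, so labels stay crisp; the image
    is background gradient + body plateaus, Gaussian-blurred, plus noise.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    kps = solve_keypoints(spec)
    mask = render_mask(spec, kps)

    rows, cols = spec.shape
    lo, hi = spec.background_range
    image = (lo + (hi - lo) * np.linspace(0, 1, rows)[:, None]) * np.ones(
        (rows, cols), dtype=np.float64
    )
    image[mask == LABEL_LUMBAR] = spec.lumbar_intensity
    image[mask == LABEL_SACRUM] = spec.sacrum_intensity
    if spec.blur_sigma > 0:
        image = gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return PhantomSample(
        image=image, mask=mask, keypoints=kps, truth=spec.targets(), spec=spec
    )


def split_sizes(n: int) -> tuple[int, int, int]:
    """Deterministic 8:1:1 (train, val, test) sizes."""
    n_test = int(round(n / 10.0))
    n_val = int(round(n / 10.0))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(
    n: int,
    population: PopulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
    render: bool = True,
) -> tuple[list[PhantomSample | PhantomSpec], pd.DataFrame]:
    """Generate ``n`` phantoms plus a manifest with seeds and an 8:1:1 split.

    With ``render=False`` only specs are produced (fast path for
    geometry-closure sweeps).  The split permutation and every per-sample
    seed derive from ``rng``, so a fixed master seed reproduces the manifest
    byte-for-byte.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    pop = population or PopulationConfig()
    n_train, n_val, n_test = split_sizes(n)
    splits = np.array(
        ["train"] * n_train + ["val"] * n_val + ["test"] * n_test, dtype=object
    )
    splits = splits[rng.permutation(n)]

    samples: list[PhantomSample | PhantomSpec] = []
    records = []
    for i in range(n):
        spec = sample_spec(pop, rng)
        item: PhantomSample | PhantomSpec = (
            render_phantom(spec) if render else spec
        )
        samples.append(item)
        records.append(
            {
                "sample_id": f"phantom_{i:05d}",
                "split": splits[i],
                "seed": spec.seed,
                "pixel_spacing_row": spec.pixel_spacing[0],
                "pixel_spacing_col": spec.pixel_spacing[1],
                "anterior_side": spec.anterior_side,
                **{k: getattr(spec, k) for k in
                   ("ll", "sha", "isa_l4l5", "isa_l5s1", "pls_l4l5", "pls_l5s1",
                    "body_width", "body_height", "disc_height")},
                **{f"wedge_{j + 1}": w for j, w in enumerate(spec.body_wedges)},
            }
        )
    manifest = pd.DataFrame.from_records(records)
    return samples, manifest


def spec_from_manifest_row(row: pd.Series,
                           population: PopulationConfig | None = None) -> PhantomSpec:
    """Rebuild a renderable spec from one manifest row (targets + seed)."""
    pop = population or PopulationConfig()
    base = PhantomSpec(
        shape=pop.shape, pixel_spacing=pop.pixel_spacing,
        noise_sd=pop.noise_sd, blur_sigma=pop.blur_sigma,
        anterior_side=str(row["anterior_side"]),
    )
    return replace(
        base,
        ll=float(row["ll"]), sha=float(row["sha"]),
        isa_l4l5=float(row["isa_l4l5"]), isa_l5s1=float(row["isa_l5s1"]),
        pls_l4l5=float(row["pls_l4l5"]), pls_l5s1=float(row["pls_l5s1"]),
        body_width=float(row["body_width"]),
        body_height=float(row["body_height"]),
        disc_height=float(row["disc_height"]),
        body_wedges=tuple(float(row[f"wedge_{j + 1}"]) for j in range(5)),
        seed=int(row["seed"]),
    )
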