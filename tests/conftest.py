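import math

import numpy as np
import pytest

from lumbometry import phantom
from lumbometry.geometry import KeyPointSet, Point2D
from lumbometry.phantom import _fill_quad


@pytest.fixture(scope="session")
def phantom_sample():
    """One rendered phantom shared across tests."""
    return phantom.render_phantom(phantom.sample_spec(rng=np.random.default_rng(42)))


@pytest.fixture(scope="session")
def noiseless_sample():
    spec = phantom.sample_spec(rng=np.random.default_rng(11))
    from dataclasses import replace

    return phantom.render_phantom(replace(spec, noise_sd=0.0, blur_sigma=0.0))


def make_quad_mask(angle_deg: float, width: float = 32.0, height: float = 24.0,
                   size: int = 200, center=None, label: int = 1):
    """Rasterise one rotated rectangle the same way the phantom renderer does
    (vertex pixels included).  Returns (mask, corners) with corners ordered
    (top-left, top-right, bottom-right, bottom-left) pre-rotation.
    """
    canvas = np.zeros((size, size), dtype=np.uint8)
    cy, cx = center or (size / 2, size / 2)
    a = math.radians(angle_deg)
    corners = []
    for sx, sy in ((-1, -1), (1, -1), (1, 1), (-1, 1)):
        x = cx + sx * width / 2 * math.cos(a) - sy * height / 2 * math.sin(a)
        y = cy + sx * width / 2 * math.sin(a) + sy * height / 2 * math.cos(a)
        corners.append(Point2D(x, y))
    _fill_quad(canvas, corners, label)
    return canvas.astype(bool), corners


def canonical_keypoints(**overrides) -> KeyPointSet:
    """A hand-built, anatomically plausible 10-landmark set (anterior=left).

    Endplates are horizontal except where a test overrides points, so each
    parameter has a simple closed-form value.
    """
    pts = {
        "L1SA": Point2D(20.0, 20.0), "L1SP": Point2D(60.0, 20.0),
        "L4IA": Point2D(20.0, 100.0), "L4IP": Point2D(60.0, 100.0),
        "L5SA": Point2D(20.0, 110.0), "L5SP": Point2D(60.0, 110.0),
        "L5IA": Point2D(20.0, 140.0), "L5IP": Point2D(60.0, 140.0),
        "S1SA": Point2D(20.0, 150.0), "S1SP": Point2D(60.0, 150.0),
    }
    pts.update({k: Point2D(*v) for k, v in overrides.items()})
    return KeyPointSet(points=pts, anterior_side="left")
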