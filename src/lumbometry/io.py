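"""File formats: images (PNG/JPEG/DICOM), LabelMe-style JSON, CSV reports.

Keypoint coordinates are stored in pixel units everywhere; millimetre
conversion happens only inside the metrics module.  Masks travel as 8-bit
PNG label maps (0 background, 1 lumbar, 2 sacrum); phantom images as 16-bit
PNG.  DICOM support is a deliberately minimal single-frame MONOCHROME2
explicit-VR little-endian reader/writer that honours PixelSpacing.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DataError
from .geometry import (
    EXTENDED_VOCABULARY, PARAMETER_NAMES, KeyPointSet, ParameterSet, Point2D,
)

# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


@dataclass
class RadiographRecord:
    """One ingested radiograph plus the metadata measurements need."""

    image_id: str
    image: np.ndarray  # float32 in [0, 1]
    pixel_spacing: tuple[float, float] | None  # (row_mm, col_mm)
    anterior_side: str | None
    source: str
    format: str  # "png" | "jpeg" | "dicom"


def _to_float_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        scale = 255.0 if arr.max() <= 255 else 65535.0
        arr = arr / scale
    return arr.astype(np.float32)


def read_image(path, pixel_spacing=None, anterior_side=None) -> RadiographRecord:
    """Read a grayscale radiograph from PNG/JPEG/DICOM.

    ``pixel_spacing`` overrides (PNG/JPEG have none); DICOM PixelSpacing is
    used unless an override is given.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such image file: {path}")
    if _is_dicom(path):
        image, ds_spacing = read_dicom(path)
        spacing = pixel_spacing or ds_spacing
        fmt = "dicom"
    else:
        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise DataError(f"unreadable image {path}: {exc}") from exc
        image = _to_float_gray(arr)
        spacing = pixel_spacing
        fmt = path.suffix.lstrip(".").lower().replace("jpg", "jpeg")
    return RadiographRecord(
        image_id=path.stem, image=image,
        pixel_spacing=tuple(spacing) if spacing else None,
        anterior_side=anterior_side, source=str(path), format=fmt,
    )


def write_image_png(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 65535.0).round().astype(np.uint16))


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(mask, dtype=np.uint8))


def read_mask_png(path) -> np.ndarray:
    mask = np.asarray(iio.imread(Path(path)))
    if mask.ndim != 2:
        raise DataError(f"mask {path} is not a single-channel label map")
    return mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# Minimal DICOM (single-frame MONOCHROME2, explicit VR little endian)
# ---------------------------------------------------------------------------

_TS_EXPLICIT_LE = "1.2.840.10008.1.2.1"
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in (".dcm", ".dicom"):
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr != b"UI" else b"\x00"
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def write_dicom(path, image: np.ndarray,
                pixel_spacing: tuple[float, float]) -> None:
    """Write a float [0, 1] or uint16 image as a minimal DICOM file."""
    if image.dtype != np.uint16:
        image = (np.clip(image, 0, 1) * 65535.0).round().astype(np.uint16)
    rows, cols = image.shape
    spacing_ds = f"{pixel_spacing[0]:g}\\{pixel_spacing[1]:g}".encode()
    meta_body = (
        _element(0x0002, 0x0001, b"OB", b"\x00\x01")
        + _element(0x0002, 0x0002, b"UI", b"1.2.840.10008.5.1.4.1.1.1.1")
        + _element(0x0002, 0x0003, b"UI", b"1.2.826.0.1.3680043.8.498.1")
        + _element(0x0002, 0x0010, b"UI", _TS_EXPLICIT_LE.encode())
    )
    meta = _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_body)))
    body = (
        _element(0x0008, 0x0060, b"CS", b"CR")
        + _element(0x0028, 0x0002, b"US", struct.pack("<H", 1))
        + _element(0x0028, 0x0004, b"CS", b"MONOCHROME2")
        + _element(0x0028, 0x0010, b"US", struct.pack("<H", rows))
        + _element(0x0028, 0x0011, b"US", struct.pack("<H", cols))
        + _element(0x0028, 0x0030, b"DS", spacing_ds)
        + _element(0x0028, 0x0100, b"US", struct.pack("<H", 16))
        + _element(0x0028, 0x0101, b"US", struct.pack("<H", 16))
        + _element(0x0028, 0x0102, b"US", struct.pack("<H", 15))
        + _element(0x0028, 0x0103, b"US", struct.pack("<H", 0))
        + _element(0x7FE0, 0x0010, b"OW", image.astype("<u2").tobytes())
    )
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + meta_body + body)


def read_dicom(path) -> tuple[np.ndarray, tuple[float, float] | None]:
    """Read the minimal DICOM dialect written above (and close relatives)."""
    raw = Path(path).read_bytes()
    if raw[128:132] != b"DICM":
        raise DataError(f"{path}: missing DICM magic")
    pos = 132
    fields: dict[tuple[int, int], bytes] = {}
    while pos + 8 <= len(raw):
        group, elem = struct.unpack_from("<HH", raw, pos)
        vr = raw[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", raw, pos + 8)
            start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", raw, pos + 6)
            start = pos + 8
        fields[(group, elem)] = raw[start : start + length]
        pos = start + length
        if (group, elem) == (0x0002, 0x0010):
            ts = fields[(group, elem)].rstrip(b"\x00").decode()
            if ts != _TS_EXPLICIT_LE:
                raise DataError(
                    f"{path}: unsupported transfer syntax {ts!r} "
                    "(only explicit VR little endian)"
                )
    try:
        rows = struct.unpack("<H", fields[(0x0028, 0x0010)])[0]
        cols = struct.unpack("<H", fields[(0x0028, 0x0011)])[0]
        pixels = np.frombuffer(
            fields[(0x7FE0, 0x0010)], dtype="<u2", count=rows * cols
        ).reshape(rows, cols)
    except KeyError as exc:
        raise DataError(f"{path}: missing required DICOM element {exc}") from exc
    spacing = None
    if (0x0028, 0x0030) in fields:
        parts = fields[(0x0028, 0x0030)].rstrip(b"\x00 ").decode().split("\\")
        spacing = (float(parts[0]), float(parts[1]))
    return pixels.astype(np.float32) / 65535.0, spacing


# ---------------------------------------------------------------------------
# LabelMe-style JSON
# ---------------------------------------------------------------------------

def write_labelme(path, kps: KeyPointSet,
                  image_shape: tuple[int, int] | None = None,
                  polygons: dict[str, list[tuple[float, float]]] | None = None,
                  ) -> None:
    """Write landmarks (and optional region outlines) as LabelMe JSON."""
    shapes = [
        {
            "label": name,
            "points": [[pt.x, pt.y]],
            "shape_type": "point",
            "group_id": None,
            "flags": {},
        }
        for name, pt in sorted(kps.points.items())
    ]
    if polygons:
        for label, pts in polygons.items():
            shapes.append(
                {
                    "label": label,
                    "points": [[float(x), float(y)] for x, y in pts],
                    "shape_type": "polygon",
                    "group_id": None,
                    "flags": {},
                }
            )
    doc = {
        "version": "5.2.1",
        "flags": {
            "anterior_side": kps.anterior_side,
            **(
                {"pixel_spacing": list(kps.pixel_spacing)}
                if kps.pixel_spacing else {}
            ),
        },
        "shapes": shapes,
        "imagePath": "",
        "imageData": None,
        "imageHeight": image_shape[0] if image_shape else None,
        "imageWidth": image_shape[1] if image_shape else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_labelme(path) -> tuple[KeyPointSet, dict[str, list]]:
    """Read point shapes into a KeyPointSet; return polygon shapes alongside.

    Unknown point labels are warned about and skipped; a duplicated
    vocabulary label is an error.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"unreadable LabelMe file {path}: {exc}") from exc
    points: dict[str, Point2D] = {}
    polygons: dict[str, list] = {}
    for shape in doc.get("shapes", []):
        label = shape.get("label", "")
        if shape.get("shape_type") == "point":
            if label not in EXTENDED_VOCABULARY:
                warnings.warn(f"{path}: skipping unknown point label {label!r}",
                              stacklevel=2)
                continue
            if label in points:
                raise DataError(f"{path}: duplicate landmark label {label!r}")
            (xy,) = shape["points"]
            points[label] = Point2D(float(xy[0]), float(xy[1]))
        elif shape.get("shape_type") == "polygon":
            polygons[label] = [tuple(map(float, p)) for p in shape["points"]]
    flags = doc.get("flags") or {}
    spacing = flags.get("pixel_spacing")
    return (
        KeyPointSet(
            points=points,
            pixel_spacing=tuple(spacing) if spacing else None,
            anterior_side=flags.get("anterior_side", "left"),
        ),
        polygons,
    )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def write_keypoints_csv(path, kps: KeyPointSet) -> None:
    pd.DataFrame(
        [(name, pt.x, pt.y) for name, pt in sorted(kps.points.items())],
        columns=["name", "x", "y"],
    ).to_csv(path, index=False)


def read_keypoints_csv(path, pixel_spacing=None,
                       anterior_side="left") -> KeyPointSet:
    df = pd.read_csv(path)
    if not {"name", "x", "y"} <= set(df.columns):
        raise DataError(f"{path}: expected columns name,x,y")
    if df["name"].duplicated().any():
        raise DataError(f"{path}: duplicate landmark names")
    return KeyPointSet(
        points={
            str(r["name"]): Point2D(float(r["x"]), float(r["y"]))
            for _, r in df.iterrows()
        },
        pixel_spacing=pixel_spacing,
        anterior_side=anterior_side,
    )


def write_parameters_json(path, params: ParameterSet) -> None:
    with open(path, "w") as fh:
        json.dump(params.as_dict(), fh, indent=1)


def read_parameters_json(path) -> ParameterSet:
    with open(path) as fh:
        return ParameterSet.from_mapping(json.load(fh))


def write_parameters_csv(path, named_params: dict[str, ParameterSet]) -> None:
    """One row per image id, fixed parameter column order."""
    df = pd.DataFrame.from_dict(
        {k: v.as_dict() for k, v in sorted(named_params.items())},
        orient="index", columns=list(PARAMETER_NAMES),
    )
    df.index.name = "image_id"
    df.to_csv(path)


def read_parameters_csv(path) -> dict[str, ParameterSet]:
    df = pd.read_csv(path, index_col="image_id")
    return {
        str(idx): ParameterSet.from_mapping(row)
        for idx, row in df.iterrows()
    }
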