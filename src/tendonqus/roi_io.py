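"""Image / ROI input, pixel calibration, and rasterization.

Images are 8-bit grayscale grids indexed (row, col) with the origin at the
top-left; a pixel at (r, c) has its center at continuous coordinates
(x, y) = (c + 0.5, r + 0.5), with x increasing rightward (along the tendon
for longitudinal views) and y increasing with depth.

Regions of interest come in two flavours:

* ``contour`` -- a simple polygon traced around the tendon (transverse view);
* ``band`` -- a pair of x-monotone polylines tracing the upper and lower
  tendon edges (longitudinal view), the region between them being the ROI.

Rasterization uses the pixel-center-in-region rule: a pixel belongs to the
mask iff its center lies inside (or on the boundary of) the region.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from shapely.geometry import Polygon

__all__ = [
    "DEFAULT_PIXEL_AREA_MM2",
    "PixelCalibration",
    "UltrasoundImage",
    "RegionOfInterest",
    "PixelMask",
    "ROIError",
    "load_image",
    "load_roi",
    "save_roi",
    "rasterize_roi",
    "bounding_rectangle",
    "polygon_area",
]

#: Physical area covered by one pixel (mm^2) when no calibration is supplied.
DEFAULT_PIXEL_AREA_MM2 = 0.0057

View = Literal["longitudinal", "transverse"]


class ROIError(ValueError):
    """Raised for degenerate or out-of-bounds regions of interest."""


@dataclass(frozen=True)
class PixelCalibration:
    """Physical size of a (square) pixel.

    Parameters
    ----------
    spacing_mm
        Edge length of one pixel in millimetres.
    """

    spacing_mm: float

    def __post_init__(self) -> None:
        if not (self.spacing_mm > 0 and math.isfinite(self.spacing_mm)):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm**2

    @classmethod
    def from_pixel_area(cls, pixel_area_mm2: float = DEFAULT_PIXEL_AREA_MM2) -> "PixelCalibration":
        if not pixel_area_mm2 > 0:
            raise ValueError("pixel_area_mm2 must be positive")
        return cls(spacing_mm=math.sqrt(pixel_area_mm2))

    @classmethod
    def default(cls) -> "PixelCalibration":
        return cls.from_pixel_area(DEFAULT_PIXEL_AREA_MM2)


@dataclass(frozen=True)
class UltrasoundImage:
    """An 8-bit grayscale ultrasound frame plus calibration and view tag."""

    pixels: np.ndarray
    calibration: PixelCalibration
    view: View
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))
        if self.view not in ("longitudinal", "transverse"):
            raise ValueError(f"unknown view {self.view!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (M rows, N cols)


@dataclass(frozen=True)
class RegionOfInterest:
    """A traced region: closed ``contour`` polygon or edge-pair ``band``."""

    kind: Literal["contour", "band"]
    view: View
    contour: np.ndarray | None = None
    upper_edge: np.ndarray | None = None
    lower_edge: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "contour":
            if self.contour is None:
                raise ROIError("contour ROI requires vertices")
            verts = np.asarray(self.contour, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
                raise ROIError("contour needs >= 3 (x, y) vertices")
            object.__setattr__(self, "contour", verts)
            poly = Polygon(verts)
            if not poly.is_valid or poly.area == 0:
                raise ROIError("contour is self-intersecting or has zero area")
        elif self.kind == "band":
            if self.upper_edge is None or self.lower_edge is None:
                raise ROIError("band ROI requires upper_edge and lower_edge")
            up = np.asarray(self.upper_edge, dtype=float)
            lo = np.asarray(self.lower_edge, dtype=float)
            for name, edge in (("upper_edge", up), ("lower_edge", lo)):
                if edge.ndim != 2 or edge.shape[1] != 2 or len(edge) < 2:
                    raise ROIError(f"{name} needs >= 2 (x, y) vertices")
                if np.any(np.diff(edge[:, 0]) <= 0):
                    raise ROIError(f"{name} must be strictly x-monotone")
            object.__setattr__(self, "upper_edge", up)
            object.__setattr__(self, "lower_edge", lo)
            x0, x1 = self.common_x_interval()
            if not x1 > x0:
                raise ROIError("band edges share no x-interval of positive length")
            xs = np.linspace(x0, x1, 64)
            yu = np.interp(xs, up[:, 0], up[:, 1])
            yl = np.interp(xs, lo[:, 0], lo[:, 1])
            if np.any(yl <= yu):
                raise ROIError("lower edge must lie strictly below upper edge")
        else:
            raise ROIError(f"unknown ROI kind {self.kind!r}")
        if self.view not in ("longitudinal", "transverse"):
            raise ROIError(f"unknown view {self.view!r}")

    def common_x_interval(self) -> tuple[float, float]:
        """x-range covered by both band edges (band ROIs only)."""
        if self.kind != "band":
            raise ROIError("common_x_interval applies to band ROIs only")
        up, lo = self.upper_edge, self.lower_edge
        return (max(up[0, 0], lo[0, 0]), min(up[-1, 0], lo[-1, 0]))


@dataclass(frozen=True)
class PixelMask:
    """Boolean grid marking ROI membership of each pixel."""

    mask: np.ndarray
    count: int = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "count", int(m.sum()))

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.mask)


def load_image(
    path: str | Path,
    calibration: PixelCalibration | None = None,
    view: View = "longitudinal",
    *,
    collapse_rgb: bool = False,
    rescale: bool = False,
    id: str | None = None,
) -> UltrasoundImage:
    """Read a PNG/JPEG (or anything Pillow decodes) as an 8-bit grayscale frame.

    Multi-channel images are accepted only when all channels are identical and
    ``collapse_rgb`` is set; non-8-bit data require ``rescale`` (min-max to
    [0, 255]).
    """
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop fully-opaque alpha
            if np.all(arr[:, :, 3] == arr[0, 0, 3]):
                arr = arr[:, :, :3]
        if not collapse_rgb:
            raise ValueError(f"{path}: multi-channel image; pass collapse_rgb=True")
        if not (np.array_equal(arr[:, :, 0], arr[:, :, 1]) and np.array_equal(arr[:, :, 0], arr[:, :, 2])):
            raise ValueError(f"{path}: RGB channels differ; not a grayscale export")
        arr = arr[:, :, 0]
    if arr.dtype != np.uint8:
        if not rescale:
            raise ValueError(f"{path}: bit depth is {arr.dtype}, pass rescale=True to min-max rescale")
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) * (255.0 / (hi - lo))
        arr = np.rint(arr).astype(np.uint8)
    return UltrasoundImage(
        pixels=arr,
        calibration=calibration or PixelCalibration.default(),
        view=view,
        id=id if id is not None else path.stem,
    )


def load_roi(path: str | Path) -> RegionOfInterest:
    """Read a ROI tracing from JSON (0-based pixel coordinates)."""
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc["kind"]
    if kind == "contour":
        return RegionOfInterest(kind="contour", view=doc["view"], contour=np.asarray(doc["contour"], dtype=float))
    return RegionOfInterest(
        kind="band",
        view=doc["view"],
        upper_edge=np.asarray(doc["upper_edge"], dtype=float),
        lower_edge=np.asarray(doc["lower_edge"], dtype=float),
    )


def save_roi(roi: RegionOfInterest, path: str | Path) -> None:
    doc: dict = {"kind": roi.kind, "view": roi.view}
    if roi.kind == "contour":
        doc["contour"] = np.asarray(roi.contour).tolist()
    else:
        doc["upper_edge"] = np.asarray(roi.upper_edge).tolist()
        doc["lower_edge"] = np.asarray(roi.lower_edge).tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test, boundary points counted inside."""
    poly = Polygon(vertices)
    pts = np.column_stack([xs, ys])
    from shapely import covers, points as mk_points  # vectorized, shapely >= 2

    return covers(poly, mk_points(pts))


def rasterize_roi(roi: RegionOfInterest, image_dims: tuple[int, int]) -> PixelMask:
    """Rasterize a ROI onto an (M, N) grid with the pixel-center rule.

    A pixel (r, c) is in the mask iff its center (c + 0.5, r + 0.5) lies in
    the contour polygon, or between the band edges (inclusive).
    """
    M, N = image_dims
    mask = np.zeros((M, N), dtype=bool)
    if roi.kind == "contour":
        verts = roi.contour
        cmin = max(0, int(np.floor(verts[:, 0].min())) - 1)
        cmax = min(N, int(np.ceil(verts[:, 0].max())) + 1)
        rmin = max(0, int(np.floor(verts[:, 1].min())) - 1)
        rmax = min(M, int(np.ceil(verts[:, 1].max())) + 1)
        if cmax <= cmin or rmax <= rmin:
            raise ROIError("contour lies outside the image")
        cc, rr = np.meshgrid(np.arange(cmin, cmax), np.arange(rmin, rmax))
        inside = _points_in_polygon(cc.ravel() + 0.5, rr.ravel() + 0.5, verts)
        mask[rmin:rmax, cmin:cmax] = inside.reshape(rr.shape)
    else:
        x0, x1 = roi.common_x_interval()
        cols = np.arange(N)
        xc = cols + 0.5
        in_x = (xc >= x0) & (xc <= x1)
        yu = np.interp(xc, roi.upper_edge[:, 0], roi.upper_edge[:, 1])
        yl = np.interp(xc, roi.lower_edge[:, 0], roi.lower_edge[:, 1])
        yc = np.arange(M)[:, None] + 0.5
        mask = in_x[None, :] & (yc >= yu[None, :]) & (yc <= yl[None, :])
    if not mask.any():
        raise ROIError("ROI rasterizes to an empty mask")
    return PixelMask(mask=mask)


def bounding_rectangle(contour: Sequence[Sequence[float]] | np.ndarray) -> tuple[float, float]:
    """Axis-aligned bounding rectangle (width_px, height_px) of a vertex set."""
    verts = np.asarray(contour, dtype=float)
    if verts.size == 0:
        raise ValueError("empty vertex list")
    verts = verts.reshape(-1, 2)
    width = float(verts[:, 0].max() - verts[:, 0].min())
    height = float(verts[:, 1].max() - verts[:, 1].min())
    if width == 0 or height == 0:
        warnings.warn("degenerate ROI: bounding rectangle has zero extent", stacklevel=2)
    return width, height


def polygon_area(contour: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Unsigned polygon area in px^2 (shoelace)."""
    verts = np.asarray(contour, dtype=float)
    x, y = verts[:, 0], verts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)
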