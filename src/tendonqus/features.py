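"""The eleven quantitative-ultrasound measurements.

Three families:

* geometric -- thickness (both views), width and area (transverse only);
* first-order -- echogenicity (mean), variance, skewness, kurtosis and the
  histogram entropy of the ROI's grayscale distribution, all with population
  (1/n) denominators and non-excess kurtosis (Gaussian -> 3);
* texture -- contrast, energy and homogeneity from 256-level gray-level
  co-occurrence matrices (GLCMs) at a fixed pixel offset, averaged over the
  four directions 0/45/90/135 degrees.

Entropy exists in two conventions: the default 256-bin histogram form and a
co-occurrence form (-sum p log2 p over the GLCM); ``entropy_mode`` selects
which one populates the feature set, and both are always retained in the
detail record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .roi_io import (
    PixelCalibration,
    PixelMask,
    RegionOfInterest,
    ROIError,
    UltrasoundImage,
    bounding_rectangle,
    polygon_area,
    rasterize_roi,
)

__all__ = [
    "ANGLES_DEG",
    "FeatureConfig",
    "QUSFeatureSet",
    "GrayLevelCooccurrence",
    "longitudinal_thickness",
    "transverse_geometry",
    "first_order_stats",
    "cooccurrence_matrix",
    "texture_features",
    "extract_features",
    "LONGITUDINAL_FEATURES",
    "TRANSVERSE_FEATURES",
]

ANGLES_DEG = (0, 45, 90, 135)
_LEVELS = 256

#: angle -> (row offset, col offset); y grows downward, so 45 deg is (-d, +d)
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

LONGITUDINAL_FEATURES = (
    "thickness",
    "echogenicity",
    "variance",
    "skewness",
    "kurtosis",
    "entropy",
    "contrast",
    "energy",
    "homogeneity",
)
TRANSVERSE_FEATURES = ("thickness", "width", "area") + LONGITUDINAL_FEATURES[1:]


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for feature extraction (defaults follow the measurement protocol)."""

    distance: int = 10
    angles: tuple[int, ...] = ANGLES_DEG
    symmetric: bool = True
    entropy_mode: str = "histogram"  # or "cooccurrence"
    n_points: int = 100

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        bad = set(self.angles) - set(ANGLES_DEG)
        if bad:
            raise ValueError(f"unsupported angles: {sorted(bad)}")
        if self.entropy_mode not in ("histogram", "cooccurrence"):
            raise ValueError(f"unknown entropy_mode {self.entropy_mode!r}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


@dataclass(frozen=True)
class GrayLevelCooccurrence:
    """Normalized 256x256 co-occurrence probabilities for one offset."""

    p: np.ndarray
    distance: int
    angle_deg: int
    pair_count: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (_LEVELS, _LEVELS):
            raise ValueError("co-occurrence matrix must be 256x256")
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "p", p)


@dataclass
class QUSFeatureSet:
    """The view-dependent set of named measurements for one image + ROI."""

    view: str
    values: dict[str, float] = field(default_factory=dict)
    undefined: set[str] = field(default_factory=set)
    detail: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def is_defined(self, name: str) -> bool:
        return name in self.values and name not in self.undefined

    @property
    def feature_names(self) -> tuple[str, ...]:
        return LONGITUDINAL_FEATURES if self.view == "longitudinal" else TRANSVERSE_FEATURES


def longitudinal_thickness(
    roi: RegionOfInterest, calibration: PixelCalibration, n_points: int = 100
) -> float:
    """Mean tendon thickness (cm) from a band ROI.

    ``n_points`` x-equidistant points are interpolated on each edge over the
    common x-interval, paired by index, and the mean Euclidean pair distance
    is converted to centimetres.
    """
    if roi.kind != "band":
        raise ROIError("longitudinal thickness requires a band ROI")
    x0, x1 = roi.common_x_interval()
    xs = np.linspace(x0, x1, n_points)
    yu = np.interp(xs, roi.upper_edge[:, 0], roi.upper_edge[:, 1])
    yl = np.interp(xs, roi.lower_edge[:, 0], roi.lower_edge[:, 1])
    # index-paired points share the same x, so the distance is vertical,
    # but keep the Euclidean form for future non-shared-x pairings
    dist_px = np.hypot(xs - xs, yl - yu)
    return float(dist_px.mean() * calibration.spacing_mm / 10.0)


def transverse_geometry(
    roi: RegionOfInterest, calibration: PixelCalibration
) -> tuple[float, float, float]:
    """(max thickness cm, width cm, area cm^2) of a contour ROI.

    Thickness and width come from the axis-aligned bounding rectangle; the
    area is the shoelace polygon area.
    """
    if roi.kind != "contour":
        raise ROIError("transverse geometry requires a contour ROI")
    width_px, height_px = bounding_rectangle(roi.contour)
    mm = calibration.spacing_mm
    thickness_cm = height_px * mm / 10.0
    width_cm = width_px * mm / 10.0
    area_cm2 = polygon_area(roi.contour) * mm**2 / 100.0
    return thickness_cm, width_cm, area_cm2


def first_order_stats(
    image: UltrasoundImage, mask: PixelMask
) -> tuple[float, float, float, float, float]:
    """(echogenicity, variance, skewness, kurtosis, histogram entropy).

    Population moments over the masked pixels; skewness/kurtosis are NaN when
    the ROI is constant (sigma = 0).  Entropy is -sum q log2 q over the
    256-bin normalized histogram, in bits, with 0 log 0 = 0.
    """
    vals = image.pixels[mask.mask].astype(np.float64)
    if vals.size == 0:
        raise ValueError("empty mask")
    mean = float(vals.mean())
    centered = vals - mean
    var = float(np.mean(centered**2))
    if var > 0:
        sd = math.sqrt(var)
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / var**2)
    else:
        skew = math.nan
        kurt = math.nan
    counts = np.bincount(vals.astype(np.intp), minlength=_LEVELS)
    q = counts / counts.sum()
    nz = q[q > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return mean, var, skew, kurt, entropy


def cooccurrence_matrix(
    image: UltrasoundImage,
    mask: PixelMask,
    d: int = 10,
    angle_deg: int = 0,
    symmetric: bool = True,
) -> GrayLevelCooccurrence:
    """GLCM over pixel pairs at distance ``d`` along ``angle_deg``.

    Both pixels of a pair must lie inside the mask.  Diagonal angles use
    integer (+-d, +-d) offsets.  With ``symmetric`` each ordered pair is also
    counted reversed, making p symmetric and 0/180 degrees equivalent.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    try:
        ur, uc = _ANGLE_OFFSETS[angle_deg]
    except KeyError:
        raise ValueError(f"angle must be one of {ANGLES_DEG}, got {angle_deg}") from None
    dr, dc = ur * d, uc * d
    m = mask.mask
    M, N = m.shape
    r0, r1 = max(0, -dr), min(M, M - dr)
    c0, c1 = max(0, -dc), min(N, N - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"no pixel pair fits offset ({dr}, {dc}) in a {M}x{N} image")
    valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        raise ValueError(f"mask contains no co-occurring pixel pair at d={d}, angle={angle_deg}")
    i = image.pixels[r0:r1, c0:c1][valid].astype(np.intp)
    j = image.pixels[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid].astype(np.intp)
    counts = np.bincount(i * _LEVELS + j, minlength=_LEVELS * _LEVELS).reshape(_LEVELS, _LEVELS)
    counts = counts.astype(np.float64)
    total = n_pairs
    if symmetric:
        counts = counts + counts.T
        total *= 2
    return GrayLevelCooccurrence(p=counts / total, distance=d, angle_deg=angle_deg, pair_count=total)


def _glcm_features(glcm: GrayLevelCooccurrence) -> dict[str, float]:
    p = glcm.p
    idx = np.arange(_LEVELS, dtype=np.float64)
    diff = idx[:, None] - idx[None, :]
    contrast = float((diff**2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {"contrast": contrast, "energy": energy, "homogeneity": homogeneity, "entropy": entropy}


def texture_features(
    image: UltrasoundImage,
    mask: PixelMask,
    d: int = 10,
    angles: Iterable[int] = ANGLES_DEG,
    symmetric: bool = True,
) -> tuple[float, float, float, float, dict[int, dict[str, float]]]:
    """(contrast, energy, homogeneity, co-occurrence entropy), angle-averaged.

    Per-angle values are returned in the trailing detail mapping.
    """
    per_angle: dict[int, dict[str, float]] = {}
    for angle in angles:
        glcm = cooccurrence_matrix(image, mask, d=d, angle_deg=angle, symmetric=symmetric)
        per_angle[angle] = _glcm_features(glcm)
    if not per_angle:
        raise ValueError("at least one angle is required")
    mean_of = lambda k: float(np.mean([v[k] for v in per_angle.values()]))
    return (
        mean_of("contrast"),
        mean_of("energy"),
        mean_of("homogeneity"),
        mean_of("entropy"),
        per_angle,
    )


def extract_features(
    image: UltrasoundImage,
    roi: RegionOfInterest,
    config: FeatureConfig | Mapping[str, object] | None = None,
) -> QUSFeatureSet:
    """Compute the full view-dependent measurement set for one image + ROI."""
    if config is None:
        config = FeatureConfig()
    elif not isinstance(config, FeatureConfig):
        config = FeatureConfig(**dict(config))
    if roi.view != image.view:
        raise ROIError(f"ROI view {roi.view!r} does not match image view {image.view!r}")

    fs = QUSFeatureSet(view=image.view)
    cal = image.calibration
    if image.view == "longitudinal":
        if roi.kind != "band":
            raise ROIError("longitudinal images require a band ROI")
        fs.values["thickness"] = longitudinal_thickness(roi, cal, n_points=config.n_points)
    else:
        if roi.kind != "contour":
            raise ROIError("transverse images require a contour ROI")
        thickness, width, area = transverse_geometry(roi, cal)
        fs.values.update(thickness=thickness, width=width, area=area)

    mask = rasterize_roi(roi, image.shape)
    mean, var, skew, kurt, ent_hist = first_order_stats(image, mask)
    fs.values.update(echogenicity=mean, variance=var)
    fs.values["skewness"] = skew
    fs.values["kurtosis"] = kurt
    if math.isnan(skew):
        fs.undefined.update({"skewness", "kurtosis"})
    contrast, energy, homogeneity, ent_co, per_angle = texture_features(
        image, mask, d=config.distance, angles=config.angles, symmetric=config.symmetric
    )
    fs.values.update(contrast=contrast, energy=energy, homogeneity=homogeneity)
    fs.values["entropy"] = ent_hist if config.entropy_mode == "histogram" else ent_co
    fs.detail.update(
        entropy_histogram=ent_hist,
        entropy_cooccurrence=ent_co,
        per_angle=per_angle,
        mask_count=mask.count,
    )
    return fs
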