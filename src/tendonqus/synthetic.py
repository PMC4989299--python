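"""Synthetic tendon ultrasound images and crossed-design feature tables.

Two generators:

* :func:`simulate_tendon_image` paints a tendon-like region (horizontal
  fibrillar bands between two edges in the longitudinal view, an ellipse in
  the transverse view) with multiplicative gamma speckle, and returns the
  image together with the exact ROI used to paint it and the ground-truth
  geometry.  "Pathologic" parameter sets are thicker, darker, less striated
  and carry a smooth hypoechoic blob.

* :func:`simulate_feature_study` builds a balanced Subject x Evaluator x
  Visit x Image measurement table either directly from a linear random-model
  with known variance components ("linear" mode) or by rendering an image
  per design cell and extracting real features from it ("imaging" mode,
  with evaluator gain, visit gain and evaluator-specific ROI-placement
  jitter as the error-generating mechanisms).

Everything is reproducible from the seed carried in the parameter objects.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_features
from .gtheory import EFFECTS, FACETS
from .roi_io import PixelCalibration, RegionOfInterest, UltrasoundImage

__all__ = [
    "TendonImageParams",
    "StudySimParams",
    "simulate_tendon_image",
    "simulate_feature_study",
    "healthy_params",
    "pathologic_params",
]


@dataclass(frozen=True)
class TendonImageParams:
    """Ground-truth geometry and echotexture of one simulated frame."""

    view: Literal["longitudinal", "transverse"] = "longitudinal"
    thickness_cm: float = 0.52
    width_cm: float = 1.30          # transverse only
    mean_echo: float = 83.0
    band_amplitude: float = 0.45    # fibrillar striation strength (longitudinal)
    band_period_px: float = 16.0
    lesion_depth: float = 0.0       # 0 = none; fraction of echo removed at blob center
    lesion_radius_px: float = 25.0
    speckle_shape: float = 8.0      # gamma shape; lower = grainier
    background_echo: float = 28.0
    image_shape: tuple[int, int] = (176, 192)  # (rows, cols); transverse uses (144, 256)
    pixel_spacing_mm: float = math.sqrt(0.0057)
    roi_length_cm: float = 1.0      # longitudinal ROI extent along x
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0 or self.width_cm <= 0:
            raise ValueError("thickness and width must be positive")
        if not 0 < self.mean_echo < 255:
            raise ValueError("mean_echo must lie in (0, 255)")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if not 0 <= self.lesion_depth < 1:
            raise ValueError("lesion_depth must lie in [0, 1)")


def healthy_params(view: str = "longitudinal", seed: int = 0, **overrides) -> TendonImageParams:
    """Parameter set emulating a healthy tendon (bright, striated, thinner)."""
    base = TendonImageParams(
        view=view,  # type: ignore[arg-type]
        thickness_cm=0.52,
        width_cm=1.30,
        mean_echo=83.0,
        band_amplitude=0.6 if view == "longitudinal" else 0.0,
        lesion_depth=0.0,
        speckle_shape=16.0,
        image_shape=(176, 192) if view == "longitudinal" else (144, 256),
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def pathologic_params(view: str = "longitudinal", seed: int = 0, **overrides) -> TendonImageParams:
    """Parameter set emulating a tendinopathic tendon (thicker, darker, blob)."""
    base = TendonImageParams(
        view=view,  # type: ignore[arg-type]
        thickness_cm=0.68,
        width_cm=1.37,
        mean_echo=79.0,
        band_amplitude=0.08 if view == "longitudinal" else 0.0,
        lesion_depth=0.25,
        speckle_shape=4.5,
        image_shape=(176, 192) if view == "longitudinal" else (144, 256),
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def _lesion_factor(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, r: float, depth: float) -> np.ndarray:
    if depth <= 0:
        return np.ones_like(xx, dtype=float)
    d2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * (r / 2.0) ** 2)
    return 1.0 - depth * np.exp(-d2)


def simulate_tendon_image(
    params: TendonImageParams,
) -> tuple[UltrasoundImage, RegionOfInterest, dict[str, float]]:
    """Render one frame; returns (image, ground-truth ROI, geometry truth)."""
    rng = np.random.default_rng(params.seed)
    M, N = params.image_shape
    mm = params.pixel_spacing_mm
    cal = PixelCalibration(spacing_mm=mm)
    t_px = params.thickness_cm * 10.0 / mm
    yy, xx = np.mgrid[0:M, 0:N]
    yc, xc = yy + 0.5, xx + 0.5
    echo = np.full((M, N), params.background_echo, dtype=float)

    if params.view == "longitudinal":
        roi_len_px = params.roi_length_cm * 10.0 / mm
        if t_px + 8 > M or roi_len_px > N:
            raise ValueError("tendon geometry exceeds image bounds")
        y0 = (M - t_px) / 2.0
        phase = rng.uniform(0, 2 * np.pi)
        undulation = 2.0 * np.sin(2 * np.pi * 1.5 * np.arange(N + 1) / N + phase)
        upper_y = y0 + undulation
        lower_y = upper_y + t_px
        up_cols = np.interp(xc[0], np.arange(N + 1), upper_y)
        lo_cols = up_cols + t_px
        inside = (yc >= up_cols[None, :]) & (yc <= lo_cols[None, :])
        depth_in = yc - up_cols[None, :]
        bands = 1.0 + params.band_amplitude * np.sin(2 * np.pi * depth_in / params.band_period_px)
        echo_t = params.mean_echo * bands
        lesion = _lesion_factor(
            xc, yc, cx=N / 2.0, cy=y0 + t_px / 2.0,
            r=params.lesion_radius_px, depth=params.lesion_depth,
        )
        echo = np.where(inside, echo_t * lesion, echo)

        x_lo = N / 2.0 - roi_len_px / 2.0
        x_hi = N / 2.0 + roi_len_px / 2.0
        xs = np.linspace(x_lo, x_hi, 33)
        yu = np.interp(xs, np.arange(N + 1), upper_y)
        roi = RegionOfInterest(
            kind="band",
            view="longitudinal",
            upper_edge=np.column_stack([xs, yu]),
            lower_edge=np.column_stack([xs, yu + t_px]),
        )
        truth = {"thickness_cm": params.thickness_cm, "mean_echo": params.mean_echo}
    else:
        a = params.width_cm * 10.0 / mm / 2.0   # semi-axis along x
        b = t_px / 2.0                           # semi-axis along y
        if 2 * b + 8 > M or 2 * a + 8 > N:
            raise ValueError("tendon geometry exceeds image bounds")
        cx0, cy0 = N / 2.0, M / 2.0
        inside = ((xc - cx0) / a) ** 2 + ((yc - cy0) / b) ** 2 <= 1.0
        lesion = _lesion_factor(
            xc, yc, cx=cx0, cy=cy0, r=params.lesion_radius_px, depth=params.lesion_depth
        )
        echo = np.where(inside, params.mean_echo * lesion, echo)
        theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        contour = np.column_stack([cx0 + a * np.cos(theta), cy0 + b * np.sin(theta)])
        roi = RegionOfInterest(kind="contour", view="transverse", contour=contour)
        # polygon-based truths (what a perfect tracing would measure)
        poly_area_px2 = 0.5 * abs(
            np.dot(contour[:, 0], np.roll(contour[:, 1], -1))
            - np.dot(contour[:, 1], np.roll(contour[:, 0], -1))
        )
        truth = {
            "thickness_cm": 2 * b * mm / 10.0,
            "width_cm": 2 * a * mm / 10.0,
            "area_cm2": poly_area_px2 * mm**2 / 100.0,
            "mean_echo": params.mean_echo,
        }

    speckle = rng.gamma(shape=params.speckle_shape, scale=1.0 / params.speckle_shape, size=(M, N))
    pixels = np.clip(np.rint(echo * speckle), 0, 255).astype(np.uint8)
    image = UltrasoundImage(pixels=pixels, calibration=cal, view=params.view, id=f"sim-{params.seed}")
    return image, roi, truth


@dataclass(frozen=True)
class StudySimParams:
    """Design sizes and effect magnitudes for a simulated crossed study."""

    n_s: int = 20
    n_e: int = 2
    n_v: int = 2
    n_i: int = 2
    grand_mean: float = 0.0
    variance_components: dict[str, float] = field(default_factory=dict)  # linear mode
    # imaging-mode effect sizes
    evaluator_gain_sd: float = 0.03
    visit_gain_sd: float = 0.01
    roi_jitter_sd_px: float = 0.0       # evaluator-by-subject tracing offset (SE family)
    subject_thickness_sd_cm: float = 0.05
    subject_echo_sd: float = 6.0
    group: str = "asymptomatic"
    view: str = "longitudinal"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_s, self.n_e, self.n_v, self.n_i) < 1:
            raise ValueError("design sizes must be >= 1")
        bad = set(self.variance_components) - set(EFFECTS)
        if bad:
            raise ValueError(f"unknown effects: {sorted(bad)}")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be >= 0")


def _linear_table(params: StudySimParams, rng: np.random.Generator) -> pd.DataFrame:
    sizes = {"S": params.n_s, "E": params.n_e, "V": params.n_v, "I": params.n_i}
    y = np.full(tuple(sizes[f] for f in FACETS), params.grand_mean, dtype=float)
    for eff in EFFECTS:
        sigma2 = params.variance_components.get(eff, 0.0)
        if sigma2 == 0.0:
            continue
        shape = tuple(sizes[f] if f in eff else 1 for f in FACETS)
        y = y + rng.normal(0.0, math.sqrt(sigma2), size=shape)
    recs = []
    for (s, e, v, i) in itertools.product(*(range(sizes[f]) for f in FACETS)):
        recs.append(
            {
                "tendon_id": f"T{s:04d}",
                "group": params.group,
                "evaluator": e + 1,
                "visit": v + 1,
                "image": i + 1,
                "feature": "synthetic",
                "value": y[s, e, v, i],
            }
        )
    return pd.DataFrame.from_records(recs)


def _imaging_table(params: StudySimParams, rng: np.random.Generator) -> pd.DataFrame:
    base = healthy_params if params.group == "asymptomatic" else pathologic_params
    config = FeatureConfig()
    gain_e = rng.normal(1.0, params.evaluator_gain_sd, size=params.n_e)
    gain_v = rng.normal(1.0, params.visit_gain_sd, size=params.n_v)
    recs = []
    for s in range(params.n_s):
        proto = base(view=params.view)
        t_cm = max(0.2, proto.thickness_cm + rng.normal(0.0, params.subject_thickness_sd_cm))
        echo = float(np.clip(proto.mean_echo + rng.normal(0.0, params.subject_echo_sd), 20, 230))
        # evaluator-specific tracing offsets, constant for a subject: SE family
        jitter_up = rng.normal(0.0, params.roi_jitter_sd_px, size=params.n_e)
        jitter_lo = rng.normal(0.0, params.roi_jitter_sd_px, size=params.n_e)
        for e, v, i in itertools.product(
            range(params.n_e), range(params.n_v), range(params.n_i)
        ):
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cell = base(
                view=params.view,
                thickness_cm=t_cm,
                mean_echo=float(np.clip(echo * gain_e[e] * gain_v[v], 10, 240)),
                seed=cell_seed,
            )
            image, roi, _ = simulate_tendon_image(cell)
            if params.roi_jitter_sd_px > 0 and roi.kind == "band":
                # evaluator-consistent offset (SE family) plus a smaller
                # per-image retracing wobble (residual family)
                cell_sd = 0.4 * params.roi_jitter_sd_px
                up = roi.upper_edge.copy()
                lo = roi.lower_edge.copy()
                up[:, 1] += jitter_up[e] + rng.normal(0.0, cell_sd)
                lo[:, 1] += jitter_lo[e] + rng.normal(0.0, cell_sd)
                if np.all(lo[:, 1] > up[:, 1]):
                    roi = RegionOfInterest(
                        kind="band", view=roi.view, upper_edge=up, lower_edge=lo
                    )
            fs = extract_features(image, roi, config)
            for name in fs.feature_names:
                recs.append(
                    {
                        "tendon_id": f"T{s:04d}",
                        "group": params.group,
                        "evaluator": e + 1,
                        "visit": v + 1,
                        "image": i + 1,
                        "feature": name,
                        "value": fs.values[name],
                        "undefined": name in fs.undefined,
                    }
                )
    return pd.DataFrame.from_records(recs)


def simulate_feature_study(
    params: StudySimParams, mode: Literal["linear", "imaging"] = "linear"
) -> pd.DataFrame:
    """Balanced crossed measurement table with known generating process.

    ``linear`` draws one zero-mean Gaussian effect per realized level
    combination of each of the 15 effects at its stated variance and sums
    them; ``imaging`` renders an image per cell and extracts real features.
    """
    rng = np.random.default_rng(params.seed)
    if mode == "linear":
        return _linear_table(params, rng)
    if mode == "imaging":
        return _imaging_table(params, rng)
    raise ValueError(f"unknown mode {mode!r}")
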