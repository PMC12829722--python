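"""Per-frame elasticity quantification.

Pipeline for one dual-panel frame with a left-panel lesion mask:

1. locate the marker line and split the frame into B-mode and elastogram
   panels;
2. transfer the mask to the elastogram panel (congruent crops, identity in
   panel-local coordinates);
3. restrict to the solid lesion component: drop mask pixels whose B-mode
   brightness falls below a threshold (anechoic / cystic regions carry no
   strain signal);
4. keep only *color* pixels of the overlay (saturation and value floors
   exclude the grayscale underlay showing through);
5. average the surviving RGB values at full precision, convert the mean to
   HSV, project onto the colormap by minimum distance, and report the
   matched index scaled to [0, 1] as the elasticity index (0 stiff .. 1
   soft), with a full audit trail and QC flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import colorspace
from .colorspace import Colormap, Projection
from .errors import (
    DegenerateLesionError,
    InvalidArgumentError,
    LowColorCoverageError,
)
from .panelio import (
    LesionMask,
    SplitGeometry,
    detect_marker_line,
    luma,
    map_mask_to_elasto,
    split_panels,
)


@dataclass
class QuantConfig:
    """Quantification thresholds.

    s_min, v_min
        Saturation / value floors defining a "color" overlay pixel
        (defaults 0.15 / 0.10).
    solid_tau
        B-mode brightness floor (0-255) below which a mask pixel is treated
        as anechoic and excluded; 0 disables the filter (default 20).
    min_color_fraction
        Minimum fraction of solid pixels that must be colored; below it the
        frame is rejected rather than quantified (default 0.10).
    s_indeterminate
        Mean-color saturation below which projection is refused.
    """

    s_min: float = 0.15
    v_min: float = 0.10
    solid_tau: float = 20.0
    min_color_fraction: float = 0.10
    s_indeterminate: float = colorspace.S_INDETERMINATE
    colormap: str = "canonical"
    n_entries: int = 256
    split_mode: str = "auto"
    fixed_split_x: int | None = None
    fixed_marker_width: int = 0

    def __post_init__(self):
        if not (0 <= self.s_min <= 1 and 0 <= self.v_min <= 1):
            raise InvalidArgumentError("s_min and v_min must lie in [0, 1]")
        if not 0 <= self.solid_tau <= 255:
            raise InvalidArgumentError("solid_tau must lie in [0, 255]")
        if not 0 <= self.min_color_fraction <= 1:
            raise InvalidArgumentError("min_color_fraction must lie in [0, 1]")

    def resolve_colormap(self) -> Colormap:
        return colorspace.resolve_colormap(self.colormap, self.n_entries)


@dataclass(frozen=True)
class PixelSample:
    """Colored lesion pixels with the counts of each filtering stage."""

    pixels: np.ndarray  # (n_color, 3) float RGB
    n_mask: int
    n_solid: int
    n_color: int


@dataclass(frozen=True)
class ElasticityResult:
    """Elasticity index with its audit trail."""

    eus_e_ai: float
    mean_rgb: tuple[float, float, float]
    mean_hsv: tuple[float, float, float]
    projection: Projection
    counts: tuple[int, int, int]  # (n_mask, n_solid, n_color)
    qc_flags: frozenset = field(default_factory=frozenset)


def solid_component_filter(
    bmode: np.ndarray, mask: LesionMask, tau: float
) -> LesionMask:
    """Restrict a mask to the solid lesion component.

    Keeps mask pixels whose B-mode brightness (luma) is at least ``tau``;
    anechoic / cystic pixels fall below and are removed.  ``tau <= 0``
    disables the filter.
    """
    if mask.bits.shape != bmode.shape[:2]:
        raise InvalidArgumentError("mask and B-mode panel dimensions differ")
    if tau <= 0:
        return mask
    solid = mask.bits & (luma(bmode) >= tau)
    if not solid.any():
        raise DegenerateLesionError(
            "no solid lesion pixels remain after the B-mode threshold"
        )
    return LesionMask(bits=solid, panel_side=mask.panel_side)


def select_color_pixels(
    elasto: np.ndarray,
    mask: LesionMask,
    cfg: QuantConfig,
    n_mask: int | None = None,
) -> PixelSample:
    """Select overlay color pixels inside the (solid-filtered) mask.

    A pixel counts as colored when its saturation >= ``cfg.s_min`` and value
    >= ``cfg.v_min``; the grayscale underlay fails the saturation floor.
    If fewer than ``cfg.min_color_fraction`` of the solid pixels are colored
    the frame is rejected.
    """
    if mask.bits.shape != elasto.shape[:2]:
        raise InvalidArgumentError("mask and elastogram panel dimensions differ")
    n_solid = mask.count
    if n_solid == 0:
        raise DegenerateLesionError("empty mask")
    rgb = np.asarray(elasto, dtype=float)[mask.bits]
    hsv = colorspace.rgb_to_hsv(rgb)
    keep = (hsv[:, 1] >= cfg.s_min) & (hsv[:, 2] >= cfg.v_min)
    n_color = int(keep.sum())
    if n_color / n_solid < cfg.min_color_fraction:
        raise LowColorCoverageError(
            f"only {n_color}/{n_solid} solid pixels are colored "
            f"(< {cfg.min_color_fraction:.0%})"
        )
    return PixelSample(
        pixels=rgb[keep],
        n_mask=n_solid if n_mask is None else int(n_mask),
        n_solid=n_solid,
        n_color=n_color,
    )


def mean_rgb(sample: PixelSample) -> np.ndarray:
    """Arithmetic per-channel mean of the sample, kept at full precision."""
    if sample.pixels.shape[0] == 0:
        raise DegenerateLesionError("no pixels to average")
    return sample.pixels.mean(axis=0)


def compute_eus_e_ai(
    frame: np.ndarray,
    mask: LesionMask,
    cfg: QuantConfig | None = None,
    cmap: Colormap | None = None,
) -> ElasticityResult:
    """Compute the elasticity index for one frame + left-panel mask."""
    cfg = cfg or QuantConfig()
    cmap = cmap if cmap is not None else cfg.resolve_colormap()

    geom = detect_marker_line(
        frame,
        mode=cfg.split_mode,
        fixed_x=cfg.fixed_split_x,
        fixed_marker_width=cfg.fixed_marker_width,
    )
    bmode, elasto = split_panels(frame, geom)
    n_mask = mask.count
    if n_mask == 0:
        raise DegenerateLesionError("empty lesion mask")
    right_mask = map_mask_to_elasto(mask, geom)
    solid = solid_component_filter(bmode, right_mask, cfg.solid_tau)
    sample = select_color_pixels(elasto, solid, cfg, n_mask=n_mask)

    mu_rgb = mean_rgb(sample)
    mu_hsv = colorspace.rgb_to_hsv(mu_rgb)
    proj = colorspace.project_to_colormap(mu_hsv, cmap, cfg.s_indeterminate)
    value = colorspace.index_to_elasticity(proj.index, len(cmap))

    flags = set()
    if geom.fallback:
        flags.add("fallback-split")
    if sample.n_color < 0.25 * sample.n_solid:
        # passed the hard floor but much of the lesion is uncolored
        flags.add("low-color-fraction")
    return ElasticityResult(
        eus_e_ai=value,
        mean_rgb=tuple(float(x) for x in mu_rgb),
        mean_hsv=tuple(float(x) for x in mu_hsv),
        projection=proj,
        counts=(sample.n_mask, sample.n_solid, sample.n_color),
        qc_flags=frozenset(flags),
    )


def aggregate_patients(
    frame_results: pd.DataFrame, method: str = "mean"
) -> pd.DataFrame:
    """Aggregate per-frame elasticity values to one value per patient.

    ``frame_results`` needs columns ``patient_id`` and ``eus_e_ai``.  The
    default aggregate is the mean across a patient's frames (median
    available).
    """
    if method not in ("mean", "median"):
        raise InvalidArgumentError("aggregation method must be mean or median")
    agg = (
        frame_results.groupby("patient_id")["eus_e_ai"]
        .agg(method)
        .reset_index()
    )
    agg["n_frames"] = (
        frame_results.groupby("patient_id")["eus_e_ai"].size().to_numpy()
    )
    return agg
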