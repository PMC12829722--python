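"""Elastography colormap and color math.

Strain elastograms overlay a blue(stiff)->red(soft) colormap on the B-mode
image.  The elasticity index of a lesion is the *position* of its average
color on that colormap: the mean lesion RGB is converted to HSV, projected
onto the discretized colormap curve by minimum distance, and the matched
entry's index, scaled to [0, 1], is the elasticity (0 = stiffest / blue,
1 = softest / red).

The vendor colormap is not published; the canonical colormap used here is a
linear hue sweep from 240 deg (blue) to 0 deg (red) at full saturation and
value, discretized into N entries (default 256, matching a blue-0/red-255
scale).  Alternative device colormaps can be loaded from CSV.

Conventions
-----------
* RGB triples are on the 0-255 channel scale (integers or reals).
* HSV triples are (hue in degrees [0, 360), saturation [0, 1], value [0, 1]);
  an achromatic color (s = 0) stores hue 0.
* The projection distance is ``d^2 = (dh_circ/180)^2 + ds^2 + dv^2`` where
  ``dh_circ`` is the circular hue difference in degrees (in [0, 180]); the
  division by 180 makes one full hue half-turn commensurate with the unit
  saturation and value ranges.  Ties resolve to the LOWER index (stiffer),
  a conservative choice toward flagging high malignant potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb as _hsv_to_rgb_unit
from matplotlib.colors import rgb_to_hsv as _rgb_to_hsv_unit

from .errors import IndeterminateColorError, InvalidArgumentError

#: Saturation below which a color is treated as achromatic (hue meaningless).
S_INDETERMINATE = 0.05


def rgb_to_hsv(rgb: Sequence[float] | np.ndarray) -> np.ndarray:
    """Convert RGB (0-255 scale) to HSV (degrees, unit s/v).

    Accepts a single triple or any ``(..., 3)`` array.  Standard hexcone
    conversion; achromatic inputs get hue 0.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise InvalidArgumentError("expected (..., 3) RGB input")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidArgumentError("RGB channels must lie in [0, 255]")
    hsv = _rgb_to_hsv_unit(arr / 255.0)
    hsv = np.asarray(hsv, dtype=float)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def hsv_to_rgb(hsv: Sequence[float] | np.ndarray) -> np.ndarray:
    """Convert HSV (degrees, unit s/v) to RGB on the 0-255 scale (floats).

    Callers that need 8-bit channels round the result.
    """
    arr = np.array(hsv, dtype=float)
    if arr.shape[-1] != 3:
        raise InvalidArgumentError("expected (..., 3) HSV input")
    arr[..., 0] = (arr[..., 0] % 360.0) / 360.0
    if arr[..., 1:].min() < 0 or arr[..., 1:].max() > 1:
        raise InvalidArgumentError("saturation and value must lie in [0, 1]")
    return np.asarray(_hsv_to_rgb_unit(arr), dtype=float) * 255.0


@dataclass(frozen=True)
class Colormap:
    """Ordered blue->red colormap with precomputed HSV coordinates.

    ``rgb`` is an ``(N, 3)`` uint8 array; ``hsv`` the matching ``(N, 3)``
    float array (hue in degrees).  Entry 0 is pure blue (stiff), entry N-1
    pure red (soft); hue decreases strictly with index.
    """

    rgb: np.ndarray
    hsv: np.ndarray

    def __len__(self) -> int:
        return self.rgb.shape[0]

    @property
    def n_entries(self) -> int:
        return self.rgb.shape[0]


@dataclass(frozen=True)
class Projection:
    """Result of projecting a color onto the colormap curve."""

    index: int
    hsv0: tuple[float, float, float]
    rgb0: tuple[int, int, int]
    distance: float


def build_colormap(n_entries: int = 256) -> Colormap:
    """Build the canonical linear-hue colormap with ``n_entries`` entries.

    Entry *i* has hue ``240 * (1 - i/(n_entries-1))`` degrees at full
    saturation and value, quantized to 8-bit RGB.  Endpoints are exactly
    (0,0,255) and (255,0,0).
    """
    if not isinstance(n_entries, (int, np.integer)) or n_entries < 2:
        raise InvalidArgumentError("n_entries must be an integer >= 2")
    i = np.arange(n_entries, dtype=float)
    hue = 240.0 * (1.0 - i / (n_entries - 1))
    hsv_ideal = np.stack([hue, np.ones(n_entries), np.ones(n_entries)], axis=-1)
    rgb = np.clip(np.rint(hsv_to_rgb(hsv_ideal)), 0, 255).astype(np.uint8)
    return Colormap(rgb=rgb, hsv=rgb_to_hsv(rgb))


def circular_hue_diff(h1: np.ndarray | float, h2: np.ndarray | float) -> np.ndarray:
    """Circular hue difference in degrees, in [0, 180]."""
    d = np.abs(np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def project_to_colormap(
    hsv: Sequence[float],
    cmap: Colormap,
    s_indeterminate: float = S_INDETERMINATE,
) -> Projection:
    """Minimum-distance projection of one HSV color onto the colormap.

    Raises :class:`IndeterminateColorError` when the color's saturation is
    below ``s_indeterminate``: an achromatic mean has no meaningful hue and
    must be rejected rather than mapped to a fabricated elasticity.
    """
    h, s, v = (float(x) for x in hsv)
    if s < s_indeterminate:
        raise IndeterminateColorError(
            f"mean saturation {s:.4f} < {s_indeterminate}: achromatic color "
            "has no position on the colormap"
        )
    dh = circular_hue_diff(cmap.hsv[:, 0], h) / 180.0
    d2 = dh**2 + (cmap.hsv[:, 1] - s) ** 2 + (cmap.hsv[:, 2] - v) ** 2
    idx = int(np.argmin(d2))  # argmin returns the first (lowest) index on ties
    return Projection(
        index=idx,
        hsv0=tuple(float(x) for x in cmap.hsv[idx]),
        rgb0=tuple(int(x) for x in cmap.rgb[idx]),
        distance=float(np.sqrt(d2[idx])),
    )


def index_to_elasticity(index: int, n_entries: int) -> float:
    """Map a colormap index to elasticity ``index / (n_entries - 1)``.

    0 is stiffest (blue), 1 softest (red): smaller values mean stiffer tissue.
    """
    if n_entries < 2:
        raise InvalidArgumentError("n_entries must be >= 2")
    if not 0 <= index <= n_entries - 1:
        raise InvalidArgumentError(
            f"index {index} outside [0, {n_entries - 1}]"
        )
    return float(index) / float(n_entries - 1)


def save_colormap_csv(cmap: Colormap, path) -> None:
    """Write the colormap as CSV with columns index, r, g, b."""
    import pandas as pd

    pd.DataFrame(
        {
            "index": np.arange(len(cmap)),
            "r": cmap.rgb[:, 0],
            "g": cmap.rgb[:, 1],
            "b": cmap.rgb[:, 2],
        }
    ).to_csv(path, index=False)


def load_colormap_csv(path) -> Colormap:
    """Load a device colormap from CSV (columns index, r, g, b)."""
    import pandas as pd

    df = pd.read_csv(path).sort_values("index")
    if len(df) < 2:
        raise InvalidArgumentError("colormap CSV needs at least 2 entries")
    rgb = df[["r", "g", "b"]].to_numpy()
    if rgb.min() < 0 or rgb.max() > 255:
        raise InvalidArgumentError("colormap channels must lie in [0, 255]")
    rgb = rgb.astype(np.uint8)
    return Colormap(rgb=rgb, hsv=rgb_to_hsv(rgb))


def resolve_colormap(spec: str = "canonical", n_entries: int = 256) -> Colormap:
    """Resolve a config colormap spec: ``canonical`` or ``file:<path>``."""
    if spec == "canonical":
        return build_colormap(n_entries)
    if spec.startswith("file:"):
        return load_colormap_csv(spec[5:])
    raise InvalidArgumentError(f"unknown colormap spec {spec!r}")
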