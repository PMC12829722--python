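"""Dual-panel frame I/O, marker-line detection, panel split, mask transfer.

An exported strain-elastography frame holds two registered panels side by
side — the grayscale B-mode image on the left and the color elastogram
overlay on the right — separated by a vertical marker band.  Because the
overlay is drawn on the same acquisition geometry, the two panels are
congruent crops: a lesion mask drawn on the B-mode panel transfers to the
elastogram panel by pure translation in panel-local coordinates.

Rasters are ``(H, W, 3)`` uint8 numpy arrays, origin top-left, x rightward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

from .errors import GeometryError, InvalidArgumentError

#: ITU-R BT.601 luma weights, used wherever a grayscale brightness is needed.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Maximum tolerated width difference between the two panels (px).
MAX_PANEL_WIDTH_MISMATCH = 2


def luma(img: np.ndarray) -> np.ndarray:
    """Per-pixel grayscale brightness of an RGB raster, 0-255 floats."""
    return np.asarray(img, dtype=float) @ LUMA_WEIGHTS


@dataclass(frozen=True)
class SplitGeometry:
    """Placement of the vertical marker band separating the two panels.

    ``split_x`` is the left edge of the marker band; the left panel spans
    ``[0, split_x)`` and the right panel ``[split_x + marker_width, width)``.
    """

    split_x: int
    marker_width: int
    width: int
    fallback: bool = False

    @property
    def left_slice(self) -> slice:
        return slice(0, self.split_x)

    @property
    def right_slice(self) -> slice:
        return slice(self.split_x + self.marker_width, self.width)


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask aligned to one panel ('left' or 'right')."""

    bits: np.ndarray  # (H, W) bool
    panel_side: str = "left"

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))
        if self.bits.ndim != 2:
            raise InvalidArgumentError("mask must be a 2-D binary grid")
        if self.panel_side not in ("left", "right"):
            raise InvalidArgumentError("panel_side must be 'left' or 'right'")

    @property
    def height(self) -> int:
        return self.bits.shape[0]

    @property
    def width(self) -> int:
        return self.bits.shape[1]

    @property
    def count(self) -> int:
        return int(self.bits.sum())


def load_frame(path) -> np.ndarray:
    """Load a PNG/JPEG frame as an (H, W, 3) uint8 RGB raster.

    Grayscale inputs are promoted to RGB; 16-bit channels are linearly
    rescaled to 0-255.  Unreadable or truncated files raise ``OSError``.
    """
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                # 16-bit grayscale: linear 65535 -> 255 rescale
                arr = np.asarray(im, dtype=np.float64)
                arr = np.rint(arr / 65535.0 * 255.0).clip(0, 255).astype(np.uint8)
                return np.stack([arr] * 3, axis=-1)
            if im.mode != "RGB":
                im = im.convert("RGB")
            return np.asarray(im, dtype=np.uint8).copy()
    except OSError:
        raise
    except Exception as exc:  # Pillow raises assorted types on corrupt data
        raise OSError(f"cannot read image {path}: {exc}") from exc


def save_frame(img: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


def detect_marker_line(
    img: np.ndarray,
    mode: str = "auto",
    fixed_x: int | None = None,
    fixed_marker_width: int = 0,
    contrast_floor: float = 12.0,
    probe_offset: int = 12,
) -> SplitGeometry:
    """Locate the vertical marker band between the two panels.

    ``auto`` scans the central band (40-60% of the width) for the column
    whose mean brightness stands out most against its neighbourhood at
    ``probe_offset`` px to each side; the marker band is grown from that
    peak.  When no column exceeds ``contrast_floor`` the split falls back to
    ``width // 2`` (flagged).  ``fixed`` returns the given x, which must lie
    in the central band.
    """
    h, w = img.shape[:2]
    if w < 4:
        raise InvalidArgumentError("image too narrow to split")
    lo, hi = int(0.4 * w), int(0.6 * w)
    if mode == "fixed":
        if fixed_x is None:
            raise InvalidArgumentError("fixed mode requires fixed_x")
        if not lo <= fixed_x < hi:
            raise InvalidArgumentError(
                f"fixed split x={fixed_x} outside central band [{lo}, {hi})"
            )
        return SplitGeometry(int(fixed_x), int(fixed_marker_width), w)
    if mode != "auto":
        raise InvalidArgumentError(f"unknown split mode {mode!r}")

    col = luma(img).mean(axis=0)
    k = probe_offset
    xs = np.arange(max(lo, k), min(hi, w - k))
    if xs.size == 0:
        return SplitGeometry(w // 2, 0, w, fallback=True)
    contrast = col[xs] - 0.5 * (col[xs - k] + col[xs + k])
    peak = int(xs[np.argmax(contrast)])
    if contrast.max() < contrast_floor:
        return SplitGeometry(w // 2, 0, w, fallback=True)
    # grow the marker band: columns at least halfway from background to peak
    bg = 0.5 * (col[max(peak - k, 0)] + col[min(peak + k, w - 1)])
    thresh = bg + 0.5 * (col[peak] - bg)
    x0 = peak
    while x0 > 0 and col[x0 - 1] >= thresh:
        x0 -= 1
    x1 = peak + 1
    while x1 < w and col[x1] >= thresh:
        x1 += 1
    return SplitGeometry(x0, x1 - x0, w)


def split_panels(img: np.ndarray, geom: SplitGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Crop the frame into (B-mode, elastogram) panels.

    Panel widths must agree within 2 px; a narrower right panel is padded
    with black at its right edge, a wider one trimmed, so the returned crops
    are congruent.  Larger mismatch is a geometry error, never a rescale.
    """
    h, w = img.shape[:2]
    if geom.width != w:
        raise GeometryError(f"geometry width {geom.width} != image width {w}")
    left = img[:, geom.left_slice]
    right = img[:, geom.right_slice]
    wl, wr = left.shape[1], right.shape[1]
    if wl == 0 or wr == 0:
        raise GeometryError("split produces an empty panel")
    if abs(wl - wr) > MAX_PANEL_WIDTH_MISMATCH:
        raise GeometryError(
            f"panel width mismatch {wl} vs {wr} exceeds {MAX_PANEL_WIDTH_MISMATCH} px"
        )
    if wr > wl:
        right = right[:, :wl]
    elif wr < wl:
        pad = np.zeros((h, wl - wr, 3), dtype=img.dtype)
        right = np.concatenate([right, pad], axis=1)
    return left.copy(), right.copy()


def map_mask_to_elasto(mask: LesionMask, geom: SplitGeometry) -> LesionMask:
    """Transfer a left-panel mask to the right panel.

    The panels are congruent crops of one acquisition, so the transfer is the
    identity in panel-local coordinates — rigid translation in frame
    coordinates, no scaling or rotation.
    """
    if mask.panel_side != "left":
        raise GeometryError("mask to transfer must live on the left panel")
    if mask.width != geom.split_x:
        raise GeometryError(
            f"mask width {mask.width} != left panel width {geom.split_x}"
        )
    return replace(mask, panel_side="right")


# ---------------------------------------------------------------------------
# Mask I/O: single-channel PNG (0 background / 255 foreground) or JSON RLE.

def save_mask_png(mask: LesionMask, path) -> None:
    arr = np.where(mask.bits, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_mask_png(path, panel_side: str = "left") -> LesionMask:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return LesionMask(bits=arr > 127, panel_side=panel_side)


def mask_to_rle(mask: LesionMask) -> dict:
    """Row-wise run-length encoding: per row, a list of [start, length]."""
    rows = []
    for row in mask.bits:
        runs = []
        padded = np.diff(np.r_[0, row.astype(np.int8), 0])
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            runs.append([int(s), int(e - s)])
        rows.append(runs)
    return {
        "width": mask.width,
        "height": mask.height,
        "panel_side": mask.panel_side,
        "rows": rows,
    }


def rle_to_mask(obj: dict) -> LesionMask:
    bits = np.zeros((obj["height"], obj["width"]), dtype=bool)
    for y, runs in enumerate(obj["rows"]):
        for start, length in runs:
            bits[y, start : start + length] = True
    return LesionMask(bits=bits, panel_side=obj.get("panel_side", "left"))


def save_mask_json(mask: LesionMask, path) -> None:
    with open(path, "w") as fh:
        json.dump(mask_to_rle(mask), fh)


def load_mask_json(path) -> LesionMask:
    with open(path) as fh:
        return rle_to_mask(json.load(fh))


def load_mask(path, panel_side: str = "left") -> LesionMask:
    """Load a mask from PNG or JSON-RLE, dispatching on the extension."""
    path = str(path)
    if path.endswith(".json"):
        return load_mask_json(path)
    return load_mask_png(path, panel_side=panel_side)
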