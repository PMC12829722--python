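"""Synthetic dual-panel elastography phantoms and calibrated cohorts.

No clinical images ship with this package, so every stage is exercised on
phantoms that emulate the export geometry of a strain-elastography frame:

* left panel — grayscale B-mode with speckle noise and a hypoechoic
  elliptical lesion, optionally carrying a near-black (anechoic) cystic
  core;
* a white vertical marker band separating the panels;
* right panel — the color elastogram: lesion pixels carry the colormap hue
  of the ground-truth elasticity ``e_star`` plus truncated Gaussian hue
  noise at full saturation/value; the background carries hues from a soft
  green band (60-150 deg) so it never mimics the stiff (blue) lesion
  signal; the cystic core stays dark and colorless on both panels.

Cohort generation draws per-patient ground-truth elasticities from
truncated log-normal distributions calibrated so the group medians and
interquartile ranges match the published clinical values (low-risk
0.268 [0.243-0.333]; high-risk 0.186 [0.176-0.199]) with the study's group
sizes (46 low-risk vs 38 high-risk) as defaults.  Everything is
deterministic given a seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import colorspace
from .errors import CalibrationError, InvalidArgumentError
from .panelio import LesionMask

# Published group elasticity quantiles (median, q1, q3) used as calibration
# targets for the default cohort.
LOW_RISK_QUANTILES = (0.268, 0.243, 0.333)
HIGH_RISK_QUANTILES = (0.186, 0.176, 0.199)
#: Study group sizes: 46 low-risk (15 very low + 31 low), 38 high-risk
#: (29 intermediate + 9 high).
DEFAULT_N_LOW = 46
DEFAULT_N_HIGH = 38
_NIH_WITHIN_LOW = {"very_low": 15 / 46, "low": 31 / 46}
_NIH_WITHIN_HIGH = {"intermediate": 29 / 38, "high": 9 / 38}

_Z_QUARTILE = stats.norm.ppf(0.75)  # 0.6744897...


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth and geometry for one phantom frame.

    Default geometry is a 600x300 frame with a 4 px marker band starting at
    x=298, giving two congruent 298x300 panels.  The lesion ellipse lives in
    left-panel coordinates and must fit inside the panel.
    """

    e_star: float = 0.25
    center: tuple[float, float] = (150.0, 150.0)
    axes: tuple[float, float] = (70.0, 45.0)
    rotation: float = 0.0  # radians
    cystic_fraction: float = 0.0
    hue_noise_sd: float = 5.0
    background_hue_range: tuple[float, float] = (60.0, 150.0)
    width: int = 600
    height: int = 300
    split_x: int = 298
    marker_width: int = 4
    seed: int = 0
    # B-mode appearance (0-255 luma)
    bg_mean: float = 120.0
    bg_sd: float = 12.0
    lesion_mean: float = 70.0
    lesion_sd: float = 8.0
    core_value: float = 5.0


def _ellipse_bits(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation: float,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - center[0], yy - center[1]
    c, s = np.cos(rotation), np.sin(rotation)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def elasticity_to_hue(e: float | np.ndarray) -> np.ndarray:
    """Colormap hue (degrees) of an elasticity value: 240*(1-e)."""
    return 240.0 * (1.0 - np.asarray(e, dtype=float))


def make_phantom(truth: PhantomTruth) -> tuple[np.ndarray, LesionMask]:
    """Render one dual-panel phantom frame and its left-panel truth mask."""
    if not 0.0 <= truth.e_star <= 1.0:
        raise InvalidArgumentError("e_star must lie in [0, 1]")
    if not 0.0 <= truth.cystic_fraction < 1.0:
        raise InvalidArgumentError("cystic_fraction must lie in [0, 1)")
    panel_w, h = truth.split_x, truth.height
    right_w = truth.width - truth.split_x - truth.marker_width
    if abs(right_w - panel_w) > 2 or panel_w < 1 or right_w < 1:
        raise InvalidArgumentError("split geometry does not give congruent panels")
    cx, cy = truth.center
    a, b = truth.axes
    r = max(a, b)
    if not (r <= cx <= panel_w - 1 - r and r <= cy <= h - 1 - r):
        raise InvalidArgumentError("lesion ellipse does not fit inside the panel")

    rng = np.random.default_rng(truth.seed)
    lesion = _ellipse_bits((h, panel_w), (cx, cy), (a, b), truth.rotation)
    if truth.cystic_fraction > 0:
        f = np.sqrt(truth.cystic_fraction)
        core = _ellipse_bits((h, panel_w), (cx, cy), (a * f, b * f), truth.rotation)
    else:
        core = np.zeros_like(lesion)

    # left panel: speckled B-mode, hypoechoic lesion, near-black core
    gray = rng.normal(truth.bg_mean, truth.bg_sd, size=(h, panel_w))
    gray[lesion] = rng.normal(truth.lesion_mean, truth.lesion_sd, size=int(lesion.sum()))
    gray[core] = truth.core_value
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    left = np.stack([gray] * 3, axis=-1)

    # right panel: colored overlay everywhere except the colorless core
    hue = rng.uniform(*truth.background_hue_range, size=(h, panel_w))
    lesion_hue = elasticity_to_hue(truth.e_star)
    if truth.hue_noise_sd > 0:
        noise = rng.normal(0.0, truth.hue_noise_sd, size=int(lesion.sum()))
    else:
        noise = 0.0
    hue[lesion] = np.clip(lesion_hue + noise, 0.0, 240.0)
    hsv = np.stack([hue, np.ones_like(hue), np.ones_like(hue)], axis=-1)
    right = np.clip(np.rint(colorspace.hsv_to_rgb(hsv)), 0, 255).astype(np.uint8)
    right[core] = int(truth.core_value)

    if right_w > panel_w:  # widen with extra background columns
        extra_hue = rng.uniform(*truth.background_hue_range, size=(h, right_w - panel_w))
        extra_hsv = np.stack(
            [extra_hue, np.ones_like(extra_hue), np.ones_like(extra_hue)], axis=-1
        )
        extra = np.clip(np.rint(colorspace.hsv_to_rgb(extra_hsv)), 0, 255).astype(np.uint8)
        right = np.concatenate([right, extra], axis=1)
    frame = np.zeros((h, truth.width, 3), dtype=np.uint8)
    frame[:, : truth.split_x] = left
    frame[:, truth.split_x : truth.split_x + truth.marker_width] = 255
    frame[:, truth.split_x + truth.marker_width :] = right[:, :right_w]
    return frame, LesionMask(bits=lesion, panel_side="left")


@dataclass(frozen=True)
class CalibratedLognormal:
    """Log-normal law truncated to [0, 1], pinned by median and IQR width."""

    mu: float
    sigma: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.exp(rng.normal(self.mu, self.sigma, size=n))
        bad = (out <= 0) | (out >= 1)
        while bad.any():  # truncation by resampling; targets sit well inside (0,1)
            out[bad] = np.exp(rng.normal(self.mu, self.sigma, size=int(bad.sum())))
            bad = (out <= 0) | (out >= 1)
        return out

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))


def calibrate_distribution(median: float, iqr: tuple[float, float]) -> CalibratedLognormal:
    """Fit the two log-normal parameters from a target median and IQR.

    Solves the quantile equations exactly: ``mu = ln(median)`` and
    ``q3 - q1 = 2 median sinh(z_.75 sigma)``, i.e.
    ``sigma = asinh((q3-q1)/(2 median)) / z_.75``.  Infeasible or
    degenerate targets raise a calibration error.
    """
    q1, q3 = iqr
    if not (0.0 < q1 < median < q3 < 1.0):
        raise CalibrationError(
            f"need 0 < q1 < median < q3 < 1, got q1={q1}, median={median}, q3={q3}"
        )
    sigma = float(np.arcsinh((q3 - q1) / (2.0 * median)) / _Z_QUARTILE)
    return CalibratedLognormal(mu=float(np.log(median)), sigma=sigma)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic patient cohort.

    Group sizes and elasticity distributions default to the published study
    conditions.  ``frame_template`` fixes the frame geometry for every
    generated phantom (lesion placement varies per frame).
    """

    n_low: int = DEFAULT_N_LOW
    n_high: int = DEFAULT_N_HIGH
    low_quantiles: tuple[float, float, float] = LOW_RISK_QUANTILES
    high_quantiles: tuple[float, float, float] = HIGH_RISK_QUANTILES
    frame_count: int = 1
    seed: int = 0
    frame_template: PhantomTruth = field(default_factory=PhantomTruth)

    def __post_init__(self):
        if self.n_low < 1 or self.n_high < 1:
            raise InvalidArgumentError("group sizes must be >= 1")
        if self.frame_count < 1:
            raise InvalidArgumentError("frame_count must be >= 1")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: truth records plus per-frame phantoms."""

    records: pd.DataFrame  # one row per patient
    frames: list  # list of (patient_id, frame, mask, PhantomTruth)


def _draw_patient_covariates(rng: np.random.Generator, group: str) -> dict:
    """Plausible Table-1-style covariates, conditioned on the group.

    Rates mirror the published baseline table: lesions >2 cm in 19/46 of the
    low-risk vs 34/38 of the high-risk group, etc.
    """
    if group == "low_risk":
        nih = rng.choice(list(_NIH_WITHIN_LOW), p=list(_NIH_WITHIN_LOW.values()))
        age = rng.normal(59.0, 10.87)
        p_male, p_gt2 = 16 / 46, 19 / 46
        loc_p = np.array([1, 23, 19, 1, 2]) / 46
        mitotic = int(rng.integers(0, 5))
    else:
        nih = rng.choice(list(_NIH_WITHIN_HIGH), p=list(_NIH_WITHIN_HIGH.values()))
        age = rng.normal(62.6, 10.92)
        p_male, p_gt2 = 19 / 38, 34 / 38
        loc_p = np.array([1, 22, 12, 0, 3]) / 38
        mitotic = int(rng.integers(5, 25))
    return {
        "nih": str(nih),
        "age": float(np.clip(age, 18, 95)),
        "sex": "male" if rng.random() < p_male else "female",
        "size_class": "gt2cm" if rng.random() < p_gt2 else "le2cm",
        "location": str(
            rng.choice(["cardia", "fundus", "body", "antrum", "extragastric"], p=loc_p)
        ),
        "mitotic_count": mitotic,
    }


def _lesion_geometry(
    rng: np.random.Generator, template: PhantomTruth, size_class: str
) -> tuple[tuple[float, float], tuple[float, float], float]:
    panel_w, h = template.split_x, template.height
    scale = min(panel_w, h) / 300.0
    if size_class == "gt2cm":
        a = rng.uniform(55, 85) * scale
    else:
        a = rng.uniform(25, 45) * scale
    b = a * rng.uniform(0.55, 0.85)
    r = max(a, b)
    cx = rng.uniform(r + 2, panel_w - 3 - r)
    cy = rng.uniform(r + 2, h - 3 - r)
    rot = rng.uniform(0, np.pi)
    return (cx, cy), (a, b), rot


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort deterministically from the spec seed."""
    low = calibrate_distribution(spec.low_quantiles[0], spec.low_quantiles[1:])
    high = calibrate_distribution(spec.high_quantiles[0], spec.high_quantiles[1:])
    rng = np.random.default_rng(spec.seed)
    rows, frames = [], []
    plan = [("low_risk", low)] * spec.n_low + [("high_risk", high)] * spec.n_high
    for i, (group, dist) in enumerate(plan):
        pid = f"P{i + 1:04d}"
        e_star = float(dist.sample(1, rng)[0])
        cov = _draw_patient_covariates(rng, group)
        rows.append({"patient_id": pid, "group": group, "e_star": e_star, **cov})
        for j in range(spec.frame_count):
            center, axes, rot = _lesion_geometry(rng, spec.frame_template, cov["size_class"])
            truth = replace(
                spec.frame_template,
                e_star=e_star,
                center=center,
                axes=axes,
                rotation=rot,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            frame, mask = make_phantom(truth)
            frames.append((pid, frame, mask, truth))
    return SyntheticCohort(records=pd.DataFrame(rows), frames=frames)


def split_by_patient(
    patient_ids, test_fraction: float = 0.1, seed: int = 0
) -> tuple[list, list]:
    """Patient-level train/test split: no patient appears on both sides."""
    if not 0 < test_fraction < 1:
        raise InvalidArgumentError("test_fraction must lie in (0, 1)")
    unique = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    n_test = max(1, int(round(test_fraction * len(unique))))
    test = {unique[i] for i in perm[:n_test]}
    return [p for p in unique if p not in test], sorted(test)


def write_cohort(cohort: SyntheticCohort, outdir) -> pd.DataFrame:
    """Write frames/masks as PNG plus manifest and truth CSVs; returns manifest."""
    from pathlib import Path

    from .panelio import save_frame, save_mask_png

    out = Path(outdir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    counter: dict = {}
    for pid, frame, mask, truth in cohort.frames:
        k = counter.get(pid, 0)
        counter[pid] = k + 1
        fp = out / "frames" / f"{pid}_{k:02d}.png"
        mp = out / "masks" / f"{pid}_{k:02d}.png"
        save_frame(frame, fp)
        save_mask_png(mask, mp)
        rows.append(
            {
                "frame_path": str(fp),
                "mask_path": str(mp),
                "patient_id": pid,
                "split_mode": "auto",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    cohort.records.to_csv(out / "truth.csv", index=False)
    return manifest
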