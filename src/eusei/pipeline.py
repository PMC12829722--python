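"""End-to-end orchestration: extract -> aggregate -> stratify -> report.

Also hosts the replicate simulation study used to characterize the
calibrated synthetic cohort (Youden cutoff location and AUC across seeds).
All outputs are deterministic under a fixed config and seed; report JSON is
written with sorted keys and floats rounded to 6 significant digits so
reruns are byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import lesion_quant, phantom, stratification
from .errors import EuseiError
from .lesion_quant import QuantConfig
from .panelio import load_frame, load_mask

log = logging.getLogger("eusei")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    manifest: str | None = None
    cohort: str | None = None
    outdir: str = "eusei_out"
    quant: QuantConfig = field(default_factory=QuantConfig)
    cutoff: str | float = "youden"  # 'youden' or a fixed value in [0, 1]
    ci_method: str = "wald"
    aggregate: str = "mean"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        d = self.to_dict()
        for key in ("manifest", "cohort", "outdir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return round(float(x), -int(floor(log10(abs(x)))) + sig - 1)


def _jsonable(obj):
    """Recursively convert to JSON-friendly values with 6-sig-digit floats."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, sort_keys=True, indent=2)
        fh.write("\n")


def extract_manifest(manifest: pd.DataFrame, cfg: QuantConfig) -> pd.DataFrame:
    """Run elasticity extraction for every manifest row.

    Returns the per-frame results table; QC-rejected frames get a row with
    NaN elasticity and the rejection reason in ``qc_flags``.  Every
    rejection is logged with the frame id and reason.
    """
    cmap = cfg.resolve_colormap()
    rows = []
    for rec in manifest.itertuples(index=False):
        row = {
            "patient_id": rec.patient_id,
            "frame_path": rec.frame_path,
            "eus_e_ai": np.nan,
            "n_mask": 0,
            "n_solid": 0,
            "n_color": 0,
            "mean_r": np.nan,
            "mean_g": np.nan,
            "mean_b": np.nan,
            "proj_index": -1,
            "qc_flags": "",
        }
        try:
            frame = load_frame(rec.frame_path)
            mask = load_mask(rec.mask_path)
            res = lesion_quant.compute_eus_e_ai(frame, mask, cfg, cmap)
        except (EuseiError, OSError) as exc:
            reason = getattr(exc, "flag", type(exc).__name__)
            log.warning("QC reject %s: %s", rec.frame_path, exc)
            row["qc_flags"] = f"rejected:{reason}"
            rows.append(row)
            continue
        row.update(
            eus_e_ai=res.eus_e_ai,
            n_mask=res.counts[0],
            n_solid=res.counts[1],
            n_color=res.counts[2],
            mean_r=res.mean_rgb[0],
            mean_g=res.mean_rgb[1],
            mean_b=res.mean_rgb[2],
            proj_index=res.projection.index,
            qc_flags=";".join(sorted(res.qc_flags)),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_cohort(
    patient_values: pd.DataFrame,
    cohort: pd.DataFrame,
    cutoff: str | float = "youden",
    ci_method: str = "wald",
) -> dict:
    """Stratification report from per-patient values and a labelled cohort.

    ``patient_values`` has columns patient_id, eus_e_ai; ``cohort`` needs
    patient_id and either a ``group`` column or an ``nih`` column (grouped
    here; ungroupable patients are excluded with a log entry).
    """
    df = cohort.copy()
    if "group" not in df:
        groups, excluded = [], 0
        for nih in df["nih"]:
            try:
                groups.append(stratification.group_nih(nih))
            except EuseiError:
                groups.append(None)
                excluded += 1
        df["group"] = groups
        if excluded:
            log.warning("excluded %d patients with ungroupable NIH category", excluded)
    df = df.dropna(subset=["group"])
    df = df.drop(columns=["eus_e_ai"], errors="ignore")
    merged = df.merge(patient_values, on="patient_id", how="inner").dropna(
        subset=["eus_e_ai"]
    )
    values = merged["eus_e_ai"].to_numpy(dtype=float)
    labels = merged["group"].to_numpy()

    curve = stratification.roc(values, labels)
    if cutoff == "youden":
        used_cutoff, j = stratification.youden_cutoff(curve)
    else:
        used_cutoff = float(cutoff)
        j = None
    cm = stratification.confusion(values, labels, used_cutoff)
    summary = stratification.diagnostic_metrics(cm, ci_method, cutoff=used_cutoff)
    report = {
        "n_patients": int(len(merged)),
        "n_low_risk": int((labels == stratification.LOW_RISK).sum()),
        "n_high_risk": int((labels == stratification.HIGH_RISK).sum()),
        "cutoff": used_cutoff,
        "cutoff_policy": "youden" if cutoff == "youden" else "fixed",
        "youden_j": j,
        "auc": curve.auc,
        "roc_points": curve.points,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "diagnostics": summary,
    }
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full extract -> aggregate -> stratify run and write outputs."""
    if cfg.manifest is None or cfg.cohort is None:
        raise EuseiError("run_pipeline needs manifest and cohort paths")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(cfg.manifest)
    cohort = pd.read_csv(cfg.cohort)

    frame_results = extract_manifest(manifest, cfg.quant)
    frame_results.to_csv(outdir / "frames.csv", index=False)
    ok = frame_results.dropna(subset=["eus_e_ai"])
    per_patient = lesion_quant.aggregate_patients(ok, cfg.aggregate)
    per_patient.to_csv(outdir / "patients.csv", index=False)

    report = stratify_cohort(per_patient, cohort, cfg.cutoff, cfg.ci_method)
    report["qc"] = {
        "frames_total": int(len(manifest)),
        "frames_processed": int(len(ok)),
        "frames_rejected": int(len(frame_results) - len(ok)),
    }
    report["config_hash"] = cfg.config_hash()
    report["seed"] = cfg.seed
    write_report(report, outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# Calibrated replicate study

def extract_cohort_values(
    cohort: phantom.SyntheticCohort,
    cfg: QuantConfig | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Extract per-patient elasticity from an in-memory synthetic cohort."""
    cfg = cfg or QuantConfig()
    cmap = cfg.resolve_colormap()
    rows = []
    for pid, frame, mask, _truth in cohort.frames:
        try:
            res = lesion_quant.compute_eus_e_ai(frame, mask, cfg, cmap)
        except EuseiError as exc:
            log.warning("QC reject patient %s frame: %s", pid, exc)
            continue
        rows.append({"patient_id": pid, "eus_e_ai": res.eus_e_ai})
    return lesion_quant.aggregate_patients(pd.DataFrame(rows), aggregate)


def small_frame_template(width: int = 240, height: int = 120) -> phantom.PhantomTruth:
    """Reduced-geometry frame template for large replicate studies."""
    marker = 4
    split = (width - marker) // 2
    return phantom.PhantomTruth(width=width, height=height, split_x=split, marker_width=marker)


def replicate_study(
    n_seeds: int = 200,
    base_seed: int = 0,
    spec: phantom.CohortSpec | None = None,
    cfg: QuantConfig | None = None,
) -> pd.DataFrame:
    """Repeat cohort generation + extraction + ROC/Youden across seeds.

    Returns one row per replicate with the extracted-value AUC and Youden
    cutoff.  The default cohort spec uses the published group sizes and
    calibrated distributions on a reduced frame geometry.
    """
    spec = spec or phantom.CohortSpec(frame_template=small_frame_template())
    cfg = cfg or QuantConfig()
    rng = np.random.default_rng(base_seed)
    rows = []
    for k in range(n_seeds):
        seed = int(rng.integers(0, 2**31 - 1))
        cohort = phantom.make_cohort(replace(spec, seed=seed))
        vals = extract_cohort_values(cohort, cfg)
        merged = cohort.records.merge(vals, on="patient_id")
        curve = stratification.roc(merged["eus_e_ai"], merged["group"])
        cut, j = stratification.youden_cutoff(curve)
        rows.append({"replicate": k, "seed": seed, "auc": curve.auc, "cutoff": cut, "youden_j": j})
    return pd.DataFrame(rows)
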