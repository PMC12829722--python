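# eusei

Quantitative elasticity indexing and risk stratification for dual-panel
endoscopic-ultrasound (EUS) strain elastography frames.

## The problem

Gastrointestinal stromal tumors (GISTs) carry malignant potential, and
preoperative risk stratification (NIH consensus categories: very low / low /
intermediate / high) guides surgery versus surveillance. EUS elastography
overlays a tissue-stiffness colormap — blue for stiff, red for soft — on the
B-mode image, but reading the colors is subjective. `eusei` turns the color
overlay into an objective 0–1 elasticity index for a segmented lesion and
provides the patient-level statistics to convert that index into a binary
low- vs high-risk malignant-potential call.

The package is for image-analysis and clinical-research engineers working
with exported dual-panel elastography frames (left panel B-mode, right panel
color elastogram, vertical marker band between) plus lesion masks drawn on
the B-mode panel.

## The index

For a lesion mask **M** on a frame:

1. split the frame at the marker band into congruent B-mode and elastogram
   panels, and transfer **M** to the elastogram panel (identity in
   panel-local coordinates);
2. restrict **M** to the solid lesion component: drop pixels whose B-mode
   luma is below τ (anechoic/cystic tissue carries no strain signal);
3. keep overlay *color* pixels (saturation ≥ s_min, value ≥ v_min) and form
   the full-precision channel means (R̄, Ḡ, B̄);
4. convert the mean to HSV and project it onto the blue→red colormap
   (entries indexed 0…N−1, hue 240°→0° at full saturation/value) by minimum
   distance d² = (Δh/180)² + Δs² + Δv², ties to the lower (stiffer) index;
5. the elasticity index is k/(N−1) for the matched entry k — 0 is stiffest
   (blue), 1 softest (red).

Patients are stratified by a cutoff c: index < c ⇒ high-risk malignant
potential. The operating cutoff is chosen on the ROC curve by maximizing the
Youden index J = sensitivity + specificity − 1; diagnostic metrics come with
Wald (default) or Wilson 95% CIs.

Because no clinical images ship with the package, a phantom generator
renders dual-panel frames with known ground truth, and cohort simulation
draws per-patient elasticities from truncated log-normal distributions
calibrated to the clinically reported group quantiles (low-risk median
0.268 [IQR 0.243–0.333], high-risk 0.186 [0.176–0.199], 46 vs 38 patients).

## Worked example

```python
from eusei import phantom
from eusei.lesion_quant import compute_eus_e_ai

frame, mask = phantom.make_phantom(phantom.PhantomTruth(e_star=0.30, seed=7))
res = compute_eus_e_ai(frame, mask)
print(res.eus_e_ai, res.projection.index, res.counts)
# 0.30196078431372547 77 (9883, 9883, 9883)
```

The phantom lesion was painted at true elasticity 0.30 with 5° hue noise;
the pipeline recovers index 77/255 ≈ 0.302 from the 9883 lesion pixels (all
solid, all colored). A full synthetic cohort at the published group sizes:

```python
from eusei import stratification as st
from eusei.pipeline import extract_cohort_values, small_frame_template

cohort = phantom.make_cohort(
    phantom.CohortSpec(seed=1, frame_template=small_frame_template()))
vals = extract_cohort_values(cohort)
merged = cohort.records.merge(vals, on="patient_id")
curve = st.roc(merged["eus_e_ai"], merged["group"])
cutoff, j = st.youden_cutoff(curve)
print(len(merged), round(curve.auc, 3), round(cutoff, 3))
# 84 0.868 0.222
```

84 patients (46 low-risk, 38 high-risk); the extracted values give AUC 0.868
and a Youden-optimal cutoff 0.222, which falls in the gap between the two
groups' adjacent quartiles (0.199–0.243) — the same region as the clinically
reported cutoff 0.224.

## Command line

```bash
eusei synth --spec spec.yaml --seed 1 --out cohort/      # phantom cohort
eusei extract --manifest cohort/manifest.csv --out frames.csv
eusei seg-eval --pred preds/ --truth masks/ --iou 0.5
eusei stratify --cohort cohort.csv --cutoff youden --out report.json
eusei run --config run.yaml                               # end to end
```

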