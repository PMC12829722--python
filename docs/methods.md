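# Methods

## Elasticity index

Strain elastography is qualitative: the scanner maps relative tissue strain
onto a blue(stiff)→red(soft) colormap drawn over the B-mode image. The
index computed here is the *position* of a lesion's average overlay color on
that colormap, scaled to [0, 1]. The chain is: mean lesion RGB → HSV →
minimum-distance projection onto the discretized colormap curve → matched
index k → elasticity k/(N−1).

Averaging is done in RGB first and converted to HSV afterwards. Averaging
hues directly (circularly) would give a different and arguably more
color-faithful center, but the RGB-mean convention is the one the index is
defined by, and for the narrow hue spreads of a single lesion the two agree
to well under one colormap step.

### Canonical colormap

The vendor colormap of the echoendoscope processor is not published. The
canonical colormap is therefore a linear hue sweep 240°→0° at full
saturation and value, discretized to N = 256 8-bit RGB entries, matching
the blue-0/red-255 scale that defines the index. Entry RGB values are
rounded to integers and the per-entry HSV coordinates are recomputed from
the rounded RGB, so a pixel painted with an entry's exact color projects
back to that entry with distance zero. The rounding perturbs per-entry hue
by at most ~0.12°, well under the 240/255 ≈ 0.94° inter-entry step, so hue
remains strictly monotone in index. Device colormaps can be substituted via
CSV (`colormap: file:<path>`).

### Projection metric and edge cases

The distance between two HSV points is d² = (Δh_circ/180)² + Δs² + Δv² with
Δh_circ the circular hue difference in degrees. Dividing by 180 makes the
longest possible hue excursion commensurate with the unit saturation and
value ranges; the metric is deliberately simple (no perceptual color space)
because the projection target is a synthetic colormap curve, not a
perceptual neighborhood. Distance ties resolve to the lower index, i.e. the
stiffer call — conservative in the direction of flagging malignancy. A mean
color with saturation below 0.05 has no meaningful hue and is rejected
(`achromatic` QC error) instead of being assigned a fabricated elasticity.

## Panel geometry and mask transfer

Exports place the B-mode panel left, the elastogram right, and a bright
vertical marker band between. Auto-detection scans the central 40–60% of
the width for the column whose mean brightness stands out most against its
neighborhood 12 px to each side, then grows the band to columns at least
halfway from background to peak brightness; if no column clears a contrast
floor of 12 luma units the split falls back to width/2 with a QC flag, and
a fixed split is always available. Panels must agree in width within 2 px
(right panel trimmed/padded at its right edge); a larger mismatch is an
error rather than a silent rescale, because the overlay is drawn on the
same acquisition geometry and the panels must be congruent. For the same
reason mask transfer is the identity in panel-local coordinates — no
registration, scaling or rotation.

## Quantification thresholds

| parameter | default | meaning |
|---|---|---|
| `solid_tau` | 20 (luma, 0–255) | B-mode floor separating solid tissue from anechoic/cystic regions; 0 disables |
| `s_min` | 0.15 | saturation floor for an overlay "color" pixel |
| `v_min` | 0.10 | value floor (excludes near-black pixels) |
| `min_color_fraction` | 0.10 | minimum colored fraction of solid pixels; below it the frame is rejected |
| `s_indeterminate` | 0.05 | mean-color saturation below which projection is refused |

What counts as a "color pixel" and how solid tissue is identified are not
specified by any published criterion; these thresholds are this package's
operationalization and are all configurable. The defaults separate a fully
saturated overlay from a grayscale underlay with a wide margin.

Multi-frame patients are aggregated by the mean of their per-frame indices
(median by flag); per-frame values are kept in the output CSV so either
granularity can be re-derived.

## Stratification statistics

The positive class is high-risk malignant potential and the score is
negatively oriented (stiffer = smaller index = more malignant); a patient
is called positive when the index is *strictly* below the cutoff. ROC
candidate cutoffs are the midpoints between consecutive distinct values
plus ∓∞ sentinels; AUC is the trapezoidal area, which equals the
tie-corrected Mann–Whitney statistic (asserted against
`scipy.stats.mannwhitneyu` in tests). The Youden-optimal cutoff maximizes
J = sens + spec − 1 with ties broken toward higher sensitivity, then the
lower cutoff; midpoint placement keeps the cutoff stable under small
perturbations of the data.

Proportion CIs default to Wald (p ± 1.96·√(p(1−p)/n), clamped to [0, 100]);
Wilson is available by flag. A metric with a zero denominator is reported
as undefined, never as 0. Group comparisons use t / Mann–Whitney for
continuous variables and χ² with a Fisher's-exact switch for 2×2 tables
with an expected count below 5. Logistic odds ratios are maximum-likelihood
fits (statsmodels) with Wald CIs; complete separation is detected per
covariate and reported by name.

## Phantom generator

Each phantom emulates the dual-panel export: a speckled B-mode panel
(background luma 120 ± 12) with a hypoechoic elliptical lesion (70 ± 8),
optionally an anechoic core (luma 5, below `solid_tau`) covering a set
fraction of the lesion area; a 4 px white marker band; and a color
elastogram whose lesion pixels carry the colormap hue of the ground-truth
elasticity e\* plus Gaussian hue noise (default σ = 5°, truncated to
[0°, 240°] by clipping) at full saturation/value. Background overlay hues
are drawn from the green band 60°–150°, so the background never mimics the
stiff (blue) lesion signal. Everything is deterministic per seed.

Cohorts draw per-patient e\* from log-normal distributions truncated to
[0, 1], calibrated by solving the two quantile equations exactly:
μ = ln(median) and σ = asinh(IQR/(2·median))/z₀.₇₅. The default targets are
the clinically reported group quantiles (low-risk 0.268 [0.243–0.333],
high-risk 0.186 [0.176–0.199]) with group sizes 46/38; covariates (age,
sex, size class, location, NIH subcategory) are drawn at the reported
group-conditional rates. Train/test splitting is always by synthetic
patient id, never by frame.

What the phantoms do *not* emulate: real ultrasound speckle statistics,
compression dynamics, probe-pressure artifacts, inhomogeneous intra-lesion
stiffness, and panel mis-registration. Passing recovery tests therefore
shows the color-inversion chain is correct and well-conditioned, not that
the index is clinically accurate on real frames.

### What the calibrated simulation can and cannot show

With log-normal groups pinned to the published medians/IQRs, the population
AUC is Φ(ln(0.268/0.186)/√(0.2478² + 0.0916²)) ≈ 0.917, and at n = 46 + 38
the replicate AUC exceeds 0.9 in only about 60–75% of cohorts (the
acceptance script computes the exact fraction for its seed). Median and IQR
constrain only the central half of each distribution; the clinical cohort's
reported AUC of 0.940 implies its tails were lighter than log-normal ones
matched to those quantiles. The simulated Youden cutoff, by contrast, is a
robust quantity: it falls in the gap between the groups' adjacent quartiles
(0.199–0.243) in ≈99% of replicates, bracketing the clinically reported
0.224.

## Toy segmenter

The demonstrator segmenter for phantom B-mode panels is a multi-scale
Gaussian filter bank (raw luma, σ = 1, 2, 4, 8 smoothings, gradient
magnitude at σ = 2) feeding a logistic pixel classifier, with binary
closing, hole filling and largest-component selection as post-processing —
the classic trainable-segmentation design. It requires ≥ 50 training
frames, is deterministic given a seed, and reaches held-out Dice > 0.99 on
the near-trivial phantom task. It makes no claim about clinical
segmentation performance; clinical masks are *inputs* to this package.

## Problem sizes

Recovery sweeps and the 200-replicate cohort simulation run on reduced
240×120 frames and the segmenter demonstration on 300×150 frames with
60 training / 25 held-out phantoms; geometry is a free parameter of the
generator and none of the calibrated distributions, group sizes or noise
levels are changed by this choice. Default single-frame analyses use the
full 600×300 geometry.

## Known limitations

- The canonical colormap is an idealization; against a real device export
  the colormap CSV must be measured and supplied.
- RGB-mean (rather than circular-hue-mean) averaging is part of the index
  definition; lesions with strongly bimodal color content will land between
  modes.
- The Wald CI is kept as the default for continuity with the clinical
  worked example; Wilson is preferable at small n and is one flag away.
- Image-level vs patient-level evaluation granularity changes diagnostic
  metrics when patients contribute unequal frame counts; both are
  supported, and per-frame values are always retained.
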