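# Methods

This note records the models, conventions and numerical choices behind
`sudoquant`, and what the synthetic-data validation does and does not
establish about real scans.

## Image pipeline

**Colour model.** The indicator chemistry is a blue → pink transition of a
cobalt(II) salt, so pink-vs-blue is fundamentally a *hue* distinction and
is treated in hue/saturation/value space, where it is robust to the
multiplicative illumination changes a flatbed scanner produces (a uniform
gain leaves hue and saturation unchanged). Defaults, all exposed in the
`colour` config section:

| parameter | default | meaning |
|---|---|---|
| pink hue | [270°, 360°) ∪ [0°, 30°) | magenta/pink side of the hue circle |
| blue hue | [180°, 270°) | blue side |
| saturation gate | 0.15 | below it a pixel is whitish → class "other" |
| hue bins | 36 × 10° | reporting histogram over masked pixels |

The exact hue range of a fully reacted pad is not calibrated against real
scans; the intervals are deliberately wide, documented assumptions. Pixels
passing the gate but in neither interval, and unsaturated pixels, count as
"other" and *remain in the denominator*: the percentage is pink over the
whole pad area, not pink/(pink+blue).

**Segmentation.** The pad is separated from the scanner bed by Otsu's
threshold recomputed on every image ("variable threshold") on the
saturation channel — a coloured pad is saturated, the white/grey bed is
not. A luminance-channel variant is config-selectable for pads scanned on
dark beds. Two guards turn degenerate inputs into a clean failure instead
of a nonsense mask: the foreground must cover ≥ 1 % of the frame
(`foreground_floor`) and the foreground/background mean-channel contrast
must exceed 0.10 (`min_contrast`); Otsu always *finds* a split, so without
the contrast guard an all-background image would be "segmented" into its
noise.

**Morphology.** Opening then closing with a disc of radius 0.5 mm —
specified in physical units and converted to pixels via the dpi, so
behaviour is resolution-independent — then largest-connected-component
retention and interior hole filling. One non-obvious ordering choice:
interior holes are filled *before* the opening as well. An opening first
would erode a crater of the structuring-element radius around every
isolated dropped pixel inside the pad (a salt speck converts ~1 px of
error into ~πr² px); pre-filling makes the opening act only on its real
target, isolated background specks. A known boundary effect of disc
openings is retained deliberately: a single-pixel bump exactly at a disc's
extreme point survives, which is immaterial at the 0.95-IoU level the
pipeline is validated to.

**Categories.** The three-level visual read-out is reproduced by
thresholding the percentage: normal ≥ 90, abnormal ≤ 10, intermediate
between, with boundaries inclusive toward the less-diseased category. The
visual test has no published numerical definition of its categories; 90
echoes the proposed screening cut-off for autonomic dysfunction and both
thresholds are configuration, not claims.

**Other conventions.** Intensities are normalized to [0, 1] (8- and
16-bit inputs accepted; RGBA alpha dropped; greyscale rejected since hue
is meaningless there). Missing dpi metadata falls back to the 600 dpi
protocol resolution with a logged warning. Physical pad area is
area_px · (25.4/dpi)². The pipeline contains no random number generator
anywhere, which is what makes the repeatability coefficient exactly 1.

## Synthetic pads

`synth.generate_pad` renders a 12 × 12 mm rounded-corner (r = 2 mm) pad
centred in a 3 mm margin at 600 dpi by default, assigns exactly
round(f · area) pad pixels to pink (patterns: independent uniform mix, a
reaction front advancing from the pad edge, or smoothed random blobs),
draws colours from narrow Gaussian clouds centred well inside the
classifier's intervals (pink hue 330° ± 6°, blue 225° ± 6°, saturation
0.5 ± 0.08 clipped to [0.2, 0.9], value 0.85 ± 0.04 clipped to
[0.5, 0.99]), then applies a ±10 % linear illumination ramp, Gaussian
sensor noise σ = 8/255, salt specks at density 10⁻³, and 8-bit
quantization — so the in-memory scan equals what a written PNG reads back
as. Everything is a pure function of the config including the seed.

Clipping saturation and value away from the whitish regime means
generator truth and classifier agree *by construction* on noise-free
pixels; recovery tests under noise then measure the pipeline's
degradation, not an arbitrary disagreement between two definitions of
"pink". The generator emulates colouring, patchiness, illumination and
sensor noise; it does **not** emulate perspective distortion, specular
highlights, partially detached pads, printed fiducials or the reaction's
time course. Passing its tests therefore demonstrates the pipeline's
internal correctness and noise robustness, not performance on arbitrary
phone photographs — flatbed scans are assumed.

## Synthetic cohorts

`synth.generate_cohort` draws one latent severity z per subject (standard
normal within group; the disease group's mean is shifted by
`latent_effect`, default 1.5) and builds each measure as an affine
transform of loading · z + ε, ε ~ N(0, noise_sd²) with loading 0.8 and
noise_sd 0.6 by default. The affine anchors place control/disease medians
at clinically plausible values (e.g. peroneal conduction velocity
~44 vs ~39 m/s) — scenery for realistic-looking tables, with no claim of
distributional fidelity. The default group sizes are 64 controls and 46
disease subjects, a realistic screening-study split. The indicator
percentage is clamped to [0, 100] after noise, leaving mass at the floor
and ceiling as real bounded read-outs show. The unit-variance
`latent_severity` column makes the binormal identity testable: its
empirical AUC converges to Φ(d/√2).

`generate_paired_scores` is the standard correlated-ROC fixture:
within-class bivariate normal scores with unit variances, correlation ρ,
and positive-class means √2·Φ⁻¹(AUC) per score.

## Statistics

**ROC/AUC.** The empirical curve is swept over all distinct score values;
the AUC is computed both as the trapezoid over the curve and as the
tie-corrected Mann–Whitney statistic (ties one half) and the two are
required to agree to 10⁻¹² — an internal cross-check that pins the tie
convention. The AUC standard error is the Hanley–McNeil formula. Scores
where *low* means diseased (the indicator percentage) are negated
internally; reported cut-offs are always in native units.

**Correlated AUCs.** Two methods. DeLong (default): covariance of the two
AUCs from placement values, z = (A₁−A₂)/√(SE₁²+SE₂²−2·cov), two-sided
normal p. Hanley–McNeil: the between-AUC correlation r is needed from the
average within-class Pearson correlation of the two scores; the classical
presentation tabulates r(ρ̄, Ā) on a coarse grid, and `hm_intermediate_r`
instead evaluates that same quantity exactly under the binormal model —
Cov(Â₁, Â₂) decomposes over shared-subject pair terms, each a bivariate
normal orthant probability Φ₂(Φ⁻¹(A₁), Φ⁻¹(A₂); ρ, ρ/2, ρ/2 for the
shared-pair, shared-positive and shared-negative terms) — avoiding the
interpolation choices a printed table would force. The two methods agree
to well within an order of magnitude across the tested AUC × ρ grid, and
the DeLong test's type-I error is verified at 4–6 % under a null
simulation.

**Youden cut-off.** Maximizes sensitivity + specificity − 1 over realized
thresholds; ties broken toward higher sensitivity (the screening
priority), then toward the higher native threshold.

**Boundary conventions.** Every diagnostic threshold is strict ("< 42",
"> 2"); values exactly at a threshold are normal. The case rule requires
*both* abnormal conduction (PMNCV < 42 m/s) and clinical signs (NDS > 2).
Missing data are handled complete-case per reference test with logged
counts; no imputation. Percentiles use linear interpolation between order
statistics.

**Categorical ROC.** The 3-level output is an ordinal score
(abnormal 0 < intermediate 1 < normal 2), giving a 2-point ROC whose AUC
is the tie-corrected rank statistic like any other score. A cohort whose
categorical output is constant is reported with a flag rather than an
error or a fabricated AUC.

**Repeatability.** Two definitions circulate: a Bland–Altman coefficient
(1.96 · SD of paired differences — 0 for a deterministic algorithm) and
correlation-type agreement (1 for identical runs). `repeatability`
reports both: the ICC(2,1) (two-way random effects, absolute agreement,
single measurement; cross-checked against an independent ANOVA-based
implementation) as the primary coefficient, with the Bland–Altman
coefficient as a secondary field. All-constant input is a 0/0 degenerate
case returned as ICC 1 with a `zero_variance` flag.

## Problem sizes in the validation suite

Unit tests run pads at 300 dpi (the pipeline is resolution-independent by
construction; this is verified by a 2× downsampling equivariance test).
The end-to-end suite uses the full 600 dpi protocol: 30-pad double
quantification for reproducibility, 11 fractions × 5 seeds for recovery
and segmentation fidelity (55 scenes), 1 000 fuzzed instances for the
AUC identity, 2 000 null replicates at 100/100 subjects for test
calibration, a 10 000-swap permutation oracle, 5 000/group cohorts for
the binormal closed form, and 500 replicate cohorts for the
discretization-loss property.

## Known limitations

- Hue intervals and generator colour clouds are self-consistent
  assumptions, not calibrated to scanned reference pads.
- The saturation-channel segmentation assumes a light, unsaturated
  scanner bed; use the luminance channel for dark beds.
- A completely unreacted *white* pad (neither pink nor blue) would fail
  the contrast guard by design; the pipeline expects the indicator's blue
  or pink colouring to be present.
- The cohort simulator's single-factor structure cannot represent
  measures that dissociate from overall severity (e.g. selectively
  autonomic damage); it is a test harness, not a disease model.
- No modelling of reaction kinetics; the input is one post-removal scan.
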