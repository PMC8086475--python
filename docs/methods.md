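# Methods

This note documents the models, numerical choices and limitations behind
`fastraman`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## The digital tissue phantom

A phantom emulates one excised Mohs layer pressed against the cassette
window, as a pair of co-registered rasters plus an on-demand spectrum
generator.

**Label map.** Pixel pitch defaults to 25 µm/pixel (configurable), so a
maximal 2 × 2 cm layer is an 800 × 800 image and the 6 × 6 mm layers used
throughout the tests are 240 × 240. Layers larger than 20 mm on a side are
rejected (cassette limit). The background is a single tissue class
(dermis by default); planted regions are discs or rectangles of any of
the eleven classes (dermis, epidermis, inflamed dermis, fat, muscle, hair
follicle, BCC, blood, surgical ink, substrate, out-of-contact). Regions
must fit inside the layer and may not overlap — both are hard errors, not
silent clips, so a phantom spec always means what it says.

**AF image.** Each class has a fixed mean fluorescence (16-bit counts)
with additive Gaussian pixel noise (sd 700). Dermis is deliberately the
brightest class (40 000 counts vs ≤ 21 000 for every other tissue class
and 600 for bare substrate), encoding the physical premise that
collagen-rich dermis dominates the 405 nm auto-fluorescence. The ordering
is asserted as an invariant.

**Spectra.** The spectral library lives on a fixed 800–1800 cm⁻¹ grid
(501 channels). Each class is a sum of 1–7 Gaussian bands whose positions
echo common skin Raman assignments (collagen 855/938, phenylalanine 1002,
CH₂ ~1440–1450, amide I ~1660, ester carbonyl 1745 for fat, haem
1548/1621 for blood, carbon D/G bands for ink); no biochemical accuracy
is claimed — the bands exist to give classes distinct, reproducible
signatures with realistic sparsity. Templates are peak-normalised. A
`contrast` knob linearly mixes each template with the class mean, so
separability can be lowered for stress tests; 1.0 (identity) is the
default. A measured spectrum is

    template(class at nearest pixel) + quadratic random baseline
        + N(0, σ₀² · (2 s / exposure)),

with σ₀ = 0.02 at the 2 s reference exposure — the shot-noise-like
σ ∝ 1/√t law, chosen because it makes exposure degradation exact to
simulate (below). The baseline (random quadratic, amplitude ~0.05–0.5 of
the peak) is exactly removable by the cubic baseline fit, which keeps the
preprocessing contract testable while still penalising unpreprocessed
use. Out-of-contact positions carry a zero template, so their SNR is ~3,
safely below the contact threshold of 7 (pure-noise SNR over 1000 draws
never exceeded ~4.7). Stage coordinates are continuous micrometres with
the origin at the top-left pixel centre; class lookup is nearest-pixel.

At these settings a linear SVM reaches 100% 5-fold CV accuracy with 200
spectra/class; the acceptance property (sensitivity and specificity
≥ 90%) therefore holds with a wide margin. This is the central limitation
to keep in mind: the phantom's classes are *more* separable than real
fresh-tissue spectra (the in-vivo analogue reports ~82%/~97%), so passing
tests demonstrate the correctness of the decision logic, scheduling and
accounting — not clinical performance.

## Segmentation

Tissue detection uses Otsu's threshold on the full image, clamped from
above by an absolute background ceiling (4% of full scale). The clamp
handles the two regimes where plain Otsu misbehaves: a full-footprint
image (no substrate mode — Otsu would split inside the tissue) and an
empty cassette (Otsu splits noise; detected when even the upper Otsu
class sits below the ceiling, raising `EmptyCassetteError`). Only the
largest 8-connected component is kept.

Dermis screening is per image: Otsu's threshold on the tissue pixels when
its normalised between-class variance indicates genuine bimodality
(≥ 0.80; a unimodal Gaussian peaks at ~0.64), else a relative fallback of
0.7 × median tissue AF. The fallback covers homogeneous layers (all
dermis) and layers whose only non-dermis content is too small to move the
histogram (a single 100 µm disc, ~13 px). It assumes the dominant tissue
mode is dermis — a layer consisting mostly of a darker class with no AF
contrast would be screened entirely; such layers simply proceed to a
clear verdict without Raman sampling, which is documented behaviour, not
an error.

Candidate segments: the AF image is smoothed (Gaussian, σ = 1.5 px), the
non-dermis tissue intensities are quantised into 4 equal-frequency bands,
and 8-connected components within each band become provisional segments.
Two deterministic merges follow: components below 10 px are absorbed by
the adjacent segment with the closest mean AF, and adjacent segments
whose raw mean AF differs by < 1500 counts are joined (smallest
difference first, ties toward lower ids). The second merge is what lets a
homogeneous region whose noise straddles a quantile cut remain a single
segment — without it, equal-frequency banding shatters uniform regions
into interleaved fragments. The class-mean spacing (≥ 2000 counts between
adjacent tissue classes) keeps genuinely different neighbours separate.
The partition invariant — every tissue pixel is dermis or belongs to
exactly one segment — is asserted in tests.

## Spectral model

Preprocessing: a 3rd-order polynomial baseline (least squares on a
normalised domain) is subtracted and the residual is scaled to unit
Euclidean norm. This is idempotent (the residual's polynomial projection
is zero) and invariant to added linear/quadratic/cubic baselines, both
asserted.

SNR is peak over noise: the peak of the baseline-corrected spectrum after
a 3-channel moving average (a band is always several channels wide, so
this suppresses single-channel noise excursions that would dominate the
max statistic), divided by a noise sd estimated from the Savitzky–Golay
(window 11, order 3) high-pass residual. The local cubic tracks baselines
and any smooth structure exactly but cannot follow the narrow Raman
bands, so band channels are masked (moving-average magnitude above 4× a
rough noise level or 5% of the structural peak) and the MAD of the
remaining residuals, corrected by the filter's residual-variance factor,
gives the sd. The estimator is unbiased to ~1–2% with ~7% CV at
operational noise levels and collapses to ~0 on noiseless spectra (SNR →
∞). Monte-Carlo calibration at a nominal peak/σ of 7 gives a median SNR
of ~6.4 with draws spanning roughly 4.8–9.0; the small downward bias is
the baseline projection removing part of the band peak. Contact flagging
at threshold 7 operates far from both operating points (in-contact
spectra score ~47 at 2 s, out-of-contact ~2.7).

Classification: `RamanClassifier`, a scikit-learn estimator wrapping
preprocessing plus an SVC. The linear kernel and C = 1 defaults were
chosen for determinism and speed; kernel and regularisation are exposed
as parameters. `predict_margin` returns the winning class's one-vs-rest
decision value as the model's confidence: because spectra are
unit-normalised, added noise dilutes the template component and this
score decreases monotonically with shorter exposures. (The top-minus-
second *gap* was rejected as a confidence: order-statistic spreading
inflates it under mild noise.) Five-fold CV is stratified and seeded;
confusion is aggregated over held-out folds and grouped as Healthy
(dermis, epidermis, inflamed dermis, fat, muscle, hair follicle),
Contaminants (ink, substrate), Blood, and BCC, with sensitivity and
specificity computed BCC-vs-rest. LOPO partitioning yields one
train/held-out split per patient; in cohort mode each patient's training
spectra carry a patient-specific gain jitter (lognormal, σ = 0.05) so the
LOPO protocol is exercised against real between-patient variation.

## Scheduling

Round 1 samples each segment at the pixel nearest its centroid (interior
by construction, so ring-shaped segments are handled). Round 2 allocates
up to 550 points proportionally to segment area by largest remainder
(ties to the larger area, then the earlier segment), at least one point
and at most one point per pixel per segment; within a segment, points
are spread evenly along the row-major pixel ordering, which realises the
allocated density without randomness. Round 3 centres a 4 × 4, 6 µm-step
raster on each selected segment's anchor — the centroid of its
BCC-classified points — snapped to the nearest segment pixel if it falls
outside (possible for non-convex segments); raster corners may extend up
to 9 µm beyond the segment, as the physical stage does. The 550-point cap
is read as the Round-2 budget with Round-1 points extra (the literal
reading of the protocol); Round-1 spectra do count toward segment BCC
fractions and blood/contact tallies, since they are measurements inside
the segment.

## Diagnosis

All thresholds are strict inequalities, matching the protocol's wording:
45% (9/20 negative, 10/20 positive), 75% (12/16 negative, 13/16
positive), 70% blood (7/10 not blood, 8/10 blood), SNR "below seven"
(a spectrum at exactly 7 counts as in contact). The "BCC probability
score" ranking Round-3 candidates is the Round-2 BCC fraction, with ties
broken by larger area then lower id. With fewer than three candidate
segments, the override rule's "all three" reads "all selected". Segments
flagged blood or not-in-contact are excluded from BCC scoring (their
spectra are uninformative) but still counted in the coverage
percentages, where a doubly flagged segment counts once, toward blood.
Coverage percentages are exact pixel-count ratios against total tissue
pixels and sum to 100 before any display rounding. Round-3 raster spectra
affect only their own segment's 75% rule; Round-2 fractions are not
recomputed.

## Time-reduction simulation

`degrade` adds zero-mean Gaussian noise of sd σ̂·√(t₀/t₁ − 1) to a
spectrum recorded at t₀, where σ̂ is the recording's own estimated noise
sd; under the phantom's 1/√t noise model the degraded spectrum then has
exactly the noise statistics of a genuine t₁ acquisition (verified by a
variance-addition oracle to within ±10% over 1000 draws). t₁ = t₀ is an
exact no-op, and t₁ > t₀ is an error. `rerun_with_config` re-executes the
*entire* decision pipeline on degraded spectra — including adipose
screening and Round-3 segment selection, which may therefore move.
Measurements are keyed by stage position (CRC-derived sub-seeds), so a
re-run that revisits a position sees the identical 2 s recording; the
identity configuration is consequently bit-identical to the original
report, asserted as such. On 20 phantom layers all reduced configurations
(26/21/20 min) were fully concordant with the 30-minute analysis — at the
phantom's separability the decision margins are wide; the concordance
machinery, not the 100% value, is the deliverable.

## Problem sizes and defaults

Tests and the acceptance script use 6 × 6 mm layers (240 × 240 px), a
spectral model trained on 200 spectra/class (60/class per patient in
cohort mode), 20 + 20 layers for verdict recovery and 20 layers for the
time-reduction comparison. These sizes give stable statistics at desk
scale; all are parameters, and a full 2 × 2 cm layer runs through the
same code path.

## Known limitations

- Template separability, fixed band shapes and Gaussian noise make the
  classification task easier than fresh-tissue reality; confusion between
  BCC and confounders (hair follicle, inflamed dermis) is far rarer than
  in vivo.
- The 2-D phantom ignores sampling depth, focus and tissue deformation;
  out-of-contact regions are a label, not a physical model.
- The dermis screen's relative fallback assumes dermis-dominated layers.
- Blood/ink absorption of the excitation light is modelled only as low AF
  intensity, not as altered Raman band shapes beyond the class template.
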