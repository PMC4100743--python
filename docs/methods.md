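# Methods

## Model

A face image is treated as a grid of local regions, each of which is either
usable biometric surface or an accessory artifact. The pipeline makes that
latent usability explicit (a binary flag per patch, predicted by a
classifier) and conditions the matcher on it: only patches that *both*
images of a pair flag as biometric contribute to the pair distance. The
working hypothesis is that accessory-covered patches are at best
uninformative and at worst adversarial — identical accessories on different
people shrink inter-class distances, and accessory changes on one person
inflate intra-class distances — so excluding them should improve
verification exactly when disguise is present.

## Geometry and normalization

The canonical face is 130×150 px (width×height), a 5×5 grid of 26×30-px
patches; the size is back-computed from the patch geometry so the grid tiles
the face exactly. Coordinates are 0-based, row-major, rows top→bottom.
Alignment is a two-point similarity transform mapping supplied eye centers
to canonical positions (30%/70% of width, 35% of height), bilinear sampling,
out-of-frame filled with 0. This is a deliberately simple stand-in for
heavier enrollment preprocessing stacks: the matching logic only needs a
consistent geometry, and a two-point alignment is exactly reproducible. An
inscribed-ellipse mask is available as a stimulus utility but is off by
default in the matching pipeline, since cropping decisions are orthogonal to
the patch-masking question studied here.

## Descriptors

The texture channel is the basic 8-neighbor LBP: each interior pixel is
coded by thresholding its 3×3 neighborhood against the center, neighbor ≥
center ⇒ bit 1, bits ordered clockwise from the top-left with the
most-significant bit first. The ≥ convention makes the operator total (a
constant image codes 255 everywhere) and deterministic on ties. Codes are
computed once on the whole face and histogrammed per patch, which avoids
manufacturing artificial texture at patch borders; a per-patch mode exists
for sensitivity checks. Border pixels carry no code, so edge patches have
slightly smaller histogram totals — one reason all histograms are
L1-normalized before use.

The patch descriptor concatenates the 256-bin intensity histogram and the
256-bin LBP histogram (512 dimensions). Each block is L1-normalized before
concatenation — making descriptors invariant to patch pixel count and
keeping the two blocks on a common scale — and then min-max normalized per
dimension over the training set, clamped to [0,1] at application time
(constant dimensions map to 0). The intensity block targets dark uniform
occluders (sunglasses, scarves); the LBP block targets high-texture
occluders (wigs, beards); the concatenation should classify patches at least
as well as either block alone, and the test suite checks that AUC ordering.

## Patch classifier

An RBF-kernel SVM with hyperparameters from a seeded grid search (C ∈
2^-3…2^15, γ ∈ 2^-15…2^3, both stepping ×4) maximizing 5-fold
cross-validated accuracy. The non-biometric class is the positive class, so
the decision rule reads naturally: score s < τ ⇒ biometric, s ≥ τ ⇒
non-biometric (ties to non-biometric). Raw decision values are thresholded,
not margin distances — the threshold is recalibrated on validation scores
anyway, so the scale is immaterial.

τ defaults to the 95%-biometric-recall operating point (smallest τ at which
≥95% of validation biometric patches score below it) rather than the EER
point: wrongly discarding a biometric patch costs the matcher information,
while letting a non-biometric patch through merely dilutes one pair
distance, so the asymmetric operating point helps downstream recognition.
Both operating points are exposed; threshold search is a deterministic sweep
with smallest-τ tie-breaking. Optional inverse-frequency class weighting is
available (off by default) for strongly imbalanced annotation sets.

## Matching and evaluation

The pair mask is the logical AND of the two flag matrices. The pair distance
is the χ² distance, χ²(a,b) = Σ(a−b)²/(a+b+ε) with ε = 1e-10 guarding empty
bins, between per-patch L1-normalized LBP histograms, **averaged** over
masked-in patches. The mean (rather than the sum) keeps distances comparable
across pairs using different numbers of patches; a sum mode is provided for
sensitivity analysis. Pairs with no usable patch return +∞, are rejected at
every threshold, and are counted separately — the analogue of a
failure-to-enroll case.

ROC curves sweep the acceptance threshold (accept iff D ≤ θ, inclusive)
over every distinct finite distance; GAR at a requested FAR uses linear
interpolation between adjacent operating points, and EER is the midpoint of
FAR and FRR at the sweep point minimizing their gap. Verification rates
follow the standard bookkeeping: FAR = FA/(FA+GR), GAR = GA/(GA+FR),
accuracy = (GA+GR)/total, reported as percentages; reporting FAR points
default to 0.1%, 1% and 10%.

The region analysis applies only to the 5×5 grid: forehead = row 0, eyes =
row 1, nose = row 2, lips/chin = rows 3–4. A region is disguised iff
strictly more than half its patches are non-biometric (≥3 of 5 for single
rows, ≥6 of 10 for lips/chin), giving 16 possible combinations. A *pair's*
combination is the union of its two images' disguised regions — the reading
under which "pairs with disguise on X" counts a pair whenever either image
is disguised there; a per-image mode is selectable.

## Synthetic data

The generator emulates the structure of a disguise study: 75 subjects split
35 train / 40 test by a seeded shuffle, 6–10 images per subject with at
least 1 neutral and 5 disguised, 322 train and 359 test images by default
(per-subject counts are allocated deterministically inside [6,10] to meet
the split totals; with totals unset, counts are drawn uniformly). The
gallery/probe protocol takes, per test subject, one neutral anchor plus four
seeded-random images as gallery and leaves the rest as probes (200 gallery /
159 probe at the default composition); re-seeding yields independent
cross-validation trials.

A subject identity is a procedural texture: a smooth low-frequency field
(Gaussian-filtered noise, σ=18) plus a subject-specific mid-frequency
signature (σ=1.6), quantized to 8 bits. Per-image rendering applies a small
illumination gain/offset and additive sensor noise, so within-subject
variation is nonzero but much smaller than between-subject texture
differences. Accessories overwrite grid-row-aligned footprints — sunglasses
(eye row), scarf (lips+chin rows), wig/cap (forehead row), beard (chin row),
mask (nose+lips rows) — with either near-uniform dark fill (value ≈18, σ=4)
or uniform high-variance noise; footprints jitter by up to ±3 px so the
strictly-more-than-half annotation rule is exercised on partially covered
patches. Disguised images wear one accessory (two 30% of the time), giving
roughly a 3:1 biometric:non-biometric patch ratio.

What the generator does *not* emulate: real facial structure and
landmarks, pose/illumination/expression variation, aging, accessory
diversity within a kind, or annotation noise. Passing tests therefore show
that the pipeline's machinery is correct and that masking helps when
occluders have the assumed statistics — not that the method attains any
particular accuracy on real disguised faces, where biometric-patch
appearance is far less separable from accessories.

## Problem sizes and numerical choices

Classifier-in-the-loop experiments subsample the grid search to 3000
training patches and use a coarse 3×3 hyperparameter subgrid (the threshold
τ is then set on all training scores); at the synthetic data's separability
this loses nothing measurable and keeps full runs to minutes on one CPU.
Histogram comparisons guard zero denominators with ε = 1e-10; min-max
application clamps unseen values into [0,1]; threshold and ROC sweeps
enumerate candidate values deterministically so reruns are bit-identical.
All randomness flows from explicit seeds through named substreams; the
same seed reproduces datasets, splits, searches and scores exactly.

## Known limitations

- Procedural identities are easier to separate than real faces; absolute
  GAR/EER values on synthetic data are optimistic and only orderings
  between arms (masked vs unmasked, joint vs single-block descriptors) are
  meaningful.
- The eye-based alignment assumes eye coordinates are given; no detection
  is included, and alignment quality with inaccurate eye points is not
  modeled.
- Flag matrices are predicted per image independently; no spatial smoothing
  or accessory-shape prior is applied.
- The χ² matcher uses LBP histograms only; fusing intensity information or
  holistic features at match time is out of scope.
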