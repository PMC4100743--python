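# patchverify

Occlusion-aware patch-based face verification. Disguise accessories —
sunglasses, scarves, wigs, beards, caps, masks — corrupt exactly the local
image statistics that appearance-based face matchers rely on, and a matcher
that compares *every* part of two faces ends up matching accessories instead
of people. `patchverify` implements a two-stage defense for researchers
studying recognition under disguise/occlusion:

1. **Patch classification.** A face normalized to a canonical geometry
   (130×150 px) is tessellated into a 5×5 grid of 26×30 patches. Each patch
   `P_ij` is described by a 512-dimensional concatenation of its 256-bin
   intensity histogram and its 256-bin local binary pattern (LBP) histogram
   (both L1-normalized, then min-max scaled to [0,1] over the training set).
   An RBF-kernel SVM — hyperparameters chosen by seeded grid search with
   5-fold cross-validation — scores each patch; scores below a threshold τ
   label the patch *biometric* (usable facial surface), otherwise
   *non-biometric* (accessory-covered). The per-face labels form a flag
   matrix `F`.

2. **Masked matching.** For a gallery–probe pair, the pair mask
   `δ_ij = [F^g_ij = biometric] ∧ [F^p_ij = biometric]` keeps only patches
   both images agree on. The pair distance is

   D(g, p) = mean over {ij : δ_ij} of χ²(LBP_hist(P^g_ij), LBP_hist(P^p_ij)),

   with χ²(a,b) = Σ (a−b)²/(a+b+ε). A pair with no usable patch gets D = +∞
   and is rejected at every threshold.

Verification performance is reported as ROC curves (GAR vs FAR from a sweep
over all distances), GAR at 0.1/1/10% FAR, and EER; a disguised-region
analysis maps grid rows to forehead / eyes / nose / lips-chin regions and
tabulates error rates over the 16 possible disguised-region combinations.

Because realistic disguise databases are access-restricted, the package
includes a fully seeded synthetic generator (`patchverify.synthgen`):
procedural texture identities, grid-aligned accessory overlays with
per-pixel coverage maps, and ground-truth patch annotations following the
more-than-half-covered rule. Every experiment in the test suite and the
examples runs on this generator.

## Worked example

`python examples/03_verification_roc.py` trains the patch SVM on a 14-subject
synthetic dataset and compares three masking arms on its test split:

```
   predicted masks: GAR@0.1%FAR= 88.57%  GAR@1%FAR= 91.43%  GAR@10%FAR= 92.86%  EER= 7.14%  (zero-mask pairs: 13)
ground_truth masks: GAR@0.1%FAR= 92.86%  GAR@1%FAR= 97.14%  GAR@10%FAR= 97.14%  EER= 2.86%  (zero-mask pairs: 6)
         all masks: GAR@0.1%FAR=  8.57%  GAR@1%FAR=  8.57%  GAR@10%FAR= 12.86%  EER=42.98%  (zero-mask pairs: 0)
```

Reading: at a fixed 1% false-accept rate, masked matching accepts 91–97% of
genuine pairs while the plain all-patches LBP baseline accepts under 9% —
identical accessories on different subjects make unmasked impostor pairs
look alike, and accessories on the same subject make unmasked genuine pairs
look different. "Zero-mask pairs" counts pairs with no mutually biometric
patch; they are always rejected.

The other examples generate a dataset (`01`), inspect the patch classifier
(`02`), and produce the region-combination error table (`04`). The same
pipeline is scriptable from the shell:

```
patchverify synth --out ds --subjects 14 --train-subjects 7 --seed 7
patchverify train --dataset ds --model-out model.joblib --small-grid
patchverify flags --dataset ds --model model.joblib --out flags.csv
patchverify match --dataset ds --flags-csv flags.csv --out scores.csv
patchverify evaluate --scores scores.csv --out report.csv
```

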