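# nirclass

Swarm-optimized SVM classification of near-infrared (NIR) spectra.

Grading agricultural products — the motivating case is quality levels of
brewed tea — from NIR transmittance spectra is a small-sample, ordered
multiclass problem: a handful of labeled samples per grade, thousands of
correlated spectral channels, and adjacent grades that differ only
subtly.  `nirclass` implements the full chemometric pipeline for this
setting:

1. **Photometric conversion** — absorbance to fractional transmittance,
   T = 10^(−A), so saturated spectral regions (≈0 transmittance)
   stop dominating the analysis;
2. **Savitzky–Golay smoothing** (frame length 21, polynomial order 2);
3. **PCA** (mean-centering only) to k score dimensions;
4. **One-vs-rest soft-margin RBF-SVM** with kernel
   K(x, x′) = exp(−‖x−x′‖²/(2g²)): one binary classifier per class,
   prediction by the largest decision value;
5. **Hyperparameter tuning** of the pair (c, g) — penalty and kernel
   width — by particle swarm optimization (PSO) or by
   **comprehensive-learning PSO (CLPSO)**, in which each particle learns
   each search dimension from a possibly different particle's personal
   best (chosen via a rank-dependent learning probability
   Pc_i = a + b·(e^{10(i−1)/(pop−1)}−1)/(e^{10}−1)) under a linearly
   decreasing inertia weight ω: 0.9 → 0.4 — the mechanism that resists
   premature convergence of the basic swarm;
6. **Rotation evaluation** — stratified division into 4 groups of 30,
   each group tested once with the others as training data, PCA and
   tuning confined to the training partition of each fold — plus a
   PLS-DA (NIPALS PLS2, one-hot response, argmax decision) linear
   reference.

Because no public dataset exists for the reference application, the
package ships a first-class synthetic generator of tea-like graded
spectra (6 levels × 20 samples, 1,557 points, 10,000→4,000 cm⁻¹, opaque
below 7,500 cm⁻¹) used by the tests and the reproduction script; see
`docs/methods.md` for the generative model and its calibration.

## Worked example

```python
import numpy as np
from nirclass import (SynthConfig, generate_tea_spectra, absorbance_to_transmittance,
                      sg_smooth, SGConfig, pca_fit, make_rotation_folds,
                      run_rotation_evaluation, EvalConfig, SwarmConfig)

spectra = generate_tea_spectra(SynthConfig(seed=0))        # 120 x 1557, labels 1..6
smoothed = sg_smooth(absorbance_to_transmittance(spectra), SGConfig(frame_length=21))
pca = pca_fit(smoothed.values, 3)
print("explained variance (%):", np.round(100 * pca.explained_variance_ratio, 1))

plan = make_rotation_folds(spectra.labels, G=4, seed=0)    # 4 groups, 5 per class each
cfg = EvalConfig(swarm=SwarmConfig(pop=12, max_iter=12, seed=0), cv_folds=3)
for method in ("svm_fixed", "clpso_svm"):
    results = run_rotation_evaluation(spectra, method, 16, cfg, plan)
    print(f"{method}: mean test accuracy =",
          f"{np.mean([r.test_accuracy for r in results]):.4f}")
```

Output:

```
explained variance (%): [98.7  0.5  0.2]
svm_fixed: mean test accuracy = 0.8833
clpso_svm: mean test accuracy = 0.9917
```

The first principal component carries almost all the variance (a shared
"concentration" factor scaling every absorption band); the baseline SVM
with fixed c = 2, g = 1 classifies 88% of held-out samples correctly,
and letting CLPSO choose (c, g) inside each fold's training partition
raises that to 99% — one misclassified sample out of 120.  The per-fold
tuned pairs are reported on each fold result (`r.params`).

## Command line

```sh
nirclass simulate --out spectra.csv --seed 0         # synthetic spectra table
nirclass preprocess --in spectra.csv --out smooth.csv
nirclass evaluate --in spectra.csv --method clpso-svm --pcs 1..25 --seed 0
nirclass compare --in spectra.csv --pcs 4,8,16 --seed 0 --out-dir results
```

`compare` writes `comparison.csv` / `comparison.json` with one row per
method (fixed SVM, PLS-DA, PSO-SVM, CLPSO-SVM): best PC count, mean
train and test accuracy.  Runs are deterministic given `--seed`.

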