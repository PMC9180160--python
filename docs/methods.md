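# Methods

`nirclass` classifies near-infrared (NIR) spectra of graded samples — the
motivating application is quality levels of brewed tea measured in
transmittance mode over 10,000–4,000 cm⁻¹ — by a four-stage pipeline:
photometric conversion, Savitzky–Golay smoothing, PCA feature extraction,
and a one-vs-rest soft-margin RBF-SVM whose two hyperparameters are tuned
by particle-swarm search.  This note records the models, the defaults and
why, the numerical choices, and the known limitations.

## Photometric conversion

Raw spectra arrive as absorbance A(ν).  Regions of near-total absorption
(here, everything below ≈7,500 cm⁻¹, where the aqueous matrix absorbs
almost all light) carry no usable signal but dominate least-squares fits
in absorbance units.  Converting to fractional transmittance
T = 10^(−A) maps those regions to ≈0, so they contribute almost nothing
to downstream variance decompositions.  The inverse A = −log₁₀(T) floors
T at 1e−10 before the log (a warning counts floored points); above the
floor the round trip is an identity to 1e−12.

## Smoothing

A Savitzky–Golay filter with frame length 21 points and polynomial order
2 (order configurable; 2 is the common chemometrics default) removes
high-frequency instrument noise.  The filter is a moving least-squares
polynomial fit, so any signal that is locally a polynomial of degree ≤
order passes through unchanged — the property the unit tests pin down.
Edges are handled by evaluating the boundary polynomial fits
(same-length output); an "interior" mode trims the half-window instead.
Smoothed transmittance is clipped to [0, 1] to absorb filter overshoot at
band shoulders.

## PCA

Mean-centering only, no unit-variance scaling: all channels share one
physical unit and scaling would inflate the dead (saturated) channels.
Loadings are the top-k right singular vectors of the centered data
matrix; explained-variance ratios come from the squared singular values.
Each loading's largest-magnitude element is made positive so fitted
models are reproducible across runs and BLAS builds.  Inside the
evaluation protocol PCA is fitted on the training partition of each fold
only and both partitions are projected with it; a `global_pca` switch
exists for comparison but leaks test information by construction (a
dedicated canary test demonstrates the difference).

## One-vs-rest RBF-SVM

The kernel is K(x, x′) = exp(−‖x−x′‖²/(2g²)); the width g maps onto the
conventional parameterization as γ = 1/(2g²), and that mapping lives in a
single tested function.  For L classes, L binary soft-margin classifiers
are trained (class ℓ vs rest, targets ±1) with one shared (c, g) pair;
a sample is assigned the class with the largest signed decision value,
ties going to the lowest class index.  The binary quadratic programs are
solved by scikit-learn's SVC on a precomputed kernel matrix (solver
tolerance 1e−7, so decision values are reproducible to ≈1e−7 regardless
of sample order); the OVR assembly and decision rule are this package's
own, so the multiclass behaviour does not depend on any library's
built-in multiclass mode.  Class imbalance in each binary problem (20 vs
100 in the reference design) is left unweighted by default.

## Swarm optimizers

Both optimizers search the 2-D (c, g) box, by default
c, g ∈ [0.01, 100] traversed in log₁₀ coordinates — decades are the
natural scale for both parameters.  Velocities are clamped per dimension
to 0.2 × range and positions reflected at the bounds.  One seeded
generator drives every draw of a run.

**Basic PSO.**  V′ = V + c₁r₁(pbest − X) + c₂r₂(gbest − X), X′ = X + V′,
with fresh uniform r₁, r₂ per particle and c₁ = c₂ = 1.49445 (the same
constriction-derived value used for the CLPSO acceleration factor; no
inertia term by default, an optional linearly decreasing inertia can be
enabled).

**CLPSO.**  Each particle i learns each dimension d from the personal
best of an "exemplar" particle f_i(d): with probability Pc_i the exemplar
is the winner of a two-particle tournament on personal-best fitness,
otherwise the particle itself; if every dimension self-selects, one
random dimension is forced to another particle.  The learning
probability Pc_i = a + b·(e^{10(i−1)/(pop−1)} − 1)/(e^{10} − 1) rises
from a (first particle) to a + b (last), defaults a = 0, b = 0.5;
particle indices are fixed, not fitness-sorted.  Velocities use a
linearly decreasing inertia ω(k) = ω_max − (ω_max − ω_min)·k/max_iter
with ω_max = 0.9, ω_min = 0.4, and acceleration ca = 1.49445:
V′_d = ω·V_d + ca·r_d·(pbest_{f_i(d),d} − X_d).  Exemplars are
reassigned after 7 iterations without personal-best improvement (the
refresh gap conventional in the CLPSO literature).  Spreading the
learning targets across the swarm is what resists premature convergence;
the benchmark tests verify that at equal budget (pop 40 × 40 iterations)
CLPSO's median Rastrigin error is no worse than basic PSO's and that it
reaches a 2-D sphere optimum within 1e−2 in ≥95% of seeds.

Defaults pop = 40 and max_iter = 40 follow the reference tuning setup.
The update loop evaluates all particles after each step, so a run costs
pop × (max_iter + 1) fitness evaluations; the global-best trace is
non-decreasing by construction and returned for plotting.

**Tuning fitness.**  The tuned objective is the accuracy of the OVR-SVM
at the candidate (c, g).  Plain training accuracy saturates at 100% for
many parameter pairs and cannot rank them, so the default fitness is
stratified k-fold cross-validation accuracy *within the training
partition* (folds drawn once per tuning run, so fitness is a
deterministic function of position); a `"train"` switch reproduces the
plain training-accuracy objective.

## Evaluation protocol

120 labeled samples are split into 4 groups of 30 (stratified: 5 per
class per group — the only split that keeps all classes represented in
every group); each group serves once as the test set while the other
three train the model, and the reported test accuracy is the average of
the four rotations.  For the tuned methods the swarm is re-run inside
each fold's training partition (each fold may select different (c, g),
all four pairs are reported).  A sweep over the retained PC count
(default 1–25) records the best count per method, ties resolved toward
the smaller count.  PLS-DA — the parameter-free linear reference — is
fitted on the smoothed transmittance spectra directly, with the swept
count read as its number of latent variables, since projecting onto
PCA scores first would not change the linear span it fits in.

## PLS-DA

NIPALS PLS2 on a centered one-hot class matrix, no response scaling;
prediction is the argmax response column.  With orthogonal X-scores the
regression step coincides with least squares of the centered responses
on the scores, which the tests verify to 1e−8, alongside a cross-check
against an independent NIPALS implementation.

## Synthetic data generator

No public dataset exists for the reference application, so the generator
is a first-class module that emulates its structure: for each of 6
quality levels × 20 samples it builds an absorbance spectrum on a
descending 1,557-point grid from 10,000 to 4,000 cm⁻¹ as

* a gently tilted low baseline (0.05 absorbance units),
* four Gaussian absorption bands centred at 9,350 / 8,750 / 8,200 /
  7,750 cm⁻¹ (widths 260 / 200 / 170 / 130 cm⁻¹, base depths 0.25 /
  0.40 / 0.30 / 0.20 absorbance units) — all in the informative window,
* a sigmoid saturation ramp to absorbance 3 below 7,500 cm⁻¹
  (transmittance ≤ 0.1% there, reproducing the opaque aqueous region),
* and white measurement noise (sd 0.006 absorbance units per point).

Class identity enters as graded multiplicative band-depth offsets:
level ℓ scales band b by 1 + step_b·(ℓ−1) with steps
(0.12, 0.05, 0.02, 0.09).  Adjacent levels therefore differ least and
adjacent-level confusion is the typical error, as expected of ordered
quality grades.  Two correlated noise sources make the task realistically
hard: a per-sample "concentration" factor (sd 1.5%) scaling all bands
together — the dominant variance component, which is why PC1 carries
≈99% of the variance after preprocessing — and independent per-band
depth jitter (sd 1%).

These defaults were calibrated once so that the fixed-parameter baseline
(c = 2, g = 1, 16 PCs) lands in the 0.85–0.97 held-out accuracy band,
leaving measurable headroom for the tuned methods; the calibration was
not revisited afterwards.

**What passing tests do and do not show.**  The generator reproduces the
*structure* of graded NIR data (shared smooth curves, saturation,
ordered class effects, correlated sample-level variation) but not real
band assignments, instrument line shapes, scatter effects or
batch-to-batch drift.  Accuracy figures on synthetic panels demonstrate
that the pipeline recovers class structure of this kind and that swarm
tuning helps; they are not estimates of accuracy on real tea spectra.
One consequence is visible in the shipped comparison: because the six
synthetic class means lie almost on a single line in feature space,
linear one-hot regression (PLS-DA) suffers the classic class-masking
failure and scores near 50% on the default panel, whereas on the real
(richer-geometry) data of the motivating study PLS-DA was competitive.
With non-collinear class patterns (see the easy-mode test) all four
methods reach 100% here too.

## Problem sizes

Package defaults follow the reference setup (swarm 40 × 40, 5-fold CV
fitness, PC sweep 1–25).  The shipped acceptance tests and
`scripts/acceptance.py` run the synthetic-panel comparisons with a
reduced swarm (pop 12, 12 iterations, 3-fold CV fitness) and a PC grid
of {8, 16, 24}: at these sizes one tuned method costs ≈15 s per panel
seed on one CPU, which keeps the 10-seed panel and the script at desk
scale while leaving the tuning behaviour qualitatively unchanged (the
swarm still performs 156 fitness evaluations over a 2-D box).

## Degenerate inputs and tie-breaks

* Argmax ties (OVR decision, PLS-DA decision, best-PC selection) resolve
  to the lowest index / smallest count.
* All-identical spectra give a zero-variance PCA (ratios reported as 0).
* Non-finite swarm fitness values are scored −∞ and logged, never
  propagated.
* Transmittance zeros are floored at 1e−10 before logs.
* Rotation grouping with class counts not divisible by G spreads the
  remainders so group sizes differ by at most one per class.

## Known limitations

* Only RBF kernels and the (c, g) pair are searched; no feature/interval
  selection.
* The swarm fitness treats CV accuracy as deterministic given the fold
  draw; a different fold draw can select a different (c, g).
* PLS-DA inherits the masking weakness on ordered, nearly collinear
  class structures (see above) — a property of the model, not a bug.
* The generator's difficulty dial is calibrated for the default design
  (6 × 20 × 1557); heavily changed configurations may need recalibrated
  class-effect steps.
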