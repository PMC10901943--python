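# Methods

This note records the models, conventions and numerical choices behind
`stainshift`, and what the synthetic benchmark does and does not show.

## Optical density and stain separation

Pixels are converted to optical density with base-10 logs against a
per-channel background intensity `I0`: `od = log10(I0 / max(I, 1))`,
clamped at intensity 1 so saturated black pixels stay finite, and clipped
below at 0 so pixels brighter than the background carry zero density. The
default `I0 = (255, 255, 255)`; a flag estimates it per tile as the
95th-percentile channel intensity instead. The inverse transform rounds
`I0·10^(−od)` and clips to [0, 255]; the round trip is exact to within one
intensity level for nonzero pixels.

Stain estimation treats tissue pixels (max-channel OD > 0.15; at least 100
required, otherwise an "insufficient tissue" error) as nonnegative
two-atom codes: `od ≈ W c` with unit-norm nonnegative columns of `W` and an
L1 penalty (default 0.1) on `c`. The solver is alternating minimization:

* **Code step.** For two stains the per-pixel nonnegative lasso has only
  four active sets, so it is solved exactly and vectorized (enumerate the
  interior solution and the two single-stain solutions, pick the feasible
  one with the lowest objective). The same routine with penalty 0 is the
  per-pixel unmixing used everywhere else; it recovers constructed
  concentrations to machine precision.
* **Dictionary step.** Least squares for the atoms, projected onto the
  nonnegative orthant and renormalized to unit columns.
* **Initialization.** Data-driven, Macenko-style: project tissue OD onto
  its two leading principal directions and take the 1st/99th-percentile
  angular extremes of the pixel cloud as the starting rays. A fixed
  canonical H&E start point was tried first and can converge to a local
  minimum when the true stains are rotated away from it; the data-driven
  start does not have that failure mode. Degenerate clouds fall back to
  the canonical vectors.

Iteration stops when the matrix moves less than 1e-7 in max-norm or after
80 iterations; collapse of an atom or near-parallel columns (cosine >
0.999) raises a convergence error. Pixels are subsampled (seeded, cap
10 000) before fitting, which makes a profile fit take ~0.05 s on a 96 px
tile and keeps it deterministic. Column order is fixed by relative red+blue
absorption (hematoxylin-like first, blue breaking ties).

Normalization re-renders a tile's concentrations through a reference
profile after scaling each stain by the ratio of 99th-percentile
concentrations (a robust max; per-pixel histogram matching was deliberately
not used). Tiles without enough tissue either raise or, in batch contexts,
pass through unchanged with a warning so a cohort run never aborts on a
glass tile.

## Artifacts

Four families, each a deterministic, shape-preserving transform: Gaussian
blur (σ in px, reflective borders, kernel radius ⌈3σ⌉), JPEG re-encoding
(quality 1–100; chroma subsampling is disabled at quality ≥ 95 so quality
100 is near-lossless), additive brightness, and linear contrast pivoting at
mid-gray 128. Neutral strengths (σ=0, q=100, offset 0, factor 1) are
identities (JPEG within codec tolerance). JPEG distortion is additionally
summarized as PSNR, capped at 100 dB for lossless round trips. When an
artifact and stain normalization are both configured, the artifact is
applied after normalization.

## Cohorts and splitting

A cohort is a list of (tile, patient, binary label, institute/domain,
slide) records backed by a plain CSV manifest. Splitting is at the patient
level only — all tiles of a patient land in one split — with largest-
remainder apportionment of patients to the (0.6, 0.2, 0.2) fractions and
bounded re-draws (50) until every split's class balance is within 0.1 of
the cohort's; if no draw qualifies, the best-balanced one is returned with
a warning rather than failing, which keeps small synthetic cohorts usable.
Patients spanning two domains are an error, not a guess. Per-case sampling
takes up to n tiles per (slide, class) uniformly without replacement.

## NoisyEnsemble plans

One member plan = a patient subset (⌈0.8·n⌉ drawn without replacement by
default; classical bootstrap available) plus label flips. For each selected
patient one candidate class is drawn uniformly; candidate (patient, class)
groups are visited in random order and flipped whole, stopping at the group
boundary whose cumulative flipped fraction is closest to the 15 % target.
Groups are never split, so at most one class per patient is ever noised and
the realized rate (recorded in the plan) is within one group of the target
whenever reachable; a target farther than twice the group granularity from
anything attainable raises a planning error. Noise is accounted in tiles
(label instances), not patients. Zero noise reduces exactly to plain
bagging — byte-identical plan JSON at equal seed — so the bagging baseline
and the noisy arm differ only by the flips. Aggregation is the unweighted
probability mean with ties going to class 1; majority vote is available.

## Reference classifier

A deliberately small stand-in so protocols run in seconds, not a claim
about deep-model behavior: fixed features (8×8 mean-pooled RGB, 8-bin
channel histograms, mean/std of the grayscale gradient magnitude), feature
standardization, and an L2-regularized logistic decision rule trained by
AdaMax-type adaptive gradient steps (25 epochs, learning rate 0.001,
binary cross-entropy, minibatch 32, seeded shuffles). The pooled-pixel and
histogram features are color-sensitive — which is what makes the synthetic
transfer gap open — while the gradient features carry morphology. Anything
satisfying the fit/predict_proba contract can replace it; the conformance
checker verifies probability bounds, output length, predict-before-fit
behavior and determinism under seed.

## Synthetic two-institute benchmark

The generator enforces the separation that makes the experiments
interpretable: class → morphology only, domain → color only.

* Class 0: Poisson(0.0015/px²) nucleus disks of radius 3–6 px; class 1:
  Poisson(0.0045/px²) of radius 2–5 px. Disk absorption amplitudes are
  drawn per nucleus; a smooth Gaussian-filtered eosin texture (identical in
  law across classes) fills the stroma and is suppressed ×0.12 inside
  nuclei — chromatin displacing cytoplasm, which is also what gives the
  factorization near-pure pixels of each stain.
* Domain A renders through the canonical H&E stain matrix; domain B
  through the same matrix rotated 15° about the normal of the
  hematoxylin–eosin plane (clipped nonnegative, renormalized), plus
  brightness +10, contrast ×1.1, on a 245 background with pixel noise
  σ = 2 levels. These defaults were calibrated once so that the raw
  transfer gap is large and stain normalization can close most of it, and
  are pinned.
* Patients carry a lognormal morphology jitter (sd 0.1 on density, 0.05 on
  radius) and belong to exactly one domain; labels are balanced per
  patient; everything is deterministic under the seed tree.
* Tile size defaults to 96 px for speed (299 px, the common real-data tile
  size at 1 µm/px, is a parameter away). Default experiment cohorts use 20
  patients per domain and 3 tiles per patient per class; 80 tiles per class
  per case — the realistic sampling depth — is supported by
  `sample_tiles_per_case` but not used in the desk-scale defaults.

What passing on this benchmark shows: the pipeline mechanics (OD math,
factorization, planning, pairing) are correct, and the directional effects
— raw color shift breaks transfer, normalization repairs it with internal
accuracy essentially unchanged, artifacts degrade clean-trained models and
train-time injection buys the accuracy back, ensembles transfer at least
as well as their average member — reproduce. What it does not show:
magnitudes on real cohorts. Real H&E has texture, >2 dyes' worth of color
complexity, annotation noise and morphological domain effects the
generator deliberately omits, and the reference classifier is not a CNN.

## Experiment protocols and statistics

All protocols pair by seed: each seed fixes one patient split and one
training seed shared by every mode, so per-seed differences are paired and
an exact binomial sign test applies at small n (5 seeds by default).
Accuracy is tile-level. In the color-handling experiment, normalization is
applied to training and test tiles of both institutes (one deterministic
reference tile: the lexicographically first fit-able tile of the internal
cohort) while HSV jitter (hue ±0.1 of the circle, saturation/value factors
0.8–1.25) is applied to training tiles only, each tile contributing three
augmented copies since the reference classifier has no per-epoch
augmentation hook. Normalized cohorts are computed once — the transform is
deterministic and seed-independent — so paired seeds only re-split and
retrain. The artifact experiment trains, per strength, one clean and one
artifact-injected model and evaluates both on test tiles carrying that
strength, internally and externally; Δ is their signed difference. The
ensemble experiment runs single/bagging/noisy with the plan seed shared
between bagging and noisy (identical subsets, flips the only difference)
and is run on stain-normalized cohorts, where external accuracy is in a
responsive regime (on raw cohorts the synthetic color shift pins every
external accuracy to exactly 0.5 and all comparisons tie). The
ensemble-averaging comparison (ensemble vs the mean of its own members'
accuracies) holds with small margins on these conditions; the
noisy-vs-bagging external difference is reported directionally, as its
magnitude is data-dependent.

## Known limitations

* Two stains only; no learned (GAN-style) color transfer.
* The exact nonnegative-lasso code step is specific to two stains; a third
  stain would need a generic solver.
* The sign test at five seeds has little power; it is a directional check,
  not an effect-size estimate.
* Brightness/contrast are intensity-space distortions: after them, the
  nominal stain matrix is no longer the OD-space ground truth, so
  stain-vector "recovery" is only a well-posed oracle for pure
  stain-matrix renderings.
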