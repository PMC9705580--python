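# Methods

`ffrcta` implements a two-stage deep-learning pipeline that predicts the
functional significance of a coronary stenosis — invasively measured
fractional flow reserve (FFR) at or below 0.8 — from a coronary CT
angiography (CCTA) scan and a labeled coronary centerline tree. Because no
clinical dataset ships with the package, a synthetic phantom module
generates every input the pipeline needs, end to end, with known ground
truth. This note documents the models, the phantom's assumptions, the
numerical choices, and what the synthetic experiments do and do not show.

## Pipeline

### MPR reconstruction (`ffrcta.mpr`, `ffrcta.centerline`)

Each artery centerline is resampled to a uniform 0.5 mm arc-length spacing
(piecewise-linear parameterization; a tolerant floor keeps the slice count
stable when the total length sits within 1e-6 mm of a spacing multiple).
For every resampled point a 127 x 127 cross-section with 0.1 mm in-plane
pixel size is sampled perpendicular to the local tangent by trilinear
interpolation, producing a straightened multiplanar reformation (MPR) with
pixel (63, 63) on the centerline.

Choices the straightening leaves open and how they are fixed here:

* **In-plane orientation** — rotation-minimizing frames (double-reflection
  propagation of an arbitrary fixed ostial normal). Frenet frames would
  flip at inflection points and inject torsion into the 3-slice stacks fed
  to the characterization network.
* **Tangents** — central differences of the resampled points, one-sided at
  the ends; repeated points are rejected as degenerate.
* **Out-of-volume samples** — filled with air (-1024 HU) and counted; an
  artery with more than 5% filled samples is rejected, mirroring the
  requirement that analyzed arteries lie inside the field of view.

MPR intensities are z-normalized with a mean/sd pooled over all voxels of
the training MPRs; the statistics are persisted and reapplied unchanged at
test time.

### Artery characterization (`ffrcta.characterizer`, `ffrcta.treechar`)

A 2-D CNN maps a stack of three neighboring cross-sections (edge-replicated
at the artery ends) to three scalars for the central slice: lumen area
(mm^2), mean lumen attenuation (HU), and calcium area (mm^2). The trunk is
four blocks of two 3x3 convolutions (16 filters, batch normalization,
ReLU), each block followed by 2x2 max pooling (127 -> 63 -> 31 -> 15 -> 7);
each head is a global average pool plus one linear unit. Max pooling and
the minimal head are our choices where the block structure is the only
constraint; a single linear unit per head keeps the parameter count
(~17 k) small against overfitting.

Training minimizes `MAE(lumen) + 0.1 * MAE(attenuation) + MAE(calcium)`
with AdamW. Targets are z-normalized over the training slices (statistics
stored in the checkpoint, outputs de-normalized at inference); this is what
puts the 0.1-weighted attenuation term on the same scale as the area
terms. Reference targets come from segmentation masks: per-slice pixel
counts times 0.01 mm^2 for the areas, and the mean image HU over the lumen
mask for attenuation, with a NaN sentinel for empty-lumen slices that
becomes 0 after normalization.

Two per-slice indicators are read from the centerline tree: bifurcation
(nearest tree node within 1.0 mm has >= 2 children) and main-branch
membership (node label in LM/LAD/LCX/RCA). Both are binary, flagged only at
the mapped node's slices; trifurcations count as bifurcations. All five
characteristics are z-normalized with statistics pooled over the training
arteries.

### Stenosis assessment (`ffrcta.stenosis`)

A 1-D network consumes the five characteristic series of one artery per
forward pass (variable length S >= 4):

1. Lumen area and attenuation enter as fractional slice-to-slice
   differences `d[i] = (x[i] - x[i-1]) / (|x[i-1]| + 1e-6)` (`d[0] = 0`),
   computed on the raw positive-valued series — the transform is
   scale-free, so z-normalization is unnecessary there — and pass through
   separate two-layer convolutional pre-encoders (16 filters, LeakyReLU in
   between).
2. The pre-encodings are concatenated with the normalized calcium,
   bifurcation and main-branch series (16+16+3 = 35 channels), average
   pooled (kernel 4), and passed through two convolutions with dilations 1
   and 2, each followed by LeakyReLU, instance normalization (per channel
   over the sequence) and dropout 0.5.
3. The encoding is concatenated with pooled copies (average pooling,
   kernel 4) of the normalized lumen-area and attenuation series and fed to
   one transformer encoder layer. The concatenation has 16 + 2 = 18
   channels, so the transformer width is 18 with 2 heads; no positional
   encoding is used — the layer exists for its global receptive field, and
   the sum-pooling heads downstream are order-aware through their binning.
4. **Regression head**: two conv + LeakyReLU + instance-norm + dropout
   stages, then a single-channel convolution with ReLU produces
   non-negative per-position pressure drops. Drops distal to the
   measurement location are masked, the rest are summed, and
   `FFR = 1 - sum` — the additivity of sequential flow resistances is built
   into the architecture, and `FFR <= 1` holds for arbitrary weights.
5. **Classification head**: adaptive sum pooling into 5 contiguous
   near-equal bins (remainder assigned proximally; empty distal bins sum to
   0 for very short arteries), two dense(16) + LeakyReLU + dropout stages,
   and a sigmoid unit for the probability of functional significance. It
   consumes the full post-transformer feature map, bypass channels
   included.

All convolutions use kernel 3 with zero padding; all dropout probabilities
are 0.5. The final drop-producing convolution is initialized near zero so
training starts from the healthy prior (FFR ~ 1) instead of a huge random
drop sum whose MSE gradient would dominate early updates.

The measurement mask covers slices up to 10 mm (20 slices) distal to the
annotated lesion, or — without a lesion — up to the most distal slice with
lumen area > 2 mm^2 (whole artery, with a warning, if none qualifies). A
pooled position is unmasked iff any of its 4 source slices is unmasked
(conservative inclusion of the measurement location).

Training: per-artery loss `MSE(FFR) + BCE(probability)` with equal
weights, gradients accumulated over 8 arteries per AdamW update (effective
batch 8), triangular cyclic learning rate from 5e-4 down to 1e-5 and back
over a 40-epoch period, 150 epochs by default. The BCE is unweighted
despite the 0.42 prevalence.

### Merging, ensembling, uncertainty (`ffrcta.ensemble`)

Regressed FFR values are mapped to pseudo-probabilities by linearly scaling
a symmetric window around the threshold: `p = 0.5 - (FFR - 0.8)/0.4` on
[0.6, 1.0] and `p = 1` on [0, 0.6); the transformation is continuous,
monotone non-increasing, and dichotomizing p at 0.5 is equivalent to
dichotomizing FFR at 0.8. The pseudo-probability is averaged with the
classification probability. Member merging happens before ensemble
averaging; with arithmetic means the two orders coincide (asserted by
test).

k-fold (default 10) cross-validation splits patients, not arteries, into
random folds; each member trains on k-1 folds. At test time member merged
probabilities and FFR values are averaged; the prediction uncertainty is
the *population* standard deviation across members (the ensemble is fixed;
no sampling correction is implied). The referral simulation ranks cases by
merged-probability sd by default, with FFR sd as an alternative.

### Evaluation (`ffrcta.evaluation`)

AUC follows the Mann-Whitney construction (ties count 1/2; computed via
scikit-learn and cross-checked against an exhaustive pairwise oracle in the
tests). Accuracy/sensitivity/specificity use an operating threshold of 0.5
on probabilities — the merged output is calibrated around 0.5 by the
pseudo-probability's design — and FFR-mode dichotomization is positive iff
value <= 0.8. Patient-level scores take the maximum over the patient's
arteries; a patient is reference-positive iff any artery has FFR <= 0.8.
The paired AUC permutation test swaps the two models' scores per case with
probability 1/2 (1 000 iterations by default) and applies add-one
smoothing, `p = (count + 1) / (n_iter + 1)`, so p is never 0. The referral
simulation removes or corrects the ceil(fraction * n) highest-uncertainty
cases, breaking ties by case index for determinism.

## Synthetic phantoms (`ffrcta.phantom`, `ffrcta.hemodynamics`, `ffrcta.cohort`)

No generative model of clinical CCTA exists in the sources this package is
built from; every phantom distribution below is an artifact choice, made
once and documented here.

**Geometry.** An artery is a tube of baseline radius r0 (default 1.0 mm ~
3.14 mm^2) following a smooth curve: a straight path with a cubic-spline
in-plane perturbation (control points every ~8 mm, sd 1 mm, clipped at
2.5 mm) bounded so the tube never self-intersects and the
rotation-minimizing frames stay well-defined. A stenosis is a
cosine-squared area reduction `reduction(s) = sev * cos^2(pi (s-c)/L)` over
length L; `r(s) = r0 * sqrt(1 - reduction(s))`. Stenoses overlapping the
artery ends are rejected. Optional side branches (radius 0.6 r0) attach
partway along the main artery and are labeled `side-branch` in the tree.

**Intensities.** Lumen 400 HU, soft-tissue background 50 HU, calcified
plaque 800 HU, Gaussian noise sd 20 HU — inside typical contrast-enhanced
acquisition ranges. Voxels default to 0.3 mm isotropic. The tube-edge HU
ramps linearly over one voxel (partial-volume emulation), and the tube
center is deliberately offset from the voxel lattice by a fixed sub-voxel
amount: real arteries are never grid-aligned, and exact alignment is the
worst case for mask-derived areas. Calcium occupies an 0.8 mm-thick annular
arc *adjacent to* (never inside) the lumen, so lumen and calcium areas are
separable regression targets. Masks are voxel-exact binary indicators.

**Ground truth** is computed analytically from r(s) and the calcium
geometry, indexed by arc length so it aligns slice-for-slice with the MPR.

**Toy FFR model.** The ground-truth label generator is a serial-resistance
model: `dP = Q * sum_i c*l/A_i^2 + k * Q^2 * max(0, 1/A_min - 1/A_ref)^2`,
`FFR = (P_a - dP)/P_a` clipped to (0, 1], with P_a = 100 mmHg, Q = 1,
A_ref = 3.5 mm^2 and c = 0.5. The separation coefficient k is fixed by
root-finding on a single calibration anchor — a 70%-area, 10 mm stenosis in
a 3 mm^2, 40 mm artery must give FFR = 0.70 — with the unobstructed anchor
artery at FFR ~ 0.977 (>= 0.97). The separation term deliberately uses the
single most severe narrowing against a *fixed* reference area rather than a
per-lesion decomposition: region-based decompositions are not monotone
under pointwise area reduction (merging two lesion regions can shrink the
summed term), whereas this form makes FFR provably non-increasing when any
part of the lumen narrows. Serial lesions still accumulate through the
viscous sum.

**Cohorts.** Each patient carries 1-3 main arteries (lengths 35-50 mm,
baseline radii 0.85-1.25 mm). Stenosis severities are rejection-sampled so
that a requested fraction of arteries (default 0.42, the development-set
prevalence) has FFR <= 0.8, with positives kept above FFR 0.25 so the FFR
distribution sits around the threshold (an intermediate-stenosis
population; realized mean ~ 0.82). Measured profiles add characterization
noise: 5% relative on lumen area, 10 HU on attenuation, 0.05 mm^2 on
calcium area. The lesion location is the area minimum; the measurement
location is 10 mm distal to it (clipped), or the most distal slice with
area > 2 mm^2 for unobstructed arteries.

**What the phantoms do not emulate** — and hence what passing tests do not
show about clinical data: cardiac background anatomy, motion and
step-and-shoot artifacts, contrast-bolus dynamics, non-calcified plaque,
and any hemodynamic signal in the attenuation series (phantom lumen HU is
constant along the artery, so the transluminal attenuation gradient carries
no information here; in real CCTA it does). Phantom FFR is, by
construction, a deterministic function of the lumen-area profile, which is
why the synthetic discrimination task is much easier than the clinical one
and why the lumen-ablation experiment must degrade performance.

## Desk-scale experiment sizes

The two study harnesses in `ffrcta.experiments` default to problem sizes
chosen to run in minutes on a single CPU core with the pure-numpy layer
library (`ffrcta.nn`, hand-written forward/backward passes validated by
central-difference gradient checks):

* **Parameter recovery** — 80 patients (~160 phantom arteries; 12 patients
  held out), 14 training slices sampled per artery, 450 AdamW steps at
  batch 8, learning rate 3e-4 (the 800-epoch / batch-512 / 1e-5 defaults
  remain available in `CharacterizerConfig` for full-scale runs). Passing
  bar: held-out lumen-area relative MAE < 15%.
* **Cohort discrimination** — 60 patients (~125 arteries, prevalence 0.42),
  12 test patients, 10-fold patient-disjoint ensemble, 45 epochs with the
  cyclic schedule between 2e-3 and 1e-5 over 20 epochs (a faster-converging
  desk-scale variant of the default 150-epoch / 5e-4 schedule), averaged
  over 3 seeds. Passing bar: held-out merged-probability AUC >= 0.85 and a
  strictly lower AUC when the lumen-area input is zeroed at train and test
  time.

## Numerical notes and limitations

* Network arithmetic is float32; gradient checks run the same code in
  float64. Convolutions are GEMM-based (2-D) or tap-loop (1-D); max pooling
  truncates odd trailing rows (127 -> 63), average pooling drops remainder
  slices, and the pooled measurement mask inherits the same floor rule.
* AdamW uses decoupled weight decay 1e-4, betas (0.9, 0.999), eps 1e-8.
* Dropout layers draw from a model-owned seeded generator; training is
  bit-reproducible for a fixed seed on fixed hardware, and inference is
  deterministic (dropout off, no batch statistics in the 1-D path).
* Instance normalization couples all sequence positions, so the
  finite-receptive-field locality of the convolutional path holds exactly
  only with the normalization (and transformer) ablated; the corresponding
  test does exactly that.
* The characterization network is trained here against analytic phantom
  ground truth rather than mask-derived references; on phantoms the two
  agree to ~3% (discretization), which is below the 15% recovery bar.
* `pct_difference` is fractional (not x100) with an epsilon guard; its
  scale is absorbed by the pre-encoders.
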