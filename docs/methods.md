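# Methods

`encodeaudit` audits whether a disease-detection model *encodes* protected
characteristics (race-like group, biological sex) in its learned feature
representation, and whether it *uses* them for its predictions.  The two
questions are deliberately separated: a linear probe can read an attribute
out of the penultimate layer whenever the attribute is encoded there, but
encoding alone does not imply that the prediction layer weights that
information into the disease score.  The package combines four evidence
streams on one cohort so the distinction becomes observable.

## Model anatomy

A classifier is decomposed into a **backbone** (all layers up to and
including the penultimate layer, producing a d-dimensional representation)
and one or more linear **prediction heads**.  The disease head emits one
pre-sigmoid logit per condition (14 binary labels, multi-label binary
cross-entropy).  A multitask model adds sex (2-way softmax) and group (3-way
softmax) heads to the same penultimate layer, trained with an equal-weight
sum of the three losses.

Three task inter-relationship regimes organize the interpretation:

* **Scenario A** — tasks use disjoint features: a probe for the secondary
  attribute on the primary task's representation performs at chance.
* **Scenario B** — tasks share features but their optimal decision
  boundaries are orthogonal: the probe is perfect, yet the attribute is
  irrelevant to the primary output.
* **Scenario C** — tasks are coupled at the output level: the probe is
  positive *and* the attribute separates the primary task's logits, and
  subgroup operating-point disparities survive composition correction.

The 2-D scenario toys realize these regimes quantitatively.  A deliberate
geometry choice: in scenario C the stated ideal is a single shared boundary
direction for both labels, but that makes the label-disagreeing points
exactly non-separable at zero noise.  We therefore give the secondary label
a small orthogonal offset (0.2 by default) so both labels remain exactly
separable at zero noise while the label correlation stays above 0.9 and one
direction dominates both boundaries.

For the toys, the primary-task "feature map" is obtained by relevance
pruning: an L1-regularized logistic fit for the primary task keeps the
coordinates whose coefficient magnitude exceeds 10% of the largest.  This
reproduces, from training alone, the single-coordinate representation of
scenario A and the full two-coordinate representation of scenario B.

## Synthetic cohorts

The generator emulates the statistical skeleton of a large public chest
X-ray population without emulating its appearance: three unbalanced groups
(defaults 78/15/7%), group-dependent sex ratios (female fractions
0.40/0.43/0.49), group-dependent ages (Gaussian means 64/61/56 years,
sd 17, truncated to [18, 95]), and two mutually exclusive focal labels —
`no_finding` (a rule-out label, prevalences 0.08/0.09/0.10 per group) and
`condition_x` (a pathology label, 0.41/0.42/0.33) — plus 12 independent
filler labels (prevalence 0.10 each).  Mutual exclusivity holds by
construction (one categorical draw per sample).

Latent features are a sum of orthonormal factor directions (QR of a
Gaussian matrix): disease (+1 for `condition_x`, −1 for `no_finding`,
strength 1.5), sex (±1, strength 1.0), standardized age (strength 0.5), a
2-D simplex embedding of group (strength 1.0), one direction per filler
label (strength 0.5), and unit isotropic noise.  The `encoding` switch
controls group information: `none` omits it, `orthogonal` keeps it
orthogonal to the disease direction, and `entangled` rotates the group axis
toward the disease axis (cosine 0.8 by default).  Age–disease coupling is a
free parameter with no reported value to anchor it; the default shifts a
sample's age by ±4 years with disease status, enough that age visibly
organizes the feature space (as it does in real cohorts) without dominating
it.

With these defaults a single-task MLP reaches test AUC ≈ 0.86–0.91 for the
focal labels — the range typical of deep classifiers on large chest X-ray
cohorts — so the audit operates at realistic discrimination levels.

An optional deterministic renderer maps factors to small grayscale images
(disease → central blob, group → border sinusoid frequency, sex → corner
bar orientation, age → global brightness) so convolutional backbones can be
exercised end to end.  The images make no attempt at radiographic realism.

What passing tests on these cohorts do **not** show: behavior under label
noise, under non-linear or interaction-structured attribute encodings, or
at real-data scale (the real test sets are ~12× larger, which shrinks every
operating-point standard error by ~3.5×).

### The composition-shift scenario

One audit question needs a cohort whose subgroup disparities come *only*
from test-set composition (population and prevalence shifts), not from the
model.  The population-mirroring defaults do not satisfy that premise: a 41% vs 33%
focal prevalence gap is genuinely learned by empirical risk minimization as
a prior shift on the group axis, so residual post-correction disparity is
the *correct* finding there.  `composition_shift_config()` therefore keeps
the full age gaps (64/61/56) as the composition driver, flattens the focal
prevalence gaps to a few tenths of a percent (still group-dependent), and
uses moderately unbalanced groups (50/30/20%) so each group's operating
point is measurable (at 78/15/7 the minority group has ~190 negatives,
putting a ±0.03 binomial band out of reach for any model).  Validated over
10 random seeds: median worst-group |FPR − 0.20| after resampling = 0.017.

## Training and model selection

All networks are small NumPy modules with manual backpropagation: MLP
backbones (input → 64 ReLU → 32 ReLU penultimate), a 3-block CNN for
images, and a forward-only DenseNet-121 feature extractor (growth 32,
blocks 6/12/24/16, penultimate dimension 1024) used for architecture parity
checks and random-projection baselines.  Optimization is Adam (lr 5e-3,
batch 128, weight decay 5e-3, 30 epochs by default), deterministic given
the seed.  The defaults were chosen on validation AUC; the weight decay
matters because the latent features are noise-dominated and wider,
lightly regularized nets memorize noise (val AUC drops ~0.03).

Model selection keeps the epoch snapshot with the best *primary-task*
(disease) validation loss.  Selecting on the combined multitask loss is
structurally wrong here: the sex/race heads overfit within 1–2 epochs, and
their rising validation loss pulls the combined minimum to epochs where the
disease head is far from converged (disease AUC 0.75–0.79 vs 0.86
single-task).  With primary-task selection the multitask model matches the
single-task disease AUC within 0.02 across seeds while keeping strong
attribute heads — the parity property the audit relies on.  Single-head
models select on their own head's loss, so nothing changes for them.

Freezing a backbone is a hard contract: a frozen backbone's parameters are
verified bitwise unchanged (SHA-256 over parameter bytes) across any
subsequent head training or probe.

## Subgroup statistics

Decision rule: positive iff score ≥ threshold.  The global threshold is
calibrated to a target population FPR of 0.20 as the smallest threshold
whose achieved FPR does not exceed the target (the empirical upper quantile
of negative-class scores); with finite samples the achieved FPR is the
largest attainable value at or below the target.  Per subgroup we report
AUC (midrank/Mann–Whitney tie convention), TPR, FPR, and Youden's
J = TPR − FPR at the shared threshold, each with a 95% percentile bootstrap
interval from 2000 label-stratified resamples (each stratum resampled with
replacement to its own size).  The threshold is held fixed inside bootstrap
replicates; re-calibrating per replicate would fold calibration noise into
the subgroup intervals and is available as a user-level choice by
re-running calibration.  BCa intervals were not used: the percentile
variant is the simplest member of the family and is what the coverage
study validates (92–98% empirical coverage for a Bernoulli mean).
Metrics undefined on a subgroup (no positives or no negatives) are flagged,
never silently NaN.  Probe (SPLIT) operating points are reported at the
Youden-optimal threshold, ties broken toward the larger threshold.

## Test-set resampling

Balanced test sets are drawn with replacement to match three targets
simultaneously: group proportions (default uniform), a per-group age-bin
histogram (default: the pooled test population's histogram applied to every
group), and per-group focal-label prevalence (default: pooled prevalence
applied to every group).  Joint cell masses are the product of the three
marginal targets (conditional independence across controlled factors);
integer cell counts come from largest-remainder apportionment; cells are
filled by with-replacement draws from matching source records.  A required
cell with positive mass but no source members raises a named infeasibility
error — deliberately never silent reweighting, so the user learns the
correction they asked for is not supported by their data.

Default age bins are three coarse clinical bins (18–45, 45–65, 65–96).
Ten-year bins are the natural choice at real-data scale, but at synthetic
scale they make the product-cell construction infeasible for the minority
group in a large fraction of draws; bin edges are configurable, so finer
stratification is available when the source supports it.  The cost of
coarse bins is residual within-bin age mismatch (~0.01–0.02 on FPR for a
5-year group age gap), which the shift-diagnosis table exposes rather than
hides.  Output sizes default to the source test-set size so confidence
intervals remain comparable between original and resampled reports.

## Probe test and backbone panel

The probe head is an L2-regularized multinomial logistic regression
(C = 1.0, standardized features) trained on frozen penultimate features of
the train split and evaluated one-vs-rest on the test split — a convex,
deterministic surrogate for "training a new linear prediction layer".  The
panel compares four backbones: random initialization (an untrained random
projection, the task-difficulty baseline), a generically pretrained
backbone (trained on a synthetic non-cohort task — random-teacher sign
classification for vector inputs, bar-orientation classification for
images — so it has provably never seen cohort data), the all-data disease
backbone, and a disease backbone trained only on the largest subgroup
(majority group for the race panel, male patients for the sex panel, the
largest subgroups by design to minimize the sample-size confound).  Two
reference rows — a direct single-task attribute classifier and the
multitask model's attribute head — bound what the representation could
support when the attribute is an explicit training target.

## Feature and logit inspection

PCA (centered, unwhitened, 4 modes) is fitted on the full test-set
features; scatter plots subsample a fixed number per group (default 1000,
with-replacement plus a warning flag for smaller groups) while statistics
use the full test set.  t-SNE runs with perplexity 30 (reduced for tiny
inputs), 1000 iterations, PCA initialization, and a fixed seed; the exact
hyperparameters are recorded in the result manifest because t-SNE
coordinates are otherwise irreproducible.  The logit view pairs the two
focal labels' pre-sigmoid scores; samples with neither focal label are
overlaid as 'other' and excluded from the focal-pair statistical row.

Marginal distributions along each axis (each PCA mode's own 1-D projection,
and each focal logit) are compared for the focal-label pair, all three
group pairs, and the sex pair with two-sample Kolmogorov–Smirnov tests:
exact null when both sides have ≤ 25 samples, asymptotic otherwise.  All
entries of one model's table form a single family for Benjamini–Yekutieli
adjustment (valid under arbitrary dependence, which these tests have —
shared axes and shared samples); significance is marked at adjusted
p < 0.05 and < 0.001.  The alignment summary condenses the picture to a
separation score per mode × attribute (maximum pairwise KS D between the
attribute's classes along that mode), making "which mode encodes which
factor" quantitative.

## Audit orchestration and verdict

`run_audit` derives all stage seeds from one master seed, writes every
table as CSV plus a manifest (seeds, config hash, package version), scores
each site's test set with the other site's model when two sites are
configured, and aborts with the failing stage's name while keeping
completed artifacts.  The verdict block is an explicitly labeled
interpretation aid, a pure function of three booleans/values: probe AUC in
[0.45, 0.55] → scenario-A signature; positive probe with neither
significant group separation in logit space nor residual post-resampling
FPR disparity (> 0.03) → scenario-B signature; positive probe with either →
scenario-C signature.  The raw evidence always ships alongside.

## Problem sizes

Defaults used by the test suite and the acceptance script: cohorts of
4,000–10,000 samples (60/10/30 train/val/test), 30 training epochs, 2000
bootstrap resamples for reported intervals (reduced in unit tests), 500
replicate experiments for the coverage study, 200 simulated tables for the
false-discovery study.  These sizes keep every stage's sampling error well
below the effect sizes under test while the entire suite runs on one CPU
core in a few minutes.

## Known limitations

* Linear factor geometry makes attribute shortcuts easier to learn than in
  image data; prevalence-shift exploitation appears at gaps (~8 percentage
  points) that real models may shrug off.  This is a feature for testing
  the audit's detection ability and a caveat for quantitative transfer.
* Per-group operating points on minority groups of a few hundred samples
  carry ±0.02–0.03 binomial noise; bands tighter than that are not
  meaningful at synthetic scale.
* The uncertainty-label handling of real chest X-ray annotations is out of
  scope; synthetic labels are clean binary.
* DenseNet-121 is provided for feature-dimension parity and random
  projections, not for training; training it in NumPy would be impractical
  and is not needed by any audit stage.
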