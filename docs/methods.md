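# Methods

## Overview

`plaquemark` implements a detection-by-classification idea: amyloid
plaques are not directly visible on T2-weighted MR, but they depress the
local signal, so the image-level class labels (disease model vs. control)
can supervise a search for the *pixels* that carry that depression.  The
pipeline is: pixel feature extraction → elastic length alignment →
repeated feature selection → voting → test classification → inverse
mapping and marking → evaluation.  This note records the model choices,
the defaults and why, and what the synthetic phantom can and cannot show.

## Feature space and elastic mapping

Each slice's in-mask gray values, in row-major raster order, form its
feature vector; coordinates are kept per feature so any selected feature
can be traced to one pixel.  Vectors differ in length because masks differ
in size.  They are aligned to the shortest vector's length T with

    m(t) = floor(t * L / T),   t = 0 .. T-1,

i.e. nearest-lower-index resampling.  Interpolation was deliberately
rejected: an interpolated value has no unique source pixel, and the whole
point of the pipeline is to mark real pixels.  m is nondecreasing and
injective whenever T ≤ L, so the inverse map (template index → source
coordinate) is well defined and always lands inside the brain mask.  This
is a 1-D length alignment, not image registration: it assumes roughly
self-similar masks (the phantom's uniformly scaled ellipses satisfy this
approximately; strongly deformed anatomies would not).

## Separability distance criterion (filter fitness)

For a candidate feature subset with M selected columns and classes of
sizes N₁, N₂ (priors Pᵢ = Nᵢ/(N₁+N₂)):

    S_b = (c̄₁ − c̄₂)²
    S_w = (P₁/N₁) Σᵢ Σₖ (c₁ᵢₖ − c̄₁)² + (P₂/N₂) Σⱼ Σₖ (c₂ⱼₖ − c̄₂)²
    λ   = S_b / S_w

where c̄₁, c̄₂ are scalar means over *all* selected values of a class.
When S_w < ε (= 1e-12) the ratio is taken against ε.  Two consequences
worth knowing:

* Because S_w sums over selected features while S_b does not, λ rewards
  compact subsets: among equally informative pixels the criterion prefers
  fewer of them.  Over a 30-generation budget this shows up as steady mask
  shrinkage (from ~50 % of the template at initialization to ~25–30 %)
  with preferential retention of class-informative pixels.
* The scalar centers mean the criterion measures separation of the pooled
  gray-value distributions, not a per-feature Fisher score; mixing pixels
  with very different baselines inflates S_w.  On the phantom (uniform
  baseline) this is immaterial.

The hot path is an O(M)-per-evaluation implementation using precomputed
per-feature sums of values and squared values; it is algebraically
identical to the direct formula and tested against an independent loop
re-summation at 1e-9.

## CAGA search

Agents (binary chromosomes with cached fitness, "energy") live on a closed
ring; each interacts only with its two neighbours.  One generation:

1. **Dynamic neighbourhood competition**, ascending ring order.  Agent i's
   rival is the fitter of its neighbours, taking already-updated agents to
   the left and pre-sweep agents to the right (at the ring ends the wrap
   partner is taken in its pre-sweep state for position 0 and updated
   state for the last position).  An agent whose energy is ≥ the rival's
   survives; otherwise it is rebuilt by gene competition: agreeing loci
   kept, differing loci replaced by independent uniform bits.
2. **Adaptive crossover** of each agent with its fitter neighbour.  The
   pair probability is 1 below the generation mean, otherwise
   ((f_max − f′)/(f_max − f_ave))^(1/GH) with f′ the pair's better
   fitness and GH the pair Hamming distance.  Degenerate cases (decided
   here, since the rule leaves them open): a flat generation
   (f_max = f_ave) returns 1 to keep mixing; identical parents (GH = 0)
   return 0, crossover being a no-op anyway.  The exchange itself is
   one-point at a uniformly random cut; uniform per-locus exchange is
   available behind `CAGAConfig.uniform_crossover`.
3. **Mutation** at p_m = 1/length.  The configured initial probabilities
   (p_c0 = 0.8, p_m0 = 0.05) apply to generation 0 only, before adaptive
   statistics exist.
4. **Elitist reinsertion**: parents and offspring are pooled and the best
   `elite_count` (default 50 = the whole population) form the next ring.

Stopping: f_best tracks the best population-*average* fitness since the
start; a stall counter increments each generation without improvement and
the run stops when it exceeds `stall_limit` (default 5) or after
`max_iterations` (default 30) generations.  The defaults — population 50,
p_c0 0.8, p_m0 0.05, 30 generations, full elitism — are the reference
operating point for this algorithm family.  All randomness flows through
one seeded generator; identical seeds give identical trajectories.
All-zero chromosomes are repaired (one random gene set) before
classifier-based fitness evaluation, including replacements created inside
the competition sweep.

## Wrapper fitness and classifier adapters

Wrapper fitness trains on the training split restricted to the candidate
mask and scores accuracy on the validation split.  The SVM adapter is a
linear-kernel SVC with C = 1 (no value is prescribed; the linear kernel
is).  The random-forest adapter averages the accuracies of `rf_repeats`
independently seeded forests to damp forest randomness; 500 trees is the
default for the CAGA wrapper and 650 for the PCA comparator.  At desk
scale `rf_repeats` defaults to 1 (the reference protocol averaged 100
forests when calibrating tree counts; that value remains available in
config but makes the wrapper two orders of magnitude slower).

## PCA comparator

Principal components are fitted on the train+validation samples;
components up to 95 % cumulative explained variance are retained, each
original feature is scored by the explained-variance-weighted sum of its
absolute loadings, and the top `n_features` (default 125) form the mask.
"Transforming components back to pixels" is ambiguous in general; the
loading-rank reading was chosen because downstream marking requires real
pixels, not component scores.  The selector is deterministic and invariant
to sample order.

## Voting

Selection is repeated k = 10 times per split (same split, reseeded
search); a feature enters the final mask iff its vote count strictly
exceeds T_select = 8, i.e. 9 of 10 runs.  The strict comparison is kept as
printed; `VotingConfig(strict=False)` relaxes it to ≥, and T_select must
lie in (k/2, k).  Voting is what turns a stochastic search into a stable
marker: on the default phantom the individual run masks hold ~120–140
pixels while the voted mask holds ~11–21, almost all on plaque sites.

## Synthetic phantom

The generator emulates the study design the method assumes: two classes of
masked 2-D slices, 10 AD + 12 CTL subjects × 6 slices = 132 samples.
Defaults (all in `PhantomConfig`):

| parameter | default | rationale |
|---|---|---|
| image_size | 64 px | quarter-scale slice keeping the template near 500 |
| brain_shape | (12, 15) px semi-axes | elliptical "brain" of ~560 px |
| slice_scale_range | (0.93, 1.0) | per-slice mask-size variation so vector lengths differ and the elastic mapping is exercised |
| base_intensity | 150 (0–255 scale) | mid-gray tissue signal |
| plaque_count_per_slice | 5 | several distinct deposits per slice, as in aged disease-model histology |
| plaque_radius | 2.5 px | small cluster, a few pixels across at this resolution |
| plaque_contrast | −0.30 | hypointensity: 30 % local signal loss |
| plaque_position_jitter | 1.0 px | per-subject anatomical variation around class-shared canonical sites |
| noise_sigma | 7.5 | 5 % of base intensity, additive Gaussian, truncated at 0 |

Canonical plaque sites are drawn once per dataset (rejection-sampled with
restarts to keep one plaque diameter of separation and a safety margin
inside the smallest mask) and jittered once per subject, so a pixel-level
selector can generalize across subjects — the analogue of spatially
recurrent deposition in hippocampus and cortex.  Slices are split at the
slice level (not subject level), matching the reference protocol; note
this lets slices of one subject appear in both train and test, which
inflates absolute accuracy for any method.

**What the phantom does not model:** MR physics (relaxation, coil bias,
partial volume), anatomy (no tissue contrast inside the mask), plaque
morphology (disks, uniform contrast), and histology registration.  Passing
tests therefore show that the pipeline's machinery is correct and that it
recovers planted, spatially recurrent hypointensity; they do not certify
detection performance on real MR data.  Notably, at the default contrast
and noise the *classification* task is nearly saturated — even random
masks of moderate size classify well because any plaque-footprint pixel
is informative — so classification accuracy alone under-identifies
selection quality here; match rate and the mapped-pixel significance test
are the discriminating metrics.

## Splits, evaluation, significance

Each experiment uses 8 independent train/validation/test divisions
(test = 32 CTL + 20 AD slices; the remaining 80 split evenly 40/40 into
train and validation — the even split is a choice, no sizes being
prescribed).  Evaluation per split:

* accuracy, sensitivity, specificity with AD positive (undefined ratios
  are reported as NaN, not raised);
* match rate = matched plaques / total plaques, a plaque counting as
  matched when a marked coordinate on its slice lies within the match
  radius (default plaque_radius + 1 px; the histology-to-MR
  correspondence this stands in for was visual, so the radius is exposed
  in config).  AD slices misclassified as control receive no marks and
  contribute misses;
* mean total intensity of the selected pixels per class
  (MTI_AD = TI_AD/20, MTI_CTL = TI_CTL/32), with a Welch t-test across
  splits;
* significance against random selection, two ways: (a) per split, a Welch
  t-test comparing per-pixel mean gray values (over the AD test samples)
  of the voted mask against a uniformly random mask of the same
  cardinality — the per-split check that the selected pixels differ from
  chance; and (b) a t-test of the k selection-run test accuracies against
  matched-cardinality random-mask accuracies.  On the default phantom (b)
  saturates for the reason given above, which is precisely why (a) is the
  reported per-split test.  Welch's variant is the default everywhere
  (equal variances are not assumed; the pooled variant is selectable).

Stage seeds derive from the master seed via
`SeedSequence([master_seed, repeat, stage, run])`, so any stage can be
reproduced in isolation and the whole report is byte-identical under a
fixed master seed.

## Problem sizes

The default study runs at quarter scale: template length ≈ 490 (vs. ~2900
at full slice resolution), 132 samples, 8 splits × 10 selection runs × 30
CAGA generations, completing in well under a minute on one core.  A
full-scale run only changes `PhantomConfig` (image_size 128, brain_shape
(24, 30)) and scales linearly in template length.

## Known limitations

* The separability criterion's preference for compact masks means the
  voted mask size (and hence match rate) depends on how consistently the
  10 searches converge; with the 30-generation budget the voted masks are
  small (~15 pixels), enough to hit most planted sites at the default
  geometry but with little redundancy per site.
* PCA selection ranks features marginally by loading weight; it has no
  notion of class separation beyond what variance captures, and is
  included as the comparator it is.
* The significance machinery assumes approximately normal group values;
  with k = 10 accuracies clustered at a boundary (0 or 1) the t-test is
  conservative.
* DICOM support is read-only and single-frame, behind an optional
  dependency.
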