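# Methods

`mrmcbe` evaluates two-round multi-reader multi-case (MRMC) reader studies
of AI-assisted fracture detection on radiographs. The reference design it
implements: a consensus ground truth of bounding boxes labelled acute or
healing, several radiologists annotating every image twice (round 1
unaided, round 2 with the standalone AI's boxes visible after a washout),
and one AI reader that localizes fractures but cannot grade healing. This
note records the model, its assumptions, the parameters that matter, and
the design choices made where the published design was open.

## Box matching

A source box (reader or AI) detects a ground-truth fracture when its
overlap reaches a threshold, default **0.40**. The overlap normalisation is
configurable because the study that motivated this package did not publish
which convention its 40% referred to:

- `gt_fraction` (default): intersection area / ground-truth box area.
  Detection-oriented; insensitive to readers drawing generously large
  boxes, and asymmetric by design.
- `iou`: intersection over union (object-detection standard, symmetric).
- `min_area_fraction`: intersection / min of the two areas.

The comparator is inclusive (`>= 0.40`) by default and exposed in config,
since "at least 40%" and "over 40%" are both defensible readings. Boxes are
half-open `[x_min, x_max) x [y_min, y_max)` in continuous pixels so
adjacent boxes sharing an edge do not intersect.

Matching is **one-to-one optimal assignment**: among pairs at or above the
threshold, the assignment maximises the number of matched pairs, then the
total overlap (solved exactly with a linear sum assignment in which each
matched pair carries a bonus larger than any achievable overlap sum).
One-to-one prevents a single sprawling box from claiming several fractures.
We deliberately use exact assignment rather than a greedy
highest-overlap-first heuristic: greedy is not cardinality-optimal (one box
overlapping two fractures can block a two-pair assignment), and the exact
solution is what the brute-force enumeration oracle in the test suite
defines as correct. Unmatched source boxes are false positives; unmatched
ground-truth boxes are false negatives. Acute/healing status is ignored
during matching — a detection with the wrong status label is still a
detection; status correctness is scored separately.

The unavailable derivation of the 0.40 operating point is replaced by a
threshold-sensitivity sweep (`threshold_sweep`), reporting per-fracture
TP/FP/FN per source across thresholds; TP is provably non-increasing in the
threshold.

## Scoring levels

- **Per fracture** (strictest): each ground-truth fracture must be hit by a
  sufficiently overlapping box. FP counts every unmatched box. TN has no
  natural lesion unit; it is defined as a fracture-free image correctly
  left unannotated, one unit per image, making per-fracture TN coincide
  with per-image TN for every source. (Published tables in the reference
  trial are internally inconsistent on the AI's per-fracture TN; we use the
  single consistent definition throughout.)
- **Per image**: a source's image call is positive iff it drew any box on
  the image; correctness ignores location entirely.
- **Per examination** (most generous): OR over the examination's images,
  for both the call and the ground-truth status.

Image- and examination-level quadruples always sum to the number of images
and examinations; per-fracture TP+FN equals the number of ground-truth
fractures. These conservation identities are enforced by property tests
and survive averaging.

Averaging across readers is a cell-wise arithmetic mean, yielding
fractional counts. Metrics are computed from the averaged counts. For
accuracy, sensitivity and specificity this equals the mean of per-reader
metrics (fixed denominators); for PPV/NPV the two differ slightly because
per-reader denominators vary — this package always reports the
ratio-of-mean-counts.

## Metrics and intervals

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp), NPV
tn/(tn+fn), accuracy (tp+tn)/n. Zero-denominator metrics are flagged
undefined rather than raising. Intervals at a configurable level (default
95%):

- **Clopper-Pearson** exact binomial (beta quantiles) for accuracy,
  sensitivity and specificity; endpoints are exactly 0/1 at boundary
  counts.
- **Wilson score** (Newcombe's efficient-score method, no continuity
  correction by default; the corrected variant is available) for PPV and
  NPV.

Binomial intervals need integer counts, so on averaged fractional counts
the successes/trials are rounded to the nearest integer for the interval
only; the point estimate keeps full precision. How the original trial
handled fractional averages is unknowable; only integer-count intervals
are treated as reproduction targets.

Displayed percentages are rounded half-up to one decimal. Delta columns
(assisted minus unaided, AI minus either) are computed on unrounded values
and rounded last.

## Agreement and decision changes

Inter-reader agreement is the arithmetic mean of pairwise Cohen's kappa
over all reader pairs; reader-vs-AI agreement averages each reader's kappa
with the AI. Kappa uses the standard marginal-product chance correction;
two constant identical raters get kappa = 1 by convention, and the only
other p_e = 1 configuration is unreachable. At the fracture level the unit
set is all ground-truth fractures plus **one false-positive pseudo-unit per
image** ("any stray box on this image"), so multiple FPs on one image count
once; the pseudo-units can be excluded via `include_fp_units=False`. This
pseudo-unit construction is our concretization of counting only the first
false-positive instance per image; the trial did not define it further.

Round-1 to round-2 decision changes are recorded per unit with direction
(positive-to-negative or the reverse), correctness (round-2 call equals
ground truth) and AI alignment (round-2 call equals the AI's call on that
unit). At the fracture level, detection flips are tracked per ground-truth
fracture; false positives, whose count differs between rounds, contribute
one change record per unit change of the per-image FP count — a removal
lands on a true negative and is a correct change, an addition is a wrong
one. AI alignment of these FP-delta records uses the AI's image-level call,
since an FP has no AI counterpart box (the trial is silent here). The
change-rate denominator is the unit total per level; at the fracture level
it defaults to ground-truth fractures plus all distinct FP events across
both rounds (per image, the larger of the two rounds' FP counts), and is
configurable — the reference trial's printed "fracture events" denominator
is not reconstructible from its stated counts.

Averaged change tables report the mean numerator over the mean denominator
for each nested subgroup (overall; by direction; by AI agreement; each
split correct/wrong).

Acute/healing status accuracy is the proportion of detection TPs whose
reader status matches ground truth, pooled over readers by default;
requesting it for the AI is an error because the AI carries no status.

## Failure analysis

Units where at least a majority threshold of readers (default 5 of 7)
contradicted the AI in round 1, categorised by who ground truth vindicates:
AI-correct reader overcall (FP) / undercall (FN), reader-correct AI
overcall / undercall. Fracture units compare detection vs miss; FP sites
are compared at image level (any stray box present), implementing the
location-free FP comparison. Raising the threshold can only remove cases.

## Synthetic study generator

The generator emulates the reference dataset's structure in expectation:
48 patients, 107 examinations, image count per exam 1 + Poisson(2.14)
(~336 images), examination positivity 65/107, image positivity within
positive examinations at the conditional rate (~148 positive images, with
at least one forced per positive examination — the forcing inflates the
expectation by ~2%), fracture count per positive image 1 + Poisson(0.39)
(~206 fractures), 40/206 acute, 2000x2500 px images with box sides uniform
in [80, 400] px. Positivity is clustered at examination level because
independent per-image positivity cannot reproduce the positive-image and
positive-examination totals simultaneously.

Reader and AI behaviour are parameterised per profile: per-fracture
detection probability, Poisson false-positive rate per image, localization
jitter (Gaussian centre shift with sd = jitter x box side and log-normal
size noise with sd = jitter), and for readers a status-flip probability.
Defaults (readers ~0.80 detection spread 0.74-0.86, 0.17 FP/image, jitter
0.08, status error 0.30; AI 0.61 detection, 0.185 FP/image) are loosely
scaled to the reference trial's count magnitudes and are not claimed to
reproduce its tables. Ground-truth boxes are placed mutually disjoint;
false-positive boxes are rejection-sampled to be disjoint from every
ground-truth box, so every simulated box's TP/FP identity is exact by
construction and the generator doubles as an oracle for the matcher.
Infeasible placements raise after 500 attempts with a diagnostic.

Round-2 behaviour operates on per-unit binary calls (each ground-truth
fracture plus one FP-presence unit per image): where the reader's round-1
call disagrees with the AI, it flips to the AI's call with probability
`p_adopt_ai_when_disagree` (inheriting the AI's box geometry when flipping
positive, which makes AI alignment deterministic); otherwise it flips
spontaneously with probability `p_spontaneous_flip`. With full adoption and
no spontaneous flips, every round-2 image call equals the AI call and
reader-vs-AI kappa is exactly 1. Randomness is one seeded stream per
(seed, source, round) keyed by reader id, so per-reader output is stable
under reader reordering and the whole dataset is byte-identical given a
seed.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: reader errors are independent across readers
and fractures (no difficulty correlation, so majority-overcall failure
cases are much rarer than in real studies, and inter-reader kappas are
driven purely by marginal rates); adoption of the AI is symmetric in
direction, whereas real readers selectively accepted the AI's
false-positive removals and overruled its misses (so the simulated
assisted condition need not outperform the unaided one, unlike the
reference trial); there is no body-region or patient-level effect
structure; and no image pixels exist at all.

## Problem sizes and numerical choices

Analysis is exact and deterministic; the only tolerances are in tests
(oracle agreement to 1e-9 for intervals, 1e-9 total-overlap ties for the
matcher). The test suite uses compact studies (12-20 examinations) for
pipeline checks, 100 replicates of a 15-examination study for conservation
sweeps, and a single ~20x-scaled study (~2140 examinations, ~4000
fractures) for parameter recovery, chosen to give binomial/Poisson interval
half-widths near one percentage point. Assignment ties (equal overlap) are
resolved by the LSA solver and then reported in canonical
(gt index, source index) order; equal-cardinality, equal-overlap
assignments are interchangeable for every downstream count.

## Known limitations

- Per-fracture TN is a per-image construct; per-fracture specificity and
  NPV inherit it and should be read accordingly.
- Averaged PPV/NPV are ratio-of-means, not mean-of-ratios (see above).
- The FP pseudo-unit kappa at fracture level is a convention, not a
  published definition; compare only within a fixed convention.
- The generator's reader model is intentionally minimal; it validates the
  pipeline, not radiologist psychology.
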