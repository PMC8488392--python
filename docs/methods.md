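# Methods

## The measurement model

The package analyses two spine dimensions per dendritic protrusion: total
length L (μm, spine base to tip) and head width W (μm, across the broadest
part of the head), plus a boolean for branched spines (two heads on one
neck, counted as a single spine carrying one L/W pair). Measurements are
organised hierarchically — strain → mouse → brain region (CA1 hippocampus
or layer II/III prefrontal cortex) → neuron → dendritic compartment
(apical/basal) → position (proximal/distal, split at 40 μm from the soma)
→ segment — and exchanged as three tidy CSV tables (spines, segments,
somata) with fixed lower-case snake-case tokens and μm/μm² units. Floats
are written with `%.17g` and parsed with numpy so a write/read cycle is
bit-exact; validation is total (any malformed row rejects the table with a
1-based row diagnostic, never a silently truncated load).

## Soma circularity

CI = 4π·A/P² compares the traced outline's area with that of a circle of
equal perimeter; the isoperimetric inequality bounds CI ≤ 1, with equality
for a circle of any radius. Polygonal traces use the polygon's own
perimeter and shoelace area with no smoothing (no smoothing procedure is
defensible without knowing the tracing software's internals); orientation
of the vertex list is irrelevant, self-intersecting or collinear outlines
are rejected.

## Shape classification

Two rule systems operate on (L, W, LWR = L/W):

* Binary: filopodia-like ⇔ L > 2 μm; mushroom-head-like ⇔ W > 0.6 μm.
  Boundary values fall in the "non-" classes (the cut-offs are strict
  exact comparisons, no epsilon).
* Seven-class, Risher-style: filopodia (L > 2, LWR > 1, W ≤ 0.6),
  long-thin (1 < L ≤ 2, W ≤ 0.6), thin (L ≤ 1, W ≤ 0.6), stubby (LWR ≤ 1),
  mushroom medium head (W > 0.6), mushroom wide head (W > 0.6, LWR < 1),
  branched. Written as plain predicates these rules overlap (a short wide
  spine satisfies both the stubby and mushroom-wide conditions), so they
  are applied in a fixed precedence that makes them a total partition:

  branched → W > 0.6 (wide if LWR < 1 else medium) → LWR ≤ 1 (stubby) →
  L > 2 (filopodia) → L > 1 (long-thin) → thin.

  Head width first because mushroom identity is width-primary in this
  tradition; after the width and ratio gates, the remaining classes reduce
  to pure length cut-offs and the filopodia width clause is automatically
  satisfied. A spine with LWR exactly 1 and W > 0.6 is mushroom-medium
  (the wide-head rule's "< 1" is strict). This precedence is a documented
  design choice, not inferred from any dataset.

## Distributions and the KS test

Histograms use the √N rule — bins = nearest integer to √N, halves rounded
away from zero — over the observed [min, max]; relative frequency divides
counts by N and the ogive is the running sum (last value 1). An
all-identical sample degenerates to one flagged bin. The two-sample
Kolmogorov–Smirnov statistic is computed on raw samples, never on binned
ogives (binning would make D depend on the bin rule; the binned supremum
converges to the raw D as bins grow, which a test verifies). The two-sided
p-value uses the asymptotic Kolmogorov distribution at effective size
n = n₁n₂/(n₁+n₂) — appropriate for the thousands-scale samples this
pipeline sees, and calibrated: under the null at n = 500 per group the
empirical rejection rate at α = 0.05 is 0.05 ± 0.01 over 2,000 replicates.

## Clustering

(W, L) pairs are z-scored per axis with the sample (n−1) standard
deviation; the scaling parameters are retained so centroids can be mapped
back to μm. K-means uses k-means++ seeding, 10 restarts keeping the lowest
within-cluster sum of squares (WSS), and an explicit seed, so fits are
deterministic; empty clusters are re-seeded internally at points farthest
from their centroids. The cluster count is the argmax of mean silhouette
over k = 2..8, with the WSS curve reported for elbow inspection (the two
diagnostics are not combined by any formula; silhouette decides, WSS is
shown). Silhouette is Euclidean on the scaled coordinates; above 5,000
points a fixed-seed subsample of 5,000 is scored, since the computation is
O(n²). For k = 3 clusters are named from raw-μm centroids: *long* = max
mean length, *wide* = max mean width of the remaining two, *small* = the
third; ties raise and demand manual labels. By default spines of both
strains within one region are clustered jointly, so cluster definitions
are shared across groups; per-strain clustering is available by subsetting
first.

## Group statistics

The analysis unit is the neuron: spine density per 25 μm (mean over a
neuron's 25-μm counting segments; the shorter morphology segments are
excluded from density), per-class and per-cluster spine counts, and soma
metrics are each reduced to one value per neuron, keeping the mouse of
origin so users can re-aggregate to mouse means and probe
pseudoreplication. Strains are compared with the classic pooled-variance
unpaired two-tailed Student's t (df = n₁+n₂−2); a zero-pooled-variance
family with equal means returns p = 1 flagged, with unequal means it is an
error. Holm–Bonferroni step-down adjustment is applied within one
family — the set of simultaneous categories of one region × compartment
panel (e.g., the four binary shape cells, or the three cluster labels) —
and significance is judged at α = 0.05 on adjusted p-values.

## Synthetic data

The generator emulates the study design end to end: per strain × region,
4 mice × 5 traced neurons; 12 density segments (25 μm; 3 per compartment ×
position) with Poisson spine counts (defaults 30 per segment in
hippocampus, 27 in prefrontal cortex); 20 morphology segments (10 μm; 5
per cell) whose Poisson mean of 15 spines yields ≈ 6,000 measured spines
per strain per region; 10 soma-only neurons per mouse (40 somata per
strain per region). Spine (W, L) pairs come from a three-component
mixture of independent-axis normals truncated by rejection to W ∈ (0, 2]
and L ∈ (0, 4] μm (configurations with < 1% acceptance are rejected as
infeasible). Component means default to the published per-region cluster
centroids; the per-axis SDs (0.12 μm width, 0.25 μm length) are a
generator calibration chosen so the three components are distinguishable
yet overlapping, and the weights (small 0.45, long 0.20, wide 0.35) encode
a realistic predominance of small spines. Branched flags are Bernoulli
(0.02). Somata are 64-vertex ellipse polygons whose axis ratio is solved
(via the complete elliptic integral of the second kind) to hit a
per-soma target circularity draw, with 1.5% multiplicative radial noise
and the perimeter rescaled to a target draw; the small polygonisation and
noise bias of CI is within the configured spread.

Two presets define study conditions: `null_twostrain` (identical strain
configurations, used for calibration and familywise-error checks) and
`paper_like_effect` (the autistic-like strain gets +0.15 mixture weight on
the small component taken from the wide component in hippocampus, and a
×0.85 apical / ×0.97 basal density reduction in prefrontal cortex). All
randomness flows from one master seed through deterministic
per-(strain, region, mouse, neuron) sub-streams.

What the generator does **not** emulate: within-neuron and within-mouse
correlation of spine dimensions (an optional neuron-level random effect
was considered and omitted — real intra-class correlation is unknown, and
asserting one would be as arbitrary as asserting none), measurement error
of manual tracing, anisotropic optical distortion, and any dependence of
spine shape on position along the dendrite. Passing tests therefore
demonstrate the correctness and calibration of the pipeline under a
well-specified hierarchical mixture model, not the reproduction of any
particular biological dataset.

## Numerical choices and problem sizes

Exact comparisons throughout the classifiers; 1e-9 tolerances on
conservation and fixed-point invariants; silhouette subsampling cap 5,000;
k-selection range 2..8. The simulation suites use the study-design sample
sizes (20 neurons per strain, ≈ 6,000 spines per strain per region) with
2,000 replicates for KS calibration, 500 for familywise error and 200 for
power; the familywise and power replicates generate only the hippocampal
region, which is the one their metric families test. Empirical rate checks
allow the two-standard-error Monte-Carlo margin of a binomial proportion
at the stated replicate count.

## Known limitations

Density and morphology use separate segment pools, so per-segment density
and per-spine shape cannot be linked at segment resolution in generated
data. The asymptotic KS p-value is slightly conservative below n ≈ 50 per
group (an exact-enumeration oracle is used in tests at small n). The
seven-class precedence resolves rule overlaps in one documented way;
datasets classified under a different stubby/mushroom-wide tie-break will
differ for short wide spines. Cluster labels (small/long/wide) are defined
only for k = 3.
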