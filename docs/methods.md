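# Methods

This note documents the models, conventions and numerical choices behind
`wearmap`, and what its synthetic validation does and does not show.

## Image model and conventions

A wear-scar image is a binary canvas of 170 rows × 220 columns; pixel
value 0 is worn (black), 1 unworn (white).  Conventions, fixed so trained
models are portable across sessions:

* rows run along the anterior–posterior (AP) axis with anterior at row 0;
  columns along the medial–lateral (ML) axis;
* on a right-side (or right-normalized) canvas the medial compartment is
  the right half (columns 110–219), the lateral compartment the left half;
* encoding flattens row-major, giving vectors of length 37,400;
* left-side components are mirrored about the vertical axis and relabeled
  right before any analysis;
* standardization resamples by nearest neighbor (order-0), never by
  interpolation, so the image stays binary; the mm-per-pixel calibration
  is rescaled by the same factors.

Default calibration is 0.35 mm/px on both axes, so the canvas spans
roughly 77 × 60 mm — a plausible tibial-insert envelope.  The true
dimensions of any particular insert design are not fixed by the method,
so calibration is a parameter everywhere.

Side inference, when the implantation side is unrecorded, is a
deterministic mirror-distance rule: encode the image as-is and mirrored,
and keep the orientation whose mean Euclidean distance to a
right-normalized reference cohort is smaller (ties resolve to right).
This replaces any opaque trained side classifier on purpose: the rule is
reproducible, testable, and recovers ≥ 95% of known sides on the
generator's presets.  It relies on a systematic medial/lateral asymmetry
of the wear pattern (see presets below); on a cohort with no such
asymmetry it degrades to chance.

## Synthetic cohort generator

Real retrieval images are not publicly available, so the generator is a
first-class, tested component, not a fixture.  Each component carries one
scar blob per compartment, rendered as a superellipse
|u/a|ᵖ + |v/b|ᵖ ≤ 1 (p ≥ 1: ellipse at p = 2, boxier above) with an
optional low-order random Fourier perturbation of the boundary radius,
r(φ) → r(φ)·(1 + ρ·f(φ)) with |f| ≤ 1 and amplitude ρ ∈ [0, 0.5).  The
family spans the blob-like, irregular contours of digitized wear scars;
the rasterized area of the unperturbed shape matches the closed form
4ab·Γ(1+1/p)²/Γ(1+2/p) within 2% at the tested calibrations.

Population presets (all values mm / degrees; each parameter is drawn from
a normal with the stated mean and spread):

* **postmortem-like** (n = 21 in the default cohort) — the reference
  population: moderate spreads (e.g. scar centers ±3 mm AP), roughness
  ≈ 0.10, time-in-host ≈ 79 ± 30 months;
* **revision-like** (n = 54) — larger spreads, rougher boundaries,
  slightly posterior lateral scars, time-in-host ≈ 26 ± 20 months;
* **simulator-like** (n = 6) — anterior scar centers (medial +8, lateral
  +5 mm AP) and every parameter spread at most one quarter of the
  postmortem spread: machine-worn scars are reproducible.  Side is fixed
  to left (simulator mounting), time-in-host to 60 months — 5 million
  gait cycles at the 1 Mc = 12 months walking-equivalence convention.

All presets place a larger scar on the medial than the lateral
compartment and shift the lateral scar posteriorly.  This encodes the
clinically typical medial-dominant loading of the tibial plateau and is
what makes implantation side recoverable from the image alone.

An optional covariate model makes total analytic scar area a linear
function of time-in-host plus Gaussian noise; the realized analytic area
is recorded in the cohort table, so with zero noise the regression
recovers the constructed slope with R² = 1 exactly.

Randomness: a master seed feeds `numpy.random.SeedSequence`, which spawns
one child per component; a fixed `CohortSpec` therefore reproduces the
cohort byte-for-byte.

What the generator does **not** emulate: delamination and third-body
damage, multi-blob scars within one compartment, digitization artifacts
of contour tracing, and any physics of wear.  Passing tests therefore
show that the pipeline recovers structure *of the kind the generator
plants* (location/size/shape families with population-level variability);
they do not certify performance on real retrieval images.

## Self-organizing map

From-scratch implementation on a rectangular lattice (rows × cols
neurons; lattice distance = Euclidean distance of integer grid
coordinates).

* **Initialization**: codebook vectors drawn from the data with
  replacement (`sample`, default) or uniformly on the per-feature data
  range (`uniform_random`); seeded.
* **BMU search**: smallest Euclidean distance; ties break to the lowest
  row-major neuron index, making every run bit-reproducible given a seed.
* **Kernel**: Gaussian h = exp(−d²/2σ²) by default — it smooths small
  maps and is the common default in SOM software; a bubble (hard-radius)
  kernel is available.
* **Radius schedule**: linear decay between the configured endpoints
  (default 4 → 1).  The decay law between the endpoints is a choice; we
  use the simplest one and expose the endpoints.
* **Training length**: two phases, 10 epochs shrinking 4 → 1 and 40
  epochs at radius 1.  Epoch counts are a package choice: at this data
  scale the batch update reaches a fixed point well within the budget.
* **Batch vs sequential**: the batch rule (neighborhood-weighted mean;
  neurons with zero total neighborhood mass keep their weights) is the
  default and ignores any learning rate.  A sequential mode
  (w ← w + α·h·(x − w), linear α decay, seeded random presentation order
  per epoch) is provided as well, since descriptions of this workflow
  mention both a learning rate and the batch algorithm; the two should
  not be mixed in one run.
* **Quantization error**: mean Euclidean distance of samples to their
  BMU, logged per epoch.  It decreases with map size on fixed data, which
  is why model selection pairs it with a structure requirement (below).

The codebook is float32 by default — ample for binary inputs, and it
halves memory and time at the 37,400-dimensional scale; float64 is a
parameter away and is used in the oracle-equivalence tests.

## U-matrix and cluster delineation

The u-matrix assigns each neuron the mean codebook distance to its
4-neighbors (corners average 2 neighbors, edges 3).  Delineation is
automated — reading cluster boundaries by eye is not reproducible — with
two deterministic methods:

* **threshold** (default): neurons with u ≤ quantile(u, q), q = 0.5,
  seed 4-connected regions; the rest stay unlabeled ridge.  q = 0.5 keeps
  roughly the valley half of the map as cluster area; raising q merges,
  lowering q fragments (the labeling is nested in q).
* **watershed**: flood from the local minima of the u-matrix (minima
  shallower than a merge tolerance are suppressed first); labels every
  neuron.

Cluster ids are relabeled contiguously from 1 in order of each region's
minimum row-major neuron index, so ids are stable across runs.
Assignment of a component is its BMU's cluster; a BMU on a ridge falls
back to the nearest labeled neuron by lattice distance, ties to the lower
cluster id.  Assignment never updates the codebook.

Model selection across map sizes uses the smallest quantization error
*among configurations producing at least 2 clusters*: quantization error
alone always prefers the largest map, so a minimal
clustering-structure requirement stands in for the visual
"well-defined cluster structure" judgment.

## Robustness protocol

Retrain the map under several seeds with identical hyperparameters (only
codebook initialization and presentation order vary), assign the full
cohort with each map, then compare runs pairwise:

* **Cohen's kappa** over co-membership indicators of all unordered
  component pairs.  This unit of analysis makes kappa invariant to
  arbitrary cluster relabeling, which any cross-run comparison of raw
  cluster ids would not be.  CI: large-sample SE
  √(p₀(1−p₀)/n)/(1−pₑ); the test of κ = 0 uses the null SE
  √(pₑ/(n(1−pₑ))).  Kappa is undefined (raises) when both series are
  constant and equal.
* **Consistency fraction**: per component, the fraction of its
  cluster-mates in a baseline run that are again its mates in another
  run; components with no mates in the baseline count as fully consistent.
  Reported as mean ± SD over components.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure — over the per-component, per-run consistency values, with the
  F-based CI.  The choice of consistency values as the ICC input is a
  documented convention (cross-run cluster ids themselves are not
  comparable numerically).

On the default synthetic cohort the ensemble kappa is positive but modest
(≈ 0.1–0.2): a 120-neuron map retrained on 21 reference images legitimately
redraws fine cluster boundaries.  On strongly planted structure
(`planted_triplet_spec`, three well-separated populations, map sized to
the data) retraining agreement is essentially perfect (κ ≈ 1 vs ≈ 0 after
label permutation), which is the property the protocol is meant to detect.

## Shape descriptors and statistics

Computed per compartment on the worn-pixel set, in mm via the
calibration: area (pixel count × pixel area); perimeter by the Crofton
formula with 4 projection directions — chosen over boundary-chain
estimators because it converges to the true length for smooth blobs, so
the circularity 4πA/P² of a rasterized disk approaches 1 (0.99 at radius
50 px) instead of saturating ~6% low; centroid relative to the
compartment center (anterior positive); bounding-box ML/AP stretches
(extents, hence non-negative — the signed centroid offset is a separate
field); second area moments about the centroid axes; circularity, aspect
ratio and solidity as shape factors; and a whole-component symmetry index
in [0, 1], the product of the medial/lateral area balance
1 − |A_m − A_l|/(A_m + A_l) and the AP centroid alignment of the two
compartments.  An empty compartment yields zeroed descriptors with an
`empty` flag rather than an error.

Statistics: one-way ANOVA of each descriptor across clusters, excluding
singleton clusters (no within-group variance; their means still appear in
the summary table; a fully constant descriptor returns F = 0);
per-cluster OLS of descriptors on time-in-host and age-at-surgery,
restricted to clusters with more than three components with known
covariate, flagged when p < 0.05 **and** R² > 0.4 (significant and
meaningful); and the exact binomial tail P(X ≥ k) = Σⱼ₌ₖⁿ C(n,j) pʲ(1−p)ⁿ⁻ʲ
for cluster enrichment, with the success probability estimated from the
fraction of retrieved components in the cluster.  At the reference
composition — 5 of 6 held-out components in a cluster holding 9 of 75
retrieved — the exact tail is 1.3437 × 10⁻⁴.

## Numerical and degenerate-input choices

* All ties (BMU search, ridge fallback, side inference) break toward the
  lowest index / right side, so outputs are deterministic.
* Quantile-threshold q is validated to (0, 1]; radius schedules require
  σ₀ ≥ σ₁ > 0; kappa and ICC raise specific errors on zero-variance
  input instead of returning NaN.
* P(X ≥ 0) returns exactly 1 (the float summation would give 1 − 1e-16).
* The bounds clamp in the generator shrinks or recenters a drawn shape
  that cannot fit its compartment; with the shipped presets this is rare
  and the recorded analytic area is always the post-clamp value.

## Problem sizes used in validation

The test suite and the acceptance script run at the study scale: cohorts
of 81 components (21 training), maps up to 20 × 10, five retraining seeds
for trend and recovery checks, three seeds for the robustness report.
These sizes were chosen to match the emulated study design while keeping
a full validation run in the minutes range on a single CPU.

## Known limitations

* The generator's scar family is unimodal per compartment; real damage
  modes (delamination, scratching, embedded debris) are out of scope.
* Cluster counts on synthetic data depend on the delineation parameters;
  there is no ground-truth "correct" number of clusters for weakly
  separated populations, which is why validation targets planted
  structure and qualitative behaviors, not specific counts.
* The ICC input encoding (consistency fractions) is one reasonable
  convention among several; alternatives (e.g. co-membership rates) would
  change the number but not the qualitative reliability story.
* Retraining agreement on small reference cohorts is intrinsically
  limited; reported kappas should be read against the permutation
  baseline, not against 1.
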