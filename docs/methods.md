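# Methods

This note records the model, the parameter defaults and the numerical
choices behind `mwmtsa`, and what the synthetic benchmark does and does not
demonstrate.

## Problem and pipeline

A Morris Water Maze trial is a time-ordered planar track of one rodent in a
circular pool (radius *R*, default 100 cm) containing a hidden platform
(default radius 6 cm, centred mid-quadrant at (45, 45) cm).  Animals express
stereotyped exploration strategies — wall hugging (thigmotaxis, TT),
incursion (IC), centre scanning (SC), focused search (FS), chaining response
(CR: circling at the remembered platform-to-wall distance), self orienting
(SO), scanning surroundings (SS), target scanning (ST) and direct finding
(DF) — and typically several of them within one trial.  The pipeline
recovers the within-trial strategy sequence and compares it between animal
groups.

Stages: read/validate tracks → constant-arc-length overlapping segmentation
→ eight features per segment → partial expert labels → pairwise constraints
→ MPCK-Means classifier pool over target cluster counts → cross-validation
gating → majority-vote ensemble → Gaussian smoothing onto R-length intervals
→ per-trial profiles, transition counts, Friedman tests and per-member
binomial confidence intervals.

## Segmentation

Segments span `segment_length` cm of arc (configure as 2–3·R; 200–250 cm is
the regime in which conclusions are stable for a 100 cm-radius maze) with
fractional `overlap` (0.70 or 0.90).  Boundaries snap to the nearest sample
at or beyond the target arc position; segments are therefore true sample
runs and "constant length" holds to within one sampling step.  A trailing
start that cannot fit a full segment is dropped.  Trajectories shorter than
one segment produce no segments, are flagged, and are classified DF
end-to-end unless a whole-path label is supplied — a deliberate policy: a
path shorter than the segment scale is almost always a direct run to the
platform.

## Features

All length-like descriptors are normalised by *R*, making the vector
invariant under rotation, translation and uniform rescaling of the setup:
median and IQR of the distance to the arena centre; focus
(1 − 2·r_spread/L, clamped to [0, 1]); eccentricity of the point covariance;
efficiency (endpoint displacement over arc length); radial variation
(std/mean of centre distance); total absolute turning (headings computed
after merging sub-0.1 cm steps, which suppresses tracker jitter that would
otherwise dominate the angle sum); and minimum platform distance.
Columns are standardised by median and IQR before clustering (zero-IQR
columns keep scale 1); the fitted scaling is stored for reuse.

## Labels and constraints

Experts label 8–12% of segments with one or two strategy codes (two labels
mark genuine straddlers).  Must-links join sampled pairs of single-labelled
segments sharing a class; cannot-links join sampled pairs with disjoint
label sets.  Two-label segments anchor no must-link and never generate a
cannot-link against either of their own labels — a hard constraint on a
straddler would be wrong by construction.  Pair sampling is capped (default
500 per class or class pair) and seeded: the constraint count, not the label
count, drives the clustering cost.

## MPCK-Means

The per-point assignment cost under cluster k with diagonal metric a_k is
`Σ_d a_kd (x_d − μ_kd)² − Σ_d log a_kd` plus a constant penalty (default 1
in standardised units) per violated constraint.  Iteration: greedy
single-point assignment (unconstrained points in one vectorised pass;
constrained points sequentially in seeded random order, each taking the
cost-minimising cluster given the current assignment of its partners),
centroid means, then the closed-form metric update a_kd = n_k/S_kd clipped
into [1e−6, 1e3].  Each phase exactly minimises its block of the objective,
so the objective is non-increasing — the property tests assert this on
every fixture.  Two choices protect that exactness: violation penalties are
constants and therefore excluded from the metric update, and empty clusters
retain their previous centroid and metric rather than being reseeded.
Initialisation: transitive closure of must-links gives labelled
neighbourhoods whose means seed the first centroids; the remainder come
from farthest-first traversal.  Convergence is an assignment fixpoint, by
default exact (`tol=0`), with `max_iter=200` as the library ceiling; the
pipeline caps sweeps at 30, where assignments are essentially converged on
desk-scale cohorts (cross-validation errors match the exact fixpoint to
within a point).

Clusters become a classifier by mapping each cluster to the modal expert
class among its labelled members (two-label records contribute ½ to each);
no labelled member, or a tie, leaves the cluster unassigned and its
predictions UNDEFINED.  Cross-validation uses 10 stratified folds over the
labelled records (stratification by a deterministic representative class;
classes rarer than the fold count simply appear in fewer folds).  Each fold
refits on the *full* feature matrix — clustering is transductive — with
constraints restricted to train-fold pairs, and scores held-out records; a
prediction inside the record's label set is correct, UNDEFINED is an error.

## Ensemble

One classifier per K in 10..100 (seeds derived from the master seed and K).
Members with CV error strictly below 25% are strong; fewer than 40 strong
members aborts the run with an "insufficient labelling" diagnostic — the
remedy is better labels, not a looser gate.  The ensemble votes with equal
weights; member abstentions are discarded before counting (an abstention is
not an opinion), and a strict tie leaves the segment UNDEFINED, which in
practice keeps the unclassified rate far below the 3% guideline.  The
ensemble's own CV error is computed by voting the members' held-out
predictions on the fold split they all share.  Diagnostics: the pairwise
agreement matrix (diagonal 100 by construction) and agreement between 21
random 11-member sub-ensembles.

## Smoothing

Paths are re-divided into abutting intervals of length *R* (short final
remainder kept).  Classified segments overlapping an interval vote with
weight `w_k · exp(−d²/2σ²)`; σ = *R* keeps the kernel proportionate to the
arena.  The cutoff is implemented as exp(−2) = 0.13534 — the exact value at
d = 2σ that is conventionally printed as 0.14 — so segments at exactly 2σ
still vote.  Class weights invert the class's share of all classified
segments *after* clipping the share into [0.01, 0.5]; clipping the final
weights instead would hand rare classes the smallest weights and defeat the
stated purpose of the weighting (protecting rare strategies from common
ones).  Shares are computed over the whole experiment, not per trajectory.
Ties and empty candidate sets leave the interval UNDEFINED; transition
counts are taken on the interval sequence after removing UNDEFINED entries.

## Statistics

Group comparisons use the Friedman test on a trials × groups block matrix:
each of the (default 12) trials is one block holding the two per-group
means of the per-animal measure, giving k = 2 and df = 1.  Animal-paired
blocks are impossible with unequal group sizes, which is why blocks are
trials.  Ranks use mid-ranks with the standard tie correction; the p-value
is the chi-square upper tail.  The implementation is cross-checked against
an independent reference implementation in the test suite.  Per-member
confidence: every strong classifier's own classification is smoothed and
tested, giving a binary significance verdict per member; the Clopper–Pearson
(exact) 95% interval of the verdict proportion must lie wholly above 0.5
for the conclusion to be "confirmed".  Exact intervals were chosen over
Wald because member counts are small and proportions extreme.

## Synthetic cohorts

The generator emulates the standard rat protocol: 200 cm pool, 12 cm
platform, 90 s timeout, 12 trials over 3 days, release near the wall at a
random angle, default cohort sizes 30 and 27.  Kinematics default to
25 cm/s at 10 Hz — values that give realistic trial path lengths (hundreds
to ~2250 cm).  Each trial concatenates strategy bouts drawn from the
group's mixture; a trial ends at platform contact or timeout.  Bout arc
lengths are strategy dependent (in units of *R*: TT 4–10, IC 3–7, SC 3–6,
FS 2.5–5, CR 2.5–6, SO 1.5–2.5, SS 2.5–5, ST 2.5–5, DF geometry-bound):
behavioural episodes must generally exceed the segment scale for
segment-level labelling to be meaningful at all, and the framework states
its own resolution floor at twice the arena radius — only the
intrinsically short SO loop sits below it.  Default group mixtures follow a
clean benchmark design: TT carries the planted difference (0.45 vs 0.15),
SC/SS/ST/DF absorb the complement on the control side, and IC/FS/CR/SO are
exact nulls, so class-level false-positive behaviour is testable and
cross-segmentation consistency is a property rather than a coin flip.

What the generator does **not** emulate: learning across trials (mixtures
are stationary), inter-animal variability beyond sampling noise, tracker
dropouts and jitter, wall-following curvature artefacts, or any cognitive
dynamics.  Passing tests therefore demonstrate that the pipeline recovers
planted, stereotyped structure at realistic geometry and sample sizes —
not that it matches expert judgement on real tracking data.

## Study conditions used by the tests and the acceptance script

Full-pipeline checks run two groups of 10 animals × 12 trials, 2.5·R
segments at 70% overlap, 10% auto-labels and a K = 10..40 pool with a
15-member minimum — a scale at which one run takes well under a minute.
Under these conditions the pipeline typically yields ~31/31 strong
classifiers with mean member CV error around 15%, ensemble CV error below
the member mean, unclassified rates under 1.5%, interval-level ground-truth
recovery of ~75%, and decisive detection of the planted thigmotaxis
difference.  The null calibration (identical mixtures, 6 animals per group,
ground-truth shares) keeps the Friedman rejection rate near the nominal 5%.
Robustness is assessed as in the framework's own validation: the set of
strategies flagged conclusively (p < 0.05 with confirmed member CI) must
agree between 2·R and 2.5·R segmentations of the same cohort.

## Known limitations

- The eight descriptors are this package's fixed choice of informative
  segment geometry; other descriptor sets could classify differently.
- Diagonal metrics only; full-matrix MPCK variants are out of scope.
- The Friedman block design collapses animals into per-trial group means;
  with very few trials the test is coarse (k = 2 makes it a signed
  comparison over trials).
- Strategies with episodes shorter than the segment length are
  systematically absorbed by their neighbours — a stated property of the
  method, visible here for SO.
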