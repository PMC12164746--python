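# Methods

`tractquant` implements an along-tract ("tractometry") analysis pipeline
for drug-resistant focal epilepsy cohorts, together with a synthetic-cohort
generator that emulates the study design such analyses are run on. This
note documents the models, the defaults and their rationale, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The along-tract model

Six white-matter tract families are analyzed — IFOF, TR, CFMe, CH, ILF and
Un — all bilateral except the midline commissural CFMe, giving 11 tract
instances per subject and timepoint once sides are recoded. Following the
automated fiber quantification (AFQ) convention, each tract is represented
at 100 equally spaced nodes. Four quantitative variables are carried per
tract: fractional anisotropy (FA, dimensionless in [0, 1]), mean
diffusivity (MD, ×10⁻³ mm²/s), volume (Vol, mm³) node-wise, and the
streamline count (Fib) as a single global number.

**Resampling.** Streamlines are resampled by piecewise-linear arc length
(no spline): node k of an n-node profile sits at arc position
(k−1)/(n−1) of the total length, endpoints preserved exactly. This choice
is deterministic and oracle-checkable against closed-form geometry; a
smoother interpolant would change node values by far less than the
biological noise the pipeline models.

**Node aggregation.** FA/MD at a node are the *unweighted* mean over
streamlines of the scalar interpolated at that streamline's node.
Mahalanobis-distance weighting of core-distant fibers, used by some AFQ
implementations, is deliberately out of scope; the unweighted mean is the
simplest defensible contract and is what the synthetic generator inverts.

**Volume.** Vol at node k is the number of distinct voxel cells (edge =
acquisition voxel size, default 2 mm, a typical DWI slice thickness)
containing any streamline's k-th node, times the voxel volume. Defining
Vol node-wise makes *segmental* volume well-defined; whole-tract volume is
recovered as the sum over nodes up to overlap between adjacent node
clouds.

**Discarding.** A bundle with fewer than `min_fibers` (default 5)
streamlines yields a profile flagged invalid rather than an exception;
invalid profiles are excluded from statistics, and every tract instance
touched by an exclusion is reported as *skipped* in the comparison grid
and *not evaluable* in the taxonomy — missingness is never treated as
normality.

**Summaries.** Each profile is reduced to a global mean and 5 segment
means over 20 consecutive nodes (segment 1 = nodes 1–20, …, segment 5 =
nodes 81–100, 1-based). The global FA/MD/Vol mean is computed as the mean
of the equal-size segment means — algebraically identical to the
whole-profile mean and bitwise consistent with the aggregation identity
the tests assert. Fib is global-only.

**Laterality.** Patient tract sides are recoded ipsilateral/contralateral
to the ictal onset zone (IOZ); the CFMe is always midline. Controls have
no IOZ, so their hemispheres are *combined*: the default `pool` policy
enters left and right as separate observations (a bilateral tract
contributes 2 observations per control, and the same combined sample
serves as reference for both the ipsi and the contra instance); a
`subject-mean` policy averaging sides per subject is also provided, since
published descriptions of "combining" hemispheres are usually ambiguous
between the two. Profile orientation (which end is node 1) is taken as
given by the input and assumed consistent within a tract across subjects.

## Statistics

Demographic contrasts use the tie-corrected Kruskal–Wallis rank test
(`scipy.stats.kruskal`; H = 0, p = 1 when every observation is identical).

Tract variables are compared with a general linear model. The default
"combined" analysis fits a 3-level one-way ANOVA (control, FLE, TLE) per
cell of the grid and reads patient-vs-control significance from Fisher's
least-significant-difference (LSD) pairwise contrasts: two-sided t
statistics on the group-mean difference using the pooled error mean square
and its degrees of freedom, with no multiplicity adjustment. When one
diagnosis group is analyzed independently, a 2-level model is used, where
the LSD contrast reduces exactly to the pooled-variance two-sample t test.
Outcome analyses compare operated patients with Engel class I (seizure
freedom) against classes II–IV (recurrence) one year after surgery.

Covariates (age, sex) can be entered linearly (ANCOVA); the default is
none, because small published cohorts typically report raw LSD contrasts
even when groups differ demographically — the option exists for users who
want the adjusted analysis. Tests are two-sided throughout, with the
direction of the mean difference reported separately rather than folded
into one-sided tests. No multivariate omnibus gate is applied: each
variable is tested univariately, matching how such results are reported.
Raw p < α (default 0.05) defines significance; optional
Benjamini–Hochberg adjustment is available and, when enabled, the
significance flag is set from the adjusted p-values.

**The grid.** Per group pair, the grid spans 11 tract instances × 19
scopes (global for all four variables + segments 1–5 for FA/MD/Vol) = 209
contrasts. The grid engine is a vectorized sums-of-squares implementation;
the scalar `lsd_anova` entry point is an independent regression-based
(design-matrix) path, and the two are cross-checked in the tests, along
with a brute-force sums-of-squares oracle.

**Degenerate variance.** When all within-group variance is zero the F
statistic is undefined; `lsd_anova` raises. The grid instead applies an
exact-comparison convention — p = 0 where group means differ, p = 1 where
they are equal, the row annotated "degenerate" — so that noise-free
synthetic cohorts classify deterministically. Because identical floating
point values accumulate rounding of order 10⁻¹⁶ in a mean, "zero variance"
and "equal means" are judged relative to the data's magnitude (residual
mean square ≤ 10⁻²⁰ of the mean square of the data; mean difference ≤
10⁻⁹ of the root-mean-square), thresholds far below any real signal.

## The abnormality taxonomy

Counting rules per tract instance against controls:

* **consistent global** — 3 or 4 of the 4 variables significant at global
  scope;
* **consistent segmental** — ≥ 2 of the 3 node-wise variables significant
  within a segment ("co-significance" is evaluated per segment, not
  cumulatively across different segments, so the label is spatially
  coherent), in 1 to 4 of the 5 segments. "Up to four of five" is read as
  1–4: a tract abnormal in all 5 segments spans its entire length and is
  surfaced by `whole_length_segments` rather than labeled segmental;
* **de novo (global/segmental)** — the same counting rules applied
  postsurgically to variables (or segment-variable pairs) *not*
  significant presurgically;
* **reinforced (global/segmental)** — variables (pairs) significant at
  both timepoints with the same direction. Direction agreement is required
  for reinforcement (the abnormality *persisted*) but not for de novo
  emergence; significance counting otherwise ignores direction, which is
  recorded alongside each label.

A tract may receive de novo and reinforced labels simultaneously on
disjoint variable sets. Fib, being global-only, can contribute to global
categories (including a de novo label resting on Fib plus two node-wise
variables) but never to segmental ones. Cohort scopes: "FLE-only" and
"TLE-only" labels come from the 2-level grids; "combined" labels require
the contrast to be significant with the same direction in both patient
groups within the 3-level model (the intersection grid).

## The synthetic cohort generator

The generator emulates the study design end to end; its defaults are the
study conditions. Cohort: 19 controls, 8 FLE, 12 TLE; 7/8 FLE and 10/12
TLE operated; 1/7 FLE and 6/10 TLE seizure-free; group age means/sds
(34.2 ± 11.9, 22 ± 5, 33.6 ± 13.8 years) and epilepsy durations
(13.4 ± 8.3, 17.6 ± 9.7 years) matching the published cohort. Operated
and seizure-free *counts* are deterministic (`round(fraction × n)`) so the
printed percentages reproduce exactly; *which* subjects fall in each
class is randomized. Controls are scanned once (presurgical reference for
both timepoints); operated patients get pre and post scans.

Per tract and variable, a subject's node curve is

    archetype(tract, var) + between-subject offset + correlated node noise
      [+ planted effects]

* **Archetypes**: baseline + a smooth three-harmonic shape per tract
  (amplitude 0.05 FA, 0.05 MD, 2 mm³ Vol). Baselines FA 0.45, MD 0.80,
  Vol 15 mm³/node, Fib mean 80 are plausible white-matter magnitudes, not
  fitted values, and are freely configurable.
* **Noise**: between-subject sd 0.02 FA, 0.02 MD, 0.75 Vol; node-noise sd
  0.04 FA, 0.04 MD, 1.5 Vol with exponential correlation over node index
  (length 10 nodes) — AFQ profiles are smooth, so i.i.d. node noise would
  be unrealistic. The between-subject offset is drawn per tract
  *instance*, i.e. hemispheres are independent; real hemispheres
  correlate, see limitations.
* **Fib**: negative binomial (mean 80, dispersion 20 — overdispersed
  counts); a `None` dispersion makes the count deterministic, which the
  noise-free experiments use.
* **Effects** are additive, signed (positive = patients above the control
  baseline; the disease direction is MD up, FA/Vol/Fib down), and can be
  restricted by group, timepoint, surgical outcome, laterality and scope
  (whole tract or one segment).
* **Randomness**: one root seed feeds a `numpy` SeedSequence substream per
  subject, so cohorts are bit-identical for equal (spec, seed) and stable
  under any generation order. An optional per-tract dropout probability
  (default 0) exercises the discard path.
* **Bundle mode** renders each profile as streamlines around a smooth
  deterministic centerline per tract with per-fiber offsets, for
  exercising the geometry pipeline; profile mode is the fast path used by
  the Monte-Carlo experiments.

## Monte-Carlo experiments and their design

**Null calibration.** With zero planted effects every grid cell's LSD
contrast is an exact t test under the generator's Gaussian model, so the
per-contrast type-I rate is α by construction — the experiment verifies
the *pipeline* (recoding, pooling, summarization, grid plumbing) preserves
that. Contrasts within one cohort are dependent (scope cells of a variable
share nodes; the subject offset shifts all of them), so the replicate, not
the contrast, is the independent unit: the acceptance check holds the
grid-average rate to the 99% binomial interval around α at n = 500
replicates and allows at most 5% of individual cells (expected ≈ 1%)
outside their own n = 500 band. The acceptance script reports the pooled
rate over a 200-replicate run.

**Planted-effect recovery.** One arm plants the disease-direction triple
(MD +, FA −, Vol −) along the whole ipsilateral CH in TLE (reaching the
3-variable global rule); the other plants MD + and FA − confined to
segment 3 (reaching the 2-variable segmental rule while staying below the
3-variable global threshold). Each effect is sized at twice that
variable's node-noise sd; cohorts use 19 controls vs 12 TLE patients. The
correct category must be recovered in the majority of 200 noisy
replicates. A separate noise-free arm (all sds zero, deterministic Fib)
uses the degenerate-variance convention to check *exactly* that the wrong
category never fires: a whole-tract effect makes all 5 segments abnormal
(hence no segmental label), and a segment-confined effect leaves only 2
variables significant globally (hence no global label).

## Problem sizes

The shipped experiments use study-sized cohorts (19/8/12) with 500
replicates for calibration and 200 per recovery arm in the test suite,
and 200/100 in the acceptance script; these sizes give Monte-Carlo
standard errors well inside the asserted bands while keeping a full run in
minutes on one core.

## Known limitations

* Noise magnitudes are free parameters: the source study publishes no
  within-group variance for the AFQ variables, so only calibration and
  recovery properties — not the study's specific anomaly counts — are
  reproducible.
* The generator omits inter-hemispheric correlation, site/scanner effects,
  age/sex dependence of the diffusion variables, and any spatial
  correlation between tracts; passing tests show the pipeline's rules and
  statistics behave correctly under the stated model, not that the model
  captures all structure of clinical DWI.
* Real tractography (waypoint-ROI segmentation, probabilistic atlas
  refinement) and NIfTI/DICOM handling are out of scope; inputs are
  profile tables or synthetic bundles.
* The MANOVA-style multivariate layer is not implemented; variables are
  tested univariately.
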