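# Methods

## The activity-landscape model

A PAH activity landscape samples enzyme activity (pmol Tyr/mg protein/min)
on a fixed 12 × 8 grid of substrate and cofactor concentrations.  Activity
rises and then falls along both axes (substrate inhibition), and the
resulting drop-shaped surface is well approximated by a separable Gaussian
in log-concentration coordinates.  The package treats that Gaussian as an
*empirical* surface model — it denoises the measured grid and provides
well-defined peak parameters — not as a mechanistic kinetic model; no
ordered-binding or inhibition-constant interpretation is attached to the
fitted widths.

Assumptions the model makes of the data:

* activity is nonnegative, and a single dominant activity peak exists
  (multi-peaked surfaces are a quality-control failure, not a model case);
* the surface is approximately axis-aligned in (ln [Phe], ln [BH4]) — no
  rotation/correlation term is fitted;
* wells at zero concentration carry no information about the log-space
  surface and are excluded from fitting (they are kept for visualization);
* each run's wild-type control defines the activity scale; all %WT values
  are per-run, which absorbs batch-to-batch variation in expression and
  assay efficiency.

### Processing order

1. **Background subtraction** — the run's no-DNA control plate is subtracted
   element-wise; negative wells are clipped to 0 (activity is physical).
2. **Normalization** — each replicate is scaled by the maximum well of the
   background-subtracted wild-type plate of the same run (× 100 → %WT).
3. **Aggregation** — element-wise median across the triplicates.
4. **Fitting** — bounded trust-region least squares on the nonzero-
   concentration wells.  Initialization: amplitude and peak location at the
   observed argmax, unit log-widths.  Bounds: a ∈ [0, 10·max z]; peak
   coordinates within the sampled log range ± 1; widths ∈ [0.05, 5].  The
   wide location bound deliberately admits peaks beyond the assay box so the
   artifact filter can see them.  A failed optimization is reported as
   `converged=False`, never an exception.
5. **Features** — amplitude %WT (relative to the same-run WT fit), peak
   concentrations, and the 50 %-of-maximum working range along [Phe] at the
   BH4 optimum, in closed form.  Because the surface is Gaussian in log
   space the endpoints satisfy low · high = peak² exactly; the test suite
   holds this to 1e-9.
6. **No-residual-activity filter (subpopulation 0)** — a genotype is
   excluded from clustering when its fit has no usable peak (amplitude
   < 1.5 %WT, half the artifact cutoff) or shows the conversion-artifact
   signature: peak strictly above 1500 µM [Phe] with activity strictly
   below 3 %WT.  The activity criterion is evaluated on the modeled maximum
   *within the sampled concentration box*: when the optimizer pushes the
   peak beyond 2500 µM, the fitted amplitude extrapolates far above anything
   observed, and judging the filter on it would let exactly the flat
   landscapes it exists to catch slip through.  For peaks inside the box the
   two numbers are identical.

## Quality control

Three statistics gate each genotype:

* **RMSE** between observed and modeled landscape, on the landscape rescaled
  to unit fitted amplitude — dimensionless and portable across activity
  levels;
* **NoP**, the number of strict 8-neighborhood local maxima in the lightly
  smoothed landscape (σ = 0.8 cells, minimum prominence 1 % of the grid
  maximum);
* **VT**, the maximum over wells of replicate (max − min)/median, computed
  on the *raw* replicate plates.  Raw plates carry the shared assay baseline,
  so the ratio is well defined everywhere; on background-subtracted or
  normalized plates the denominator of low-activity genotypes is dominated
  by additive noise and the statistic degenerates.  Wells whose replicate
  median falls below 1 % of the plate's maximum median well are skipped.

Thresholds follow an exponential model of each statistic's cohort
distribution: with rate λ̂ = 1/mean, the cutoff mean + 2/λ̂ equals 3× the
cohort mean.  The pipeline calibrates all three thresholds from the
residual-activity cohort it is gating (genotypes already flagged as
subpopulation 0 are excluded from calibration); the constants
(0.26, 8.4, 0.23) are retained as defaults when no calibration cohort is
available, and a user-supplied λ is honored in the two-term form.  Samples
within ±10 % of any threshold (without exceeding one) are flagged
*borderline* and passed through for manual review, mirroring how such
cohorts are curated in practice.

## Subpopulation discovery

QC-passing residual-activity genotypes enter a standardized four-feature
space: activity %WT, ln peak [Phe], ln peak [BH4], ln working-range width.
The working range enters as width only — its endpoints are determined by
peak and width, and duplicating the peak coordinate would double-weight it.

**Consensus clustering.**  For each candidate k (2–8), 250 subsamples of
80 % of the cohort are clustered by k-means++ with a single seeded restart;
the consensus matrix records, for every pair, the fraction of co-sampled
runs assigning them together.  Final labels per k cut an average-linkage
tree of (1 − consensus).  A master seed derives per-(k, resample) child
seeds, and subsampling is keyed to sorted genotype ids, so results are
invariant to input order.

*Single restart is deliberate.*  With many restarts the base clusterer
becomes effectively deterministic given a subsample; a merge of two true
clusters at too-small k is then perfectly stable, and stability-based model
selection cannot see that it is wrong.  One k-means++ restart leaves genuine
structure stable at the true k while keeping forced merges and splits at
wrong k visibly unstable.

**Choosing k.**  PAC (proportion of ambiguous consensus entries, window
0.1–0.9) is the stability score.  Selection: if any k achieves essentially
perfect stability (PAC ≤ 0.01), the *finest* such partition (largest k)
wins — at every k below the true one, merging separated clusters is exactly
as stable as the true partition, so among perfectly stable options the most
resolved one is the informative choice; otherwise the smallest k within 0.01
of the PAC minimum wins (parsimony under noise).  On 10 independently
simulated default cohorts this selects k = 5 in 9 of 10 (the planted
partition is recovered with ARI ≥ 0.925 at k = 5 in all 10); on a noiseless
cohort and on tight planted clusters the selection and partition are exact.

**Naming.**  Clusters map to subpopulations 1–5 by medians: 5 = highest
activity; 2 = lowest peak [Phe]; 3 and 4 = the two clusters whose median
peak [Phe] exceeds the cohort's wild-type peak, split by activity (3 higher);
1 = the remainder.  Geometry that breaks these rules (not exactly two
right-shifted clusters, ties) raises a naming error and the clusters are
reported unnamed rather than misnamed.

**k-NN labeling.**  Future samples are standardized with the reference
cohort's stored transform and labeled by majority vote of the 5 nearest
reference genotypes (Euclidean distance); ties break by smaller mean
neighbor distance, then smaller label.  Leave-one-out accuracy on the
default cohort is 81/81.

## Clinical correlation

Each genotype carries counts of phenotype records (classical PKU,
blood [Phe] > 1200 µmol/L; mild PKU, 600–1200; MHPA, < 600) and of
BH4-response records (responder + slow-responder pooled as "responders" vs
non-responder).  Genotypes enter a correlation only with strictly more than
10 records *for that purpose* — the two filters run independently, so the
phenotype and response cohorts differ — and genotypes carrying the
annotation-unstable variants p.Ile65Thr or p.Phe39Leu are excluded.
Subpopulation summaries pool patient records across genotypes (patient-level
percentages, not genotype-averaged), and the headline statistic is the
non-responder share among all response records of genotypes with residual
activity (labels 1–5).

## The synthetic study generator

The generator is the forward model of every assumption above.  Each
genotype draws a ground-truth surface from its subpopulation archetype;
plates are baseline + surface (+ artifact) with replicate noise; clinical
records are multinomial/binomial draws with subpopulation-specific rates.

**Archetypes** (activity %WT, peak [Phe] µM, peak [BH4] µM, log-widths):

| class | activity | peak [Phe] | peak [BH4] | sx′ | sy′ |
|---|---|---|---|---|---|
| WT | 100 | 315–345 | 84–118 | 1.15–1.25 | 0.85–0.95 |
| 0 (artifact half) | 0.3–0.8 | 1700–2200 | 80–200 | 0.5–1.0 | 0.5–1.0 |
| 0 (null half) | 0 | — | — | — | — |
| 1 reduced | 4–11 | 220–360 | 84–118 | 1.05–1.30 | 0.80–1.05 |
| 2 left-shifted | 4–9 | 105 ± 30 % | 55–72 | 0.45–0.75 | 0.55–0.85 |
| 3 right, higher | 6–16 | 547 ± 30 % | 85–120 | 1.40–1.75 | 0.70–0.95 |
| 4 right, lower | 3–6 | 476 ± 30 % | 110–170 | 1.30–1.60 | 0.70–0.95 |
| 5 high activity | 23–32 | 150–500 | 70–130 | 0.90–1.40 | 0.70–1.05 |

Draws are truncated normals centered mid-range with σ = range/4 (~95 % of
draws inside): the ranges describe the observed spread of a clustered class,
whose members concentrate around a mode; uniform boxes would make flat
clusters whose consistent k-means splits defeat stability-based model
selection for structural rather than noise reasons.  The WT log-width
follows from its working range (80 ≈ 330·exp(−sx′√(2 ln 2)) ⇒ sx′ ≈ 1.2);
class-2 widths are narrow and classes 3–4 broad, as their working ranges
require.  Where a class is described only by a median, a ±30 % band is used.
The class-4 BH4 optimum (110–170 µM) sits in the instrument's well-sampled
region; peaks between the two sparse top BH4 levels (125, 250 µM) of a 3–6
%WT landscape are not identifiable and would only inject fit noise, not
biology.

**Noise and artifacts** (defaults): multiplicative CV 8 % and additive noise
0.5 %WT per replicate well; a shared assay baseline of 3 %WT; and the
Phe→Tyr conversion artifact — a linear ramp above 1300 µM [Phe] reaching
1.5 %WT at 2500 µM — applied to transfected-cell plates only, so it survives
background subtraction exactly as observed landscapes show it.  An optional
corruption mode multiplies a random half of one replicate's wells by 5
(probability configurable), the failure class the VT gate exists to catch.
A cohort groups 8 genotypes per run, each run with its own WT/no-DNA
triplicates; the default composition is {0: 18, 1: 24, 2: 14, 3: 16, 4: 19,
5: 8} — 99 genotypes.

**Clinical rates.**  Phenotype probability vectors (classical, mild, MHPA)
per class: 0 → (1, 0, 0); 1 → (.15, .35, .50); 2 → (.13, .35, .52);
3 → (.29, .35, .53) renormalized to sum to one; 4 → (.29, .38, .33);
5 → (0, .20, .80).  Responder probabilities: 0, 0.80, 1.0, 0.80, 0.27, 1.0
for classes 0–5; responders split 75/25 into full vs slow.  Record volumes
are negative binomial (dispersion 3) with means 79 phenotype and 14 response
records per genotype, so a realistic minority falls below the >10-records
filter; three genotypes (drawn from class 3, where annotation instability
was observed) are flagged as excluded-variant carriers.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: non-Gaussian surface shapes (shoulders, plateaus,
rotated ridges), spatially correlated plate effects (edge evaporation,
gradients), run-level batch shifts beyond what per-run normalization
absorbs, heavy-tailed replicate outliers other than the 5× corruption mode,
and any genotype whose true class is ambiguous between archetypes.  Real
cohorts may also violate the archetype geometry the naming rules assume.

## Numerical choices

* Median aggregation before fitting (robust to single-replicate outliers);
  ties and even replicate counts follow the standard midpoint median.
* Negative wells clip to 0 before normalization; %WT landscapes are
  nonnegative by construction.
* The fit's RMSE is reported in the landscape's own units; QC RMSE divides
  by the fitted amplitude.
* Consensus matrices are symmetrized and given a unit diagonal; pairs never
  co-sampled (possible at small resample counts) contribute consensus 0.
* All randomness flows from explicit seeds through `numpy` `SeedSequence`
  spawning; identical seeds give byte-identical plates, tables, and labels.
* Degenerate inputs: an all-zero landscape yields a non-convergent fit and
  subpopulation 0; identical feature rows refuse to cluster ("no cluster
  structure"); a statistic whose cohort values are all zero (noiseless data)
  falls back to the default threshold rather than calibrating a zero cutoff.

## Problem sizes

The default study is 99 genotypes × 3 replicates × 96 wells plus 13 control
pairs (~30 k wells); consensus clustering resamples 250 × 7 candidate k on
≤ 81 × 4 features.  The full pipeline runs in well under a minute on one
CPU; the test suite's heaviest properties (200-seed corruption detection,
10-master-seed optimal-k majority) are sized to keep the whole suite a
few minutes.

## Known limitations

* **Right-shift bias from the conversion artifact.**  For low-amplitude,
  broad, right-shifted landscapes (class 4, and to a lesser degree 3) the
  high-[Phe] artifact ramp pulls the fitted peak toward higher [Phe]: at
  default noise the recovered class-4 peak [Phe] median sits ~40–50 % above
  the planted one (the bias vanishes with the ramp off).  Clustering and
  naming are robust to it — the shift is coherent within the class — but
  absolute peak positions of right-shifted genotypes should be read with
  this bias in mind.  The amplitude and BH4-peak recoveries are unbiased
  (median errors ~4 % and ~2 %).
* Optimal-k selection is correct in ~90 % of simulated default cohorts; the
  failure mode selects k = 6 by splitting one cluster.  The subpopulation
  taxonomy is therefore always reported at the five-cluster cut alongside
  the selected k.
* The Gaussian surface cannot represent genuinely bimodal landscapes; QC's
  NoP statistic excludes them rather than modeling them.
* Published threshold constants (0.26, 8.4, 0.23) are tied to the units and
  normalization of the cohort they were derived from; they are defaults, not
  portable truths, which is why the pipeline calibrates from its own cohort.
* Clinical correlation treats record counts as independent draws; registry
  records of one patient across centers, or ascertainment bias between
  phenotype classes, are not modeled.
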