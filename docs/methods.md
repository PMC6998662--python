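# Methods

## The problem this package models

Serum biobank cohorts make it possible to ask when, before a cancer
diagnosis, circulating RNA becomes informative. The design emulated here is
a lung-cancer case-control study nested in such a biobank: case serum
samples donated up to 10 years (120 months) before diagnosis, cancer-free
control donors frequency-matched on sex, age at donation and blood-donor
group (BDg, a technical batch combining storage time and handling), stage at
diagnosis classified as early / locally advanced / advanced / unknown, and
histology as NSCLC / SCLC / other. Smoking dominates lung-cancer risk, so
all time-resolved analyses restrict both cases and controls to current or
former smokers; with the default cohort margins this leaves 531 of 542 case
samples and 189 of 519 controls.

Because the underlying human data are access-restricted, the package's
first-class data source is a synthetic cohort generator with complete ground
truth. Everything downstream — matching, windowing, differential expression,
trajectories, enrichment — operates identically on real tabular inputs
(sample TSV + count TSV) and on generated cohorts.

## Synthetic cohort generator

**Cohort structure.** `CohortMargins` fixes case sample counts per
histology x stage, male and ever-smoker counts per stage, and control
totals; the defaults reproduce the emulated study's summary table exactly,
at any seed. Ages are truncated normals per group (controls mean 49.9, sd
11.2; case means 51.8-55.0 by stage); prediagnostic times are uniform on
[0, 120] months by default so every analysis window is populated — an
`empirical` mode instead draws per-stage truncated normals with means near
5.5-6.8 years. Subjects may contribute more than one sample (repeat samples
share stage, histology and sex), matching the biobank's sample:subject
ratio. BDg is a 3-level categorical assigned at random.

**Counts.** For RNA *i*, sample *j*:

```
y_ij ~ NB(mean = s_j * 2^(b_i + c_ij + e_ij),  dispersion alpha_i)
```

* baseline `b_i` (log2): 1 + Exponential(scale 2.5), clipped at 14 — a
  long-tailed abundance distribution in which a minority of RNAs dominates
  reads, as in serum small-RNA sequencing;
* dispersion `alpha_i`: log-uniform on [0.05, 1.0] (configurable);
* library size `s_j`: log-normal, sigma 0.3;
* covariate shifts `c_ij`: per-RNA normal shifts (sd 0.2, clipped to
  |log2| <= 0.5) attached to the non-reference BDg levels and (half-sized)
  to male sex — deliberate confounding that makes covariate adjustment
  testable;
* case effect `e_ij`: a Gaussian bump in log2 space,
  `amplitude * exp(-(t - center)^2 / (2 width^2))` of the sample's time to
  diagnosis `t`, applied when the sample's stage/histology match the
  profile. The bump is a two-parameter stand-in for the smooth rise and
  fall of prediagnostic signals; real signals need not be Gaussian or
  single-peaked.

Two RNG streams separate cohort/parameter generation (`seed`) from count
noise (`count_seed`), so the same underlying means can be re-sampled
independently.

**What the generator does not emulate:** sequencing-level artifacts
(mapping bias, adapter content), storage-time RNA degradation, correlated
RNA modules, and zero-inflation beyond what the NB produces. Passing tests
on synthetic cohorts therefore demonstrate correctness of the pipeline
under its own model assumptions, not performance on real serum data.

## Matching

Cohort assembly uses frequency matching: controls are sampled without
replacement so the case:control ratio is constant within strata
(categorical covariates x 5-year age bins). Within analysis windows,
controls are attached by **exact optimal 1:k matching** on age: each case is
replicated k times and the min-cost bipartite assignment (solved with the
Hungarian algorithm via `scipy.optimize.linear_sum_assignment`) minimizes
the total absolute age difference; an optional caliper makes distant pairs
inadmissible. Optional `exact_vars` partition the problem into blocks that
must agree exactly.

By default within-window matching uses age only (`exact_vars=()`): the
control pool is already frequency-matched on sex and BDg at the cohort
level, both enter the regression as covariates, and with the study-sized
pool (189 ever-smoker controls serving 135-control quotas) exact sex or
sex x BDg cells are intermittently deficient by pigeonhole. Controls may be
reused across windows but never within one window or bootstrap iteration.

## Differential expression engine

A deliberately simplified analogue of the standard count-based DE
machinery, chosen so every step is oracle-verifiable:

* **Size factors** — median-of-ratios against the per-RNA geometric-mean
  reference, computed over RNAs with all-positive counts; no rescaling.
* **Dispersions** — method-of-moments on normalized counts,
  `alpha = max(floor, (var - mean)/mean^2)` with floor 1e-8, shrunk 50/50 in
  log space toward a mean-dispersion trend `a0/mean + a1` fitted by
  non-negative least squares across RNAs.
* **GLM fit** — per-RNA NB log-link regression at fixed dispersion with
  `log s_j` offsets, by iteratively reweighted least squares (Fisher
  weights `mu/(1 + alpha mu)`), vectorised across RNAs as one batched p x p
  solve per iteration with step-halving if the likelihood decreases.
  Convergence: relative log-likelihood change < 1e-8, max 100 iterations;
  non-convergent or all-zero RNAs are flagged with missing p-values and
  excluded from adjustment, never raised as errors.
* **Inference** — Wald z = beta/SE from the expected information, two-sided
  normal p, Benjamini-Hochberg within each window only (no cross-window
  correction, mirroring the emulated design's own limitation).

Omitted relative to full DESeq2: Cox-Reid adjusted dispersion likelihood,
dispersion-outlier refitting, fold-change shrinkage, independent filtering,
and outlier-count handling. Tests cross-check coefficients and standard
errors against an independent `statsmodels` NB GLM fit and the significance
ranking against a likelihood-ratio oracle.

Design encoding: intercept; case indicator; age z-scored; sex (reference
female), smoking (reference former), BDg (reference first label
alphabetically) as indicators, constant columns dropped. Phase 1 keeps all
samples and treats missing smoking as an explicit `unknown` level; phases
2-4 operate on ever-smokers only, so smoking drops out as constant.

The count filter retains an RNA iff it has >= 5 reads in >= 20% of samples
(both boundaries inclusive); the filter is applied once per phase to the
full matrix before windowing.

## Windows, phases, trajectories

Windows are half-open `[start, end)` month intervals, time measured
backward from diagnosis, so fixed windows partition the span without double
counting. Defaults: 7 fixed windows of 120/7 ~ 17.1 months; sliding windows
of 17 months advanced by 2.5 months (42 windows).

Per window, cases are drawn stage-balanced by iterative smallest-quota
allocation (equivalent to largest remainder toward equal proportions),
backfilling from better-populated stages when a stage runs short — a
warning is logged when exact balance is impossible. Case quotas: 27 pooled
(phase 2), 9/14/18 for early / locally advanced / advanced (phases 3-4),
always with 5 matched controls per case. Controls carry no prediagnostic
time and are eligible for every window.

The per-window **signal** is the number of RNAs with BH-adjusted p < 0.05,
tabulated by RNA class. An effect-weighted alternative (sum of |log2FC|
over DE RNAs) is exposed for peak localization: near a strong effect the
thresholded count saturates — every affected RNA is detected across several
adjacent windows — flattening the peak, while the weighted signal retains
curvature. Phase runs can redraw each window's case set `n_resample` times
(rematching controls each draw, analogous to the stage-specific
replication); trajectories then use the mean signal.

**Peak detection** operationalizes what is usually read off a figure:
interior local maxima of the total series (plateau midpoints included) with
height >= `min_height`, kept greedily in decreasing height order subject to
pairwise separation >= `min_separation_months`, reported as window-center
times. Kernel smoothing (bandwidth = step size) is available for plotting
but never used for detection.

**Bootstrap.** The stage-specific analysis is resampled (default 20
iterations), each iteration redrawing cases without replacement and
rematching controls; the per-window mean/sd/min/max of the DE count
quantifies signal stability. A 2-year-window variant (5 windows of 24
months) probes robustness to the window grid using the same selection rule.

## Pathway enrichment

Only mRNAs and predicted miRNA/isomiR targets carry functional annotation;
piRNA, tRF and the other classes contribute nothing. The selected gene set
is the union of DE mRNA ids and targets with prediction score **strictly**
greater than 60 of DE miRNAs (isomiRs map to their parent miRNA via an
explicit mapping). Each pathway is tested with the one-sided hypergeometric
tail against a universe of all annotated genes, BH-adjusted across
pathways. The test is exact and therefore conservative at small pathway
sizes (the null positive rate sits below the nominal 5%). A synthetic toy
annotation (30 pathways x 500 genes plus a target table) ships as a
generator function for tests and demos; real annotation databases can be
supplied as TSVs but are never required.

## Numerical and design choices

* IRLS mean floor 1e-10, eta clipped to ±40; singular normal equations fall
  back to pseudo-inverse with the RNA flagged.
* Tie-breaks are lexicographic everywhere (strata, case/control ordering),
  making matching and selection deterministic given a seed; one master seed
  fans out to per-stage streams via a fixed name-hash derivation.
* Margins are reproduced exactly by construction (allocation, then
  shuffling within strata), not by rejection sampling.
* Degenerate inputs: empty count matrices, all-zero RNAs, windows with too
  few cases, and infeasible matching all produce flagged results or
  structured errors; a phase run never aborts because one window fails.

## Problem sizes used in tests

The test suite and the acceptance script run the full-size default cohort
(1061 samples) with 120-2000 RNAs depending on the check: 2000 RNAs for
null calibration of the Wald test, 500 for trajectory peak recovery (10
seeds), 300 for stage specificity (2 seeds). These sizes give stable Monte
Carlo estimates while keeping a full run in the tens of seconds on one CPU.

## Known limitations

* The NB engine's dispersion estimate ignores the design when computing
  moments; strong case effects inflate dispersions slightly, which is
  conservative.
* Within-subject correlation of repeat samples is neither simulated beyond
  shared covariates nor modelled in the GLM.
* The Gaussian-bump effect model cannot express asymmetric onset/decay; the
  trajectory machinery itself is agnostic to the shape.
* Peak *height* comparisons across stages are affected by the different
  case quotas (9 vs 14 vs 18); the package reports counts per window and
  leaves cross-stage normalization to the analyst.
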