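# serumrna

Analysis pipeline for **prediagnostic serum RNA dynamics**: how circulating
RNA signals in blood serum evolve during the years before a lung-cancer
diagnosis, and when disease-related differential expression becomes
detectable.

The package is aimed at molecular-epidemiology studies built on serum
biobanks: repositories of serum samples donated years before donors were
diagnosed, with matched cancer-free controls. Because such cohort data are
typically access-restricted, the package ships a synthetic-cohort generator
that reproduces the statistical structure of this study design — exact
case margins over tumor stage, histology, sex and smoking, confounded
covariates, and time-to-diagnosis-dependent effects — with full ground
truth, so every stage of the pipeline is testable end to end.

## What it computes

Counts for RNA *i* in sample *j* are modelled as negative binomial,

```
y_ij ~ NB(mu_ij, alpha_i),        Var(y) = mu + alpha * mu^2
log mu_ij = log s_j + x_j' beta_i
```

with median-of-ratios size factors `s_j`, per-RNA dispersion `alpha_i`
(trend-shrunken method of moments), and a design `x_j` containing the
case/control indicator plus age (z-scored), sex, smoking, and blood-donor
group (a storage/handling batch factor). The case coefficient is tested per
RNA with a Wald statistic `beta / SE(beta)` against the standard normal and
adjusted by Benjamini–Hochberg within each analysis window.

Around this engine the pipeline provides:

* **Matching** — cohort-level frequency matching, and exact optimal 1:k
  age matching within analysis windows (min-cost bipartite assignment).
* **Windowing** — the 120-month prediagnostic span split into 7 fixed
  ~17-month windows, or swept by 17-month sliding windows with 2.5-month
  steps; per-window stage-balanced case quotas (27 pooled; 9/14/18 for
  early / locally advanced / advanced stage) with 5 matched controls each.
* **Phases** — (1) all cases vs all controls; (2) time-resolved fixed
  windows; (3) stage-specific windows with 20x resampling; (4) sliding-window
  trajectories, optionally stage- and histology-specific.
* **Trajectories** — per-window counts of differentially expressed RNAs by
  RNA class (miRNA, isomiR, piRNA, tRF, tRNA, ...), peak detection, and
  recurrence of RNAs across windows.
* **Enrichment** — hypergeometric over-representation of pathways among DE
  mRNAs and predicted miRNA/isomiR targets (prediction score > 60).

## Worked example

```python
import serumrna as sr

cfg = sr.StudyConfig()                     # the study design defaults
rna_ids, _ = sr.make_rna_features(500)

# inject a prediagnostic effect bump at 7 years (84 months) into 15% of RNAs
profiles = sr.make_signal_profiles(
    rna_ids, fraction=0.15, amplitude_log2=1.5,
    center_months=84, width_months=9, seed=0,
)
samples, counts, truth = sr.generate_cohort(
    cfg, n_rnas=500, signal_spec=profiles, seed=1000,
)

# phase 4: sliding-window differential expression trajectory
summaries = sr.run_phase(samples, counts, phase=4, cfg=cfg, seed=0)
traj = sr.build_trajectory(summaries, signal="effect")
peaks = sr.detect_peaks(traj, min_height=2, min_separation_months=24)
print(len(summaries), "windows, peak(s) at", peaks, "months before diagnosis")
```

Output:

```
42 windows, peak(s) at [83.5] months before diagnosis
```

i.e. the pipeline sweeps 42 overlapping windows across the 10-year span and
localizes the injected 84-month effect bump at 83.5 months — the nearest
window center (windows step by 2.5 months). On a null cohort (no injected
profiles) the same run yields a median of 0 differentially expressed RNAs
per window.

The same analyses are available from a shell:

```sh
serumrna simulate --seed 1 --out cohort/
serumrna run --phase 2 --counts cohort/counts.tsv --samples cohort/samples.tsv \
             --seed 1 --out phase2/
serumrna demo --seed 7 --out demo/        # end-to-end on a small cohort
```

Every command writes TSV outputs plus a JSON manifest (config snapshot,
seed, input digests, wall-clock).

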