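# cerebgraph

Graph analysis of intra-cerebellar resting-state functional connectivity,
from ROI-level BOLD time series to covariate-adjusted nodal group
statistics — with a synthetic-cohort generator that plants a known network
alteration so the whole chain can be validated against ground truth.

The package is aimed at neuroimaging researchers studying regional
connectivity changes in small clinical cohorts (the shipped defaults
emulate a cerebellar study of Friedreich's Ataxia patients vs. healthy
controls), and at methodologists who want a denoising → thresholding →
graph-metric → GLM pipeline whose every stage is unit-tested and whose
statistical operating characteristics are measured, not assumed.

## What it computes

Starting from per-subject ROI time series `X ∈ R^{T×R}`, motion parameters
and WM/CSF nuisance signals:

1. **Denoising** — drop the first 5 volumes; replace frames whose
   framewise differential signal exceeds 9 z; regress out the 6 motion
   parameters and WM/CSF; zero-phase band-pass 0.008–0.09 Hz.
2. **Motion QC** — subjects with mean relative RMS ≥ 0.20 mm, or any
   displacement > 2.0 mm / rotation > 2.0°, are excluded; a subject ledger
   (enrolled → refused → quality → motion → analyzed) is conserved and
   validated.
3. **Connectivity** — Pearson correlation matrix per subject, binarized at
   a fixed network cost: the strongest 20% of the N(N−1)/2 pairs become
   edges (65 of 325 for the 26-ROI scheme).
4. **Graph measures** (from-scratch, oracle-validated) — nodal degree,
   nodal/network global efficiency `E_i = ⟨1/d_ij⟩_j`, local efficiency
   (efficiency of the neighbor-induced subgraph), betweenness centrality
   (Brandes, normalized by (N−1)(N−2)/2), clustering coefficient,
   average path length over reachable pairs.
5. **Statistics** — per (node, metric) GLM
   `value ~ 1 + group + age + sex + mean_rms`, effect size = adjusted
   group coefficient in metric units, Benjamini–Hochberg FDR across nodes
   within each metric; Pearson brain–behavior correlations within patients
   with Fisher-z 95% CIs, `tanh(atanh r ± 1.96/√(n−3))`.

Two cerebellar parcellations ship as label lists: a 26-ROI anatomical
scheme (AAL3-style lobules and vermal segments) and a 17-ROI functional
scheme (Buckner network labels).

The synthetic generator draws each subject's time series from a
subject-specific ground-truth correlation matrix (fixed population
backbone + individual jitter), attenuates the edges of designated
"affected" ROIs in patients, adds group-specific head motion and confound
leakage, and couples a cognitive score to each subject's *true*
affected-node efficiency — so effect recovery, null calibration and
correlation recovery all have defined targets. See `docs/methods.md`.

## Worked example

```python
from cerebgraph import CohortConfig, RunConfig, run_pipeline, report

config = RunConfig(out_dir="demo_run", simulate=CohortConfig(seed=1), seed=1)
result = run_pipeline(config)
print(report(result))
```

prints

```
# cerebgraph run summary

## Subject ledger
- enrolled: 37
- refused: 0
- quality-excluded: 0
- motion-excluded: 5
- analyzed: 32

## Demographics
- age: t = 0.57, p = 0.57 (Bartlett p = 0.92)
- sex: chi-square = 0.14, p = 0.71

## Significant nodal differences (q <= 0.05)
- Vermis_8 / clustering: effect -0.514 (p = 9.5e-05, q = 0.00257, patients_lower)
- Vermis_8 / degree: effect -5.706 (p = 4.43e-05, q = 0.0012, patients_lower)
- Vermis_8 / global_efficiency: effect -0.484 (p = 1.45e-08, q = 3.92e-07, patients_lower)
- Vermis_8 / local_efficiency: effect -0.637 (p = 3.31e-06, q = 8.93e-05, patients_lower)

## Brain-behavior correlations (patients)
- Vermis_8 global efficiency vs verbal_memory: r = 0.58, n = 12, p = 0.0473, CI = 0.01-0.87
```

Reading: 37 subjects were simulated (17 patients, 20 controls); 5 lost to
motion QC (patients move more by design). The groups are demographically
comparable. The planted alteration — a 40% attenuation of every edge of
the vermal lobule-VIII node in patients — is recovered as reduced degree
(−5.7 edges), global efficiency (−0.48) and related measures at exactly
that node, with nothing flagged elsewhere; and the estimated efficiency of
that node correlates with the simulated verbal-memory score within
patients (the score was coupled to the *true* efficiency, so this is a
genuine recovery, not circularity).

The same stages are scriptable from a shell:

```sh
cerebgraph simulate --config cohort.yaml --out cohort/ --seed 1
cerebgraph run --in cohort/ --out results/ --seed 1
cerebgraph report --in results/
```

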