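# Methods

`cerebgraph` implements an intra-cerebellar resting-state functional
connectivity (FC) graph analysis operating on ROI-level BOLD time series,
together with a synthetic-cohort generator that plants a known network
alteration so every stage of the analysis can be validated against a
recoverable truth. This note documents the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
validation does and does not establish about real data.

## Analysis pipeline

### Denoising

The chain is: drop the first 5 volumes (T1 equilibration), despike,
regress confounds, band-pass filter. Inputs are a `(T, R)` ROI time-series
matrix, a `(T, 6)` realignment-parameter trace (3 translations in mm,
3 rotations in degrees) and a `(T, 2)` nuisance matrix (white-matter and
CSF signals).

*Despiking.* The framewise differential signal at frame *t* is the RMS
across ROIs of the first difference `x[t] − x[t−1]`. Differentials are
z-scored over frames and frames exceeding 9 z (default) are replaced, in
every ROI, by the ROI's mean over clean frames. The z-score is computed on
the aggregate framewise differential, not per ROI: the quantity being
screened is a whole-frame artifact (motion, spike), which manifests as a
single scalar excursion per frame. A one-frame interior excursion makes
both the entering and the leaving differential outlying, so both
transition frames are replaced.

*Confound regression.* OLS of each ROI column on an intercept, the six
motion parameters and the two nuisance signals; the residual is, by
construction, orthogonal to every regressor, and the operation is an
idempotent projection. Regression precedes filtering so that the fit
cannot reintroduce frequencies outside the passband; the stage order is a
pipeline option.

*Band-pass filter.* Zero-phase frequency-domain filter, 0.008–0.09 Hz by
default, with raised-cosine transitions of width 0.002 Hz starting at the
band edges; the DC bin is always zeroed. A frequency-domain realization
has no filter-order or phase ambiguity and is bit-reproducible across
platforms. At TR = 2.5 s the passband retains roughly 40% of the Nyquist
range; this is the dominant loss of effective temporal degrees of freedom
in the pipeline (about 80 effective samples from 195 volumes).

### Motion quality control

Per-frame displacement is the RMS of the three frame-to-frame translation
differences ("relative" = successive differences; rotations are excluded
from this summary but covered by their own absolute rule). A subject is
excluded when the mean relative RMS is ≥ 0.20 mm (inclusive, by
convention), or any |translation| exceeds 2.0 mm, or any |rotation|
exceeds 2.0°, evaluated on the trimmed trace that matches the analysed
volumes. Exclusion reasons are enumerated per rule in the QC report.

### Connectivity and thresholding

FC is the Pearson correlation between denoised ROI time courses. Matrices
are binarized at a fixed network cost (edge density): with `N` ROIs and
`E = N(N−1)/2` unique pairs, the `k = round(cost · E)` pairs with the
largest correlation become edges (round half up; cost 0.20 on 26 ROIs
keeps exactly 65 of 325 pairs). Ranking is by *signed* correlation —
"strongest" in this FC tradition means most positive; an absolute-value
ranking is available behind a flag but is not the default. Ties at the
cutoff are broken by ascending (row, column) order so the graph is a
deterministic function of the matrix. The graph therefore depends only on
the ranking of the weights: any strictly increasing transform (e.g. a
Fisher z transform of the correlations) yields the identical graph.

### Graph measures

Six measures on the binary graph, all implemented from first principles
and validated against exhaustive and independent oracles:

* nodal degree: row sum of the adjacency;
* nodal global efficiency: mean over other nodes of `1/d(i,j)` with hop
  distances from BFS and the convention `1/∞ = 0`;
* network global efficiency: mean nodal global efficiency;
* local efficiency: network global efficiency of the subgraph induced by a
  node's neighbors (Latora–Marchiori convention; 0 for degree < 2). The
  alternative convention that measures distances in the full graph rather
  than the induced subgraph is *not* used;
* betweenness centrality: Brandes accumulation, endpoints excluded,
  normalized by `(N−1)(N−2)/2` so values lie in [0, 1];
* clustering coefficient: `2·T(v)/(k(k−1))`, 0 for degree < 2;
* average path length: mean hop count over *reachable* pairs; a graph with
  no reachable pair returns NaN. Cost-thresholded graphs at 20% density
  can be disconnected, so these disconnection conventions matter and are
  fixed here rather than left to chance.

### Group statistics

Each (node, metric) cell is compared between groups with the GLM
`value ~ 1 + group + age + sex + mean_rms` (group: patient = 1; sex:
M = 1). The reported effect size is the group coefficient — the
covariate-adjusted difference in the metric's own units — with a two-sided
t test. p-values are corrected by Benjamini–Hochberg FDR across nodes
*within each metric* (the common convention for nodal statistics; a
single pooled family is available as an option). A covariate with zero
variance (e.g. a single-sex subsample) is dropped with a warning; genuine
collinearity among informative columns is an error naming the columns.

Demographic comparability uses Bartlett's test followed by a two-sample
t-test for age and a chi-square test (no continuity correction) for sex.

Exploratory brain–behavior correlations are Pearson coefficients between
the estimated nodal global efficiency of significantly reduced nodes and
cognitive scores within patients, reported with 95% confidence intervals
from the Fisher z transform, `tanh(atanh(r) ± 1.96/√(n−3))`, and — being
exploratory — deliberately not corrected for multiplicity.

## Synthetic cohort generator

The generator emulates a two-group resting-state study: 17 patients and
20 controls with usable data, 200 volumes at TR = 2.5 s, ROI counts of 26
(anatomical cerebellar scheme) or 17 (functional network scheme).

*Ground truth.* A population backbone correlation matrix has constant mean
off-diagonal level (`base_correlation`, default 0.45) plus symmetric
Gaussian heterogeneity (`correlation_spread`, entry sd 0.15 — real FC
matrices are strongly heterogeneous, and heterogeneity is what makes
proportional thresholding non-degenerate). The backbone is drawn once from
its own seed (`backbone_seed`, default 42) and PSD-repaired (eigenvalue
clipping at zero, then rescaling to unit diagonal): the truth network is a
fixed property of the simulated population, so replicate cohorts re-sample
subjects from the *same* population rather than redrawing the universe.
In patients, every off-diagonal entry incident to an affected ROI
(default: the vermal lobule-VIII ROI, or the Control-A network in the
functional scheme) is multiplied by `1 − edge_attenuation` (default 0.4);
for a single affected node this is a congruence transform plus a positive
diagonal load, so positive semi-definiteness survives exactly.

*Subjects.* Each subject receives their own truth matrix: backbone plus
symmetric jitter (`subject_spread`, sd 0.05 — individual connectomes
differ) and a subject-specific attenuation drawn symmetrically around the
group value (`attenuation_subject_sd`, default 0.08; negative values mean
stronger-than-average edges, keeping the group means exact). Time series
are drawn by filtering spatially correlated innovations (Cholesky of the
subject truth) through an AR(1) recursion `x_t = φ x_{t−1} + √(1−φ²) e_t`
(φ = 0.3), which preserves the target cross-correlation in the stationary
limit while adding BOLD-like temporal smoothness. Confound leakage adds
standardized motion/WM/CSF signals into every ROI with loading-scaled
random weights (loadings 0.3), and white observation noise of sd 0.3 is
appended. The noise level reflects that ROI-averaged signals are
substantially cleaner than voxel data; it is part of the generator's
operating point and was chosen, together with the attenuation, so that the
planted single-node effect is detectable by design in a 17-vs-20 cohort —
the regime the emulated study reports.

*Motion.* A reflected Gaussian random walk (folded into ±3 mm/deg so the
absolute QC rules can trigger on both sides) with group mean step
amplitudes 0.054/0.022 mm and an across-subject spread of 45%, which
reproduces mean relative RMS distributions of ≈ 0.05 ± 0.02 mm in
patients vs ≈ 0.02 ± 0.01 mm in controls — including the occasional
subject crossing an exclusion threshold. Amplitude must vary across
subjects: a constant within-group amplitude would make mean RMS a perfect
group surrogate and confound the GLM's motion covariate.

*Behavior.* The cognitive score is `intercept + coupling × (subject's true
mean affected-node efficiency) + noise`. True nodal efficiency is defined
on the *weighted* subject truth matrix (shortest paths by Dijkstra over
lengths `1/w` on positive weights; efficiency = mean inverse distance):
the truth is a weighted object, and the weighted definition varies
continuously with the subject jitter, giving the coupling a well-defined,
recoverable target. (A binary-graph truth definition would be degenerate:
at attenuation 0.4 the affected node is isolated in every subject's
thresholded truth graph.) The default coupling (58 score points per
efficiency unit, noise sd 3) yields a true efficiency–score correlation of
≈ 0.5 under the default conditions.

*Demographics.* Ages ~ Normal(29, 10) truncated to [18, 60] in both
groups; sex F with probability 9/24 in both groups — the groups are
covariate-comparable by construction, mirroring the matched design of the
emulated study.

Determinism: a cohort is a pure function of its configuration; the same
seed yields byte-identical serialized cohorts.

## Validation experiments and problem sizes

The test suite runs three replicate studies (sizes chosen to keep the full
suite within a routine CI budget):

* **Null calibration** — 500 cohorts of 10 + 10 subjects with attenuation
  0: the fraction of (node, metric) cells at q ≤ 0.05 stays within the
  binomial envelope of the nominal 5% level (measured rate ≈ 0.1%: under
  a global null, BH controls the family-wise error, so per-node rejections
  are far rarer than 5%).
* **Planted-effect recovery** — 100 cohorts at the default operating point
  (attenuation 0.4, 17 vs 20): the affected node's degree and global
  efficiency are flagged as reduced (negative adjusted coefficient,
  q ≤ 0.05) in ≥ 80% of replicates, qualitatively matching a pattern of
  reduced degree/efficiency with no increases anywhere.
* **Behavior-correlation recovery** — 200 cohorts at attenuation 0.15 with
  subject sd 0.15 and coupling 32 (true r ≈ 0.5): the correlation between
  estimated affected-node efficiency and the cognitive score is positive
  in ≥ 90% of replicates. This experiment uses a moderate, heterogeneous
  attenuation because at 0.4 the affected node is nearly isolated in
  patients' thresholded graphs — a floor effect that leaves the estimated
  efficiency without dynamic range, which is a property of the operating
  point, not of the estimator.

## What the synthetic validation does not show

The generator produces stationary Gaussian signals with a single global
AR(1) constant; real BOLD has hemodynamic structure, non-stationarities,
physiological rhythms aliased into the passband, and spatially structured
artifacts that WM/CSF regressors only partially capture. Parcellations are
label lists: no spatial information, no signal mixing between adjacent
ROIs, no atlas misregistration. Passing the recovery experiments shows the
pipeline correctly propagates a connectivity alteration of the simulated
kind into nodal statistics at realistic sample sizes — not that effects of
this size exist or are detectable in any particular real cohort.

## Numerical conventions and degenerate inputs

* Constant ROI columns cannot be correlated: their rows/columns are set to
  0 with a warning rather than propagating NaN.
* `k = 0` edges after thresholding yields an empty graph with a warning.
* PSD repair is only applied when an eigenvalue is genuinely negative;
  already-PSD matrices pass through bit-unchanged.
* A numerically perfect correlation (|r| ≥ 1 − 1e−12) collapses its CI to
  the point {±1}.
* The ledger (enrolled → refused → quality-excluded → motion-excluded →
  analyzed) is validated at construction and again before any report is
  rendered; inconsistent counts are an error, not a footnote.
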