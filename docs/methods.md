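# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `cagedyn`, and what the synthetic-data tests do and do
not establish about real CAGE data.

## Data model and conventions

A CAGE library is a vector of non-negative integer tag counts over
promoters; a time course is a set of libraries at 0 (unstimulated baseline)
and 15–360 min after stimulation with one of two agonists. The baseline is
shared between agonists. The growth-factor-like course omits the 240-min
point, mirroring a library excluded by quality control in the emulated
design; the cytokine-like course has all ten points.

Expression is tags-per-million (TPM): counts scaled so each library column
sums to 10⁶. Fold changes are log2((x_t + 1)/(x₀ + 1)) on time-point mean
TPM — the 1-TPM pseudocount bounds ratios for silent promoters and makes
up- and down-regulation symmetric. Genomic intervals are 0-based half-open
(BED). Promoter names follow `pN@GENE`, rank 1 being the promoter of a gene
with the most tag support.

Two inclusive expression gates: differential testing uses promoters with at
least 5 tags summed over the course's libraries; motif-activity fitting
uses promoters reaching 10 TPM in at least one sample.

## Differential expression

Counts are modelled NB(μ, φ) with variance μ + φμ² and one dispersion φ
shared by all promoters.

**Common dispersion.** φ maximizes the summed conditional log-likelihood of
within-group counts given their totals (the Dirichlet-multinomial
conditional of sums of iid NB variables), over all groups with ≥ 2
replicates, via a bounded 1-D search on log φ (tolerance 1e-4, range
1e-6…20; estimates at the lower bound are reported as 0, i.e. Poisson).
Counts are first mean-scaled to the geometric-mean library size so depth
differences are not absorbed into φ. This deliberately replaces
quantile-based pseudo-count equalization with plain mean scaling; the
estimator's contract is the simulation suite (recovery of a planted φ = 0.1
within 15% from 5,000 promoters × two groups of four; Poisson data driven
to the boundary). With no replication anywhere φ cannot be estimated and a
user-supplied fixed value is required (the CLI suggests 0.1).

**Exact test.** For one promoter and two time points, group counts are
mean-scaled to the common effective library size and summed to pseudo-totals
a and b. Conditional on n = a + b, the null distribution of a is negative
hypergeometric with weights r_g = n_g/φ (group sizes n_g); as φ → 0 it
collapses to binomial(n, n_a/(n_a+n_b)). The two-sided p-value sums the
probabilities of all splits at most as likely as the observed one
("minimum-likelihood" two-sided rule); ties within 1e-12 relative count as
extreme, and p is clipped into (0, 1]. φ below 1e-8 is treated as 0 to
avoid overflow of r. The test is symmetric in the two groups and monotone
in imbalance at fixed total. Under a matched NB null with known φ the
empirical rejection rate at α = 0.05 lands in [0.035, 0.065] (10,000
promoters, 3 vs 3) — slightly conservative, as expected for a discrete
exact test.

**Multiplicity.** Benjamini–Hochberg step-up q-values are computed within
each pairwise comparison family (each unordered pair of time points), not
pooled across families, matching per-comparison usage of exact tests;
promoters at q < 0.05 are significant. The implementation is checked
against a brute-force transcription of the step-up definition and against
statsmodels.

An edgeR (Bioconductor) cross-check runs in the test suite on a small
simulated dataset: the dispersion estimate agrees within 30% and exact-test
p-values are rank-correlated at ρ ≥ 0.95. Bit-compatibility with edgeR is
explicitly not a goal.

## Response dynamics

Per-time tallies count promoters significant in the (0, t) family only —
"changed versus unstimulated cells". Responders for the partition are
promoters significant in ≥ 1 pairwise family with both times ≤ 360 min; the
partition is exact set algebra over the union, with percentages displayed
to one decimal (half-up).

The shape taxonomy is a reduced, fully parameterized stand-in (the richer
published taxonomies are not specified operationally). From the
t0-anchored significance flags and the log2FC profile:

- onset = first significant time; no significant time ⇒ `flat`;
- peak = significant time with the largest |log2FC| (so onset ≤ peak);
- `rapid_*` if onset ≤ 60 min, `early`/`long` if ≤ 120 min, `late_*`
  otherwise;
- "short"/returned: |log2FC| < 0.5 at every time ≥ 180 min (rapid branch)
  or at the last time (early/late branches), giving `rapid_short`,
  `rapid_long`, `early_standard`, `long`, `late`, `late_flat`;
- direction is `up`/`down` by the sign at the peak, or `biphasic` when the
  sign of log2FC differs between significant times.

All thresholds live in `ShapeParams` (defaults: 60/120 min onset bounds,
180 min return horizon, 0.5 log2 return threshold). The classifier is total
and deterministic. On high signal-to-noise synthetic courses ≥ 95% of
planted trajectories receive their planted call (biphasic plants are scored
by direction).

## Profile clustering

k-means with Euclidean distance on items × time profiles, Lloyd's algorithm
with k-means++ seeding, best of 25 restarts by inertia, deterministic given
the seed (scikit-learn's `KMeans`). Defaults: k = 10 for TF-promoter
expression profiles (log2FC versus baseline), k = 5 for motif activities
(already centered by the MARA fit). Zero-variance rows under the z-score
transform map to zero vectors rather than NaN. Cluster indices are
relabelled by centroid peak time so reports are stable; labels carry no
other meaning. The exact transform applied before clustering in the
emulated study is unstated; log2FC-vs-baseline is this package's declared
default, not an inference.

## Motif activity response analysis

The model: e₍p,s₎ = noise + c_p + c_s + Σₘ N₍p,m₎·A₍m,s₎, with Gaussian
noise of one standard deviation for all promoters. Expression enters as
log2(TPM + 1): the base matches the fold-change convention and the
pseudocount matches the normalization module; the underlying description
specifies only "the logarithm".

Fitting: E is double-centered (row means → c_p, then column means of the
residual → c_s); each site-count column is centered over regions so motif
terms cannot masquerade as sample offsets; activities solve the per-sample
ridge system A_s = (NᵀN + λI)⁻¹NᵀẼ_s with one shared Cholesky
factorization (the model couples nothing across samples). Each motif's
activity is then re-centered to zero mean across samples, the removed mean
being absorbed into c_p. At λ = 0 the minimum-norm least-squares solution
is used and requires at least as many regions as motifs. The noise scale is
RSS over effective residual degrees of freedom (P·S − (P + S − 1) −
S·Σᵢdᵢ²/(dᵢ²+λ), clamped ≥ 1); standard errors are noise_sd·√diag((NᵀN +
λI)⁻¹), constant across samples. Ridge regression with region-wise K-fold
cross-validation for λ replaces the Gaussian-prior machinery of the
original motif-activity framework, which is not specified in reimplementable
detail; the contract is recovery: median per-motif Pearson r ≥ 0.9 against
planted activities at P = 2000, M = 50, S = 10, noise 0.1, and exact
recovery (RMS ≤ 1e-6) in the noiseless λ = 0 case.

The per-motif dynamism score is z_m = √(mean_s (A_{m,s}/se_{m,s})²);
motifs with z ≥ 2 (default) are "dynamic". Compartment categories compare a
promoter fit and an enhancer fit over shared motifs: dynamic in one
compartment only → `enhancer_only`/`promoter_only`; in both with the
enhancer peak strictly earlier → `enhancer_before_promoter`, otherwise
`both_other`; in neither → `static`. Peak time defaults to the maximum
activity (an `absmax` variant serves trough-shaped dynamics). Both the
z-threshold and the peak convention are declared choices, not inferences.

**GC-rich caveat, by construction.** A motif whose site counts are (nearly)
constant across regions has a (nearly) zero centered column: its activity
is unidentifiable from this model and the ridge solution returns exactly
zero however strongly its targets respond. This reproduces the known
insensitivity of site-count regression to GC-rich motifs in CpG-island
promoters. `MaraFit.site_count_variance` exposes the per-motif column
variance so the failure mode is inspectable.

## Enhancer calling

A deliberately minimal stand-in for atlas-scale enhancer identification:
strand-split, sorted, non-overlapping signal bins; a minus bin pairs with
the first plus bin starting at or after its end within 400 bp (divergent
orientation; each bin consumed once, left to right); the merged locus must
have ≥ 1 tag on each strand and lie ≥ 500 bp from every supplied gene
interval. The pairing window and tag threshold are stand-in defaults —
adequate for generating an enhancer compartment for motif analysis, not a
reproduction of any published enhancer atlas.

## Synthetic data generator

The generator is the package's study-condition definition, not a tuning
surface. Defaults: 2,000 promoters (200 TF-flagged), 50 motifs, 3
replicates per time point, library size 10⁶, φ = 0.1, the two time grids
above, and agonist-specific responder fractions that skew toward rapid
shapes under the growth-factor-like agonist and later shapes under the
cytokine-like one.

Counts: baseline TPM is log-normal (log2 mean 6, sd 1.5). Responder
promoters follow named trajectory templates (rapid pulses, sustained
inductions, late waves, a biphasic dip-then-peak, and single-time pulses at
60 or 240 min for peak-time experiments) scaled by `effect_log2fc`. Mean
TPM per sample is renormalized to 10⁶ — a library sequences a fixed number
of tags, so induced promoters take reads from everything else — and counts
are NB via gamma-Poisson mixing (Poisson at φ = 0). Responders are planted
only among promoters with baseline in 20–60 pre-normalization TPM: they are
well expressed (power) but a small share of library mass, keeping the
compositional distortion of planted inductions below ~5% so recorded
trajectories match empirical fold changes. Truth records shapes,
trajectories, baselines and φ, sufficient to score any stage without
re-simulation.

The motif system draws N ~ Poisson(0.5) sparse site counts, assigns
activity archetypes (pulse at 60 min, ramp peaking 240 min, biphasic,
static) cyclically with per-motif amplitudes, centers activities per motif,
and assembles e = c_p + c_s + N·A + Normal(0, noise_sd) exactly —
Gaussian noise in log space, matching the MARA model, whereas counts are NB
on the raw scale, matching the exact test's model. The two noise
conventions coexist intentionally. An optional constant-site motif
(zero column variance) is available for the GC-rich demonstration.

Everything is deterministic given the seed (one `numpy` PCG64 stream per
simulation).

**What passing these tests shows — and does not.** Recovery on this
generator establishes internal consistency: the estimators invert the
models they assume, at realistic sizes and noise. Real CAGE data violate
those models in ways the generator does not emulate: promoter-specific
(tagwise) dispersion, compositional shifts from highly induced programs,
mapping and annotation artifacts, correlated replicates, motif collinearity
from shared sequence composition, and post-transcriptional effects on tag
counts. Headline constants from any particular study (responder counts,
partition percentages) depend on its libraries and are not reproducible
from synthetic data.

## Problem sizes and numerics

Simulation-backed tests run at 1,200–2,000 promoters with library sizes
1–2×10⁵ (per-promoter coverage ≈ a real library's, at a scaled-down
promoter universe), chosen so the full suite and the acceptance script each
complete in minutes on one CPU. Exact-test enumeration is linear in the
pooled pseudo-count; tail truncation is unnecessary at these depths.
Degenerate inputs are defined: zero totals give p = 1; empty filters warn
rather than fail; zero-variance profile rows z-score to zero; all-zero site
columns are dropped with a warning; λ = 0 with fewer regions than motifs is
an error instructing λ > 0.
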