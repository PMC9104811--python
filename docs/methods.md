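# Methods

This package re-implements, end to end and on synthetic data with known
ground truth, the statistical analysis of a randomized, double-blind,
placebo-controlled crossover probiotic intervention: task-fMRI brain
activity and connectivity during an emotional-attention paradigm, plus
16S-based fecal microbiota composition. This note documents the models,
the defaults and the design choices that were genuinely open.

## Task paradigm and regressors

The Emotional Attention Task (EAT) alternates face-emotion matching (ME)
and shape matching (MS) in four blocks ordered MS-ME-ME-MS. Each block is
20 trials of 5 s with no inter-stimulus interval (100 s), followed by a
10 s instruction screen and 10 s of crosshair fixation. With the
instruction/fixation pair placed after every block — including the last —
the run totals 4 x 120 s = 480 s (8 min), which matches the published
total; the alternative reading (instructions before each block) gives the
same total but would put instructions before any trial has occurred, so
the block-first layout was adopted.

Indicators are sampled on the scanner grid (TR = 2.5 s, 192 volumes) as
the fractional coverage of each half-open volume interval
[k·TR, (k+1)·TR), rather than point sampling; this is exact for a block
design and configurable.

The hemodynamic response is the canonical double-gamma: a positive lobe
(shape 6, scale 0.9 s, peaking at 5.4 s) minus 0.35 times an undershoot
lobe (shape 12, scale 0.9 s), truncated at 28 s and rescaled to unit
peak. Only the ME and MS indicators are HRF-convolved; the instruction
and fixation components enter the model as raw indicators, matching their
role as nuisance "indicator variables". All HRF parameters are
configurable through `HRFParams`.

## Session GLM

Per voxel,

    y = b0 + b1·t + b2·INSTR + b3·FIX + b4·(ME+MS) + b5·(ME−MS) + err

is fit by ordinary least squares; the drift regressor t is the 0-based
volume index scaled to [0, 1]. b5, the ME−MS contrast, isolates the
emotional response and is the tested coefficient (two-sided t with
df = n − 6; the direction of reported activations is not assumed). Group
maps pool subjects in a single fixed-effects regression in which the only
subject-specific term is an intercept — a rigid correction of individual
mean signal level that leaves the time course untouched. Zero-variance
voxels are assigned p = 1 and flagged rather than raised. No spatial or
temporal autocorrelation is modelled, consistent with the analysis this
package mirrors.

A region-averaged variant fits the same pooled model to per-label mean
timecourses of an integer atlas and applies Bonferroni over the number of
labels (0.05/246 for a 246-region parcellation).

## Cluster definition

Voxels with ME−MS p below a nominal threshold are clustered by DBSCAN in
voxel-index space with eps = 1.5 and minPts = 10; eps = 1.5 joins face
(d = 1) and edge (d = √2) neighbours but not corner (d = √3) neighbours.
An isotropic grid is required (anisotropic affines are rejected) because
index-space distances are only meaningful after resampling to a cubic
voxel (3 mm here). DBSCAN's border-point ambiguity is resolved
deterministically by sorting voxels lexicographically before clustering.
Clusters spanning several atlas labels are split into single-label
sub-clusters; each sub-cluster's peak is its minimum-p voxel with
lexicographic tie-breaking, and its activity profile is the plain mean of
its voxels' series at each volume.

The published voxel threshold is p < 1e-50, attainable only with the
original scan counts; the synthetic default is p < 1e-6, which at the
simulated SNR (amplitude 2, noise SD 1, 12 subjects pooled) passes every
planted voxel while admitting ~0.01 false voxels per study. The
threshold-map text in the source analysis labels the tested coefficient
"β4" while describing the ME−MS effect; this package thresholds the
ME−MS (b5) map.

## Intervention model

For each sub-cluster, both sessions' mean timecourses are stacked and

    y = b0 + b1·t + b2·INSTR + b3·FIX + b4·(ME+MS) + b5·(ME−MS)
        + b6·TREAT + b7·TREAT·(ME−MS) + err

is fit by REML with subject-level random effects on b4, b5, b6 and b7.
The random effects are modelled as independent variance components
(diagonal covariance): an unstructured 4 x 4 covariance is poorly
identified with ~22 subjects and two sessions. Treatment is coded 0 =
placebo, 1 = probiotic, so b7 > 0 means a larger ME−MS response under
probiotic. No session/period effect is included (none is part of the
modelled analysis). Inference on b7 is a Wald z test from the REML fit;
with a true interaction variance of zero this is close to nominal at 12
subjects (measured empirically in the acceptance suite), and slightly
conservative when the boundary variance component is estimated positive.
Optimisation uses L-BFGS with a derivative-free (Powell) restart on
non-convergence; if both fail the model is refit with random effects on
b5 and b7 only and flagged.

Screening across sub-clusters reports three tiers — nominal p < 0.05,
Bonferroni over all sub-clusters tested, Bonferroni over the predefined
ROI count (10) — plus Benjamini-Hochberg FDR values.

Sample-size planning uses the exact noncentral-t power of a two-sided
paired t-test and searches n upward; dz = 1, alpha = 0.05/10 and 80%
power give n = 18.

## Task connectivity

Sub-cluster series are linearly detrended and band-pass filtered at
0.008-0.09 Hz with a zero-phase (forward-backward) Butterworth filter,
order 2 per pass by default (configurable); measured response: < 2%
amplitude loss at 0.05 Hz, > 98% attenuation at 0.18 Hz. "HRF weighting"
is implemented as a simple weighted Pearson correlation whose weights are
the HRF-convolved indicator of the condition of interest (ME), rectified
and normalised to sum 1 — so volumes during and shortly after ME blocks
dominate. Whether the original toolbox used this simple weighting or a
gPPI-style variant is not recoverable; the simple form is implemented and
stated. Correlations are Fisher z-transformed, contrasted probiotic −
placebo with a paired t-test per ROI pair, and thresholded by seed-level
BH FDR: BH is applied within each seed's row (n_roi − 1 tests), a pair is
significant if it survives in at least one of its two rows, and its
reported q is the smaller row-wise value.

## Microbiome

Counts are aggregated to a taxonomic rank by summing ASVs sharing the
rank label (unclassified ASVs pool into an explicit bucket), and taxa
absent in strictly more than 85% of samples are removed, with the removed
taxa's per-group prevalence summarised so removals can be checked for
structure. Differential abundance per taxon is a zero-inflated negative
binomial with log link: count-model covariates TREAT, TIME and
TREAT x TIME, an intercept-only logit zero-inflation component, and a
log-library-size offset. The model is fit on raw counts with the offset
rather than on pre-normalised real-valued counts — normalising before a
count likelihood is ill-posed — and a compatibility flag rounds
normalised tables instead. If the zero-inflation estimate collapses to
the zero boundary or the ZINB optimisation fails, the taxon is refit as a
plain negative binomial and flagged. The interaction Wald p-values are
BH-corrected across taxa. Total-sum scaling to the median library size is
provided for the normalised route (the original normalisation method is
unstated).

Alpha diversity is Shannon H = −Σ p ln p (natural log) and Simpson
1 − Σ p² (the variant was not named; the common ecology default is
used). Before/after effects per arm use the Wilcoxon matched-pairs
signed-rank test; differential effects between arms use a Friedman test
across the four treatment x time cells. Beta diversity is Bray-Curtis
dissimilarity embedded by classical PCoA (double-centred Gram
eigendecomposition); negative eigenvalues are reported, never silently
dropped, and coordinates are returned for positive eigenvalues only.

## Ancillary paired statistics

Baseline correction is after − before per subject. The outlier rule is
applied once, verbatim from its idiosyncratic statement: a subject is
excluded when its minimum value exceeds the mean + 3.5 SD of all other
subjects' values (leave-one-out). The paired-test gate applies
Shapiro-Wilk at alpha 0.05 to the paired differences (whether the gate
was applied to differences or raw values was unstated); normal
differences get a paired t-test, otherwise Wilcoxon signed-rank, and the
report names the branch taken.

## Synthetic data

The BOLD generator plants rectangular activation blobs on a 20^3 grid of
3 mm isotropic voxels (192 volumes, TR 2.5 s, 12 subjects x 2 crossover
sessions by default). Planted voxels follow the intervention model
exactly: baseline 100, linear drift, ME+MS amplitude 1, ME−MS amplitude
2, interaction amplitude 0.3, white Gaussian noise SD 1, and
between-subject SDs (0.5, 0.3, 0.5, 0) on the four random slopes — the
zero default on the interaction slope matches the null-calibration
conditions; a nonzero value is configurable. Noise is white because the
downstream models assume independent errors; an AR(1) option exists for
robustness experiments and is off by default. Two 40-voxel (2 x 4 x 5)
blobs are planted by default, dense enough that minPts = 10 cores exist
at eps = 1.5. The synthetic atlas is a nearest-seed-point (Voronoi)
partition. The desk-scale geometry (about 150 MB per study held as
float32) runs the full pipeline in seconds.

The taxa generator draws NB counts (size k = 1, i.e., strongly
overdispersed), zero-inflated at pi = 0.15, with per-taxon baseline
log-means N(3, 1.5^2) and library sizes uniform on 15k-45k, for 22
subjects x 4 samples = 88 samples — the scale of the original cohort.
Planted interaction taxa shift the probiotics-after cell by a log-fold
effect. Under these heavy-tailed defaults a single replicate does not
guarantee that a planted taxon tops the FDR ranking; the positive-control
test therefore uses a moderate-dispersion configuration (k = 5, baseline
SD 0.8, pi = 0.1), which is stated explicitly in the test.

What the generators do not emulate: anatomy and tissue contrast, head
motion, physiological noise, spatial smoothness of BOLD noise,
phylogenetic correlation between taxa, and compositional coupling across
taxa. Passing recovery tests therefore demonstrates correctness of the
estimators under their assumed models, not robustness to real-data
artefacts that the out-of-scope preprocessing would have to remove.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 replicates for mixed-model calibration and
recovery (12 subjects each), 200 + 500 replicates for ZINB recovery and
type-I error (88 samples each), 100 replicates for the connectivity
planted-pair check (20 ROIs, 20 subjects), and brute-force DBSCAN
equality on random instances up to 500 voxels — sizes chosen so the whole
suite runs in a few minutes on one CPU. Convolution is discrete and
causal with edge truncation at the run end; p-values are clipped away
from exact 0/1; perfect correlations are clipped at |r| = 1 − 1e-12
before the Fisher transform; DBSCAN ties and peak ties are broken
lexicographically.

## Known limitations

- External (non-synthetic) BOLD ingestion is wired through the NIfTI
  reader, but the packaged pipeline driver runs the synthetic study; a
  BIDS-directory driver is future work.
- The Wald z for the interaction ignores the finite number of subjects;
  a Satterthwaite correction is not implemented.
- Subject-level pairing is deliberately absent from the taxa interaction
  model, which tests the printed two-factor specification; a
  subject-effect extension is a clearly marked non-default idea, not
  implemented.
- The effect-size column reproduced in the intervention report is the
  Wald ratio b7/SE(b7); the unit of the original table's effect sizes is
  undefined, so no numerical comparison is attempted.
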