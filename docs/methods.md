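# Methods

This note documents the models, parameter choices, and numerical decisions
behind the package, and what the synthetic cohorts do and do not establish
about real data.

## Temporal cleaning

Cleaning operates on already-parcellated series in a fixed order: discard
the first 10 volumes (signal equilibration), polynomial detrend (default
linear; quadratic available for slow nonlinear drifts), optional confound
regression (generic regressor matrix — the confound set is a user choice),
then a zero-phase band-pass. The filter is a 4th-order Butterworth applied
forward-backward (`sosfiltfilt`), so in-band signal is not phase-shifted;
the default band 0.01–0.08 Hz is the conventional resting-state range, and
validity is checked against the Nyquist frequency 1/(2·TR). `band=None`
skips filtering, which the tests use to isolate the detrending step.
Missing values are rejected rather than imputed: silent imputation distorts
connectivity estimates downstream. Volume-space preprocessing (slice
timing, realignment, spatial normalisation, smoothing) is assumed done
upstream; the synthetic generator produces parcel series directly.

## Gradient mapping

Units of analysis are parcels. Two modes exist: per-network (units = one
canonical network's parcels, profiles = their Fisher-z connectivity to all
parcels) and whole-cortex (profiles = the full Fisher-z matrix). The
self-connectivity entry of each profile row is set to 0, i.e. excluded
from the similarity computation.

Affinity: per profile row, the strongest `ceil(0.10 · n_columns)` entries
are retained (row-wise top-10% sparsification, the convention of the
gradient literature); cosine similarity between sparsified rows; negative
cosines clipped to 0 so the matrix is admissible for a Markov
normalisation; symmetrized as `(A + Aᵀ)/2`.

Embedding: anisotropic normalisation `W' = D^−α W D^−α` with α = 0.5
(balancing local and global geometry), row-normalisation to a Markov
operator `M`, eigendecomposition through the conjugate symmetric operator
`S = D'^−1/2 W' D'^−1/2` (dense `eigh`; eigenvectors of `M` recovered as
`D'^−1/2 · eigvecs(S)`, identical eigenvalues). The trivial λ = 1 constant
eigenvector is dropped. Diffusion time t = 0 leaves components unscaled;
t > 0 scales by `λ^t`. Variance explained is defined as `λᵢ²/Σλ²` over the
retained non-trivial components. A disconnected affinity (zero-degree
row) is an error, not silently patched.

Alignment: the group template embeds the elementwise mean connectivity
matrix; individual embeddings are aligned by orthogonal Procrustes
(rotation/reflection on column-centered matrices, no scaling), z-scored
per component, and oriented so the somatomotor-network mean of gradient 1
is negative (a deterministic reporting convention; sign is otherwise
arbitrary). No spatial smoothing of gradients is applied — no kernel would
be principled at parcel resolution.

Dispersion reports both readings of "gradient dispersion": within-network
(sum of squared Euclidean distances of members to the network centroid in
the first three components) and between-network (pairwise centroid
distances); empty networks are excluded.

## Dynamic connectivity states

Windows default to 50 TR (≈100 s at TR = 2 s) with step 1 — short enough
to resolve state transitions, long enough for stable correlation
estimates. With T retained volumes the window count is
`W = floor((T − L)/step) + 1`; 230 volumes give 181 windows. A rectangular
window is the default; a Gaussian taper (sd = L/6) is available. Per
window: Pearson correlation, Fisher z (|r| clipped at 1 − 1e−7 before
atanh), vectorized upper triangle.

Clustering pools windows across all subjects of both groups, so states are
shared configurations; k-means uses k-means++ initialisation, 50 restarts
by default, and the best SSE. The cluster number is scanned (default
2–20) and chosen by elbow candidates — k values where the SSE curve has a
positive second difference, anchored at the low end by the closed-form
k = 1 total scatter — refined by maximum silhouette, ties broken by larger
Calinski-Harabasz and then smaller k. For large window pools the
silhouette is evaluated on a seeded subsample (default 2,000 windows); the
exact all-pairs computation is available and is what the definitional
oracle tests use. Distances are Euclidean on z-edge vectors, consistent
with the SSE objective.

Temporal metrics per subject: FO (fraction of windows per state), MDT
(mean run length in windows and seconds), NT (label changes). MDT of an
unvisited state is missing data and is excluded pairwise from group
comparisons; FO = 0 is retained. Per-state edge contrasts average each
subject's windows within the state, then run the covariate-adjusted
contrast per edge with BH-FDR; subjects lacking the state are excluded and
logged, and a group reduced below 3 subjects is an error.

## Group statistics

The covariate-adjusted contrast fits `feature ~ intercept + group +
covariates` by least squares, vectorized across features; with no
covariates it reduces exactly to the pooled-variance two-sample t-test
(verified to 1e−6). The group indicator's reference level is configurable
(`baseline`), so reported signs follow the cohort convention (AD − HC).

Multiplicity: BH-FDR (statsmodels step-up, monotone-enforced) applied
within each network's feature set by default, with a global option.
Family-wise control is a max-|t| permutation test: group labels are
permuted, the adjusted t recomputed for every feature, and each observed
|t| referred to the null distribution of permutation maxima, with
`p = (1 + #{max ≥ |t|})/(n_perm + 1)`. Label permutation is exact under
exchangeability when covariates are independent of group, which the
generator's matched design guarantees; Freedman–Lane residual permutation
would be the refinement if covariates were confounded with group.
Random-field cluster correction is deliberately not implemented: features
here are parcels, not smooth voxel lattices, so a permutation family-wise
bound is the appropriate guarantee.

Clinical correlations use Pearson or Spearman, chosen per variable pair by
a Shapiro-Wilk normality screen (either vector failing at p < 0.05 →
Spearman); the choice is recorded in the output.

## Classification

A linear SVM (regularisation C = 1, the conventional default) under
leave-one-out cross-validation: per fold, features are standardized using
training-fold statistics only (a unit test recomputes a fold by hand to
verify no leakage), the held-out subject's decision score is recorded, and
the confusion matrix accumulates over the N folds. The ROC and AUC are
computed from the pooled held-out scores; AUC uses the Mann-Whitney rank
formulation with midrank ties, and is reported on [0, 1]. Metrics with a
zero denominator are undefined (`None`), never 0. Feature importance is
the mean absolute weight across folds. Class imbalance is left unweighted
by default.

## The synthetic cohort generator

The generator is the package's substitute for clinical fMRI and defines
the study conditions of every recovery test.

**Baseline covariance.** Parcels carry a latent axis `g` (default
`linspace(−1, 1, P)`, parcels ordered by the seven canonical networks in
contiguous blocks). Coupling decays with axis distance,
`0.55·exp(−|gₚ−g_q|/0.75)`, plus a within-network elevation of 0.10 and
unit diagonal. The decay makes connectivity profiles vary smoothly along
`g`, so the top-10% sparsified affinity is a banded path graph and the
first diffusion component recovers the axis.

**States.** Each of K states adds a rank-one network-level coupling mode
`0.6 · v vᵀ`, where `v` is a ±1 Hadamard sign pattern over the seven
networks (rows 1..K of the order-8 Hadamard matrix, so every state pair
disagrees on about half the networks and all pairwise separations are
comparable), tapered to zero at network block boundaries so the local
couplings that carry the gradient are untouched. The sum is renormalized
to unit variance by a congruence, so positive semi-definiteness holds by
construction; the eigenvalue floor at 1e−8 is a guard. This design was
reached after block-multiplicative alternatives proved unable to support
gradient recovery and window-state separation simultaneously: signatures
on the large local couplings bend the diffusion manifold, signatures
confined to the small distant couplings drown in correlation-sampling
noise.

**Temporal structure.** States switch at epoch resolution (10 timepoints)
via a per-group Markov chain; within an epoch, timepoints are i.i.d. draws
from the active state's covariance, then AR(1)-smoothed
(variance-preserving, φ = 0.2) and corrupted with white noise (sd 0.25).
Chains default to the sticky form `(1−s)·I + s·1πᵀ` with stickiness 0.6
(mean dwell ≈ 25 TR), so a full scan averages over many state visits and
full-scan connectivity approximates the baseline — the regime gradient
analyses assume. Analyses that recover *window-level* state labels instead
pass stickier chains (0.95, dwell ≈ 270 TR ≫ the 50-TR window), because a
window spanning several states has no well-defined label; the ground-truth
window label is the state occupying the majority of the window.

**Group effects and covariates.** A planted effect re-wires target
parcels' coupling profiles toward the parcel at the opposite axis extreme
(blend weight = magnitude × per-subject severity, severity ~ N(1, 0.15)).
The gradient shift is emergent, not imposed, and is validated empirically:
at magnitude 0.7 the strongest target parcel shifts by |t| ≈ 4 in a
20-vs-20 cohort, with a genuine positive echo at the opposite end of the
axis (re-wiring one end perturbs the other end's profiles). Clinical
covariates are linear in severity plus Gaussian noise. Age and sex are
drawn independently of group (matched design); confounded designs require
explicit covariate construction.

**What the cohorts do not emulate.** No hemodynamic response convolution,
scanner noise physics, motion artifacts, or voxel-level volumes; noise is
Gaussian and stationary; states are exactly Markov at epoch scale.
Passing recovery tests therefore demonstrates that the *pipeline*
recovers planted structure of realistic magnitude under realistic sampling
noise — not that real AD cohorts carry effects of these sizes.

## Problem sizes and numerical choices

Recovery analyses use desk-scale cohorts chosen by design-phase power
analysis: gradient recovery at P = 100 parcels, 20 subjects, 240
timepoints; state-label recovery at P = 60, 20 subjects, 400 timepoints
(sticky chains); k selection at 10 subjects, 520 timepoints, window step 2,
scan k ∈ 2..8 with a 1,500-window silhouette subsample; the planted
FO-shift power analysis at P = 40, 2,000 timepoints, window step 10, with
a chain-level power calculation (predicted 0.94 at n = 20/20 for a 0.10
stationary-occupancy difference) preceding the full-path run. Calibration
checks use 200 replicates; the Benjamini-Hochberg empirical FDR under the
global null has true value exactly 0.05, with Monte-Carlo sd ≈ 0.015 at
200 replicates, which is why those tests run under fixed seeds.

Other numerical choices: Fisher z clips |r| at 1 − 1e−7; eigenvector sign
is fixed only at the reporting stage (somatomotor convention); Procrustes
alignment requires full column rank; PSD repair floors eigenvalues at
1e−8 and errors if the result is still indefinite; the k-means restart
protocol is matched across the k scan so SSE is non-increasing in k.

## Known limitations

- The per-network embedding mode embeds parcels, not voxels; voxelwise
  gradients of real volumes are out of scope.
- Window-level state labels are only meaningful when dwell times exceed
  the window length; the generator's fast-mixing default is intentionally
  the wrong regime for that purpose.
- The severity→gradient-score link is nonlinear and partially saturating,
  so planted clinical correlations attenuate through the pipeline.
- MDT estimates from finite scans are censored at run boundaries, biasing
  them slightly low for very sticky chains.
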