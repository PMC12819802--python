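# gradstates

Functional-gradient and dynamic-connectivity-state analysis of parcellated
resting-state BOLD time series, built around a synthetic cohort generator
that plants every structure the analysis is meant to recover.

## The problem

Two complementary views of resting-state organisation are combined in one
pipeline:

1. **Functional gradients.** Region-to-region connectivity profiles are
   compared by cosine similarity, and diffusion map embedding of the
   resulting Markov operator yields continuous axes of connectivity
   variation. The principal gradient typically runs from unimodal
   sensorimotor to transmodal association cortex. Per-subject embeddings
   are Procrustes-aligned to a group template, z-scored, and compared
   between groups (e.g. Alzheimer's disease vs healthy controls) with age
   and sex as covariates.

2. **Dynamic functional connectivity (dFC) states.** Pearson connectivity
   in sliding windows (50 TR, step 1), Fisher z-transformed and pooled
   across subjects, is clustered with k-means into recurrent connectivity
   states; the number of states is chosen by the elbow rule on the SSE
   curve refined by silhouette and Calinski-Harabasz diagnostics.
   Per-subject state sequences yield fractional occupancy (FO), mean dwell
   time (MDT) and number of transitions (NT), which are contrasted between
   groups, with per-state edge-level contrasts under BH-FDR and
   max-statistic permutation control. Significant gradient features feed a
   leave-one-out cross-validated linear SVM.

Real clinical fMRI is not distributable, so the package includes a
generative model (`gradstates.synthetic`) producing multi-subject parcel
time series with (a) a latent unimodal-to-transmodal connectivity axis,
(b) Markov-switching covariance states with group-specific transition
matrices, (c) planted group shifts in gradient scores, and (d) clinical
covariates linearly linked to the planted severity. Analytic expectations
(stationary occupancy, 1/(1−p_ss) dwell times) make every stage testable.

## The core methods

Diffusion embedding: given a nonnegative symmetric affinity `W`, with
degree matrix `D`, the anisotropic kernel is `W' = D^−α W D^−α` (α = 0.5);
the Markov operator `M` row-normalizes `W'`; eigenvectors of `M` (computed
through the conjugate symmetric operator) ranked by descending eigenvalue
give the gradients, the trivial constant eigenvector dropped, components
scaled by `λ^t` with diffusion time t = 0.

State metrics, for a window-label sequence: `FO_s` = fraction of windows in
state s; `MDT_s` = mean consecutive-run length of s (windows, or seconds =
windows × step × TR); `NT` = number of label changes. For the generating
chain these have closed forms: stationary π solves `πT = π`, and expected
dwell is `1/(1 − p_ss)`.

Classification metrics from the confusion matrix: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/N, precision = TP/(TP+FP), and
AUC via the Mann-Whitney rank formulation with midrank tie handling.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_cohort.py --seed 1   # 20 AD + 20 HC subjects
python analysis/02_preprocess.py                 # discard 10, detrend, band-pass
python analysis/03_gradients.py                  # embed, align, z-score
python analysis/04_dfc_states.py                 # windows, k scan, FO/MDT/NT
python analysis/05_group_stats.py                # contrasts, FDR, permutation
python analysis/06_classify.py                   # LOOCV linear SVM
```

With seed 1 this prints, along the way:

```
cleaned 40 subjects: 240 -> 230 volumes, detrend order 1, band 0.01-0.08 Hz (zero-phase)
40 subjects embedded; template variance explained (top 3): [0.176 0.174 0.168]
gradient-1 contrasts (AD - HC, age/sex adjusted): 2/60 parcels at q<0.05, 2 family-wise significant
state-metric contrasts: 5 of 16 at p<0.05 (state 1 fo, state 1 mdt_windows, ...)
LOOCV over 40 folds, 2 gradient features
confusion TP=20 FN=0 TN=16 FP=4
accuracy 90.00%  sensitivity 100.00%  specificity 80.00%  AUC 0.865
```

Reading the output: the cohort plants a severity-scaled re-wiring of five
transmodal (default-network) parcels in the AD group. The group contrast
recovers the strongest planted parcel (negative gradient-1 shift, t ≈ −4.4,
family-wise p = 0.002) plus its echo at the sensory end of the axis
(positive shift — re-wiring one end of the axis necessarily perturbs the
other end's profiles). Those two parcels alone separate the groups at 90%
LOOCV accuracy. Each driver writes its tables under `results/`.

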