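# Methods

This note documents the models, estimators and design choices behind
`cohgraph`, in the order the pipeline applies them, together with the
assumptions each stage makes and what the synthetic tests do and do not
establish about real recordings.

## Recording model and montage

All stages assume the fixed 19-site 10–20 montage (Fp1/Fp2, F3/F4,
F7/F8, Fz, C3/C4, Cz, T3/T4, T5/T6, P3/P4, Pz, O1/O2), a 200 Hz
sampling rate, and amplifier band-limiting to 0.5–30 Hz. Channel order
is fixed alphabetically so matrices and tables align positionally
everywhere. Electrode geometry is the unit sphere: the 15 sites the
10–20 system places directly on the cardinal circles are given their
angular coordinates, and F3/F4/P3/P4 are constructed as spherical-arc
midpoints of their defining neighbors (e.g. F3 midway between Fz and
F7), which is how the 10–20 system itself defines them. No realistic
head geometry is modeled; see Limitations.

## Artifact removal

The 19-channel record is decomposed with FastICA (full rank by
default; seeded, so deterministic given the config). Components are
flagged by deterministic heuristics replacing expert visual judgment:

* **ocular** — |correlation| of the component's scalp projection with a
  frontal-pole-dominant pattern (Fp1/Fp2 weighted 1.0, F7/F8 0.45,
  F3/F4 0.15) above 0.7;
* **muscular** — fraction of component power above 15 Hz exceeding 0.6;
* **transient** — excess kurtosis of the time course above 10.

All three thresholds are configurable. Flagged components are zeroed
and the record reconstructed; with no flags the reconstruction is the
identity up to numerical tolerance. Rank-deficient input (a constant
or duplicated channel) is rejected because whitening is then
degenerate. No amplitude-based epoch rejection is applied: the
decomposition step is the only artifact control, and simulated trials
are flagged "correct/incorrect" only by the event log.

## Epoch selection

Epochs span −100…+900 ms around stimulus onset (200 samples at
200 Hz). Only correct trials are used, earliest first, and the same
number (default 57) is taken per subject so cohort members contribute
equally. Requesting more epochs than there are correct trials is an
error naming the deficit.

## Surface Laplacian

A spherical-spline surface Laplacian (spline order m = 4,
regularization λ = 1e−5, Legendre series truncated at 50 terms)
estimates the second spatial derivative of the scalp potential at
every electrode, suppressing volume-conduction smearing before
coherence estimation. The constrained spline system is factorized once
and applied to all time samples. The operator is linear, reference-free
(insensitive to a common offset) and maps spatially constant fields to
zero — all verified by tests. Output units are proportional to current
source density on the unit sphere; no head-size calibration is applied,
which is irrelevant downstream because MSC is scale-invariant per
channel.

## Coherence estimation

MSC is estimated with one segment per epoch: each 200-sample epoch is
Hamming-windowed, zero-padded to nfft = 256 (frequency spacing
200/256 = 0.78125 Hz), and cross-/auto-spectra are averaged across
epochs before forming the ratio. The DC bin is dropped. At least two
epochs are required — a single segment gives the degenerate estimate 1
everywhere. For independent signals the estimator's bias is ≈ 1/n
segments, which the tests verify at n = 10 and 57.

Band matrices are the arithmetic mean of the MSC over the bins inside
the closed band interval; a bin on a shared edge (e.g. 8 Hz) belongs to
both adjacent bands, consistent with treating band ranges as
approximate at 0.78 Hz resolution. The mean-over-bins form is used
rather than a 2/Fs-scaled integral because only the mean keeps band
values inside [0, 1].

## Thresholding and normalization

Per subject and band, the threshold U is the midpoint of the
off-diagonal [min, max] range. Entries below U become exactly 0;
survivors are divided by the off-diagonal maximum, so the surviving
maximum is 1. Sub-threshold entries are zeroed (not the graph
binarized) because downstream tables and rule thresholds require
non-integer weighted metrics; a `binarize` option exists for
sensitivity analysis. The all-equal off-diagonal case is handled (all
entries survive and normalize to 1) and logged as degenerate. The
transform is invariant to positive rescaling of the coherence matrix.

## Graph metrics

The connectivity matrix is an undirected weighted graph (edge iff
weight > 0). Per vertex: weighted degree d_v (sum of incident
weights), neighbor-edge weight E_v (sum of weights among the
neighbors), and clustering coefficient C_v = 2 E_v / (k_v (k_v − 1))
with k_v the *binary* neighbor count, 0 when k_v < 2. Using the binary
count in the denominator is the module's principal interpretive
decision: with a weighted denominator the ratio is unbounded, whereas
the binary count bounds C_v by 1 (each of the k_v(k_v−1)/2 possible
neighbor edges has weight ≤ 1) and reduces to the classical clustering
coefficient on binary graphs — the only reading consistent with
weighted non-integer degrees and rule thresholds ≤ 1 appearing
together. A fully binary mode is provided.

## Cohort screening and experiments

Silhouette scores treat the achievement labels as fixed clusters
(Euclidean distance over the 19 electrode features; members of
singleton clusters score 0 by convention). A participant is flagged in
a table variant when their score is ≤ 0 *and* more than 70% of that
variant's participants score > 0 — the second condition prevents
removals from variants that are not cohesive enough for a non-positive
score to mean anything. The positive fraction is computed on the full
variant membership, not after provisional removals. Flags aggregate
across the 15 variants by union (outlier if flagged anywhere); a
minimum-variant-count alternative is configurable. Removal is applied
cohort-wide.

Experiments pair the classes six ways (HA-AA, HA-LA, HA-OA, AA-LA,
AA-OA, LA-OA) per table variant — 90 datasets. The OA ("other
achievement") side is drawn without replacement from the two
complementary classes, size-matched to the target class and split as
evenly as counts allow; for odd targets the extra member's source
class is a seeded coin flip, and if one class cannot supply its share
the deficit moves to the other. OA membership is drawn once per pair
and shared across the 15 variants so every feature space compares the
same participants. Dataset names follow the grammar
`Co<pair>_B<band>_G<metric>` and round-trip through a parser.

## Classification

The decision tree maximizes gain ratio over candidate thresholds at
midpoints of consecutive distinct feature values, with binary splits,
a minimum leaf size (default 2), and growth stopping at zero gain.
Ties resolve to the earlier feature column, then the lower threshold —
determinism over elegance. Pruning is pessimistic-error pruning at
confidence factor 0.25: each node's training errors are inflated to a
normal-approximation upper confidence bound (with the standard
small-count special cases) and a subtree collapses to a leaf when the
leaf's bound is no worse; no subtree raising is performed. The
release-8 MDL penalty for continuous attributes is off by default
(`mdl_penalty=True` enables it). Reference tools expose an internal
"3 folds" option that pessimistic pruning does not use; it is accepted
in configs for provenance and has no effect. Exact numeric agreement
with any particular historical C4.5 build is not a goal; the dialect
here is fixed, documented, and self-consistent.

Evaluation is repeated stratified k-fold cross-validation (default
10×10, re-shuffled per repeat from the seed), reporting the mean fold
accuracy (TP+TN over all outcomes) as a percentage with two decimals
and the aggregated confusion counts; the fold count drops to the
smallest class size (with a warning) when a class is too small. Each
leaf yields one conjunctive rule; the rule set partitions the feature
space and reproduces tree predictions exactly, which is tested on 10⁴
random probes. Class-average connectivity matrices summarize, per
class and band, the mean graph and the strongest-partner neighborhoods
of tree-selected electrodes.

## Synthetic data: what it emulates and what it does not

Each simulated recording is one stationary Gaussian process
synthesized on the full-record frequency grid: 1/f-shaped (default
exponent 1.0) noise exactly band-limited to 0.5–30 Hz, scaled to
~20 µV RMS. Within the planted band the planted electrodes share a
common source with mixing chosen so the planted MSC is analytically
exact (sharing amplitude a = c^(1/4) ⇒ MSC = c). The planted interval
is widened by a 0.5 Hz guard — half the 1-s epoch resolution — so the
estimator's band-edge bins are not diluted by mainlobe leakage from
incoherent neighbors; the guard means a band's closing edge bin in the
*adjacent* band is partially coherent, consistent with shared band
edges. Trials sit in non-overlapping slots (1-s window plus 0.2 s pad
each side) and all simulated responses are correct. Default couplings
0.2 / 0.45 / 0.8 for HA / AA / LA place class differences in the alpha
band at T3–Cz.

Artifact templates are stereotyped: a ~300 ms frontal-dominant blink
(≥80% of spatial weight on Fp1/Fp2/F7/F8, 120 µV) and a ~500 ms
temporal-region burst above 15 Hz (40 µV). Injection superimposes them
at seeded uniform onsets at a given events/minute rate.

The feature-level generator draws Gaussian electrode values around a
baseline (default mean 0.55, SD 0.06 — the clustering-coefficient
scale) with class-specific offsets at the planted electrodes, clipped
to [0, 1]. The outlier-cohort generator places each class in a tight
ball in feature space and relocates designated participants to a
foreign class's ball; its defaults build an 18/20/19 cohort with
3/6/4 planted outliers, leaving 15/14/15 after screening.

None of this reproduces real EEG: no event-related potentials, no
nonstationarity or drift, no volume conduction (so the Laplacian is
exercised only for its operator properties, not its physiological
benefit), no realistic artifact morphology variability, and Gaussian
class structure in feature space. Passing tests therefore establish
the pipeline's *correctness and recoverability* — that planted effects
of known size are found where they were planted — not classification
performance on real cohorts.

## Problem sizes and numerics

The test suite and the acceptance script size their simulations for
desk-scale runs: full-cohort bookkeeping uses 57 subjects at 8 epochs
each (counts do not depend on epoch number), parameter recovery uses
15 + 15 subjects with a 3-SD single-electrode offset over 50 seeded
fits, the chance-level check uses 20 seeds of 10×10-fold CV, and the
estimator-bias check uses 10 and 57 epochs of white noise. Exhaustive
oracles cover all binary graphs on ≤ 6 vertices, random cohorts of
≤ 10 for silhouettes, and datasets of ≤ 8 instances for split
selection. Numerical tolerances: MSC clipped to [0, 1] and symmetrized
exactly; spline Laplacian solved through one LU factorization;
silhouette agreement asserted to 1e−10; rule/tree agreement exact.

## Known limitations

* The spherical-spline Laplacian on an idealized sphere replaces any
  realistic-geometry operator; absolute output scale is arbitrary.
* ICA component flagging is heuristic; on real data the thresholds
  would need tuning against expert-labeled components.
* The C4.5 dialect is one fixed, documented variant; accuracies are
  not expected to match other implementations digit-for-digit.
* Coherence is the only connectivity estimator (no imaginary
  coherence, PLV or phase-lag index), and no statistical significance
  thresholding of coherence values is performed — the dynamic midpoint
  threshold is a per-subject normalization device, not a test.
* EDF files are read (via mne) but not written; delimited text plus a
  JSON sidecar is the native on-disk format.
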