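# Methods

This note documents the models and procedures `odorkit` implements, the
defaults it ships, the numerical choices that matter, and what its
synthetic-data tests do and do not demonstrate.

## Data model

A compound record is keyed by canonical SMILES (RDKit canonicalization,
stereochemistry retained as written — relevant for chiral volatiles such as
menthyl acetate). Name inputs resolve through a local case-insensitive
lookup table (a small built-in table of common flavor volatiles, extensible
by the user); no network access occurs anywhere in the package. Records
sharing a canonical SMILES merge: descriptors union, threshold observations
pool, conflicting names keep the lexicographically first with the rest as
aliases. Unresolvable names and unparseable SMILES are dropped into a JSON
exclusion manifest rather than aborting a table.

## Descriptor curation

Raw odor descriptors are free text. Curation is data, not code: a YAML
`CurationConfig` holds five maps — synonym collapse, descriptor→category,
sparse-category merging (e.g. Dairy/Buttery → Sweet/Vanilla/Caramel;
Rancid/Sweaty/Animalic and Chemical/Solvent/Plastic → Off-flavor), a
priority order that picks one category when descriptors disagree (Fruity
outranks Green/Herbal, etc.), and a polarity map assigning each final
category a binary aroma contribution. The shipped defaults cover the
descriptor vocabulary common in flavor databases; the whole file is
user-editable and validated on load (every reachable category must have a
priority rank and a polarity). Two deliberate rules: category assignment
depends only on the descriptor *set* (order never matters), and "Odorless"
is an explicit descriptor-derived category — an empty descriptor list means
*unlabeled*, never odorless.

Thresholds are harmonized to mg/L, values ≤ 0 discarded, and multiple
literature observations collapsed per compound — median by default
(robust to outlier reports), with `policy="mean"` available for workflows
that average duplicates. The modeling target is y = −log10(t mg/L): larger
y = more potent odorant, and the transform makes threshold distributions
approximately normal.

## Featurization

- **ECFP4 / ECFP6**: Morgan circular fingerprints at radius 2 / 3 (the
  standard diameter naming), hashed to 1024 presence bits. Counts are
  folded to binary; a molecule and its disconnected duplicate can therefore
  coincide bitwise — documented saturation behavior.
- **MACCS**: the standard 167-key set (key 0 is a placeholder).
- **Physchem block**: [MW, Crippen logP, TPSA, Crippen molar refractivity],
  appended raw. Standardization of this block happens *inside* model
  pipelines, fitted on training folds only, so no validation statistics
  leak into scaling; fingerprint bits are never scaled.
- **Graphs**: heavy-atom graphs with one-hot element (C/N/O/S/F/Cl/Br/P +
  other), degree, and aromatic flag per node; undirected bonds stored once
  with bond order; the physchem 4-vector is appended at readout rather than
  to node features.

All featurization is a pure function of the canonical molecule: any SMILES
spelling yields bit-identical output.

## Scaffold split

Generalization is measured across chemotypes: compounds sharing a
Bemis–Murcko scaffold (ring systems + linkers, terminal chains stripped)
never straddle the split. The greedy direction fills the *training* side
with the largest scaffold groups first (deterministic tie-break by scaffold
key) until the next group would exceed (1−f)·N, then sends every remaining
group to validation. Rare scaffolds therefore validate — the harder, more
honest test. Consequences worth knowing:

- the achieved validation fraction is ≥ f and within (largest group − 1)/N
  of f; with singleton groups it is exact;
- all acyclic molecules (esters, aldehydes — common among volatiles) share
  the empty scaffold `""` and move as one indivisible group. This
  coarseness is deliberate and can dominate small corpora;
- the procedure is deterministic and row-order independent; a seed matters
  only in the optional shuffled-greedy mode.

## Model harness

Families: random forest and MLP (scikit-learn), GBDT (XGBoost), and a
graph-convolution family. Search domains are fixed grids (e.g. GBDT
n_estimators ∈ {300, 600, 900}, max_depth ∈ {4, 6, 8}, learning rate ∈
{0.03, 0.05, 0.1}, subsample ∈ {0.7, 0.9, 1.0}, colsample ∈ {0.6, 0.8,
1.0}, L2 ∈ {0, 1, 3}; MLP hidden sizes {(512,128), (256,128), (256,64)}
with log-spaced L2 and learning-rate grids). Randomized search draws 30
seeded configurations per family–scheme pair by default (configurable) and
scores each by 5-fold cross-validation on the training set only —
stratified folds for classification, plain k-fold for regression.
Selection: fold-mean macro-F1 for classification; fold-mean R² with RMSE
tie-break for regression; exact ties resolve to draw order. The winner is
refit on the full training set and evaluated once on the held-out
validation set; fingerprint–model combinations are ranked lexicographically
by (macro-F1, Accuracy, Macro-Precision, Macro-Recall).

Class imbalance is handled at training time only: the majority class is
downsampled to at most 5,000 instances (seeded, without replacement) and
inverse-frequency weights w_c = N/(K·N_c) are passed as sample weights
where the estimator supports them (tree families; the scikit-learn MLP does
not accept per-sample weights and relies on the downsampling). Validation
composition is never touched. Downsampling defaults apply to classification
only; threshold corpora are small and are used in full.

The decision cutoff for the binary contribution label is probability 0.5.

**Graph family.** Implemented as a simplified graph convolution: two rounds
of propagation through the symmetric-normalized adjacency with self-loops
(D^−1/2 (A+I) D^−1/2, edge weights = bond order), mean-pooled after each
round, concatenated with the physchem block, and fed to an MLP readout
whose width, learning rate, weight decay, and batch size come from the
searched domains. The propagation is parameter-free and deterministic, so
the dropout domain is accepted for interface compatibility but has no
effect. This family is a lightweight member of the benchmark, not a full
message-passing network with learned edge functions.

Artifacts persist as a directory (joblib params + JSON manifest with task,
scheme, family, config, training-data hash, seed, version) and reload to
bit-identical predictions; a version mismatch refuses to load.

## Evaluation

Classification: accuracy, macro-/weighted-F1, macro-precision/recall, ROC
AUC, average precision, Brier score, a 10-equal-width-bin calibration curve
(empty bins omitted), and row-normalized confusion matrices. Single-class
ground truth reports AUC/AP as NaN markers. Regression: R², RMSE, and RMSE
within target tertiles Low (≤ q1), Mid (q1–q2], High (> q2), where q1/q2
are the 1/3 and 2/3 quantiles of the validation targets.

**Quantiles** throughout use the conservative ceil(p·n) order statistic
("higher" interpolation): with |residuals| = 1..100, the 95% conformal
half-width is exactly 95. Points exactly at q2 fall in the Mid tertile
(inclusive upper bound).

**Conformal band.** Half-width q = the 95th-percentile order statistic of
absolute calibration residuals; an interval y ± q on the −log10 scale, i.e.
a multiplicative factor 10^±q on thresholds. The default workflow uses a
calibration set disjoint from evaluation, which yields the distribution-
free guarantee (coverage ≈ level, verified by Monte-Carlo in the tests at
n = 500 over 20 seeds). An in-sample emulation mode — scoring coverage on
the same residuals that set q — is available and flagged; its coverage is
mechanically ≥ level − 1/n and should not be read as a validity claim.

## Sensory panel estimation

The design is an ascending method of limits in a water matrix with a
single-bottle yes/no task (not 3-AFC), so the classical geometric-mean BET
estimate does not apply; the group threshold is instead the lowest tested
concentration at which ≥ 50% of the panel detects (≥ 10 of 20). If no level
qualifies, the estimate is censored "> max tested".

Uncertainty: resample the panelists with replacement (B = 10,000),
recompute the rule per replicate, and take the 2.5/97.5 percentiles of the
ordered replicate thresholds. Because replicate thresholds live on the
discrete dilution grid, percentiles use the inverse-empirical-CDF
(lower-value) order statistic, keeping CI endpoints on tested
concentrations. Censored replicates sort above the maximum tested
concentration; a CI endpoint landing there is reported as "> max". The
point estimate is the bootstrap median.

Published sessions usually report only per-concentration yes-counts.
`reconstruct_monotone` builds the unique detection matrix consistent with
non-decreasing counts under the assumption that each assessor has a
personal sensitivity and detects everything above it — exactly the
structure an ascending series elicits. This is an assumption, not data:
estimates derived from reconstructed matrices carry a
`monotone_reconstruction_assumed` flag in their output metadata, and
decreasing counts are rejected with a pointer to supply the raw matrix.
Intensity summaries use the n−1 SD denominator; a single rating reports
SD = 0 by convention.

## OAV ranking

Predicted y de-logs to t = 10^−y mg/L with conformal interval
[10^−(y+q), 10^−(y−q)]. OAV = concentration / threshold (both mg/L,
dimensionless, scale-invariant). Candidates rank novel-first (novelty =
canonical SMILES absent from the training corpus; structure match only),
then by OAV descending; when concentrations are missing, by predicted
threshold ascending — most potent first — with canonical SMILES as the
final key so the order is a reproducible total order. Positive and negative
predicted contributors are reported in separate sections.

## Synthetic data

Generators are pure functions of (spec, seed) and define the conditions the
test suite measures under:

- **Molecules** by template substitution (ring-system templates with one or
  two substituent slots × a fragment library), guaranteeing parseable
  SMILES and controllable scaffold-group structure (~3,000 enumerable
  structures under the default libraries). Sampling targets a positive-
  structure prevalence of 0.856 by default, mirroring the roughly 26,900 :
  4,500 positive:negative imbalance of curated contribution corpora.
- **Labels**: positive iff the molecule contains an aromatic ring, with
  optional flip noise ε. At ε = 0 labels are perfectly recoverable from
  structure (a trained GBDT reaches macro-F1 ≥ 0.95 held-out); at ε = 0.5
  there is no signal.
- **Thresholds**: y = −1.0 + β·physchem + N(0, 0.3) with β = (0.02, −0.35,
  0.015, 0.01), chosen so y spans a few log units over the library and the
  mixture distribution is near-normal (|skew| < 0.3 at n = 2000, checked in
  the tests at the library's enumerable scale).
- **Panels**: assessor sensitivities s_i ~ N(log10 t, 1/slope) detect c iff
  log10 c ≥ s_i, giving the cumulative-normal psychometric law
  P(detect) = Φ(slope·(log10 c − log10 t)) with per-assessor monotone
  profiles by construction. The estimator never sees this law — it applies
  only the 50% rule — so simulator recovery (within one 10-fold step in
  ≥ 90% of 200 runs at slope 2, n = 20) is a genuine check.

What passing these tests shows: the pipeline's algorithms are correct,
leak-free, and statistically calibrated under known generating processes.
What it does not show: performance on real volatiles. Real descriptor
corpora are noisier and vocabulary-rich, real thresholds carry matrix and
inter-laboratory variance that no linear physchem rule captures, and real
chemical space is far less clustered than a template library. Metrics on
synthetic corpora (often near-perfect, because the generating rules are
simple functions of the features) must not be read as expected real-world
performance.

## Problem sizes

Default test and validation runs use corpora of 50–800 synthetic molecules,
100-corpus split sweeps, 20-seed conformal checks at n = 500, 200-seed
panel recovery runs, and 10,000-replicate bootstraps — sizes chosen so the
full suite runs in well under a minute of compute per concern on a single
CPU while keeping every statistical check's Monte-Carlo error far from its
decision boundary.

## Known limitations

- The acyclic-scaffold group is indivisible; corpora dominated by acyclic
  volatiles split coarsely.
- The graph family is a fixed-propagation approximation (see above), kept
  out of benchmark conclusions.
- Name resolution is table-driven only; there is no structure elucidation
  or external lookup.
- Panel CIs from published marginal counts inherit the monotone-
  reconstruction assumption and are flagged as such.
- Water-matrix thresholds do not transfer to juice or food matrices without
  caution; matrix effects are out of scope.
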