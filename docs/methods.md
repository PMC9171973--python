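# Methods

## Model and workflow

A pharmacological affinity fingerprint (Ph-fp) is a binary vector over a
registry of bioassays. The registry is built from per-assay bioactivity
datasets: for each (target accession, organism, activity type) triple, the
actives (pX ≥ cutoff, pX = 9 − log10 of the standard value in nM) are
diluted with randomly sampled decoys at exactly 4:1, a random-forest
classifier is tuned and scored by ten-fold nested cross-validation with
the Matthews correlation coefficient, and only assays whose mean MCC
reaches 0.90 are retained. A compound's bit for a retained assay is the
strict-majority vote of 50 replicate models, each trained on an
independently drawn 90% subsample (without replacement) of that assay's
labeled data. The registry's canonical order — assay keys sorted
lexicographically — freezes the bit order of every fingerprint built from
it.

The two downstream evaluations mirror standard virtual-screening and
cluster-validation practice. Similarity search draws a query set (10 class
actives + 10 decoys per active) and a test set (the remaining class
actives + 10 decoys per active, hence an exact 1/11 active fraction),
scores each test compound by its maximum similarity to any query compound,
and summarizes the descending-sorted list by ROC AUC (Mann–Whitney form,
ties counted ½) and the enrichment factor EF(χ) = (P_χ/N_χ)/(P_tot/N_tot)
at χ = 0.10. Clustering operates on n × n similarity matrices
(Tanimoto for structural bit fingerprints, Rogot-Goldberg for Ph-fp,
Spearman for real-valued descriptor vectors), converted to distances
d = 1 − s, and is validated internally by the silhouette score and
externally against reference class labels by ARI and NMI.

## Key numerical conventions

* **MCC with a vanishing denominator is 0.** Any confusion matrix with an
  empty margin gives MCC = 0, the value of an uninformative classifier.
* **Rogot-Goldberg zero-denominator terms contribute 0.** This is forced
  by the index's defining behavior on the all-zero pair: the active term
  is 0/0, the inactive term is d/2d, and the total must be 0.5. Tanimoto
  of two all-zero vectors is defined as 0.
* **Majority-vote ties are inactive.** With 50 replicates, a 25/25 split
  yields bit 0 — the conservative call for an activity prediction.
* **Decoy exclusion is strict.** A candidate decoy is removed only when
  its Tanimoto similarity to some active exceeds 0.9; a candidate at
  exactly 0.9 stays eligible. The structural encoding used for this filter
  is configurable and defaults to the circular (Morgan) fingerprint, the
  sharper discriminator of the two structural encodings.
* **EF top-fraction size** is the nearest integer to χ·N with half
  rounding up, and never below 1. Under this rule a 21-active class whose
  11 test actives all rank first scores EF10 = (11/12)/(11/121) ≈ 10.08,
  i.e. EF10 can exceed 10 slightly — ceiling rounding would cap it at 10.
* **G-mean threshold ties resolve to the lowest qualifying score**;
  candidate thresholds are the observed scores, and a compound scoring at
  or above the threshold is called active.
* **S_c pooling.** The structural-diversity threshold S_c = Zσ + y pools
  all k·n nearest-neighbor similarities of a class (k = 5, Z = 0.5) and
  takes the pooled mean and sample standard deviation (ddof = 1), rather
  than averaging per-compound statistics.
* **Ranking ties** are broken by a seeded shuffle followed by a stable
  descending sort; AUC uses the tie-corrected rank statistic and is
  therefore independent of that shuffle.
* **Distance diagonals are forced to 0** even where the metric's
  self-similarity is below 1 (an all-zero Ph-fp has Rogot-Goldberg
  self-similarity 0.5). Linkage and silhouette require d_ii = 0;
  off-diagonal entries keep the metric's semantics.
* **Spectral clustering** forms L = D − W and solves the generalized
  problem Lu = λDu (equivalently the eigenproblem of the random-walk
  Laplacian D⁻¹L) with a dense symmetric solver — exact at the problem
  sizes this package targets (a few hundred compounds), so the
  `eigen_tol` hyperparameter is accepted and recorded for provenance but
  has no effect on the exact solve. The k-means step is seeded with 10
  restarts, best inertia kept. The RBF affinity is W_ij = exp(−γ(1−s_ij)²),
  i.e. the Gaussian of the derived distance with γ = 1/(2σ²); the kNN
  graph connects i and j when either is among the other's k most similar
  neighbors (union symmetrization) and weights edges by s_ij.
* **NMI** is normalized by the arithmetic mean of the two entropies
  (geometric available by flag). Spearman ties take average ranks.
* **Nested CV folds** are seeded shuffled K-folds without stratification.
  Shuffling is required because assembled datasets are ordered
  actives-then-decoys; a contiguous unshuffled fold would be single-class.
  A fold that still ends up single-class raises an error rather than
  silently producing a degenerate score; dataset sizes should make this
  event negligible (at the default sizes the probability is far below
  1%). The inner loop is a 5-fold grid search over the tree counts
  {20, 60, 100, 140, 180}; inner ties go to the smaller forest, and the
  replicate predictors reuse the modal inner-loop winner.

## Aggregation order

Duplicate activity records for the same compound and assay are averaged on
the nM scale first and converted to pX afterwards. Averaging on the linear
scale follows the convention of taking the mean of standard values; note
this is not equivalent to averaging pX values (geometric mean of nM).

One documented tension in the activity scale: the cutoff values 5, 6 and 7
correspond to 10 μM, 1 μM and 100 nM under pX = 9 − log10(value/nM). A
cutoff of 7 is sometimes glossed as "10 nM"; this package follows the
arithmetic, not the gloss.

The assay-size filter requires at least 50 *distinct actives* (the
stricter of the two natural readings of "50 distinct compounds"); the
count of compounds including decoys is five times that.

## Synthetic study conditions

The synthetic module generates the three pipeline inputs with a planted,
recoverable signal. Compounds are binary descriptor vectors of 32 bits:
five classes own four signature bits each, expressed with probability
`signal_strength` (default 0.95) in members of the owning class and
`noise_rate` (default 0.05) otherwise, over a Bernoulli(0.2) background.
Twelve assays are assigned round-robin to classes, each probing one
designated signature bit of its class; a record is active iff the bit is
set, with the label flipped at `noise_rate`. Active records carry a value
of 10 nM (pX 8, active at every cutoff) and inactive records ~316 μM
(pX ≈ 3.5). Decoys express signature bits at rate 0.02 only. The default
benchmark set has five classes sized 73/29/53/21/13 (189 compounds),
matching the class structure of the reference NPS compound panel; each
assay generates 80 candidate actives so that ≥ 50 survive label noise
with a comfortable margin.

The bit-pattern activity rule is intentionally representable exactly by
decision trees, so the MCC ≥ 0.90 retention path is exercised rather than
bypassed. What the generator does *not* emulate: real chemotype and
assay-value distributions, correlated descriptor noise, activity cliffs,
or property-matched decoys. Passing the planted-recovery tests therefore
demonstrates that the machinery is correct and well-calibrated on
recoverable signal — not that real bioactivity data will yield comparable
MCC, AUC or ARI values.

## Problem sizes

The end-to-end test trains 12 assays of ~360 compounds each under the full
nested-CV grid (≈ 3 100 forest fits) and builds 50-replicate fingerprints
for 189 compounds; it completes in a few minutes on one CPU. Unit tests
run on 2–3 assay configurations scaled to tens of compounds. Exhaustive
oracles cover all 4 096 ordered pairs of 6-bit fingerprints, all 6-element
ranked-list labelings, and the 203 set partitions of 6 points.

## Known limitations

* Ph-fp quality is bounded by the registry: classes whose targets are
  under-represented among retained assays produce sparse fingerprints, and
  the Rogot-Goldberg index then reads shared inactivity as similarity —
  all-zero compounds are indistinguishable from decoys.
* Leave-one-out averaging of clustering indices re-clusters n submatrices;
  it quantifies stability under single-compound deletion, not sampling
  variance.
* No structure standardization (salt stripping, neutralization, tautomer
  canonicalization) is applied beyond RDKit's default sanitization.
* The optional live-database adapters are out of scope; all I/O is
  file-based CSV/JSON.
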