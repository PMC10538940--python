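# Methods

## Representation and distance

All models, clusterings and filters operate on binary Morgan fingerprints:
radius 2, 1024 bits, chirality off by default (configurable). Structures
are standardized before hashing — counter-ions stripped with the RDKit
`SaltRemover` (salt list configurable) and the SMILES canonicalized — so a
salt form and its parent map to identical features. The canonical SMILES
dialect is whatever the RDKit build emits; model artifacts record the
fingerprint settings so cached features remain interpretable.

Distance is the Tanimoto (Jaccard) distance over bit sets. Degenerate
cases are fixed by convention: two empty fingerprints have distance 0,
empty versus non-empty distance 1. This avoids 0/0 while keeping the
distance a metric on non-degenerate inputs (triangle inequality is
property-tested). Bulk operations (nearest-active queries, clustering,
model features) run on dense matrices in blocks, so memory stays
proportional to the block size; a bit-packed cache format
(`VSFP` magic, n_bits header, row-major packed rows) supports streaming
very large libraries.

## Labels and folds

A compound is labeled active iff median(primary % inhibition) ≥ 35, the
retest median (when a retest exists) is also ≥ 35, and the PAINS flag
passes. Medians of an even number of replicates are the midpoint of the
two central values; % inhibition may be negative or exceed 100 (assay
noise is real and is not clipped). A record missing the required filter
flag is an error — structural-alert status is never defaulted to pass.
Compounds never retested are labeled from primary + PAINS alone, matching
the screening workflow in which only primary threshold-passers are
retested.

Cross-validation folds are built per source library: within each library
group, shuffled actives then shuffled inactives are dealt cyclically over
a seeded fold permutation. Per group, fold totals and fold active counts
each differ by at most one; the split is deterministic given the seed and
independent of record order. The tuning stage uses four runs confined to
folds 0–7 (test folds 4, 5, 6, 7, each trained on the other seven); the
selection stage uses folds 0–7 / 8 / 9 as train / validation / test. The
four tuning combinations are configurable; the default is one reasonable
instantiation of "four runs over the first eight folds".

## Model zoo

Five base classes behind one contract (`train_model` / `predict_scores`):
random forest classification (RF-C; no RF-R — regression forests on sparse
fingerprints grow impractically large and are excluded by design), XGBoost
classification and regression (XGB-C/XGB-R), and fully connected MLPs
(NN-C/NN-R, scikit-learn implementation, Adam optimizer; the grid exposes
layers, units, activation, learning rate and L2 `alpha` — the sklearn MLP
has no dropout, so L2 plays the regularization role). Classification
scores are P(active); regression scores are predicted % inhibition.
Training is deterministic given (spec, data, seed); single-class
classification training sets are an error.

The similarity baseline scores a query by its maximum Tanimoto similarity
to the training actives and ignores every inactive — it is the
hit-expansion / analog-by-catalog strategy, kept as a control.

Ensembles combine base models. Probabilities and % inhibition are not
commensurable, so regression members pass through a **frozen empirical-CDF
normalizer** fit on training-set predictions at build time. A plain
within-batch rank normalization would make a compound's score depend on
which batch it is scored in, breaking the batching-invariance contract of
streaming scoring; the frozen ECDF is monotone (rank-preserving) and
per-compound deterministic. Max-vote takes the elementwise maximum of
normalized member scores. The stacking ensemble trains bases on the
training folds, fits a regularized logistic meta-classifier on their
validation-fold outputs, then retrains every base on the complete training
data (training + validation folds) for final scoring.

Default hyperparameter grids are configuration data, deliberately small
(two settings per class) so the full tuning stage runs at desk scale;
larger grids are supplied through the YAML config.

## Metrics

NEF_F = A_s / min(A, s) with s = ⌈F·N⌉ (floor available as an option; the
ceiling is the default). Ties straddling the top-s boundary are resolved
by the deterministic ranking order — score descending, compound id
ascending — rather than fractional counting, for exact reproducibility.
ROC-AUC and average precision are delegated to scikit-learn, whose
implementations carry the required semantics (pair counting with ties as
1/2; step-wise summation without interpolation); both are verified against
brute-force oracles on all instances up to N = 50 in the test suite.
Hit-rate tables report each selector, the union, the intersection and the
exclusive differences, with rates rounded to two decimals; set-algebra
consistency (counts and hits add up across regions) is property-tested.

## Clustering and diversity

Taylor–Butina leader clustering with an inclusive neighbor relation
(distance ≤ threshold). The algorithm is order-dependent in general, so
the candidate order is fixed canonically: descending neighbor count, ties
by id ascending. Each unassigned candidate becomes a centroid and absorbs
its unassigned neighbors; leftovers become singletons. The partition is
deterministic, input-order invariant, and every member lies within the
threshold of its centroid (property-tested, together with monotonicity of
the cluster count across thresholds 0.2 / 0.3 / 0.4).

Diversity statistics: *unique cluster hits* = clusters containing ≥ 1 hit;
*novel cluster hits* = clusters containing hits but no previously known
active. Actives are binned as weak [35, 50), moderate [50, 75) and strong
[75, ∞) % inhibition by default (bins configurable) for the
cluster-by-category contingency table; the exact association test itself
is delegated to standard statistical routines.

## Selection workflows

*Union purchase list*: each model nominates its top-N (default 1500), a
user-supplied attribute predicate (cost, delivery, vendor — no vendor
integration) prunes each list, the top per-model budgets (default 600) are
unioned. Hit accounting credits a model for any ordered compound in its
original top-N, not only its post-filter budget list. The confirmatory
hit call requires every replicate ≥ 50% inhibition (configurable
strict/inclusive boundary — sources differ on "exceeds" versus "at least")
plus a PAINS pass; a median-of-replicates variant covers the
dose–response-style follow-up screen.

*Diversity funnel*: cluster-novelty filter → structural filters →
distance-novelty filter (≥ 0.35 from the nearest known active, inclusive)
→ per-cluster top-scoring representative → greedy diversity picking.
Greedy picking is max-min by default ("most distant from the already
selected" read as maximizing the minimum distance, the standard MaxMin
picker; max-average is available as `maxavg`), first pick = highest score,
ties by higher score then id. The funnel emits a per-stage audit whose
counts must chain exactly; a stage that empties the candidate set raises
an error naming the stage. Structural filters are fail-closed: a filter
that cannot be evaluated (no rule catalog and no precomputed flag) is an
error, never a pass. PAINS and Inpharmatica rules come from the RDKit
FilterCatalog when SMILES are available; fingerprint-native pipelines use
precomputed flags. Lipinski passes with at most one violation of
MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10 (classic usage; the tolerance is
configurable).

## Synthetic libraries

The generator emulates the features of a primary screening deck that the
analysis relies on, without any real chemistry:

- **Chemotype series.** Templates are random 45-bit cores kept mutually
  farther than Tanimoto 0.6; members are the core plus symmetric bit-flip
  noise (1% per bit), so within-series distances are small and
  between-series distances large. A background fraction (30%) gets
  uniform sparse bits at a Poisson(45) popcount, emulating the long tail
  of unrelated singletons.
- **Imbalance by calibration.** A 10% minority of templates is active
  (potency drawn U(45, 95) mean, U(5, 12) SD of % inhibition). The number
  of active-series members is solved so that the *labeled* active fraction
  hits the target (0.13% by default) in expectation, using Gauss–Hermite
  integration of the label-pass probability (primary and retest medians
  both ≥ 35) over the latent potency distribution. An infeasible target is
  an error, not a silent shortfall.
- **Assay noise.** Each compound has a latent % inhibition; replicates add
  Gaussian noise (SD 8). Background potency SD (8.5) is set so the total
  single-readout spread is ≈ 35/3 — i.e. the 35% threshold sits at ~3
  standard deviations of the background readout distribution, as in large
  single-point screens. Primary passers (PAINS-passing) are retested,
  mirroring the screening workflow. 2% of compounds carry PAINS flags.
- **Activity cliffs are structural.** Each active template has a 12-bit
  deactivation motif; with probability `cliff_rate` (0.15) a member gets
  the motif and background potency. Inactives thereby carry learnable
  signal: a supervised model can use the motif, a pure similarity search
  cannot — which is the mechanism behind the expectation that the
  similarity baseline does not beat RF-C when cliffs are present.
- **Prospective libraries** mix training-series analogs, novel series, and
  background, with ground truth held behind an oracle (latent potency,
  PAINS status, simulated replicate assays) used only by tests and
  simulated confirmatory screens. Novel *active* series are scaffold
  hops: they inherit 60% of a training active core and stay ≥ 0.45 from
  every training core — close enough in substructure for a trained model
  to reach, far enough to form separate clusters at threshold 0.4. Novel
  inactive series are fresh random cores. Fingerprint-native generation
  is the default (no chemistry toolkit needed at test time); an optional
  SMILES mode emits scaffold+substituent structures (with counter-ion
  forms) to exercise the standardization path end-to-end.

What passing tests on these libraries do **not** show: real decks have
correlated fingerprints across series, heavy-tailed series sizes,
assay-specific artifacts, and actives whose neighbors-in-feature-space are
not neighbors-in-activity in more intricate ways than a single motif. The
synthetic results demonstrate that the machinery is correct and that the
pipeline recovers planted structure — not that any given model will enrich
a particular real library.

## Scaled-down study conditions

The reproduction studies (see `vscreen/studies.py`, driven by
`scripts/acceptance.py` and the acceptance tests) use problem sizes chosen
for a single-CPU desk run: parameter recovery trains on a 20,000-compound
library at 0.5% labeled prevalence and evaluates fold-9 NEF₁%; generator
calibration uses the default conditions at n = 100,000 (target 0.13%,
checked against the 99% binomial interval [101, 159]); the end-to-end
pipeline trains on 8,000 compounds at 1% prevalence (so every fold holds
enough actives for stable NEF at this scale), tunes the default mini-grids
(10 settings across 5 classes × 4 CV runs), scores a 100,000-compound
prospective library containing both analog and novel series, and funnels
the top 1% through the novelty/diversity stages to 50 picks. The 1% pool
depth is deliberate: a deeper pool dilutes the post-novelty stage with
low-confidence background clusters, which max-min picking then favors.
The funnel returns min(requested, available representatives) picks; at
unusual seeds fewer than 50 distinct novel clusters may survive.

## Known limitations

- The synthetic world has no real chemistry: no synthesizability, no
  property distributions, no scaffold hierarchy; the SMILES mode is a
  small combinatorial toy.
- The stacking meta-classifier is refit on stage-1 validation outputs but
  applied to retrained bases — the standard stacking approximation.
- NEF at very small test folds is coarse (one active in or out of the
  window moves it by 1/min(A, s)); at the default study scale most
  competent models saturate at NEF₁% = 1.0 and the AP tie-break decides.
- Streaming top-K and batch scoring are single-machine; distributing
  batches over a cluster is out of scope (the batching contract makes the
  scores independent of any such arrangement).
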