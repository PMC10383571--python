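# Methods

## Prediction task and data model

The package addresses four-class compound activity prediction: dual-target
actives (DT), single-target actives for each target of a pair (ST_A,
ST_B), and randomly selected, presumed inactive compounds (R). Class codes
are fixed as DT=0, ST_A=1, ST_B=2, R=3; all probability vectors are indexed
in this order and argmax ties break toward the smallest code. Structures
are stripped to their largest fragment and stereochemistry is discarded
before canonicalization — attributions are atom-level and stereo-agnostic,
so one canonical key per connectivity graph is the reproducible convention.

Activity-record curation mirrors standard database practice: records are
dropped when the activity comment contains a blocklisted phrase
("inactive", "not active", "inconclusive", "potential transcription
error"; case-insensitive substring match), the molecular mass is ≥ 1000 Da,
the potency type is not Ki/Kd/IC50, the relation is not "=", or the target
confidence score is not 9. The potency criterion keeps records with
potency ≤ 10 µM by default — i.e. compounds active at 10 µM or better,
which is the direction consistent with curating *active* ST/DT compounds —
with both the cutoff and the direction configurable. Removals are audited
per filter in a fixed application order; the kept set is
order-independent because it is the intersection of per-filter pass sets.

## Fingerprint

Features are circular atom environments of bond radius 0–2 (bond diameter
up to 4) hashed from standard connectivity invariants (element, degree,
formal charge, H count, ring membership; no chirality), enumerated with
RDKit's Morgan machinery. Within a molecule, environments are
deduplicated by hash (set semantics — the fingerprint is binary); when
several symmetry-equivalent atoms share a hash, the representative with
the smallest (radius, center index) is kept. Folding maps
`bit = hash mod 4096`; the fingerprint retains, per set bit, the list of
environments that set it (the provenance map). Distinct environments may
collide on a bit after folding; provenance keeps all of them. Exact
bit-for-bit parity with any external fingerprint implementation is not
claimed — the hashing scheme is RDKit's, and all downstream statements
are invariant to the concrete hash values.

## Models and evaluation

Multiclass random forests are trained with scikit-learn and immediately
exported to a backend-independent flat tree structure (split feature,
threshold, children, per-class leaf distributions); all predictions in the
package traverse that structure, and the Shapley module depends only on
it. The protocol per independent trial t (seed = base_seed + t):
stratified 70/30 train/test split; hyperparameter selection on an inner
70/30 split of the training partition over the grid
min_samples_leaf ∈ {1, 2, 5, 10} × min_samples_split ∈ {2, 3, 5, 10} ×
n_trees ∈ {25, 50, 100, 200, 400} (80 points), scored by macro balanced
accuracy; final fit on the entire training partition. Remaining forest
settings stay at conventional defaults (bootstrap, √p features per split,
unlimited depth) and are recorded in the run manifest. The selection
criterion is not prescribed by the protocol's metric definitions, which
are binary; macro BA was chosen for consistency with the evaluation, and
the tie-break is deterministic (lexicographically smallest
(n_trees, min_samples_leaf, min_samples_split), preferring smaller
forests).

Metrics are computed one-vs-rest per class from explicit confusion
tallies: BA = (TPR + TNR)/2, precision, recall, F1, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). The printed
definitions are binary; for the four-class task all five are
macro-averaged (unweighted mean over classes) for internal consistency.
A micro or generalized multiclass variant would be an equally defensible
reading; macro is documented here and used throughout. Zero-denominator
ratios report 0 and set a degenerate flag rather than raising.

## Exact interventional Shapley attributions

For foreground x, background sample z and tree T, the coalition value is
v(S) = T(h(S; x, z)) with the hybrid h taking bits in S from x, others
from z. Attributions are exact Shapley values of this game, averaged over
the background set and the ensemble (both exact by linearity). The
per-class base value is the mean background probability, giving local
accuracy base_c + Σφ = P(c|x) by construction (asserted at 1e-8 wherever
explanations are produced under the debug flag, and at 1e-12..1e-16 in
the exactness tests).

Computation exploits that fingerprints are binary: every root-to-leaf
path imposes a required bit per tested feature. Relative to (x, z), a
path feature either agrees (x=z; the leaf is dead unless the requirement
matches) or disagrees, splitting into a set A (must come from the
foreground) and B (must come from the background). The leaf's restricted
game is the conjunction u(S)=[A⊆S, B∩S=∅], with closed-form Shapley
values (a−1)!b!/(a+b)! for i∈A and −a!(b−1)!/(a+b)! for j∈B. Summing
leaves with these weights is linear in leaves × path length and is
vectorized over the background. Trees whose split thresholds fall outside
(0,1) are handled by pruning branches unreachable for binary inputs.

The independent oracle is brute-force coalition enumeration (all 2^M
subsets, M ≤ 16); the exactness test drives both routes over random
ensembles and requires agreement below 1e-10 (observed: ~1e-15).

Cumulative aggregation restricts to correctly predicted test compounds;
each contributes the present-bit and absent-bit attribution sums of its
true (= predicted) class, reduced per trial by the mean over compounds.
"Sum over compounds" is available via a flag — the two readings differ
only by the class-size factor and produce the same distributional shape.
The background defaults to the entire training partition; a seeded
subsample is available for speed and recorded in the manifest.

## Counterfactual search

Base compounds are correctly predicted single-target test compounds;
candidates are analogues generated by pluggable strategies, and a
candidate qualifies as a counterfactual when its argmax class equals the
target class (DT). No similarity cutoff is applied at qualification;
Tanimoto similarity to the base is recorded and used to rank qualified
records (descending similarity, then descending target probability, then
canonical key). Two generator strategies ship:

* substituent transforms — attach a library substituent at an H-bearing,
  non-ring-junction atom, replace a terminal substituent, or delete one;
  the library is either a curated default or extracted from the active
  classes as the most frequent terminal substituents (cutting every
  acyclic single bond and counting the small side), which keeps the edit
  vocabulary task-agnostic;
* SMILES token mutations — k ∈ [1,3] random substitutions/insertions/
  deletions on the tokenized string, keeping only candidates that parse
  and sanitize, so every emitted candidate is chemically valid. This is a
  rejection-filtered string mutator; its contract is the same as
  robust-representation samplers (valid analogues in narrow chemical
  space, deterministic under seed).

Per-base generation seeds are derived as a stable hash of
(canonical key, base seed), so adding compounds to a run never reshuffles
the analogues of others. The candidate budget defaults to 1000 per base
per strategy.

## Atom mapping

Only present features are mapped (absent-feature attributions have no
atoms to receive them; they appear in the cumulative summaries instead).
A set bit's attribution is split equally among the environments in its
provenance list — the equal split is this package's convention for
folding collisions; it conserves the bit's mass and needs no randomness —
and each environment's share is assigned in full to every atom it covers,
accumulating over overlapping environments. The conservation identity
Σ_atoms raw = Σ_bits φ·(Σ_env |atoms|)/n_env is asserted to 1e-12 on every
map produced in tests. Maps are normalized per molecule (symmetric
max-abs scaling to [−1,1]; the per-molecule choice matches per-compound
depiction panels) and rendered as SVG with a diverging blue–white–red
scale anchored at zero, red supporting the target class.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes in
real dual-target data: class-discriminative substructures detectable by
present-feature attributions. DT compounds carry two planted substituent
motifs, ST compounds one, R compounds none; all classes share scaffold
and decoy chemistry. Defaults: motif A = 4-methylpiperidin-1-yl, motif
B = 4-phenylpiperazin-1-yl (aliphatic nitrogen heterocycles of the kind
enriched in dual-target actives), seven scaffolds with 2–3 substitutable
sites, nine neutral decoy substituents attached with probability 0.5 per
free site, 100 compounds per class. The spec validates that motifs are
distinct and absent from every scaffold and decoy. Label noise is
structural: with probability `noise`, a required motif is omitted while
the label is kept; the omission is drawn once per compound (before any
dedup retry) so the rate stays binomial. Ground truth motif atoms are
reported per compound by substructure matching (union over matches; in
symmetric cases such as the phenylpiperazine's equivalent nitrogens the
union can extend past the planted copy, which is the faithful
substructure-level read-out).

What the benchmark does *not* emulate: real potency distributions, assay
noise, activity cliffs, scaffold bias between classes, or the structural
diversity of screening collections. Passing the end-to-end tests shows
the machinery is correct and that planted signal is recovered; it does
not certify predictive performance on experimental dual-target data.

## Problem sizes and numerical conventions

The end-to-end tests and the acceptance script use 100 compounds per
class, 10 trials, and a 2×2×2 sub-grid of the hyperparameter space
(leaf ∈ {1,5} × split ∈ {2,5} × trees ∈ {25,100}) — large enough that the
benchmark separates cleanly and the attribution patterns stabilize, while
keeping a full run to minutes on one CPU; the full 80-point grid remains
the pipeline default for real runs. Backgrounds in tests are the full
training partition (280 fingerprints). Tolerances: local accuracy 1e-8;
oracle equivalence 1e-10; mapping conservation 1e-12; probability
simplex 1e-9. Determinism: every stochastic step takes an explicit seed
(trial t = base_seed + t; per-base generation seeds hashed as above);
re-running a pipeline config reproduces byte-identical tabular artifacts.

## Known limitations

* Exact attributions are computed per (tree, background, compound); cost
  grows linearly in each. Very large ensembles with deep trees and
  thousands of background samples call for the seeded background
  subsample.
* The Shapley path decomposition assumes binary feature vectors; it is
  not applicable to count or continuous descriptors.
* The string-mutation generator explores a small edit neighborhood and
  rarely assembles large ring systems; the substituent-transform strategy
  is the one that realizes motif-level gains of function.
* There is no guarantee that counterfactuals exist for a given base; the
  search reports an empty qualified set in that case.
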