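# Methods

`acpkit` implements a classification stack for short functional peptides —
anticancer peptides (ACPs) being the motivating case — whose defining data
problem is severe class imbalance: experimentally validated actives are
scarce relative to background peptides (the reference imbalance built into
the toolkit's defaults is 487 positives against 1,479 negatives). The stack
has five scientific components: peptide feature extraction, adaptive
boundary-aware resampling, a soft-voting tree ensemble, a six-metric
evaluation protocol, and residue-level attribution.

## Sequence handling

Peptides are validated against the 20 canonical amino-acid letters
(non-canonical codes X/B/Z/U/O, stops and gaps are rejected by default, or
dropped with a count under the `drop` policy) and filtered to lengths in the
inclusive band [5, 50], the range characteristic of most functional
peptides. Labels travel either in a `|label=0/1` FASTA-header suffix or a
two-column id/label file; both are artifact conventions, since no standard
exists. Redundancy clustering (CD-HIT-style) and PSSM profile generation are
external preprocessing steps outside this package; apply them before import.

## Feature extraction

Four classical encoders serve as baselines, with fixed alphabetical feature
ordering so matrices are bit-reproducible:

* **AAC** (20-d): letter frequencies.
* **DC** (400-d): adjacent-pair frequencies, row-major over the alphabet.
* **PAAC** (20+λ dims): Chou-style pseudo amino-acid composition over
  standardized hydrophobicity, hydrophilicity (Hopp–Woods) and
  side-chain-mass scales. Defaults λ = 4, w = 0.05: the shortest admissible
  peptide has 5 residues, so λ ≤ 4 keeps every valid input encodable; w =
  0.05 is the conventional sequence-order weight.
* **CTD**: composition/transition/distribution descriptors over a
  configurable property table, default the seven standard three-class
  physicochemical groupings (hydrophobicity, van der Waals volume, polarity,
  polarizability, charge, secondary structure, solvent accessibility),
  yielding 21 + 21 + 105 = 147 dimensions. Distribution percentiles are the
  positions of the first, 25 %, 50 %, 75 % and last occurrence of each
  class, reported as fractions of sequence length; an absent class reports
  zeros. Other CTD dimensionalities circulating in the literature (e.g. a
  60-d variant) correspond to property subsets that are not derivable
  unambiguously; the property table is therefore an explicit parameter.

Learned per-residue embeddings enter through a backend contract: a backend
maps a sequence to an L×d matrix with exactly one row per residue (marker
rows stripped). The shipped `MockBackend` is a pure function of
(dim, seed, period): the row for residue `a` at position `i` is a
pseudo-random vector keyed by `(a, i mod period)` via BLAKE2, so identical
letters at nearby positions share rows and everything is reproducible
offline. Its default width, 1152, mirrors the 600M-parameter protein
language model the toolkit targets; an adapter for that model is an
optional extra that raises a capability error when the model stack is
absent. Sequence-level features are the arithmetic mean of residue rows —
mean pooling is the convention for this model family and, being linear,
makes the residue-level attribution an exact decomposition.

What the mock backend does **not** emulate: contextual dependence (a
residue's real embedding depends on its neighbours), long-range structure,
and any correspondence between embedding geometry and physicochemistry.
Tests passing on mock embeddings therefore validate the *pipeline
mechanics and the attribution mathematics*, not biological transferability.

## Adaptive resampling

**ADASYN (reference).** Each minority sample i gets a difficulty
r_i = Δ_i/k, the fraction of majority points among its k nearest
neighbours in the full set (self excluded). Normalized difficulties
r̃_i = r_i/Σr allocate a synthesis budget G as G_i = r̃_i·G; each synthetic
point interpolates x_new = x_i + δ(x_zi − x_i) with δ ~ U(0,1) toward a
uniform draw among i's k nearest *minority* neighbours. Numerical choices:
if every r_i = 0 (no boundary contact) the normalization is undefined and
the allocation falls back to uniform; real allocations are rounded by the
largest-remainder method (ties to the lower row index) so ΣG_i = G holds
exactly — integer conservation is what makes the final class counts a
deterministic function of the input counts.

**ANBS.** The boundary-aware sampler iterates, up to an iteration cap
(default 100), the sequence: stop if |D_min|/|D_maj| ≥ max_ratio; remove
the single majority row at minimal Euclidean distance to any minority row
(distance ties to the lowest row index); synthesize
`ceil(max_ratio·|D_maj|) − |D_min|` minority points (never negative) with
the ADASYN machinery, neighbour count capped at |D_min| − 1; re-check the
ratio. Removing exactly one majority row per iteration and topping the
minority class up to the ceiling target is the parameterization under which
the reference imbalance 487/1,479 at max_ratio = 1.0 terminates in a single
iteration at exactly 1,478/1,478 — the count identity the acceptance
machinery recomputes. Because the top-up is exact, the ratio guard is
satisfied at the end of the first productive iteration for any reachable
target; the iteration cap is a defensive bound and its exhaustion is
reported with a warning status, never silently. Features are used as-is (no
internal standardization): distances are the caller's geometry, so scale
before sampling if features are incommensurate. Synthesis is seeded; at a
fixed seed the output is bit-identical across runs. Outputs carry
provenance flags (`original`/`synthetic`), and the result object exposes
the per-iteration removed/added counts for audit.

ADASYN synthesis seeds are all minority rows, with the difficulty
weighting concentrating the budget on boundary samples; restricting
synthesis to an explicit "critical sample" subset would change counts only
through the allocation, which the weighting already dominates.

## Classifier

The final model is a soft-voting ensemble: member classifiers' predicted
class-probability vectors are combined by a weighted arithmetic mean
(weights normalized to sum 1; default equal). Default members are Random
Forest, Gradient Boosting and histogram Gradient Boosting with library
defaults and pinned seeds — no tuned hyperparameters are baked in, and all
member parameters are surfaced in `EnsembleConfig`. A decision threshold of
0.5 maps combined probabilities to labels; a probability exactly at the
threshold resolves to positive. Members are pluggable by name
(logistic regression, SVM, k-NN, decision tree included) so single-model
comparisons reuse the same machinery.

## Evaluation

Six metrics from confusion counts — ACC, SN, SP, MCC, F1, Precision — in
their standard closed forms, with the convention that a zero denominator
yields 0 (keeping MCC defined for degenerate predictors). AUC is the
trapezoidal area under the ROC curve over descending thresholds with tied
scores grouped; this equals the Mann–Whitney pairwise statistic with ties
counted one half, which the tests verify to 1e-12.

Cross-validation is stratified with seeded shuffling; per-fold seeds derive
deterministically from the master seed. Resampling placement is explicit:

* `safe` (default) — ANBS runs inside each training fold only, so no
  synthetic point derived from a test sample can leak into training;
* `paper` — the full set is balanced once and folds are drawn from the
  balanced data: the protocol to use when every model must see the
  identical balanced dataset, at the cost of synthetic-sample leakage
  across folds (optimistic estimates);
* `none` — no resampling, the matched baseline arm.

The toolkit reports both resampling placements rather than asserting one;
the distinction matters whenever resampled CV numbers are compared across
publications.

## Residue-level attribution

The classifier operates on pooled features, so its Shapley attributions
live in feature space. The projection step maps them onto residues: given
a global weight vector w ∈ R^d and a peptide's residue embedding matrix
E = [e_1 … e_L]^T, the raw residue scores are s_i = e_i·w (no 1/L factor;
with mean pooling the raw scores sum to L times the pooled features'
combined contribution — a known constant, so ranks are unaffected), then
min–max normalized per peptide: s̃_i = (s_i − min s)/(max s − min s). A
constant score vector maps to all zeros, since the min–max map is undefined
there. The explained output is the positive-class (active-peptide)
probability.

Shapley values are estimated by a seeded permutation sampler: for each
explained instance and each sampled feature ordering, the coordinates of a
random background row are switched to the instance's values one at a time
and the output increments are credited to the switched features; the d+1
hybrid rows per ordering are scored in one batched model call. For a linear
model this is exact up to Monte-Carlo noise, and the 2-feature case is
checked against exhaustive enumeration over both orderings.

**Collapsing per-instance values into the global w** was a genuinely open
design point, and the choice matters. Three summaries are provided:

* `regression` (default): the per-dimension least-squares slope of Shapley
  values on feature values over the explained set. For f(x) = β·x this
  equals β exactly, independent of centering — the weights carry the
  *direction* of each dimension's effect, which is what the inner product
  with residue embeddings needs: residues whose embeddings point toward the
  positive class score high, those pointing away score low.
* `mean_signed`: the plain mean of signed Shapley values. This is
  approximately β ⊙ (explained mean − background mean) — an elementwise
  product whose entries are predominantly non-negative for any explained
  set shifted toward one class. It measures *where attribution mass sits*,
  not direction, and in experiments with randomized embedding signatures it
  carries no per-letter signal; it is retained for feature-space summaries.
* `mean_abs`: magnitude-only importance for ranking displays.

Per-amino-acid aggregation averages normalized scores over every
occurrence of each letter across a peptide collection, sorted descending;
letters absent from the data are flagged by a zero occurrence count and an
undefined (NaN) mean rather than zero-filled. A second entry point builds
the same ranking table directly from per-letter importance values, for
models trained on composition features where weights already index letters.

## Synthetic data

`make_blobs` draws two isotropic Gaussian classes (defaults: 487/1,479
rows, 16 dims, class-mean separation 2.0 at unit spread — overlapping
enough that boundary resampling has work to do). `make_sequences` draws
negatives i.i.d. uniform over the alphabet and positives from a multinomial
upweighting a designated residue set (default {K, L, F, G}, the residues
recurrently implicated in membrane binding, basicity and flexibility of
anticancer peptides) by an enrichment factor, default 3, renormalized;
lengths are uniform on [5, 50]. Uniform background composition is the
simplest null under which the planted compositional signal is recoverable;
it does not model natural amino-acid abundance, sequence motifs, or real
ACP statistics, and results on it say nothing about real-data performance.

## Problem sizes and determinism

The test and acceptance workloads run at the sizes the statistics require:
the resampling count identity at the full reference imbalance (1,966 rows,
16 dims), attribution recovery at 500 peptides per class with 64-dim mock
embeddings, conservation and metric oracles at 100–1,000 random instances,
and the resampling-benefit comparison over 5 seeds of 200-row blob sets.
Every stochastic component takes an explicit seed; pipelines derive
per-stage seeds from a single master seed, so reruns are byte-identical.

## Known limitations

* ANBS distances live in the raw feature space; for embeddings on highly
  curved manifolds Euclidean proximity may not reflect semantic proximity.
* The permutation Shapley estimator assumes feature independence in its
  interventional backgrounds; strongly correlated features share credit in
  ways the additive model cannot resolve.
* The attribution pathway is validated on synthetic compositional signal
  only; contextual (position- and neighbour-dependent) signal requires a
  real embedding backend.
* The iteration structure of the boundary step (one removal per iteration)
  is the parameterization that reproduces the reference counts; datasets
  needing bulk boundary pruning would need a different removal schedule.
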