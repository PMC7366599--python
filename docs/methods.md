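# Methods

## The representation

A relational database is a set of typed tables joined by foreign keys,
with one designated target table and class column. Let *C* be the columns
that are neither keys, ids, nor the target. Wordification describes the
*i*-th target instance by the disjoint multiset union, over every row of
every reachable table joined to it, of the items `(table, column, value)`
for columns in *C*. Within one row, every unordered pair of those items
is additionally emitted as a size-2 conjunct, so within-row co-occurrence
(a car that is simultaneously short and peaked-roofed) becomes a single
feature. Duplicates are kept in the bag — two identical cars contribute
each item twice — but the final matrix is a binary indicator: entry
(i, j) is 1 iff instance *i*'s bag contains vocabulary item *j*.

Reachability is the shortest foreign-key path from the target table,
edges traversed in both directions, capped at order 2 by default. The
restriction keeps item generation linear in total row count: a row with
`col` attribute columns yields at most `col + col(col−1)/2` items, and
each row is visited once per join witness, so total work is bounded by
Σ_t rows(t)·col(t) up to the conjunct factor. Tables on a foreign-key
cycle are indexed once, at their minimal order. Items are deduplicated
through exact dictionary identity (Python hashing provides the fast
64-bit path; collisions can never merge distinct items).

**Vocabulary.** Document frequency — the number of instance bags
containing an item at least once, the text-mining convention — is the
pruning statistic; items below `min_freq` (default 1) are dropped.
Column indices follow canonical lexicographic item order, which makes
matrices identical across runs and platforms.

**Numeric columns.** Symbolic values are required, so numeric attribute
columns are discretized to `binK_of_N` labels before wordification —
quantile binning with 4 bins by default, equal-width available. Bin edges
are interior quantiles strictly inside (min, max); a constant column
collapses to a single bin. Missing values generate no items anywhere.

## PropStar

Items and class labels share one d-dimensional space (d = 32 by
default). An instance bag embeds as the element-wise sum of its unique
in-vocabulary item vectors divided by √|M_unique|; a config switch
(`multiset_sum`) sums with multiplicities instead, keeping the same
divisor, since either reading of the bag-summation convention is
defensible. Classification is the argmax of dot-product similarity to
the label vectors — exactly |𝒞| similarity evaluations per prediction —
with ties broken by stable label order.

Training is one pass of plain SGD per epoch over shuffled instances.
For each instance, k = 5 negatives are sampled uniformly with
replacement from the non-true labels, and the margin ranking loss

    max(0, m − sim_pos) + (1/k) Σ max(0, m + sim_neg),   m = 0.05

is minimized; the positive hinge pulls the true label above the margin
and the negative hinge pushes sampled wrong labels below −m. (Applying
the positive-branch hinge to negatives as well would *reward* similarity
to wrong labels, so the standard ranking sign is used on the negative
branch.) The e_M gradient is distributed to each participating item
vector scaled by 1/√|M_unique| — the chain rule through the
normalization. Vectors initialize uniformly in [−0.5/d, +0.5/d]. Defaults
lr = 0.05, 5 epochs; all defaults are engineering choices surfaced in
`PropStarConfig`, and every random draw (init, shuffling, negative
sampling) derives from its seed.

## PropDRM

A single-hidden-layer network over the sparse matrix:

    ω = σ(W_o^T (ELU(Drop(W_1^T P + b_1))) + b_o)

Dropout acts on the pre-activation exactly as the composition reads,
with inverted scaling (kept units divided by 1 − rate) so inference needs
no rescaling and is deterministic. ELU uses a user constant c (default
1). Each of the |𝒞| outputs is an independent sigmoid trained with
per-output binary cross-entropy — softmax is deliberately not used —
averaged over the mini-batch; prediction is the argmax output, and the
binary decision score is the positive-class probability. Probabilities
are clipped to [1e−7, 1 − 1e−7] inside the loss.

Training traverses P in shuffled chunks of bs = 32 rows, densifying one
chunk at a time, so peak extra memory is O(bs·|W|) plus the parameter
count — never the dense n × |W| matrix. Forward and backward passes are
explicit numpy; the backward pass is verified against central finite
differences to 1e−4 relative error, and chunked-sparse inference matches
a full dense pass to 1e−6. Weights initialize He-normal under the config
seed. Defaults: hidden 32, dropout 0.2, lr 0.1, 30 epochs — sized so that
plain SGD takes enough update steps to converge on training sets of a few
hundred instances; adaptive optimizers are intentionally absent from the
default path to keep the baseline minimal and reproducible.

## Synthetic study conditions

The generator emulates two schema families: trains(id, direction) ←
cars(id, train_id, length, roof, shape, wheels, load), and molecules(id,
active) ← atoms(id, mol_id, element, charge_bin) + bonds(id, mol_id,
bond_type, ring_flag). Bonds reference the molecule only, keeping all
signal inside the order-≤2 neighborhood the transformation reaches — an
honest reflection of the method's expressiveness limit rather than a
simplification of chemistry. Attribute values are uniform over small
categorical alphabets; rules are enforced by minimal edits (flip one
row's values) rather than rejection sampling, so class balance is exact
at any n. Default conditions: n = 200 instances, balance 0.5, 2–5 child
rows per instance, label noise 0, and the conjunct rule "positive iff
some car has length=short ∧ roof=peaked" (trains) or "some bond has
bond_type=aromatic ∧ ring_flag=yes" (molecules). With label noise p,
labels flip independently; the pre-noise oracle labels are always
returned.

The `balance_marginals` mode makes the conjunct rule strictly
non-linear in singletons: every negative instance receives the two
singleton values in *different* cars, so `length=short` and
`roof=peaked` are present in every instance of both classes and only
the size-2 conjunct column separates them. The null-control generator
assigns labels by a seeded balanced shuffle, independent of all
attributes.

What the generator does **not** emulate: realistic attribute
correlations, heavy-tailed child counts, many-to-many relations,
chemically valid molecules, or the size and sparsity of the public
relational benchmarks. Passing the recovery tests therefore shows that
the pipeline is correct and leak-free, not that the reported benchmark
accuracies on real databases are reproduced.

## Evaluation protocol

10-fold stratified cross-validation, repeated (default 5 runs, seeds
seed..seed+4). Within each fold, numeric bin edges and the vocabulary
are fitted on training instances only; held-out bags drop unseen items.
A `global_vocab` switch restores whole-database fitting for comparison.
Stratification uses scikit-learn's splitter; when a class has fewer
members than k the harness falls back to a seeded round-robin assignment
with a warning. AUC is the rank-based probability that a random positive
outscores a random negative (ties half), computed by scikit-learn and
cross-checked in the tests against the O(n²) pairwise definition. The
"positive" class of the binary score is, by convention, the last label
in sorted order; AUC is invariant to that choice up to the matching score
orientation (PropStar: similarity difference between the two labels;
PropDRM: positive-output probability).

The test suite and the acceptance script run everything at n = 200 with
one CV repetition, which completes in seconds on a single CPU; the
defaults above were fixed from the synthetic conditions before any
held-out measurement and are not tuned per dataset.

## Degenerate inputs and tie-breaks

Composite primary keys are rejected rather than guessed. Dangling
foreign keys are counted by validation, never silently joined. An
instance whose bag has no in-vocabulary items raises in the library API;
the CV harness predicts the first label with score 0 for such instances.
Prediction ties break to the earliest label in sorted label order. An
all-missing numeric column discretizes to all-missing with a warning.
Non-finite training loss aborts with a diagnostic rather than returning
a silently broken model.

## Known limitations

Only 1-to-many relationships are supported (no junction-table
semantics). The SQL reader covers the minimal dialect used by
relational-learning dumps, not full SQL. PropStar supports multiclass
problems, but the harness's AUC reporting is binary. TF-IDF/count
weighting and aggregation-style features are out of scope by design.
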