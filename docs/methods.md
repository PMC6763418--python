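# Methods

## Objects and conventions

A *simplified alphabet* is a partition of the 20 standard amino acids into
1–20 non-empty groups. All matrices share one canonical residue order,
`ACDEFGHIKLMNPQRSTVWY`; row/column *i* always means letter *i*. Extended
residues (selenocysteine, pyrrolysine) are not accepted: the 20-letter set
is hard-coded, because every published grouping the package targets is a
partition of exactly that set.

The co-membership (binary intra-group) matrix of an alphabet stores 1 on
the diagonal for convenience, but the diagonal carries no information (a
residue always groups with itself) and every statistic — alphabet
comparison, consensus normalization, matrix distance, the permutation null
— iterates over the 380 off-diagonal cells only. Consensus vote counts are
accumulated as exact integers and divided once at the end, so every
consensus value is an exact multiple of `1/n_sources` and every pairwise
similarity an exact multiple of `1/380`; matrix TSV output is rendered at
4 decimal places, JSON at full precision.

Derivation categories follow the field's usual split: `chemistry`
(properties of the free amino-acid molecule) versus the four
"within-protein" classes `sequence_alignment`, `structure_alignment`,
`protein_blocks`, `contact_potentials`, plus an explicit `other`. Unknown
category strings are rejected rather than coerced so the 29-vs-5 category
split that drives the consensus comparison stays unambiguous.

## Trees

Dendrograms are unrooted throughout: amino acids (or alphabets) have no
ancestor, so rooted/ultrametric methods (UPGMA) are deliberately excluded.

* **Neighbor joining** is the standard Saitou–Nei agglomeration on the
  Q-criterion. When several pairs tie on Q (within 1e-12), the pair whose
  cluster representatives (alphabetically first member leaf) sort first is
  chosen, making the topology deterministic even on degenerate inputs such
  as an all-equal matrix. Input must be symmetric within 1e-9 and have at
  least 3 labels.
* **OLS branch lengths** re-fit the NJ topology by unweighted least
  squares: one row of the design matrix per leaf pair, one column per
  edge, entry 1 when the edge lies on the pair's path; solved with
  `numpy.linalg.lstsq`. Topology search under least squares is out of
  scope — on the data this package targets the NJ topology is already the
  least-squares topology, and re-fitting lengths is what matters for the
  branch-score analyses. Negative fitted lengths are *kept* (they are part
  of the OLS solution and of the branch score arithmetic);
  `clamp_negative_lengths` exists for display only.
* **Branch score distance**: for every bipartition in either tree take the
  branch-length difference (0 where the split is absent) and sum the
  squares; the default reports the square root, `squared=True` the raw
  sum, since both conventions circulate in common implementations. The
  jack-knife report records which convention produced it. Splits are
  keyed by the leaf side not containing the alphabetically first leaf, and
  the two basal edges of an accidentally rooted input collapse into one
  split with summed length, so rooted and unrooted serializations of the
  same tree compare equal.
* **Jack-knife**: drop each source alphabet in turn, rebuild consensus →
  distance → NJ+OLS tree, and score against the full-collection tree.
  Residues that no scheme ever groups sit at distance 1 from everything;
  they need no special casing — NJ simply places them on long pendant
  branches.
* **Hierarchical simplification** cuts an average-linkage hierarchy of the
  consensus distances at *k* clusters (scipy `linkage` + `cut_tree`, which
  guarantees exactly *k* groups), yielding one valid alphabet per size
  from 20 down to 1.

## Randomization test

The distance between two 20×20 distance matrices is the mean absolute
difference over the 380 informative cells. Dividing the summed absolute
difference by 380 keeps the statistic on the same [0, 1] scale as a single
cell, which is what makes observed and null values directly comparable.

The null model permutes **only the row order** of one matrix; columns are
untouched. Randomizing both axes would destroy the structured information
inside each row and inflate apparent agreement, so the one-axis
permutation is the conservative choice. Two consequences are handled
explicitly:

* Permuted matrices are generally asymmetric; that is intended.
* A row permutation moves informative values onto diagonal grid positions.
  The sum still runs over the 380 off-diagonal grid cells of the *fixed*
  matrix, for consistency with the global 380-cell convention. (Including
  the 20 diagonal grid positions would only add terms of the form
  `|0 − x|` for the fixed matrix's zero diagonal and shift the null
  upward; the package exposes no option for it.)

Permutations are drawn uniformly with replacement from all 20! ≈ 2.4×10¹⁸
orderings (the identity may be drawn), vectorized in chunks of 20,000 so
100,000 replicates run in about two seconds on one CPU. The p-value uses
the add-one estimator `(1 + #{null ≤ observed}) / (n + 1)`, standard for
Monte-Carlo tests, so it is never exactly 0. The default replicate count
is 100,000 — at that size two disjoint-seed batches agree in mean to
better than 0.001, so little is gained by the 10× larger runs the `--n`
flag still allows. The test can randomize either matrix, or both in turn
(`--mode both`).

PCA of the alphabet-similarity matrix treats rows as observations and
columns as features, removes column means, and does **not** scale
variances (the columns are already commensurable: all are similarity
fractions on [0, 1]); it is computed on the similarity matrix itself, not
its distance complement — centering makes the two differ only in sign per
column, so the variance fractions agree, and the similarity orientation
keeps the score plot's axes interpretable (nearby alphabets are similar).
A collection of identical alphabets has zero total variance; that case is
reported as degenerate rather than dividing by zero.

## Bundled data: a reconstruction, and what that means

`published_collection()` returns 34 simplified alphabets spanning the five
derivation categories (5 chemistry, 29 within-protein). The groupings were
re-assembled from the original source publications cited in each record's
name field. For several sources (Dayhoff's six classes, Murphy's
ten-letter reduction, the Wang–Wang five-letter code, the Susko–Roger
six-state recoding, Li's ten groups, ...) the published partition is
well-known and transcribed directly; for others the original table was not
available and a chemically plausible partition of the size favored by that
study stands in. The fixture is therefore a *synthetic stand-in* for the
original curated table — its file and docstrings say so — and headline
numbers computed from it (the 0.1681 category-matrix distance, the 87.7 %
two-component variance share printed in the README example) characterize
the reconstruction, not the exact historical table. The collection lives
in one TSV so corrections are localized: improving the fidelity of any
single record is a one-line edit.

## Synthetic generators

`generate_random_alphabet(seed, k)` draws a uniformly random partition of
the 20 residues into exactly *k* non-empty groups. Distributionally this
equals the naive scheme "label every letter uniformly in 1..k, redraw
until all labels occur", but it is sampled exactly with Stirling-number
weights because the naive rejection loop needs ~10⁷ redraws at k = 19 and
~10¹³ at k = 20. `generate_planted_collection(base, n, noise, seed)`
emulates a literature of *n* studies reporting noisy versions of one true
partition: each letter is independently reassigned to a uniformly chosen
base group with probability *noise*. Planted tests use noise 0.05–0.1 and
n in the 20–34 range — i.e. per-study disagreement on one or two residues,
the scale of variation one alphabet collection shows — and n = 34 where a
full-size collection is emulated.

What the generator does **not** emulate: real alphabets differ in *size*
(2–19 groups across sources), are correlated through shared data (many
derive from the same substitution matrices), and err in structured,
chemistry-respecting ways rather than by uniform reassignment. Passing the
planted-recovery tests therefore shows the consensus/agglomeration
machinery is correct and robust to idiosyncratic noise; it does not show
that 34 real studies must converge.

## Problem sizes and tolerances

The test suite and the acceptance script use 100,000 null replicates,
50 random additive trees of 5–12 leaves for the NJ+OLS oracle, 100 planted
trials for consensus recovery, and 20-leaf trees throughout the jack-knife
checks; the full suite runs in well under a minute on one CPU. Numerical
tolerances: 1e-9 for symmetry and Newick round-trip, 1e-8 for additive
reconstruction, exact integer arithmetic wherever counts are involved.

## Known limitations

* The reconstruction caveat above is the dominant one: quantities that
  depend on the exact historical groupings inherit its uncertainty.
* OLS refinement keeps the NJ topology; a matrix whose least-squares
  optimum lies on another topology will not find it.
* The branch score convention of any external report must be known before
  comparing jack-knife columns across tools; both variants are computed
  but they are not interchangeable.
* The randomization test is a permutation test on matrix cells, not the
  classical Mantel correlation; no correlation mode is provided.
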