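# Methods

## The encoding model

`ican` treats an organic molecule as an undirected labeled graph: atoms
are nodes annotated with their element symbol, bonds are edges, and
hydrogens are explicit degree-1 nodes added to satisfy standard
valences. The carbon chain is taken as the molecule's backbone — the
universal scaffold of peptides, proteins and most organics — and the
encoding records, for each backbone carbon, the element composition of
its multi-level neighborhoods.

**Neighborhood level.** The level-*n* neighborhood of a carbon is the
set of atoms whose shortest-path distance from it in the full atom graph
is exactly *n*. Distances are computed by breadth-first search over the
graph including hydrogens; since hydrogens have degree 1 they can never
shorten a path between heavy atoms, so heavy-atom distances are
unaffected by their presence. Bond multiplicity is deliberately ignored:
a double bond is one adjacency, because the encoding counts atoms, not
bonds. Every atom of a carbon's connected component appears at exactly
one level (its distance), and the level-1 multiset size equals the
carbon's degree — two conservation laws the test suite enforces.

**Column order (carbon indexing).** Columns follow a deterministic
depth-first walk of the carbon-induced subgraph: start at the carbon
with the smallest atom ordinal (ordinals follow first appearance in the
SMILES text), explore unvisited carbon neighbors in ascending ordinal
order, follow each branch to exhaustion before the next, and never
revisit a carbon — a ring-closure edge therefore "opens" the cycle into
a linear stretch of the walk. Opening affects *column order only*: the
closure edge still contributes to neighborhoods, so the first and last
carbons of a ring remain level-1 neighbors of each other. Disconnected
fragments (dot-separated SMILES, accepted so salts and mixtures encode)
are walked in ascending order of their smallest carbon ordinal. The
indexing is a pure function of the SMILES text; no canonical atom
ranking is attempted, so the same molecule written as two different
SMILES strings may legitimately produce column permutations of the same
array. Sulfur-capped side-chain carbons (e.g. the terminal methyl of
methionine, attached to the rest of the molecule only through sulfur)
form their own component of the carbon subgraph and are indexed after
the main chain.

**Element alphabets.** Mode 1 counts (H, C, N, O, S) in that order —
hydrogen row first, then carbon, nitrogen, oxygen, sulfur; mode 2 drops
hydrogen, giving (C, N, O, S); mode 3 counts every element present in
the data set, ordered H, C, N, O, S first (those present) and remaining
symbols alphabetically. The data-driven mode trades cross-data-set
comparability for completeness: two data sets with different element
inventories produce incompatible layouts, and adding a molecule with a
new element forces a re-encode. Elements outside the alphabet are not
counted but still occupy graph distance.

**Array layout and flattening.** Rows are level-major: the full element
block at level 1, then the block at level 2, up to the user's maximum
level (`levels`, default 2 — for typical peptide side chains the first
two levels already cover nearly every atom of a residue; compounds with
long side chains warrant more). Arrays are flattened column-by-column
and zero-padded at the tail to the data-set maximum column count; zero
is the natural pad value because it means "no atoms". The layout triple
(alphabet, levels, max_carbons) is stored alongside the matrix
(`PREFIX.layout.json` next to `PREFIX.csv`) and makes flattening
invertible, which the heat maps rely on.

**Peptide conversion.** FASTA sequences are converted to SMILES by N-to-C
condensation of a fixed internal table of the 20 standard residue
fragments, removing one water per peptide bond and leaving a free
N-terminal amine and C-terminal carboxylic acid (the conventional choice
for an unmodified linear peptide). No stereochemistry or protonation
states are encoded. Non-standard letters (B, J, O, U, X, Z) are rejected
with a diagnostic rather than guessed — exotic residues should be
supplied as SMILES, which the pipeline accepts directly and can mix with
FASTA records in one data set. Each single-residue conversion is checked
against the literature molecular formula of the free amino acid, and
k-residue peptides against the condensation formula (sum of residues
minus (k−1)·H₂O).

## Representations

A counting array becomes a grayscale image by dividing every cell by the
array's maximum and mapping 0 → white, 1 → black (8-bit PNG, intensity
= round(255·(1−v)), optional integer zoom). Normalization is
per-molecule by default; a data-set-global maximum can be supplied for
cross-molecule comparability. An all-zero array would divide by zero;
it is defined to render all white (no signal). The image is
scale-invariant: multiplying the array by a positive constant changes
nothing.

A relevance heat map un-flattens a feature-importance vector into array
coordinates and renders it with a sequential perceptually-uniform
colormap (viridis), rows labeled element × level, columns labeled
backbone position; the numeric map is written as CSV next to the PNG.
Importances are the mean decrease in impurity (MDI) of a random forest
fit on the full data set — non-negative, summing to 1 whenever any
split occurred. MDI is known to favor high-cardinality features; for
this package's count features (small integers) the bias is mild, but
heat maps are data-set-level diagnostics, not per-molecule attributions
(per-molecule maps are out of scope).

## Evaluation harness

Classification quality of an encoding is measured as the positive-class
binary F1 of a random forest under repeated stratified k-fold
cross-validation, default 5 folds × 10 repeats = 50 scores, fold
assignment and all forests seeded from one integer (default 42) so the
entire score vector is bit-reproducible. The forest hyper-parameters are
pinned in `RF_DEFAULTS` (100 trees, Gini impurity, unlimited depth,
√p feature subsampling, bootstrap) rather than inherited from the
library, so a dependency upgrade cannot silently change the baseline.
Macro-F1 is available via the scorer's flag but the headline number is
the positive class, matching the one-F1-per-data-set convention of
peptide benchmarks.

Two encodings are compared with a Mann–Whitney U test on their 50-score
samples. The default alternative is one-sided ("greater") because the
question asked of a new encoding is directional — is it better? — with
the two-sided test available by flag. The asymptotic normal
approximation (tie-corrected, continuity-corrected) is pinned
explicitly: CV scores routinely tie, and pinning the method keeps
p-values independent of sample-size-based method switching. The tests
check the p-value against an independent pair-counting implementation of
the U statistic to 1e-8 and verify the empirical type-I error under an
exchangeable null stays at the nominal 5% level over 1,000 simulated
pairs.

## Synthetic data

`gen_random_peptides` draws sequences i.i.d. uniform over the 20
standard residues with lengths uniform in a range (default 5–30,
typical of peptide classification benchmarks); it emulates only
sequence-level structure — no residue-frequency or positional biases of
real proteomes — so passing tests demonstrate pipeline correctness, not
classification performance on real data.

`gen_separable_task` is the controlled fixture for the harness and the
heat maps: label 1 iff the sequence contains a cysteine. Sequences are
drawn over the three-carbon residues alanine, serine and cysteine
(positives uniform over {A, C, S} with one cysteine forced if none was
drawn; negatives uniform over {A, S}). The restriction to three-carbon
residues is deliberate: every residue then occupies exactly three array
columns, so positional features are aligned across sequences and the
sulfur rows are the only systematic class difference. Under any
S-counting alphabet the classes are linearly separable on those rows, a
default random forest reaches mean F1 ≈ 0.98, and the aggregate MDI
concentrates on the S rows — making the expected heat-map signal
unambiguous. With sulfur placed instead at one random position of a
full-alphabet draw the classes remain linearly separable on the
aggregate sulfur count, but the signal lands in a different
position-specific feature for every sample (variable side-chain sizes
misalign columns), an OR-structure that impurity-greedy axis-aligned
trees cannot aggregate at these sample sizes; forests score near chance
on it. The aligned design is therefore what a controlled
interpretability fixture requires, and the contrast is worth keeping in
mind when applying positional encodings to traits carried by rare,
position-variable motifs.

Curated fixture molecules (methane, ethane, isobutane, cyclohexane,
phenol, glycine, methionine, ethanethiol, cyclo-diglycine) each carry
their literature molecular formula, against which every parse is
verified; neighborhoods are additionally checked against an independent
min-plus matrix-squaring all-pairs shortest-path oracle.

## Numerical and design choices

* Counting arrays are int64; no floating point enters until image
  normalization or model fitting.
* Padding is trailing only; layouts with centered or interleaved padding
  were rejected as they break the column ↔ backbone-position reading.
* Per-record parse failures during data-set encoding are collected and
  reported with record identifiers as a warning; the run aborts only if
  every record fails.
* Problem sizes in the test suite (200-sample tasks, 100-peptide round
  trips, 10²–10⁴-residue timing sets) were chosen as the smallest sizes
  at which the measured properties are stable.
* The timing check asserts a log-log slope of 1.0 ± 0.3 for encoding
  time vs. input bytes — a scaling property, not a hardware-specific
  throughput number.

## Known limitations

* Column order is defined relative to the input SMILES, not a canonical
  atom ranking; encodings of the same molecule from different SMILES
  writings differ by column permutation.
* Stereochemistry, 3-D geometry, conformers and protonation states are
  not encoded.
* Positional features misalign across molecules whose side-chain carbon
  counts differ, which blunts tree ensembles on position-variable rare
  motifs (see the synthetic-task discussion above).
* MDI importances are computed on the full data set (no held-out
  attribution) and inherit MDI's known biases.
* Mode-3 layouts are data-set-specific and not comparable across data
  sets.
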