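# Methods

`cpbarcode` implements the comparative analysis used to evaluate whole
chloroplast genomes ("super-barcodes") and marker subsets for species
identification in closely related plant groups: quadripartite genome
partitioning, divergence statistics, sliding-window mutation-hotspot
discovery, distance- and tree-based discrimination scoring, and a
synthetic plastome simulator that provides ground truth for every
stage.

## Genome partitioning

A plastome is modelled as a circular sequence carrying two identical
inverted repeats (IRa/IRb) that separate a large and a small
single-copy region (LSC/SSC). `detect_inverted_repeats` finds the
maximal pair of reverse-complementary **exact** repeats by
seed-and-extend: shared 25-mers between the sequence and its reverse
complement seed maximal exact extensions; origin wrap-around is handled
by extending inside a concatenated copy of the genome so a repeat
spanning the origin grows freely in both directions. The longer
inter-repeat segment is labelled LSC. Ties between equal-length
candidate pairs raise an error rather than silently picking one,
because a mis-partitioned genome corrupts every downstream per-region
statistic. The default minimum repeat length (10 kb) reflects real
plastome IRs (~25 kb); tests and the simulator use smaller values for
speed.

Exact matching is a deliberate determinism-first choice. Real deposited
genomes can carry a handful of mismatches between their IR copies; a
mismatch-tolerant extension mode is a known limitation, not currently
implemented — on such data the detector returns the largest exact core,
which can be slightly shorter than the annotated IR.

`canonicalize_orientation` rotates the genome to start at LSC position
0 with region order LSC, IRb, SSC, IRa. Both strands admit such a
rotation; the lexicographically smaller of the two candidate strings is
chosen. This makes canonicalization idempotent, rotation-invariant, and
strand-invariant (a genome and its reverse complement canonicalize
identically). For sets of closely related genomes the choice is
consistent across the set in practice, because the deciding bases are
conserved.

## Divergence statistics

Alignments are encoded as small-integer matrices (A=0, C=1, G=2, T=3;
anything else — gaps and IUPAC ambiguity codes — is missing data).
Purines are even and pyrimidines odd, so a substitution is a transition
exactly when the two codes share parity.

Gap handling follows the common desktop-tool conventions:

* **pairwise deletion** for distances — each pair of rows uses every
  column where both have unambiguous bases;
* **complete deletion** for nucleotide diversity and site
  classification — a column with a gap or ambiguity in any row is
  excluded for everybody.

A column is *variable* when at least two distinct bases occur and
*parsimony-informative* when at least two distinct bases each occur in
at least two rows. Report percentages divide by total alignment
columns, including excluded ones; this convention changes every
percentage and is therefore stated explicitly.

The Kimura two-parameter distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the transition and transversion proportions. When the
correction saturates (either logarithm argument is non-positive) the
distance is undefined and masked, never clamped; downstream consumers
(window profiles, discrimination, NJ) treat masked entries explicitly.
Nucleotide diversity π is the mean over unordered row pairs of their
per-site difference proportion on the complete-deletion columns.
Substitution counts are raw site differences under pairwise deletion,
not model-corrected counts.

Per-region reports analyse one IR copy only; duplicating the columns of
a mirrored repeat would double-weight identical data.

## Sliding windows and hotspots

Windows are fixed-length (default 800 columns) at a fixed step (default
100); trailing columns not covered by the last full window are ignored,
matching the fixed-window semantics of the standard sliding-scan tools.
Each window reports π, the mean defined pairwise K2P distance, and the
proportion of zero pairwise distances (computed over pairs; a
per-species variant is a possible alternative reading of that statistic
but is not built).

Hotspot calling selects windows at or above a threshold — by default
the top-2% quantile of the window metric, since no principled absolute
cut-off exists for arbitrary data — merges selected windows that
overlap or are within one step of each other, and ranks merged regions
by peak metric. Both the metric (π or mean K2P) and the threshold
(quantile or absolute) are configurable. For small simulated genomes
where the planted hotspot occupies a sizeable fraction of all columns,
tests use the top-10% quantile so that the selected window set matches
the planted geometry; on genome-scale data the 2% default plays the
same role.

Named markers are obtained by mapping hotspot regions onto a reference
genome's feature annotations through a column-to-position map that
skips reference gaps; regions inside features take the feature names,
regions between features are named `left-right`, and unannotated
regions keep coordinate names.

## Discrimination scoring

Two distance-based criteria are implemented and always named in
reports:

* **unique_haplotype** (default): a species is identified iff its
  minimum distance to every heterospecific sequence is strictly
  positive. This is the appropriate criterion when each species
  contributes a single sequence, where nearest-neighbour logic
  degenerates (every singleton would fail by definition). Zero distance
  is the failure condition with no epsilon, because distances derive
  from discrete site differences.
* **near_neighbour**: an individual is identified iff its nearest
  non-self neighbour is conspecific; ties that include a heterospecific
  sequence fail; a species succeeds iff all its individuals succeed;
  singleton species necessarily fail.

Success percentages are rounded half-up to two decimals. Species
involved in undefined distances are flagged and removed from the
denominator with a warning.

## Neighbor joining and bootstrap

NJ follows the canonical Saitou–Nei formulation: iteratively join the
pair minimizing Q(i,j) = (n−2)·d(i,j) − Σd(i,·) − Σd(j,·), with
standard branch-length formulas and a final trifurcating root. Ties in
Q are broken lexicographically on the pair of cluster labels (each
cluster labelled by its smallest leaf), so output is deterministic on
every platform. Negative branch lengths are retained and flagged (a
`--clamp` display option exists in the CLI). On additive matrices the
reconstruction is exact; the test suite verifies path-length recovery
to 1e-9 and cross-checks topology against an independent NJ
implementation.

Bootstrap resamples alignment columns with replacement; replicate *r*
draws from a generator seeded with (seed, r), so supports are
bit-reproducible and independent of evaluation order. Support is the
percentage of retained replicates containing the same leaf-set
bipartition; replicates with undefined distances are dropped and shrink
the denominator. Species monophyly on the unrooted tree requires the
species' leaf set to equal one side of some bipartition; singleton
species count as monophyletic by convention.

## Synthetic data

The simulator evolves sequences along a pure-birth (Yule) species tree
under the Kimura two-parameter process — the same model family as the
K2P estimator, so parameter recovery is a clean acceptance surface.
Within-species sampling appends star branches per individual. The
realized ultrametric depth is rescaled so the root-to-tip height equals
`tree_height` exactly.

Default conditions emulate the study system at one-tenth genome scale:
24 single-individual species; a 16.1 kb quadripartite genome (LSC
9000 bp, IR 2600 bp × 2, SSC 1900 bp); per-region rate multipliers
IR 0.2 < LSC 1.0 < SSC 1.5, reproducing the empirical diversity
ordering of plastome compartments; four planted 5× hotspots (two in
LSC, two in SSC); transition/transversion rate ratio κ = 2, typical
for plastid DNA; and tree height 0.0016 substitutions/site. On a Yule
tree most pairwise coalescences sit near the root, so expected pairwise
diversity is roughly twice the height — about 0.003, the few-per-mille
regime observed among congeneric oak plastomes.

For circular genomes the core (LSC + IRb + SSC) evolves once and IRa is
appended as the exact reverse complement of the evolved IRb, so the IR
rate multiplier applies once and the mirror invariant holds by
construction. One base at each single-copy junction is adjusted when
needed so the planted IR is also the *maximal* exact repeat (an
accidentally complementary junction base would otherwise let extension
overshoot the planted boundary by chance in roughly a quarter of
genomes). Every genome is independently rotated by a random offset and
strand-flipped with probability 1/2 to exercise canonicalization.

Indels are modelled as deletions relative to the ancestral coordinate
system (a geometric-length run, mean 5, of one row becomes gaps), which
produces gapped columns while keeping planted interval coordinates
valid; insertions are not simulated, and indels are disallowed for
circular-genome simulation where positional homology across the set is
required. The simulator has no coalescent within-species model and no
hybridization or introgression — real oak data violate both
simplifications, so passing tests demonstrate correctness of the
statistics and detection machinery, not robustness to reticulate
evolution or alignment error. External alignment (e.g. MAFFT) is
likewise out of scope: aligned inputs are consumed, not produced, and
the simulator's gap-free output stands in for a perfect alignment.

All randomness flows from one integer seed through named substreams;
identical configuration and seed give bit-identical sequences, trees,
and bootstrap supports.

## Problem sizes in tests

The test suite and the acceptance script run the full pipeline at the
default one-tenth scale (24 × 16.1 kb; seconds per stage), 20-replicate
recovery experiments for hotspots and for the K2P estimator (two taxa
at separation 0.1 on 100 kb), and 200 bootstrap replicates for the
reported tree — the same replicate count used for the study-scale
analyses this package targets.
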