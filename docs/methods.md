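# Methods

## Model

`alntensor` treats a multiple sequence alignment as a third-order tensor
rather than a matrix.  Each cell of the K-organisms × M-positions grid is
one of six sequence elements — A, C, G, U, unknown (N) and gap (–) — and is
one-hot encoded, giving a binary tensor 𝒯 of shape K × 6 × M whose six
slices tabulate each element's occurrence pattern.  The encoding is
deliberately assumption-free: collapsing the alignment to a matrix (e.g.
integer-coding the nucleotides) would impose an arbitrary metric on the
relations among the elements, while analysing slices separately would
discard their coupling through the one-hot constraint Σₛ 𝒯[i,s,m] = 1.

The mode-1 higher-order SVD (the Tucker-1 decomposition along the organism
mode) is computed from the SVD of the mode-1 unfolding X = U Σ Vᵀ, where X
is K × 6M with the six K × M slices appended side by side in slice order
(A, C, G, U, N, –).  Columns of U are *eigenpositions*; rows of Vᵀ refolded
into 6 × M arrays are *eigenorganisms*, each composed of six
nucleotide-specific length-M segments.  R = min(K, 6M) components are kept
(the full decomposition — inputs here are small, so no truncated or
randomized solver is used).

Two conventions and one normalization choice deserve note:

* **Unfolding orientation.** Appending slices along the *position* axis
  (K × 6M) is the only orientation in which the left factor is indexed by
  organisms (K × K) and the right factor has the six length-M segments; the
  alternative (6K × M) would transpose the interpretation.  This is stated
  prominently because verbal descriptions of "appending slices" are easy to
  read either way.
* **Information fraction.** A component's significance is its share of the
  total information; the default is the squared convention
  fᵣ = σᵣ² / Σσ², the standard choice in SVD-based data modeling (the
  squared singular values partition ‖X‖²_F exactly).  A linear convention
  fᵣ = σᵣ / Σσ is available via `convention="linear"` since significance
  need only be *proportional* to the singular value.
* **No centering.** The tensor is not mean-centered.  The first component
  therefore absorbs the grand average: its eigenposition is nearly constant
  across organisms and each of its segments tracks the per-column mean
  frequency of its element.  `mean_frequency_correlation` quantifies this
  (per-symbol Pearson correlation with the mean-frequency profile, plus the
  coefficient of variation of the eigenposition across organisms); a
  component is flagged "mean-like" when the CV is ≤ 0.5 and the median
  defined correlation is ≥ 0.5 — generous margins on both sides of the
  empirical separation, which is orders of magnitude (CV ~0.02 for the
  average component vs ≫ 1 for contrast components, whose entries are
  signed and near zero-mean).

**Sign convention.** Each (eigenposition, eigenorganism) pair is defined
only up to a joint sign.  At fit time the sign is canonicalised so the
largest-magnitude organism entry is positive (deterministic across runs);
`Results.orient(r, rule="group", group=...)` re-orients a component so a
chosen clade sits on the positive ("correlated") side, and `flip` flips
unconditionally.  All downstream statistics are equivariant: flipping a
component exactly swaps correlated/anticorrelated and increase/decrease
record sets.

Ties in singular values are left in the order produced by the underlying
factorization (deterministic for fixed input), so repeated runs are
byte-identical.

## Enrichment procedure

**Organism side.**  For component r, the k organisms with the largest and
the k with the smallest eigenposition entries form the correlated and
anticorrelated extreme sets (exact float ties at the k-th value are broken
by organism file order and logged).  Candidate groups are every named group
at lineage levels 1..depth (default depth 6) with at least `min_size`
members (default 3, suppressing singleton "groups"), plus every
ancestor∖descendant difference set meeting the same size floor — difference
groups let the procedure report, e.g., a domain excluding one divergent
phylum.  For each group and direction the upper hypergeometric tail
P(X ≥ j | K, J, k) is computed by log-space summation of exact log-pmf
terms (`scipy.stats.hypergeom.logpmf` + `logsumexp`), so deep tails
(P ~ 1e-40) are exact to floating precision.  P-values are reported raw, as
is conventional for this enrichment procedure; Bonferroni over
(groups × directions) is available as a column, not a filter.  The default
k = round(0.2 K) generalises the documented presets (k = 75 of 339,
k = 15 of 75).

**Position side.**  For each nucleotide-specific segment the m most extreme
positions per direction are selected.  Default m follows the documented
presets by alignment width — 100 for ~3k columns, 200 for ~6k columns,
otherwise round(M/32).  Tie handling is explicit because segment values of
a coherently gapped block are nearly identical: `rank` mode (default)
takes the m most extreme values and expands to include every position tied
with the m-th value within a relative tolerance (1e-9 of the segment's
largest magnitude); `extreme_set` mode takes exactly the positions tied at
the single most extreme value, which can be fewer or more than m — the mode
to use when an entire tie set (e.g. a deleted substructure's gap columns,
or tie sets of 91/100/124/199 positions in real rRNA alignments) is the
natural selection.  Selected positions are ordered most-extreme-first,
ties by column order.  Enrichment in a motif annotation with N columns
among M is again the upper hypergeometric tail, with m_effective (the
realised set size) as the draw size.

**Motifs.**  Three per-group conservation motifs over alignment columns:
exclusive gaps (gap frequency ≥ 80 % in the group, < 20 % outside),
exclusive unpaired adenosines (A frequency ≥ 80 % in / < 20 % out, and a
strictly greater unpaired fraction inside the group), and conserved helices
(paired state ≥ 60 % of the group).  Counting rules the definitions leave
open are fixed as follows and recorded in each annotation's parameters:
'N' cells count toward no numerator but remain in the group-size
denominator (a conservative reading of "conservation within the group's
organisms"); the unpaired fraction is taken over non-gap cells, since a gap
is neither paired nor unpaired (an all-gap group side fails the condition;
an all-gap outside counts as zero unpaired); for difference groups
"remaining organisms" means everyone outside the difference set, including
the subtracted descendant.  All threshold comparisons use exact rational
arithmetic (`fractions.Fraction` built from the threshold's decimal
string), so "at least 80 %" includes exactly-80 % and "less than 20 %"
excludes exactly-20 % regardless of binary float rounding; the same
mechanism implements the "at least 1 %" position filter.

**Reference mapping.**  Hit columns are reported in original alignment
labels (preserved through filtering) and can be projected onto an ungapped
reference organism's coordinates (cumulative non-gap count; None where the
reference is gapped), the form needed to locate hits on a secondary
structure model.  Rendering onto structure diagrams is out of scope; the
pipeline instead exports raster-ready organisms × hit-columns character
matrices.

## Synthetic study conditions

The generator produces matched alignment, taxonomy and pairing tables plus
a ground-truth manifest.  Default conditions (`default_config`): K = 60
organisms in three clades of 20 — CladeA and CladeB flat, CladeC split into
nested subgroups of 12 and 8 so that difference-group enumeration is
exercised without touching the planted signal; M = 400 columns.  Planted
features: a 30-column contiguous gap block in each of CladeA and CladeB
(in-group gap probability 0.95, out-group 0.05), six unpaired-A columns per
feature clade (in-group A probability 0.97 with unpaired probability 0.9;
out-group 0.02 and 0.4), and 60 universal helix columns (paired probability
0.9 vs 0.55 background).  Background columns draw a consensus nucleotide
per column (composition A 0.26, C 0.22, G 0.30, U 0.22) kept with
probability 0.85, with 2 % random gaps outside planted feature columns and
a 1 % unknown-symbol rate everywhere.  Feature columns are exempt from the
random gap noise and the A-site conservation is set high enough that each
planted feature satisfies its motif definition not just in expectation but
in essentially every realisation — the manifest is then a valid
per-realisation oracle for recovery tests.  Balanced 20/20/20 clades are
the regime in which perfect separation is certifiable at all: the smallest
attainable organism-side P at k = 12 is C(J,12)/C(60,12), which is below
1e-6 only for groups of J ≲ 23.

The null configuration (`null_config`) is the same background with three
flat clades of 20 and no planted features.  Balanced groups are also the
right choice for calibration: the hypergeometric test is discrete, so its
attainable size at the 0.05 level depends on J — 0.046 for J = 20 (reject
at j ≥ 7) but only 0.01–0.02 for the unbalanced or small groups, where a
nominal-level check would be uninformative.  Calibration is measured over
independently simulated components (one component per null dataset), since
the binomial reference band assumes independent replicates; components
taken from a shared dataset are mutually dependent.

What the generator does *not* emulate: phylogenetic correlation within
clades (organisms are exchangeable given their clade), substitution-model
evolution along a tree, covariation between paired columns,
alignment-uncertainty artefacts, and the long-tailed column-conservation
spectrum of real rRNA.  Passing recovery tests on these conditions
therefore demonstrates that the pipeline detects the planted class of
structure at realistic noise levels — not that real alignments contain
such structure, nor how the method degrades under tree-correlated noise.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on
K = 60 × M = 400 instances (unfolding 60 × 2400, milliseconds per SVD):
50 instances for planted-signal recovery, 200 for null calibration, 1000
random ≤ 8 × 6 × 10 tensors against a brute-force SVD oracle (agreement to
1e-10), and the full ≤ 12-organism hypergeometric grid against exact
integer enumeration.  These sizes give the recovery and calibration
estimates standard errors of a few percent while keeping a complete run in
seconds.

Degenerate inputs: an all-zero tensor, an all-filtered alignment, a group
covering every organism (for exclusivity motifs) and inconsistent
hypergeometric counts are errors; constant profiles make a correlation
undefined and are reported as NaN rather than zero.

## Known limitations

* Ambiguity codes beyond N are not interpreted (reads either error or
  coerce to N explicitly).
* The organism-side test treats organisms as exchangeable draws; shared
  ancestry within groups inflates significance on real data, so reported
  P-values rank associations rather than calibrate error rates there (the
  original tables' convention).
* Only the mode-1 (organism-mode) decomposition is provided; position- or
  nucleotide-mode unfoldings (Tucker-2/3) are out of scope.
* Building or improving the alignment itself, covariation-based pair
  prediction and tertiary-contact annotation are out of scope.
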