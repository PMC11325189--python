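# Methods

## The clustering model

`funfamkit` subdivides a protein domain superfamily into functional
families by a four-stage hierarchical procedure. The underlying
assumption is that function tracks sequence neighborhoods at two scales:
very close relatives (≥90% identity) share function essentially always,
so they can be collapsed into starting clusters represented by a single
sequence; and between clusters, functional boundaries reveal themselves
as *differentially conserved positions* (DCPs) — alignment columns that
each side of a candidate merge conserves strongly, but around different
residues. Such columns behave like specificity-determining positions:
conservation within each group plus disagreement between groups is
evidence the two groups do different chemistry, so the merge is refused.

### Stage contracts and key decisions

**Identity clustering.** Greedy incremental semantics: sequences are
processed longest-first (ties by id, which makes the outcome independent
of input order) and join the first cluster, in creation order, whose
*representative* they match at ≥ the threshold (default 0.90). Identity
is the number of identical aligned residue pairs in the optimal global
alignment divided by the shorter sequence length — the convention of the
greedy clustering tools this stage emulates. `X` never counts as a
match. Membership is tested against representatives only, keeping the
stage O(n·k). An external tool's clustering can be substituted through
the membership-TSV adapter; the in-repo algorithm is the reference
behavior.

**GO filtering.** A cluster survives iff at least one member carries a
GO term with evidence in the whitelist (default: the six classic
experimental codes EXP, IDA, IPI, IMP, IGI, IEP). The whitelist is
configurable because "experimentally derived" admits readings (e.g.
whether high-throughput codes count).

**Distances.** All sources are funnelled into one condensed half-matrix
over cluster representatives (scipy `pdist` layout). Embedding metrics:
cosine (default), Euclidean, Manhattan. Score tables: 1/bitscore or raw
RMSD; directed pairs are symmetrized by the arithmetic mean, and pairs
missing from a sparse table are filled with 10× the largest observed
distance rather than silently becoming zero. The default metric choice
(cosine) is recorded in run provenance, since results depend on it.

**Tree building.** Iterative closest-pair merging with Lance–Williams
updates. Default linkage is unweighted group average (UPGMA-style): the
average of all representative-pair distances is the closest
distance-space analogue of comparing merged profiles, and average
linkage is reducible, so merge heights are non-decreasing — a property
the tests assert. Ties on the minimum distance break on the
lexicographically smallest (left, right) id pair, making the merge list
fully deterministic. Single and complete linkage are exposed for
experimentation; recomputing node centroids after each merge is
deliberately not done (the medoid pooling between protocol iterations
covers the same need at the place it matters).

**Alignment machinery.** Cluster MSAs are built progressively
(length-descending insertion; starting clusters are ≥90% identical, so
guide-order sensitivity is negligible), and internal-node MSAs by
profile–profile alignment: column-vs-column scores are the mean pairwise
substitution score over the cross rows, with residue-vs-gap pairs
charged `gap_extend` and gap-vs-gap pairs free. Default scheme is
BLOSUM62 with affine gaps open 11 / extend 1 (community convention); a
flat identity scheme (match 1 / mismatch −1 / linear gap 1) supports
exact-arithmetic tests. A gap run of length L costs
`open + (L−1)·extend`. Traceback ties resolve diagonal > up > left, and
profile alignment canonicalizes its operand order on the smallest
seq_id, which is what makes DCP detection exactly symmetric in its two
arguments. The DP optimum is verified against exhaustive path
enumeration in the tests.

**Conservation and DCPs.** Column conservation uses the entropy proxy
`score = (1 − H/ln 20)(1 − g)` (H = Shannon entropy of non-gap residue
frequencies, g = gap fraction). This honors the endpoints that matter —
an invariant gap-free column scores 1, a maximally diverse column 0, and
gaps attenuate — and is the single point of substitution if an exact
scorecons implementation is wanted later; absolute values are therefore
not comparable to published scorecons/DOPS numbers, only orderings are.
DOPS = `100 · (1 − |{j : score_j ≥ c_cons}| / n_cols)` with
`c_cons = 0.9`, chosen so a fully conserved alignment scores exactly 0.
A merged column is a DCP iff both sides score ≥ `c_high` (0.8), both
gap fractions are < `g_max` (0.5), and the modal residues differ
(ties in the modal residue break alphabetically).

**Tree cutting.** Post-order: leaves are accepted; an internal node is
accepted iff both children are accepted, the DCP count between the child
alignments is ≤ `d_max` (default 0), and — when a `distance_ceiling` is
set — its merge height does not exceed it. Acceptance being recursive
encodes "largest coherent subsets": a boundary anywhere below a node
poisons it. The ceiling is the optional distance-based gate layered on
the conservation test; the default is DCP-only. `min_funfam_size`
defaults to 1 (no floor); when raised, undersized families are folded
into the nearest family found by walking up the merge tree — a
pragmatic semantic for a parameter whose behavior is otherwise
unspecified.

One consequence of `d_max = 0` worth knowing: a singleton leaf's
alignment is trivially "conserved" at every column, so an outlier
sequence that seeded its own starting cluster tends to survive as its
own small FunFam whenever it carries any fixed difference from its
family's consensus. This splits conservatively (families stay pure) at
the cost of a few extra small families; raising `d_max` trades in the
other direction.

**Protocols.** MARC partitions sequences by MDA string before iteration
1; an MDA with at least `mda_min_size` sequences becomes its own
partition and the rest pool into a residual set. The threshold is a pure
scale parameter (production settings put it in the millions; the
default here is 5, suited to desk-scale data), and it is read as a
*per-MDA* condition — the natural reading when partitions are processed
independently. Pooled FunFams become starting clusters represented by
their embedding-space **medoid** (the member minimizing summed distance
to co-members, among members that have vectors), which keeps the
representative a real sequence. FRAN shuffles the starting clusters
with one seeded PRNG permutation and slices them into consecutive
projects of `fran_project_size`; its second iteration can only merge,
so the final count never exceeds iteration 1's. GO filtering applies in
iteration 1 only; pooled FunFams inherit eligibility.

## The synthetic generator

The generator emulates one superfamily with K planted families, all
descended from a single random root ancestor of length L:

* **SDP columns** (`n_sdp`, default 3): a shared set of columns at which
  each family is assigned a distinct residue, held fixed in every
  member — the planted functional signal.
* **Family divergence** (`family_divergence`, default 0.30): per-site
  probability that a family ancestor differs from the root at non-SDP
  sites. This is what puts cross-family identity well below the 0.90
  clustering threshold; with it at 0, families differ *only* at SDP
  columns, which is the configuration used to verify that DCP detection
  finds exactly the planted columns.
* **Within-family mutation** (`mutation_rate`, default 0.03): each
  member independently substitutes non-SDP sites of its family ancestor,
  uniformly over the 19 alternatives — a star topology with a neutral
  substitution model. Realism is not the goal; separability control is.
* **Embeddings**: one Gaussian center per family (spread `between_sd`,
  default 6) plus isotropic member noise (`within_sd`, default 1). The
  6:1 ratio makes within-family distances clearly smaller than
  between-family distances at the default dimension (16).
* **Labels**: family *i* gets EC `1.1.1.(i+1)` — distinct EC4, shared
  EC3, so the two purity levels behave differently — one experimental GO
  term (IDA) on every member, and an MDA string (default the single
  domain `3.40.50.620`, overridable per family). Annotating every member
  keeps the GO filter from silently dropping splinter clusters in
  pipeline fixtures; filter behavior itself is tested on dedicated toys.

All draws come from two seeded streams (sequences and embeddings), so a
given seed reproduces the dataset byte-for-byte.

What the generator does *not* emulate: indels (alignments of generated
families are gapless), rate heterogeneity, phylogenetic tree structure
within families, annotation noise, multi-EC members, or unannotated
sequences. Passing end-to-end tests therefore demonstrates that the
pipeline recovers cleanly separable planted structure deterministically —
not that it handles the alignment ambiguity or annotation sparsity of
real superfamilies.

## Numerical choices and degenerate inputs

* Traceback equality comparisons use a 1e-9 tolerance (profile column
  scores are rational numbers; substitution-matrix arithmetic is exact).
* `pdist` cosine output is clipped at 0 to remove negative float noise;
  cosine of a vector with itself returns exactly 0.
* Threshold comparisons (DOPS `c_cons`, purity 80/90/100%) are inclusive
  with a 1e-12 guard; "over 80%" is read as ≥ 0.80.
* A run that collapses to a single starting cluster short-circuits: one
  FunFam, no tree. Zero surviving clusters yield an empty result.
* EC purity of a FunFam with no usable EC is *undefined* and excluded
  from averages, never reported as 0; summary proportions are reported
  with both denominators (EC-defined FunFams, and all FunFams).
* `d_max` accepts `math.inf` to disable the DCP test (used by the
  boundary-law checks: infinite tolerance yields exactly one FunFam; a
  zero distance ceiling with positive merge heights yields one FunFam
  per leaf).

## Problem sizes

The standard end-to-end study conditions are 6 families × 40 sequences
of length 80 with 3 SDP columns, 3% mutation, spread ratio 6 — small
enough that a full protocol run completes in well under a minute while
still exercising clustering, tree building, refilling, and cutting on
non-trivial structure. The linkage oracle check covers 100 random
matrices with 3–20 leaves under all three linkages, and the alignment
oracle 500 random pairs of length ≤ 6 against exhaustive enumeration.

## Known limitations

* The conservation score is an entropy proxy, not Valdar's trident
  score: no stereochemical similarity weighting, no sequence weighting.
* Profile alignment is greedy-progressive without a guide tree; for the
  ≥90%-identity clusters it aligns this is inconsequential, but deep
  internal nodes of very divergent superfamilies would benefit from a
  proper guide tree or external aligner.
* The DCP rule counts columns against a hard threshold pair
  (`c_high`, `d_max`) with no statistical test; singleton and
  low-diversity alignments are trivially conserved (see above).
* HMM–HMM scoring between nodes is out of scope; the distance-based
  tree stands in for it, and embedding/structural distances are consumed
  as input rather than computed (a toy k-mer embedder is provided for
  self-contained demos).
* MDA strings are treated as flat ordered lists; discontinuous domains
  have no special handling.
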