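# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `pocketmotif`.

## Pocket representation

A pocket is an unordered set of surface residues, each reduced to its CA
atom (coordinates in Å, author numbering with insertion codes preserved).
CA-only is the standard reduced representation and matches the ~10-residue
scale of surface pockets; an all-atom mode is deliberately out of scope.
Alternate locations keep the highest-occupancy conformer (ties by altloc
letter); modified amino acids map to their parent residue for one-letter
codes, unmapped residues become `X` (alignable, excluded from motif
frequencies). Pocket definitions must agree with the coordinate file's
author numbering exactly; mismatches are reported as resolution errors
rather than guessed around.

## Binding-residue criterion

A protein residue is RNA-binding iff any of its heavy atoms lies within
`cutoff` (default 5.0 Å, boundary inclusive) of any RNA atom. This single
distance union stands in for per-type interaction classification (hydrogen
bond / electrostatic / hydrophobic / van der Waals): it is the standard
operational definition of an interface residue, is configurable
(`cutoff`, `atom_scope`), and avoids depending on unmaintained
interaction-typing tools. Hydrogens are ignored by default because deposited
structures rarely include them. A pocket is RNA-binding iff it contains at
least one binding residue; pockets with fewer than 4 residues are removed.

## Non-sequential alignment

The two alignment objectives — minimise the total squared distance of
aligned residues, maximise the number of aligned residues — are optimised by
the canonical alternating scheme rather than a monolithic mixed-integer
program:

1. **Assignment step.** Given a rigid superposition, solve the linear
   assignment problem on squared distances with pairs farther than
   `d_max = 5 Å` forbidden (a forbidden-pair cost larger than any feasible
   total makes the solver first maximise the number of allowed pairs, then
   minimise their total squared distance). Ties are resolved
   deterministically by the LAP solver.
2. **Superposition step.** Given the assignment, recompute the least-squares
   (Kabsch/SVD) proper rotation — reflections are explicitly excluded.

The loop stops when the mapping is stable and the RMSD change falls below
`tol = 1e-6 Å`, or after `max_iter = 50` rounds. Because the scheme is
local, it is restarted from multiple orientations: the four proper
sign-combinations of the principal-axis frames of the two clouds, plus
`n_rotation_seeds = 24` quasi-uniform rotations (Shoemake map over a Halton
sequence) expressed *in the principal-axis frames*. Axis signs are fixed by
the skewness of the coordinate projections, so the entire start set
co-rotates with either input — this makes the result invariant under rigid
motion of either pocket (up to eigen-degeneracy of nearly symmetric clouds,
which has measure zero for real pockets). The reported result is the
converged start with the largest Q-score; pairs are processed in canonical
lexicographic id order, so `q(a,b) = q(b,a)` exactly.

Chain-scale alignment reuses the same engine with principal-axis starts
only: at ~200 residues each assignment round costs O(n²·log) and exhaustive
rotational seeding buys little, since the refinement basin is wide for
global folds.

**Q-score.** `Q = N_align²/((1+(RMSD/R₀)²)·N₁·N₂)` with `R₀ = 3.0 Å`.
`Q = 1` iff all residues of two equal-size pockets align at RMSD 0; it
decreases monotonically in RMSD and increases in `N_align`.

## Significance calibration

Q-scores of random pocket pairs from a background set are fitted with a
generalized extreme value distribution by maximum likelihood, initialised
with L-moment estimates (Hosking's formulas); the shape convention is
`k > 0` = heavy right tail (scipy's `genextreme` shape is `-k`). The
P-value of an observed score is the fitted survival function, with the
Gumbel limit used for `|k| < 1e-10` and clamping outside the support
(below the lower endpoint for `k > 0`: P = 1; above the upper endpoint for
`k < 0`: P = 0). The Kolmogorov–Smirnov statistic of the fit is reported as
goodness. The default background is 20,000 sampled pairs — ample for a
threshold at α = 0.05, and alignments are cached per distinct pair, so the
cost is governed by the number of distinct background pockets, not the pair
count. Far larger backgrounds (hundreds of thousands of pairs) are a flag away
(`--n-pairs`) when calibrating against a big pocket collection.

Two calibration caveats are deliberate design positions:

* **The background must match the query population.** The Q null shifts
  strongly with pocket size (a 6-vs-14-residue pair can never exceed
  Q = 36/84 ≈ 0.43), so a size-diluted background drags the significance
  threshold below the like-for-like null and floods the network with
  spurious edges. The synthetic generator therefore calibrates on
  backgrounds size-matched to the planted pockets, and real-use backgrounds
  should be pockets comparable to those analysed.
* **Protein-level networks need their own background** of random chain
  pairs, never the pocket null, for the same size-dependence reason.

Significance is `P < α` with strict inequality, `α = 0.05` by default; no
multiple-testing correction is applied by default (a Benjamini–Hochberg
helper is provided, off by default).

## Similarity network and pocket groups

Nodes are pockets (or proteins); edges connect pairs with `P < α`;
isolated nodes are retained. Modularity is the unweighted Newman–Girvan
`Σ_c (e_cc − a_c²)` — the edges were already binarised by the significance
threshold, so weighting them again by Q is redundant (and left as an option
off by default).

Community detection is deterministic greedy agglomeration (CNM-style):
starting from singletons, repeatedly merge the connected community pair with
the largest modularity gain (ties: lexicographically smallest label pair,
labels being the smallest member id) along the full merge schedule. Pure
agglomeration cannot undo an early misplacement — on some sparse graphs it
(and the reference networkx implementation) lands measurably below the true
maximum — so every partition on the merge path is additionally refined by a
deterministic single-node relocation sweep (move the node with the largest
strictly positive gain to a neighbouring community or a fresh singleton,
nodes visited in sorted order), and the best refined partition is returned.
The result is invariant to node input order.

Groups are partition blocks sorted by size (then smallest member id),
numbered from 1; a group is *major* when it has at least `min_size = 5`
members (there is no canonical rule for delimiting major groups, so the
threshold is an explicit, configurable proxy); the representative
is the highest-degree member (ties lexicographic). In tabular output,
members of non-major groups are reported with group_id 0 ("grey" pockets).

## Consensus multiple alignment

Pairwise non-sequential alignments within a group are generally mutually
inconsistent. The consensus assigns each pocket's residues to at most one of
at most `N` columns (`N` = largest pocket size in the group; a single symbol
cannot honour varying sizes, so the maximum is used) so as to maximise the
number of pairwise-aligned residue pairs `δ_ijkl` placed in a common column,
summed over unordered pocket pairs (self-pairs and double counting would
only rescale the objective). Solved greedily and deterministically:

* **Seed.** The pocket triple with the most *cyclically consistent* residue
  triples (k↔l, k↔m and l↔m all present in the pairwise alignments; three-way
  closure is this package's operational definition of a consistently
  aligned residue set). Ties: lexicographic
  triple. For groups of 2 the consensus is the pairwise mapping; a singleton
  group is its own consensus with objective 0.
* **Insertion.** Remaining pockets are added in descending order of total
  pairwise-alignment overlap with the assigned set (ties by pocket index):
  residue-to-column weights count agreeing assigned residues, a
  maximum-weight matching (zero-weight pairs excluded) places the residues,
  and unmatched residues open new columns while fewer than `N` exist.
* **Refinement.** Each pocket in turn is removed and re-added; a
  re-assignment is kept iff the objective does not decrease, so the
  objective is monotone non-decreasing; at most 10 rounds. δ is treated as
  fixed input — pairwise alignments are not re-estimated during refinement.

One-to-one constraints are asserted after every operation. On mutually
consistent families the greedy objective provably reaches the optimum
`C(M,2)·N`; on random small instances it is verified never to exceed the
brute-force optimum.

## Motif profiles and enrichment

Per consensus column: amino-acid frequencies over assigned residues (`X`
excluded; frequencies over occupied entries sum to 1), occupancy (fraction
of group pockets assigned), and binding ratio (fraction of assigned residues
flagged RNA-binding, `X` included). Concatenated per-pocket sequences carry
the original residue positions for traceability.

Enrichment of a group's parent proteins against a population uses the
one-tailed upper hypergeometric probability of at least the observed count;
the EASE variant subtracts one success first (a single-hit term is never
significant), covering the convention of the external annotation service it
replaces. Terms are opaque labels; no ontology propagation. No correction by
default, BH optional — printed significance from external services is not
expected to be numerically reproducible because their effective list/
population totals differ per term.

## Synthetic data: what it emulates, what it does not

The generator plants exactly the structure the method must recover:

* **Templates** — random point clouds in a ball, minimum pairwise separation
  3.5 Å (CA-like packing), default 10 residues (typical pocket size),
  random amino-acid letters. Within a family dataset, candidate templates
  are redrawn until all template pairs align with Q ≤ 0.6, i.e. the planted
  families are no more alike than random pocket pairs — otherwise two
  "families" can by chance share a structure and the planted labels stop
  describing distinct groups.
* **Members** — template + iid Gaussian noise (σ, default 0.3 Å) + uniform
  random rotation + random translation + optional residue-order permutation;
  an optional deletion rate produces partial alignments. Ground-truth
  correspondences are kept as metadata.
* **Background** — independent random pockets, size-matched to the members
  by default (see the calibration caveat above).
* **Complexes** — a CA-only protein chain at 8 Å spacing with planted RNA
  contact atoms at `cutoff − gap` and all other cross distances beyond
  `cutoff + gap`, so any cutoff between the two bands recovers exactly the
  planted residues.
* **Planted-partition graphs** — independent within/between edges for
  community-detection tests.

All generators are pure functions of their seeds. What passing synthetic
tests shows: the aligner undoes rigid motion and residue permutation at
realistic noise; the calibration yields near-uniform null P-values; the
clustering recovers well-separated planted families; the consensus
reconstructs full columns on noisy copies. What it does not show: behaviour
on real pockets with backbone continuity, correlated noise, flexible or
partially conserved sub-structures, or heterogeneous pocket sizes within a
family — real-data thresholds (α, `min_size`, `d_max`) may need adjustment,
and reproducing the corpus-scale counts of any specific published analysis
additionally depends on external pocket/contact/redundancy tooling outside
this package's scope.

## Numerical choices and degenerate inputs

* Kabsch uses SVD with an explicit determinant correction; < 3 points or
  length mismatch is an error. Collinear point sets still return a
  minimiser (the rotation is then not unique).
* Assignment with an empty allowed set returns an empty mapping; alignments
  whose mapping drops below 3 pairs stop iterating and are scored as-is.
* GEV fitting requires ≥ 100 finite, non-constant samples; MLE failure
  raises a numerical error carrying the L-moment fallback estimates.
* Modularity is undefined (error) on edgeless graphs; community detection on
  an edgeless network returns singletons with modularity reported as 0.
* All tie-breaks (assignment, merges, representatives, seed triples,
  insertion order) are fixed and documented so that reruns are
  byte-identical; every stochastic step takes an explicit seed.

## Default problem sizes

The shipped study conditions — 6 templates × 15 members, 30 background
pockets, 20,000 calibration pairs, α = 0.05, `min_size` 5 — run the full
pipeline in about a minute on one CPU and are the conditions under which the
acceptance quantities are computed.
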