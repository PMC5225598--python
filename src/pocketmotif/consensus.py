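"""Consistent multiple structure alignment of a pocket group.

Pairwise non-sequential alignments within a group need not be mutually
consistent. The consensus alignment assigns each pocket's residues to shared
consensus columns so as to maximise the number of pairwise-aligned residue
pairs that the columns agree with:

    max  sum_{i<j} sum_{k,l,c} delta_ijkl * x_ikc * x_jlc
    s.t. each residue in at most one column, each column holds at most one
         residue per pocket,

where delta_ijkl = 1 iff residue k of pocket i is aligned to residue l of
pocket j in the pairwise result, and x_ikc = 1 iff residue k of pocket i
occupies consensus column c. The number of columns is capped at the largest
pocket size in the group.

Solved greedily: a seed of three pockets with the most cyclically consistent
aligned residue triples starts the columns; remaining pockets are added one
at a time by a maximum-weight matching of their residues against columns;
finally each pocket is removed and re-added in turn, keeping any
re-assignment that does not lower the objective (so the objective is
monotonically non-decreasing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .structio import InputError

__all__ = [
    "PairwiseAlignmentSet",
    "ConsensusAlignment",
    "objective_score",
    "find_seed",
    "max_weight_matching",
    "add_pocket",
    "refine",
    "build_consensus",
]


@dataclass(frozen=True)
class PairwiseAlignmentSet:
    """Pairwise residue correspondences delta_ijkl for a pocket group.

    ``delta[(i, j)]`` for i < j maps residue k of pocket i to residue l of
    pocket j (a one-to-one dict). Lookups are symmetric.
    """
    pocket_ids: tuple            # ordered pocket ids
    sizes: tuple                 # residue counts, same order
    delta: dict                  # (i, j) i<j -> {k: l}

    @property
    def m(self) -> int:
        return len(self.pocket_ids)

    @property
    def n_max(self) -> int:
        return max(self.sizes) if self.sizes else 0

    def pair_map(self, i: int, j: int) -> dict:
        """Mapping k (pocket i) -> l (pocket j); works for any i != j."""
        if i < j:
            return self.delta.get((i, j), {})
        return {l: k for k, l in self.delta.get((j, i), {}).items()}

    def aligned(self, i: int, k: int, j: int, l: int) -> bool:
        return self.pair_map(i, j).get(k) == l

    @staticmethod
    def from_alignment_results(pocket_ids: Sequence[str],
                               sizes: Sequence[int],
                               results: Sequence) -> "PairwiseAlignmentSet":
        """Build from AlignmentResult objects (any superset of the group's
        pairs; results are matched by pocket id)."""
        idx = {pid: i for i, pid in enumerate(pocket_ids)}
        delta: dict = {}
        for r in results:
            if r.id_a in idx and r.id_b in idx:
                i, j = idx[r.id_a], idx[r.id_b]
                mp = dict(r.mapping)
                if i > j:
                    i, j = j, i
                    mp = {l: k for k, l in mp.items()}
                delta[(i, j)] = mp
        return PairwiseAlignmentSet(tuple(pocket_ids), tuple(sizes), delta)


@dataclass
class ConsensusAlignment:
    """Assignment of pocket residues to consensus columns.

    ``columns[c]`` maps pocket index -> residue index. ``objective`` is the
    consistency score recomputed from the assignment.
    """
    pa: PairwiseAlignmentSet
    columns: list                # of dict {pocket_index: residue_index}
    assigned: set                # pocket indices currently assigned
    objective: int = 0

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column_of(self, i: int, k: int) -> Optional[int]:
        for c, col in enumerate(self.columns):
            if col.get(i) == k:
                return c
        return None

    def check_constraints(self) -> None:
        """Assert the one-to-one constraints; raise on violation."""
        for i in self.assigned:
            seen = [col[i] for col in self.columns if i in col]
            if len(seen) != len(set(seen)):
                raise InputError(
                    f"pocket {i}: residue assigned to multiple columns")
            if any(not (0 <= k < self.pa.sizes[i]) for k in seen):
                raise InputError(f"pocket {i}: residue index out of range")


# ---------------------------------------------------------------------------

def objective_score(cons: ConsensusAlignment,
                    pa: Optional[PairwiseAlignmentSet] = None) -> int:
    """Number of pairwise-aligned residue pairs consistent with the columns
    (summed over unordered pocket pairs)."""
    pa = pa or cons.pa
    cons.check_constraints()
    total = 0
    for col in cons.columns:
        items = sorted(col.items())
        for (i, k), (j, l) in itertools.combinations(items, 2):
            if pa.aligned(i, k, j, l):
                total += 1
    return total


def find_seed(pa: PairwiseAlignmentSet) -> ConsensusAlignment:
    """Seed consensus from the pocket triple with the most cyclically
    consistent aligned residue triples.

    A residue triple (k, l, m) of pockets (i, j, p) is consistent when all
    three pairwise alignments agree: k<->l, k<->m and l<->m. Ties between
    triples are broken by lexicographic pocket-index order. For M <= 2 the
    consensus is the pairwise mapping (M = 2) or the pocket itself (M = 1).
    """
    m = pa.m
    if m == 0:
        return ConsensusAlignment(pa, [], set(), 0)
    if m == 1:
        cols = [{0: k} for k in range(pa.sizes[0])]
        return ConsensusAlignment(pa, cols, {0}, 0)
    if m == 2:
        cols = [{0: k, 1: l} for k, l in sorted(pa.pair_map(0, 1).items())]
        cons = ConsensusAlignment(pa, cols, {0, 1})
        cons.objective = objective_score(cons)
        return cons

    best = (-1, None, None)  # count, triple, columns
    for i, j, p in itertools.combinations(range(m), 3):
        ij = pa.pair_map(i, j)
        ip = pa.pair_map(i, p)
        jp = pa.pair_map(j, p)
        cols = []
        for k in sorted(ij):
            l = ij[k]
            mm = ip.get(k)
            if mm is not None and jp.get(l) == mm:
                cols.append({i: k, j: l, p: mm})
        if len(cols) > best[0]:
            best = (len(cols), (i, j, p), cols)
    count, triple, cols = best
    cons = ConsensusAlignment(pa, list(cols), set(triple))
    cons.objective = objective_score(cons)
    return cons


def max_weight_matching(weights) -> list:
    """One-to-one matching maximising total weight on a non-negative n x m
    matrix; zero-weight pairs are excluded. Returns sorted (row, col) pairs."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        return []
    if np.any(w < 0):
        raise InputError("max_weight_matching requires non-negative weights")
    rows, cols = linear_sum_assignment(w, maximize=True)
    return sorted((int(r), int(c)) for r, c in zip(rows, cols) if w[r, c] > 0)


def add_pocket(cons: ConsensusAlignment, i: int,
               pa: Optional[PairwiseAlignmentSet] = None) -> ConsensusAlignment:
    """Greedily assign pocket ``i`` against the current columns.

    weight(k, c) = number of already-assigned residues in column c that are
    pairwise-aligned with residue k of pocket i. Residues matched to no
    column may open new columns while the total stays within the group's
    maximum pocket size.
    """
    pa = pa or cons.pa
    if not cons.columns and not cons.assigned:
        raise InputError("cannot add to an empty consensus; build a seed first")
    if i in cons.assigned:
        raise InputError(f"pocket {i} is already assigned")
    n_i = pa.sizes[i]
    n_cols = len(cons.columns)
    w = np.zeros((n_i, n_cols))
    maps = {j: pa.pair_map(i, j) for j in cons.assigned}
    for c, col in enumerate(cons.columns):
        for j, l in col.items():
            mj = maps.get(j)
            if mj is None:
                continue
            for k, l2 in mj.items():
                if l2 == l:
                    w[k, c] += 1
    matching = max_weight_matching(w) if n_cols else []
    columns = [dict(col) for col in cons.columns]
    matched_residues = set()
    for k, c in matching:
        columns[c][i] = k
        matched_residues.add(k)
    for k in range(n_i):
        if k not in matched_residues and len(columns) < pa.n_max:
            columns.append({i: k})
    out = ConsensusAlignment(pa, columns, set(cons.assigned) | {i})
    out.objective = objective_score(out)
    return out


def refine(cons: ConsensusAlignment,
           pa: Optional[PairwiseAlignmentSet] = None,
           max_rounds: int = 10) -> ConsensusAlignment:
    """Iteratively remove and re-add each pocket, keeping re-assignments
    that do not decrease the objective; stops after a round with no
    improvement or ``max_rounds``. Objective is monotone non-decreasing."""
    pa = pa or cons.pa
    current = cons
    for _ in range(max_rounds):
        improved = False
        for i in range(pa.m):
            if i not in current.assigned:
                continue
            if len(current.assigned) <= 1:
                continue
            stripped_cols = []
            for col in current.columns:
                col2 = {j: l for j, l in col.items() if j != i}
                if col2:
                    stripped_cols.append(col2)
            stripped = ConsensusAlignment(
                pa, stripped_cols, current.assigned - {i})
            stripped.objective = objective_score(stripped)
            candidate = add_pocket(stripped, i, pa)
            if candidate.objective > current.objective:
                current = candidate
                improved = True
            elif candidate.objective == current.objective:
                current = candidate  # keep (does not decrease)
        if not improved:
            break
    return current


def build_consensus(member_ids: Sequence[str],
                    pa: PairwiseAlignmentSet) -> ConsensusAlignment:
    """Full greedy consensus for a group: seed of three, greedy insertion in
    descending order of pairwise-alignment overlap with the assigned set
    (ties by pocket index), then refinement. Deterministic."""
    missing = [pid for pid in member_ids if pid not in pa.pocket_ids]
    if missing:
        raise InputError(f"pockets absent from pairwise set: {missing}")
    cons = find_seed(pa)
    while len(cons.assigned) < pa.m:
        remaining = [i for i in range(pa.m) if i not in cons.assigned]

        def overlap(i: int) -> int:
            tot = 0
            for j in cons.assigned:
                tot += len(pa.pair_map(i, j))
            return tot

        nxt = max(remaining, key=lambda i: (overlap(i), -i))
        cons = add_pocket(cons, nxt, pa)
    cons = refine(cons, pa)
    # drop empty columns and order deterministically
    cols = [col for col in cons.columns if col]
    cols.sort(key=lambda col: (min(col), col[min(col)]))
    out = ConsensusAlignment(pa, cols, set(cons.assigned))
    out.objective = objective_score(out)
    return out
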