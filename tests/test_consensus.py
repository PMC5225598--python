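"""Consensus multiple alignment: objective, seed, matching, greedy solver."""

import itertools

import numpy as np
import pytest

from pocketmotif.consensus import (ConsensusAlignment, PairwiseAlignmentSet,
                                   add_pocket, build_consensus, find_seed,
                                   max_weight_matching, objective_score,
                                   refine)
from pocketmotif.nsalign import all_vs_all
from pocketmotif.structio import InputError
from pocketmotif.synthetic import make_family, make_template_pocket


def identity_pa(m, n):
    """M pockets of size n whose pairwise alignments are all the identity."""
    ident = {k: k for k in range(n)}
    delta = {(i, j): dict(ident) for i in range(m) for j in range(i + 1, m)}
    return PairwiseAlignmentSet(tuple(f"p{i}" for i in range(m)),
                                tuple([n] * m), delta)


def brute_force_optimum(pa):
    """Exhaustive maximum of the consistency objective for small instances.

    Adding assignments never lowers the objective, so it suffices to search
    over full per-pocket bijections residue -> column (columns = n_max).
    """
    n = pa.n_max
    best = 0
    perms = list(itertools.permutations(range(n)))
    for combo in itertools.product(perms, repeat=pa.m):
        # combo[i][k] = column of residue k in pocket i
        total = 0
        for i in range(pa.m):
            for j in range(i + 1, pa.m):
                mp = pa.pair_map(i, j)
                for k, l in mp.items():
                    if k < n and l < n and combo[i][k] == combo[j][l]:
                        total += 1
        best = max(best, total)
    return best


class TestObjective:
    def test_identity_family_hand_count(self):
        pa = identity_pa(3, 4)
        cols = [{0: k, 1: k, 2: k} for k in range(4)]
        cons = ConsensusAlignment(pa, cols, {0, 1, 2})
        assert objective_score(cons) == 12  # 3 pocket pairs x 4 columns

    def test_empty_assignment(self):
        pa = identity_pa(3, 4)
        cons = ConsensusAlignment(pa, [], set())
        assert objective_score(cons) == 0

    def test_m2_counts_delta_columns(self):
        delta = {(0, 1): {0: 1, 1: 0, 2: 2}}
        pa = PairwiseAlignmentSet(("a", "b"), (3, 3), delta)
        # columns 1 and 3 agree with delta; column 2 does not
        cols = [{0: 0, 1: 1}, {0: 1, 1: 2}, {0: 2, 1: 0}]
        cons = ConsensusAlignment(pa, cols, {0, 1})
        assert objective_score(cons) == 1

    def test_constraint_violation_rejected(self):
        pa = identity_pa(2, 3)
        cons = ConsensusAlignment(pa, [{0: 0, 1: 0}, {0: 0, 1: 1}], {0, 1})
        with pytest.raises(InputError):
            objective_score(cons)  # pocket 0 residue 0 in two columns


class TestFindSeed:
    def test_best_triple_wins(self):
        # pockets 0,1,2 share 5 cyclically consistent triples; any triple
        # with pocket 3 shares at most 2
        ident5 = {k: k for k in range(5)}
        small = {0: 0, 1: 1}
        delta = {(0, 1): dict(ident5), (0, 2): dict(ident5),
                 (1, 2): dict(ident5), (0, 3): dict(small),
                 (1, 3): dict(small), (2, 3): dict(small)}
        pa = PairwiseAlignmentSet(("a", "b", "c", "d"), (5, 5, 5, 5), delta)
        seed = find_seed(pa)
        assert seed.assigned == {0, 1, 2}
        assert seed.n_columns == 5

    def test_empty_alignments_empty_seed(self):
        pa = PairwiseAlignmentSet(("a", "b", "c"), (4, 4, 4), {})
        seed = find_seed(pa)
        assert seed.n_columns == 0
        assert seed.objective == 0

    def test_m3_unique_triple(self):
        pa = identity_pa(3, 4)
        seed = find_seed(pa)
        assert seed.assigned == {0, 1, 2}
        assert seed.n_columns == 4

    def test_m1_consensus_is_pocket(self):
        pa = PairwiseAlignmentSet(("a",), (4,), {})
        seed = find_seed(pa)
        assert seed.n_columns == 4 and seed.objective == 0

    def test_m2_consensus_is_pairwise(self):
        delta = {(0, 1): {0: 2, 1: 0}}
        pa = PairwiseAlignmentSet(("a", "b"), (3, 3), delta)
        seed = find_seed(pa)
        assert [(c.get(0), c.get(1)) for c in seed.columns] == [(0, 2), (1, 0)]


class TestMaxWeightMatching:
    def test_diagonal_dominant(self):
        w = np.array([[5.0, 1, 1], [1, 6, 1], [1, 1, 7]])
        assert max_weight_matching(w) == [(0, 0), (1, 1), (2, 2)]

    def test_all_zero(self):
        assert max_weight_matching(np.zeros((3, 4))) == []

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            max_weight_matching(np.array([[1.0, -1.0]]))

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(200 + trial)
        n, m = rng.integers(1, 7, 2)
        w = np.round(rng.random((n, m)) * 10, 3)
        w[rng.random((n, m)) < 0.3] = 0.0
        got = max_weight_matching(w)
        got_weight = sum(w[i, j] for i, j in got)
        best = 0.0
        cols = range(m)
        for k in range(min(n, m) + 1):
            for rows_sel in itertools.combinations(range(n), k):
                for cols_sel in itertools.permutations(cols, k):
                    best = max(best, sum(
                        w[r, c] for r, c in zip(rows_sel, cols_sel)))
        assert got_weight == pytest.approx(best, abs=1e-9)


class TestAddAndRefine:
    def test_add_identical_pocket_increments(self):
        pa = identity_pa(4, 4)
        seed = find_seed(pa)  # pockets 0,1,2 assigned, objective 12
        grown = add_pocket(seed, 3)
        # new pocket matches all 4 columns against 3 assigned pockets
        assert grown.objective == seed.objective + 3 * 4

    def test_add_unaligned_pocket_no_gain(self):
        ident = {k: k for k in range(4)}
        delta = {(0, 1): dict(ident), (0, 2): dict(ident),
                 (1, 2): dict(ident)}
        pa = PairwiseAlignmentSet(("a", "b", "c", "d"), (4, 4, 4, 4), delta)
        seed = find_seed(pa)
        grown = add_pocket(seed, 3)  # no delta rows for pocket 3
        assert grown.objective == seed.objective

    def test_add_to_empty_consensus_rejected(self):
        pa = identity_pa(3, 4)
        empty = ConsensusAlignment(pa, [], set())
        with pytest.raises(InputError):
            add_pocket(empty, 0)

    def test_refine_fixed_point_on_consistent_family(self):
        pa = identity_pa(4, 4)
        cons = build_consensus([f"p{i}" for i in range(4)], pa)
        refined = refine(cons, pa)
        assert refined.objective == cons.objective == 6 * 4

    @pytest.mark.parametrize("trial", range(10))
    def test_refine_never_decreases(self, trial):
        rng = np.random.default_rng(300 + trial)
        pa = _random_pa(rng, m=4, n=3)
        cons = find_seed(pa)
        for i in range(pa.m):
            if i not in cons.assigned:
                cons = add_pocket(cons, i)
        refined = refine(cons, pa)
        assert refined.objective >= cons.objective


def _random_pa(rng, m, n):
    delta = {}
    for i in range(m):
        for j in range(i + 1, m):
            ks = list(rng.permutation(n))
            ls = list(rng.permutation(n))
            size = int(rng.integers(0, n + 1))
            delta[(i, j)] = {int(ks[t]): int(ls[t]) for t in range(size)}
    return PairwiseAlignmentSet(tuple(f"p{i}" for i in range(m)),
                                tuple([n] * m), delta)


class TestBuildConsensus:
    def test_noisy_family_full_columns(self):
        tpl = make_template_pocket(8, seed=51)
        members = [m.pocket for m in
                   make_family(tpl, 6, 0.2, permute=True, seed=52)]
        results = all_vs_all(members)
        ids = sorted(p.pocket_id for p in members)
        pa = PairwiseAlignmentSet.from_alignment_results(
            ids, [8] * 6, results)
        cons = build_consensus(ids, pa)
        full = sum(1 for col in cons.columns if len(col) == 6)
        assert full == 8  # every template residue occupies one full column
        assert cons.objective == 15 * 8

    def test_single_pocket_group(self):
        pa = PairwiseAlignmentSet(("a",), (5,), {})
        cons = build_consensus(["a"], pa)
        assert cons.objective == 0
        assert cons.n_columns == 5

    def test_two_pocket_group_is_pairwise_mapping(self):
        delta = {(0, 1): {0: 1, 2: 0}}
        pa = PairwiseAlignmentSet(("a", "b"), (3, 3), delta)
        cons = build_consensus(["a", "b"], pa)
        pairs = sorted((c[0], c[1]) for c in cons.columns if len(c) == 2)
        assert pairs == [(0, 1), (2, 0)]

    @pytest.mark.parametrize("trial", range(8))
    def test_greedy_bounded_by_brute_force(self, trial):
        rng = np.random.default_rng(400 + trial)
        pa = _random_pa(rng, m=4, n=3)
        cons = build_consensus(list(pa.pocket_ids), pa)
        assert cons.objective <= brute_force_optimum(pa)

    def test_relabel_invariance_up_to_columns(self):
        rng = np.random.default_rng(500)
        pa = _random_pa(rng, m=4, n=3)
        cons1 = build_consensus(list(pa.pocket_ids), pa)
        # relabeled ids, same structure
        pa2 = PairwiseAlignmentSet(tuple(f"z{i}" for i in range(4)),
                                   pa.sizes, pa.delta)
        cons2 = build_consensus(list(pa2.pocket_ids), pa2)
        assert cons1.objective == cons2.objective
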