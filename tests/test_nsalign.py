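"""Non-sequential alignment engine: Kabsch, assignment, Q-score, outer loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pocketmotif.nsalign import (AlignmentParams, Superposition, align_pockets,
                                 all_vs_all, assign_correspondence,
                                 kabsch_superpose, q_score)
from pocketmotif.structio import InputError
from pocketmotif.synthetic import make_family, make_template_pocket

from conftest import make_pocket


def _random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()


class TestKabsch:
    def test_identity(self):
        a = np.random.default_rng(0).uniform(0, 10, (6, 3))
        sup, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(sup.translation, 0, atol=1e-12)

    def test_recovers_rigid_motion(self):
        a = np.random.default_rng(1).uniform(0, 10, (8, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = (a - a.mean(0)) @ Rz.T + a.mean(0) + [1, 2, 3]
        sup, rmsd = kabsch_superpose(a, b)
        assert rmsd < 1e-9
        np.testing.assert_allclose(sup.apply(b), a, atol=1e-8)

    def test_matches_numeric_minimizer(self):
        # independent oracle: direct minimization over a rotation-vector
        # parameterization of SO(3)
        a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        b = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1.2, 0]])
        _, rmsd = kabsch_superpose(a, b)

        ac, bc = a - a.mean(0), b - b.mean(0)

        def cost(rv):
            R = Rotation.from_rotvec(rv).as_matrix()
            return np.sum((bc @ R.T - ac) ** 2)

        best = min(minimize(cost, x0, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14}).fun
                   for x0 in [np.zeros(3), [0.1, 0.2, 0.3], [2, -1, 0.5],
                              [-2, 2, -2]])
        assert rmsd == pytest.approx(np.sqrt(best / len(a)), abs=1e-6)

    def test_no_reflection(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10, (5, 3))
        b = a.copy()
        b[:, 0] = -b[:, 0]  # mirrored copy
        sup, _ = kabsch_superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_errors(self):
        with pytest.raises(InputError):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(InputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestAssign:
    def test_permutation_recovery(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 30, (8, 3))
        perm = rng.permutation(8)
        b = a[perm]
        mapping = assign_correspondence(a, b, Superposition.identity(), 5.0)
        assert dict(mapping) == {int(perm[j]): j for j in range(8)}

    def test_all_too_far(self):
        a = np.zeros((4, 3))
        b = np.zeros((4, 3)) + [100, 0, 0]
        assert assign_correspondence(a, b, Superposition.identity(), 5.0) == ()

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = rng.uniform(0, 8, (6, 3))
        b = rng.uniform(0, 8, (6, 3))
        d_max = 4.0
        mapping = assign_correspondence(a, b, Superposition.identity(), d_max)
        d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
        allowed = d2 <= d_max ** 2
        best = None
        for perm in itertools.permutations(range(6)):
            pairs = tuple((i, perm[i]) for i in range(6) if allowed[i, perm[i]])
            score = (-len(pairs), sum(d2[i, j] for i, j in pairs), pairs)
            if best is None or score < best:
                best = score
        assert mapping == best[2]
        assert len(mapping) == -best[0]


class TestQScore:
    def test_reference_values(self):
        assert q_score(5, 0.0, 5, 5, 3.0) == 1.0
        assert q_score(5, 3.0, 5, 5, 3.0) == 0.5
        assert q_score(4, 1.5, 5, 8, 3.0) == pytest.approx(0.32, abs=1e-15)

    def test_preconditions(self):
        with pytest.raises(InputError):
            q_score(6, 1.0, 5, 5)
        with pytest.raises(InputError):
            q_score(3, -0.1, 5, 5)
        with pytest.raises(InputError):
            q_score(0, 0.0, 0, 5)

    @given(n_align=st.integers(1, 10), rmsd=st.floats(0, 20),
           extra=st.floats(0.01, 10))
    @settings(deadline=None, max_examples=50)
    def test_monotonicity(self, n_align, rmsd, extra):
        n1 = n2 = 10
        base = q_score(n_align, rmsd, n1, n2)
        assert 0 <= base <= 1
        assert q_score(n_align, rmsd + extra, n1, n2) < base
        if n_align < min(n1, n2):
            assert q_score(n_align + 1, rmsd, n1, n2) > base


class TestAlignPockets:
    def test_self_alignment_under_permutation(self):
        tpl = make_template_pocket(10, seed=21)
        (member,) = make_family(tpl, 1, 0.0, permute=True, seed=22)
        res = align_pockets(tpl, member.pocket)
        assert res.n_align == 10
        assert res.rmsd < 1e-6
        assert abs(res.q - 1.0) < 1e-9
        # recovered mapping composes with the stored permutation to identity
        for a_idx, b_idx in res.mapping:
            assert member.correspondence[b_idx] == a_idx

    def test_noisy_copy_rmsd_in_band(self):
        sigma = 0.2
        tpl = make_template_pocket(10, seed=23)
        members = make_family(tpl, 40, sigma, permute=True, seed=24)
        rmsds = []
        for m in members:
            res = align_pockets(tpl, m.pocket)
            assert res.n_align == 10
            rmsds.append(res.rmsd)
        mean = np.mean(rmsds)
        assert 0.5 * sigma * np.sqrt(3) <= mean <= 1.5 * sigma * np.sqrt(3)

    def test_unrelated_clouds_score_lower(self):
        tpl = make_template_pocket(10, seed=25)
        noisy = make_family(tpl, 10, 0.2, permute=True, seed=26)
        noisy_qs = [align_pockets(tpl, m.pocket).q for m in noisy]
        rng = np.random.default_rng(27)
        random_qs = []
        for i in range(10):
            other = make_template_pocket(10, seed=int(rng.integers(2 ** 31)),
                                         pocket_id=f"R{i}:1:A")
            random_qs.append(align_pockets(tpl, other).q)
        assert max(random_qs) < min(noisy_qs)

    def test_rigid_motion_invariance(self):
        tpl = make_template_pocket(10, seed=28)
        other = make_template_pocket(10, seed=29, pocket_id="OTH:1:A")
        base = align_pockets(tpl, other)
        rng = np.random.default_rng(30)
        R = _random_rotation(rng)
        t = rng.uniform(-50, 50, 3)
        moved = make_pocket(other.coords() @ R.T + t, pocket_id="OTH:1:A",
                            letters=other.sequence())
        res = align_pockets(tpl, moved)
        assert abs(res.q - base.q) < 1e-6
        assert res.n_align == base.n_align

    def test_symmetry_exact(self):
        a = make_template_pocket(9, seed=31, pocket_id="AAA:1:A")
        b = make_template_pocket(11, seed=32, pocket_id="BBB:1:A")
        assert align_pockets(a, b).q == align_pockets(b, a).q

    def test_too_small(self):
        a = make_pocket(np.eye(2, 3) * 5)
        b = make_pocket(np.eye(5, 3) * 5, pocket_id="B:1:A")
        with pytest.raises(InputError):
            align_pockets(a, b)


class TestAllVsAll:
    def test_pair_count(self):
        pockets = [make_template_pocket(8, seed=40 + i,
                                        pocket_id=f"P{i}:1:A")
                   for i in range(4)]
        results = all_vs_all(pockets)
        assert len(results) == 6
        assert all(r.id_a < r.id_b for r in results)

    def test_duplicate_ids_rejected(self):
        p = make_template_pocket(8, seed=44)
        with pytest.raises(InputError, match="duplicate"):
            all_vs_all([p, p])

    def test_identical_pockets_score_one(self):
        tpl = make_template_pocket(8, seed=45)
        pockets = [make_pocket(tpl.coords(), pocket_id=f"C{i}:1:A",
                               letters=tpl.sequence()) for i in range(3)]
        for r in all_vs_all(pockets):
            assert abs(r.q - 1.0) < 1e-9
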