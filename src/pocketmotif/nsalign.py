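"""Non-sequential rigid-body structure alignment and Q-score.

Aligns two residue point sets (CA representation) without any constraint
from primary-sequence order. The two classical objectives — minimise the
total squared distance of aligned residues and maximise the number of
aligned residues — are optimised by an alternating scheme:

1. given a rigid superposition, solve an optimal one-to-one assignment on
   squared inter-residue distances, with pairs farther than ``d_max``
   forbidden (so the assignment is as large as possible, and among maximal
   assignments has minimal total squared distance);
2. given the assignment, recompute the least-squares (Kabsch) superposition
   of the mapped residues;

iterated from multiple deterministic initial orientations (principal-axis
frames plus a fixed low-discrepancy set of rotations), keeping the converged
result with the best Q-score.

The similarity of an alignment is summarised by the Q-score

    Q = N_align^2 / ((1 + (RMSD/R0)^2) * N1 * N2),       R0 = 3.0 A

which is 1 for identical pockets and decreases with fewer aligned residues
or a worse geometric fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .structio import InputError, PocketMotifError, PocketStructure

__all__ = [
    "Superposition",
    "AlignmentParams",
    "AlignmentResult",
    "kabsch_superpose",
    "assign_correspondence",
    "q_score",
    "align_pockets",
    "all_vs_all",
]


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform x -> R x + t (Angstrom)."""
    rotation: np.ndarray   # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "Superposition":
        return Superposition(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AlignmentParams:
    r0: float = 3.0              # Q-score normalising factor, Angstrom
    d_max: float = 5.0           # assignment distance gate, Angstrom
    n_rotation_seeds: int = 24   # quasi-uniform extra starting rotations
    max_iter: int = 50
    tol: float = 1e-6            # RMSD-change convergence threshold

    def __post_init__(self):
        for name in ("r0", "d_max", "max_iter", "tol"):
            if getattr(self, name) <= 0:
                raise InputError(f"AlignmentParams.{name} must be positive")
        if self.n_rotation_seeds < 0:
            raise InputError("n_rotation_seeds must be >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    id_a: str
    id_b: str
    mapping: tuple               # of (a_index, b_index), sorted
    n_align: int
    rmsd: float
    q: float
    n1: int
    n2: int
    superposition: Superposition

    def swapped(self) -> "AlignmentResult":
        """The same alignment viewed from the other side (mapping flipped)."""
        inv_rot = self.superposition.rotation.T
        inv_t = -inv_rot @ self.superposition.translation
        return AlignmentResult(
            self.id_b, self.id_a,
            tuple(sorted((j, i) for i, j in self.mapping)),
            self.n_align, self.rmsd, self.q, self.n2, self.n1,
            Superposition(inv_rot, inv_t))


# ---------------------------------------------------------------------------
# Kabsch superposition

def kabsch_superpose(points_a, points_b):
    """Least-squares proper rigid superposition of B onto A.

    Returns ``(Superposition, rmsd)`` where the transform minimises
    sum ||R b_i + t - a_i||^2 over proper rotations; rmsd is the root mean
    of the minimised squared distances. Reflections are never returned.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise InputError(
            f"point sets differ in length: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise InputError(f"need at least 3 points, got {len(a)}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    A, B = a - ca, b - cb
    M = A.T @ B
    U, S, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = ca - R @ cb
    diff = B @ R.T - A
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return Superposition(R, t), rmsd


# ---------------------------------------------------------------------------
# Correspondence assignment

def assign_correspondence(coords_a, coords_b, sup: Superposition,
                          d_max: float) -> tuple:
    """Optimal one-to-one residue correspondence under a fixed superposition.

    Solves a linear assignment on squared distances after applying ``sup``
    to B, with pairs farther than ``d_max`` forbidden. Among assignments of
    maximal size the returned one has minimal total squared distance. May be
    empty. Returned as a sorted tuple of (a_index, b_index).
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        return ()
    tb = sup.apply(b)
    d2 = cdist(a, tb, "sqeuclidean")
    allowed = d2 <= d_max * d_max
    if not allowed.any():
        return ()
    # Forbidden cost exceeds any total allowed cost, so the assignment first
    # maximises the number of allowed pairs, then minimises their total d^2.
    big = d_max * d_max * (min(len(a), len(b)) + 1.0) + 1.0
    cost = np.where(allowed, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return tuple(sorted((int(i), int(j)) for i, j in zip(rows, cols)
                        if allowed[i, j]))


# ---------------------------------------------------------------------------
# Q-score

def q_score(n_align: int, rmsd: float, n1: int, n2: int,
            r0: float = 3.0) -> float:
    """Q = N_align^2 / ((1 + (RMSD/R0)^2) * N1 * N2), in [0, 1]."""
    if n1 < 1 or n2 < 1:
        raise InputError("pocket sizes must be >= 1")
    if not (0 <= n_align <= min(n1, n2)):
        raise InputError(
            f"n_align={n_align} outside [0, min({n1}, {n2})]")
    if rmsd < 0:
        raise InputError("rmsd must be >= 0")
    return (n_align * n_align) / ((1.0 + (rmsd / r0) ** 2) * n1 * n2)


# ---------------------------------------------------------------------------
# Initial orientation seeds

def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Canonical right-handed principal-axis frame (columns = axes,
    descending variance).

    Axis signs are fixed by the third moment (skewness) of the projections,
    which is intrinsic to the point cloud, so the frame co-rotates with any
    rigid motion of the input — this is what makes the seeded alignment
    invariant under rigid motion of either structure.
    """
    c = points - points.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1].copy()  # descending eigenvalues
    for k in range(2):
        proj = c @ v[:, k]
        s = np.sum(proj ** 3)
        if s < 0 or (s == 0 and proj.min() + proj.max() < 0):
            v[:, k] = -v[:, k]
    v[:, 2] = np.cross(v[:, 0], v[:, 1])  # right-handed third axis
    return v


_PA_SIGNS = (
    (1.0, 1.0, 1.0), (1.0, -1.0, -1.0), (-1.0, 1.0, -1.0), (-1.0, -1.0, 1.0),
)


def _halton(index: int, base: int) -> float:
    f, r = 1.0, 0.0
    i = index
    while i > 0:
        f /= base
        r += f * (i % base)
        i //= base
    return r


def _quasi_uniform_rotations(n: int) -> list:
    """Deterministic quasi-uniform rotation matrices (Shoemake's uniform
    quaternion map applied to a Halton sequence in bases 2, 3, 5)."""
    out = []
    for idx in range(1, n + 1):
        u1, u2, u3 = _halton(idx, 2), _halton(idx, 3), _halton(idx, 5)
        s1, s2 = np.sqrt(1.0 - u1), np.sqrt(u1)
        w = s1 * np.sin(2 * np.pi * u2)
        x = s1 * np.cos(2 * np.pi * u2)
        y = s2 * np.sin(2 * np.pi * u3)
        z = s2 * np.cos(2 * np.pi * u3)
        # quaternion (w, x, y, z) -> rotation matrix
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        out.append(R)
    return out


def _seed_rotations(a: np.ndarray, b: np.ndarray, n_extra: int) -> list:
    """Initial rotations applied to centred B: principal-axis frames of A
    matched to those of B under 4 proper sign flips, plus quasi-uniform
    rotations expressed in the intrinsic frames (Va R Vb^T), so that the
    whole start set co-rotates with either structure."""
    va, vb = _principal_axes(a), _principal_axes(b)
    seeds = [va @ np.diag(s) @ vb.T for s in _PA_SIGNS]
    seeds.extend(va @ R @ vb.T for R in _quasi_uniform_rotations(n_extra))
    return seeds


# ---------------------------------------------------------------------------
# Core alternating alignment

def align_coords(coords_a, coords_b, params: AlignmentParams,
                 pa_seeds_only: bool = False):
    """Align two coordinate sets; returns (mapping, rmsd, Superposition).

    ``pa_seeds_only`` restricts the start set to the four principal-axis
    frames — appropriate at chain scale where exhaustive rotational seeding
    is wasteful (O(seeds * n^2) per iteration at ~200 residues).
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if len(a) < 3 or len(b) < 3:
        raise InputError(
            f"alignment needs >= 3 residues per structure, got {len(a)}, {len(b)}")
    n_extra = 0 if pa_seeds_only else params.n_rotation_seeds
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    best = ((), 0.0, Superposition.identity(), -1.0)  # mapping, rmsd, sup, q
    max_q = 1.0
    n1, n2 = len(a), len(b)
    for R0 in _seed_rotations(a, b, n_extra):
        sup = Superposition(R0, ca - R0 @ cb)
        mapping = assign_correspondence(a, b, sup, params.d_max)
        rmsd = _mapped_rmsd(a, b, mapping, sup)
        prev_rmsd = np.inf
        for _ in range(params.max_iter):
            if len(mapping) < 3:
                break
            ai = a[[i for i, _ in mapping]]
            bj = b[[j for _, j in mapping]]
            sup, rmsd = kabsch_superpose(ai, bj)
            new_mapping = assign_correspondence(a, b, sup, params.d_max)
            if new_mapping == mapping and abs(prev_rmsd - rmsd) < params.tol:
                break
            prev_rmsd = rmsd
            if len(new_mapping) >= 3:
                ai = a[[i for i, _ in new_mapping]]
                bj = b[[j for _, j in new_mapping]]
                _, rmsd = kabsch_superpose(ai, bj)
            else:
                rmsd = _mapped_rmsd(a, b, new_mapping, sup)
            mapping = new_mapping
        # final consistent refit on the converged mapping
        if len(mapping) >= 3:
            ai = a[[i for i, _ in mapping]]
            bj = b[[j for _, j in mapping]]
            sup, rmsd = kabsch_superpose(ai, bj)
        q = q_score(len(mapping), rmsd, n1, n2, params.r0)
        if q > best[3]:
            best = (mapping, rmsd, sup, q)
        if best[3] >= max_q - 1e-12:
            break  # cannot improve on a perfect alignment
    return best[0], best[1], best[2]


def _mapped_rmsd(a, b, mapping, sup) -> float:
    if not mapping:
        return 0.0
    ai = a[[i for i, _ in mapping]]
    bj = sup.apply(b[[j for _, j in mapping]])
    return float(np.sqrt(np.mean(np.sum((bj - ai) ** 2, axis=1))))


def align_pockets(a: PocketStructure, b: PocketStructure,
                  params: AlignmentParams = AlignmentParams()
                  ) -> AlignmentResult:
    """Non-sequential alignment of two pockets; symmetric in its arguments.

    Internally the pair is put in canonical (lexicographic pocket_id) order,
    so ``align_pockets(a, b).q == align_pockets(b, a).q`` exactly.
    """
    if len(a) < 3 or len(b) < 3:
        raise InputError(
            f"pockets must have >= 3 residues: {a.pocket_id} has {len(a)}, "
            f"{b.pocket_id} has {len(b)}")
    swap = b.pocket_id < a.pocket_id
    first, second = (b, a) if swap else (a, b)
    mapping, rmsd, sup = align_coords(first.coords(), second.coords(), params)
    res = AlignmentResult(
        id_a=first.pocket_id, id_b=second.pocket_id,
        mapping=tuple(mapping), n_align=len(mapping), rmsd=rmsd,
        q=q_score(len(mapping), rmsd, len(first), len(second), params.r0),
        n1=len(first), n2=len(second), superposition=sup)
    return res.swapped() if swap else res


def all_vs_all(pockets: Sequence[PocketStructure],
               params: AlignmentParams = AlignmentParams(),
               progress: bool = False) -> list:
    """All-against-all pocket alignment.

    Returns one AlignmentResult per unordered pair, in canonical
    (lexicographic pocket_id) order, hence deterministic.
    """
    if len(pockets) < 2:
        raise InputError("all_vs_all needs at least 2 pockets")
    ids = [p.pocket_id for p in pockets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate pocket ids: {dupes}")
    ordered = sorted(pockets, key=lambda p: p.pocket_id)
    results = []
    n = len(ordered)
    total = n * (n - 1) // 2
    done = 0
    log = logging.getLogger("pocketmotif.align")
    for i in range(n):
        for j in range(i + 1, n):
            try:
                results.append(align_pockets(ordered[i], ordered[j], params))
            except PocketMotifError as exc:  # pragma: no cover - re-raise w/ ids
                raise type(exc)(
                    f"pair ({ordered[i].pocket_id}, {ordered[j].pocket_id}): {exc}")
            done += 1
        if progress and n > 10:
            log.info("aligned %d/%d pairs", done, total)
    return results
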