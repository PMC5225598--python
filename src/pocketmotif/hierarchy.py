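"""Protein-level similarity and pocket <-> protein group correspondence.

Whole chains are aligned with the same non-sequential engine as pockets (the
Q-score then uses chain lengths for N1, N2), but starting only from the four
principal-axis frames — exhaustive rotational seeding is wasteful at chain
scale, where the alternating refinement converges from a coarse start
(cost per iteration is O(n^2) in chain length). Protein-level significance
must be calibrated on its own background of random chain pairs, never the
pocket EVD: the Q null shifts with structure size.

The correspondence table joins each pocket's group with its parent protein's
group, and summarises how often the pockets of one protein scatter across
several pocket groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .nsalign import AlignmentParams, AlignmentResult, align_coords, q_score
from .simnet import PocketGroup
from .structio import ChainStructure, InputError, write_table

__all__ = [
    "CorrespondenceTable",
    "align_chains",
    "build_correspondence",
    "write_correspondence_table",
]


@dataclass(frozen=True)
class CorrespondenceTable:
    rows: tuple                  # of (protein_id, protein_group, pocket_id, pocket_group)
    summary: dict                # protein_group -> {pocket_group: count}
    spanning_fraction: float     # multi-pocket proteins spanning >1 pocket group


def align_chains(a: ChainStructure, b: ChainStructure,
                 params: AlignmentParams = AlignmentParams()
                 ) -> AlignmentResult:
    """Non-sequential chain-vs-chain alignment (principal-axis seeds only)."""
    ca, cb = a.ca_coords(), b.ca_coords()
    if len(ca) < 3 or len(cb) < 3:
        raise InputError(
            f"chains need >= 3 CA residues: {a.id} has {len(ca)}, "
            f"{b.id} has {len(cb)}")
    swap = b.id < a.id
    (first, cf), (second, cs) = ((b, cb), (a, ca)) if swap else ((a, ca), (b, cb))
    mapping, rmsd, sup = align_coords(cf, cs, params, pa_seeds_only=True)
    res = AlignmentResult(
        id_a=first.id, id_b=second.id, mapping=tuple(mapping),
        n_align=len(mapping), rmsd=rmsd,
        q=q_score(len(mapping), rmsd, len(cf), len(cs), params.r0),
        n1=len(cf), n2=len(cs), superposition=sup)
    return res.swapped() if swap else res


def all_vs_all_chains(chains: Sequence[ChainStructure],
                      params: AlignmentParams = AlignmentParams()) -> list:
    """All-against-all chain alignment in canonical id order."""
    if len(chains) < 2:
        raise InputError("need at least 2 chains")
    ids = [c.id for c in chains]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate chain ids")
    ordered = sorted(chains, key=lambda c: c.id)
    return [align_chains(ordered[i], ordered[j], params)
            for i in range(len(ordered)) for j in range(i + 1, len(ordered))]


def build_correspondence(pocket_groups: Sequence[PocketGroup],
                         protein_groups: Sequence[PocketGroup],
                         pocket_parents: Mapping[str, str]
                         ) -> CorrespondenceTable:
    """Join pocket and protein group assignments.

    ``pocket_parents`` maps pocket id -> parent protein id. Every pocket in
    ``pocket_groups`` must have a parent that appears in ``protein_groups``.
    The spanning fraction is the share of proteins with more than one pocket
    whose pockets fall into more than one pocket group.
    """
    pocket_group_of = {pid: g.group_id
                       for g in pocket_groups for pid in g.members}
    protein_group_of = {pid: g.group_id
                        for g in protein_groups for pid in g.members}
    orphans = sorted(p for p in pocket_group_of if p not in pocket_parents)
    if orphans:
        raise InputError(f"pockets without a parent protein: {orphans}")
    missing = sorted({pocket_parents[p] for p in pocket_group_of}
                     - set(protein_group_of))
    if missing:
        raise InputError(f"parent proteins without a protein group: {missing}")

    rows = []
    per_protein: dict = {}
    for pocket_id in sorted(pocket_group_of):
        protein_id = pocket_parents[pocket_id]
        pg = protein_group_of[protein_id]
        kg = pocket_group_of[pocket_id]
        rows.append((protein_id, pg, pocket_id, kg))
        per_protein.setdefault(protein_id, []).append(kg)

    summary: dict = {}
    for protein_id, pg, pocket_id, kg in rows:
        summary.setdefault(pg, {}).setdefault(kg, 0)
        summary[pg][kg] += 1

    multi = [p for p, groups in per_protein.items() if len(groups) > 1]
    spanning = [p for p in multi if len(set(per_protein[p])) > 1]
    frac = len(spanning) / len(multi) if multi else 0.0
    return CorrespondenceTable(tuple(rows), summary, frac)


def write_correspondence_table(table: CorrespondenceTable, path) -> None:
    write_table(path, ("protein_id", "protein_group", "pocket_id",
                       "pocket_group"), table.rows)
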