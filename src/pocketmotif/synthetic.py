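"""Synthetic fixtures: pocket families, background pockets, toy
protein-RNA complexes and planted-partition graphs.

The family generator is the minimal generative model the non-sequential
aligner must undo: each member is its template plus iid Gaussian coordinate
noise, a uniform random rotation, a random translation and (optionally) a
random residue-order permutation; an optional deletion rate produces partial
alignments. Template pockets are random point clouds with a minimum pairwise
separation of 3.5 Angstrom (CA-like packing) and about 10 residues, the
typical surface-pocket size. The geometry is deliberately abstract: no
backbone continuity, no rotamers — it exercises the alignment, calibration
and clustering machinery, not protein physics.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .structio import (AA3TO1, ChainStructure, InputError, PocketDefinition,
                       PocketMotifError, PocketResidue, PocketStructure,
                       ResidueRecord)
from .simnet import SimilarityNetwork

__all__ = [
    "FamilySpec",
    "FamilyMember",
    "FamilyDataset",
    "PlacementError",
    "make_template_pocket",
    "make_family",
    "make_background",
    "make_complex",
    "make_planted_partition",
    "family_dataset",
    "write_chains_pdb",
    "write_pocket_pdb",
]

AA1TO3 = {v: k for k, v in AA3TO1.items()}
MIN_SEPARATION = 3.5  # Angstrom, CA-like packing


class PlacementError(PocketMotifError):
    """Geometric construction could not satisfy its constraints."""


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for an end-to-end synthetic run."""
    n_templates: int = 6
    members_per_template: int = 15
    n_residues: int = 10
    noise_sigma: float = 0.3     # Angstrom
    permute: bool = True
    n_background: int = 30
    seed: int = 0
    deletion_rate: float = 0.0
    # planted families are *distinct* structures: candidate templates are
    # redrawn until every template pair scores below this Q bound, i.e. no
    # more alike than typical random pocket pairs
    template_max_q: float = 0.6

    def __post_init__(self):
        if min(self.n_templates, self.members_per_template,
               self.n_background) < 0:
            raise InputError("FamilySpec counts must be >= 0")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be >= 0")
        if not 0 <= self.deletion_rate < 1:
            raise InputError("deletion_rate must be in [0, 1)")


@dataclass(frozen=True)
class FamilyMember:
    pocket: PocketStructure
    template_index: int
    # member residue position -> template residue position
    correspondence: tuple


@dataclass(frozen=True)
class FamilyDataset:
    members: tuple               # of FamilyMember
    background: tuple            # of PocketStructure
    spec: FamilySpec

    def member_pockets(self) -> list:
        return [m.pocket for m in self.members]

    def labels(self) -> dict:
        return {m.pocket.pocket_id: m.template_index for m in self.members}


# ---------------------------------------------------------------------------
# Point-cloud templates

def _sample_cloud(n: int, rng: np.random.Generator,
                  min_sep: float = MIN_SEPARATION) -> np.ndarray:
    """Uniform points in a ball with a minimum pairwise separation, by
    rejection sampling with bounded retries."""
    radius = max(6.0, 3.6 * n ** (1.0 / 3.0))
    for _restart in range(100):
        pts: list = []
        failed = False
        for _ in range(n):
            for _try in range(300):
                p = rng.uniform(-radius, radius, 3)
                if p @ p > radius * radius:
                    continue
                if all(np.linalg.norm(p - q) >= min_sep for q in pts):
                    pts.append(p)
                    break
            else:
                failed = True
                break
        if not failed:
            return np.asarray(pts)
    raise PlacementError(
        f"could not place {n} points with separation {min_sep} "
        f"in radius {radius}")


def make_template_pocket(n_residues: int, seed: int,
                         pocket_id: Optional[str] = None) -> PocketStructure:
    """A random template pocket: point cloud with >= 3.5 A separation,
    random amino-acid letters, deterministic per seed."""
    if n_residues < 4:
        raise InputError(f"templates need >= 4 residues, got {n_residues}")
    rng = np.random.default_rng(seed)
    coords = _sample_cloud(n_residues, rng)
    letters = rng.choice(list(AA1TO3), size=n_residues)
    seq_nums = np.sort(rng.choice(
        np.arange(1, 8 * n_residues + 1), size=n_residues, replace=False))
    pid = pocket_id or f"TPL{seed}:1:A"
    defn = PocketDefinition(
        pid, frozenset(("A", int(s), "") for s in seq_nums))
    residues = [
        PocketResidue(("A", int(seq_nums[i]), ""), str(letters[i]),
                      tuple(coords[i]), False, i)
        for i in range(n_residues)]
    return PocketStructure(defn, residues)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    u1, u2, u3 = rng.random(3)
    s1, s2 = np.sqrt(1 - u1), np.sqrt(u1)
    w = s1 * np.sin(2 * np.pi * u2)
    x = s1 * np.cos(2 * np.pi * u2)
    y = s2 * np.sin(2 * np.pi * u3)
    z = s2 * np.cos(2 * np.pi * u3)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_family(template: PocketStructure, n_members: int,
                noise_sigma: float, permute: bool, seed: int,
                deletion_rate: float = 0.0,
                template_index: int = 0,
                id_prefix: str = "FAM") -> list:
    """Noisy rigid copies of a template; returns FamilyMember objects whose
    ``correspondence`` maps member residue positions back to the template."""
    rng = np.random.default_rng(seed)
    coords = template.coords()
    n = len(template)
    members = []
    for m in range(n_members):
        kept = np.arange(n)
        if deletion_rate > 0:
            keep_mask = rng.random(n) >= deletion_rate
            if keep_mask.sum() < 4:
                keep_mask[:] = False
                keep_mask[rng.choice(n, size=4, replace=False)] = True
            kept = np.flatnonzero(keep_mask)
        order = rng.permutation(kept) if permute else kept
        noisy = coords[order] + rng.normal(0.0, noise_sigma, (len(order), 3))
        R = _random_rotation(rng)
        t = rng.uniform(-30.0, 30.0, 3)
        moved = noisy @ R.T + t
        protein = f"{id_prefix}T{template_index}M{m:03d}"
        pid = f"{protein}:1:A"
        residues = []
        for pos, tpos in enumerate(order):
            src = template.residues[int(tpos)]
            residues.append(PocketResidue(
                ("A", src.key[1], ""), src.aa, tuple(moved[pos]), False, pos))
        defn = PocketDefinition(pid, frozenset(r.key for r in residues))
        members.append(FamilyMember(
            PocketStructure(defn, residues), template_index,
            tuple(int(t) for t in order)))
    return members


def make_background(n_pockets: int, seed: int, n_residues: int = 10,
                    size_spread: int = 0, id_prefix: str = "BG") -> list:
    """Independent random pockets (no shared template) for null calibration.

    By default the background is size-matched to ``n_residues``: the Q-score
    null shifts strongly with pocket size (a 6-vs-14 residue pair can never
    exceed Q = 36/84), so a size-diluted background drags the significance
    threshold below the like-for-like null of the pockets actually compared.
    ``size_spread`` > 0 varies sizes uniformly within +/- that many residues
    (never below 4) when a heterogeneous background is wanted.
    """
    rng = np.random.default_rng(seed)
    out = []
    for b in range(n_pockets):
        lo = max(4, n_residues - size_spread)
        hi = n_residues + size_spread
        size = int(rng.integers(lo, hi + 1))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        out.append(make_template_pocket(
            size, sub_seed, pocket_id=f"{id_prefix}{b:04d}:1:A"))
    return out


def family_dataset(spec: FamilySpec) -> FamilyDataset:
    """Generate the full study fixture: ``n_templates`` mutually distinct
    template families plus independent background pockets.

    A candidate template is rejected (and redrawn) when it aligns to an
    already-accepted template with Q above ``spec.template_max_q`` —
    otherwise two "families" would by chance share a planted structure and
    the ground-truth labels would not describe distinct groups.
    """
    from .nsalign import align_pockets  # local import: avoid module cycle

    rng = np.random.default_rng(spec.seed)
    templates: list = []
    members = []
    for t in range(spec.n_templates):
        template = None
        for _attempt in range(200):
            tpl_seed = int(rng.integers(0, 2 ** 31 - 1))
            candidate = make_template_pocket(
                spec.n_residues, tpl_seed, pocket_id=f"TPL{t}:1:A")
            if all(align_pockets(candidate, prev).q <= spec.template_max_q
                   for prev in templates):
                template = candidate
                break
        if template is None:
            raise PlacementError(
                f"could not draw {spec.n_templates} templates with pairwise "
                f"Q <= {spec.template_max_q}")
        templates.append(template)
        fam_seed = int(rng.integers(0, 2 ** 31 - 1))
        members.extend(make_family(
            template, spec.members_per_template, spec.noise_sigma,
            spec.permute, fam_seed, spec.deletion_rate, template_index=t))
    bg_seed = int(rng.integers(0, 2 ** 31 - 1))
    background = make_background(spec.n_background, bg_seed, spec.n_residues)
    return FamilyDataset(tuple(members), tuple(background), spec)


# ---------------------------------------------------------------------------
# Toy protein-RNA complexes

def make_complex(n_protein_res: int, n_rna_res: int, planted_contacts: int,
                 gap: float, seed: int, cutoff: float = 5.0):
    """A toy two-chain complex with exactly ``planted_contacts`` protein
    residues at distance ``cutoff - gap`` from an RNA atom and every other
    cross-molecule atom pair farther than ``cutoff + gap``.

    Returns ``(protein ChainStructure, rna ChainStructure, ground-truth
    residue keys)``.
    """
    if planted_contacts > n_protein_res:
        raise InputError("planted_contacts cannot exceed n_protein_res")
    if gap <= 0:
        raise InputError("gap must be > 0")
    if cutoff - gap <= 0:
        raise InputError("cutoff - gap must be > 0")
    spacing = 8.0
    if cutoff + gap >= spacing:
        raise PlacementError(
            f"cutoff + gap = {cutoff + gap} too large for residue spacing "
            f"{spacing}")
    rng = np.random.default_rng(seed)
    planted = sorted(int(i) for i in
                     rng.choice(n_protein_res, planted_contacts, replace=False))

    protein_residues = []
    for i in range(n_protein_res):
        protein_residues.append(ResidueRecord(
            "A", i + 1, "", "ALA", "protein",
            (("CA", "C", (spacing * i, 0.0, 0.0)),)))
    protein = ChainStructure("CPLX", "A", protein_residues)

    rna_names = ["A", "C", "G", "U"]
    rna_atoms: dict = {j: [("P", "P", (spacing * j, 60.0, 0.0))]
                       for j in range(n_rna_res)}
    for c_idx, i in enumerate(planted):
        j = c_idx % n_rna_res
        rna_atoms[j].append(
            (f"C{c_idx + 1}", "C", (spacing * i, cutoff - gap, 0.0)))
    rna_residues = [
        ResidueRecord("B", j + 1, "", rna_names[j % 4], "rna",
                      tuple(rna_atoms[j]))
        for j in range(n_rna_res)]
    rna = ChainStructure("CPLX", "B", rna_residues)

    truth = {("A", i + 1, "") for i in planted}
    _validate_complex(protein, rna, truth, cutoff, gap)
    return protein, rna, truth


def _validate_complex(protein, rna, truth, cutoff, gap):
    rna_pts = np.vstack([r.atom_coords() for r in rna.residues])
    for res in protein.residues:
        pts = res.atom_coords()
        d = np.min(np.linalg.norm(
            rna_pts[:, None, :] - pts[None, :, :], axis=2))
        if res.key in truth:
            if not np.isclose(d, cutoff - gap):
                raise PlacementError(
                    f"planted residue {res.key} at distance {d}")
        elif d <= cutoff + gap:
            raise PlacementError(
                f"non-planted residue {res.key} too close ({d})")


# ---------------------------------------------------------------------------
# Planted-partition graphs

def make_planted_partition(k_groups: int, group_size: int, p_in: float,
                           p_out: float, seed: int):
    """Planted-partition random graph; returns (SimilarityNetwork, labels)."""
    if not (0 <= p_out < p_in <= 1):
        raise InputError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    nodes = [(g, f"g{g:02d}n{i:03d}") for g in range(k_groups)
             for i in range(group_size)]
    g = nx.Graph()
    g.add_nodes_from(name for _, name in nodes)
    for a in range(len(nodes)):
        ga, na = nodes[a]
        for b in range(a + 1, len(nodes)):
            gb, nb = nodes[b]
            p = p_in if ga == gb else p_out
            if rng.random() < p:
                g.add_edge(na, nb, q=1.0, p=0.0)
    labels = {name: grp for grp, name in nodes}
    return SimilarityNetwork(g, alpha=0.05), labels


# ---------------------------------------------------------------------------
# PDB writing (synthetic structures only)

def _pdb_atom_line(serial, name, resname, chain, resseq, icode, xyz, element):
    name4 = name if len(name) == 4 else f" {name:<3s}"
    return (f"ATOM  {serial:>5d} {name4}{'':1s}{resname:>3s} {chain:1s}"
            f"{resseq:>4d}{icode or ' ':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def write_chains_pdb(chains: Sequence[ChainStructure], path) -> None:
    """Write chains as a fixed-column PDB file (synthetic output)."""
    lines = []
    serial = 1
    for ch in chains:
        for res in ch.residues:
            for name, element, xyz in res.atoms:
                lines.append(_pdb_atom_line(
                    serial, name, res.name3, ch.chain_id, res.seq_num,
                    res.insertion_code, xyz, element))
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pocket_pdb(pocket: PocketStructure, path,
                     structure_id: Optional[str] = None) -> None:
    """Write a pocket as a CA-only PDB file (synthetic output)."""
    residues = [
        ResidueRecord(r.key[0], r.key[1], r.key[2],
                      AA1TO3.get(r.aa, "UNK"), "protein",
                      (("CA", "C", tuple(r.ca)),))
        for r in pocket.residues]
    sid = structure_id or pocket.protein_id
    write_chains_pdb([ChainStructure(sid, residues[0].chain_id, residues)],
                     path)
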