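"""RNA-binding residue detection and pocket filtering.

A protein residue is RNA-binding when any of its atoms lies within a distance
cutoff of any RNA atom. This single distance criterion (default 5.0 Angstrom,
inclusive, heavy atoms only) is a deliberately simple union over the
physical interaction types (hydrogen bonds, electrostatic, hydrophobic, van
der Waals) that specialised interface tools classify individually; it is the
standard operational definition of an interface residue and is configurable.

A pocket is an RNA-binding pocket when it contains at least one RNA-binding
residue. Very small pockets (fewer than 4 residues by default) are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import ChainStructure, InputError, PocketStructure

__all__ = [
    "ContactParams",
    "detect_binding_residues",
    "label_pockets",
    "filter_pockets",
]


@dataclass(frozen=True)
class ContactParams:
    """Distance-contact criterion for protein-RNA interface residues."""
    cutoff: float = 5.0          # Angstrom, inclusive
    atom_scope: str = "heavy"    # 'heavy' or 'all'

    def __post_init__(self):
        if self.cutoff <= 0:
            raise InputError(f"contact cutoff must be positive, got {self.cutoff}")
        if self.atom_scope not in ("heavy", "all"):
            raise InputError(f"unknown atom_scope {self.atom_scope!r}")


def detect_binding_residues(protein: ChainStructure,
                            rna: Sequence[ChainStructure],
                            params: ContactParams = ContactParams()) -> set:
    """Return keys of protein residues with any in-scope atom within
    ``params.cutoff`` (inclusive) of any RNA atom.

    An empty RNA set yields an empty result. The result is independent of
    RNA chain order and invariant under rigid motion applied jointly to both
    molecules.
    """
    heavy = params.atom_scope == "heavy"
    rna_pts = []
    for ch in rna:
        for res in ch.residues:
            pts = res.atom_coords(heavy_only=heavy)
            if len(pts):
                rna_pts.append(pts)
    if not rna_pts:
        return set()
    tree = cKDTree(np.vstack(rna_pts))
    binding = set()
    for res in protein.residues:
        if res.polymer_class != "protein":
            continue
        pts = res.atom_coords(heavy_only=heavy)
        if not len(pts):
            continue
        d, _ = tree.query(pts, k=1)
        if np.min(d) <= params.cutoff:
            binding.add(res.key)
    return binding


def label_pockets(pockets: Iterable[PocketStructure], binding: set) -> list:
    """Set per-residue binding flags; a pocket is RNA-binding iff at least
    one of its residues is in the binding set."""
    return [p.with_binding(binding) for p in pockets]


def filter_pockets(pockets: Iterable[PocketStructure],
                   min_residues: int = 4) -> list:
    """Keep pockets that are RNA-binding and have >= min_residues residues."""
    return [p for p in pockets
            if p.is_rna_binding and len(p) >= min_residues]
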