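"""Shared fixtures: hand-written coordinate files and small synthetic inputs.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

import textwrap

import numpy as np
import pytest

from pocketmotif.structio import (ChainStructure, PocketDefinition,
                                  PocketResidue, PocketStructure,
                                  ResidueRecord)

# Minimal hand-written PDB: one protein chain, three residues, CA + CB atoms.
MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.841  -5.023  1.00  0.00           C
ATOM      4  CA  GLY A   2      10.121   3.725  -3.727  1.00  0.00           C
ATOM      5  CA  LEU A   3       7.298   3.145  -1.514  1.00  0.00           C
END
"""

# Same three residues plus a uracil nucleotide with ribose/base atoms.
PDB_WITH_RNA = """\
ATOM      1  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      2  CA  GLY A   2      10.121   3.725  -3.727  1.00  0.00           C
ATOM      3  CA  LEU A   3       7.298   3.145  -1.514  1.00  0.00           C
ATOM      4  P     U B   1       2.000   2.000   2.000  1.00  0.00           P
ATOM      5  C1'   U B   1       3.100   2.500   2.600  1.00  0.00           C
ATOM      6  N1    U B   1       4.000   3.100   3.000  1.00  0.00           N
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  LEU A   3       9.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def rna_pdb(tmp_path):
    p = tmp_path / "with_rna.pdb"
    p.write_text(PDB_WITH_RNA)
    return p


@pytest.fixture
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_ONLY_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def make_pocket(coords, pocket_id="P:1:A", letters=None, binding=None,
                chain="A"):
    """Build a PocketStructure directly from a coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    letters = letters or "A" * n
    binding = binding or [False] * n
    residues = [
        PocketResidue((chain, i + 1, ""), letters[i], tuple(coords[i]),
                      binding[i], i)
        for i in range(n)]
    defn = PocketDefinition(pocket_id, frozenset(r.key for r in residues))
    return PocketStructure(defn, residues)


def make_chain(coords, structure_id="S", chain_id="A", name3="ALA",
               polymer_class="protein"):
    """CA-only chain from a coordinate array."""
    residues = [
        ResidueRecord(chain_id, i + 1, "", name3, polymer_class,
                      (("CA", "C", tuple(c)),))
        for i, c in enumerate(np.asarray(coords, dtype=float))]
    return ChainStructure(structure_id, chain_id, residues)


def random_chain_walk(n, seed, step=3.8, min_sep=3.5):
    """Pseudo self-avoiding random walk as a toy protein fold."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    while len(pts) < n:
        for _ in range(200):
            d = rng.normal(size=3)
            d *= step / np.linalg.norm(d)
            cand = pts[-1] + d
            if all(np.linalg.norm(cand - q) >= min_sep for q in pts[:-1]):
                pts.append(cand)
                break
        else:  # restart tail on a dead end
            pts = [np.zeros(3)]
    return np.asarray(pts)
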