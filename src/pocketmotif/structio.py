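"""Coordinate and pocket-definition I/O.

Reads protein/RNA structures from PDB or mmCIF files (via gemmi), reads and
writes pocket definitions (residue-list tables), and resolves pocket
definitions against parsed chains into alignable coordinate sets.

Conventions
-----------
* Coordinates are in Angstrom; author residue numbering (with insertion
  codes) is preserved verbatim, never renumbered.
* Each residue is represented by its CA atom for alignment purposes.
* Alternate locations: the highest-occupancy conformer is kept, ties broken
  by altloc letter order.
* Modified amino acids are mapped to their parent residue via a built-in
  table; unmapped residues get the one-letter code 'X' (alignable, but
  excluded from motif frequency counts downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "ResidueKey",
    "ResidueRecord",
    "ChainStructure",
    "PocketDefinition",
    "PocketResidue",
    "PocketStructure",
    "PocketMotifError",
    "InputError",
    "FormatError",
    "EmptyInputError",
    "ResolutionError",
    "read_structure",
    "read_pocket_definitions",
    "write_pocket_definitions",
    "resolve_pocket",
    "fmt_float",
]

# ---------------------------------------------------------------------------
# Errors

class PocketMotifError(Exception):
    """Base class for all package errors."""


class InputError(PocketMotifError):
    """Malformed or missing user input (CLI exit code 2)."""


class FormatError(InputError):
    """A file did not parse in the declared format."""


class EmptyInputError(InputError):
    """A file parsed but contained nothing usable."""


class ResolutionError(InputError):
    """A pocket definition referenced residues absent from the structure."""


class NumericalError(PocketMotifError):
    """A numerical procedure failed (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# Residue classification tables

AA3TO1: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Common modified amino acids -> parent 3-letter code.
MODIFIED_AA_PARENT: Mapping[str, str] = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "CSD": "CYS", "CME": "CYS", "OCS": "CYS", "HYP": "PRO", "MLY": "LYS",
    "M3L": "LYS", "KCX": "LYS", "LLP": "LYS", "PCA": "GLU", "FME": "MET",
    "SEC": "CYS", "MLZ": "LYS", "AIB": "ALA", "DAL": "ALA", "SAR": "GLY",
}

# Standard and common modified ribonucleotides.
RNA_NAMES = frozenset({
    "A", "C", "G", "U", "I", "N",
    "PSU", "5MU", "5MC", "1MA", "2MG", "M2G", "7MG", "G7M", "OMC", "OMG",
    "OMU", "4SU", "H2U", "A2M", "MA6", "6MZ", "UR3", "RSQ", "4OC", "MIA",
    "T6A", "YG", "1MG",
})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

ResidueKey = tuple  # (chain_id: str, seq_num: int, icode: str) — '' when absent


def classify_residue(name3: str) -> str:
    """Classify a residue name as 'protein', 'rna' or 'other'."""
    name = name3.strip().upper()
    if name in AA3TO1 or name in MODIFIED_AA_PARENT:
        return "protein"
    if name in RNA_NAMES:
        return "rna"
    return "other"


def one_letter(name3: str) -> str:
    """One-letter amino-acid code; modified residues map to their parent,
    anything unmapped becomes 'X'."""
    name = name3.strip().upper()
    if name in AA3TO1:
        return AA3TO1[name]
    if name in MODIFIED_AA_PARENT:
        return AA3TO1[MODIFIED_AA_PARENT[name]]
    return "X"


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class ResidueRecord:
    chain_id: str
    seq_num: int
    insertion_code: str          # '' when absent
    name3: str
    polymer_class: str           # protein | rna | other
    atoms: tuple                 # of (atom_name, element, (x, y, z))

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def atom_coords(self, heavy_only: bool = True) -> np.ndarray:
        pts = [xyz for (_n, el, xyz) in self.atoms
               if not (heavy_only and el.upper() == "H")]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def ca(self) -> Optional[np.ndarray]:
        for name, _el, xyz in self.atoms:
            if name.strip() == "CA":
                return np.asarray(xyz, dtype=float)
        return None


@dataclass
class ChainStructure:
    structure_id: str
    chain_id: str
    residues: list               # of ResidueRecord, in file order
    polymer_class: str = "other"  # protein | rna | other | mixed

    def __post_init__(self):
        classes = {r.polymer_class for r in self.residues}
        if len(classes) == 1:
            self.polymer_class = next(iter(classes))
        elif classes:
            self.polymer_class = "mixed"

    @property
    def id(self) -> str:
        return f"{self.structure_id}:{self.chain_id}"

    def ca_coords(self) -> np.ndarray:
        """CA coordinates of protein residues, in chain order."""
        pts = []
        for r in self.residues:
            if r.polymer_class != "protein":
                continue
            ca = r.ca()
            if ca is not None:
                pts.append(ca)
        return np.asarray(pts, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class PocketDefinition:
    pocket_id: str               # protein_ID:pocket_ID:chain_ID
    member_keys: frozenset       # of ResidueKey

    def __post_init__(self):
        if not self.member_keys:
            raise InputError(f"pocket {self.pocket_id!r} has no member residues")


@dataclass(frozen=True)
class PocketResidue:
    key: ResidueKey
    aa: str                      # one-letter code, 'X' if unknown
    ca: tuple                    # (x, y, z) in Angstrom
    binding: bool = False
    seq_index: int = -1          # 0-based position in the parent chain

    def ca_array(self) -> np.ndarray:
        return np.asarray(self.ca, dtype=float)


@dataclass
class PocketStructure:
    definition: PocketDefinition
    residues: list               # of PocketResidue, ordered by key

    def __post_init__(self):
        if not self.residues:
            raise InputError(
                f"pocket {self.definition.pocket_id!r} resolved to no residues")
        coords = self.coords()
        if not np.all(np.isfinite(coords)):
            raise InputError(
                f"pocket {self.definition.pocket_id!r} has non-finite coordinates")

    @property
    def pocket_id(self) -> str:
        return self.definition.pocket_id

    @property
    def protein_id(self) -> str:
        """The parent protein identifier (first field of the pocket id)."""
        return self.definition.pocket_id.split(":", 1)[0]

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        return np.asarray([r.ca for r in self.residues], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def is_rna_binding(self) -> bool:
        return any(r.binding for r in self.residues)

    def with_binding(self, binding_keys) -> "PocketStructure":
        binding_keys = set(binding_keys)
        new = [PocketResidue(r.key, r.aa, r.ca, r.key in binding_keys, r.seq_index)
               for r in self.residues]
        return PocketStructure(self.definition, new)


# ---------------------------------------------------------------------------
# Structure reading

def _pick_altlocs(res: gemmi.Residue) -> list:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    best = {}
    for atom in res:
        key = atom.name
        cand = (-atom.occ, atom.altloc or "~")  # '~' sorts after letters
        if key not in best or cand < best[key][0]:
            best[key] = (cand, atom)
    out = []
    for name in best:
        _, atom = best[name]
        out.append((atom.name, atom.element.name,
                    (atom.pos.x, atom.pos.y, atom.pos.z)))
    out.sort()
    return out


def read_structure(path, format: str = "pdb") -> list:
    """Read a coordinate file into a list of :class:`ChainStructure`.

    Parameters
    ----------
    path : str or Path
        Coordinate file.
    format : {'pdb', 'mmcif'}
        Declared file format.

    Returns one ChainStructure per chain of the first model. Waters are
    excluded; polymer class is assigned per residue from its name.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    if format not in ("pdb", "mmcif"):
        raise InputError(f"unknown structure format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc

    structure_id = (st.name or path.stem).strip() or path.stem
    chains = []
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no models in structure")
    model = st[0]
    for chain in model:
        residues = []
        for res in chain:
            name = res.name.strip().upper()
            if name in WATER_NAMES:
                continue
            icode = res.seqid.icode.strip() if res.seqid.icode else ""
            residues.append(ResidueRecord(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                insertion_code=icode,
                name3=name,
                polymer_class=classify_residue(name),
                atoms=tuple(_pick_altlocs(res)),
            ))
        if residues:
            chains.append(ChainStructure(structure_id, chain.name, residues))
    if not chains:
        raise EmptyInputError(f"{path}: structure contains no non-water residues")
    return chains


# ---------------------------------------------------------------------------
# Pocket definitions

def _parse_icode(token: str) -> str:
    token = token.strip()
    return "" if token in ("-", "", ".") else token


def read_pocket_definitions(path, dialect: str = "tsv") -> list:
    """Read pocket definitions.

    dialect 'tsv': tab-separated columns ``pocket_id  chain_id  seq_num
    icode``, one residue per row, '-' for an empty insertion code, '#' starts
    a comment, first non-comment line may be the header.

    dialect 'castp_poc': the residue list of a CASTp ``.poc`` file —
    PDB-style ATOM/HETATM records whose trailing whitespace-separated token
    is the pocket number, e.g.::

        ATOM    123  CA  LEU A  45      11.1  22.2  33.3  1.00 10.00  POC  12

    Chain, residue number and insertion code are taken from the fixed PDB
    columns; pocket ids are synthesized as ``<stem>:<poc>:<chain>`` from the
    file stem. CASTp dialects vary; this reader targets the layout above.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"pocket definition file not found: {path}")
    if dialect == "tsv":
        return _read_pockets_tsv(path)
    if dialect == "castp_poc":
        return _read_pockets_poc(path)
    raise InputError(f"unknown pocket dialect {dialect!r}")


def _read_pockets_tsv(path: Path) -> list:
    groups: dict = {}
    first_row: dict = {}
    last_row: dict = {}
    prev_id = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}")
            pid, chain, seq, icode = (p.strip() for p in parts)
            if pid == "pocket_id":  # header
                continue
            try:
                seq_num = int(seq)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: seq_num {seq!r} is not an integer")
            if pid in groups and prev_id != pid:
                raise InputError(
                    f"{path}: duplicate pocket_id {pid!r} "
                    f"(rows {last_row[pid]} and {lineno})")
            groups.setdefault(pid, set()).add((chain, seq_num, _parse_icode(icode)))
            first_row.setdefault(pid, lineno)
            last_row[pid] = lineno
            prev_id = pid
    if not groups:
        raise EmptyInputError(f"{path}: no pocket rows found")
    return [PocketDefinition(pid, frozenset(keys))
            for pid, keys in groups.items()]


def _read_pockets_poc(path: Path) -> list:
    stem = path.stem
    groups: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(raw) < 54:
                raise FormatError(f"{path}:{lineno}: truncated ATOM record")
            chain = raw[21].strip()
            try:
                seq_num = int(raw[22:26])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: bad residue number {raw[22:26]!r}")
            icode = raw[26].strip()
            tokens = raw.split()
            poc = tokens[-1]
            pid = f"{stem}:{poc}:{chain}"
            groups.setdefault(pid, set()).add((chain, seq_num, icode))
    if not groups:
        raise EmptyInputError(f"{path}: no pocket ATOM records found")
    return [PocketDefinition(pid, frozenset(keys)) for pid in sorted(groups)
            for keys in [groups[pid]]]


def write_pocket_definitions(defs: Iterable[PocketDefinition], path) -> None:
    """Write definitions in the TSV dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("pocket_id\tchain_id\tseq_num\ticode\n")
        for d in sorted(defs, key=lambda d: d.pocket_id):
            for chain, seq, icode in sorted(d.member_keys):
                fh.write(f"{d.pocket_id}\t{chain}\t{seq}\t{icode or '-'}\n")


# ---------------------------------------------------------------------------
# Resolution

def resolve_pocket(defn: PocketDefinition, chains: Sequence[ChainStructure]
                   ) -> PocketStructure:
    """Resolve a pocket definition against parsed chains.

    Every member key must exist and carry a CA atom; otherwise a
    :class:`ResolutionError` listing all offending keys is raised.
    """
    index = {}
    for ch in chains:
        for pos, res in enumerate(ch.residues):
            index[res.key] = (res, pos)
    missing, no_ca = [], []
    rows = []
    for key in sorted(defn.member_keys):
        hit = index.get(key)
        if hit is None:
            missing.append(key)
            continue
        res, pos = hit
        ca = res.ca()
        if ca is None:
            no_ca.append(key)
            continue
        rows.append(PocketResidue(
            key=key, aa=one_letter(res.name3), ca=tuple(ca),
            binding=False, seq_index=pos))
    if missing or no_ca:
        parts = []
        if missing:
            parts.append(f"missing residues: {missing}")
        if no_ca:
            parts.append(f"residues without CA: {no_ca}")
        raise ResolutionError(
            f"pocket {defn.pocket_id!r} cannot be resolved ({'; '.join(parts)})")
    return PocketStructure(defn, rows)


# ---------------------------------------------------------------------------
# Tabular output helpers

def fmt_float(x: float) -> str:
    """Render a float with 6 significant digits (table convention)."""
    if x == 0:
        return "0"
    if not math.isfinite(x):
        return repr(x)
    return f"{x:.6g}"


def write_table(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write a tab-separated table with a single header line; floats are
    rendered with 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            cells = [fmt_float(c) if isinstance(c, float) else str(c)
                     for c in row]
            fh.write("\t".join(cells) + "\n")
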