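"""Motif profiles and functional enrichment for pocket groups.

Each group's consensus alignment is summarised as a position profile:
per-column amino-acid frequencies (sequence-logo input), occupancy (fraction
of group pockets with a residue in the column) and the RNA-binding ratio
(fraction of assigned residues flagged as RNA-binding). Unknown residues
('X') count toward occupancy and binding ratio but are excluded from the
frequency distribution.

Functional enrichment of a group's parent proteins against a background
population uses the one-tailed upper hypergeometric test, optionally in the
conservative EASE variant (one success removed before taking the tail).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Set

from scipy import stats

from .consensus import ConsensusAlignment
from .structio import InputError, PocketStructure, write_table

__all__ = [
    "MotifProfile",
    "AA_LETTERS",
    "build_profile",
    "concatenated_sequences",
    "enrich_terms",
    "write_profile_table",
    "write_sequences_fasta",
]

AA_LETTERS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifProfile:
    n_columns: int
    frequencies: tuple           # per column: dict letter -> relative freq
    occupancy: tuple             # per column: fraction of pockets assigned
    binding_ratio: tuple         # per column: fraction of assigned residues binding

    def __post_init__(self):
        for c, freqs in enumerate(self.frequencies):
            if freqs:
                s = sum(freqs.values())
                if abs(s - 1.0) > 1e-9:
                    raise InputError(
                        f"column {c}: frequencies sum to {s}, expected 1")


def _pocket_lookup(cons: ConsensusAlignment,
                   pockets: Sequence[PocketStructure]) -> dict:
    by_id = {p.pocket_id: p for p in pockets}
    lookup = {}
    for i, pid in enumerate(cons.pa.pocket_ids):
        if pid in by_id:
            lookup[i] = by_id[pid]
    missing = set(cons.assigned) - set(lookup)
    if missing:
        ids = [cons.pa.pocket_ids[i] for i in sorted(missing)]
        raise InputError(f"consensus references pockets not supplied: {ids}")
    return lookup


def build_profile(cons: ConsensusAlignment,
                  pockets: Sequence[PocketStructure]) -> MotifProfile:
    """Per-column residue frequencies, occupancy and binding ratios."""
    if cons.n_columns == 0:
        return MotifProfile(0, (), (), ())
    lookup = _pocket_lookup(cons, pockets)
    n_pockets = max(len(cons.assigned), 1)
    freqs, occ, bind = [], [], []
    for col in cons.columns:
        letters = []
        binding_flags = []
        for i, k in col.items():
            res = lookup[i].residues[k]
            letters.append(res.aa)
            binding_flags.append(res.binding)
        known = [a for a in letters if a != "X"]
        if known:
            counts: dict = {}
            for a in known:
                counts[a] = counts.get(a, 0) + 1
            total = len(known)
            freqs.append({a: counts[a] / total for a in sorted(counts)})
        else:
            freqs.append({})  # column has no standard residues
        occ.append(len(letters) / n_pockets)
        bind.append(sum(binding_flags) / len(binding_flags) if binding_flags
                    else 0.0)
    return MotifProfile(cons.n_columns, tuple(freqs), tuple(occ), tuple(bind))


def concatenated_sequences(cons: ConsensusAlignment,
                           pockets: Sequence[PocketStructure]) -> list:
    """Column-ordered sequence per pocket, with original residue positions.

    Returns one record per assigned pocket:
    ``(pocket_id, letters, annotations)`` where ``letters`` uses '-' for
    columns the pocket misses and ``annotations`` holds the (chain, seq_num,
    icode) key per column (None at gaps).
    """
    lookup = _pocket_lookup(cons, pockets)
    records = []
    for i in sorted(cons.assigned):
        pid = cons.pa.pocket_ids[i]
        pocket = lookup[i]
        letters, notes = [], []
        for col in cons.columns:
            k = col.get(i)
            if k is None:
                letters.append("-")
                notes.append(None)
            else:
                res = pocket.residues[k]
                letters.append(res.aa)
                notes.append(res.key)
        records.append((pid, "".join(letters), tuple(notes)))
    return records


# ---------------------------------------------------------------------------
# Enrichment

def enrich_terms(group_proteins: Set[str], population: Set[str],
                 annotations: Mapping[str, Set[str]],
                 mode: str = "hypergeometric") -> list:
    """Term enrichment of a protein group against a population.

    Returns rows ``(term, count, list_total, pop_hits, pop_total, p)`` sorted
    by p ascending (then term id), where p is the one-tailed upper
    hypergeometric probability of observing at least ``count`` annotated
    proteins in a draw of ``list_total`` from the population. mode 'ease'
    subtracts one success from the count before the tail (the conservative
    DAVID convention), so a single-hit term is never significant.
    """
    if mode not in ("hypergeometric", "ease"):
        raise InputError(f"unknown enrichment mode {mode!r}")
    group = set(group_proteins)
    population = set(population)
    if not group:
        raise InputError("enrichment requires a non-empty protein group")
    if not group <= population:
        raise InputError(
            f"group proteins outside population: {sorted(group - population)}")
    pop_total = len(population)
    list_total = len(group)
    term_to_pop: dict = {}
    for prot in population:
        for term in annotations.get(prot, ()):  # missing -> unannotated
            term_to_pop.setdefault(term, set()).add(prot)
    rows = []
    for term in sorted(term_to_pop):
        pop_hits = len(term_to_pop[term])
        count = len(term_to_pop[term] & group)
        if count == 0:
            continue
        eff = count - 1 if mode == "ease" else count
        # P(X >= eff), X ~ Hypergeom(pop_total, pop_hits, list_total)
        p = float(stats.hypergeom.sf(eff - 1, pop_total, pop_hits, list_total))
        p = min(p, 1.0)
        rows.append((term, count, list_total, pop_hits, pop_total, p))
    rows.sort(key=lambda r: (r[5], r[0]))
    return rows


# ---------------------------------------------------------------------------
# Outputs

def write_profile_table(profile: MotifProfile, path) -> None:
    header = ["column", "occupancy", "binding_ratio"] + list(AA_LETTERS)
    rows = []
    for c in range(profile.n_columns):
        freqs = profile.frequencies[c]
        rows.append([c + 1, float(profile.occupancy[c]),
                     float(profile.binding_ratio[c])]
                    + [float(freqs.get(a, 0.0)) for a in AA_LETTERS])
    write_table(path, header, rows)


def write_sequences_fasta(records: Sequence, path) -> None:
    """FASTA-like file of column-ordered pocket sequences; the header line
    carries the original residue positions."""
    with open(path, "w") as fh:
        for pid, letters, notes in records:
            pos = ",".join(
                "-" if key is None else f"{key[0]}{key[1]}{key[2]}"
                for key in notes)
            fh.write(f">{pid} positions={pos}\n{letters}\n")


def write_enrichment_table(rows: Sequence, path) -> None:
    write_table(path, ("term", "count", "list_total", "pop_hits",
                       "pop_total", "p"),
                [(t, c, lt, ph, pt, float(p)) for t, c, lt, ph, pt, p in rows])
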