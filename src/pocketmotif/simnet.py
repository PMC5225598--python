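"""Similarity network construction and community-based pocket grouping.

Nodes are pockets (or proteins); an undirected edge links two nodes whose
alignment P-value is below the significance threshold (strict, default
alpha = 0.05). The network is decomposed into communities by greedy
agglomerative modularity maximisation: starting from singletons, repeatedly
merge the pair of communities with the largest modularity gain (ties broken
by the lexicographically smallest community-label pair) and stop when no
merge increases modularity. Edges are unweighted — significance already
binarised them.

Communities become pocket groups: sorted by size (descending, then smallest
member id), numbered from 1, each represented by its highest-degree member
(ties by lexicographic id), and flagged "major" when at least ``min_size``
members. In tabular outputs members of non-major groups get group_id 0
(the "grey" nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .calibration import CalibrationModel, p_value
from .structio import InputError, PocketMotifError

__all__ = [
    "SimilarityNetwork",
    "Partition",
    "PocketGroup",
    "ModularityUndefinedError",
    "build_network",
    "modularity",
    "detect_communities",
    "extract_groups",
    "write_edge_list",
    "write_groups_table",
    "write_sif",
]


class ModularityUndefinedError(PocketMotifError):
    """Modularity is undefined on an edgeless graph."""


@dataclass
class SimilarityNetwork:
    """Simple undirected graph of significantly similar nodes."""
    graph: nx.Graph
    alpha: float = 0.05

    def __post_init__(self):
        if any(u == v for u, v in self.graph.edges):
            raise InputError("similarity network must not contain self-loops")

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        return sorted(tuple(sorted((u, v))) for u, v in self.graph.edges)


@dataclass(frozen=True)
class Partition:
    assignment: dict             # node -> community label
    modularity: float

    def blocks(self) -> list:
        by_label: dict = {}
        for node, label in self.assignment.items():
            by_label.setdefault(label, set()).add(node)
        return [by_label[k] for k in sorted(by_label)]


@dataclass(frozen=True)
class PocketGroup:
    group_id: int
    members: tuple               # sorted node ids
    representative: str
    is_major: bool


# ---------------------------------------------------------------------------

def build_network(results: Sequence, model: CalibrationModel,
                  alpha: float = 0.05) -> SimilarityNetwork:
    """Threshold pairwise alignments into a similarity network.

    An edge is added iff p_value(q) < alpha (strictly); every pocket that
    appears in ``results`` is kept as a node even when isolated.
    """
    g = nx.Graph()
    for r in results:
        g.add_node(r.id_a)
        g.add_node(r.id_b)
        p = p_value(r.q, model.params)
        if p < alpha:
            g.add_edge(r.id_a, r.id_b, q=r.q, p=p)
    return SimilarityNetwork(g, alpha)


def modularity(net: SimilarityNetwork, part: Partition) -> float:
    """Newman-Girvan modularity sum_c (e_cc - a_c^2), unweighted edges."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise ModularityUndefinedError(
            "modularity is undefined on an edgeless network")
    uncovered = set(g.nodes) - set(part.assignment)
    if uncovered:
        raise InputError(f"partition does not cover nodes: {sorted(uncovered)}")
    return float(nx.algorithms.community.modularity(
        g, [b for b in _blocks_on(g, part)]))


def _blocks_on(g: nx.Graph, part: Partition) -> list:
    by_label: dict = {}
    for node in g.nodes:
        by_label.setdefault(part.assignment[node], set()).add(node)
    return [by_label[k] for k in sorted(by_label)]


def detect_communities(net: SimilarityNetwork) -> Partition:
    """Greedy agglomerative modularity maximisation (CNM-style) with a
    deterministic local-move refinement.

    Community labels are their lexicographically smallest member; at each
    step the connected community pair with the largest modularity gain is
    merged (ties broken by the smallest label pair) along the full
    agglomeration schedule, and the partition with maximal modularity on
    that path is kept. A single-node relocation pass then repairs the
    misplacements pure agglomeration cannot undo. Fully deterministic and
    invariant to node input order. Isolated nodes remain singleton
    communities. An edgeless network yields all singletons with modularity
    reported as 0.
    """
    g = net.graph
    nodes = sorted(g.nodes)
    if g.number_of_edges() == 0:
        return Partition({n: n for n in nodes}, 0.0)

    m = g.number_of_edges()
    # community state: label -> set of nodes; degree sums; inter-edge counts
    comm: dict = {n: {n} for n in nodes}
    deg_sum = {n: g.degree(n) for n in nodes}
    between: dict = {}
    for u, v in g.edges:
        key = (min(u, v), max(u, v))
        between[key] = between.get(key, 0) + 1

    two_m = 2.0 * m

    def snapshot():
        assignment = {}
        for members in comm.values():
            lab = min(members)
            for n in members:
                assignment[n] = lab
        return assignment

    # full agglomeration schedule: always merge the connected community pair
    # with the largest modularity gain (ties -> smallest label pair),
    # recording the partition after every merge
    snapshots = [snapshot()]
    while between:
        best_gain, best_pair = -np.inf, None
        for (la, lb) in sorted(between):
            e_ab = between[(la, lb)]
            # gain of merging a and b: 2*(e_ab/2m - (d_a/2m)*(d_b/2m))
            gain = 2.0 * (e_ab / two_m
                          - (deg_sum[la] / two_m) * (deg_sum[lb] / two_m))
            if gain > best_gain + 1e-15:
                best_gain, best_pair = gain, (la, lb)
        la, lb = best_pair
        new_label = min(la, lb)
        other = lb if new_label == la else la
        comm[new_label] = comm[la] | comm[lb]
        del comm[other]
        deg_sum[new_label] = deg_sum[la] + deg_sum[lb]
        del deg_sum[other]
        new_between: dict = {}
        for (x, y), e in between.items():
            if (x, y) == (min(la, lb), max(la, lb)):
                continue
            x2 = new_label if x in (la, lb) else x
            y2 = new_label if y in (la, lb) else y
            if x2 == y2:
                continue
            key = (min(x2, y2), max(x2, y2))
            new_between[key] = new_between.get(key, 0) + e
        between = new_between
        snapshots.append(snapshot())

    # refine every partition on the path by single-node moves and keep the
    # best result (earliest snapshot wins ties) -- pure agglomeration cannot
    # undo an early misplacement, the relocation sweep can
    best_assignment, best_q = None, -np.inf
    for snap in snapshots:
        refined = _local_moves(g, snap, m)
        q = _modularity_value(g, refined, m)
        if q > best_q + 1e-12:
            best_q, best_assignment = q, refined

    part = Partition(best_assignment, 0.0)
    q = modularity(net, part)
    return Partition(best_assignment, q)


def _modularity_value(g: nx.Graph, assignment: dict, m: int) -> float:
    intra: dict = {}
    comm_deg: dict = {}
    for n, d in g.degree:
        lab = assignment[n]
        comm_deg[lab] = comm_deg.get(lab, 0) + d
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            lab = assignment[u]
            intra[lab] = intra.get(lab, 0) + 1
    return sum(intra.get(lab, 0) / m - (comm_deg[lab] / (2.0 * m)) ** 2
               for lab in comm_deg)


def _local_moves(g: nx.Graph, assignment: dict, m: int,
                 max_passes: int = 100) -> dict:
    """Deterministic single-node refinement: repeatedly move the node whose
    relocation (to a neighbouring community or a fresh singleton) gives the
    largest strictly positive modularity gain; nodes visited in sorted order,
    target ties broken by smallest label."""
    assignment = dict(assignment)
    deg = dict(g.degree)
    two_m2 = 2.0 * m * m
    comm_deg: dict = {}
    for n, lab in assignment.items():
        comm_deg[lab] = comm_deg.get(lab, 0) + deg[n]
    fresh_counter = 0
    for _ in range(max_passes):
        moved = False
        for v in sorted(g.nodes):
            a = assignment[v]
            k_to: dict = {}
            for u in g.neighbors(v):
                lab = assignment[u]
                k_to[lab] = k_to.get(lab, 0) + 1
            k_va = k_to.get(a, 0)
            d_v = deg[v]
            fresh = f"\x00fresh{fresh_counter}"  # split into own community
            best_gain, best_lab = 1e-12, None
            for lab in sorted(k_to, key=str) + [fresh]:
                if lab == a:
                    continue
                k_vb = 0 if lab == fresh else k_to[lab]
                d_b = 0 if lab == fresh else comm_deg[lab]
                gain = (k_vb - k_va) / m - d_v * (
                    d_b - comm_deg[a] + d_v) / two_m2
                if gain > best_gain:
                    best_gain, best_lab = gain, lab
            if best_lab is not None:
                comm_deg[a] -= d_v
                assignment[v] = best_lab
                comm_deg[best_lab] = comm_deg.get(best_lab, 0) + d_v
                moved = True
                if best_lab == fresh:
                    fresh_counter += 1
        if not moved:
            break
    # canonicalise labels to the smallest member of each community
    members: dict = {}
    for n, lab in assignment.items():
        members.setdefault(lab, []).append(n)
    relabel = {lab: min(ns) for lab, ns in members.items()}
    return {n: relabel[lab] for n, lab in assignment.items()}


def extract_groups(part: Partition, net: SimilarityNetwork,
                   min_size: int = 5) -> list:
    """Partition blocks as numbered pocket groups.

    Sorted by size descending then smallest member id; numbered from 1;
    representative = highest-degree member (ties by lexicographic id);
    major iff size >= min_size.
    """
    g = net.graph
    blocks = sorted(part.blocks(), key=lambda b: (-len(b), min(b)))
    groups = []
    for gid, members in enumerate(blocks, start=1):
        rep = min(members, key=lambda n: (-g.degree(n) if n in g else 0, n))
        groups.append(PocketGroup(
            group_id=gid, members=tuple(sorted(members)),
            representative=rep, is_major=len(members) >= min_size))
    return groups


# ---------------------------------------------------------------------------
# Exports

def write_edge_list(net: SimilarityNetwork, path) -> None:
    from .structio import write_table
    rows = []
    for u, v in net.edges:
        d = net.graph.edges[u, v]
        rows.append((u, v, float(d.get("q", float("nan"))),
                     float(d.get("p", float("nan")))))
    write_table(path, ("node_a", "node_b", "q", "p"), rows)


def write_groups_table(groups: Sequence[PocketGroup], path) -> None:
    """Groups TSV; members of non-major groups are reported with group_id 0."""
    from .structio import write_table
    rows = []
    for grp in groups:
        gid = grp.group_id if grp.is_major else 0
        for member in grp.members:
            rows.append((member, gid, int(member == grp.representative)))
    write_table(path, ("pocket_id", "group_id", "is_representative"), rows)


def write_sif(net: SimilarityNetwork, path) -> None:
    """SIF export (Cytoscape-compatible)."""
    with open(path, "w") as fh:
        linked = set()
        for u, v in net.edges:
            fh.write(f"{u}\tsim\t{v}\n")
            linked.update((u, v))
        for n in net.nodes:
            if n not in linked:
                fh.write(f"{n}\n")


def write_graphml(net: SimilarityNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
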