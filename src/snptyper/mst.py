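"""Minimum spanning tree over SNP genotypes with an n-locus-variant
priority rule, and group partitioning.

The tree is grown Prim-style over the complete graph of ST nodes
weighted by SNP differences.  Among tied minimum-weight candidate
edges, attachment is preferred to the already-included node with the
highest priority score — 10000 x (its single-SNP-variant count) +
10 x (its double-SNP-variant count), counted on the full distance
matrix — then to the larger node, then to the lowest ST id.  The
priority rule only resolves ties: the total weight always equals that
of an unconstrained minimum spanning tree.

Groups are connected components (of size >= 2 STs) of the MST after
dropping edges heavier than 2 SNPs; founder candidates are ranked by
(single-SNP MST neighbours, node size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import UsageError
from .genotyping import SnpProfile, StRegistry, assign_sts
from .phylo import SnpDistanceMatrix, distance_matrix

DEFAULT_PRIORITY_WEIGHTS = {1: 10000, 2: 10}


@dataclass(frozen=True)
class MstNode:
    st_id: int
    members: tuple[str, ...]
    profile: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MstEdge:
    u: int
    v: int
    weight: int


@dataclass(frozen=True)
class MstGraph:
    nodes: tuple[MstNode, ...]
    edges: tuple[MstEdge, ...]
    groups: tuple[frozenset[int], ...] = ()
    founder_ranking: tuple[int, ...] = ()

    def node(self, st_id: int) -> MstNode:
        return next(n for n in self.nodes if n.st_id == st_id)

    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges)

    def neighbours(self, st_id: int) -> dict[int, int]:
        out = {}
        for e in self.edges:
            if e.u == st_id:
                out[e.v] = e.weight
            elif e.v == st_id:
                out[e.u] = e.weight
        return out


def collapse_identical(profiles: Sequence[SnpProfile], registry: StRegistry | None = None
                       ) -> list[MstNode]:
    """One node per ST: all samples at zero inter-taxon distance share a
    node."""
    registry = registry or assign_sts(profiles)
    vec_of_st = {st: vec for vec, st in registry.st_of_vector.items()}
    return [
        MstNode(st, members, profile=vec_of_st[st])
        for st, members in sorted(registry.members.items())
    ]


def _restricted(D: SnpDistanceMatrix, nodes: Sequence[MstNode]) -> dict[tuple[int, int], int]:
    """ST-pair distances; falls back to node profiles when D is keyed by
    samples rather than STs."""
    label_set = set(D.labels)
    key_of = {}
    for n in nodes:
        if str(n.st_id) in label_set:
            key_of[n.st_id] = str(n.st_id)
        elif n.members and n.members[0] in label_set:
            key_of[n.st_id] = n.members[0]
        else:
            raise UsageError(f"ST {n.st_id} not resolvable in distance matrix labels")
    out = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            w = D.value(key_of[a.st_id], key_of[b.st_id])
            out[(a.st_id, b.st_id)] = out[(b.st_id, a.st_id)] = int(w)
    return out


def build_mst(
    nodes: Sequence[MstNode],
    D: SnpDistanceMatrix | None = None,
    priority_weights: Mapping[int, int] | None = None,
) -> MstGraph:
    """Prim growth with the n-locus-variant tie-break (see module
    docstring).  When `D` is omitted it is computed from node profiles."""
    if not nodes:
        raise UsageError("no nodes")
    weights = dict(priority_weights or DEFAULT_PRIORITY_WEIGHTS)
    if D is None:
        D = distance_matrix({str(n.st_id): n.profile for n in nodes})
    dist = _restricted(D, nodes)
    by_id = {n.st_id: n for n in nodes}

    # n-locus-variant counts on the full matrix
    def priority(st: int) -> int:
        score = 0
        for other in by_id:
            if other == st:
                continue
            w = dist[(st, other)]
            score += weights.get(w, 0)
        return score

    prio = {st: priority(st) for st in by_id}

    start = min(by_id, key=lambda s: (-prio[s], -by_id[s].size, s))
    included = {start}
    edges: list[MstEdge] = []
    while len(included) < len(by_id):
        # candidate edges (u in tree, v outside); pick min weight, then
        # included endpoint with max priority, then larger size, lowest ids
        best = None
        for u in sorted(included):
            for v in sorted(set(by_id) - included):
                w = dist[(u, v)]
                key = (w, -prio[u], -by_id[u].size, u, v)
                if best is None or key < best[0]:
                    best = (key, u, v, w)
        _, u, v, w = best
        edges.append(MstEdge(u, v, w))
        included.add(v)
    graph = MstGraph(tuple(nodes), tuple(edges))
    groups = find_groups(graph)
    ranking = founder_candidates(graph)
    return MstGraph(tuple(nodes), tuple(edges), groups, ranking)


def find_groups(
    graph: MstGraph, max_diff: int = 2, min_size: int = 2
) -> tuple[frozenset[int], ...]:
    """Connected components of MST edges with weight <= `max_diff`;
    components with >= `min_size` STs are groups (ordered by size
    descending, then lowest member ST)."""
    parent = {n.st_id: n.st_id for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in graph.edges:
        if e.weight <= max_diff:
            parent[find(e.u)] = find(e.v)
    comps: dict[int, set[int]] = {}
    for n in graph.nodes:
        comps.setdefault(find(n.st_id), set()).add(n.st_id)
    groups = [frozenset(c) for c in comps.values() if len(c) >= min_size]
    groups.sort(key=lambda g: (-len(g), min(g)))
    return tuple(groups)


def founder_candidates(graph: MstGraph) -> tuple[int, ...]:
    """ST ids ranked by (single-SNP MST neighbours desc, node size desc,
    st_id asc); the first entry is the founder candidate."""
    def key(node: MstNode):
        slv = sum(1 for w in graph.neighbours(node.st_id).values() if w == 1)
        return (-slv, -node.size, node.st_id)

    return tuple(n.st_id for n in sorted(graph.nodes, key=key))
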