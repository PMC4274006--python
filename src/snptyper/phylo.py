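"""Tree building over concatenated SNP profiles.

Three views of the same character data:

* UPGMA dendrogram on the pairwise SNP (Hamming) distance matrix, with
  the cophenetic correlation as a clustering-fidelity measure.  Merge
  heights are half the inter-cluster distance, so cophenetic distances
  are in SNP units.
* Maximum parsimony: Fitch small parsimony scores a fixed topology;
  tree search is either exhaustive (<= 9 taxa) or simulated annealing
  over NNI rearrangements from a random-addition greedy start.  The
  returned tree is rooted on the longest edge of the longest path,
  measuring edges by reconstructed change counts.
* Bootstrap support: SNP columns are resampled with replacement and the
  search repeated; support of a branch is the percentage of replicates
  whose tree contains the same bipartition.

Symbols (including IUPAC heterozygote codes) are categorical states:
A vs R is one difference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .errors import UsageError
from .genotyping import SnpProfile

Adjacency = dict[Hashable, set]


# ---------------------------------------------------------------------------
# distances


@dataclass(frozen=True)
class SnpDistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, integer SNP differences

    def __post_init__(self):
        a = np.asarray(self.d)
        if a.shape != (len(self.labels), len(self.labels)):
            raise UsageError("distance matrix shape does not match labels")
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise UsageError("distance matrix must be symmetric with zero diagonal")

    def value(self, a: str, b: str) -> int:
        i, j = self.labels.index(a), self.labels.index(b)
        return int(self.d[i, j])


def _vectors(profiles: Sequence[SnpProfile] | Mapping[str, Sequence[str]]):
    if isinstance(profiles, Mapping):
        return [(k, tuple(v)) for k, v in profiles.items()]
    return [(p.sample_id, p.alleles) for p in profiles]


def distance_matrix(profiles: Sequence[SnpProfile] | Mapping[str, Sequence[str]]) -> SnpDistanceMatrix:
    """Pairwise count of differing SNP columns (literal symbol
    comparison)."""
    items = _vectors(profiles)
    labels = tuple(k for k, _ in items)
    lengths = {len(v) for _, v in items}
    if len(lengths) > 1:
        raise UsageError("allele vectors differ in length")
    n = len(items)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(a != b for a, b in zip(items[i][1], items[j][1]))
            d[i, j] = d[j, i] = diff
    return SnpDistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass(frozen=True)
class ClusterNode:
    height: float
    children: tuple["ClusterNode", ...] = ()
    label: str | None = None

    @property
    def leaves(self) -> tuple[str, ...]:
        if self.label is not None:
            return (self.label,)
        return tuple(l for c in self.children for l in c.leaves)

    def newick(self) -> str:
        return self._newick(parent_height=self.height) + ";"

    def _newick(self, parent_height: float) -> str:
        length = parent_height - self.height
        if self.label is not None:
            return f"{self.label}:{length:g}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner}):{length:g}"


@dataclass(frozen=True)
class Dendrogram:
    root: ClusterNode
    labels: tuple[str, ...]
    cophenetic_r: float

    def cophenetic_distance(self, a: str, b: str) -> float:
        """2 x height of the lowest common ancestor (SNP units)."""
        node = self.root
        while node.label is None:
            below = [c for c in node.children if a in c.leaves and b in c.leaves]
            if not below:
                return 2.0 * node.height
            node = below[0]
        return 0.0

    def newick(self) -> str:
        return self.root.newick()


def upgma(D: SnpDistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration; merge height = distance / 2.

    Ties are broken by the lowest (min original label index) pair.  The
    cophenetic correlation against the input distances is attached.
    """
    n = len(D.labels)
    if n < 2:
        raise UsageError("UPGMA needs at least two taxa")
    # cluster id -> (min original index, size, node, member indices)
    clusters: dict[int, tuple[int, int, ClusterNode]] = {
        i: (i, 1, ClusterNode(0.0, label=D.labels[i])) for i in range(n)
    }
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(D.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        # choose min distance; tie -> lowest sorted (min-index_i, min-index_j)
        def sort_key(pair):
            i, j = sorted(pair, key=lambda c: clusters[c][0])
            return (dist[pair], clusters[i][0], clusters[j][0])

        best = min(dist, key=sort_key)
        i, j = sorted(best, key=lambda c: clusters[c][0])
        h = dist[best] / 2.0
        mi, si, ni = clusters[i]
        mj, sj, nj = clusters[j]
        merged = ClusterNode(h, children=(ni, nj))
        del clusters[i], clusters[j]
        del dist[best]
        new_dists = {}
        for k in clusters:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            new_dists[frozenset((next_id, k))] = (si * dik + sj * djk) / (si + sj)
        dist.update(new_dists)
        clusters[next_id] = (min(mi, mj), si + sj, merged)
        next_id += 1
    root = next(iter(clusters.values()))[2]
    dendro = Dendrogram(root, D.labels, cophenetic_r=float("nan"))
    r = _cophenetic_r(dendro, D)
    return Dendrogram(root, D.labels, cophenetic_r=r)


def _cophenetic_r(dendro: Dendrogram, D: SnpDistanceMatrix) -> float:
    orig, coph = [], []
    # LCA heights via recursive merge maps (O(n^2) total)
    heights: dict[frozenset[str], float] = {}

    def visit(node: ClusterNode):
        if node.label is not None:
            return [node.label]
        groups = [visit(c) for c in node.children]
        for ga, gb in itertools.combinations(groups, 2):
            for a in ga:
                for b in gb:
                    heights[frozenset((a, b))] = 2.0 * node.height
        return [l for g in groups for l in g]

    visit(dendro.root)
    n = len(D.labels)
    for i in range(n):
        for j in range(i + 1, n):
            orig.append(float(D.d[i, j]))
            coph.append(heights[frozenset((D.labels[i], D.labels[j]))])
    orig_a, coph_a = np.asarray(orig), np.asarray(coph)
    if np.ptp(orig_a) == 0 or np.ptp(coph_a) == 0:
        # degenerate: identical distances everywhere reproduce exactly
        return 1.0 if np.allclose(orig_a, coph_a) else float("nan")
    return float(np.corrcoef(orig_a, coph_a)[0, 1])


# ---------------------------------------------------------------------------
# character matrices and Fitch parsimony


@dataclass(frozen=True)
class CharacterMatrix:
    """Leaves x columns of categorical symbols, bit-encoded per column."""

    labels: tuple[str, ...]
    symbols: tuple[tuple[str, ...], ...]  # row-major, literal symbols
    masks: np.ndarray = field(init=False, repr=False)  # same shape, uint32 bitmasks

    def __post_init__(self):
        ncol = len(self.symbols[0]) if self.symbols else 0
        if any(len(row) != ncol for row in self.symbols):
            raise UsageError("ragged character matrix")
        masks = np.zeros((len(self.labels), ncol), dtype=np.uint32)
        for j in range(ncol):
            alphabet: dict[str, int] = {}
            for i, row in enumerate(self.symbols):
                bit = alphabet.setdefault(row[j], 1 << len(alphabet))
                masks[i, j] = bit
        object.__setattr__(self, "masks", masks)

    @property
    def n_columns(self) -> int:
        return self.masks.shape[1]

    @classmethod
    def from_profiles(cls, profiles: Sequence[SnpProfile] | Mapping[str, Sequence[str]]):
        items = _vectors(profiles)
        return cls(tuple(k for k, _ in items), tuple(tuple(v) for _, v in items))

    def resample_columns(self, rng: np.random.Generator) -> "CharacterMatrix":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        return CharacterMatrix(
            self.labels, tuple(tuple(row[c] for c in cols) for row in self.symbols)
        )


def _postorder(adj: Adjacency, root: Hashable):
    order, stack, seen = [], [root], {root}
    while stack:
        node = stack.pop()
        order.append(node)
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return list(reversed(order))  # children before parents


def fitch_score(adj: Adjacency, matrix: CharacterMatrix) -> int:
    """Sum over columns of Fitch small-parsimony change counts on the
    given unrooted topology."""
    leaves = [n for n in adj if isinstance(n, str)]
    if set(leaves) != set(matrix.labels):
        raise UsageError("topology leaves do not match character matrix")
    if len(leaves) == 1 or matrix.n_columns == 0:
        return 0
    row = {lab: i for i, lab in enumerate(matrix.labels)}
    if len(leaves) == 2:
        a, b = (matrix.masks[row[l]] for l in leaves)
        return int(np.count_nonzero((a & b) == 0))
    root = next(n for n in adj if not isinstance(n, str))
    order = _postorder(adj, root)
    parent = {}
    for node in reversed(order):
        for nb in adj[node]:
            if nb not in parent and nb != order[-1]:
                parent[nb] = node
    parent[order[-1]] = None
    sets: dict[Hashable, np.ndarray] = {}
    score = np.zeros(matrix.n_columns, dtype=np.int64)
    for node in order:
        if isinstance(node, str):
            sets[node] = matrix.masks[row[node]]
            continue
        children = [nb for nb in adj[node] if parent.get(nb) is node]
        acc = sets[children[0]]
        for ch in children[1:]:
            inter = acc & sets[ch]
            union = acc | sets[ch]
            empty = inter == 0
            score += empty
            acc = np.where(empty, union, inter)
        sets[node] = acc
    return int(score.sum())


# ---------------------------------------------------------------------------
# topologies


def _star(leaves: Sequence[str], internal_id: int = 0) -> Adjacency:
    adj: Adjacency = {internal_id: set(leaves)}
    for l in leaves:
        adj[l] = {internal_id}
    return adj


def _edges(adj: Adjacency):
    seen = set()
    for u, nbs in adj.items():
        for v in nbs:
            if frozenset((u, v)) not in seen:
                seen.add(frozenset((u, v)))
                yield (u, v)


def _insert_leaf(adj: Adjacency, leaf: str, edge: tuple, new_internal: int) -> Adjacency:
    u, v = edge
    out = {k: set(vs) for k, vs in adj.items()}
    out[u].discard(v)
    out[v].discard(u)
    out[u].add(new_internal)
    out[v].add(new_internal)
    out[new_internal] = {u, v, leaf}
    out[leaf] = {new_internal}
    return out


def enumerate_topologies(leaves: Sequence[str]):
    """All unrooted leaf-labelled binary topologies (1*3*5*...*(2n-5))."""
    leaves = list(leaves)
    n = len(leaves)
    if n < 3:
        adj: Adjacency = {l: set(leaves) - {l} for l in leaves}
        yield adj
        return

    def build(current: Adjacency, remaining: list[str], next_internal: int):
        if not remaining:
            yield current
            return
        leaf = remaining[0]
        for edge in list(_edges(current)):
            yield from build(
                _insert_leaf(current, leaf, edge, next_internal), remaining[1:], next_internal + 1
            )

    yield from build(_star(leaves[:3], 0), leaves[3:], 1)


def _nni_swap(adj: Adjacency, u, v, a, b) -> Adjacency:
    """Exchange subtree `a` of `u` with subtree `b` of `v` across the
    internal edge (u, v)."""
    out = {k: set(vs) for k, vs in adj.items()}
    out[u].discard(a)
    out[a].discard(u)
    out[v].discard(b)
    out[b].discard(v)
    out[u].add(b)
    out[b].add(u)
    out[v].add(a)
    out[a].add(v)
    return out


def _internal_edges(adj: Adjacency) -> list[tuple]:
    return sorted(
        ((u, v) for u, v in _edges(adj) if not isinstance(u, str) and not isinstance(v, str)),
        key=str,
    )


def _nni_neighbours(adj: Adjacency):
    """All NNI rearrangements around internal edges (two per edge)."""
    for u, v in _internal_edges(adj):
        u_subs = sorted((x for x in adj[u] if x != v), key=str)
        v_subs = sorted((x for x in adj[v] if x != u), key=str)
        for a, b in ((u_subs[0], v_subs[0]), (u_subs[0], v_subs[1])):
            yield _nni_swap(adj, u, v, a, b)


def _random_nni(adj: Adjacency, rng: np.random.Generator) -> Adjacency:
    """One uniformly chosen NNI rearrangement."""
    edges = _internal_edges(adj)
    u, v = edges[rng.integers(len(edges))]
    u_subs = sorted((x for x in adj[u] if x != v), key=str)
    v_subs = sorted((x for x in adj[v] if x != u), key=str)
    b = v_subs[rng.integers(2)]
    return _nni_swap(adj, u, v, u_subs[0], b)


def bipartitions(adj: Adjacency) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised as the side not
    containing the lexicographically smallest leaf."""
    leaves = sorted(n for n in adj if isinstance(n, str))
    anchor = leaves[0]
    out = set()
    for u, v in _edges(adj):
        if isinstance(u, str) or isinstance(v, str):
            continue
        side = _leaves_behind(adj, u, v)
        canon = frozenset(set(leaves) - side) if anchor in side else frozenset(side)
        if 2 <= len(canon) <= len(leaves) - 2:
            out.add(canon)
    return frozenset(out)


def _leaves_behind(adj: Adjacency, u, v) -> set[str]:
    """Leaves on the v-side of edge (u, v)."""
    stack, seen, out = [v], {u, v}, set()
    while stack:
        node = stack.pop()
        if isinstance(node, str):
            out.add(node)
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return out


# ---------------------------------------------------------------------------
# search


@dataclass(frozen=True)
class AnnealSchedule:
    t0: float = 5.0
    cooling: float = 0.95
    proposals_per_temp: int = 100
    t_min: float = 0.01


@dataclass(frozen=True)
class ParsimonyResult:
    adj: Adjacency
    score: int
    rooted_newick: str
    bootstrap_support: Mapping[frozenset[str], float] = field(default_factory=dict)


def _random_addition_tree(matrix: CharacterMatrix, rng: np.random.Generator) -> Adjacency:
    """Greedy stepwise addition in a random taxon order."""
    order = list(matrix.labels)
    rng.shuffle(order)
    if len(order) <= 3:
        return _star(order, 0)
    adj = _star(order[:3], 0)
    next_internal = 1
    for leaf in order[3:]:
        best_adj, best_score = None, None
        for edge in list(_edges(adj)):
            cand = _insert_leaf(adj, leaf, edge, next_internal)
            s = fitch_score(cand, _submatrix(matrix, [n for n in cand if isinstance(n, str)]))
            if best_score is None or s < best_score:
                best_adj, best_score = cand, s
        adj = best_adj
        next_internal += 1
    return adj


def _submatrix(matrix: CharacterMatrix, labels: Sequence[str]) -> CharacterMatrix:
    row = {lab: i for i, lab in enumerate(matrix.labels)}
    return CharacterMatrix(tuple(labels), tuple(matrix.symbols[row[l]] for l in labels))


def mp_search(
    matrix: CharacterMatrix,
    mode: str = "anneal",
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
) -> ParsimonyResult:
    """Search for a minimum-change topology.

    ``exhaustive`` scores every topology (allowed for <= 9 taxa; ties
    resolved in enumeration order).  ``anneal`` runs NNI simulated
    annealing with geometric cooling from a random-addition start and
    returns the best topology encountered.
    """
    n = len(matrix.labels)
    if n < 2:
        raise UsageError("tree search needs at least two taxa")
    rng = np.random.default_rng(seed)
    if mode == "exhaustive":
        if n > 9:
            raise UsageError("exhaustive search allowed only for <= 9 taxa")
        best_adj, best_score = None, None
        for adj in enumerate_topologies(sorted(matrix.labels)):
            s = fitch_score(adj, matrix)
            if best_score is None or s < best_score:
                best_adj, best_score = adj, s
    elif mode == "anneal":
        sched = schedule or AnnealSchedule()
        adj = _random_addition_tree(matrix, rng)
        score = fitch_score(adj, matrix)
        best_adj, best_score = adj, score
        t = sched.t0
        n_internal_edges = max(n - 3, 0)
        while t >= sched.t_min and n_internal_edges > 0:
            for _ in range(sched.proposals_per_temp):
                cand = _random_nni(adj, rng)
                cand_score = fitch_score(cand, matrix)
                delta = cand_score - score
                if delta <= 0 or rng.random() < math.exp(-delta / t):
                    adj, score = cand, cand_score
                    if score < best_score:
                        best_adj, best_score = adj, score
            t *= sched.cooling
    else:
        raise UsageError(f"unknown mode {mode!r}")
    newick = root_by_deepest_branch(best_adj, matrix)
    return ParsimonyResult(best_adj, int(best_score), newick)


# ---------------------------------------------------------------------------
# rooting and Newick output


def _edge_changes(adj: Adjacency, matrix: CharacterMatrix) -> dict[frozenset, int]:
    """Reconstructed change count per edge (Fitch downpass + deterministic
    uppass resolution, lowest bit preferred)."""
    leaves = [n for n in adj if isinstance(n, str)]
    row = {lab: i for i, lab in enumerate(matrix.labels)}
    if len(leaves) == 2:
        a, b = leaves
        d = int(np.count_nonzero((matrix.masks[row[a]] & matrix.masks[row[b]]) == 0))
        return {frozenset((a, b)): d}
    root = next(n for n in adj if not isinstance(n, str))
    order = _postorder(adj, root)
    parent: dict = {order[-1]: None}
    for node in reversed(order):
        for nb in adj[node]:
            if nb not in parent:
                parent[nb] = node
    down: dict[Hashable, np.ndarray] = {}
    for node in order:
        if isinstance(node, str):
            down[node] = matrix.masks[row[node]]
            continue
        children = [nb for nb in adj[node] if parent.get(nb) is node]
        acc = down[children[0]]
        for ch in children[1:]:
            inter = acc & down[ch]
            acc = np.where(inter == 0, acc | down[ch], inter)
        down[node] = acc
    lowbit = lambda m: (m & (~m + 1)).astype(np.uint32)  # lowest set bit
    state: dict[Hashable, np.ndarray] = {root: lowbit(down[root])}
    for node in order[-2::-1]:
        p = parent[node]
        inter = down[node] & state[p]
        state[node] = np.where(inter != 0, inter, lowbit(down[node])).astype(np.uint32)
    return {
        frozenset((node, parent[node])): int(np.count_nonzero(state[node] != state[parent[node]]))
        for node in order[:-1]
    }


def root_by_deepest_branch(adj: Adjacency, matrix: CharacterMatrix,
                           support: Mapping[frozenset[str], float] | None = None) -> str:
    """Rooted Newick: root on the longest edge of the longest
    (change-count-weighted) path — a midpoint-style reading of "deepest
    branch by maximum branch length"."""
    lengths = _edge_changes(adj, matrix)

    def farthest(start):
        dist = {start: 0.0}
        prev = {start: None}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + lengths[frozenset((u, v))]
                    prev[v] = u
                    stack.append(v)
        end = max(dist, key=lambda k: (dist[k], str(k)))
        return end, dist, prev

    leaves = sorted(n for n in adj if isinstance(n, str))
    a, _, _ = farthest(leaves[0])
    b, _, prev = farthest(a)
    path = [b]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    path_edges = list(zip(path, path[1:]))
    u, v = max(path_edges, key=lambda e: lengths[frozenset(e)])

    def write(node, parent_node, length_override: float | None = None) -> str:
        edge = frozenset((node, parent_node))
        length = lengths.get(edge, 0) if length_override is None else length_override
        if isinstance(node, str):
            return f"{node}:{length:g}"
        children = [nb for nb in adj[node] if nb != parent_node]
        inner = ",".join(write(c, node) for c in children)
        label = ""
        if support is not None:
            side = frozenset(_leaves_behind(adj, parent_node, node))
            canon = side if leaves[0] not in side else frozenset(set(leaves) - side)
            if canon in support:
                label = f"{support[canon]:.0f}"
        return f"({inner}){label}:{length:g}"

    half = lengths[frozenset((u, v))] / 2.0
    return f"({write(u, v, half)},{write(v, u, half)});"


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap(
    matrix: CharacterMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
    reference: ParsimonyResult | None = None,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for the bipartitions of the
    reference tree (computed here if not given).  Each replicate re-runs
    the annealing search with a fresh derived seed."""
    if len(matrix.labels) < 4:
        raise UsageError("bootstrap needs at least four taxa")
    sched = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = mp_search(matrix, "anneal", seed=int(rng.integers(2**31)), schedule=sched)
    ref_biparts = bipartitions(reference.adj)
    counts = {bp: 0 for bp in ref_biparts}
    for _ in range(n_reps):
        rep_matrix = matrix.resample_columns(rng)
        rep = mp_search(rep_matrix, "anneal", seed=int(rng.integers(2**31)), schedule=sched)
        rep_biparts = bipartitions(rep.adj)
        for bp in counts:
            if bp in rep_biparts:
                counts[bp] += 1
    return {bp: 100.0 * c / n_reps for bp, c in counts.items()}
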