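"""Distance-based phylogeny: p-distances, Poisson correction, neighbor
joining, bootstrap support, and support-based subgroup assignment.

The workflow mirrors the classical gene-family recipe: amino-acid
p-distances under pairwise deletion (columns with a gap in either row of a
pair are ignored for that pair), Poisson-corrected to ``-ln(1 - p)``,
a Saitou-Nei neighbor-joining tree, bootstrap support from column
resampling, and subgroups defined as the maximal clades whose support
reaches a cutoff (50% in standard practice) with at least two members.

Determinism: Q-matrix ties are broken by the lexicographically smallest
pair of cluster ids (a cluster is identified by its smallest leaf label),
and negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class SaturationError(ValueError):
    """p-distance at or beyond 1.0: the Poisson correction diverges."""


class NoComparableColumnsError(ValueError):
    """A sequence pair shares no gap-free column under pairwise deletion."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned amino-acid rows keyed by sequence id."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    @classmethod
    def from_dict(cls, rows: dict[str, str]) -> "Alignment":
        ids = tuple(sorted(rows))
        return cls(ids, tuple(rows[i] for i in ids))

    def resample_columns(self, column_indices: np.ndarray) -> "Alignment":
        rows = tuple("".join(r[c] for c in column_indices) for r in self.rows)
        return Alignment(self.ids, rows)


def pdistance(alignment: Alignment, id_a: str, id_b: str) -> float:
    """Proportion of mismatching residues under pairwise deletion."""
    a, b = alignment.row(id_a), alignment.row(id_b)
    compared = mismatches = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        compared += 1
        mismatches += x != y
    if compared == 0:
        raise NoComparableColumnsError(
            f"no comparable columns for pair ({id_a}, {id_b})")
    return mismatches / compared


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance ``-ln(1 - p)`` for a p-distance ``p``."""
    if not 0.0 <= p:
        raise ValueError("p-distance must be non-negative")
    if p >= 1.0:
        raise SaturationError(f"p-distance {p} saturated (>= 1)")
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix keyed by sequence id."""

    ids: tuple[str, ...]
    data: np.ndarray
    method: str = "poisson"

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.data = d

    def get(self, a: str, b: str) -> float:
        return float(self.data[self.ids.index(a), self.ids.index(b)])


def distance_matrix(alignment: Alignment, method: str = "poisson") -> DistanceMatrix:
    """All-pairs distances; ``method`` is ``p`` (raw) or ``poisson``."""
    n = len(alignment.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = pdistance(alignment, alignment.ids[i], alignment.ids[j])
            d[i, j] = d[j, i] = poisson_correct(p) if method == "poisson" else p
    return DistanceMatrix(alignment.ids, d, method)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class SupportTree:
    """Unrooted NJ tree stored rooted at the final (trifurcating) join."""

    root: Node

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def _internal_nodes(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node):
            for child, _ in node.children:
                if not child.is_leaf:
                    out.append(child)
                    walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, normalized to the side excluding the
        lexicographically smallest leaf."""
        leaves = set(self.root.leaves())
        ref = min(leaves)
        out = set()
        for node in self._internal_nodes():
            clade = frozenset(node.leaves())
            side = frozenset(leaves - clade) if ref in clade else clade
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return out

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: Node, length: float | None) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c, ln) for c, ln in node.children)
                sup = ""
                if include_support and node.support is not None:
                    sup = f"{node.support:g}"
                label = f"({inner}){sup}"
            return label if length is None else f"{label}:{length:.6f}"

        return fmt(self.root, None) + ";"

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (additivity check oracle)."""
        names = self.leaf_names()
        index = {n: i for i, n in enumerate(names)}
        d = np.zeros((len(names), len(names)))

        def below(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}  # type: ignore[dict-item]
            groups = []
            for child, ln in node.children:
                groups.append({k: v + ln for k, v in below(child).items()})
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            d[index[a], index[b]] = d[index[b], index[a]] = da + db
            merged: dict[str, float] = {}
            for g in groups:
                merged.update(g)
            return merged

        below(self.root)
        return DistanceMatrix(tuple(names), d, method="tree")


def nj_build(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking."""
    if len(dm.ids) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if not np.isfinite(dm.data).all():
        raise ValueError("non-finite distance in matrix")
    # active clusters keyed by their smallest leaf label
    nodes: dict[str, Node] = {i: Node(name=i) for i in dm.ids}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            dist[frozenset((a, dm.ids[j]))] = float(dm.data[i, j])

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(nodes) > 3:
        keys = sorted(nodes)
        n = len(keys)
        r = {k: sum(d(k, m) for m in keys if m != k) for k in keys}
        best_pair = None
        best_q = math.inf
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                q = (n - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and best_pair is not None
                                          and (a, b) < best_pair):
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair  # type: ignore[misc]
        dab = d(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        if lb < 0:
            la, lb = dab, 0.0
        new = Node(children=[(nodes[a], la), (nodes[b], lb)])
        for k in keys:
            if k in (a, b):
                continue
            dist[frozenset((min(a, b), k))] = max(0.0, 0.5 * (d(a, k) + d(b, k) - dab))
        for k in keys:
            dist.pop(frozenset((max(a, b), k)), None)
        del nodes[a], nodes[b]
        nodes[min(a, b)] = new

    (ka, na), (kb, nb), (kc, nc) = sorted(nodes.items())
    dab, dac, dbc = d(ka, kb), d(ka, kc), d(kb, kc)
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    root = Node(children=[(na, la), (nb, lb), (nc, lc)])
    return SupportTree(root)


@dataclass
class BootstrapResult:
    tree: SupportTree
    n_replicates: int
    n_dropped: int


def bootstrap_support(alignment: Alignment, n_replicates: int = 1000,
                      seed: int = 0, method: str = "poisson") -> BootstrapResult:
    """NJ tree with internal-node bootstrap supports (percent of replicates).

    Columns are resampled with replacement to the original alignment length;
    replicates in which a pair has no comparable column (or a saturated
    distance) are dropped and counted.  Supports are attached to the
    point-estimate tree's internal nodes.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = nj_build(distance_matrix(alignment, method))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}
    rng = np.random.default_rng(seed)
    successful = 0
    dropped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        try:
            rep = nj_build(distance_matrix(alignment.resample_columns(cols), method))
        except (NoComparableColumnsError, SaturationError):
            dropped += 1
            continue
        successful += 1
        rep_bps = rep.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = set(point.root.leaves())
    ref = min(leaves)
    for node in point._internal_nodes():
        clade = frozenset(node.leaves())
        side = frozenset(leaves - clade) if ref in clade else clade
        if side in counts:
            node.support = 100.0 * counts[side] / max(successful, 1)
    return BootstrapResult(point, n_replicates, dropped)


@dataclass
class SubgroupAssignment:
    """Leaf -> subgroup label mapping plus per-subgroup evidence."""

    mapping: dict[str, str]
    subgroups: dict[str, dict]  # label -> {"support": float, "members": tuple}

    UNASSIGNED = "unassigned"


def _unrooted_adjacency(tree: SupportTree):
    """Adjacency view of the tree; edge support lives on the child node."""
    adj: dict[int, list[tuple[int, float | None]]] = {}
    nodes: dict[int, Node] = {}
    order: list[int] = []

    def visit(node: Node):
        nodes[id(node)] = node
        order.append(id(node))
        for child, _ in node.children:
            sup = child.support if not child.is_leaf else None
            adj.setdefault(id(node), []).append((id(child), sup))
            adj.setdefault(id(child), []).append((id(node), sup))
            visit(child)

    visit(tree.root)
    return adj, nodes, order


def assign_subgroups(tree: SupportTree, min_support: float = 50.0,
                     min_size: int = 2, reroot: bool = False) -> SubgroupAssignment:
    """Subgroups from well-supported clades.

    A clade becomes a subgroup when its edge support reaches ``min_support``
    and it has at least ``min_size`` members, taking the *maximal* such
    clade (a qualifying clade is never descended into).

    An NJ tree is unrooted, and bootstrap support belongs to edges, not
    sides: reading clades off an arbitrary rooting can credit a stem edge's
    support to the complement of the group it actually delimits, merging
    well-separated groups or splitting one across the root.  With
    ``reroot=True`` every internal node is tried as root and the rooting
    minimizing the number of unassigned leaves (ties: highest mean subgroup
    support, then fewest subgroups, then traversal order) is used; with the
    default ``reroot=False`` the tree's stored rooting is taken as-is.
    Recovering a partition this way needs at least three groups — with only
    two, an unrooted tree cannot say which side of its single supported
    edge is "the" subgroup.
    """
    adj, nodes, order = _unrooted_adjacency(tree)
    total_leaves = tree.leaf_names()
    leafsets: dict[tuple[int, int], tuple[str, ...]] = {}

    def leafset(parent: int, node: int) -> tuple[str, ...]:
        key = (parent, node)
        if key not in leafsets:
            if nodes[node].is_leaf:
                leafsets[key] = (nodes[node].name,)  # type: ignore[assignment]
            else:
                acc: list[str] = []
                for other, _ in adj[node]:
                    if other != parent:
                        acc.extend(leafset(node, other))
                leafsets[key] = tuple(sorted(acc))
        return leafsets[key]

    def edge_support(parent: int, node: int) -> float | None:
        for other, sup in adj[parent]:
            if other == node:
                return sup
        return None

    def qualifies(parent: int, node: int) -> bool:
        sup = edge_support(parent, node)
        return (sup is not None and sup >= min_support
                and len(leafset(parent, node)) >= min_size)

    def collect(root_id: int) -> list[tuple[float, tuple[str, ...]]]:
        found: list[tuple[float, tuple[str, ...]]] = []

        def walk(parent: int, node: int):
            if qualifies(parent, node):
                found.append((edge_support(parent, node),  # type: ignore[arg-type]
                              leafset(parent, node)))
                return  # maximality: never descend into a qualifying clade
            if not nodes[node].is_leaf:
                for other, _ in adj[node]:
                    if other != parent:
                        walk(node, other)

        for other, _ in adj[root_id]:
            walk(root_id, other)
        return found

    candidates = [id(tree.root)]
    if reroot:
        candidates += [nid for nid in order
                       if nid != id(tree.root) and not nodes[nid].is_leaf]
    best = None
    for index, root_id in enumerate(candidates):
        found = collect(root_id)
        unassigned = len(total_leaves) - sum(len(m) for _, m in found)
        mean_support = (sum(s for s, _ in found) / len(found)) if found else 0.0
        key = (unassigned, -mean_support, len(found), index)
        if best is None or key < best[0]:
            best = (key, found)
    found = sorted(best[1], key=lambda t: min(t[1]))  # type: ignore[index]
    mapping = {leaf: SubgroupAssignment.UNASSIGNED for leaf in total_leaves}
    subgroups = {}
    for i, (support, members) in enumerate(found, start=1):
        label = f"S{i}"
        subgroups[label] = {"support": support, "members": members}
        for m in members:
            mapping[m] = label
    return SubgroupAssignment(mapping, subgroups)
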