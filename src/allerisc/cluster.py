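"""Phylogroup clustering from A-RISC-derived distances.

Allergens are grouped by agglomerative clustering of the distance matrix
``d = 1 - arisc/100``; the default UPGMA linkage yields an ultrametric merge
tree whose k-cut gives unambiguous phylogroups.  This distance-based
clustering is a deliberate, documented stand-in for likelihood-based
phylogenetics: the claims it supports (number of phylogroups, within-group
homogeneity) do not require a maximum-likelihood tree.

Supported linkages: ``upgma`` (= ``average``), ``complete``, and ``nj``
(neighbour joining via scikit-bio, midpoint-rooted).  Agglomeration ties are
broken on the lexicographically smallest pair of cluster representatives, so
the tree — and in particular the partition from :func:`cut_clusters` — is
invariant to input order.

Branch support comes from a column-resampling bootstrap: for every pairwise
alignment the (identical / similar-only / dissimilar / gap) column counts
are resampled multinomially, distances are rebuilt, and each reference-tree
clade's support is the fraction of replicate trees containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import AlignParams, global_align, percent_counts
from .arisc import ARiscMatrix, arisc_index
from .records import ProteinRecord

LINKAGES = ("upgma", "average", "complete", "nj")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal, entries in [0, 1]."""

    ids: List[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(v), 0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    @classmethod
    def from_arisc(cls, matrix: ARiscMatrix) -> "DistanceMatrix":
        frac = matrix.as_fraction()
        d = 1.0 - frac
        np.fill_diagonal(d, 0.0)
        return cls(ids=list(matrix.ids), values=np.clip(d, 0.0, 1.0))


@dataclass
class TreeNode:
    """Node of a rooted merge tree; leaves carry ids, internal nodes heights
    (merge order index) and optional bootstrap support."""

    name: Optional[str] = None
    children: List["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    support: Optional[float] = None
    merge_order: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> List[str]:
        return [l.name for l in self.leaves()]

    def postorder(self) -> List["TreeNode"]:
        out = []
        for c in self.children:
            out.extend(c.postorder())
        out.append(self)
        return out


@dataclass
class ClusterTree:
    root: TreeNode

    @property
    def leaf_ids(self) -> List[str]:
        return self.root.leaf_names()

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def internal_nodes(self) -> List[TreeNode]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    def clades(self) -> List[frozenset]:
        """Leaf sets of all internal nodes (the rooted bipartitions)."""
        return [frozenset(n.leaf_names()) for n in self.internal_nodes()]


def _cluster_key(members: frozenset) -> str:
    return min(members)


def _agglomerate(d: DistanceMatrix, linkage: str) -> ClusterTree:
    ids = d.ids
    n = len(ids)
    active: Dict[int, TreeNode] = {i: TreeNode(name=ids[i]) for i in range(n)}
    sizes: Dict[int, int] = {i: 1 for i in range(n)}
    # lexicographically smallest leaf id in each cluster — the tie-break
    # representative, so input order cannot change the result
    reps: Dict[int, str] = {i: ids[i] for i in range(n)}
    dist: Dict[Tuple[int, int], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(a, b)] = float(d.values[a, b])
    next_key = n
    merge_order = 0
    while len(active) > 1:
        best_v = None
        best_rep = None
        best_pair = None
        for (x, y), v in dist.items():
            if best_v is not None and v > best_v:
                continue
            rep = tuple(sorted((reps[x], reps[y])))
            if best_v is None or v < best_v or rep < best_rep:
                best_v, best_rep, best_pair = v, rep, (x, y)
        x, y = best_pair
        node = TreeNode(
            children=sorted([active[x], active[y]], key=lambda c: min(c.leaf_names())),
            height=_round_height(best_v / 2.0),
            merge_order=merge_order,
        )
        # guard against float noise breaking height monotonicity
        node.height = max(node.height, max(c.height for c in node.children))
        merge_order += 1
        merged = next_key
        next_key += 1
        sz_x, sz_y = sizes[x], sizes[y]

        def get_dist(u, w):
            return dist[(u, w)] if (u, w) in dist else dist[(w, u)]

        others = [k for k in active if k not in (x, y)]
        new_entries = {}
        for other in others:
            dx = get_dist(x, other)
            dy = get_dist(y, other)
            if linkage in ("upgma", "average"):
                nd = (sz_x * dx + sz_y * dy) / (sz_x + sz_y)
            else:  # complete
                nd = max(dx, dy)
            new_entries[(other, merged)] = nd
        dist = {
            (a, b): v for (a, b), v in dist.items() if x not in (a, b) and y not in (a, b)
        }
        dist.update(new_entries)
        reps[merged] = min(reps[x], reps[y])
        sizes[merged] = sz_x + sz_y
        active[merged] = node
        for k in (x, y):
            del active[k], sizes[k], reps[k]
    return ClusterTree(root=next(iter(active.values())))


def _nj_tree(d: DistanceMatrix) -> ClusterTree:
    """Neighbour joining via scikit-bio, midpoint-rooted and converted to a
    merge tree with heights = max root-ward distance to a leaf (negative NJ
    branch lengths clamped to zero)."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    sk = nj(SkbioDM(d.values, ids=d.ids))
    sk = sk.root_at_midpoint()

    order = [0]

    def convert(node) -> TreeNode:
        if node.is_tip():
            return TreeNode(name=node.name)
        children = [convert(c) for c in node.children]
        height = _round_height(
            max(
                c.height + max(float(orig.length or 0.0), 0.0)
                for c, orig in zip(children, node.children)
            )
        )
        t = TreeNode(children=children, height=height, merge_order=order[0])
        order[0] += 1
        return t

    tree = ClusterTree(root=convert(sk))
    # merge order must follow height for cutting; re-rank by height
    ranked = sorted(tree.internal_nodes(), key=lambda n: (n.height, n.merge_order))
    for rank, node in enumerate(ranked):
        node.merge_order = rank
    return tree


def build_tree(d: DistanceMatrix, linkage: str = "upgma") -> ClusterTree:
    """Build a rooted cluster tree from a distance matrix.

    Deterministic for fixed input and linkage; requires >= 3 leaves.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(d.ids) < 3:
        raise ValueError("need at least 3 leaves")
    if linkage == "nj":
        return _nj_tree(d)
    return _agglomerate(d, linkage)


def cut_clusters(tree: ClusterTree, k: int) -> Dict[str, int]:
    """Cut the tree into exactly *k* clusters by undoing the last k-1 merges.

    Returns leaf id -> cluster label (1..k); labels are assigned in tree
    traversal order, so they are stable across runs.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    components: List[TreeNode] = [tree.root]
    while len(components) < k:
        # split the most recently merged (highest) internal node present
        candidates = [c for c in components if not c.is_leaf]
        target = max(candidates, key=lambda c: c.merge_order)
        components.remove(target)
        components.extend(target.children)
    traversal = tree.root.leaf_names()
    first_leaf_pos = {
        id(c): min(traversal.index(name) for name in c.leaf_names()) for c in components
    }
    components.sort(key=lambda c: first_leaf_pos[id(c)])
    assignment: Dict[str, int] = {}
    for label, comp in enumerate(components, start=1):
        for name in comp.leaf_names():
            assignment[name] = label
    return assignment


# ---------------------------------------------------------------------------
# Newick serialisation
#
# Node heights are kept on a 1e-9 decimal grid (see _round_height); branch
# lengths are height differences and therefore also grid values, written in
# fixed-point.  This makes write -> read -> write byte-stable.


def _round_height(x: float) -> float:
    return round(x, 9)


def _fmt(x: float) -> str:
    s = f"{x:.9f}".rstrip("0")
    return s + "0" if s.endswith(".") else s


def _fmt_support(x: float) -> str:
    return f"{x:.6g}"


def to_newick(tree: ClusterTree, include_support: bool = True) -> str:
    """Serialise as Newick; internal node labels carry bootstrap support when
    present; branch lengths are height differences (ultrametric for UPGMA)."""

    def render(node: TreeNode, parent_height: Optional[float]) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(render(c, node.height) for c in node.children)
            label = (
                _fmt_support(node.support)
                if (include_support and node.support is not None)
                else ""
            )
            body = f"({inner}){label}"
        if parent_height is None:
            return body
        return f"{body}:{_fmt(max(parent_height - node.height, 0.0))}"

    return render(tree.root, None) + ";"


def from_newick(text: str) -> ClusterTree:
    """Parse a Newick string produced by :func:`to_newick` (binary or
    multifurcating; internal labels read as supports).  Heights are
    reconstructed as the maximum leaf-ward path length below each node."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = text[:-1]
    pos = [0]

    def parse_node() -> Tuple[TreeNode, float]:
        node = TreeNode()
        if s[pos[0]] == "(":
            pos[0] += 1
            while True:
                child, blen = parse_node()
                child._blen = blen  # type: ignore[attr-defined]
                node.children.append(child)
                if s[pos[0]] == ",":
                    pos[0] += 1
                    continue
                if s[pos[0]] == ")":
                    pos[0] += 1
                    break
            label = _read_token()
            if label:
                node.support = float(label)
        else:
            node.name = _read_token()
        blen = 0.0
        if pos[0] < len(s) and s[pos[0]] == ":":
            pos[0] += 1
            blen = float(_read_token())
        return node, blen

    def _read_token() -> str:
        start = pos[0]
        while pos[0] < len(s) and s[pos[0]] not in "(),:;":
            pos[0] += 1
        return s[start : pos[0]]

    root, _ = parse_node()
    if pos[0] != len(s):
        raise ValueError("trailing characters in Newick string")

    def set_heights(node: TreeNode) -> float:
        if node.is_leaf:
            node.height = 0.0
            return 0.0
        node.height = _round_height(
            max(set_heights(c) + getattr(c, "_blen", 0.0) for c in node.children)
        )
        return node.height

    set_heights(root)
    order = [0]

    def set_order(node: TreeNode) -> None:
        for c in node.children:
            set_order(c)
        if not node.is_leaf:
            node.merge_order = order[0]
            order[0] += 1

    set_order(root)
    ranked = sorted(
        [n for n in root.postorder() if not n.is_leaf],
        key=lambda n: (n.height, n.merge_order),
    )
    for rank, node in enumerate(ranked):
        node.merge_order = rank
    return ClusterTree(root=root)


# ---------------------------------------------------------------------------
# Bootstrap support


def _pairwise_category_counts(
    records: Sequence[ProteinRecord], params: AlignParams
) -> Tuple[List[str], Dict[Tuple[int, int], Tuple[int, int, int, int]], Dict[Tuple[int, int], Tuple[int, int]]]:
    ids = [r.id for r in records]
    counts: Dict[Tuple[int, int], Tuple[int, int, int, int]] = {}
    lengths: Dict[Tuple[int, int], Tuple[int, int]] = {}
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            res = global_align(records[i].sequence, records[j].sequence, params)
            counts[(i, j)] = res.category_counts()
            lengths[(i, j)] = (len(records[i].sequence), len(records[j].sequence))
    return ids, counts, lengths


def bootstrap_support(
    records: Sequence[ProteinRecord],
    params: Optional[AlignParams] = None,
    n_reps: int = 100,
    seed: int = 0,
    linkage: str = "upgma",
) -> ClusterTree:
    """Reference tree with per-node column-resampling bootstrap supports.

    Each replicate resamples the columns of every pairwise alignment with
    replacement (multinomially over the identical / similar-only /
    dissimilar / gap column categories), recomputes I, S, A-RISC, and the
    tree; support of a reference clade is the fraction of replicate trees
    containing it.  Reproducible for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    params = params or AlignParams()
    ids, counts, lengths = _pairwise_category_counts(records, params)
    n = len(ids)

    def distances_from(cat: Dict[Tuple[int, int], Sequence[int]]) -> DistanceMatrix:
        d = np.zeros((n, n))
        for (i, j), (n_id, n_sim, n_dis, n_gap) in cat.items():
            ncol = n_id + n_sim + n_dis + n_gap
            la, lb = lengths[(i, j)]
            identity, similarity = percent_counts(
                n_id, n_sim, ncol, n_gap, la, lb, params.denominator
            )
            a = arisc_index(identity, similarity)
            d[i, j] = d[j, i] = 1.0 - a / 100.0
        return DistanceMatrix(ids=list(ids), values=np.clip(d, 0.0, 1.0))

    reference = build_tree(distances_from(counts), linkage)
    rng = np.random.default_rng(seed)
    clade_hits = {frozenset(c): 0 for c in reference.clades()}
    for _ in range(n_reps):
        resampled = {}
        for key, cat in counts.items():
            ncol = sum(cat)
            probs = np.array(cat, dtype=float) / ncol
            resampled[key] = tuple(rng.multinomial(ncol, probs))
        rep_tree = build_tree(distances_from(resampled), linkage)
        rep_clades = set(rep_tree.clades())
        for clade in clade_hits:
            if clade in rep_clades:
                clade_hits[clade] += 1
    for node in reference.internal_nodes():
        node.support = clade_hits[frozenset(node.leaf_names())] / n_reps
    return reference


def write_assignment_tsv(assignment: Dict[str, int], path) -> None:
    """Write a two-column (id, cluster) TSV, rows in label-then-id order."""
    import pandas as pd

    df = pd.DataFrame(
        sorted(assignment.items(), key=lambda kv: (kv[1], kv[0])),
        columns=["id", "cluster"],
    )
    df.to_csv(path, sep="\t", index=False)
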