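"""Distance trees, midpoint rooting and monophyly tests.

Duplicated-segment proteins that arose by gene duplication inside one virus
are expected to form a clade in a tree of their homolog cluster.  This
module provides exactly the machinery needed to state that check at desk
scale: p-distances from a protein MSA, canonical neighbor joining with
deterministic tie-breaking, midpoint rooting, and an exact monophyly test.
p-distance is the default (a Poisson correction is available); trees are
dendropy objects and serialize as Newick.
"""

from __future__ import annotations

import math

import dendropy
from skbio import DistanceMatrix

from .align import Msa

__all__ = [
    "p_distance_matrix",
    "neighbor_joining",
    "midpoint_root",
    "is_monophyletic",
    "is_split",
    "to_newick",
    "from_newick",
]


def p_distance_matrix(msa: Msa, poisson: bool = False) -> DistanceMatrix:
    """Pairwise fraction of differing residues over columns ungapped in
    both rows.  ``poisson`` applies -ln(1 - p) to correct for multiple
    hits.  A pair with zero comparable columns is an error."""
    if len(msa.rows) < 3:
        raise ValueError("p_distance_matrix requires >= 3 rows")
    n = len(msa.rows)
    data = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for x, y in zip(msa.rows[i], msa.rows[j]):
                if x != "-" and y != "-":
                    comparable += 1
                    if x != y:
                        diffs += 1
            if comparable == 0:
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no "
                    "ungapped columns"
                )
            p = diffs / comparable
            if poisson:
                if p >= 1.0:
                    raise ValueError("saturated distance under Poisson correction")
                p = -math.log(1.0 - p)
            data[i][j] = data[j][i] = p
    return DistanceMatrix(data, ids=msa.ids)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical NJ agglomeration; exact on additive matrices.

    Tie-breaking: among minimal-Q pairs, the pair whose (sorted) smallest
    leaf labels are lexicographically smallest is joined, which makes the
    output deterministic.  Negative branch-length estimates are clamped at
    zero.  The returned tree is unrooted (trifurcating seed node).
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires >= 3 labels")
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False

    nodes: dict[str, dendropy.Node] = {}
    minleaf: dict[str, str] = {}
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes[lab] = node
        minleaf[lab] = lab
    d: dict[str, dict[str, float]] = {
        a: {b: float(dm[a, b]) for b in labels if b != a} for a in labels
    }
    active = list(labels)
    counter = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        best_key = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d[a][b] - r[a] - r[b]
                key = (q, tuple(sorted((minleaf[a], minleaf[b]))))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        dab = d[a][b]
        la = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        counter += 1
        new_label = f"__nj{counter}"
        new_node = dendropy.Node()
        new_node.add_child(nodes[a])
        new_node.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        nodes[new_label] = new_node
        minleaf[new_label] = min(minleaf[a], minleaf[b])
        d[new_label] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = (d[a][c] + d[b][c] - dab) / 2
            d[new_label][c] = d[c][new_label] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [new_label]

    u, v = active
    # attach the remaining node to the internal one (trifurcating root)
    if nodes[u].is_leaf():
        u, v = v, u
    nodes[u].add_child(nodes[v])
    nodes[v].edge.length = max(d[u][v], 0.0)
    tree.seed_node = nodes[u]
    return tree


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else ""


def _adjacency(tree: dendropy.Tree):
    """Undirected adjacency with edge lengths and the connecting edge."""
    adj: dict[int, list[tuple[dendropy.Node, float, dendropy.Edge]]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            length = child.edge.length or 0.0
            adj.setdefault(id(node), []).append((child, length, child.edge))
            adj.setdefault(id(child), []).append((node, length, child.edge))
    return adj


def _distances_from(tree, start, adj):
    dist: dict[int, float] = {id(start): 0.0}
    prev: dict[int, tuple[dendropy.Node, dendropy.Edge]] = {}
    node_by_id = {id(start): start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, length, edge in adj.get(id(node), ()):
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + length
                prev[id(nbr)] = (node, edge)
                node_by_id[id(nbr)] = nbr
                stack.append(nbr)
    return dist, prev, node_by_id


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    After rooting, the root has degree 2 and the two deepest root-to-leaf
    distances are equal within 1e-9 (unless the midpoint coincides with an
    unbalanced node, when the closest attainable point on the path is
    used).  An all-zero-branch-length tree is an error.
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=_leaf_label)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    adj = _adjacency(tree)

    best = None  # (-pathlen, labelA, labelB, leafA)
    dist_cache = {}
    for leaf in leaves:
        dist, prev, node_by_id = _distances_from(tree, leaf, adj)
        dist_cache[id(leaf)] = (dist, prev, node_by_id)
        for other in leaves:
            if _leaf_label(other) <= _leaf_label(leaf):
                continue
            key = (-dist[id(other)], _leaf_label(leaf), _leaf_label(other), leaf, other)
            if best is None or key[:3] < best[:3]:
                best = key
    total = -best[0]
    if total <= 0:
        raise ValueError("midpoint rooting undefined for all-zero branch lengths")
    leaf_a, leaf_b = best[3], best[4]
    dist, prev, node_by_id = dist_cache[id(leaf_a)]

    # walk back from leaf_b toward leaf_a until the midpoint edge is found
    half = total / 2.0
    node = leaf_b
    walked = 0.0  # distance from leaf_b back toward leaf_a
    while True:
        parent_on_path, edge = prev[id(node)]
        length = edge.length or 0.0
        if walked + length >= half - 1e-12:
            break
        walked += length
        node = parent_on_path
    # midpoint lies on `edge`, at `half - walked` from the leaf_b side
    from_b_side = half - walked
    length = edge.length or 0.0
    # edge.head_node is the child in the rooted representation; determine
    # which side of the edge faces leaf_b on the path
    head_faces_b = node is edge.head_node
    if head_faces_b:
        length_head = from_b_side
        length_tail = length - from_b_side
    else:
        length_tail = from_b_side
        length_head = length - from_b_side
    tree.reroot_at_edge(edge, length1=length_tail, length2=length_head)
    tree.is_rooted = True
    return tree


def is_monophyletic(tree: dendropy.Tree, labels: set[str]) -> bool:
    """True iff some node's leaf descendants equal exactly ``labels``."""
    leaf_labels = {_leaf_label(l) for l in tree.leaf_node_iter()}
    unknown = set(labels) - leaf_labels
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    target = set(labels)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([_leaf_label(node)])
        else:
            acc = frozenset()
            for child in node.child_nodes():
                acc |= child._leafset
            node._leafset = acc
        if node._leafset == target:
            return True
    return False


def is_split(tree: dendropy.Tree, labels: set[str]) -> bool:
    """True iff some edge bipartitions the leaves into ``labels`` vs rest.

    This is the unrooted reading of clade-ness: the set is monophyletic
    under some rooting outside it.  On small midpoint-rooted trees a long
    pendant branch inside the set can attract the root and break rooted
    monophyly even though the unrooted topology groups the set; this
    predicate is the robust statement for trees of a handful of leaves.
    """
    leaf_labels = {_leaf_label(l) for l in tree.leaf_node_iter()}
    unknown = set(labels) - leaf_labels
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    target = set(labels)
    complement = leaf_labels - target
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {_leaf_label(l) for l in node.leaf_iter()}
        if side == target or side == complement:
            return True
    return False


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=False).strip()


def from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")
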