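"""Dendrograms of similarity matrices: neighbor joining, OLS branch lengths,
branch score distance, jack-knife robustness, and agglomerative simplification.

Trees here are *unrooted* leaf-labeled trees with real branch lengths
(no ancestry is implied among amino acids or among alphabets); they are
carried as :class:`dendropy.Tree` objects and serialized as Newick.

The pipeline mirrors classical distance-based phylogenetics: a neighbor
joining (Saitou-Nei) topology whose branch lengths are then re-fit by
ordinary least squares against the input distance matrix, i.e. lengths
minimizing ``sum_(i<j) (path_length(i,j) - d(i,j))^2`` on the fixed
topology. Negative fitted lengths are kept (they are part of the OLS
solution); a display-only clamp is available downstream.

Tree-to-tree distance is the branch score distance of Kuhner & Felsenstein:
for every bipartition (split) occurring in either tree take the difference
of its branch lengths (0 where absent), and aggregate the squared
differences. The square-root form is the default; the squared form is
available via ``squared=True`` since both conventions circulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .alphabet_io import AMINO_ACIDS, AlphabetCollection, SimplifiedAlphabet
from .bigmat import (
    AlphabetSimilarityMatrix,
    AminoAcidDistanceMatrix,
    ConsensusSimilarityMatrix,
    build_consensus,
    similarity_to_distance,
)

_SYM_TOL = 1e-9
_TIE_TOL = 1e-12


def _as_labeled_array(d) -> tuple[np.ndarray, list[str]]:
    """Coerce the accepted distance-matrix flavors to (ndarray, labels)."""
    if isinstance(d, AminoAcidDistanceMatrix):
        return np.asarray(d.values, dtype=float), list(AMINO_ACIDS)
    if isinstance(d, AlphabetSimilarityMatrix):
        # similarity -> distance complement
        m = 1.0 - np.asarray(d.values, dtype=float)
        np.fill_diagonal(m, 0.0)
        return m, list(d.ids)
    if isinstance(d, pd.DataFrame):
        return d.to_numpy(dtype=float), [str(c) for c in d.index]
    raise TypeError(f"unsupported distance-matrix type: {type(d).__name__}")


def _validate_distance(m: np.ndarray, labels: list[str]) -> None:
    n = len(labels)
    if m.shape != (n, n):
        raise ValueError(f"matrix shape {m.shape} does not match {n} labels")
    if n < 3:
        raise ValueError("need at least 3 labels to build an unrooted tree")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")
    if np.abs(m - m.T).max() > _SYM_TOL:
        raise ValueError("distance matrix is asymmetric beyond tolerance 1e-9")


def neighbor_joining(d, labels: list[str] | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a distance matrix; unrooted tree.

    Accepts an :class:`AminoAcidDistanceMatrix`, an
    :class:`AlphabetSimilarityMatrix` (complemented to distances), a labeled
    :class:`pandas.DataFrame`, or a bare array plus explicit *labels*.

    Ties in the Q-criterion are broken by the lexicographically smallest
    pair of cluster representative labels (the representative of a cluster
    being its alphabetically first leaf), so the topology is deterministic.
    """
    if isinstance(d, np.ndarray):
        if labels is None:
            raise ValueError("labels required with a bare array")
        m, labs = np.asarray(d, dtype=float).copy(), list(labels)
    else:
        m, labs = _as_labeled_array(d)
        m = m.copy()
    _validate_distance(m, labs)

    tns = dendropy.TaxonNamespace(labs)
    nodes = []
    for lab in labs:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    reps = list(labs)  # representative (alphabetically first leaf) per cluster
    active = list(range(len(labs)))

    def pick_pair() -> tuple[int, int]:
        n = len(active)
        sub = m[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(n, k=1)
        qv = q[iu]
        qmin = qv.min()
        best = None
        for a, b, val in zip(iu[0], iu[1], qv):
            if val <= qmin + _TIE_TOL:
                i, j = active[a], active[b]
                key = tuple(sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        return best[1], best[2]

    while len(active) > 3:
        a, b = pick_pair()
        i, j = active[a], active[b]
        n = len(active)
        sub = m[np.ix_(active, active)]
        r = sub.sum(axis=1)
        dij = m[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (n - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new cluster to every other active cluster
        new_row = np.empty(m.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (m[i, k] + m[j, k] - dij)
        u = m.shape[0]
        m = np.pad(m, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            m[u, k] = m[k, u] = new_row[k]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    # join the final three clusters at a central node (closed form)
    i, j, k = active
    center = dendropy.Node()
    for x, y, z in ((i, j, k), (j, i, k), (k, i, j)):
        lx = 0.5 * (m[x, y] + m[x, z] - m[y, z])
        center.add_child(nodes[x])
        nodes[x].edge.length = lx
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits


def _canonical_splits(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Map each bipartition to its branch length (lengths of duplicate
    splits — e.g. the two basal edges of a degree-2 root — are summed).

    A split is keyed by the leaf-label side *not* containing the
    alphabetically first leaf, so complementary sides coincide. The trivial
    all-leaves split is dropped.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(all_leaves)
    splits: dict[frozenset[str], float] = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        side = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        if anchor in side:
            side = all_leaves - side
        if not side:  # root edge / trivial
            continue
        splits[side] = splits.get(side, 0.0) + (edge.length or 0.0)
    return splits


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """The set of canonical (non-trivial-side-normalized) splits of a tree."""
    return set(_canonical_splits(tree))


def branch_score_distance(
    t1: dendropy.Tree, t2: dendropy.Tree, *, squared: bool = False
) -> float:
    """Kuhner-Felsenstein branch score distance between two trees.

    Splits present in only one tree contribute their full length (the other
    length is 0). ``squared=True`` returns the sum of squared differences
    without the square root.
    """
    l1 = frozenset(lf.taxon.label for lf in t1.leaf_node_iter())
    l2 = frozenset(lf.taxon.label for lf in t2.leaf_node_iter())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    s1, s2 = _canonical_splits(t1), _canonical_splits(t2)
    total = 0.0
    for split in set(s1) | set(s2):
        diff = s1.get(split, 0.0) - s2.get(split, 0.0)
        total += diff * diff
    return total if squared else float(np.sqrt(total))


# ---------------------------------------------------------------------------
# OLS branch lengths


def path_length_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path lengths (sum of branch lengths along the path)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for t1 in pdm.taxon_iter():
        for t2 in pdm.taxon_iter():
            if t1 is not t2:
                out.loc[t1.label, t2.label] = pdm.distance(t1, t2)
    return out


def fit_ols_branch_lengths(topology: dendropy.Tree, d) -> dendropy.Tree:
    """Re-fit branch lengths by unweighted least squares on a fixed topology.

    Solves the edge-path incidence system ``A x = d`` (one row per leaf
    pair, one column per edge; entry 1 when the edge lies on the pair's
    path) in the least-squares sense. The topology is untouched; a new tree
    is returned. Negative solutions are kept.
    """
    if isinstance(d, np.ndarray):
        raise TypeError("pass a labeled matrix (DataFrame or package matrix type)")
    m, labs = _as_labeled_array(d)
    tree = topology.clone(depth=1)
    if len(tree.seed_node.child_nodes()) == 2:
        # a rooted bifurcation at the seed leaves one unrooted edge split in
        # two, making the OLS system singular; collapse it first
        tree.collapse_basal_bifurcation()
    leaf_labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if set(leaf_labels) != set(labs):
        raise ValueError("topology leaf set does not match matrix labels")
    idx = {lab: i for i, lab in enumerate(labs)}

    edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
    n = len(leaf_labels)
    pairs = [(leaf_labels[i], leaf_labels[j]) for i in range(n) for j in range(i + 1, n)]
    pair_pos = {p: r for r, p in enumerate(pairs)}
    a_mat = np.zeros((len(pairs), len(edges)))
    for c, e in enumerate(edges):
        side = {lf.taxon.label for lf in e.head_node.leaf_iter()}
        for p, (u, v) in enumerate(pairs):
            if (u in side) != (v in side):
                a_mat[p, c] = 1.0
    y = np.array([m[idx[u], idx[v]] for (u, v) in pairs])
    x, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
    if not np.all(np.isfinite(x)):  # pragma: no cover - defensive
        raise ValueError("singular least-squares system for branch lengths")
    for e, length in zip(edges, x):
        e.length = float(length)
    del pair_pos
    return tree


def nj_ols_tree(d) -> dendropy.Tree:
    """Neighbor joining topology with OLS-refit branch lengths."""
    return fit_ols_branch_lengths(neighbor_joining(d), d)


def total_branch_length(tree: dendropy.Tree) -> float:
    return float(sum(abs(e.length or 0.0) for e in tree.preorder_edge_iter()
                     if e.tail_node is not None))


def clamp_negative_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Display-only copy with negative branch lengths set to 0."""
    t = tree.clone(depth=1)
    for e in t.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    return t


# ---------------------------------------------------------------------------
# Newick round-trip


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip() + "\n"


def newick_to_tree(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from None
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# consensus tree + jack-knife


def consensus_tree(collection: AlphabetCollection) -> dendropy.Tree:
    """NJ+OLS amino-acid dendrogram from the collection's consensus matrix."""
    return nj_ols_tree(similarity_to_distance(build_consensus(collection)))


@dataclass
class JackknifeReport:
    """Leave-one-out effect of each alphabet on the consensus tree."""

    rows: list[tuple[str, float]]
    convention: str  # "sqrt" or "squared" branch-score variant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["dropped_id", "branch_score_distance"])

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# branch score convention: {self.convention}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def jackknife_consensus(
    collection: AlphabetCollection, *, squared: bool = False
) -> JackknifeReport:
    """Drop each alphabet in turn, rebuild the consensus tree, and score the
    branch score distance to the full-collection tree."""
    if len(collection) < 2:
        raise ValueError("need at least 2 alphabets to jack-knife")
    full = consensus_tree(collection)
    rows = []
    for aid in collection.ids:
        sub_tree = consensus_tree(collection.drop(aid))
        rows.append((aid, branch_score_distance(full, sub_tree, squared=squared)))
    return JackknifeReport(rows=rows, convention="squared" if squared else "sqrt")


# ---------------------------------------------------------------------------
# hierarchical simplification


def agglomerate_alphabet(
    m: ConsensusSimilarityMatrix, k: int, *, aid: str | None = None
) -> SimplifiedAlphabet:
    """Cut an average-linkage hierarchy of the consensus distances at *k*
    clusters, yielding one simplified alphabet per requested size (2..19 in
    the usual sweep; 1 and 20 are the degenerate ends)."""
    if not 1 <= k <= 20:
        raise ValueError(f"k must be in 1..20, got {k}")
    dist = similarity_to_distance(m).values
    z = linkage(squareform(dist, checks=False), method="average")
    labels = cut_tree(z, n_clusters=k).ravel()
    groups = tuple(
        frozenset(AMINO_ACIDS[i] for i in np.flatnonzero(labels == g))
        for g in np.unique(labels)
    )
    return SimplifiedAlphabet(
        id=aid or f"agglom_k{k}",
        name=f"average-linkage consensus cut at k={k}",
        category="other",
        groups=groups,
    )
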