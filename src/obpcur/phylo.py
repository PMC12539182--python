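"""Distance-based phylogenetics: alignment distances, neighbor-joining,
and clade queries used by consolidation and naming.

Distances come from pairwise global alignments (p-distance over aligned
non-gap columns, optional Poisson correction) rather than a multiple
alignment; the downstream clade queries need only topology and path
lengths.  Neighbor-joining is the Saitou–Nei agglomeration on the
Q-criterion with an explicit deterministic tie-break (minimal (i, j) index
pair in creation order) and branch lengths clamped at zero.  No support
values are computed or represented.
"""

from __future__ import annotations

import io
import math
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .homology import DEFAULT_SCHEME, ScoringScheme, _aligner
from .seqio import SequenceRecord

#: distance reported when the Poisson correction diverges (p == 1)
MAX_DISTANCE = 10.0


def pairwise_distance(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                      correction: Optional[str] = None,
                      max_distance: float = MAX_DISTANCE) -> float:
    """Distance between two proteins from one global alignment.

    p = 1 - identities / aligned non-gap columns; ``correction="poisson"``
    applies -ln(1 - p), saturating at ``max_distance`` when p -> 1.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 0.0
    aln = _aligner(scheme, "global").align(a, b)[0]
    qb, sb = aln.aligned
    identities = aligned = 0
    for (qa, qz), (sa, sz) in zip(qb, sb):
        aligned += qz - qa
        identities += sum(x == y for x, y in zip(a[qa:qz], b[sa:sz]))
    if aligned == 0:
        p = 1.0
    else:
        p = 1.0 - identities / aligned
    if correction is None:
        return p
    if correction != "poisson":
        raise ValueError(f"unknown correction {correction!r}")
    if p >= 1.0:
        return max_distance
    return min(-math.log(1.0 - p), max_distance)


def distance_matrix(records: Sequence[SequenceRecord],
                    scheme: ScoringScheme = DEFAULT_SCHEME,
                    correction: Optional[str] = None) -> DistanceMatrix:
    """Symmetric distance matrix over records (ids must be unique)."""
    ids = [r.id for r in records]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(
                records[i].seq, records[j].seq, scheme, correction)
    return DistanceMatrix(d, ids)


def nj(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; returned as a trifurcating root).

    Deterministic: the joined pair minimizes Q, ties broken by the minimal
    (i, j) pair in index order (input label order, then creation order of
    internal nodes).  Negative branch lengths are clamped to 0.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 labels")
    size = 2 * n  # enough room for all internal nodes
    D = np.zeros((size, size))
    D[:n, :n] = dm.data
    nodes: dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best_q, best = None, None
        for ai in range(m):
            i = active[ai]
            for j in active[ai + 1:]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best_q is None or q < best_q:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        ni, njn = nodes.pop(i), nodes.pop(j)
        ni.length, njn.length = max(li, 0.0), max(lj, 0.0)
        u = TreeNode(children=[ni, njn])
        for k in active:
            if k in (i, j):
                continue
            D[nxt, k] = D[k, nxt] = max(0.5 * (D[i, k] + D[j, k] - D[i, j]), 0.0)
        nodes[nxt] = u
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def nearest_reference(tree: TreeNode, query_leaf: str,
                      reference_ids: Sequence[str]) -> str:
    """Reference leaf with the smallest path length (sum of branch lengths)
    to the query leaf; ties broken lexicographically."""
    if not reference_ids:
        raise ValueError("reference set is empty")
    try:
        q = tree.find(query_leaf)
    except Exception as exc:
        raise ValueError(f"leaf {query_leaf!r} not in tree") from exc
    best = None
    for rid in sorted(reference_ids):
        try:
            node = tree.find(rid)
        except Exception as exc:
            raise ValueError(f"reference leaf {rid!r} not in tree") from exc
        d = q.distance(node)
        if best is None or d < best[0]:
            best = (d, rid)
    return best[1]


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path_or_handle) -> TreeNode:
    """Read newick; internal support-value labels are accepted and ignored
    for all path-length computations."""
    if isinstance(path_or_handle, (str,)) and "(" in path_or_handle:
        return TreeNode.read(io.StringIO(path_or_handle), format="newick")
    return TreeNode.read(str(path_or_handle), format="newick")


def tree_tip_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length distance matrix between all tips."""
    return tree.tip_tip_distances()
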