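"""Distance-based tree reconstruction and monophyly scoring.

Tree reconstruction per simulated alignment uses neighbor joining on
Kimura two-parameter distances.  At the divergences relevant here (1-3%)
the group-monophyly question is driven by the signal in the data rather
than by the estimator, which makes tens of thousands of replicate
reconstructions desk-scale.  An external tree (Newick) can be supplied
instead via :func:`tree_from_newick` for users who want ML parity.

Monophyly of a tip set is evaluated on the unrooted topology: the set is
monophyletic iff some edge induces exactly the bipartition (set | rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seq_io import Alignment

logger = logging.getLogger(__name__)

__all__ = [
    "UnrootedTree",
    "k2p_distance",
    "neighbor_joining",
    "is_monophyletic",
    "monophyly_edge_length",
    "tree_from_newick",
]

#: distance assigned to saturated pairs (K2P log argument <= 0)
SATURATION_CAP = 5.0


@dataclass(frozen=True)
class UnrootedTree:
    """Unrooted tree stored as its edge bipartitions.

    ``labels`` fixes a tip order; each edge is a (bitmask, length) pair
    where the bitmask selects the tips on one side of the edge.  Tip
    (pendant) edges have masks of popcount 1.  ``newick`` is a string
    rendering rooted arbitrarily at the last join.
    """

    labels: tuple[str, ...]
    edges: tuple[tuple[int, float], ...]
    newick: str

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def _mask_of(self, tips) -> int:
        index = {lab: i for i, lab in enumerate(self.labels)}
        mask = 0
        for t in tips:
            if t not in index:
                raise KeyError(f"unknown tip label {t!r}")
            mask |= 1 << index[t]
        return mask


def k2p_distance(aln: Alignment) -> np.ndarray:
    """Pairwise Kimura two-parameter distance matrix.

    d = -0.5 ln(1-2P-Q) - 0.25 ln(1-2Q), with P and Q the transition and
    transversion proportions over pairwise-complete (non-gap, non-N) sites.
    Saturated pairs (non-positive log argument) receive SATURATION_CAP with
    a warning.
    """
    if aln.n < 2:
        raise ValueError("need >= 2 sequences")
    codes = aln.codes()
    n, L = codes.shape
    valid = codes < 4
    # pairwise complete-site counts
    ok = valid[:, None, :] & valid[None, :, :]
    m = ok.sum(axis=2)
    if np.any((m == 0) & ~np.eye(n, dtype=bool)):
        raise ValueError("a sequence pair shares no comparable sites")
    a = codes[:, None, :]
    b = codes[None, :, :]
    diff = (a != b) & ok
    ts = diff & ((a >> 1) == (b >> 1))  # A<->G (0,1) and C<->T (2,3)
    P = ts.sum(axis=2) / m
    Q = (diff.sum(axis=2) / m) - P
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    sat = (w1 <= 0) | (w2 <= 0)
    if sat.any():
        logger.warning("capping %d saturated K2P pair(s)", int(sat.sum() // 2))
        d[sat] = SATURATION_CAP
    np.fill_diagonal(d, 0.0)
    return d


def neighbor_joining(
    dist: np.ndarray, labels: tuple[str, ...] | None = None
) -> UnrootedTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties are broken by the lowest index pair (row-major argmin).  Negative
    branch lengths are floored at zero with the excess transferred to the
    sister branch, preserving path lengths through the joined pair.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with n >= 3")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if labels is None:
        labels = tuple(f"t{i}" for i in range(n))
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    masks = [1 << i for i in range(n)]
    newicks = [lab for lab in labels]
    edges: list[tuple[int, float]] = []
    D = D.copy()
    active = list(range(n))  # indices into D rows

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # floor negatives, transfer excess to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ai, aj = active[i], active[j]
        # new node distances (reduction formula)
        dnew = 0.5 * (D[ai, active] + D[aj, active] - dij)
        new_idx = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_idx, active] = dnew
        D[active, new_idx] = dnew
        D[new_idx, new_idx] = 0.0
        edges.append((masks[ai], li))
        edges.append((masks[aj], lj))
        masks.append(masks[ai] | masks[aj])
        newicks.append(f"({newicks[ai]}:{li:.10g},{newicks[aj]}:{lj:.10g})")
        active.pop(j)
        active.pop(i)
        active.append(new_idx)

    ai, aj = active
    dij = max(D[ai, aj], 0.0)
    edges.append((masks[ai], dij))
    newick = f"({newicks[ai]}:{dij:.10g},{newicks[aj]}:0):0;"
    return UnrootedTree(tuple(labels), tuple(edges), newick)


def _bipartition_length(tree: UnrootedTree, mask: int) -> float | None:
    full = (1 << tree.n_tips) - 1
    comp = mask ^ full
    best = None
    for emask, elen in tree.edges:
        if emask == mask or emask == comp:
            best = elen if best is None else max(best, elen)
    return best


def monophyly_edge_length(tree: UnrootedTree, tips) -> float | None:
    """Length of the edge separating ``tips`` from the rest, or None.

    None means no edge induces the bipartition (the set is not
    monophyletic on the unrooted topology).
    """
    mask = tree._mask_of(tips)
    if mask == 0 or mask == (1 << tree.n_tips) - 1:
        raise ValueError("tip set must be a proper non-empty subset")
    if mask.bit_count() == 1:
        # a single tip is trivially monophyletic; report its pendant edge
        length = _bipartition_length(tree, mask)
        return length if length is not None else 0.0
    return _bipartition_length(tree, mask)


def is_monophyletic(tree: UnrootedTree, tips) -> bool:
    """True iff some edge induces exactly the bipartition (tips | rest)."""
    return monophyly_edge_length(tree, tips) is not None


def tree_from_newick(newick: str) -> UnrootedTree:
    """Parse an externally reconstructed tree (e.g. an ML tree) from Newick.

    The tree is interpreted as unrooted: every internal branch contributes
    one bipartition.  Branch lengths default to 1 when absent so that the
    zero-length-edge rule is not triggered by absent annotations.
    """
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    labels = tuple(
        leaf.taxon.label.replace(" ", "_") for leaf in t.leaf_node_iter()
    )
    index = {lab: i for i, lab in enumerate(labels)}
    edges = []

    def mask_of(node) -> int:
        m = 0
        for leaf in node.leaf_iter():
            m |= 1 << index[leaf.taxon.label.replace(" ", "_")]
        return m

    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length if node.edge.length is not None else 1.0
        edges.append((mask_of(node), float(length)))
    return UnrootedTree(labels, tuple(edges), newick.strip())
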