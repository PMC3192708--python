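"""Between-group divergence and polymorphism partitioning.

Dxy is the mean per-site divergence over all between-group sequence pairs;
Da subtracts the average within-group diversity (net divergence).  Each
polymorphic site over the pooled pair of groups is classified as a fixed
difference, an exclusive polymorphism of one group, or a shared
polymorphism.  All quantities use the net sites of the *union* of the two
groups (complete deletion over both), so the within-group pi entering Da is
recomputed on that same mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popstats import InsufficientDataError, nucleotide_diversity, _allele_counts
from .seq_io import Alignment, GroupMap, apply_mask, net_site_mask, subset

__all__ = ["DivergenceStats", "dxy_da", "polymorphism_partition", "divergence_stats"]


@dataclass(frozen=True)
class DivergenceStats:
    """Pairwise between-group divergence summary (one table row)."""

    n1: int
    n2: int
    L_net: int
    avg_diff: float
    dxy_pct: float
    da_pct: float
    fixed: int
    excl1: int
    excl2: int
    shared: int


def _union_net(a1: Alignment, a2: Alignment) -> tuple[Alignment, Alignment]:
    """Restrict both groups to the net sites of their union."""
    if a1.length != a2.length:
        raise ValueError("groups must come from the same alignment columns")
    mask = net_site_mask(a1) & net_site_mask(a2)
    return apply_mask(a1, mask), apply_mask(a2, mask)


def dxy_da(a1: Alignment, a2: Alignment) -> tuple[float, float, float]:
    """Return (avg_diff, dxy_pct, da_pct) on the union's net sites.

    avg_diff is the mean difference count over all between-group pairs;
    dxy_pct = 100*avg_diff/L_net; da_pct = dxy_pct - (pi1 + pi2)/2.
    """
    if a1.n < 1 or a2.n < 1:
        raise InsufficientDataError("both groups must be non-empty")
    m1, m2 = _union_net(a1, a2)
    c1, c2 = m1.codes(), m2.codes()
    L = c1.shape[1]
    # between-group difference counts per site via allele count products
    n1cnt = _allele_counts(c1).astype(float)
    n2cnt = _allele_counts(c2).astype(float)
    same = (n1cnt * n2cnt).sum(axis=0)
    total_pairs = a1.n * a2.n
    avg_diff = float((total_pairs - same).sum()) / total_pairs
    dxy_pct = 100.0 * avg_diff / L
    if a1.n >= 2 and a2.n >= 2:
        pi1, _ = nucleotide_diversity(m1)
        pi2, _ = nucleotide_diversity(m2)
        da_pct = dxy_pct - (pi1 + pi2) / 2.0
    else:
        raise InsufficientDataError("Da needs >= 2 sequences in each group")
    return avg_diff, dxy_pct, da_pct


def polymorphism_partition(
    a1: Alignment, a2: Alignment
) -> tuple[int, int, int, int]:
    """Classify each union net site: (fixed, excl1, excl2, shared).

    fixed: the two groups share no allele; exclusive: polymorphic in one
    group only (the other monomorphic); shared: polymorphic in both.
    """
    m1, m2 = _union_net(a1, a2)
    p1 = _allele_counts(m1.codes()) > 0
    p2 = _allele_counts(m2.codes()) > 0
    na1 = p1.sum(axis=0)
    na2 = p2.sum(axis=0)
    overlap = (p1 & p2).any(axis=0)
    fixed = int((~overlap).sum())
    poly1, poly2 = na1 > 1, na2 > 1
    excl1 = int((poly1 & ~poly2).sum())
    excl2 = int((poly2 & ~poly1).sum())
    shared = int((poly1 & poly2).sum())
    return fixed, excl1, excl2, shared


def divergence_stats(
    aln: Alignment, gm: GroupMap, label1: str, label2: str
) -> DivergenceStats:
    """Full divergence summary between two labelled groups of one alignment."""
    a1 = subset(aln, gm, label1)
    a2 = subset(aln, gm, label2)
    m1, m2 = _union_net(a1, a2)
    avg_diff, dxy_pct, da_pct = dxy_da(a1, a2)
    fixed, excl1, excl2, shared = polymorphism_partition(a1, a2)
    return DivergenceStats(
        n1=a1.n, n2=a2.n, L_net=m1.length,
        avg_diff=avg_diff, dxy_pct=dxy_pct, da_pct=da_pct,
        fixed=fixed, excl1=excl1, excl2=excl2, shared=shared,
    )
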