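"""Within-group diversity, neutrality tests and recombination tests.

Implements the classical summary statistics for a single locus/group:

* nucleotide diversity pi and the mean pairwise difference count k,
* Watterson's theta from the number of segregating sites S,
* Tajima's D, Fu's Fs and the Ramos-Onsins & Rozas R2 neutrality tests,
* the Hudson & Kaplan four-gamete minimum recombination count Rm,
* a windowed pairwise-homoplasy (PHI) permutation test for recombination,
* empirical p-values for D, Fs and R2 against a neutral, constant-size
  coalescent null conditioned on the observed S (fixed-S mutation scheme).

pi and theta are reported as percent per net site, matching the convention
of standard polymorphism tables.  Statistics that are undefined for the
input (e.g. S = 0) are returned as NaN, never as zero.

Tail conventions for the coalescent-null p-values: Tajima's D is two-tailed;
Fu's Fs and R2 are lower-tailed (small values are the departure of interest
under population growth or a sweep).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seq_io import Alignment, GroupMap, apply_mask, net_site_mask, subset

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "InsufficientDataError",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "fus_fs",
    "ewens_log_pmf",
    "r2_statistic",
    "segregating_sites",
    "haplotype_count",
    "min_recombination_events",
    "phi_test",
    "neutral_null_pvalue",
    "sample_fixed_s",
    "summarize",
    "summarize_groups",
]


class InsufficientDataError(ValueError):
    """Raised when a statistic is requested for too few sequences."""


@dataclass(frozen=True)
class SummaryStats:
    """Per-locus, per-group polymorphism summary (one table row)."""

    n: int
    L_total: int
    L_net: int
    S: int
    H: int
    pi_pct: float
    theta_pct: float
    k: float
    tajima_D: float
    fu_Fs: float
    r2: float
    rm: int
    phi_obs: float
    phi_p: float
    p_D: float
    p_Fs: float
    p_r2: float


# ---------------------------------------------------------------------------
# harmonic sums
# ---------------------------------------------------------------------------

def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def _a2(n: int) -> float:
    return sum(1.0 / (i * i) for i in range(1, n))


# ---------------------------------------------------------------------------
# site bookkeeping
# ---------------------------------------------------------------------------

def _allele_counts(codes: np.ndarray) -> np.ndarray:
    """(4, L) counts of A/G/C/T per column of a gap-free code matrix."""
    n, L = codes.shape
    counts = np.zeros((4, L), dtype=np.int64)
    for a in range(4):
        counts[a] = (codes == a).sum(axis=0)
    return counts


def segregating_sites(aln: Alignment) -> int:
    """Number of polymorphic columns on the alignment's net sites."""
    codes = apply_mask(aln, net_site_mask(aln)).codes()
    counts = _allele_counts(codes)
    return int(((counts > 0).sum(axis=0) > 1).sum())


def haplotype_count(aln: Alignment) -> int:
    """Distinct sequences after restriction to net sites."""
    net = apply_mask(aln, net_site_mask(aln))
    return len(set(net.seqs))


def nucleotide_diversity(aln: Alignment) -> tuple[float, float]:
    """Return (pi_pct, k) on net sites.

    k is the mean number of pairwise differences over all unordered
    sequence pairs; pi_pct = 100 * k / L_net.
    """
    if aln.n < 2:
        raise InsufficientDataError("nucleotide diversity needs >= 2 sequences")
    net = apply_mask(aln, net_site_mask(aln))
    codes = net.codes()
    n, L = codes.shape
    counts = _allele_counts(codes)
    npairs = n * (n - 1) // 2
    same = (counts * (counts - 1) // 2).sum(axis=0)
    diffs_per_site = npairs - same
    k = float(diffs_per_site.sum()) / npairs
    return 100.0 * k / L, k


def watterson_theta(n: int, S: int, L_net: int) -> float:
    """Watterson's theta as percent per net site: 100*S/(a1*L_net)."""
    if n < 2 or L_net < 1 or S < 0:
        raise ValueError("need n >= 2, L_net >= 1, S >= 0")
    if S == 0:
        return 0.0
    return 100.0 * S / (_a1(n) * L_net)


# ---------------------------------------------------------------------------
# neutrality statistics
# ---------------------------------------------------------------------------

def tajimas_d(n: int, S: int, k: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise k.

    Returns NaN when S = 0 (the statistic is undefined, not zero).
    """
    if n < 4:
        raise InsufficientDataError("Tajima's D needs n >= 4")
    if S == 0:
        return math.nan
    a1, a2 = _a1(n), _a2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = j) for j = 1..n alleles under the Ewens sampling formula.

    Uses the unsigned-Stirling-number recurrence in log space so that
    n around 100 is exact to machine precision without overflow.
    Index 0 of the returned array corresponds to j = 1.
    """
    if n < 1 or theta <= 0:
        raise ValueError("need n >= 1 and theta > 0")
    # log |S_n^j| by the recurrence |S_m^j| = |S_{m-1}^{j-1}| + (m-1)|S_{m-1}^j|
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S_0^0| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = np.logaddexp(
            row[0:m], math.log(m - 1) + row[1 : m + 1] if m > 1 else -np.inf
        )
        row = new
    log_denom = sum(math.log(theta + i) for i in range(n))
    j = np.arange(1, n + 1)
    return row[1:] + j * math.log(theta) - log_denom


def fus_fs(n: int, H: int, k: float) -> float:
    """Fu's Fs from sample size, haplotype count and mean pairwise k.

    S' = P(K >= H) under the Ewens sampling formula with theta-hat = k;
    Fs = ln(S'/(1-S')).  Returns NaN when H = 1 or k = 0 (undefined) and a
    signed infinity, with a warning, when S' underflows to 0 or 1.
    """
    if n < 2 or not (1 <= H <= n):
        raise ValueError("need n >= 2 and 1 <= H <= n")
    if H == 1 or k <= 0:
        return math.nan
    logp = ewens_log_pmf(n, k)
    log_sp = float(np.logaddexp.reduce(logp[H - 1 :]))
    log_1m = float(np.logaddexp.reduce(logp[: H - 1])) if H > 1 else -np.inf
    if log_sp == -np.inf or log_1m == -np.inf:
        logger.warning("Fu's Fs tail probability saturated (n=%d H=%d k=%g)", n, H, k)
        return math.inf if log_1m == -np.inf else -math.inf
    return log_sp - log_1m


def _singleton_counts(codes: np.ndarray) -> np.ndarray:
    """Per-sequence count of folded singletons (alleles of count 1)."""
    n, L = codes.shape
    counts = _allele_counts(codes)
    U = np.zeros(n, dtype=np.int64)
    for a in range(4):
        single = counts[a] == 1
        if single.any():
            U += ((codes == a) & single[None, :]).sum(axis=1)
    return U


def _r2_from_parts(n: int, S: int, k: float, U: np.ndarray) -> float:
    if S == 0:
        return math.nan
    return float(np.sqrt(np.mean((U - k / 2.0) ** 2)) / S)


def r2_statistic(aln: Alignment) -> float:
    """Ramos-Onsins & Rozas R2 on net sites.

    R2 = sqrt(mean_i (U_i - k/2)^2) / S where U_i is the number of folded
    singletons (minor-allele count 1) carried by sequence i.  NaN if S = 0.
    """
    if aln.n < 2:
        raise InsufficientDataError("R2 needs >= 2 sequences")
    net = apply_mask(aln, net_site_mask(aln))
    codes = net.codes()
    S = segregating_sites(aln)
    _, k = nucleotide_diversity(aln)
    return _r2_from_parts(net.codes().shape[0], S, k, _singleton_counts(codes))


# ---------------------------------------------------------------------------
# recombination: four-gamete Rm and the PHI permutation test
# ---------------------------------------------------------------------------

def _biallelic_partitions(aln: Alignment) -> tuple[list[int], list[int]]:
    """Bit-mask partitions and column positions of biallelic net sites.

    Sites with more than two alleles are skipped with a warning (rare in
    these data; the four-gamete test is defined for two alleles).
    """
    net = apply_mask(aln, net_site_mask(aln))
    codes = net.codes()
    n, L = codes.shape
    masks, positions = [], []
    skipped = 0
    for j in range(L):
        col = codes[:, j]
        alleles = np.unique(col)
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            skipped += 1
            continue
        mask = 0
        for i in np.nonzero(col == alleles[0])[0]:
            mask |= 1 << int(i)
        masks.append(mask)
        positions.append(j)
    if skipped:
        logger.warning("skipped %d site(s) with >2 alleles", skipped)
    return masks, positions


def _four_gamete(mask_i: int, mask_j: int, full: int) -> bool:
    return (
        (mask_i & mask_j) != 0
        and (mask_i & ~mask_j & full) != 0
        and (~mask_i & mask_j & full) != 0
        and (~mask_i & ~mask_j & full) != 0
    )


def min_recombination_events(aln: Alignment) -> int:
    """Hudson & Kaplan (1985) minimum number of recombination events Rm.

    Site pairs showing all four gametes delimit intervals that must contain
    a recombination event; Rm is the maximum number of pairwise-disjoint
    such (open) intervals, found by the standard greedy right-endpoint scan.
    """
    masks, positions = _biallelic_partitions(aln)
    full = (1 << aln.n) - 1
    intervals = []
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            if _four_gamete(masks[a], masks[b], full):
                intervals.append((positions[a], positions[b]))
    if not intervals:
        return 0
    intervals.sort(key=lambda iv: iv[1])
    rm = 0
    last_right = -1
    for left, right in intervals:
        if left >= last_right:  # open intervals (l,r): disjoint when l >= prev r
            rm += 1
            last_right = right
    return rm


def _informative_masks(aln: Alignment) -> list[int]:
    """Parsimony-informative biallelic sites (both alleles count >= 2)."""
    masks, _ = _biallelic_partitions(aln)
    n = aln.n
    out = []
    for m in masks:
        c = m.bit_count()
        if 2 <= c <= n - 2:
            out.append(m)
    return out


def phi_test(
    aln: Alignment,
    window: int = 100,
    permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pairwise homoplasy index (PHI) permutation test for recombination.

    PHI is the mean four-gamete incompatibility over pairs of
    parsimony-informative biallelic sites whose rank distance (among
    informative sites) is at most ``window``.  The p-value is the
    permutation probability of a PHI at most as small as observed:
    p = (#{perm PHI <= obs} + 1)/(permutations + 1).  Returns
    (NaN, NaN) when fewer than two informative sites exist.
    """
    masks = _informative_masks(aln)
    m = len(masks)
    if m < 2:
        logger.info("PHI test undefined: fewer than 2 informative sites")
        return math.nan, math.nan
    full = (1 << aln.n) - 1
    incompat = np.zeros((m, m), dtype=float)
    for a in range(m):
        for b in range(a + 1, m):
            if _four_gamete(masks[a], masks[b], full):
                incompat[a, b] = incompat[b, a] = 1.0
    # pairs at rank distance <= window under a given ordering
    pair_mask = np.zeros((m, m), dtype=bool)
    for a in range(m):
        pair_mask[a, a + 1 : min(m, a + window + 1)] = True

    def phi_of(order: np.ndarray) -> float:
        return float(incompat[np.ix_(order, order)][pair_mask].mean())

    identity = np.arange(m)
    phi_obs = phi_of(identity)
    rng = np.random.default_rng(seed)
    leq = 0
    for _ in range(permutations):
        perm = rng.permutation(m)
        if phi_of(perm) <= phi_obs + 1e-12:
            leq += 1
    p = (leq + 1) / (permutations + 1)
    return phi_obs, p


# ---------------------------------------------------------------------------
# coalescent null (fixed-S) for p-values
# ---------------------------------------------------------------------------

def sample_fixed_s(
    n: int, S: int, rng: np.random.Generator
) -> tuple[float, int, np.ndarray]:
    """One neutral constant-size coalescent draw conditioned on S mutations.

    Simulates a Kingman genealogy of ``n`` tips, places exactly ``S``
    mutations uniformly on total branch length (infinite sites), and
    returns (k, H, U): mean pairwise differences, haplotype count, and the
    per-sequence folded singleton counts.
    """
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    active = [1 << i for i in range(n)]
    seg_masks: list[int] = []
    seg_len: list[float] = []
    k_lin = n
    while k_lin > 1:
        t = rng.exponential(2.0 / (k_lin * (k_lin - 1)))
        for msk in active:
            seg_masks.append(msk)
            seg_len.append(t)
        i = int(rng.integers(k_lin))
        j = int(rng.integers(k_lin - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        active[i] |= active[j]
        active.pop(j)
        k_lin -= 1
    lengths = np.asarray(seg_len)
    probs = lengths / lengths.sum()
    chosen = rng.choice(len(seg_masks), size=S, p=probs)
    mut_masks = [seg_masks[int(c)] for c in chosen]

    npairs = n * (n - 1) / 2.0
    k_sum = 0.0
    U = np.zeros(n, dtype=np.int64)
    for msk in mut_masks:
        c = msk.bit_count()
        k_sum += c * (n - c)
        if c == 1:
            U[msk.bit_length() - 1] += 1
        elif c == n - 1:
            U[(msk ^ ((1 << n) - 1)).bit_length() - 1] += 1
    k = k_sum / npairs
    # haplotypes: signature of carried mutations per tip
    sigs = set()
    for i in range(n):
        bit = 1 << i
        sigs.add(tuple(bool(msk & bit) for msk in mut_masks))
    return k, len(sigs), U


def neutral_null_pvalue(
    stat_name: str,
    observed: float,
    n: int,
    S: int,
    reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Empirical p-value against the neutral equilibrium coalescent null.

    ``stat_name`` is one of 'D' (two-tailed), 'Fs' or 'R2' (lower-tailed).
    The null distribution is generated from ``reps`` genealogies with
    exactly S mutations each.  NaN observed gives NaN.
    """
    if stat_name not in {"D", "Fs", "R2"}:
        raise ValueError(f"unknown statistic {stat_name!r}")
    if reps < 100:
        raise ValueError("need reps >= 100")
    if math.isnan(observed) or S == 0:
        return math.nan
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        k, H, U = sample_fixed_s(n, S, rng)
        if stat_name == "D":
            null[r] = tajimas_d(n, S, k)
        elif stat_name == "Fs":
            null[r] = fus_fs(n, H, k) if k > 0 and H > 1 else 0.0
        else:
            null[r] = _r2_from_parts(n, S, k, U)
    null = null[~np.isnan(null)]
    reps_eff = len(null)
    if reps_eff == 0:
        return math.nan
    lo = (np.sum(null <= observed) + 1) / (reps_eff + 1)
    if stat_name == "D":
        hi = (np.sum(null >= observed) + 1) / (reps_eff + 1)
        return float(min(1.0, 2.0 * min(lo, hi)))
    return float(min(1.0, lo))


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def summarize(
    aln: Alignment,
    *,
    null_reps: int = 0,
    phi_window: int = 100,
    phi_permutations: int = 1000,
    seed: int | None = None,
) -> SummaryStats:
    """All per-group statistics for one alignment (one table row).

    ``null_reps`` = 0 skips the coalescent-null p-values (NaN); the PHI test
    is skipped the same way when ``phi_permutations`` = 0.
    """
    net = net_site_mask(aln)
    L_net = int(net.sum())
    S = segregating_sites(aln)
    H = haplotype_count(aln)
    pi_pct, k = nucleotide_diversity(aln)
    theta_pct = watterson_theta(aln.n, S, L_net)
    D = tajimas_d(aln.n, S, k) if aln.n >= 4 else math.nan
    Fs = fus_fs(aln.n, H, k)
    r2 = r2_statistic(aln)
    rm = min_recombination_events(aln)
    if phi_permutations > 0:
        phi_obs, phi_p = phi_test(
            aln, window=phi_window, permutations=phi_permutations, seed=seed
        )
    else:
        phi_obs, phi_p = math.nan, math.nan
    if null_reps > 0:
        ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
        s_d, s_fs, s_r2 = ss.spawn(3)
        p_D = neutral_null_pvalue("D", D, aln.n, S, null_reps, s_d.generate_state(1)[0] % (2**31))
        p_Fs = neutral_null_pvalue("Fs", Fs, aln.n, S, null_reps, s_fs.generate_state(1)[0] % (2**31))
        p_r2 = neutral_null_pvalue("R2", r2, aln.n, S, null_reps, s_r2.generate_state(1)[0] % (2**31))
    else:
        p_D = p_Fs = p_r2 = math.nan
    return SummaryStats(
        n=aln.n, L_total=aln.length, L_net=L_net, S=S, H=H,
        pi_pct=pi_pct, theta_pct=theta_pct, k=k,
        tajima_D=D, fu_Fs=Fs, r2=r2, rm=rm,
        phi_obs=phi_obs, phi_p=phi_p, p_D=p_D, p_Fs=p_Fs, p_r2=p_r2,
    )


def summarize_groups(
    aln: Alignment,
    gm: GroupMap,
    labels: Sequence[str] | None = None,
    **kwargs,
):
    """One SummaryStats row per group label; returns a pandas DataFrame."""
    import pandas as pd

    if labels is None:
        labels = gm.labels()
    rows = []
    for label in labels:
        sub = subset(aln, gm, label)
        stats = summarize(sub, **kwargs)
        row = {"group": label, **stats.__dict__}
        rows.append(row)
    return pd.DataFrame(rows)
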