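import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from cytodiscord import (
    fus_fs,
    min_recombination_events,
    neutral_null_pvalue,
    nucleotide_diversity,
    phi_test,
    r2_statistic,
    tajimas_d,
    watterson_theta,
)
from cytodiscord.popstats import (
    InsufficientDataError,
    ewens_log_pmf,
    haplotype_count,
    sample_fixed_s,
    segregating_sites,
    summarize,
)
from conftest import aln, random_aln


# -- independent oracles -----------------------------------------------------

def naive_pairwise_k(a):
    """Exhaustive enumeration over all unordered sequence pairs."""
    diffs = [
        sum(x != y for x, y in zip(s1, s2))
        for s1, s2 in itertools.combinations(a.seqs, 2)
    ]
    return sum(diffs) / len(diffs)


def exact_stirling(n):
    """Unsigned Stirling numbers of the first kind, exact integers."""
    row = [1]  # |S_0^0|
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for j in range(1, m + 1):
            new[j] = (row[j - 1] if j - 1 < len(row) else 0) + (m - 1) * (
                row[j] if j < len(row) else 0
            )
        row = new
    return row  # row[j] = |S_n^j|


def exact_ewens_pmf(n, theta):
    stir = exact_stirling(n)
    weights = [stir[j] * theta**j for j in range(1, n + 1)]
    total = sum(weights)
    return [w / total for w in weights]


class TestDiversity:
    def test_identical_pair_is_zero(self):
        assert nucleotide_diversity(aln("ACGT" * 25, "ACGT" * 25)) == (0.0, 0.0)

    def test_one_diff_in_100_sites(self):
        s = "A" * 100
        t = "A" * 99 + "T"
        pi, k = nucleotide_diversity(aln(s, t))
        assert pi == pytest.approx(1.0) and k == pytest.approx(1.0)

    def test_matches_exhaustive_pair_enumeration(self, rng):
        for _ in range(10):
            a = random_aln(rng, 4, 30, alleles=4)
            _, k = nucleotide_diversity(a)
            assert k == pytest.approx(naive_pairwise_k(a))

    def test_needs_two_sequences(self):
        with pytest.raises(InsufficientDataError):
            nucleotide_diversity(aln("ACGT"))

    def test_computed_on_net_sites(self):
        # the gapped column must not contribute
        a = aln("A-AAA", "ATAAC")
        pi, k = nucleotide_diversity(a)
        assert k == 1.0 and pi == pytest.approx(25.0)


class TestWattersonTheta:
    def test_zero_segregating_sites(self):
        assert watterson_theta(10, 0, 100) == 0.0

    def test_consistency_with_direct_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 120))
            S = int(rng.integers(0, 60))
            L = int(rng.integers(100, 1000))
            a1 = sum(1.0 / i for i in range(1, n))
            expect = 100.0 * S / (a1 * L) if S else 0.0
            assert watterson_theta(n, S, L) == pytest.approx(expect, rel=1e-12)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson_expectation(self):
        n, S = 20, 9
        a1 = sum(1.0 / i for i in range(1, n))
        assert tajimas_d(n, S, S / a1) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_for_no_variation(self):
        assert math.isnan(tajimas_d(10, 0, 0.0))

    def test_matches_independent_naive_implementation(self, rng):
        def naive_d(n, S, k):
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            var = (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
            return (k - S / a1) / math.sqrt(var)

        for _ in range(100):
            n = int(rng.integers(4, 100))
            S = int(rng.integers(1, 50))
            k = float(rng.uniform(0, 2 * S))
            assert tajimas_d(n, S, k) == pytest.approx(naive_d(n, S, k), rel=1e-12)


class TestFusFs:
    def test_ewens_probabilities_sum_to_one_exactly(self):
        for n in range(2, 13):
            for theta in (0.3, 1.0, 4.2):
                p = np.exp(ewens_log_pmf(n, theta))
                assert abs(p.sum() - 1.0) < 1e-10
                assert np.allclose(p, exact_ewens_pmf(n, theta), atol=1e-10)

    def test_small_case_against_exact_enumeration(self):
        # n=5, H=3, theta-hat=1: S' = P(K>=3) from exact Stirling numbers
        pmf = exact_ewens_pmf(5, 1.0)
        sp = sum(pmf[2:])
        expect = math.log(sp / (1 - sp))
        assert fus_fs(5, 3, 1.0) == pytest.approx(expect, rel=1e-10)

    def test_undefined_markers(self):
        assert math.isnan(fus_fs(10, 1, 1.0))
        assert math.isnan(fus_fs(10, 4, 0.0))

    def test_many_haplotypes_drive_fs_negative(self):
        # H = n with large theta: monotone toward -infinity direction
        vals = [fus_fs(12, 12, th) for th in (5.0, 2.0, 1.0)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < -5


class TestR2:
    def test_hand_computed_three_sequence_case(self):
        # sites: one singleton in s1, one in s2; k = 4/3, U = (0,1,1), S = 2
        a = aln("AAAA", "AAAT", "AATA")
        expect = math.sqrt(((0 - 2 / 3) ** 2 + 2 * (1 - 2 / 3) ** 2) / 3) / 2
        assert r2_statistic(a) == pytest.approx(expect, rel=1e-12)

    def test_matches_brute_force_singleton_tally(self, rng):
        for _ in range(10):
            a = random_aln(rng, 5, 40)
            n, L = 5, 40
            U = [0] * n
            S = 0
            for j in range(L):
                col = [s[j] for s in a.seqs]
                counts = {b: col.count(b) for b in set(col)}
                if len(counts) > 1:
                    S += 1
                for i, b in enumerate(col):
                    if counts[b] == 1:
                        U[i] += 1
            k = naive_pairwise_k(a)
            if S == 0:
                assert math.isnan(r2_statistic(a))
            else:
                expect = math.sqrt(
                    sum((u - k / 2) ** 2 for u in U) / n
                ) / S
                assert r2_statistic(a) == pytest.approx(expect, rel=1e-12)

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(r2_statistic(aln("AAAA", "AAAA")))


class TestRm:
    def test_no_incompatible_pair(self):
        # sites nested: compatible under infinite sites
        a = aln("AATT", "AATA", "AAAA", "TTAA")
        assert min_recombination_events(aln("AAAA", "AATA", "AATT")) == 0

    def test_single_four_gamete_pair(self):
        a = aln("AA", "AT", "TA", "TT")
        assert min_recombination_events(a) == 1

    def test_overlapping_incompatible_pairs_count_once(self):
        # four sites, two partitions: incompatible pairs (0,2),(0,3),(1,2),
        # (1,3) all overlap in the region between sites 1 and 2 -> Rm = 1
        cols = ["AATT", "AATT", "ATAT", "ATAT"]
        seqs = ["".join(col[i] for col in cols) for i in range(4)]
        a = aln(*seqs)
        assert min_recombination_events(a) == 1

    def test_mutually_crossing_sites_need_two_events(self):
        # three pairwise-incompatible sites: intervals (0,1) and (1,2) are
        # disjoint, so at least two recombination events are required
        cols = ["AATT", "ATAT", "TAAT"]
        seqs = ["".join(col[i] for col in cols) for i in range(4)]
        assert min_recombination_events(aln(*seqs)) == 2

    def test_matches_exhaustive_disjoint_interval_oracle(self, rng):
        def oracle(a):
            from cytodiscord.popstats import _biallelic_partitions, _four_gamete

            masks, pos = _biallelic_partitions(a)
            full = (1 << a.n) - 1
            ivs = [
                (pos[i], pos[j])
                for i in range(len(masks))
                for j in range(i + 1, len(masks))
                if _four_gamete(masks[i], masks[j], full)
            ]
            best = 0
            for r in range(1, len(ivs) + 1):
                for sub in itertools.combinations(ivs, r):
                    ok = all(
                        b[0] >= a_[1] or a_[0] >= b[1]
                        for a_, b in itertools.combinations(sub, 2)
                    )
                    if ok:
                        best = max(best, r)
            return best

        for _ in range(15):
            a = random_aln(rng, 6, 10)
            assert min_recombination_events(a) == oracle(a)


class TestPhi:
    def test_all_compatible_gives_phi_zero_p_one(self):
        # two informative, mutually compatible sites
        a = aln("AATT", "AATT", "TTAA", "TTAA")
        phi, p = phi_test(a, permutations=100, seed=1)
        assert phi == 0.0 and p == 1.0

    def test_undefined_below_two_informative_sites(self):
        phi, p = phi_test(aln("AAAA", "AAAT", "AATA"))
        assert math.isnan(phi) and math.isnan(p)

    def test_deterministic_given_seed(self, rng):
        a = random_aln(rng, 8, 40)
        assert phi_test(a, window=3, permutations=200, seed=5) == phi_test(
            a, window=3, permutations=200, seed=5
        )


class TestNeutralNull:
    def test_fixed_s_sample_shapes(self, rng):
        k, H, U = sample_fixed_s(10, 5, rng)
        assert k > 0 and 1 <= H <= 10 and U.shape == (10,) and U.sum() <= 5

    def test_observed_at_median_is_not_significant(self):
        null = [sample_fixed_s(15, 6, np.random.default_rng(i))[0] for i in range(300)]
        n = 15
        med_k = float(np.median(null))
        d_med = tajimas_d(n, 6, med_k)
        p = neutral_null_pvalue("D", d_med, n, 6, reps=500, seed=3)
        assert p > 0.5

    def test_extreme_fs_saturates_lower_tail(self):
        p = neutral_null_pvalue("Fs", -50.0, 20, 8, reps=500, seed=4)
        assert p <= 1 / 500 + 1e-9

    def test_undefined_observed_gives_undefined_p(self):
        assert math.isnan(neutral_null_pvalue("D", math.nan, 10, 0, reps=100, seed=0))


class TestSummarize:
    def test_consistency_identity_k_pi(self, rng):
        a = random_aln(rng, 8, 60, alleles=3)
        st = summarize(a, phi_permutations=0)
        assert st.k == pytest.approx(st.pi_pct / 100.0 * st.L_net)
        assert 1 <= st.H <= st.n and 0 <= st.S <= st.L_net

    def test_haplotypes_collapse_on_net_sites(self):
        # rows differ only inside a gapped column -> one haplotype
        a = aln("AC-T", "ACGT", "ACGT")
        assert haplotype_count(a) == 1
        assert segregating_sites(a) == 0
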