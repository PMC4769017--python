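"""Tajima's D, the relative-rate test and their gap-handling modes.

The brute-force oracle below recomputes every quantity with plain Python
loops over pairs and columns, independently of the vectorized code paths.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from mapkscan import (
    Alignment,
    DegenerateStatisticError,
    chi2_upper_tail,
    filter_site_coverage,
    pairwise_differences,
    rel_rate_chi2,
    relative_rate_counts,
    relative_rate_test,
    segregating_sites,
    tajima_d,
    tajima_d_from_summary,
)

MISSING = set("-XBZ")


def oracle_tajima_d(aln: Alignment) -> float:
    """Plain-loop Tajima's D (pairwise deletion), straight from the formula."""
    seqs = aln.sequences
    m = len(seqs)
    s_count = 0
    for j in range(aln.n_sites):
        present = {s[j] for s in seqs} - MISSING
        if len(present) >= 2:
            s_count += 1
    total = 0
    pairs = 0
    for x, y in itertools.combinations(seqs, 2):
        comparable = diffs = 0
        for cx, cy in zip(x, y):
            if cx in MISSING or cy in MISSING:
                continue
            comparable += 1
            if cx != cy:
                diffs += 1
        if comparable > 0:
            total += diffs
            pairs += 1
    k_hat = total / pairs
    a1 = sum(1 / i for i in range(1, m))
    a2 = sum(1 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3 * (m - 1))
    b2 = 2 * (m * m + m + 3) / (9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - s_count / a1) / math.sqrt(
        e1 * s_count + e2 * s_count * (s_count - 1)
    )


def _random_alignment(rng, m, n, alphabet="ACDE-X"):
    return Alignment(
        tuple(
            (f"s{i}", "".join(rng.choice(list(alphabet), size=n)))
            for i in range(m)
        )
    )


class TestPairwiseDifferences:
    def test_identical_pair(self):
        aln = Alignment((("a", "ACD"), ("b", "ACD")))
        diffs, sites = pairwise_differences(aln)
        assert (diffs[0, 1], sites[0, 1]) == (0, 3)

    def test_single_difference(self):
        aln = Alignment((("a", "ACD"), ("b", "ACE")))
        diffs, sites = pairwise_differences(aln)
        assert (diffs[0, 1], sites[0, 1]) == (1, 3)

    def test_pairwise_deletion_skips_gapped_sites(self):
        aln = Alignment((("a", "A-D"), ("b", "ACD")))
        diffs, sites = pairwise_differences(aln)
        assert (diffs[0, 1], sites[0, 1]) == (0, 2)

    def test_complete_deletion_drops_column_for_all_pairs(self):
        aln = Alignment((("a", "AWD"), ("b", "AWE"), ("c", "A-E")))
        diffs, sites = pairwise_differences(aln, "complete_deletion")
        assert sites[0, 1] == 2
        assert diffs[0, 1] == 1  # only the D/E column survives and differs

    def test_ambiguity_codes_count_as_missing(self):
        aln = Alignment((("a", "AXD"), ("b", "ACD")))
        _, sites = pairwise_differences(aln)
        assert sites[0, 1] == 2


class TestSegregatingSites:
    def test_identical_sequences(self):
        aln = Alignment((("a", "ACD"), ("b", "ACD"), ("c", "ACD")))
        assert segregating_sites(aln) == (0, 3)

    def test_column_tally(self):
        aln = Alignment((("a", "AAA"), ("b", "AAC"), ("c", "ATG")))
        assert segregating_sites(aln) == (2, 3)

    def test_gap_only_variation_not_segregating(self):
        aln = Alignment((("a", "A"), ("b", "-"), ("c", "A")))
        assert segregating_sites(aln) == (0, 1)

    def test_complete_deletion_shrinks_denominator(self):
        aln = Alignment((("a", "ACD"), ("b", "A-E"), ("c", "ACD")))
        assert segregating_sites(aln, "complete_deletion") == (1, 2)


class TestTajimaD:
    def test_requires_four_sequences(self):
        aln = Alignment((("a", "ACD"), ("b", "ACE")))
        with pytest.raises(ValueError, match="at least 4"):
            tajima_d(aln)

    def test_no_variation_is_degenerate(self):
        aln = Alignment(tuple((f"s{i}", "ACDE") for i in range(4)))
        with pytest.raises(DegenerateStatisticError):
            tajima_d(aln)

    def test_internal_consistency_with_summary_entry_point(self):
        rng = np.random.default_rng(5)
        aln = _random_alignment(rng, 6, 40, alphabet="ACDEFG")
        full = tajima_d(aln)
        from_summary = tajima_d_from_summary(full.m, full.S, full.n, full.pi)
        assert from_summary.D == pytest.approx(full.D, abs=1e-12)

    def test_zero_numerator_gives_zero_d(self):
        # pi * n chosen exactly equal to S / a1
        m, S, n = 8, 20, 100
        a1 = sum(1 / i for i in range(1, m))
        res = tajima_d_from_summary(m, S, n, (S / a1) / n)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_alignments(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 400:
            m = int(rng.integers(4, 7))
            n = int(rng.integers(4, 13))
            aln = _random_alignment(rng, m, n)
            try:
                got = tajima_d(aln).D
            except DegenerateStatisticError:
                continue
            assert got == pytest.approx(oracle_tajima_d(aln), abs=1e-10)
            checked += 1

    def test_sign_matches_estimator_comparison(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            aln = _random_alignment(rng, 5, 10)
            try:
                res = tajima_d(aln)
            except DegenerateStatisticError:
                continue
            excess = res.k_hat - res.S / res.coefficients.a1
            if excess != 0:
                assert math.copysign(1, res.D) == math.copysign(1, excess)

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(11)
        aln = _random_alignment(rng, 5, 12)
        permuted = Alignment(tuple(reversed(aln.records)))
        assert tajima_d(aln).D == pytest.approx(tajima_d(permuted).D, abs=1e-12)


class TestCoverageFilter:
    def test_drops_high_missing_columns(self):
        aln = Alignment(
            tuple(
                (f"s{i}", ("A-C" if i == 0 else "AAC"))
                for i in range(10)
            )
        )
        filtered = filter_site_coverage(aln, max_missing_frac=0.05)
        assert filtered.n_sites == 2

    def test_all_columns_dropped_raises(self):
        aln = Alignment((("a", "-"), ("b", "A")))
        with pytest.raises(DegenerateStatisticError):
            filter_site_coverage(aln, max_missing_frac=0.05)


class TestRelativeRate:
    def test_all_identical(self):
        aln = Alignment((("A", "W" * 10), ("B", "W" * 10), ("C", "W" * 10)))
        res = relative_rate_counts(aln)
        assert res.identical_all == 10
        assert (res.unique_a, res.unique_b, res.unique_c, res.divergent_all) == (
            0, 0, 0, 0,
        )

    def test_per_column_case_analysis(self):
        aln = Alignment((("A", "ATAC"), ("B", "AATG"), ("C", "AAAT")))
        res = relative_rate_counts(aln)
        assert res.identical_all == 1
        assert res.unique_a == 1
        assert res.unique_b == 1
        assert res.divergent_all == 1

    def test_outgroup_selection_reorders(self):
        aln = Alignment((("x", "AAT"), ("y", "AAA"), ("z", "ATA")))
        res = relative_rate_counts(aln, outgroup_id="y")
        assert (res.id_a, res.id_b, res.id_c) == ("x", "z", "y")

    def test_complete_deletion_drops_masked_columns(self):
        aln = Alignment((("A", "AXT"), ("B", "AAT"), ("C", "AAA")))
        res = relative_rate_counts(aln)
        assert res.n_used == 2
        assert res.unique_c == 1

    def test_partition_conservation_on_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            aln = _random_alignment(rng, 3, int(rng.integers(3, 30)))
            try:
                res = relative_rate_counts(aln)
            except DegenerateStatisticError:
                continue
            total = (
                res.identical_all
                + res.divergent_all
                + res.unique_a
                + res.unique_b
                + res.unique_c
                + res.shared_pair_remainder
            )
            assert total == res.n_used
            assert res.shared_pair_remainder == 0

    def test_swapping_ingroup_preserves_chi2(self):
        a, b = 17, 5
        chi_ab, p_ab = rel_rate_chi2(a, b)
        chi_ba, p_ba = rel_rate_chi2(b, a)
        assert chi_ab == pytest.approx(chi_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_equal_counts_give_null_result(self):
        chi2, p = rel_rate_chi2(9, 9)
        assert chi2 == 0
        assert p == pytest.approx(1.0)

    def test_no_information_flagged(self):
        aln = Alignment((("A", "WW"), ("B", "WW"), ("C", "WA")))
        res = relative_rate_test(relative_rate_counts(aln))
        assert res.no_information
        assert (res.chi2, res.p) == (0.0, 1.0)

    def test_wrong_sequence_count_rejected(self, small_alignment):
        with pytest.raises(ValueError, match="exactly 3"):
            relative_rate_counts(small_alignment)


class TestChi2UpperTail:
    def test_boundary_and_monotonicity(self):
        assert chi2_upper_tail(0.0) == 1.0
        xs = np.linspace(0, 20, 200)
        ps = [chi2_upper_tail(float(x)) for x in xs]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chi2_upper_tail(-0.1)

    @pytest.mark.parametrize("x", [0.5, 3.84, 6.63, 10.0])
    def test_matches_numeric_integration_and_scipy(self, x):
        density = lambda t: math.exp(-t / 2.0) / math.sqrt(2.0 * math.pi * t)
        numeric, _ = integrate.quad(density, x, np.inf)
        assert chi2_upper_tail(x) == pytest.approx(numeric, abs=1e-8)
        assert chi2_upper_tail(x) == pytest.approx(stats.chi2.sf(x, df=1), abs=1e-12)
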