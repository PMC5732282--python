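from fractions import Fraction

import numpy as np
import pytest

from tailscope.sd_detect import SDMatch, TailSequence
from tailscope.usage_stats import (
    SiteUsageTable,
    enumerate_core_sd_set,
    expected_usage,
    infer_core_asd,
    observed_usage,
    usage_ratio,
)


def brute_force_expected(n_m, L):
    """Enumerate every (length, window) placement with exact rationals."""
    exp = [Fraction(0)] * L
    for m, count in n_m.items():
        windows = L - m + 1
        for start in range(windows):
            for p in range(start, start + m):
                exp[p] += Fraction(count) / windows
    return exp


def mk_match(p_start, p_end, gene="g", tail=None):
    from tailscope.seq_io import rna_revcomp

    tail = tail or TailSequence("GAUCACCUCCUUUCU")
    m = p_end - p_start + 1
    return SDMatch(
        gene_id=gene,
        sd=rna_revcomp(tail.segment(p_start, p_end)),
        m=m,
        upstream_interval=(-m - 7, -7),
        p_start=p_start,
        p_end=p_end,
        g=7,
        d_to_start=7 + (tail.L - p_start + 1),
    )


class TestObservedUsage:
    def test_single_match_covers_its_segment(self):
        obs = observed_usage([mk_match(6, 10)], 15)
        assert obs.tolist() == [0] * 5 + [1] * 5 + [0] * 5

    def test_overlapping_matches_accumulate(self):
        obs = observed_usage([mk_match(6, 10), mk_match(8, 12)], 15)
        assert obs[7:10].tolist() == [2, 2, 2]
        assert obs.sum() == 5 + 5

    def test_total_equals_sum_of_lengths(self, rng):
        matches = [
            mk_match(a, a + m - 1)
            for a, m in zip(rng.integers(1, 9, 40), rng.integers(4, 8, 40))
        ]
        obs = observed_usage(matches, 15)
        assert obs.sum() == sum(m.m for m in matches)

    def test_segment_outside_tail_rejected(self):
        bad = mk_match(6, 10)
        bad.p_end = 16
        with pytest.raises(ValueError):
            observed_usage([bad], 15)


class TestExpectedUsage:
    def test_site1_matches_first_site_formula_term_by_term(self):
        # expected(1) = sum_m N_m / (15 - m + 1), single covering window per m
        n_m = {m: 1 for m in range(4, 13)}
        exp = expected_usage(n_m, 15)
        assert exp[0] == pytest.approx(sum(1 / (15 - m + 1) for m in range(4, 13)))
        for m in range(4, 13):
            single = expected_usage({m: 1}, 15)
            assert single[0] == pytest.approx(1 / (15 - m + 1))

    def test_site6_single_tetramer(self):
        # 4 of the 12 length-4 windows cover site 6
        assert expected_usage({4: 1}, 15)[5] == pytest.approx(4 / 12)

    def test_site1_single_tetramer(self):
        assert expected_usage({4: 1}, 15)[0] == pytest.approx(1 / 12)

    @pytest.mark.parametrize("L", range(10, 21))
    def test_brute_force_oracle_basis_vectors(self, L):
        for m in range(4, min(12, L) + 1):
            for count in (1, 5):
                got = expected_usage({m: count}, L, max_len=min(12, L))
                want = brute_force_expected({m: count}, L)
                np.testing.assert_allclose(got, [float(w) for w in want], rtol=1e-12)

    @pytest.mark.parametrize("L", range(10, 21))
    def test_brute_force_oracle_mixed_vectors(self, L, rng):
        for _ in range(30):
            n_m = {m: int(rng.choice([0, 1, 5])) for m in range(4, min(12, L) + 1)}
            got = expected_usage(n_m, L, max_len=min(12, L))
            want = brute_force_expected(n_m, L)
            np.testing.assert_allclose(got, [float(w) for w in want], rtol=1e-12)

    def test_conservation_and_symmetry(self, rng):
        for _ in range(200):
            L = int(rng.integers(12, 21))
            n_m = {m: int(rng.integers(0, 50)) for m in range(4, 13)}
            exp = expected_usage(n_m, L)
            assert exp.sum() == pytest.approx(sum(m * c for m, c in n_m.items()))
            np.testing.assert_allclose(exp, exp[::-1], rtol=1e-12)

    def test_expected_nondecreasing_toward_center(self):
        exp = expected_usage({m: 3 for m in range(4, 13)}, 15)
        mid = len(exp) // 2 + 1
        assert np.all(np.diff(exp[:mid]) >= -1e-12)

    def test_tail_shorter_than_max_len_rejected(self):
        with pytest.raises(ValueError):
            expected_usage({4: 1}, 11, max_len=12)

    def test_eq2_literal_overrides_site6_coefficients(self):
        # the historically printed site-6 coefficients use 6 (m=11) and 5
        # (m=12) where only 5 and 4 windows cover the site
        for m, printed_c in ((11, 6), (12, 5)):
            literal = expected_usage({m: 1}, 15, eq2_literal=True)
            general = expected_usage({m: 1}, 15)
            assert literal[5] == pytest.approx(printed_c / (15 - m + 1))
            assert general[5] == pytest.approx(min(6, 15 - m + 1) / (15 - m + 1))


class TestUsageRatio:
    def test_identity_and_scaling(self):
        e = np.array([1.0, 2.0, 4.0])
        np.testing.assert_allclose(usage_ratio(e, e), 1.0)
        np.testing.assert_allclose(usage_ratio(2 * e, e), 2.0)

    def test_zero_observed_gives_zero(self):
        assert usage_ratio(np.zeros(3), np.ones(3)).tolist() == [0, 0, 0]

    def test_zero_expected_is_nan_not_inf(self):
        r = usage_ratio(np.array([1.0]), np.array([0.0]))
        assert np.isnan(r[0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            usage_ratio(np.ones(3), np.ones(4))


class TestInferCoreASD:
    def _table(self, tail, segments):
        matches = [mk_match(a, b, gene=f"g{i}", tail=tail) for i, (a, b) in enumerate(segments)]
        return SiteUsageTable.build(matches, tail)

    def test_bsu_like_core_cuccuuu(self, bsu_tail):
        # matches pairing only sites 7-13 (CUCCUUU) leave outside sites at
        # ratio < 1 and inside sites above expectation
        segments = [(7, 13)] * 6 + [(7, 11), (9, 13), (8, 12)] * 2
        core = infer_core_asd(self._table(bsu_tail, segments), bsu_tail)
        assert (core.start, core.end) == (7, 13)
        assert core.rna == "CUCCUUU"
        assert core.extended_rna == "CCUCCUUU"
        assert core.extended_start == 6

    def test_eco_like_core_cuccuua(self, eco_tail):
        # on the shorter 13-nt tail the expected-usage peak sits at site 7,
        # so observed usage must concentrate there to clear ratio > 1
        segments = [(7, 10)] * 3 + [(10, 13)] * 3 + [(7, 13)] * 6
        core = infer_core_asd(self._table(eco_tail, segments), eco_tail)
        assert core.rna == "CUCCUUA"
        assert core.extended_rna == "CCUCCUUA"

    def test_run_outside_motif_not_extended(self, bsu_tail):
        segments = [(12, 15)] * 8
        core = infer_core_asd(self._table(bsu_tail, segments), bsu_tail)
        assert core.start == 12  # strictly 3' of the CCUCC motif's flank
        assert core.extended_start == core.start
        assert core.extended_rna == core.rna

    def test_no_favored_sites_is_error(self, bsu_tail):
        table = SiteUsageTable(
            tail=bsu_tail,
            observed=np.zeros(15),
            expected=np.ones(15),
            ratio=np.zeros(15),
            n_m={},
        )
        with pytest.raises(ValueError, match="no favored"):
            infer_core_asd(table, bsu_tail)


class TestEnumerateCoreSDSet:
    def test_contains_canonical_sd_sequences(self):
        df = enumerate_core_sd_set("CCUCCUUU")
        sds = set(df["sd"])
        # complements of CCUCCUUU: substrings of AAAGGAGG
        assert {"AGGAGG", "GGAGG", "AAAGGAG", "GGAG", "AAAGGAGG"} <= sds

    def test_substring_count_before_dedup(self):
        # 8-nt core with all-distinct substrings: 5 + 4 + 3 + 2 + 1
        df = enumerate_core_sd_set("CCUCCUUA")
        anti = "UAAGGAGG"
        n_windows = sum(len(anti) - m + 1 for m in range(4, 9))
        assert n_windows == 15
        assert len(df) == len(set(df["sd"]))
        assert len(df) <= 15

    def test_duplicate_substrings_collapse(self):
        df = enumerate_core_sd_set("CCCCCCCC")  # complements GGGGGGGG
        assert len(df[df["m"] == 4]) == 1  # all 4-mers identical

    def test_usage_tagging(self, bsu_tail):
        matches = [mk_match(6, 10)] * 3  # sd = GGAGG
        df = enumerate_core_sd_set("CCUCCUUU", matches=matches)
        assert int(df.loc[df["sd"] == "GGAGG", "usage"].iloc[0]) == 3
        assert int(df.loc[df["sd"] == "AGGAGG", "usage"].iloc[0]) == 0
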