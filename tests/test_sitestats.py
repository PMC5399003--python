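import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_map, make_matrix
from sweepscan.sitestats import (
    compute_site_stats,
    genomewide_summary,
    ratio_of_sums_fst,
    site_fst,
    site_pi,
    substitute_undefined_fst,
)


def pi_oracle(n_a: int, n_b: int) -> float:
    """Probability two allele observations drawn with replacement differ,
    counted by explicit enumeration of ordered pairs."""
    obs = ["A"] * n_a + ["B"] * n_b
    pairs = [(x, y) for x in obs for y in obs]
    return sum(x != y for x, y in pairs) / len(pairs)


def fst_oracle(counts) -> float:
    """Loop-based evaluation of the n_j^2-weighted differentiation index."""
    num = 0.0
    wsum = 0.0
    pooled_a = pooled_b = 0
    for n_a, n_b in counts:
        n_j = n_a + n_b
        num += n_j**2 * pi_oracle(n_a, n_b)
        wsum += n_j**2
        pooled_a += n_a
        pooled_b += n_b
    pi_pool = pi_oracle(pooled_a, pooled_b)
    return 1.0 - num / (pi_pool * wsum)


class TestSitePi:
    @pytest.mark.parametrize(
        "n_a,n_b,expected",
        [(5, 5, 0.5), (10, 0, 0.0), (3, 1, 0.375)],
    )
    def test_printed_formula(self, n_a, n_b, expected):
        assert site_pi(n_a, n_b) == pytest.approx(expected)

    @given(st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_label_permutation_and_monomorphic(self, n_a, n_b):
        if n_a + n_b == 0:
            assert np.isnan(site_pi(n_a, n_b))
            return
        assert site_pi(n_a, n_b) == pytest.approx(site_pi(n_b, n_a))
        assert (site_pi(n_a, n_b) == 0) == (n_a == 0 or n_b == 0)
        assert 0 <= site_pi(n_a, n_b) <= 0.5

    def test_zero_observations_nan(self):
        assert np.isnan(site_pi(0, 0))


class TestSiteFst:
    def test_no_differentiation(self):
        assert site_fst([(2, 2), (2, 2)]) == pytest.approx(0.0)

    def test_fixed_difference(self):
        assert site_fst([(4, 0), (0, 4)]) == pytest.approx(1.0)

    def test_hand_evaluated_intermediate(self):
        # pi1 = pi2 = 0.375, pooled (4,4) pi = 0.5:
        # 1 - (16*0.375*2)/(0.5*32) = 0.25
        assert site_fst([(3, 1), (1, 3)]) == pytest.approx(0.25)

    def test_requires_two_subpopulations(self):
        with pytest.raises(ValueError):
            site_fst([(3, 1)])

    def test_monomorphic_pooled_undefined(self):
        assert np.isnan(site_fst([(4, 0), (4, 0)]))

    def test_not_clamped_below_zero(self):
        # n_j^2-weighted subpopulation diversity can exceed pooled diversity
        val = site_fst([(0, 5), (1, 12)])
        assert val < 0

    def test_identical_scaled_counts_zero(self):
        assert site_fst([(6, 2), (3, 1)]) == pytest.approx(0.0)


class TestOracleEquivalence:
    def test_matches_enumeration_on_random_sites(self, rng):
        for _ in range(200):
            n_a1, n_b1 = rng.integers(0, 12, size=2)
            n_a2, n_b2 = rng.integers(0, 12, size=2)
            if n_a1 + n_b1 == 0 or n_a2 + n_b2 == 0:
                continue
            assert site_pi(n_a1, n_b1) == pytest.approx(
                pi_oracle(n_a1, n_b1), abs=1e-12
            )
            counts = [(int(n_a1), int(n_b1)), (int(n_a2), int(n_b2))]
            if pi_oracle(n_a1 + n_a2, n_b1 + n_b2) == 0:
                assert np.isnan(site_fst(counts))
            else:
                assert site_fst(counts) == pytest.approx(
                    fst_oracle(counts), abs=1e-12
                )


class TestSubstitution:
    def _records(self, fst_values):
        n = len(fst_values)
        return pd.DataFrame(
            {
                "snp_id": [f"m{i}" for i in range(n)],
                "lg": "1",
                "cm": np.arange(n, dtype=float),
                "n_pop1": 8,
                "n_pop2": 8,
                "pi_pop1": 0.3,
                "pi_pop2": 0.2,
                "pi_pooled": 0.3,
                "fst": fst_values,
                "substituted": False,
            }
        )

    def test_undefined_gets_mean_of_defined(self):
        rec = substitute_undefined_fst(self._records([0.2, 0.4, np.nan]))
        assert rec["fst"].iloc[2] == pytest.approx(0.3)
        assert rec["substituted"].tolist() == [False, False, True]

    def test_noop_when_all_defined(self):
        base = self._records([0.1, 0.2])
        rec = substitute_undefined_fst(base)
        pd.testing.assert_frame_equal(rec, base)

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            substitute_undefined_fst(self._records([np.nan, np.nan]))

    def test_defined_values_and_their_mean_unchanged(self, rng):
        vals = rng.normal(0.2, 0.1, size=50)
        vals[rng.choice(50, 10, replace=False)] = np.nan
        rec = substitute_undefined_fst(self._records(vals))
        defined = ~np.isnan(vals)
        np.testing.assert_allclose(rec["fst"][defined], vals[defined])
        assert rec["fst"].mean() == pytest.approx(np.nanmean(vals))


class TestComputeSiteStats:
    def test_end_to_end_counts_and_stats(self, two_pop_assignment):
        # pop1: s1,s2  pop2: s3,s4; SNP m1: pop1 A-fixed, pop2 B-fixed
        g = make_matrix(["AA", "AH", "BA", "B-"])
        gmap = make_map(["m1", "m2"], ["1", "1"], [0.0, 1.0])
        rec = compute_site_stats(g, gmap, two_pop_assignment(2, 2), "pop1", "pop2")
        m1 = rec[rec.snp_id == "m1"].iloc[0]
        assert m1.n_pop1 == 4 and m1.n_pop2 == 4
        assert m1.pi_pop1 == 0.0 and m1.pi_pop2 == 0.0
        assert m1.fst == pytest.approx(1.0)
        # m2: pop1 counts (3A,1B), pop2 (1A,1B) from one call + missing
        m2 = rec[rec.snp_id == "m2"].iloc[0]
        assert m2.n_pop2 == 2
        assert m2.pi_pop1 == pytest.approx(0.375)

    def test_unmapped_snps_excluded(self, two_pop_assignment):
        g = make_matrix(["AA", "AB", "BA", "BB"])
        gmap = make_map(["m1"], ["1"], [0.0])
        rec = compute_site_stats(g, gmap, two_pop_assignment(2, 2), "pop1", "pop2")
        assert rec.snp_id.tolist() == ["m1"]

    def test_excluded_samples_dropped(self, two_pop_assignment):
        # 5th sample is 'excluded'; its B calls must not enter counts
        g = make_matrix(["AA", "AA", "AB", "AB", "BB"])
        gmap = make_map(["m1", "m2"], ["1", "1"], [0.0, 1.0])
        rec = compute_site_stats(g, gmap, two_pop_assignment(2, 2, 1), "pop1", "pop2")
        assert (rec.n_pop1 == 4).all() and (rec.n_pop2 == 4).all()


class TestSummary:
    def _records(self):
        return pd.DataFrame(
            {
                "n_pop1": [8, 8],
                "n_pop2": [8, 8],
                "pi_pop1": [0.5, 0.1],
                "pi_pop2": [0.2, 0.2],
                "pi_pooled": [0.4, 0.2],
                "fst": [0.25, 0.15],
            }
        )

    def test_means(self):
        s = genomewide_summary(self._records())
        assert s.mean_fst == pytest.approx(0.2)
        assert s.mean_pi_pop1 == pytest.approx(0.3)
        assert s.mean_pi_pop2 == pytest.approx(0.2)

    def test_single_site(self):
        s = genomewide_summary(self._records().iloc[:1])
        assert s.mean_fst == pytest.approx(0.25)

    def test_ratio_of_sums_aggregate(self):
        rec = self._records()
        expected = 1.0 - (
            (64 * 0.5 + 64 * 0.2) + (64 * 0.1 + 64 * 0.2)
        ) / (0.4 * 128 + 0.2 * 128)
        assert ratio_of_sums_fst(rec) == pytest.approx(expected)
        s = genomewide_summary(rec, fst_aggregate="ratio_of_sums")
        assert s.mean_fst == pytest.approx(expected)
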