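"""Exact-test oracle equivalence, BH correction, screens and indicator calls."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from amdcomp.abundance import CountMatrix
from amdcomp.differential import (
    bh_adjust,
    call_indicators,
    fisher_two_tailed,
    indicator_counts,
    odds_ratio_ci,
    pairwise_screen,
    per_taxon_gene_screen,
    sample_odds_ratio,
)
from amdcomp.simulate import (
    PlantedIndicator,
    SimulationConfig,
    simulate_paired_counts,
    to_read_table,
)

TIE = 1 + 1e-7


def enumeration_oracle(a11, a12, a21, a22):
    """Independent two-tailed p: brute-force scan of all tables with the
    observed margins, summing hypergeometric point probabilities <= observed."""
    r1, r2, c1 = a11 + a12, a21 + a22, a11 + a21
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (a12 + a22) == 0:
        return 1.0
    dist = scipy.stats.hypergeom(n, c1, r1)
    ks = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = dist.pmf(ks)
    p_obs = dist.pmf(a11)
    return min(float(pmf[pmf <= p_obs * TIE].sum()), 1.0)


def _cm(data, layer="cDNA", level="cog"):
    df = pd.DataFrame(data)
    df.index = df.index.astype(str)
    return CountMatrix(df, level=level, layer=layer)


class TestFisher:
    def test_identical_empty_columns_degenerate(self):
        assert fisher_two_tailed(0, 100, 0, 100) == 1.0

    def test_perfect_separation_matches_enumeration(self):
        p = fisher_two_tailed(10, 0, 0, 10)
        assert p == pytest.approx(enumeration_oracle(10, 0, 0, 10), rel=1e-10)
        # closed form: the two extreme tables out of C(20,10) arrangements
        assert p == pytest.approx(2.0 / 184756.0, rel=1e-12)

    @given(
        a11=st.integers(0, 30), a12=st.integers(0, 30),
        a21=st.integers(0, 30), a22=st.integers(0, 30),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a11, a12, a21, a22):
        p = fisher_two_tailed(a11, a12, a21, a22)
        assert 0 < p <= 1
        assert p == pytest.approx(enumeration_oracle(a11, a12, a21, a22), rel=1e-10, abs=1e-12)

    @given(
        a11=st.integers(0, 400), a12=st.integers(200, 1500),
        a21=st.integers(0, 400), a22=st.integers(200, 1500),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_cross_check(self, a11, a12, a21, a22):
        """Independent implementation check, covering the large-table float
        path as well as the exact path."""
        p = fisher_two_tailed(a11, a12, a21, a22)
        p_scipy = scipy.stats.fisher_exact([[a11, a12], [a21, a22]])[1]
        assert p == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)

    @given(
        a11=st.integers(0, 25), a12=st.integers(0, 25),
        a21=st.integers(0, 25), a22=st.integers(0, 25),
    )
    @settings(max_examples=100, deadline=None)
    def test_row_swap_symmetry(self, a11, a12, a21, a22):
        assert fisher_two_tailed(a11, a12, a21, a22) == pytest.approx(
            fisher_two_tailed(a21, a22, a11, a12), rel=1e-12
        )

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(-1, 2, 3, 4)

    def test_odds_ratio_and_ci(self):
        assert sample_odds_ratio(10, 5, 2, 8) == pytest.approx(8.0)
        assert sample_odds_ratio(1, 0, 1, 1) == np.inf
        lo, hi = odds_ratio_ci(20, 80, 5, 95, confidence=0.99)
        assert lo < sample_odds_ratio(20, 80, 5, 95) < hi


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_applied_step_up(self):
        # min over j >= i of p_(j) * m / j, m = 4:
        # (0.01*4, 0.02*2, 0.03*4/3, 0.04) -> cummin from the right -> all 0.04
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_naive_step_up_and_dominates_raw(self, p):
        """Element-wise agreement with an O(n^2) direct evaluation of
        min_{j>=i} (p_(j) * m / j), capped at 1, mapped back to input order."""
        out = bh_adjust(p)
        m = len(p)
        order = np.argsort(np.asarray(p), kind="mergesort")
        sorted_p = np.asarray(p)[order]
        naive_sorted = [
            min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
            for i in range(m)
        ]
        naive = np.empty(m)
        naive[order] = naive_sorted
        assert np.allclose(out, naive, atol=1e-12)
        assert (out >= np.asarray(p) - 1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPairwiseScreen:
    def test_four_communities_give_six_pairs_per_feature(self):
        cm = _cm({c: [10, 20] for c in "ABCD"})
        results, _ = pairwise_screen(cm)
        assert results.groupby("feature").size().eq(6).all()

    def test_identical_proportions_never_flagged(self):
        cm = _cm({c: [10, 90] for c in "ABCD"})
        results, significant = pairwise_screen(cm)
        assert significant == set()
        assert (results["p"] == 1.0).all()

    def test_all_zero_feature_excluded(self):
        cm = _cm({"A": [0, 10], "B": [0, 10]})
        results, _ = pairwise_screen(cm)
        assert set(results["feature"]) == {"1"}

    def test_direction_follows_proportions_not_counts(self):
        # A has more reads of the feature but a *smaller* proportion
        cm = _cm({"A": [30, 2970], "B": [20, 480]})
        results, _ = pairwise_screen(cm)
        row = results.iloc[0]
        assert row["a11"] > row["a21"] and row["direction"] == "lower"

    def test_per_pair_family_mode(self):
        rng = np.random.default_rng(0)
        cm = _cm({c: rng.integers(0, 50, size=20) + 1 for c in "ABC"})
        joint, _ = pairwise_screen(cm, family="joint")
        per_pair, _ = pairwise_screen(cm, family="per_pair")
        assert (joint["p"] == per_pair["p"]).all()
        assert not (joint["p_adjusted"] == per_pair["p_adjusted"]).all()

    def test_zero_total_community_rejected(self):
        cm = _cm({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError, match="zero totals"):
            pairwise_screen(cm)


class TestIndicators:
    def test_planted_higher_indicator_recovered(self, planted_dataset, planted_config):
        _, cdna, truth = planted_dataset
        results, _ = pairwise_screen(cdna)
        calls = call_indicators(results)
        plant = planted_config.planted_indicators[0]
        higher = calls[calls["direction"] == "higher"]
        assert (plant.feature, plant.community) in set(
            zip(higher["feature"], higher["community"])
        )

    def test_identical_communities_yield_no_calls(self):
        cm = _cm({c: [10, 90] for c in "ABCD"})
        results, _ = pairwise_screen(cm)
        assert call_indicators(results).empty

    def test_contradictory_direction_is_corrupt_input(self):
        cm = _cm({"A": [50, 50], "B": [10, 90]})
        results, _ = pairwise_screen(cm)
        results.loc[0, "direction"] = "lower" if results.loc[0, "direction"] == "higher" else "higher"
        with pytest.raises(ValueError, match="contradicts"):
            call_indicators(results)

    def test_per_community_count_summary_shape(self, planted_dataset):
        _, cdna, _ = planted_dataset
        results, _ = pairwise_screen(cdna)
        calls = call_indicators(results)
        counts = indicator_counts(calls, communities=cdna.communities)
        assert list(counts.columns) == ["higher", "lower", "total"]
        assert list(counts.index) == cdna.communities
        assert counts["total"].sum() == len(calls)


@pytest.fixture(scope="module")
def taxon_reads():
    config = SimulationConfig(
        n_communities=3, n_genera=2, n_cogs=50, depth_dna=5000, depth_cdna=5000,
        seed=31,
        planted_indicators=(
            PlantedIndicator("Acidithiobacillus|COG0003", "S01", 5.0, "higher"),
        ),
    )
    dna, cdna, _ = simulate_paired_counts(config)
    return to_read_table(dna, cdna)


class TestPerTaxonScreen:
    def test_only_planted_gene_flagged(self, taxon_reads):
        results, significant, _ = per_taxon_gene_screen(
            taxon_reads, "Acidithiobacillus", alpha=0.05
        )
        assert significant == {"COG0003"}

    def test_three_communities_give_three_pairs(self, taxon_reads):
        results, _, _ = per_taxon_gene_screen(taxon_reads, "Acidithiobacillus")
        assert results.groupby("feature").size().eq(3).all()

    def test_denominators_are_taxon_totals(self, taxon_reads):
        _, _, matrix = per_taxon_gene_screen(taxon_reads, "Acidithiobacillus")
        taxon_cdna = taxon_reads[
            (taxon_reads["genus"] == "Acidithiobacillus") & (taxon_reads["layer"] == "cDNA")
        ]
        expected = taxon_cdna.groupby("sample").size()
        assert (matrix.column_totals == expected).all()

    def test_read_floor_drops_sparse_communities(self, taxon_reads):
        with pytest.raises(ValueError, match="fewer than 2"):
            per_taxon_gene_screen(taxon_reads, "Acidithiobacillus", min_taxon_reads=10**6)

    def test_absent_taxon_is_an_error(self, taxon_reads):
        with pytest.raises(ValueError, match="no cDNA reads"):
            per_taxon_gene_screen(taxon_reads, "Nitrospira")
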