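"""Turnover statistics: randomization null, rates, adjacency, positions,
composition, sizes, contingency tests and the summary."""

import math

import numpy as np
import pandas as pd
import pytest

import intronpa as ip
from intronpa.stats import (dinucleotide_counts, normalized_chromosome_position,
                            position_bin, relative_position)
from oracles import binomial_upper_tail


class TestRandomization:
    def test_single_absence_can_never_be_recurrent(self):
        res = ip.randomization_test(50, 5, n_absences=1, replicates=200,
                                    seed=0)
        assert res.mean == 0.0 and res.max == 0

    def test_reproducible_and_seed_sensitive(self):
        a = ip.randomization_test(100, 5, n_absences=40, replicates=300,
                                  seed=5)
        b = ip.randomization_test(100, 5, n_absences=40, replicates=300,
                                  seed=5)
        c = ip.randomization_test(100, 5, n_absences=40, replicates=300,
                                  seed=6)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_mean_matches_analytic_pair_expectation(self):
        n_groups, n_abs, reps = 400, 50, 3000
        res = ip.randomization_test(n_groups, 5, n_absences=n_abs,
                                    replicates=reps, seed=13)
        expected = ip.expected_recurrent_pairs(n_abs, n_groups * 5)
        mc_se = res.counts.std() / math.sqrt(reps)
        assert abs(res.mean - expected) < 3 * mc_se + 0.05

    def test_empirical_p_and_formatting(self):
        res = ip.randomization_test(100, 5, n_absences=40, replicates=500,
                                    seed=1, observed=10 ** 6)
        assert res.p_value == 0.0
        assert res.p_string == "<0.002"
        res2 = ip.randomization_test(100, 5, n_absences=40, replicates=500,
                                     seed=1, observed=0)
        assert res2.p_value == 1.0

    def test_too_many_absences_is_an_error(self):
        with pytest.raises(ValueError):
            ip.randomization_test(10, 5, n_absences=51, replicates=10, seed=0)

    def test_dollo_mode_counts_at_least_strict_unique(self):
        a = ip.randomization_test(200, 5, n_absences=60, replicates=200,
                                  seed=2, resolution_mode="strict_unique")
        d = ip.randomization_test(200, 5, n_absences=60, replicates=200,
                                  seed=2, resolution_mode="dollo")
        assert d.counts.sum() >= a.counts.sum()


class TestRates:
    def _events(self, n, branch="Zmay", kind="loss"):
        return pd.DataFrame({"branch": [branch] * n, "kind": [kind] * n,
                             "category": ["single_loss"] * n})

    def test_direct_frequency_formula(self, grass6):
        rates = ip.compute_rates(self._events(12), grass6)
        row = rates[(rates.branch == "Zmay") & (rates.category == "all")]
        assert float(row.frequency_per_my.iloc[0]) == 1.0
        expected_rate = 12 / (12 * 1e6 * ip.ANALYZED_INTRON_COUNTS["Zmay"])
        assert float(row.rate_per_intron_per_year.iloc[0]) == pytest.approx(
            expected_rate)

    def test_rate_linearity(self, grass6):
        r1 = ip.compute_rates(self._events(5), grass6)
        r2 = ip.compute_rates(self._events(10), grass6)
        m = r1.category == "all"
        assert np.allclose(2 * r1[m].frequency_per_my.fillna(0),
                           r2[m].frequency_per_my.fillna(0))

    def test_zero_events_gives_zero_table(self, grass6):
        rates = ip.compute_rates(
            pd.DataFrame(columns=["branch", "kind"]), grass6)
        assert (rates["count"] == 0).all()

    def test_per_site_rate_formula(self):
        assert ip.per_site_rate(93, 25535, 150) == pytest.approx(
            93 / 25535 / 150)


class TestAdjacency:
    def _table(self, statuses, cluster="c1", absent=None):
        return pd.DataFrame({
            "cluster_id": [cluster] * len(statuses),
            "boundary": list(range(100, 100 + 30 * len(statuses), 30)),
            "status": statuses,
            "absent": absent or [""] * len(statuses)})

    def test_zero_adjacent_pairs_gives_p_one(self):
        df = pd.concat([
            self._table(["PA", "conserved", "PA"], "c1"),
            self._table(["conserved", "conserved"], "c2")],
            ignore_index=True)
        res = ip.adjacent_loss_test(df)
        assert res.adjacent_pairs == 0
        assert res.p_value == 1.0

    def test_exact_binomial_tail_matches_direct_summation(self):
        statuses = (["PA", "PA", "conserved"] * 5 +
                    ["conserved"] * 85)
        df = self._table(statuses)
        res = ip.adjacent_loss_test(df)
        assert res.adjacent_pairs == 5
        oracle = binomial_upper_tail(res.adjacent_pairs, res.trials, res.p0)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        assert res.reject_at_005 == (res.p_value < 0.05)

    def test_triple_counts_as_two_pairs_and_lineage_match(self):
        df = self._table(["PA", "PA", "PA"], absent=["gX", "gX", "gX"])
        res = ip.adjacent_loss_test(df)
        assert res.adjacent_pairs == 2
        assert res.same_lineage_pairs == 2

    def test_undefined_without_multi_group_cluster(self):
        df = self._table(["PA"])
        with pytest.raises(ValueError):
            ip.adjacent_loss_test(df)


class TestPositions:
    def test_bin_conventions(self):
        assert position_bin(relative_position(100, 1000)) == 1
        assert position_bin(relative_position(999, 1000)) == 9
        with pytest.raises(ValueError):
            relative_position(5, 0)

    def test_uniform_positions_fill_bins_within_three_sd(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0.001, 0.999, size=2000)
        ref = rng.uniform(0.001, 0.999, size=5000)
        df = ip.gene_position_distribution(pos, ref, bootstrap=200, seed=1)
        # binomial sampling bound: sd of a 10% bin percentage at n=2000
        sd = 100 * math.sqrt(0.1 * 0.9 / 2000)
        assert np.all(np.abs(df.pct - 10.0) < 3 * sd + 1e-9)
        assert df.pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_chromosome_normalization_and_density_ratio(self):
        assert normalized_chromosome_position(50, 50, 100) == 0.0
        assert normalized_chromosome_position(0, 50, 100) == -1.0
        assert normalized_chromosome_position(80, 50, 150) == pytest.approx(
            0.3)
        with pytest.raises(ValueError):
            normalized_chromosome_position(200, 50, 100)
        rng = np.random.default_rng(3)
        ref = rng.uniform(-1, 1, 4000)
        df = ip.chromosome_position_distribution(ref[:1000], ref,
                                                 bootstrap=100, seed=2)
        assert df.pct.sum() == pytest.approx(100.0, abs=1e-9)
        # identical densities -> ratio near 1 in populated bins
        assert np.nanmean(df.density_ratio) == pytest.approx(1.0, abs=0.15)


class TestComposition:
    def test_direct_dinucleotide_count_and_ratio(self):
        counts = dinucleotide_counts("TGTGCG")
        assert counts["TG"] == 2 and counts["CG"] == 1 and counts["GT"] == 1
        profiles, _ = ip.composition_profile(
            {"x": [("TGTGCG", "GGCC", "GGCC")]})
        intron = next(p for p in profiles if p.region == "intron")
        assert intron.tg_cg == 2.0
        flank = next(p for p in profiles if p.region == "flank")
        assert flank.gc == 1.0

    def test_dinucleotide_count_is_length_minus_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 200))
            seq = "".join(rng.choice(list("ACGT"), n))
            assert sum(dinucleotide_counts(seq).values()) == n - 1

    def test_frequencies_sum_to_one_and_zero_cg_flagged(self):
        profiles, _ = ip.composition_profile({"x": [("ATATAT", "AT", "AT")]})
        intron = next(p for p in profiles if p.region == "intron")
        assert sum(intron.dinucleotide_freqs.values()) == pytest.approx(1.0)
        assert math.isnan(intron.tg_cg)          # CG count 0 -> undefined

    def test_bonferroni_alpha_for_three_comparisons(self):
        triples = [("TGTGCGTG" * 5, "A" * 20, "C" * 20)]
        profiles, comp = ip.composition_profile(
            {"recurrent_loss": triples, "PA": triples, "conserved": triples})
        assert len(comp) == 3
        assert np.allclose(comp.bonferroni_alpha, 0.05 / 3)


class TestSizesAndContingency:
    def test_identical_samples_are_not_significant(self):
        res = ip.compare_intron_sizes([1, 2, 3], [1, 2, 3])
        assert res["p"] > 0.9

    def test_fully_separated_samples_match_exact_enumeration(self):
        # oracle: U=0; 2 of the C(6,3)=20 equally likely rank arrangements
        # are as extreme -> two-sided exact p = 0.1
        res = ip.compare_intron_sizes([1, 2, 3], [10, 20, 30])
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(0.1)
        assert (res["mean_a"], res["mean_b"]) == (2.0, 20.0)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ip.compare_intron_sizes([], [1])

    def test_single_intron_gene_enrichment_reproduces_reported_p(self):
        # turnover in single-intron genes (65/18,226) vs all introns
        # (1,026/588,669), continuity correction on
        table = [[65, 18226 - 65], [1026, 588669 - 1026]]
        chi2, p = ip.contingency_tests(table, continuity=True)
        assert p == pytest.approx(1.75e-8, rel=0.05)

    def test_equal_proportions_give_zero_statistic(self):
        chi2, p = ip.contingency_tests([[10, 90], [100, 900]],
                                       continuity=False)
        assert chi2 == 0.0 and p == 1.0

    def test_expression_enrichment_2x2(self):
        a, n_a = round(0.68 * 207), 207
        b, n_b = round(0.45 * 57381), 57381
        _, p = ip.contingency_tests([[a, n_a - a], [b, n_b - b]])
        assert p == pytest.approx(4.5e-11, rel=0.2)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError):
            ip.contingency_tests([[0, 0], [5, 5]])


class TestSummary:
    def test_printed_category_counts_give_published_ratio(self):
        ratio = ip.loss_gain_ratio(652 + 206, 118)
        assert ratio == pytest.approx(7.2, abs=0.1)

    def test_empty_input_flags_undefined_ratio(self):
        df = ip.build_summary([])
        assert (df.groups == 0).all()
        assert math.isnan(df.attrs["loss_gain_ratio"])

    def test_single_loss_group_bookkeeping(self, grass6):
        hists = ip.enumerate_min_histories(
            grass6.tree, {"Zmay": "absent", "Sbic": "present",
                          "Sita": "present", "Bdis": "present",
                          "Osat": "present", "Atha": "present"})
        cls = ip.classify_group(hists)
        df = ip.build_summary([cls])
        row = df[df.category == "single_loss"].iloc[0]
        assert (row.groups, row.events, row.affected_genes) == (1, 1, 1)
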