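import numpy as np
import pandas as pd
import pytest

from regdiver import dynamics as dy

from oracles import fisher_p_oracle


def make_traj(rows, class_map, site_counts):
    df = pd.DataFrame(rows, columns=list(dy.TRAJECTORY_COLUMNS))
    return dy.AlleleTrajectorySet(records=df, class_map=class_map,
                                  site_counts=site_counts)


@pytest.fixture(scope="module")
def hand_table():
    """20-row hand-written trajectory table; all numbers checkable by eye.

    Classes: gA, gB are TFs; gC, gD are TGs. Population p1 only, except m5
    in p2. TF non-synonymous sites: 1000; TG sites: 2000.
    """
    rows = [
        # m1: nonsyn in gA, appears at t=500, sweeps to fixation by 10500
        ("p1", "m1", "gA", "nonsynonymous", 500, 0.10),
        ("p1", "m1", "gA", "nonsynonymous", 1000, 0.40),
        ("p1", "m1", "gA", "nonsynonymous", 10500, 1.00),
        ("p1", "m1", "gA", "nonsynonymous", 20000, 1.00),
        # m2: nonsyn in gA, transient within the first interval
        ("p1", "m2", "gA", "nonsynonymous", 1000, 0.20),
        ("p1", "m2", "gA", "nonsynonymous", 1500, 0.30),
        ("p1", "m2", "gA", "nonsynonymous", 2000, 0.00),
        # m3: synonymous in gB (never counts towards nonsyn DAF)
        ("p1", "m3", "gB", "synonymous", 500, 0.50),
        ("p1", "m3", "gB", "synonymous", 1000, 0.60),
        # m4: nonsyn in gC, first nonzero at 15000
        ("p1", "m4", "gC", "nonsynonymous", 10000, 0.00),
        ("p1", "m4", "gC", "nonsynonymous", 15000, 0.25),
        ("p1", "m4", "gC", "nonsynonymous", 20000, 0.35),
        # m5: nonsyn in gC but in population p2
        ("p2", "m5", "gC", "nonsynonymous", 1000, 0.15),
        ("p2", "m5", "gC", "nonsynonymous", 1500, 0.05),
        # m6: nonsyn in gD, rises then falls inside interval 2
        ("p1", "m6", "gD", "nonsynonymous", 11000, 0.10),
        ("p1", "m6", "gD", "nonsynonymous", 12000, 0.40),
        ("p1", "m6", "gD", "nonsynonymous", 13000, 0.20),
        # m7: second nonsyn mutation in gA at t=1000
        ("p1", "m7", "gA", "nonsynonymous", 1000, 0.10),
        ("p1", "m7", "gA", "nonsynonymous", 1500, 0.00),
        ("p1", "m7", "gA", "nonsynonymous", 2000, 0.00),
    ]
    class_map = {"gA": "TF", "gB": "TF", "gC": "TG", "gD": "TG"}
    return make_traj(rows, class_map, {"TF": 1000.0, "TG": 2000.0})


class TestGeneDaf:
    def test_sum_of_frequencies(self, hand_table):
        # at t=1000 gA carries m1 (0.40), m2 (0.20) and m7 (0.10)
        assert dy.gene_daf(hand_table, "p1", "gA", 1000) == pytest.approx(0.7)

    def test_no_mutations_is_zero(self, hand_table):
        assert dy.gene_daf(hand_table, "p1", "gD", 500) == 0.0

    def test_fixed_mutation_is_one(self, hand_table):
        assert dy.gene_daf(hand_table, "p1", "gA", 20000) == pytest.approx(1.0)

    def test_unknown_population_or_gene_errors(self, hand_table):
        with pytest.raises(KeyError):
            dy.gene_daf(hand_table, "p9", "gA", 500)
        with pytest.raises(KeyError):
            dy.gene_daf(hand_table, "p1", "gX", 500)


class TestClassMeanDaf:
    def test_zero_inclusion_rule(self, hand_table):
        # TF class at t=1000: gA sums 0.7, gB (synonymous only) counts 0
        assert dy.class_mean_daf(hand_table, "TF", "p1", 1000) == \
            pytest.approx(0.35)

    def test_all_unmutated_is_zero(self, hand_table):
        assert dy.class_mean_daf(hand_table, "TG", "p1", 500) == 0.0

    def test_synonymous_only_gene_contributes_zero(self, hand_table):
        assert dy.class_mean_daf(hand_table, "TF", "p1", 500) == \
            pytest.approx(0.05)  # only m1's 0.10 over 2 genes

    def test_empty_class_errors(self, hand_table):
        with pytest.raises(ValueError):
            dy.class_mean_daf(hand_table, "LR", "p1", 500)

    def test_series_averages_populations(self, hand_table):
        s = dy.class_mean_daf_series(hand_table, "TG",
                                     grid=np.array([1000]))
        # p1: 0; p2: m5 0.15 / 2 genes -> mean over populations = 0.0375
        assert s.loc[1000] == pytest.approx(0.0375)


class TestDeNovoRate:
    def test_binning_and_normalization(self, hand_table):
        starts, rates = dy.de_novo_rate(hand_table, "TG", interval=10_000)
        assert starts.tolist() == [0, 10_000]
        # m5 first nonzero at 1000 (interval 0); m4 at 15000, m6 at 11000
        assert rates.tolist() == pytest.approx([1 / 2000, 2 / 2000])

    def test_counts_sum_to_total_mutations(self, hand_table):
        _, tf_rates = dy.de_novo_rate(hand_table, "TF", interval=10_000)
        assert tf_rates.sum() * 1000 == pytest.approx(3)  # m1, m2, m7
        _, tg_rates = dy.de_novo_rate(hand_table, "TG", interval=10_000)
        assert tg_rates.sum() * 2000 == pytest.approx(3)  # m4, m5, m6

    def test_missing_site_count_errors(self, hand_table):
        with pytest.raises(ValueError):
            dy.de_novo_rate(hand_table, "LR")


class TestMaxFreqPerInterval:
    def test_max_within_interval(self, hand_table):
        out = dy.max_freq_per_interval(hand_table, "TG", interval=10_000)
        # interval [10000, 20000): m4 max 0.25, m6 max 0.40
        assert sorted(out[10_000].tolist()) == pytest.approx([0.25, 0.40])

    def test_pooled_across_populations(self, hand_table):
        out = dy.max_freq_per_interval(hand_table, "TG", interval=10_000)
        assert out[0].tolist() == pytest.approx([0.15])  # m5 from p2

    def test_zero_throughout_interval_excluded(self, hand_table):
        out = dy.max_freq_per_interval(hand_table, "TF", interval=10_000)
        # m2/m7 are zero from t=2000 on; only m1 (at t=10500) is observed
        # nonzero inside [10000, 20000)
        assert out[10_000].tolist() == pytest.approx([1.0])

    def test_fixed_variant_stays_one(self, hand_table):
        out = dy.max_freq_per_interval(hand_table, "TF", interval=10_000)
        assert 1.0 in out[20_000].tolist()


class TestDropOutlierGene:
    def test_mutation_count_dominates(self, hand_table):
        reduced, dropped = dy.drop_outlier_gene(hand_table, "TG")
        assert dropped == "gC"  # 2 mutations (m4, m5) vs 1 for gD
        assert "gC" not in set(reduced.records["gene"])

    def test_fixation_fraction_breaks_ties(self):
        rows = [
            ("p1", "m1", "g1", "nonsynonymous", 500, 1.0),
            ("p1", "m2", "g2", "nonsynonymous", 500, 0.4),
        ]
        traj = make_traj(rows, {"g1": "TG", "g2": "TG"}, {"TG": 100.0})
        _, dropped = dy.drop_outlier_gene(traj, "TG")
        assert dropped == "g1"

    def test_single_mutated_gene_errors(self):
        rows = [("p1", "m1", "g1", "nonsynonymous", 500, 0.4)]
        traj = make_traj(rows, {"g1": "TG", "g2": "TG"}, {"TG": 100.0})
        with pytest.raises(ValueError):
            dy.drop_outlier_gene(traj, "TG")


class TestAleEnrichment:
    STUDIES = pd.DataFrame({
        "study": ["S1", "S2", "S3", "S4"],
        "type": ["ALE", "ALE", "MA", "MA"],
        "tf_mut": [10, 8, 2, 1],
        "tg_mut": [10, 30, 20, 9],
        "tf_sites": [1000, 1000, 1000, 1000],
        "tg_sites": [10000, 10000, 10000, 10000],
    })

    def test_odds_ratio_and_exact_p(self):
        results, _ = dy.ale_enrichment(self.STUDIES)
        s1 = results[0]
        assert s1.odds_ratio == pytest.approx(10 * 9990 / (990 * 10))
        table = [[10, 990], [10, 9990]]
        assert s1.p_value == pytest.approx(
            fisher_p_oracle(table, "greater"), abs=1e-12)

    def test_holm_adjustment_is_monotone(self):
        results, _ = dy.ale_enrichment(self.STUDIES)
        assert all(r.p_adjusted >= r.p_value for r in results)

    def test_equal_rates_give_or_one_and_large_p(self):
        df = pd.DataFrame({
            "study": ["S"], "type": ["ALE"], "tf_mut": [10], "tg_mut": [100],
            "tf_sites": [1010], "tg_sites": [10100]})
        results, _ = dy.ale_enrichment(df)
        assert results[0].odds_ratio == pytest.approx(1.0)
        assert results[0].p_value >= 0.5

    def test_zero_tf_mutations_give_p_one(self):
        df = pd.DataFrame({
            "study": ["S"], "type": ["ALE"], "tf_mut": [0], "tg_mut": [10],
            "tf_sites": [1000], "tg_sites": [10000]})
        results, _ = dy.ale_enrichment(df)
        assert results[0].p_value == pytest.approx(1.0)

    def test_ale_vs_ma_rank_sum_direction(self):
        _, ranksum = dy.ale_enrichment(self.STUDIES)
        assert ranksum.alternative == "greater"
        assert ranksum.p_value < 0.5  # ALE odds ratios are larger here

    def test_zero_sites_error(self):
        bad = self.STUDIES.copy()
        bad.loc[0, "tf_sites"] = 0
        with pytest.raises(ValueError):
            dy.ale_enrichment(bad)


class TestMutatedProteinTest:
    def test_background_fraction(self):
        expected, _ = dy.mutated_protein_test(2, 30)
        assert expected == pytest.approx(304 / 4140)
        assert expected == pytest.approx(0.0734, abs=5e-4)

    def test_expected_count_not_significant(self):
        _, res = dy.mutated_protein_test(2, 30)
        assert res.p_value >= 0.05

    def test_strong_excess_significant(self):
        _, res = dy.mutated_protein_test(15, 30)
        assert res.p_value < 0.001

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            dy.mutated_protein_test(31, 30)
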