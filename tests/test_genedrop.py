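"""Gene-drop null: cohort logic, Mendelian transmission, selection tests, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import embryoscan as es
from embryoscan.genedrop import CohortFrequencySeries


def ped_from(rows):
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "birth_year", "sex", "genotyped"])
    return es.Pedigree.from_dataframe(df)


def series(years, freqs, label="simulated"):
    years = np.asarray(years)
    return CohortFrequencySeries(
        years=years, frequency=np.asarray(freqs, dtype=float),
        n_alleles=np.full(len(years), 10), label=label,
    )


class TestClassifyCohorts:
    def test_all_parentless_are_founders(self):
        ped = ped_from(
            [(f"i{k}", "", "", 1990 + k % 5, "F", 1) for k in range(10)]
        )
        part = es.classify_cohorts(ped, es.GeneDropConfig(n_sampled_cohorts=3))
        assert part.founder.all()

    def test_coverage_rule_sets_first_cohort(self, cohort_pedigree):
        res, _ = cohort_pedigree
        part = es.classify_cohorts(res.pedigree)
        # pre-study cohorts are under the 70% genotyped floor
        assert part.sampled_years.tolist() == [1990, 1991, 1992]
        assert part.simulated_years[0] == 1993
        assert part.simulated_years[-1] == 2018

    def test_single_known_parent_not_founder(self):
        ped = ped_from(
            [
                ("a", "", "", 1990, "M", 1),
                ("b", "", "", 1991, "F", 1),
                ("c", "a", "", 1992, "F", 1),
                ("d", "a", "b", 1993, "F", 1),
            ]
        )
        part = es.classify_cohorts(ped, es.GeneDropConfig(n_sampled_cohorts=3))
        assert part.founder.tolist() == [True, True, False, False]


class TestGeneDrop:
    def mini_pedigree(self):
        """Het x het pair (sampled cohorts) with one simulated-cohort offspring."""
        rows = [("dam", "", "", 1990, "F", 1), ("sire", "", "", 1990, "M", 1)]
        rows += [(f"f{k}", "", "", 1991 + k % 2, "F", 1) for k in range(4)]
        rows += [("kid", "sire", "dam", 1993, "F", 1)]
        return ped_from(rows)

    def test_mendelian_ratio_for_het_pair_offspring(self):
        ped = self.mini_pedigree()
        dosage = np.array([1, 1, 1, 1, 1, 1, 0], dtype=np.int8)
        cfg = es.GeneDropConfig(n_sims=4000, seed=5)
        sims = es.gene_drop(ped, dosage, cfg)
        kid = 6
        # recover each sim's kid genotype from the 1993 cohort frequency (kid is alone)
        kid_freqs = np.array([s.frequency[-1] for s in sims])
        hom_rate = np.mean(kid_freqs == 1.0)
        # both transmitted alleles are Bernoulli(1/2) -> homozygous carrier 25%
        assert hom_rate == pytest.approx(0.25, abs=0.02)

    def test_sampled_cohort_founder_draw_is_binomial(self):
        # all founders: sampled-cohort frequencies are binomial resamples
        rows = [(f"i{k}", "", "", 1990 + k // 10, "F", 1) for k in range(40)]
        ped = ped_from(rows)
        dosage = np.array(([2] * 3 + [1] * 2 + [0] * 5) * 4, dtype=np.int8)
        cfg = es.GeneDropConfig(n_sims=3000, seed=1)
        sims = es.gene_drop(ped, dosage, cfg)
        f0 = np.array([s.frequency[0] for s in sims])
        # cohort 1990: 10 individuals, observed freq 0.4, denominator 20 alleles
        assert f0.mean() == pytest.approx(0.4, abs=0.01)
        assert f0.var() == pytest.approx(0.4 * 0.6 / 20, rel=0.1)

    def test_absent_allele_stays_absent(self):
        ped = self.mini_pedigree()
        dosage = np.zeros(7, dtype=np.int8)
        sims = es.gene_drop(ped, dosage, es.GeneDropConfig(n_sims=50, seed=2))
        for s in sims:
            assert np.all(s.frequency == 0.0)

    def test_seed_determinism(self, cohort_pedigree):
        res, dosage = cohort_pedigree
        cfg = es.GeneDropConfig(n_sims=20, seed=42)
        a = es.gene_drop(res.pedigree, dosage, cfg)
        b = es.gene_drop(res.pedigree, dosage, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.frequency, y.frequency)

    def test_genotyped_only_in_frequencies(self):
        rows = [("a", "", "", 1990, "F", 1), ("b", "", "", 1990, "M", 0),
                ("c", "", "", 1991, "F", 1), ("d", "", "", 1992, "F", 1),
                ("e", "a", "", 1993, "F", 1)]
        ped = ped_from(rows)
        dosage = np.array([2, -1, 2, 2, 2], dtype=np.int8)
        obs = es.observed_series(ped, dosage, [1990, 1991, 1992, 1993])
        assert obs.n_alleles.tolist() == [2, 2, 2, 2]  # b excluded
        assert np.all(obs.frequency == 1.0)


class TestRecombinationVariant:
    def test_zero_length_identical_to_plain_drop(self, cohort_pedigree):
        res, dosage = cohort_pedigree
        a = es.gene_drop(res.pedigree, dosage, es.GeneDropConfig(n_sims=10, seed=9))
        b = es.gene_drop_recomb(
            res.pedigree, dosage, es.GeneDropConfig(n_sims=10, seed=9, recombination_cm=0.0)
        )
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.frequency, y.frequency)

    def test_breakdown_lowers_final_frequency(self, cohort_pedigree):
        res, dosage = cohort_pedigree
        plain = es.gene_drop(res.pedigree, dosage, es.GeneDropConfig(n_sims=150, seed=3))
        rec = es.gene_drop_recomb(
            res.pedigree, dosage, es.GeneDropConfig(n_sims=150, seed=3, recombination_cm=10.0)
        )
        final_plain = np.mean([s.frequency[-1] for s in plain])
        final_rec = np.mean([s.frequency[-1] for s in rec])
        assert final_rec < final_plain

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            es.GeneDropConfig(recombination_cm=-1.0)


class TestSelectionSummaries:
    def test_observed_steeper_than_every_sim(self):
        yrs = np.arange(2000, 2005)
        obs = series(yrs, [0.5, 0.4, 0.3, 0.2, 0.1], label="observed")
        sims = [series(yrs, 0.5 - 0.01 * k * np.arange(5)) for k in range(1, 6)]
        s = es.gene_drop_summary(obs, sims, yrs)
        assert s.directional_quantile == 0.0
        assert s.slope_quantile_low == 0.0

    def test_two_year_cumulative_change(self):
        yrs = np.array([2000, 2001])
        obs = series(yrs, [0.2, 0.3], label="observed")
        s = es.gene_drop_summary(obs, [series(yrs, [0.2, 0.2])], yrs)
        assert s.observed_cumulative_change == pytest.approx(0.1)

    def test_constant_observed_has_zero_change_quantile_zero(self):
        yrs = np.arange(2000, 2004)
        obs = series(yrs, [0.3] * 4, label="observed")
        sims = [series(yrs, 0.3 + 0.01 * np.random.default_rng(k).standard_normal(4)) for k in range(20)]
        s = es.gene_drop_summary(obs, sims, yrs)
        assert s.observed_cumulative_change == 0.0
        assert s.balancing_quantile == 0.0

    def test_constant_observed_slope_quantile_near_half(self, cohort_pedigree):
        res, dosage = cohort_pedigree
        part = es.classify_cohorts(res.pedigree)
        sims = es.gene_drop(res.pedigree, dosage, es.GeneDropConfig(n_sims=400, seed=8),
                            partition=part)
        obs = series(part.years, np.full(len(part.years), 0.2), label="observed")
        s = es.gene_drop_summary(obs, sims, part.simulated_years)
        assert 0.3 < s.slope_quantile_low < 0.7

    def test_directional_is_direction_aware(self):
        yrs = np.arange(2000, 2005)
        rising = series(yrs, [0.1, 0.2, 0.3, 0.4, 0.5], label="observed")
        sims = [series(yrs, 0.1 + 0.02 * k * np.arange(5)) for k in range(1, 9)]
        s = es.gene_drop_summary(rising, sims, yrs)
        # 5 of 8 sims rise faster than the observed slope of 0.1/yr
        assert s.directional_quantile == pytest.approx(np.mean([0.02 * k > 0.1 for k in range(1, 9)]))


class TestCalibration:
    def test_neutral_quantiles_uniform(self):
        import embryoscan.studies as st

        cal = st.neutral_calibration(n_replicates=120, n_sims=120, seed=17)
        assert stats.kstest(cal["slope_quantiles"], "uniform").pvalue > 0.01
        assert stats.kstest(cal["balancing_quantiles"], "uniform").pvalue > 0.01

    def test_selection_pulls_slope_quantile_down(self):
        import embryoscan.studies as st

        rec = st.selection_recovery(s_values=(0.47,), n_replicates=15, n_sims=100, seed=23)
        assert rec[0.47]["median"] < 0.5
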