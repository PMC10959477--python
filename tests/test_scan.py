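"""Deficiency scan: haplotype enumeration, carrier trios, the chi-square test,
the exhaustive transmission oracle, SimpleM and genome-scan behaviour."""

import itertools

import numpy as np
import pytest
from scipy import stats

import embryoscan as es
from embryoscan.io import Trio
from embryoscan.scan import CarrierTrio, HaplotypeWindow, haplotype_dosage


def matrix_from_phases(phases):
    """Build a PhasedHaplotypeMatrix from a list of per-individual phase pairs."""
    phases = np.asarray(phases, dtype=np.uint8)
    n_ind, _, n_snp = phases.shape
    snps = es.SnpMap(
        snp_id=np.array([f"s{j}" for j in range(n_snp)]),
        chromosome=np.array(["1"] * n_snp),
        position_bp=np.arange(1, n_snp + 1) * 100,
        position_cm=np.zeros(n_snp),
    )
    return es.PhasedHaplotypeMatrix([f"i{k}" for k in range(n_ind)], snps, phases)


def window(length, start=0):
    return HaplotypeWindow(
        chromosome="1", start=start, length=length,
        start_bp=(start + 1) * 100, end_bp=(start + length) * 100,
    )


class TestEnumerateWindowHaplotypes:
    def test_monomorphic_window_single_haplotype(self):
        geno = matrix_from_phases([[[0, 0], [0, 0]], [[0, 0], [0, 0]]])
        haps = es.enumerate_window_haplotypes(geno, window(2))
        assert len(haps) == 1
        assert haps[0].alleles == (0, 0)
        assert haps[0].frequency == 1.0

    def test_hand_counted_frequencies_with_floor(self):
        # 8 phases: 00 x4, 01 x2, 11 x2 -> only 00 (freq 0.5) passes 0.3
        geno = matrix_from_phases(
            [
                [[0, 0], [0, 0]],
                [[0, 0], [0, 0]],
                [[0, 1], [0, 1]],
                [[1, 1], [1, 1]],
            ]
        )
        haps = es.enumerate_window_haplotypes(geno, window(2), min_freq=0.3)
        assert [(h.alleles, h.frequency) for h in haps] == [((0, 0), 0.5)]

    def test_floor_above_max_frequency_empty(self):
        geno = matrix_from_phases([[[0, 0], [1, 1]], [[0, 1], [1, 0]]])
        assert es.enumerate_window_haplotypes(geno, window(2), min_freq=0.5) == []

    def test_deterministic_ordering(self):
        geno = matrix_from_phases(
            [
                [[0, 0], [1, 1]],
                [[0, 1], [1, 0]],
                [[0, 0], [1, 1]],
            ]
        )
        haps = es.enumerate_window_haplotypes(geno, window(2), min_freq=0.01)
        # counts: 00 x2, 11 x2, 01 x1, 10 x1 -> ties broken lexicographically
        assert [h.alleles for h in haps] == [(0, 0), (1, 1), (0, 1), (1, 0)]


class TestCarrierTrios:
    def build(self, dam_phases, sire_phases, off_phases):
        geno = matrix_from_phases([dam_phases, sire_phases, off_phases])
        geno.individuals[:] = ["dam", "sire", "off"]
        geno._index = {k: i for i, k in enumerate(geno.individuals)}
        hap = es.enumerate_window_haplotypes(geno, window(2), min_freq=0.01)
        focal = [h for h in hap if h.alleles == (1, 1)][0]
        trio = Trio(offspring="off", sire="sire", dam="dam")
        return es.carrier_trios_for(focal, [trio], geno)

    def test_noncarrier_parent_excluded(self):
        out = self.build([[1, 1], [0, 0]], [[0, 0], [0, 1]], [[0, 0], [0, 0]])
        assert out == []

    def test_hom_dam_het_sire_transmissions(self):
        out = self.build([[1, 1], [1, 1]], [[1, 1], [0, 0]], [[1, 1], [0, 0]])
        assert len(out) == 1
        assert (out[0].p, out[0].q) == (1.0, 0.5)
        assert not out[0].offspring_hom

    def test_offspring_homozygous_state(self):
        out = self.build([[1, 1], [0, 0]], [[1, 1], [0, 0]], [[1, 1], [1, 1]])
        assert out[0].offspring_hom
        assert (out[0].p, out[0].q) == (0.5, 0.5)


def make_carriers(pq_pairs, homs=None):
    homs = homs or [False] * len(pq_pairs)
    return [
        CarrierTrio(Trio(f"o{i}", f"s{i}", f"d{i}"), p, q, h)
        for i, ((p, q), h) in enumerate(zip(pq_pairs, homs))
    ]


class TestExpectedHomozygotes:
    def test_four_het_by_het(self):
        assert es.expected_homozygotes(make_carriers([(0.5, 0.5)] * 4)) == 1.0

    def test_hom_by_het(self):
        assert es.expected_homozygotes(make_carriers([(1.0, 0.5)])) == 0.5

    def test_empty_is_error(self):
        with pytest.raises(ValueError, match="no carrier matings"):
            es.expected_homozygotes([])


def enumerate_transmissions(pq_pairs):
    """Brute-force oracle: weighted enumeration of all per-trio outcomes.

    Each trio has four dam x sire transmission outcomes; the offspring is
    homozygous only when both parents transmit the focal haplotype, which
    happens with probability p*q. Returns the exact distribution of the
    total homozygote count and its mean.
    """
    dist = {}
    for outcome in itertools.product(*[[(1, p * q), (0, 1 - p * q)] for p, q in pq_pairs]):
        k = sum(o[0] for o in outcome)
        w = np.prod([o[1] for o in outcome])
        dist[k] = dist.get(k, 0.0) + w
    mean = sum(k * w for k, w in dist.items())
    return dist, mean


def poisson_binomial_pmf(probs):
    """Independent DP convolution oracle for the homozygote-count distribution."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1 - p, p])
    return pmf


@pytest.mark.parametrize("seed", [0, 1])
def test_expected_homozygotes_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    pq = [tuple(rng.choice([0.5, 1.0], size=2)) for _ in range(8)]
    carriers = make_carriers(pq)
    dist, mean = enumerate_transmissions(pq)
    assert es.expected_homozygotes(carriers) == pytest.approx(mean, abs=1e-12)
    pmf = poisson_binomial_pmf([p * q for p, q in pq])
    for k, w in dist.items():
        assert w == pytest.approx(pmf[k], abs=1e-12)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestDeficiencyTest:
    def test_published_strong_deficit(self):
        # 800 carrier matings, 258.5 expected vs 189 observed homozygotes
        t = es.deficiency_test(189, 258.5, 800)
        assert t.chi2 == pytest.approx(27.61, abs=0.01)
        assert t.p == pytest.approx(1.49e-7, rel=0.01)
        assert round(t.percent_fewer) == 27

    def test_zero_observed_suggestive(self):
        t = es.deficiency_test(0, 8.25, 33)
        assert t.chi2 == pytest.approx(11.0, abs=1e-9)
        assert t.p == pytest.approx(0.0009, abs=0.00002)

    def test_observed_equals_expected(self):
        t = es.deficiency_test(10, 10.0, 50)
        assert t.chi2 == 0.0
        assert t.p == 1.0
        assert t.percent_fewer == 0.0

    def test_degenerate_expectation_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            es.deficiency_test(0, 0.0, 10)
        with pytest.raises(ValueError, match="degenerate"):
            es.deficiency_test(10, 10.0, 10)

    def test_p_monotone_in_deficit(self):
        ps = [es.deficiency_test(o, 40.0, 160).p for o in range(40, -1, -1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_extreme_statistic_stays_finite_in_log_space(self):
        t = es.deficiency_test(0, 5000.0, 20000)
        assert t.p > 0
        assert t.log10_p < -1000

    def test_null_pvalues_approximately_uniform(self):
        # binomial sampling with success prob 0.25 at 800 het x het matings
        rng = np.random.default_rng(3)
        os = rng.binomial(800, 0.25, size=1000)
        ps = [es.deficiency_test(int(o), 200.0, 800).p for o in os]
        d = stats.kstest(ps, "uniform").statistic
        # tolerance reflects the discreteness of the binomial count
        assert d < 0.06


class TestSimpleM:
    def test_independent_snps_count_fully(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.5, size=(4000, 5))
        assert es.effective_tests_simplem(dosage) == 5

    def test_identical_columns_collapse_to_one(self):
        col = np.random.default_rng(1).binomial(2, 0.4, size=500)
        dosage = np.tile(col[:, None], (1, 5))
        assert es.effective_tests_simplem(dosage) == 1

    def test_two_duplicated_blocks(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.5, size=500)
        b = rng.binomial(2, 0.5, size=500)
        dosage = np.column_stack([a, a, a, b, b, b])
        assert es.effective_tests_simplem(dosage, block_size=3) == 2

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        dosage = np.column_stack(
            [rng.binomial(2, 0.5, size=200), np.ones(200), rng.binomial(2, 0.5, size=200)]
        )
        with pytest.warns(UserWarning, match="constant"):
            m = es.effective_tests_simplem(dosage)
        assert m == 2


def test_significance_threshold_values():
    assert es.significance_threshold(39184, 0.05) == pytest.approx(1.28e-6, rel=0.005)
    assert es.significance_threshold(1, 0.05) == 0.05
    assert es.significance_threshold(10, 0.05) == 0.005


class TestScanGenome:
    def test_window_longer_than_chromosome_empty(self):
        geno = matrix_from_phases([[[0, 1], [1, 0]], [[0, 0], [1, 1]]])
        import pandas as pd

        ped = es.Pedigree.from_dataframe(
            pd.DataFrame(
                [("i0", "", "", 1990, "M", 1), ("i1", "", "", 1990, "F", 1)],
                columns=["id", "sire", "dam", "birth_year", "sex", "genotyped"],
            )
        )
        out = es.scan_genome(geno, ped, es.ScanConfig(window_lengths=(10,)))
        assert out.empty

    def test_lethal_localized_and_deterministic(self, small_lethal_dataset):
        cfg, res = small_lethal_dataset
        scan_cfg = es.ScanConfig(window_lengths=(40,))
        out = es.scan_genome(res.genotypes, res.pedigree, scan_cfg)
        out2 = es.scan_genome(res.genotypes, res.pedigree, scan_cfg)
        assert out.equals(out2)
        best = out.loc[out["p"].idxmin()]
        assert str(best["chr"]) == res.truth.focal_chromosome
        assert best["window_start"] < cfg.focal_start + cfg.focal_length
        assert best["window_start"] + 40 > cfg.focal_start
        assert best["o_hom"] < best["e_hom"]

    def test_scan_matches_single_window_path(self, small_lethal_dataset):
        """The vectorized scan row equals the explicit carrier-trio computation."""
        cfg, res = small_lethal_dataset
        trios = es.extract_trios(res.pedigree, res.genotypes)
        scan_cfg = es.ScanConfig(window_lengths=(40,))
        out = es.scan_genome(res.genotypes, res.pedigree, scan_cfg, trios=trios)
        row = out[(out["chr"] == "1") & (out["window_start"] == cfg.focal_start)].iloc[0]
        win = HaplotypeWindow(
            chromosome="1", start=cfg.focal_start, length=40,
            start_bp=int(row["start_bp"]), end_bp=int(row["end_bp"]),
        )
        haps = es.enumerate_window_haplotypes(res.genotypes, win, scan_cfg.min_freq)
        hap = haps[int(row["hap_rank"])]
        carriers = es.carrier_trios_for(hap, trios, res.genotypes)
        e = es.expected_homozygotes(carriers)
        o = sum(c.offspring_hom for c in carriers)
        assert len(carriers) == row["n_trios"]
        assert e == pytest.approx(row["e_hom"])
        assert o == row["o_hom"]
        t = es.deficiency_test(o, e, len(carriers))
        assert t.p == pytest.approx(row["p"])
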