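"""Study scenarios: published summary counts and standardized synthetic experiments.

``TABLE_HAPLOTYPES`` holds the published carrier-mating summary counts for
the three putatively semi-lethal Soay sheep haplotypes (SEL05, SEL07, SEL18)
and the suggestive chromosome-9 haplotype: the number of carrier x carrier
matings with offspring, the Mendelian expectation E_hh and the observed
homozygote count O_hh. The deficiency statistics are fully determined by
these counts, so the chi-square p-values and percent-fewer figures can be
recomputed from them without any genotype data.

The synthetic experiments below are the package's standard validation runs:

* :func:`scan_study_config` — a short, dense study (6 cohorts, ~2,700
  individuals, two 1.8-Mb chromosomes) in which carrier x carrier matings
  are plentiful while the focal haplotype is still common, used to measure
  scan localization and false-positive behaviour;
* :func:`cohort_study_config` — a 29-cohort study with a small focal region,
  used for gene-drop calibration and selection recovery where only the
  focal carrier states matter.

Problem sizes are chosen to keep a full replicate set in the minutes range
on a single core; the methods note discusses what they do and do not
represent.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from . import genedrop as gd
from . import scan as sc
from . import simulate as sim
from .io import extract_trios, trio_index_arrays

#: name -> (carrier x carrier matings n, expected homozygotes E_hh, observed O_hh)
TABLE_HAPLOTYPES = {
    "SEL05": (800, 258.5, 189),
    "SEL07": (382, 105.75, 58),
    "SEL18": (815, 254.25, 176),
}

#: the suggestive (not genome-wide significant) chromosome-9 haplotype
CHR9_SUGGESTIVE = (33, 8.25, 0)

#: effective number of independent tests reported for the 417k-SNP dataset
N_EFF_TESTS = 39184


def scan_study_config(s_embryo: float, seed: int) -> sim.SimConfig:
    """Short dense study maximizing carrier x carrier matings at high focal frequency."""
    return sim.SimConfig(
        n_founders=700,
        n_years=6,
        matings_per_year=300,
        pre_study_genotyped_prop=0.95,
        n_chromosomes=2,
        snps_per_chromosome=300,
        focal_chromosome=0,
        focal_start=100,
        focal_length=100,
        focal_founder_freq=0.32,
        s_embryo=s_embryo,
        seed=seed,
    )


def cohort_study_config(s_embryo: float, seed: int, het_advantage: float = 0.0) -> sim.SimConfig:
    """29-cohort study with a compact focal region (gene-drop experiments)."""
    return sim.SimConfig(
        n_founders=200,
        n_years=29,
        matings_per_year=100,
        n_chromosomes=1,
        snps_per_chromosome=60,
        focal_chromosome=0,
        focal_start=20,
        focal_length=20,
        s_embryo=s_embryo,
        het_advantage=het_advantage,
        seed=seed,
    )


def _derive_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def scan_replicate(s_embryo: float, seed: int, window_length: int = 100) -> dict:
    """One simulate-and-scan replicate; reports localization and hit counts.

    Returns the number of carrier x carrier trios at the injected haplotype,
    the number of genome-wide hits (deficit direction), whether the
    minimum-p window overlaps the injected window, and whether that window
    passes the SimpleM-based Bonferroni threshold.
    """
    cfg = scan_study_config(s_embryo, seed)
    res = sim.simulate_dataset(cfg)
    trios = extract_trios(res.pedigree, res.genotypes)
    off, si, da = trio_index_arrays(trios, res.genotypes)
    dos = res.truth.dosage
    carrier = (dos[si] > 0) & (dos[da] > 0)
    scan_cfg = sc.ScanConfig(window_lengths=(window_length,))
    table = sc.scan_genome(res.genotypes, res.pedigree, scan_cfg, trios=trios)
    m_eff = sc.effective_tests_simplem(res.genotypes.allele_dosage())
    threshold = sc.significance_threshold(m_eff, scan_cfg.alpha)
    hits = sc.scan_hits(table, threshold)
    best = table.loc[table["p"].idxmin()]
    focal_lo, focal_hi = cfg.focal_start, cfg.focal_start + cfg.focal_length
    overlaps = (
        str(best["chr"]) == res.truth.focal_chromosome
        and int(best["window_start"]) < focal_hi
        and int(best["window_start"]) + window_length > focal_lo
    )
    return {
        "n_individuals": len(res.pedigree),
        "n_carrier_trios": int(carrier.sum()),
        "n_culled": res.truth.n_culled,
        "m_eff": int(m_eff),
        "threshold": float(threshold),
        "n_hits": int(len(hits)),
        "min_p": float(best["p"]),
        "min_p_deficit": bool(best["o_hom"] < best["e_hom"]),
        "min_p_overlaps_injected": bool(overlaps),
        "min_p_significant": bool(best["p"] < threshold),
    }


def scan_localization_rate(s_embryo: float, n_replicates: int, seed: int) -> dict:
    """Fraction of replicates where the top window localizes the injected lethal
    and passes the threshold, and the fraction with no hits at all."""
    reps = [
        scan_replicate(s_embryo, s)
        for s in _derive_seeds(seed, n_replicates)
    ]
    localized = np.mean(
        [r["min_p_overlaps_injected"] and r["min_p_significant"] and r["min_p_deficit"] for r in reps]
    )
    no_hits = np.mean([r["n_hits"] == 0 for r in reps])
    return {
        "replicates": reps,
        "localization_rate": float(localized),
        "no_hit_rate": float(no_hits),
        "mean_carrier_trios": float(np.mean([r["n_carrier_trios"] for r in reps])),
    }


def neutral_calibration(
    n_replicates: int = 200, n_sims: int = 200, seed: int = 0
) -> dict:
    """Gene-drop self-calibration: pseudo-observed series drawn from the null.

    One neutral 29-cohort dataset is simulated; for each replicate, ``n_sims
    + 1`` gene-drop simulations are run on its pedigree and the first plays
    the role of the observed series. Under the drift null both the
    lower-tail slope quantile and the balancing quantile should be uniform
    on (0, 1) across replicates.
    """
    data_seed, *rep_seeds = _derive_seeds(seed, n_replicates + 1)
    res = sim.simulate_dataset(cohort_study_config(0.0, data_seed))
    dosage = sim.focal_dosage(res.genotypes, res.pedigree, res.truth)
    part = gd.classify_cohorts(res.pedigree)
    slope_q, bal_q = [], []
    for rs in rep_seeds:
        cfg = gd.GeneDropConfig(n_sims=n_sims + 1, seed=rs)
        sims = gd.gene_drop(res.pedigree, dosage, cfg, partition=part)
        summary = gd.gene_drop_summary(sims[0], sims[1:], part.simulated_years)
        slope_q.append(summary.slope_quantile_low)
        bal_q.append(summary.balancing_quantile)
    return {"slope_quantiles": np.array(slope_q), "balancing_quantiles": np.array(bal_q)}


def selection_recovery(
    s_values: Sequence[float] = (0.27, 0.47, 1.0),
    n_replicates: int = 50,
    n_sims: int = 200,
    seed: int = 0,
) -> dict:
    """Median lower-tail slope quantile as embryonic lethality strengthens.

    For each ``s``, ``n_replicates`` independent 29-cohort datasets are
    simulated with that embryonic death probability; each is compared to its
    own drift null. Selection should pull the quantile below 0.5, more so
    for stronger ``s``.
    """
    out = {}
    seeds = _derive_seeds(seed, 2 * n_replicates)
    for s in s_values:
        qs = []
        for k in range(n_replicates):
            cfg = cohort_study_config(s, seeds[k])
            res = sim.simulate_dataset(cfg)
            dosage = sim.focal_dosage(res.genotypes, res.pedigree, res.truth)
            gcfg = gd.GeneDropConfig(n_sims=n_sims, seed=seeds[n_replicates + k])
            part = gd.classify_cohorts(res.pedigree, gcfg)
            obs = gd.observed_series(res.pedigree, dosage, part.years)
            sims = gd.gene_drop(res.pedigree, dosage, gcfg, partition=part)
            qs.append(gd.gene_drop_summary(obs, sims, part.simulated_years).slope_quantile_low)
        out[s] = {"quantiles": np.array(qs), "median": float(np.median(qs))}
    return out
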