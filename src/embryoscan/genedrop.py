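"""Gene-dropping through a pedigree: drift-only nulls for cohort allele frequencies.

A focal haplotype is collapsed to a biallelic "carrier / other" locus. Each
simulation re-assigns alleles down the fixed, real pedigree:

* birth-year cohorts with adequate genotype coverage form the analysis span;
  the first few (default 3) are the *sampled* cohorts, the rest *simulated*;
* founders (both parents unknown) in sampled cohorts draw each allele
  Bernoulli(observed frequency of their cohort); non-founders draw from each
  known parent's simulated alleles with Pr = 0.5 (a missing parent falls back
  to the cohort-frequency draw);
* in simulated cohorts, non-founders inherit Mendelianly; founders and
  missing-parent alleles are drawn from the current simulation's frequency in
  the rest of their cohort;
* cohort frequencies are computed over genotyped individuals only, so
  simulations and observation are directly comparable.

Two summary tests compare observation to the drift null over the simulated
cohorts: the slope of an ordinary least-squares regression of frequency on
year (directional selection: is the observed decline steeper than drift?) and
the cumulative year-to-year absolute frequency change (balancing selection:
is the observed series unusually *stable*?).

The optional recombination variant destroys a carrier haplotype at each
meiotic transmission with probability r = length_cM / 100 (capped at 0.5),
never re-creating it; it quantifies how much haplotype breakdown alone could
mimic a frequency decline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import Pedigree, UNKNOWN


@dataclass(frozen=True)
class CohortFrequencySeries:
    """Focal-allele frequency per birth cohort, with allele-count denominators."""

    years: np.ndarray
    frequency: np.ndarray
    n_alleles: np.ndarray  # 2 x genotyped individuals per cohort
    label: str = "observed"

    def __post_init__(self):
        if not (len(self.years) == len(self.frequency) == len(self.n_alleles)):
            raise ValueError("series fields must have equal length")


@dataclass
class GeneDropConfig:
    """Cohort logic and simulation size.

    ``first_cohort`` defaults to the earliest year from which every later
    cohort has >= ``min_genotyped_prop`` of individuals genotyped.
    ``n_sampled_cohorts`` initial cohorts seed founder draws from observed
    frequencies; later cohorts are fully simulated. ``recombination_cm`` (if
    set) is the focal haplotype's genetic length, turned into a per-meiosis
    destruction probability.
    """

    first_cohort: Optional[int] = None
    n_sampled_cohorts: int = 3
    n_sims: int = 1000
    seed: Optional[int] = None
    min_genotyped_prop: float = 0.70
    recombination_cm: Optional[float] = None

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.n_sampled_cohorts < 1:
            raise ValueError("need at least one sampled cohort")
        if self.recombination_cm is not None and self.recombination_cm < 0:
            raise ValueError("recombination length must be >= 0 cM")


@dataclass(frozen=True)
class CohortPartition:
    sampled_years: np.ndarray
    simulated_years: np.ndarray
    founder: np.ndarray  # per-pedigree-individual flag

    @property
    def years(self) -> np.ndarray:
        return np.concatenate([self.sampled_years, self.simulated_years])


@dataclass(frozen=True)
class GeneDropSummary:
    """Observed-vs-null summaries over the simulated cohorts.

    ``slope_quantile_low`` is the fraction of simulations whose OLS slope is
    below the observed slope (uniform under the drift null).
    ``directional_quantile`` is the direction-aware version: the fraction of
    simulations *steeper* than observed in the observed slope's own direction
    (identical to ``slope_quantile_low`` for a declining haplotype).
    ``balancing_quantile`` is the fraction of simulations with cumulative
    year-to-year change lower than observed; small values flag unusual
    frequency stability.
    """

    observed_slope: float
    sim_slopes: np.ndarray
    slope_quantile_low: float
    directional_quantile: float
    observed_cumulative_change: float
    sim_cumulative_changes: np.ndarray
    balancing_quantile: float


# ---------------------------------------------------------------------------
# Cohort classification
# ---------------------------------------------------------------------------


def classify_cohorts(ped: Pedigree, config: GeneDropConfig = None) -> CohortPartition:
    """Partition birth years into sampled and simulated cohorts; flag founders.

    The analysis span starts at ``config.first_cohort`` if given, otherwise at
    the earliest year from which all later cohorts meet the genotyped-
    proportion floor. Every cohort in the span must be non-empty.
    """
    config = config or GeneDropConfig()
    years = np.unique(ped.birth_year)
    if config.first_cohort is not None:
        first = int(config.first_cohort)
    else:
        ok = []
        for y in years:
            mask = ped.birth_year == y
            ok.append(ped.genotyped[mask].mean() >= config.min_genotyped_prop)
        ok = np.asarray(ok)
        # earliest year from which the floor holds for every later cohort
        suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
        if not suffix_ok.any():
            raise ValueError("no cohort span satisfies the genotyped-proportion floor")
        first = int(years[np.argmax(suffix_ok)])
    span = np.arange(first, int(years.max()) + 1)
    for y in span:
        if not np.any(ped.birth_year == y):
            raise ValueError(f"empty cohort {y} inside analysis span")
    if len(span) <= config.n_sampled_cohorts:
        raise ValueError("analysis span has no simulated cohorts")
    return CohortPartition(
        sampled_years=span[: config.n_sampled_cohorts],
        simulated_years=span[config.n_sampled_cohorts :],
        founder=ped.founder,
    )


# ---------------------------------------------------------------------------
# Observed series
# ---------------------------------------------------------------------------


def observed_series(ped: Pedigree, dosage: np.ndarray, years: Sequence[int]) -> CohortFrequencySeries:
    """Observed carrier-allele frequency per cohort, over genotyped individuals.

    ``dosage`` is the per-pedigree-individual focal copy number (0/1/2), with
    negative values meaning "no genotype".
    """
    dosage = np.asarray(dosage)
    freqs, denom = [], []
    for y in years:
        mask = (ped.birth_year == y) & ped.genotyped & (dosage >= 0)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"no genotyped individuals in cohort {y}")
        freqs.append(dosage[mask].sum() / (2 * n))
        denom.append(2 * n)
    return CohortFrequencySeries(
        years=np.asarray(years, dtype=np.int64),
        frequency=np.asarray(freqs, dtype=float),
        n_alleles=np.asarray(denom, dtype=np.int64),
        label="observed",
    )


# ---------------------------------------------------------------------------
# The gene drop
# ---------------------------------------------------------------------------


def gene_drop(
    ped: Pedigree,
    dosage: np.ndarray,
    config: GeneDropConfig = None,
    partition: Optional[CohortPartition] = None,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Drift-only simulations of the focal allele down the pedigree.

    Returns one :class:`CohortFrequencySeries` (label ``simulated``) per
    simulation, on the full analysis-span years. Identical config + seed give
    bit-identical output.
    """
    config = config or GeneDropConfig()
    r = 0.0
    if config.recombination_cm is not None:
        r = min(config.recombination_cm / 100.0, 0.5)
    return _drop(ped, dosage, config, partition, rng, r)


def gene_drop_recomb(
    ped: Pedigree,
    dosage: np.ndarray,
    config: GeneDropConfig,
    partition: Optional[CohortPartition] = None,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Gene drop with per-meiosis haplotype destruction (see module docstring)."""
    if config.recombination_cm is None:
        raise ValueError("recombination_cm required for the recombination variant")
    return gene_drop(ped, dosage, config, partition, rng)


def _drop(ped, dosage, config, partition, rng, r) -> list:
    dosage = np.asarray(dosage)
    if partition is None:
        partition = classify_cohorts(ped, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    years = partition.years
    sampled = set(int(y) for y in partition.sampled_years)
    year_set = set(int(y) for y in years)
    n = len(ped)
    n_sims = config.n_sims

    obs = observed_series(ped, dosage, years)
    obs_freq = dict(zip(obs.years.tolist(), obs.frequency.tolist()))

    in_span = np.isin(ped.birth_year, years)
    # simulated allele states: -1 = unassigned / outside span
    alleles = np.full((n_sims, n, 2), -1, dtype=np.int8)

    def parent_available(par_idx: np.ndarray, year: int) -> np.ndarray:
        """Parent has simulated alleles: known, inside span, born strictly earlier."""
        ok = par_idx != UNKNOWN
        safe = np.where(ok, par_idx, 0)
        ok &= in_span[safe] & (ped.birth_year[safe] < year)
        return ok

    def transmit(par_idx: np.ndarray) -> np.ndarray:
        """Mendelian draw from each parent's two simulated alleles, per sim."""
        phase = rng.integers(0, 2, size=(n_sims, len(par_idx)))
        drawn = np.take_along_axis(alleles[:, par_idx, :], phase[:, :, None], axis=2)[:, :, 0]
        if r > 0:
            destroyed = rng.random(size=drawn.shape) < r
            drawn = np.where(destroyed & (drawn == 1), 0, drawn)
        return drawn

    for y in [int(v) for v in years]:
        members = np.flatnonzero(ped.birth_year == y)
        if len(members) == 0:
            continue
        sire_ok = parent_available(ped.sire_idx[members], y)
        dam_ok = parent_available(ped.dam_idx[members], y)
        for side, par_idx, ok in (
            (0, ped.sire_idx[members], sire_ok),
            (1, ped.dam_idx[members], dam_ok),
        ):
            if ok.any():
                alleles[:, members[ok], side] = transmit(par_idx[ok])
        pending = [(members[~sire_ok], 0), (members[~dam_ok], 1)]
        n_pending = sum(len(m) for m, _ in pending)
        if n_pending == 0:
            continue
        if y in sampled:
            freq = np.full(n_sims, obs_freq[y])
        else:
            # frequency in the rest of the cohort: members that inherited both alleles
            full = members[sire_ok & dam_ok]
            if len(full) > 0:
                freq = alleles[:, full, :].mean(axis=(1, 2))
            else:
                prev = [int(v) for v in years if v < y]
                if not prev:
                    raise ValueError(f"cohort {y}: no reference individuals for frequency draw")
                prev_members = np.flatnonzero(np.isin(ped.birth_year, prev))
                freq = alleles[:, prev_members, :].mean(axis=(1, 2))
        for mem, side in pending:
            if len(mem) == 0:
                continue
            draws = rng.random(size=(n_sims, len(mem))) < freq[:, None]
            alleles[:, mem, side] = draws.astype(np.int8)

    # per-sim cohort frequencies over genotyped individuals
    out = []
    freq_mat = np.empty((n_sims, len(years)))
    denom = np.empty(len(years), dtype=np.int64)
    for k, y in enumerate(years):
        mask = (ped.birth_year == y) & ped.genotyped & (dosage >= 0)
        denom[k] = 2 * int(mask.sum())
        freq_mat[:, k] = alleles[:, np.flatnonzero(mask), :].mean(axis=(1, 2))
    for s in range(n_sims):
        out.append(
            CohortFrequencySeries(
                years=np.asarray(years, dtype=np.int64),
                frequency=freq_mat[s].copy(),
                n_alleles=denom.copy(),
                label="simulated",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Selection tests
# ---------------------------------------------------------------------------


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float((xc * y).sum() / (xc**2).sum())


def _restrict(series: CohortFrequencySeries, years: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(series.years, years)
    if np.any(idx >= len(series.years)) or np.any(series.years[idx] != years):
        raise ValueError("series does not cover the requested years")
    return series.frequency[idx]


def _cumulative_change(freq: np.ndarray) -> float:
    return float(np.abs(np.diff(freq)).sum())


def gene_drop_summary(
    observed: CohortFrequencySeries,
    sims: Sequence[CohortFrequencySeries],
    simulated_years: np.ndarray,
) -> GeneDropSummary:
    """Directional and balancing summaries over the simulated-cohort years."""
    yrs = np.asarray(simulated_years, dtype=np.int64)
    obs_f = _restrict(observed, yrs)
    obs_slope = _ols_slope(yrs, obs_f)
    sim_f = np.stack([_restrict(s, yrs) for s in sims])
    xc = yrs - yrs.mean()
    sim_slopes = (sim_f * xc).sum(axis=1) / (xc**2).sum()
    low = float(np.mean(sim_slopes < obs_slope))
    if obs_slope <= 0:
        directional = low
    else:
        directional = float(np.mean(sim_slopes > obs_slope))
    obs_cum = _cumulative_change(obs_f)
    sim_cum = np.abs(np.diff(sim_f, axis=1)).sum(axis=1)
    return GeneDropSummary(
        observed_slope=obs_slope,
        sim_slopes=sim_slopes,
        slope_quantile_low=low,
        directional_quantile=directional,
        observed_cumulative_change=obs_cum,
        sim_cumulative_changes=sim_cum,
        balancing_quantile=float(np.mean(sim_cum < obs_cum)),
    )


def directional_test(
    observed: CohortFrequencySeries,
    sims: Sequence[CohortFrequencySeries],
    simulated_years: np.ndarray,
) -> GeneDropSummary:
    """Slope-based directional-selection comparison (see :class:`GeneDropSummary`)."""
    return gene_drop_summary(observed, sims, simulated_years)


def balancing_test(
    observed: CohortFrequencySeries,
    sims: Sequence[CohortFrequencySeries],
    simulated_years: np.ndarray,
) -> GeneDropSummary:
    """Cumulative-change balancing-selection comparison (see :class:`GeneDropSummary`)."""
    return gene_drop_summary(observed, sims, simulated_years)
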