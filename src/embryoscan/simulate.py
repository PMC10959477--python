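"""Synthetic study-system generator: pedigree, phased genotypes, embedded semi-lethal.

The generator emulates the statistical structure of a long-term,
individually monitored, pedigreed wild sheep population:

* ~29 annual birth cohorts with overlapping generations, a large founder
  pool before the study window plus a small immigrant trickle, so the
  founder proportion per cohort declines over time;
* a few thousand individuals, most genotyped, with lower genotype coverage
  in the pre-study cohorts;
* phased biallelic SNPs on several chromosomes, transmitted by meiosis with
  Poisson crossovers on a genetic map (no interference);
* a focal haplotype (an exact allele string over a SNP window) segregating
  at a configurable founder frequency, whose homozygous conceptuses die
  before birth with probability ``s_embryo`` (the litter is lost, not
  re-drawn — mirroring what a field study would observe) and whose
  heterozygotes may enjoy an additive first-winter survival advantage.

Culled conceptuses never appear in the emitted pedigree or genotypes; they
are recorded only in the :class:`SimTruth` ground truth, so recovery of the
embedded selection by the scan and gene-drop stages can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .io import (
    Pedigree,
    PhasedHaplotypeMatrix,
    SnpMap,
    UNKNOWN,
    write_pedigree,
    write_phased_genotypes,
    write_snp_map,
)


@dataclass
class SimConfig:
    """Generator parameters (defaults give a Soay-like scaled study system).

    Demography: ``n_founders`` pre-study adults, ``founder_trickle`` immigrant
    founders per study year, ``matings_per_year`` dam-sire pairings with
    Poisson(``mean_offspring``) conceptuses each, first-winter survival
    ``juvenile_survival`` and annual adult survival ``adult_survival``.

    Genome: ``n_chromosomes`` x ``snps_per_chromosome`` biallelic SNPs,
    ``cm_per_chromosome`` of genetic map each, founder allele frequencies
    site-wise Uniform(``founder_freq_low``, ``founder_freq_high``).

    Focal haplotype: an exact allele string spanning ``focal_length`` SNPs
    starting at ``focal_start`` on ``focal_chromosome``, carried by exactly
    fraction ``focal_founder_freq`` of founder phases; homozygous conceptuses
    die pre-birth with probability ``s_embryo``; heterozygotes get
    ``het_advantage`` added to first-winter survival probability (clipped).
    """

    n_founders: int = 200
    start_year: int = 1990
    n_years: int = 29
    founder_trickle: int = 2
    matings_per_year: int = 100
    mean_offspring: float = 1.2
    juvenile_survival: float = 0.5
    adult_survival: float = 0.78
    max_age: int = 10

    n_chromosomes: int = 3
    snps_per_chromosome: int = 2000
    bp_per_snp: int = 6000
    cm_per_mb: float = 1.0
    cm_per_chromosome: Optional[float] = None  # derived from physical span if None
    founder_freq_low: float = 0.05
    founder_freq_high: float = 0.95

    focal_chromosome: int = 0  # index into chromosomes
    focal_start: int = 800
    focal_length: int = 400
    focal_founder_freq: float = 0.20
    s_embryo: float = 0.47
    het_advantage: float = 0.0

    genotyped_prop: float = 0.95
    pre_study_genotyped_prop: float = 0.60
    seed: Optional[int] = None

    def __post_init__(self):
        for name in (
            "juvenile_survival",
            "adult_survival",
            "focal_founder_freq",
            "s_embryo",
            "genotyped_prop",
            "pre_study_genotyped_prop",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.focal_chromosome >= self.n_chromosomes:
            raise ValueError("focal chromosome out of range")
        if self.focal_start + self.focal_length > self.snps_per_chromosome:
            raise ValueError("focal window must lie within one chromosome")


@dataclass
class SimTruth:
    """Ground truth of one simulation (culled conceptuses are recorded only here)."""

    focal_chromosome: str
    focal_start: int
    focal_length: int
    focal_string: tuple
    s_embryo: float
    het_advantage: float
    dosage: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    culled: list = field(default_factory=list)  # (year, sire_id, dam_id)

    @property
    def n_culled(self) -> int:
        return len(self.culled)


@dataclass
class SimResult:
    pedigree: Pedigree
    genotypes: Optional[PhasedHaplotypeMatrix]
    snp_map: Optional[SnpMap]
    truth: SimTruth


# ---------------------------------------------------------------------------
# Genome helpers
# ---------------------------------------------------------------------------


def build_snp_map(config: SimConfig) -> SnpMap:
    """Evenly spaced SNPs on a linear genetic map.

    Defaults (6 kb between SNPs, 1 cM/Mb) match a dense-chip study system:
    a 400-SNP window spans ~2.4 Mb and ~2.4 cM, so exact haplotypes survive
    most meioses intact.
    """
    ids, chroms, bps, cms = [], [], [], []
    for c in range(config.n_chromosomes):
        n = config.snps_per_chromosome
        bp = np.arange(1, n + 1, dtype=np.int64) * config.bp_per_snp
        total_cm = (
            config.cm_per_chromosome
            if config.cm_per_chromosome is not None
            else float(bp[-1] - bp[0]) / 1e6 * config.cm_per_mb
        )
        cm = np.linspace(0, total_cm, n)
        ids.extend(f"snp{c + 1}_{j + 1}" for j in range(n))
        chroms.extend([str(c + 1)] * n)
        bps.append(bp)
        cms.append(cm)
    return SnpMap(
        snp_id=np.array(ids),
        chromosome=np.array(chroms),
        position_bp=np.concatenate(bps),
        position_cm=np.concatenate(cms),
    )


class _Meiosis:
    """Gamete formation with Poisson crossovers, positions uniform on the cM map."""

    def __init__(self, snpmap: SnpMap):
        self.slices = list(snpmap.chromosome_slices().values())
        self.cm = [
            np.asarray(snpmap.position_cm[sl]) - float(snpmap.position_cm[sl][0] if sl.stop > sl.start else 0.0)
            for sl in self.slices
        ]
        self.lengths = [float(c[-1]) if len(c) else 0.0 for c in self.cm]
        self.n_snps = len(snpmap)

    def gamete(self, parent_alleles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(self.n_snps, dtype=np.uint8)
        for sl, cm, length in zip(self.slices, self.cm, self.lengths):
            phase = rng.integers(0, 2)
            k = rng.poisson(length / 100.0) if length > 0 else 0
            if k == 0:
                out[sl] = parent_alleles[phase, sl]
                continue
            cuts = np.sort(rng.uniform(0, length, size=k))
            cut_idx = np.searchsorted(cm, cuts, side="right")
            bounds = np.concatenate([[0], cut_idx, [sl.stop - sl.start]])
            seg = np.empty(sl.stop - sl.start, dtype=np.uint8)
            for b in range(len(bounds) - 1):
                lo, hi = bounds[b], bounds[b + 1]
                seg[lo:hi] = parent_alleles[(phase + b) % 2, sl][lo:hi]
            out[sl] = seg
        return out


class _FounderPool:
    """Draws founder haplotypes; allocates the focal string to an exact fraction of phases."""

    def __init__(self, config: SimConfig, snpmap: SnpMap, n_planned_phases: int, rng):
        self.snpmap = snpmap
        self.freqs = rng.uniform(config.founder_freq_low, config.founder_freq_high, size=len(snpmap))
        chrom_sl = snpmap.chromosome_slices()[str(config.focal_chromosome + 1)]
        self.focal_slice = slice(
            chrom_sl.start + config.focal_start,
            chrom_sl.start + config.focal_start + config.focal_length,
        )
        self.focal_string = rng.integers(0, 2, size=config.focal_length).astype(np.uint8)
        n_carrier = int(round(config.focal_founder_freq * n_planned_phases))
        flags = np.zeros(n_planned_phases, dtype=bool)
        flags[:n_carrier] = True
        rng.shuffle(flags)
        self._carrier_flags = list(flags)
        self.f0 = config.focal_founder_freq

    def phase(self, rng) -> np.ndarray:
        hap = (rng.random(len(self.freqs)) < self.freqs).astype(np.uint8)
        carrier = self._carrier_flags.pop() if self._carrier_flags else (rng.random() < self.f0)
        if carrier:
            hap[self.focal_slice] = self.focal_string
        elif np.array_equal(hap[self.focal_slice], self.focal_string):
            # avoid accidental carriers so the planned founder frequency is exact
            flip = rng.integers(0, self.focal_string.size)
            hap[self.focal_slice.start + flip] ^= 1
        return hap


def _focal_dosage_of(alleles: np.ndarray, focal_slice: slice, focal_string: np.ndarray) -> int:
    return int(np.array_equal(alleles[0, focal_slice], focal_string)) + int(
        np.array_equal(alleles[1, focal_slice], focal_string)
    )


# ---------------------------------------------------------------------------
# The integrated simulation
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimResult:
    """Run the full annual-cycle simulation with selection acting in-line.

    Embryonic culling happens at conception (homozygous conceptuses of the
    focal string are lost with probability ``s_embryo`` and never enter the
    pedigree); the heterozygote advantage modifies the first-winter survival
    draw, which controls future breeding opportunity.
    """
    return _simulate(config, rng, with_genotypes=True)


def simulate_pedigree(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimResult:
    """Neutral pedigree only (no genotypes, no selection); truth is a skeleton."""
    return _simulate(config, rng, with_genotypes=False)


def _simulate(config: SimConfig, rng, with_genotypes: bool) -> SimResult:
    if rng is None:
        rng = np.random.default_rng(config.seed)
    snpmap = build_snp_map(config) if with_genotypes else None
    meiosis = _Meiosis(snpmap) if with_genotypes else None
    n_planned = 2 * (config.n_founders + config.founder_trickle * config.n_years)
    pool = _FounderPool(config, snpmap, n_planned, rng) if with_genotypes else None

    ids: list = []
    sire: list = []
    dam: list = []
    byear: list = []
    sex: list = []
    genotyped: list = []
    genomes: list = []
    culled: list = []

    alive: dict = {}  # index -> age at the start of the current year

    def add_individual(ind_sire, ind_dam, year, g_prop, genome) -> int:
        i = len(ids)
        ids.append(f"i{i + 1}")
        sire.append(ind_sire)
        dam.append(ind_dam)
        byear.append(year)
        sex.append("F" if rng.random() < 0.5 else "M")
        genotyped.append(bool(rng.random() < g_prop))
        if with_genotypes:
            genomes.append(genome)
        return i

    def new_founder(year, g_prop) -> int:
        genome = None
        if with_genotypes:
            genome = np.stack([pool.phase(rng), pool.phase(rng)])
        return add_individual(UNKNOWN, UNKNOWN, year, g_prop, genome)

    # pre-study founder adults
    for _ in range(config.n_founders):
        year = config.start_year - 1 - int(rng.integers(0, 6))
        i = new_founder(year, config.pre_study_genotyped_prop)
        alive[i] = config.start_year - byear[i]

    for y in range(config.start_year, config.start_year + config.n_years):
        for _ in range(config.founder_trickle):
            i = new_founder(y, config.genotyped_prop)
            alive[i] = 0
        females = [i for i, a in alive.items() if sex[i] == "F" and a >= 1]
        males = [i for i, a in alive.items() if sex[i] == "M" and a >= 1]
        newborns: list = []
        if females and males:
            n_mat = min(config.matings_per_year, len(females))
            dams = rng.choice(len(females), size=n_mat, replace=False)
            sires = rng.choice(len(males), size=n_mat, replace=True)
            for di, si in zip(dams, sires):
                d_i, s_i = females[di], males[si]
                for _ in range(rng.poisson(config.mean_offspring)):
                    genome = None
                    dos = 0
                    if with_genotypes:
                        genome = np.stack(
                            [meiosis.gamete(genomes[s_i], rng), meiosis.gamete(genomes[d_i], rng)]
                        )
                        dos = _focal_dosage_of(genome, pool.focal_slice, pool.focal_string)
                        if dos == 2 and rng.random() < config.s_embryo:
                            culled.append((y, ids[s_i], ids[d_i]))
                            continue
                    i = add_individual(s_i, d_i, y, config.genotyped_prop, genome)
                    newborns.append((i, dos))
        # survival: first winter for newborns (with het advantage), annual for adults
        survivors: dict = {}
        for i, age in alive.items():
            if age >= config.max_age:
                continue
            if rng.random() < config.adult_survival:
                survivors[i] = age + 1
        for i, dos in newborns:
            p = config.juvenile_survival + (config.het_advantage if dos == 1 else 0.0)
            if rng.random() < min(max(p, 0.0), 1.0):
                survivors[i] = 1
        alive = survivors

    ped = Pedigree(
        ids=np.array(ids),
        sire_idx=np.array(sire, dtype=np.int64),
        dam_idx=np.array(dam, dtype=np.int64),
        birth_year=np.array(byear, dtype=np.int64),
        sex=np.array(sex),
        genotyped=np.array(genotyped, dtype=bool),
    )
    if with_genotypes:
        geno = PhasedHaplotypeMatrix(list(ped.ids), snpmap, np.stack(genomes))
        dosage = np.array(
            [_focal_dosage_of(g, pool.focal_slice, pool.focal_string) for g in genomes],
            dtype=np.int8,
        )
        truth = SimTruth(
            focal_chromosome=str(config.focal_chromosome + 1),
            focal_start=config.focal_start,
            focal_length=config.focal_length,
            focal_string=tuple(int(a) for a in pool.focal_string),
            s_embryo=config.s_embryo,
            het_advantage=config.het_advantage,
            dosage=dosage,
            culled=culled,
        )
        return SimResult(ped, geno, snpmap, truth)
    truth = SimTruth(
        focal_chromosome=str(config.focal_chromosome + 1),
        focal_start=config.focal_start,
        focal_length=config.focal_length,
        focal_string=(),
        s_embryo=0.0,
        het_advantage=0.0,
    )
    return SimResult(ped, None, None, truth)


# ---------------------------------------------------------------------------
# Decomposed operations
# ---------------------------------------------------------------------------


def simulate_genotypes(
    ped: Pedigree, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple:
    """Drop neutral genotypes down an existing pedigree.

    Founder phases carry the focal string at exactly the configured founder
    frequency (deterministic allocation over the founder phase pool); a
    missing parent's gamete is drawn like a founder phase. Returns
    ``(PhasedHaplotypeMatrix, SnpMap, SimTruth)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    snpmap = build_snp_map(config)
    meiosis = _Meiosis(snpmap)
    n_founder_phases = int(ped.founder.sum()) * 2
    pool = _FounderPool(config, snpmap, n_founder_phases, rng)
    order = np.argsort(ped.birth_year, kind="stable")
    genomes: list = [None] * len(ped)
    for i in order:
        phases = []
        for par in (ped.sire_idx[i], ped.dam_idx[i]):
            if par == UNKNOWN or genomes[par] is None:
                phases.append(pool.phase(rng))
            else:
                phases.append(meiosis.gamete(genomes[par], rng))
        genomes[i] = np.stack(phases)
    geno = PhasedHaplotypeMatrix(list(ped.ids), snpmap, np.stack(genomes))
    dosage = np.array(
        [_focal_dosage_of(g, pool.focal_slice, pool.focal_string) for g in genomes],
        dtype=np.int8,
    )
    truth = SimTruth(
        focal_chromosome=str(config.focal_chromosome + 1),
        focal_start=config.focal_start,
        focal_length=config.focal_length,
        focal_string=tuple(int(a) for a in pool.focal_string),
        s_embryo=0.0,
        het_advantage=0.0,
        dosage=dosage,
    )
    return geno, snpmap, truth


def apply_selection(
    ped: Pedigree,
    geno: PhasedHaplotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimResult:
    """Post-hoc embryonic culling on a neutral pedigree + genotypes.

    Each non-founder homozygous for the focal string is removed with
    probability ``s_embryo``; its descendants are removed with it (a conceptus
    that dies pre-birth can leave no offspring). The heterozygote postnatal
    advantage cannot be applied retrospectively to a fixed pedigree (survival
    draws happen inside :func:`simulate_dataset`) and is ignored here.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    order = np.argsort(ped.birth_year, kind="stable")
    removed = np.zeros(len(ped), dtype=bool)
    culled = list(truth.culled)
    for i in order:
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s == UNKNOWN and d == UNKNOWN:
            continue
        if (s != UNKNOWN and removed[s]) or (d != UNKNOWN and removed[d]):
            removed[i] = True
            continue
        if truth.dosage[i] == 2 and rng.random() < config.s_embryo:
            removed[i] = True
            culled.append(
                (
                    int(ped.birth_year[i]),
                    "" if s == UNKNOWN else str(ped.ids[s]),
                    "" if d == UNKNOWN else str(ped.ids[d]),
                )
            )
    keep = ~removed
    old_to_new = np.cumsum(keep) - 1

    def remap(par_idx):
        out = np.full(int(keep.sum()), UNKNOWN, dtype=np.int64)
        j = 0
        for i in range(len(ped)):
            if not keep[i]:
                continue
            p = par_idx[i]
            out[j] = UNKNOWN if p == UNKNOWN or not keep[p] else old_to_new[p]
            j += 1
        return out

    new_ped = Pedigree(
        ids=ped.ids[keep],
        sire_idx=remap(ped.sire_idx),
        dam_idx=remap(ped.dam_idx),
        birth_year=ped.birth_year[keep],
        sex=ped.sex[keep],
        genotyped=ped.genotyped[keep],
    )
    new_geno = PhasedHaplotypeMatrix(
        list(new_ped.ids), geno.snps, geno.alleles[keep]
    )
    new_truth = SimTruth(
        focal_chromosome=truth.focal_chromosome,
        focal_start=truth.focal_start,
        focal_length=truth.focal_length,
        focal_string=truth.focal_string,
        s_embryo=config.s_embryo,
        het_advantage=0.0,
        dosage=truth.dosage[keep],
        culled=culled,
    )
    return SimResult(new_ped, new_geno, geno.snps, new_truth)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------


def emit(result: SimResult, outdir, genotype_format: str = "haps-matrix") -> dict:
    """Write pedigree CSV, genotypes, map TSV and truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "genotypes": outdir / ("genotypes.vcf" if genotype_format == "vcf" else "genotypes.haps"),
        "map": outdir / "map.tsv",
        "truth": outdir / "truth.json",
    }
    write_pedigree(result.pedigree, paths["pedigree"])
    if result.genotypes is not None:
        write_phased_genotypes(result.genotypes, paths["genotypes"], format=genotype_format)
        write_snp_map(result.snp_map, paths["map"])
    t = result.truth
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "focal_chromosome": t.focal_chromosome,
                "focal_start": t.focal_start,
                "focal_length": t.focal_length,
                "focal_string": list(t.focal_string),
                "s_embryo": t.s_embryo,
                "het_advantage": t.het_advantage,
                "dosage": [int(d) for d in np.asarray(t.dosage)],
                "n_culled": t.n_culled,
                "culled": [list(c) for c in t.culled],
            },
            fh,
            indent=1,
        )
    return paths


def focal_dosage(
    geno: PhasedHaplotypeMatrix, ped: Pedigree, truth: SimTruth
) -> np.ndarray:
    """Observed focal carrier dosage aligned to pedigree order; -1 if not genotyped."""
    chrom_sl = geno.snps.chromosome_slices()[truth.focal_chromosome]
    focal = slice(chrom_sl.start + truth.focal_start, chrom_sl.start + truth.focal_start + truth.focal_length)
    string = np.asarray(truth.focal_string, dtype=np.uint8)
    out = np.full(len(ped), -1, dtype=np.int8)
    present = {ind: i for i, ind in enumerate(geno.individuals)}
    for j, ind in enumerate(ped.ids.tolist()):
        if not ped.genotyped[j] or ind not in present:
            continue
        g = geno.alleles[present[ind]]
        out[j] = _focal_dosage_of(g, focal, string)
    return out
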