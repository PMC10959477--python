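"""Homozygous-haplotype-deficiency genome scan.

Recessive embryonic-lethal variation leaves a signature in pedigreed
populations: among offspring of matings where *both* parents carry a focal
haplotype, homozygotes for that haplotype are rarer than Mendelian
expectation. For a focal haplotype the expected number of homozygous
offspring over the carrier-mating trios is

    E_hh = sum_i p_i * q_i

where ``p_i`` and ``q_i`` are the dam's and sire's transmission
probabilities (0.5 if heterozygous, 1 if homozygous for the focal allele
string). The observed count ``O_hh`` is compared with ``E_hh`` by a 1-df
chi-square over the homozygous / non-homozygous split:

    chi2 = (O_hh - E_hh)^2 / E_hh + (O_non - E_non)^2 / E_non

The scan slides fixed-length SNP windows one SNP at a time along each
chromosome, enumerates every haplotype above a population-frequency floor in
each window, and applies the test to each. Genome-wide significance uses a
Bonferroni correction for an *effective* number of tests estimated from the
eigenvalue spectrum of the SNP correlation matrix (a SimpleM-style
procedure), since neighbouring windows and SNPs are strongly correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhasedHaplotypeMatrix, Pedigree, Trio, extract_trios, trio_index_arrays

LOG10 = np.log(10.0)


@dataclass(frozen=True)
class HaplotypeWindow:
    """A run of ``length`` consecutive SNPs on one chromosome.

    ``start`` indexes into the chromosome's SNPs (0-based); bp coordinates are
    the closed interval [first SNP bp, last SNP bp].
    """

    chromosome: str
    start: int
    length: int
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("window length must be >= 2 SNPs")


@dataclass(frozen=True)
class HaplotypeAllele:
    """A specific allele string observed in a window, with its population frequency."""

    window: HaplotypeWindow
    alleles: tuple
    frequency: float

    @property
    def string(self) -> str:
        return "".join(map(str, self.alleles))


@dataclass(frozen=True)
class CarrierTrio:
    """One carrier x carrier mating (per offspring): transmission probs and outcome."""

    trio: Trio
    p: float  # dam transmission probability, 0.5 het / 1.0 hom
    q: float  # sire transmission probability
    offspring_hom: bool


@dataclass(frozen=True)
class DeficiencyTest:
    """Chi-square comparison of observed vs expected homozygote counts."""

    n: int
    e_hom: float
    o_hom: int
    chi2: float
    p: float
    log10_p: float
    percent_fewer: float
    df: int = 1


@dataclass
class ScanConfig:
    """Scan parameters.

    ``window_lengths`` defaults to 100–500 SNPs in steps of 100 (400 is the
    primary length for reporting); ``min_freq`` is the haplotype population
    frequency floor (default 0.1%); the genome-wide threshold is
    ``alpha / m_eff`` where ``m_eff`` may be supplied or estimated via
    :func:`effective_tests_simplem`.
    """

    window_lengths: Sequence[int] = (100, 200, 300, 400, 500)
    slide: int = 1
    min_freq: float = 0.001
    alpha: float = 0.05
    m_eff: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.min_freq <= 0.5):
            raise ValueError("min_freq must be in (0, 0.5]")
        if self.slide < 1:
            raise ValueError("slide must be >= 1")


# ---------------------------------------------------------------------------
# Window haplotype enumeration
# ---------------------------------------------------------------------------


def windows_for_chromosome(snpmap, chromosome: str, length: int, slide: int = 1) -> list:
    """All sliding windows of ``length`` SNPs on one chromosome (may be empty)."""
    sl = snpmap.chromosome_slices()[chromosome]
    n = sl.stop - sl.start
    bp = np.asarray(snpmap.position_bp[sl])
    out = []
    for start in range(0, n - length + 1, slide):
        out.append(
            HaplotypeWindow(
                chromosome=chromosome,
                start=start,
                length=length,
                start_bp=int(bp[start]),
                end_bp=int(bp[start + length - 1]),
            )
        )
    return out


def _window_phase_matrix(geno: PhasedHaplotypeMatrix, window: HaplotypeWindow) -> np.ndarray:
    sl = geno.snps.chromosome_slices()[window.chromosome]
    lo = sl.start + window.start
    return geno.phases()[:, lo : lo + window.length]


def _unique_haplotypes(phase_mat: np.ndarray):
    """Distinct rows with counts and per-phase assignment, ordered by
    descending count then lexicographic allele string.

    Rows are bit-packed before grouping so the sort works on short keys;
    byte-wise order of the packed keys equals lexicographic order of the
    0/1 strings (equal-length rows, zero padding at fixed positions).
    """
    packed = np.packbits(phase_mat.astype(np.uint8, copy=False), axis=1)
    keys = np.ascontiguousarray(packed).view(
        np.dtype((np.void, packed.shape[1]))
    ).ravel()
    _, first_idx, inverse, counts = np.unique(
        keys, return_index=True, return_inverse=True, return_counts=True
    )
    order = np.lexsort((np.arange(len(counts)), -counts))
    uniq = phase_mat[first_idx[order]]
    counts = counts[order]
    remap = np.empty(len(order), dtype=np.int64)
    remap[order] = np.arange(len(order))
    return uniq, remap[inverse], counts


def enumerate_window_haplotypes(
    geno: PhasedHaplotypeMatrix, window: HaplotypeWindow, min_freq: float = 0.001
) -> list:
    """Every distinct allele string in the window with frequency >= ``min_freq``.

    Frequencies are counts over all 2N phase sequences; ordering is
    deterministic (descending frequency, then lexicographic string).
    """
    phase_mat = _window_phase_matrix(geno, window)
    uniq, _, counts = _unique_haplotypes(phase_mat)
    n_phases = phase_mat.shape[0]
    out = []
    for row, c in zip(uniq, counts):
        f = c / n_phases
        if f >= min_freq:
            out.append(HaplotypeAllele(window=window, alleles=tuple(int(a) for a in row), frequency=f))
    return out


def haplotype_dosage(geno: PhasedHaplotypeMatrix, hap: HaplotypeAllele) -> np.ndarray:
    """Per-individual copy number (0/1/2) of the focal allele string."""
    phase_mat = _window_phase_matrix(geno, hap.window)
    match = np.all(phase_mat == np.asarray(hap.alleles, dtype=np.uint8), axis=1)
    return (match[0::2].astype(np.int8) + match[1::2].astype(np.int8))


# ---------------------------------------------------------------------------
# Carrier trios and the deficiency test
# ---------------------------------------------------------------------------


def carrier_trios_for(
    hap: HaplotypeAllele, trios: Sequence[Trio], geno: PhasedHaplotypeMatrix
) -> list:
    """Trios where both parents carry >= 1 copy of the focal allele string.

    Transmission probabilities follow the carrier state: 0.5 for a
    heterozygous parent, 1.0 for a homozygous parent. The offspring is
    classified homozygous only on an exact string match of both phases.
    """
    dosage = haplotype_dosage(geno, hap)
    out = []
    for t in trios:
        d_dam = dosage[geno.index_of(t.dam)]
        d_sire = dosage[geno.index_of(t.sire)]
        if d_dam == 0 or d_sire == 0:
            continue
        out.append(
            CarrierTrio(
                trio=t,
                p=1.0 if d_dam == 2 else 0.5,
                q=1.0 if d_sire == 2 else 0.5,
                offspring_hom=bool(dosage[geno.index_of(t.offspring)] == 2),
            )
        )
    return out


def expected_homozygotes(carriers: Sequence[CarrierTrio]) -> float:
    """Mendelian expectation E_hh = sum_i p_i q_i over carrier-mating trios."""
    if len(carriers) == 0:
        raise ValueError("no carrier matings")
    return float(sum(c.p * c.q for c in carriers))


def deficiency_test(o_hom: int, e_hom: float, n: int) -> DeficiencyTest:
    """1-df chi-square test of the homozygote deficit among n carrier-mating offspring.

    The statistic is two-term (homozygous and non-homozygous classes); the
    p-value is the upper tail of chi-square with one degree of freedom, with
    no continuity correction. ``percent_fewer`` is 100*(1 - O/E).
    """
    if not (0 <= o_hom <= n):
        raise ValueError("o_hom must be in [0, n]")
    if not (0 < e_hom < n):
        raise ValueError("degenerate expected counts: need 0 < e_hom < n")
    e_non = n - e_hom
    o_non = n - o_hom
    chi2 = (o_hom - e_hom) ** 2 / e_hom + (o_non - e_non) ** 2 / e_non
    # log-space tail to stay finite for extreme statistics
    log10_p = stats.chi2.logsf(chi2, df=1) / LOG10
    p = float(np.exp(log10_p * LOG10))
    return DeficiencyTest(
        n=n,
        e_hom=float(e_hom),
        o_hom=int(o_hom),
        chi2=float(chi2),
        p=max(p, np.nextafter(0, 1)),
        log10_p=float(log10_p),
        percent_fewer=float(100.0 * (1.0 - o_hom / e_hom)),
    )


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

SCAN_COLUMNS = [
    "chr",
    "window_start",
    "window_length",
    "start_bp",
    "end_bp",
    "hap_rank",
    "hap_string",
    "frequency",
    "n_trios",
    "e_hom",
    "o_hom",
    "pct_fewer",
    "chi2",
    "p",
    "log10_p",
]


def scan_genome(
    geno: PhasedHaplotypeMatrix,
    ped: Pedigree,
    config: ScanConfig = None,
    trios: Optional[Sequence[Trio]] = None,
) -> pd.DataFrame:
    """Run the deficiency test over all windows x haplotypes.

    Returns one row per (window, haplotype above the frequency floor, >= 1
    carrier mating with non-degenerate expectation), ordered by chromosome,
    window length, window start and haplotype rank. Windows longer than a
    chromosome are skipped.
    """
    config = config or ScanConfig()
    if trios is None:
        trios = extract_trios(ped, geno)
    rows: list = []
    if len(trios) == 0:
        return pd.DataFrame(columns=SCAN_COLUMNS)
    off_idx, sire_idx, dam_idx = trio_index_arrays(trios, geno)
    phases = geno.phases()
    n_phases = phases.shape[0]
    for chrom, sl in geno.snps.chromosome_slices().items():
        n_chr = sl.stop - sl.start
        bp = np.asarray(geno.snps.position_bp[sl])
        for length in config.window_lengths:
            if length > n_chr:
                continue
            for start in range(0, n_chr - length + 1, config.slide):
                sub = phases[:, sl.start + start : sl.start + start + length]
                uniq, inv, counts = _unique_haplotypes(sub)
                inv0, inv1 = inv[0::2], inv[1::2]
                for rank, c in enumerate(counts):
                    freq = c / n_phases
                    if freq < config.min_freq:
                        break  # counts are descending
                    dosage = (inv0 == rank).astype(np.int8) + (inv1 == rank)
                    d_dam = dosage[dam_idx]
                    d_sire = dosage[sire_idx]
                    mask = (d_dam > 0) & (d_sire > 0)
                    n = int(mask.sum())
                    if n == 0:
                        continue
                    p_t = np.where(d_dam[mask] == 2, 1.0, 0.5)
                    q_t = np.where(d_sire[mask] == 2, 1.0, 0.5)
                    e_hom = float((p_t * q_t).sum())
                    o_hom = int((dosage[off_idx][mask] == 2).sum())
                    if not (0 < e_hom < n):
                        continue
                    e_non = n - e_hom
                    chi2 = (o_hom - e_hom) ** 2 / e_hom + (o_hom - e_hom) ** 2 / e_non
                    rows.append(
                        (
                            chrom,
                            start,
                            length,
                            int(bp[start]),
                            int(bp[start + length - 1]),
                            rank,
                            "".join(map(str, uniq[rank])),
                            freq,
                            n,
                            e_hom,
                            o_hom,
                            100.0 * (1.0 - o_hom / e_hom),
                            chi2,
                        )
                    )
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS[:-2])
    if len(df):
        log10_p = stats.chi2.logsf(df["chi2"].to_numpy(), df=1) / LOG10
        df["p"] = np.maximum(np.exp(log10_p * LOG10), np.nextafter(0, 1))
        df["log10_p"] = log10_p
    else:
        df = pd.DataFrame(columns=SCAN_COLUMNS)
    return df


def scan_hits(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Windows passing the genome-wide threshold in the deficit direction (O < E)."""
    if results.empty:
        return results
    return results[(results["p"] < threshold) & (results["o_hom"] < results["e_hom"])]


# ---------------------------------------------------------------------------
# Effective number of tests
# ---------------------------------------------------------------------------


def effective_tests_simplem(
    dosage: np.ndarray, block_size: int = 1000, variance_fraction: float = 0.995
) -> int:
    """SimpleM-style effective number of independent tests among correlated SNPs.

    Per block of consecutive SNPs, compute the SNP-SNP correlation matrix of
    the 0/1/2 dosages and count the smallest number of leading eigenvalues
    whose sum reaches ``variance_fraction`` of the total; sum over blocks.
    Constant SNP columns (undefined correlation) are excluded with a warning.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.ndim != 2 or dosage.shape[1] < 2:
        raise ValueError("need a (individuals x >=2 SNPs) dosage matrix")
    keep = dosage.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant SNP column(s) from M_eff")
        dosage = dosage[:, keep]
    n_snps = dosage.shape[1]
    if n_snps == 0:
        raise ValueError("no variable SNPs")
    if n_snps == 1:
        return 1
    m_eff = 0
    for lo in range(0, n_snps, block_size):
        block = dosage[:, lo : lo + block_size]
        if block.shape[1] == 1:
            m_eff += 1
            continue
        corr = np.corrcoef(block, rowvar=False)
        eigs = np.linalg.eigvalsh(corr)[::-1]
        eigs = np.clip(eigs, 0, None)
        cum = np.cumsum(eigs)
        k = int(np.searchsorted(cum, variance_fraction * cum[-1]) + 1)
        m_eff += min(k, block.shape[1])
    return m_eff


def significance_threshold(m_eff: int, alpha: float = 0.05) -> float:
    """Bonferroni-style genome-wide threshold alpha / M_eff."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    return alpha / m_eff
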