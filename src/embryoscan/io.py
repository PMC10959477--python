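"""Core domain types and file I/O for phased genotypes, pedigrees and linkage maps.

The three inputs every analysis stage shares:

* a :class:`PhasedHaplotypeMatrix` — phased biallelic SNP alleles for a set of
  individuals, two phases each, over an ordered :class:`SnpMap`;
* a :class:`Pedigree` — individuals with (possibly unknown) sire/dam links,
  birth-year cohorts and a genotyped flag;
* parent-offspring :class:`Trio` records extracted from the two above.

Genotypes can be read from phased VCF (via :mod:`cyvcf2`) or from a minimal
"haps-matrix" text format designed so that tiny fixtures are hand-writable:
one header line of SNP ids, then two lines per individual (``<id>_A`` and
``<id>_B``) of space-separated 0/1 allele codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class PedigreeError(ValueError):
    """Raised when a pedigree violates a structural invariant."""


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype input (unphased, multi-allelic, missing)."""


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpMap:
    """Ordered SNP positions on physical (bp) and genetic (cM) maps.

    SNPs must be grouped by chromosome, with bp strictly increasing and cM
    non-decreasing within each chromosome (flat stretches are legal for
    interpolated maps). Positions are 1-based as in VCF.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    position_cm: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        for name in ("chromosome", "position_bp", "position_cm"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpMap field {name!r} length mismatch")
        if len(set(self.snp_id)) != n:
            raise ValueError("duplicate SNP ids in map")
        for chrom, sl in self.chromosome_slices().items():
            bp = np.asarray(self.position_bp[sl])
            cm = np.asarray(self.position_cm[sl])
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom!r}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease on {chrom!r}")
            if np.any(bp < 0) or np.any(cm < 0):
                raise ValueError("negative map position")

    def __len__(self) -> int:
        return len(self.snp_id)

    def chromosome_slices(self) -> dict:
        """Map chromosome -> slice of consecutive SNP indices, in file order."""
        out: dict = {}
        chroms = np.asarray(self.chromosome)
        if len(chroms) == 0:
            return out
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                if chroms[start] in out:
                    raise ValueError(f"chromosome {chroms[start]!r} not contiguous in map")
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def subset(self, index) -> "SnpMap":
        return SnpMap(
            snp_id=np.asarray(self.snp_id)[index],
            chromosome=np.asarray(self.chromosome)[index],
            position_bp=np.asarray(self.position_bp)[index],
            position_cm=np.asarray(self.position_cm)[index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_id,
                "chr": self.chromosome,
                "bp": self.position_bp,
                "cM": self.position_cm,
            }
        )


def read_snp_map(path) -> SnpMap:
    """Read a linkage map TSV with columns ``snp, chr, bp, cM``."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp", "chr", "bp", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    return SnpMap(
        snp_id=df["snp"].astype(str).to_numpy(),
        chromosome=df["chr"].astype(str).to_numpy(),
        position_bp=df["bp"].to_numpy(dtype=np.int64),
        position_cm=df["cM"].to_numpy(dtype=float),
    )


def write_snp_map(snpmap: SnpMap, path) -> None:
    snpmap.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phased genotypes
# ---------------------------------------------------------------------------


@dataclass
class PhasedHaplotypeMatrix:
    """Phased biallelic alleles: shape ``(n_individuals, 2, n_snps)``, codes 0/1.

    ``alleles[i, k, j]`` is the allele carried by individual ``i`` on phase
    ``k`` at SNP ``j``; SNP order follows ``snps``. No missing data after load.
    """

    individuals: list
    snps: SnpMap
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        n_ind, n_phase, n_snp = self.alleles.shape
        if n_phase != 2:
            raise ValueError("exactly two phases per individual required")
        if n_ind != len(self.individuals):
            raise ValueError("individuals / alleles shape mismatch")
        if n_snp != len(self.snps):
            raise ValueError("snps / alleles shape mismatch")
        if len(set(self.individuals)) != n_ind:
            raise ValueError("duplicate individual ids")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("allele codes must be 0/1")
        self._index = {ind: i for i, ind in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[2]

    def index_of(self, individual) -> int:
        return self._index[individual]

    def phases(self) -> np.ndarray:
        """View of shape ``(2N, n_snps)``; rows ``2i`` and ``2i+1`` belong to individual i."""
        return self.alleles.reshape(2 * self.n_individuals, self.n_snps)

    def allele_dosage(self) -> np.ndarray:
        """Per-individual count of the ``1`` allele at each SNP (0/1/2), shape (N, n_snps)."""
        return self.alleles.sum(axis=1, dtype=np.int8)

    def subset_individuals(self, keep: Sequence) -> "PhasedHaplotypeMatrix":
        idx = [self._index[i] for i in keep]
        return PhasedHaplotypeMatrix(list(keep), self.snps, self.alleles[idx])


def read_phased_genotypes(path, format: str = "vcf", allow_missing: bool = False) -> PhasedHaplotypeMatrix:
    """Load phased genotypes from ``vcf`` or ``haps-matrix`` text.

    Parameters
    ----------
    path:
        Input file. VCF may be plain or bgzipped.
    format:
        ``"vcf"`` (phased GT fields, biallelic sites only) or ``"haps-matrix"``.
    allow_missing:
        If False (default) any missing genotype is a hard error. If True,
        individuals with any missing call are dropped with a warning —
        appropriate only for data imputed to near-completeness.
    """
    if format == "vcf":
        return _read_vcf(path, allow_missing)
    if format == "haps-matrix":
        return _read_haps_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path, allow_missing: bool) -> PhasedHaplotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, bps = [], [], []
    columns = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise GenotypeFormatError(
                f"multi-allelic site {variant.CHROM}:{variant.POS} not supported"
            )
        gts = variant.genotypes  # list of [a0, a1, phased]
        col = np.empty((len(samples), 2), dtype=np.int16)
        for i, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                if not allow_missing:
                    raise GenotypeFormatError(
                        f"missing genotype for sample {samples[i]} at "
                        f"{variant.CHROM}:{variant.POS}"
                    )
                col[i] = (-1, -1)
                continue
            if not phased and a0 != a1:
                raise GenotypeFormatError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            col[i] = (a0, a1)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(str(variant.CHROM))
        bps.append(variant.POS)
        columns.append(col)
    if not columns:
        raise GenotypeFormatError("no variants in VCF")
    alleles = np.stack(columns, axis=2)  # (N, 2, n_snps)
    keep = np.all(alleles >= 0, axis=(1, 2))
    if not keep.all():
        dropped = [s for s, k in zip(samples, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} individual(s) with missing genotypes: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
        alleles = alleles[keep]
        samples = [s for s, k in zip(samples, keep) if k]
    snpmap = SnpMap(
        snp_id=np.array(snp_ids),
        chromosome=np.array(chroms),
        position_bp=np.array(bps, dtype=np.int64),
        position_cm=np.zeros(len(bps)),
    )
    return PhasedHaplotypeMatrix(samples, snpmap, alleles.astype(np.uint8))


def _read_haps_matrix(path) -> PhasedHaplotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeFormatError("empty haps-matrix file")
    snp_ids = lines[0].split()
    body = lines[1:]
    if len(body) % 2:
        raise GenotypeFormatError("odd number of phase rows (need two per individual)")
    individuals: list = []
    rows = []
    for i in range(0, len(body), 2):
        tok_a, tok_b = body[i].split(), body[i + 1].split()
        name_a, name_b = tok_a[0], tok_b[0]
        if not (name_a.endswith("_A") and name_b.endswith("_B")):
            raise GenotypeFormatError(f"expected <id>_A / <id>_B rows, got {name_a}, {name_b}")
        if name_a[:-2] != name_b[:-2]:
            raise GenotypeFormatError(f"phase rows {name_a} and {name_b} belong to different ids")
        individuals.append(name_a[:-2])
        for tok in (tok_a, tok_b):
            if len(tok) - 1 != len(snp_ids):
                raise GenotypeFormatError(f"row {tok[0]} has {len(tok)-1} alleles, expected {len(snp_ids)}")
            if any(t not in ("0", "1") for t in tok[1:]):
                raise GenotypeFormatError(f"non-binary allele code in row {tok[0]}")
        rows.append([tok_a[1:], tok_b[1:]])
    alleles = np.array(rows, dtype=np.uint8)
    snpmap = SnpMap(
        snp_id=np.array(snp_ids),
        chromosome=np.array(["0"] * len(snp_ids)),
        position_bp=np.arange(1, len(snp_ids) + 1, dtype=np.int64),
        position_cm=np.zeros(len(snp_ids)),
    )
    return PhasedHaplotypeMatrix(individuals, snpmap, alleles)


def write_phased_genotypes(matrix: PhasedHaplotypeMatrix, path, format: str = "vcf") -> None:
    """Write genotypes as phased VCF or haps-matrix text (round-trips with the reader)."""
    if format == "vcf":
        _write_vcf(matrix, path)
    elif format == "haps-matrix":
        _write_haps_matrix(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(matrix: PhasedHaplotypeMatrix, path) -> None:
    m = matrix.snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sl in m.chromosome_slices().items():
            max_bp = int(np.asarray(m.position_bp[sl]).max())
            fh.write(f"##contig=<ID={chrom},length={max_bp + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in matrix.individuals)
            + "\n"
        )
        for j in range(matrix.n_snps):
            gts = "\t".join(
                f"{matrix.alleles[i, 0, j]}|{matrix.alleles[i, 1, j]}"
                for i in range(matrix.n_individuals)
            )
            fh.write(
                f"{m.chromosome[j]}\t{m.position_bp[j]}\t{m.snp_id[j]}\t"
                f"A\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _write_haps_matrix(matrix: PhasedHaplotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(str(s) for s in matrix.snps.snp_id) + "\n")
        for i, ind in enumerate(matrix.individuals):
            for k, tag in enumerate(("A", "B")):
                fh.write(f"{ind}_{tag} " + " ".join(map(str, matrix.alleles[i, k])) + "\n")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

UNKNOWN = -1


@dataclass
class Pedigree:
    """A validated pedigree: unique ids, acyclic, parents born no later than offspring.

    Unknown parents are encoded as index ``-1``. The ``genotyped`` flag marks
    individuals with usable genotype data; cohort logic downstream operates on
    birth years.
    """

    ids: np.ndarray
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    birth_year: np.ndarray
    sex: np.ndarray
    genotyped: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if len(set(self.ids.tolist())) != n:
            dup = pd.Series(self.ids).value_counts()
            raise PedigreeError(f"duplicate ids: {dup[dup > 1].index.tolist()[:5]}")
        self.sire_idx = np.asarray(self.sire_idx, dtype=np.int64)
        self.dam_idx = np.asarray(self.dam_idx, dtype=np.int64)
        self.birth_year = np.asarray(self.birth_year, dtype=np.int64)
        self.sex = np.asarray(self.sex)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        self._index = {ind: i for i, ind in enumerate(self.ids.tolist())}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.ids)))
        for child in range(len(self.ids)):
            for par in (self.sire_idx[child], self.dam_idx[child]):
                if par != UNKNOWN:
                    g.add_edge(int(par), int(child))
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            names = [str(self.ids[a]) for a, _ in cycle]
            raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(names)}")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, individual) -> int:
        return self._index[individual]

    @property
    def founder(self) -> np.ndarray:
        """Boolean mask: both parents unknown."""
        return (self.sire_idx == UNKNOWN) & (self.dam_idx == UNKNOWN)

    def parents_of(self, individual) -> tuple:
        i = self._index[individual]
        s, d = self.sire_idx[i], self.dam_idx[i]
        return (
            None if s == UNKNOWN else self.ids[s],
            None if d == UNKNOWN else self.ids[d],
        )

    def to_dataframe(self) -> pd.DataFrame:
        def name(idx):
            return ["" if i == UNKNOWN else str(self.ids[i]) for i in idx]

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": name(self.sire_idx),
                "dam": name(self.dam_idx),
                "birth_year": self.birth_year,
                "sex": self.sex,
                "genotyped": self.genotyped.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, strict: bool = True) -> "Pedigree":
        required = {"id", "sire", "dam", "birth_year", "sex"}
        if not required.issubset(df.columns):
            raise PedigreeError(f"pedigree table must have columns {sorted(required)}")
        ids = df["id"].astype(str).to_numpy()
        index = {}
        for i, v in enumerate(ids):
            if v in index:
                raise PedigreeError(f"duplicate id {v!r}")
            index[v] = i

        def parent_idx(col):
            out = np.full(len(df), UNKNOWN, dtype=np.int64)
            for i, v in enumerate(df[col].tolist()):
                if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in ("", "0", "NA", "nan"):
                    continue
                v = str(v)
                if v not in index:
                    raise PedigreeError(f"{col} {v!r} of {ids[i]!r} not in pedigree")
                out[i] = index[v]
            return out

        sire_idx = parent_idx("sire")
        dam_idx = parent_idx("dam")
        birth_year = df["birth_year"].to_numpy(dtype=np.int64)
        for child in range(len(ids)):
            for par in (sire_idx[child], dam_idx[child]):
                if par != UNKNOWN and birth_year[par] > birth_year[child]:
                    msg = (
                        f"parent {ids[par]!r} born {birth_year[par]} after "
                        f"offspring {ids[child]!r} born {birth_year[child]}"
                    )
                    if strict:
                        raise PedigreeError(msg)
                    warnings.warn(msg)
        genotyped = (
            df["genotyped"].astype(bool).to_numpy()
            if "genotyped" in df.columns
            else np.ones(len(df), dtype=bool)
        )
        return cls(ids, sire_idx, dam_idx, birth_year, df["sex"].astype(str).to_numpy(), genotyped)


def read_pedigree(path, strict: bool = True) -> Pedigree:
    """Read a pedigree CSV/TSV with header ``id,sire,dam,birth_year,sex[,genotyped]``."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "sire": str, "dam": str})
    return Pedigree.from_dataframe(df, strict=strict)


def write_pedigree(ped: Pedigree, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    ped.to_dataframe().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Trios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trio:
    """A fully genotyped parent-offspring trio."""

    offspring: str
    sire: str
    dam: str


def extract_trios(ped: Pedigree, geno: PhasedHaplotypeMatrix) -> list:
    """All trios where both parents are known and all three members are genotyped.

    One trio per qualifying offspring; a parent pair with several offspring
    contributes one trio per offspring. Genotyped means flagged in the
    pedigree *and* present in the haplotype matrix.
    """
    present = set(geno.individuals)
    trios = []
    for i, ind in enumerate(ped.ids.tolist()):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s == UNKNOWN or d == UNKNOWN:
            continue
        members = (ind, str(ped.ids[s]), str(ped.ids[d]))
        idxs = (i, int(s), int(d))
        if all(ped.genotyped[j] for j in idxs) and all(m in present for m in members):
            trios.append(Trio(offspring=members[0], sire=members[1], dam=members[2]))
    return trios


def trio_index_arrays(trios: Iterable[Trio], geno: PhasedHaplotypeMatrix) -> tuple:
    """Vectorized trio view: (offspring_idx, sire_idx, dam_idx) into the matrix rows."""
    off = np.array([geno.index_of(t.offspring) for t in trios], dtype=np.int64)
    sire = np.array([geno.index_of(t.sire) for t in trios], dtype=np.int64)
    dam = np.array([geno.index_of(t.dam) for t in trios], dtype=np.int64)
    return off, sire, dam
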