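"""Pedigree genotype I/O and discordant-sib-pair extraction.

Reads PLINK text PED/MAP files, recodes genotypes against the sample-wide
minor allele, extracts one discordant sib pair (DSP; one affected and one
unaffected full sib) per nuclear family, and assigns SNPs to gene intervals.

Genotype codes: 1 = homozygous minor, 2 = heterozygous, 3 = homozygous major,
0 = missing. The minor allele at each SNP is the less frequent allele over
every individual read (ties broken toward the lexicographically smaller
symbol), so coding is deterministic for a fixed file.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = 0

AFFECTED = 2
UNAFFECTED = 1


class PedParseError(ValueError):
    """Malformed PED/MAP/annotation content; carries a line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyCohortError(ValueError):
    """No discordant sib pair could be extracted from the pedigree."""


@dataclass
class PedigreeSample:
    """One individual from a PED file, genotypes already recoded."""

    family_id: str
    individual_id: str
    father_id: str
    mother_id: str
    sex: int
    phenotype: int
    genotypes: np.ndarray  # (n_snps,) int8 codes, 0 = missing

    @property
    def is_founder(self) -> bool:
        return self.father_id == "0" or self.mother_id == "0"

    @property
    def is_affected(self) -> bool:
        return self.phenotype == AFFECTED

    @property
    def is_unaffected(self) -> bool:
        return self.phenotype == UNAFFECTED


@dataclass
class MarkerMap:
    """Per-SNP metadata: chromosome, identifier, position, allele labels.

    ``allele_minor``/``allele_major`` are established from the genotype data;
    a monomorphic SNP has ``allele_minor is None``.
    """

    chromosome: list[str]
    snp_id: list[str]
    position: np.ndarray  # (n_snps,) int64, 1-based bp
    allele_minor: list[str | None] = field(default_factory=list)
    allele_major: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.snp_id)) != len(self.snp_id):
            raise PedParseError("duplicate SNP ids in marker map")
        if np.any(np.asarray(self.position) < 0):
            raise PedParseError("negative bp position in marker map")
        self._index = {s: i for i, s in enumerate(self.snp_id)}

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def index_of(self, snp: int | str) -> int:
        if isinstance(snp, (int, np.integer)):
            return int(snp)
        return self._index[snp]


@dataclass
class DspCohort:
    """Genotype codes for k discordant sib pairs.

    ``aff``/``unaff`` are (k, n_snps) int8 arrays of genotype codes for the
    affected and unaffected sib of each family.
    """

    aff: np.ndarray
    unaff: np.ndarray
    family_ids: list[str]

    @property
    def k(self) -> int:
        return self.aff.shape[0]

    @property
    def n_snps(self) -> int:
        return self.aff.shape[1]


@dataclass
class GeneInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    name: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start {self.start} > end {self.end}")


def _open_text(source):
    """Open a path (plain or .gz) or pass through a file-like object."""
    if hasattr(source, "read"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_map(map_source) -> MarkerMap:
    chroms, ids, pos = [], [], []
    with _open_text(map_source) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PedParseError(
                    f"expected 4 MAP columns, got {len(fields)}", ln
                )
            chroms.append(fields[0])
            ids.append(fields[1])
            try:
                pos.append(int(fields[3]))
            except ValueError as exc:
                raise PedParseError(f"non-integer bp position {fields[3]!r}", ln) from exc
    return MarkerMap(chroms, ids, np.asarray(pos, dtype=np.int64))


def read_ped_map(ped_source, map_source) -> tuple[list[PedigreeSample], MarkerMap]:
    """Read PLINK text PED + MAP and recode genotypes to minor-allele codes.

    The minor allele per SNP is the less frequent allele across every
    individual in the file; ties go to the lexicographically smaller symbol.
    """
    marker_map = read_map(map_source)
    m = marker_map.n_snps

    meta: list[tuple[str, str, str, str, int, int]] = []
    allele_rows: list[list[str]] = []
    with _open_text(ped_source) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise PedParseError(
                    f"expected at least 6 PED columns, got {len(fields)}", ln
                )
            if len(fields) != 6 + 2 * m:
                raise PedParseError(
                    f"expected {6 + 2 * m} columns for {m} SNPs, got {len(fields)}",
                    ln,
                )
            try:
                sex = int(fields[4])
                pheno = int(fields[5])
            except ValueError as exc:
                raise PedParseError("non-integer sex/phenotype field", ln) from exc
            if pheno not in (0, 1, 2, -9):
                raise PedParseError(f"phenotype {pheno} not in {{2,1,0,-9}}", ln)
            meta.append((fields[0], fields[1], fields[2], fields[3], sex, pheno))
            allele_rows.append(fields[6:])

    n = len(meta)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), dtype=object)

    codes = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        counts = Counter(a for a in col.ravel() if a != "0")
        symbols = sorted(counts)  # lexicographic; ties resolved below
        if len(symbols) > 2:
            raise PedParseError(
                f"SNP {marker_map.snp_id[j]} has >2 alleles: {symbols}"
            )
        if not symbols:
            minor, major = None, None
        elif len(symbols) == 1:
            minor, major = None, symbols[0]
        else:
            s1, s2 = symbols
            if counts[s1] <= counts[s2]:
                minor, major = s1, s2
            else:
                minor, major = s2, s1
        marker_map.allele_minor.append(minor)
        marker_map.allele_major.append(major)
        for i in range(n):
            a1, a2 = col[i]
            if a1 == "0" or a2 == "0":
                codes[i, j] = MISSING
            else:
                n_minor = (a1 == minor) + (a2 == minor)
                codes[i, j] = 3 - n_minor

    samples = [
        PedigreeSample(*meta[i], genotypes=codes[i]) for i in range(n)
    ]
    return samples, marker_map


def extract_dsps(samples: list[PedigreeSample]) -> DspCohort:
    """Extract one DSP per nuclear family.

    Sibs are non-founders sharing both parent ids within a family. The pair
    emitted is the first affected and first unaffected sib in file order;
    families without a discordant pair contribute nothing; parents never
    enter the cohort.
    """
    first_aff: dict[tuple, PedigreeSample] = {}
    first_unaff: dict[tuple, PedigreeSample] = {}
    order: list[tuple] = []
    for s in samples:
        if s.is_founder:
            continue
        key = (s.family_id, s.father_id, s.mother_id)
        if key not in first_aff and key not in first_unaff:
            order.append(key)
        if s.is_affected and key not in first_aff:
            first_aff[key] = s
        elif s.is_unaffected and key not in first_unaff:
            first_unaff[key] = s

    aff_rows, unaff_rows, fams = [], [], []
    for key in order:
        if key in first_aff and key in first_unaff:
            aff_rows.append(first_aff[key].genotypes)
            unaff_rows.append(first_unaff[key].genotypes)
            fams.append(key[0])
    if not aff_rows:
        raise EmptyCohortError("no nuclear family contains a discordant sib pair")
    return DspCohort(np.array(aff_rows), np.array(unaff_rows), fams)


def read_gene_intervals(annotation_source, zero_based: bool = False) -> list[GeneInterval]:
    """Read tab-delimited gene intervals (chrom, start, end, name).

    Coordinates are 1-based inclusive by default; ``zero_based=True`` reads
    BED-style 0-based half-open intervals and converts.
    """
    intervals = []
    with _open_text(annotation_source) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise PedParseError(
                    f"expected 4 tab-delimited columns, got {len(fields)}", ln
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PedParseError("non-integer interval bound", ln) from exc
            if zero_based:
                start, end = start + 1, end
            intervals.append(GeneInterval(fields[0], start, end, fields[3]))
    return intervals


def assign_snps_to_genes(
    marker_map: MarkerMap, intervals: list[GeneInterval]
) -> dict[str, set[str]]:
    """Map each SNP id to the set of gene names whose interval contains it.

    Intergenic SNPs are absent from the mapping. A SNP inside overlapping
    genes belongs to all of them. Chromosome names are compared verbatim.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(marker_map.chromosome):
        by_chrom.setdefault(c, []).append(i)
    assignment: dict[str, set[str]] = {}
    for gene in intervals:
        for i in by_chrom.get(gene.chromosome, ()):
            if gene.start <= marker_map.position[i] <= gene.end:
                assignment.setdefault(marker_map.snp_id[i], set()).add(gene.name)
    return assignment
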