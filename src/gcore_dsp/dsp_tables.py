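"""Two-SNP genotype tables for discordant sib pairs and their allelic collapse.

For a SNP pair the affected sibs' genotype combinations form a 3x3 table
(rows: AA/Aa/aa at the first SNP, columns: BB/Bb/bb at the second; uppercase
denotes the minor allele), and likewise for the unaffected sibs. Each 3x3
table collapses to a 2x2 table of phase-unknown allele-pair counts: a
homozygote contributes both of its alleles, so cell (A, B) receives
4*n11 + 2*n12 + 2*n21 + n22 and symmetrically for the other cells. The
double heterozygote contributes weight 1 to every cell since its phase is
unknown. The collapsed total is always 4x the genotype-table total.
"""

from __future__ import annotations

import numpy as np

from .genio import DspCohort

# Minor-allele dosage per genotype code 1,2,3 (index 0 unused).
_DOSE = np.array([0, 2, 1, 0], dtype=np.int64)

# (4, 9) collapse weights: rows (a, b, c, d) = (A&B, a&B, A&b, a&b) allele
# pairs, columns the flattened 3x3 cells (i-1)*3 + (j-1). Cell weight for
# e.g. (A, B) is dose_A(i) * dose_B(j).
def _collapse_matrix() -> np.ndarray:
    w = np.zeros((4, 9))
    for i in range(3):  # genotype code i+1 at SNP1
        for j in range(3):
            da, db = _DOSE[i + 1], _DOSE[j + 1]
            col = 3 * i + j
            w[0, col] = da * db                # A & B
            w[1, col] = (2 - da) * db          # a & B
            w[2, col] = da * (2 - db)          # A & b
            w[3, col] = (2 - da) * (2 - db)    # a & b
    return w


COLLAPSE_WEIGHTS = _collapse_matrix()


def allele_pair_contributions(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Per-individual (a, b, c, d) allele-pair contributions.

    ``g1``/``g2`` are genotype codes 1..3 at the two SNPs. Returns an
    (n, 4) array; summing over individuals gives the collapsed 2x2 table.
    """
    da = _DOSE[g1]
    db = _DOSE[g2]
    return np.stack([da * db, (2 - da) * db, da * (2 - db), (2 - da) * (2 - db)], axis=-1)


def build_genotype_tables(
    cohort: DspCohort, snp1: int, snp2: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Build affected/unaffected 3x3 genotype tables for one SNP pair.

    Families where any of the four genotypes (two sibs x two SNPs) is
    missing are excluded pair-wise. Returns (affected, unaffected, k_used).
    """
    if snp1 == snp2:
        raise ValueError("snp1 and snp2 must differ")
    ga1, ga2 = cohort.aff[:, snp1], cohort.aff[:, snp2]
    gu1, gu2 = cohort.unaff[:, snp1], cohort.unaff[:, snp2]
    mask = (ga1 > 0) & (ga2 > 0) & (gu1 > 0) & (gu2 > 0)
    aff = _tabulate(ga1[mask], ga2[mask])
    unaff = _tabulate(gu1[mask], gu2[mask])
    return aff, unaff, int(mask.sum())


def _tabulate(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (g1 - 1, g2 - 1), 1)
    return table


def collapse_to_allele_table(table3x3: np.ndarray) -> np.ndarray:
    """Collapse a 3x3 genotype table to (a, b, c, d) weighted allele counts."""
    t = np.asarray(table3x3, dtype=np.int64)
    if t.shape != (3, 3) or np.any(t < 0):
        raise ValueError("expected a non-negative 3x3 table")
    return COLLAPSE_WEIGHTS @ t.ravel()
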