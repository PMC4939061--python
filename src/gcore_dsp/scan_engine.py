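"""Genome-wide pairwise scan: pair enumeration, filtering, parallel scoring.

Pairs are enumerated in deterministic map order, scored with the
interaction statistic, and merged back in enumeration order regardless of
the worker count, so a 1-worker and an n-worker run produce identical
output. SNPs failing the minor-allele-frequency filter (computed from the
sibs in the cohort, the analysis units) or monomorphic among sibs are
skipped before enumeration and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .genio import DspCohort, MarkerMap
from .interaction_stat import gdsp_from_codes

PAIR_MODES = ("all_pairs", "between_genes", "chrom_pair", "pair_list")

OUTPUT_COLUMNS = [
    "CHR1", "SNP1", "CHR2", "SNP2", "K_USED",
    "LOG_OR_CASE", "LOG_OR_CTRL", "VAR", "G_DSP", "P", "STATUS",
]


@dataclass
class ScanConfig:
    mode: str = "all_pairs"
    chrom_pair: tuple[str, str] | None = None
    pair_list: list[tuple[str, str]] | None = None
    maf_min: float = 0.01
    report_threshold: float = 1.0
    n_workers: int = 1
    haldane: bool = False

    def __post_init__(self):
        if self.mode not in PAIR_MODES:
            raise ValueError(f"mode must be one of {PAIR_MODES}")
        if self.mode == "chrom_pair" and self.chrom_pair is None:
            raise ValueError("chrom_pair mode requires a chromosome pair")
        if self.mode == "pair_list" and not self.pair_list:
            raise ValueError("pair_list mode requires explicit pairs")
        if not (0 <= self.maf_min < 1):
            raise ValueError("maf_min must lie in [0, 1)")
        if self.n_workers < 1:
            raise ValueError("n_workers must be positive")


def sib_minor_allele_freq(cohort: DspCohort) -> np.ndarray:
    """Frequency of the designated minor allele among all sibs, per SNP."""
    codes = np.concatenate([cohort.aff, cohort.unaff], axis=0)
    dose = np.where(codes > 0, 3 - codes, 0).sum(axis=0)
    n_typed = (codes > 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_typed > 0, dose / (2 * n_typed), np.nan)


def enumerate_pairs(
    marker_map: MarkerMap,
    config: ScanConfig,
    gene_assignment: dict[str, set[str]] | None = None,
    keep: np.ndarray | None = None,
):
    """Yield (i, j) SNP index pairs, i before j in map order.

    ``keep`` masks out filtered SNPs. ``between_genes`` emits pairs where
    both SNPs are genic with disjoint gene sets; ``chrom_pair`` emits cross
    pairs of two chromosomes (each unordered within-chromosome pair once
    when the two chromosomes coincide).
    """
    m = marker_map.n_snps
    if keep is None:
        keep = np.ones(m, dtype=bool)
    idx = [i for i in range(m) if keep[i]]

    if config.mode == "all_pairs":
        yield from combinations(idx, 2)
    elif config.mode == "between_genes":
        if gene_assignment is None:
            raise ValueError("between_genes mode requires a gene assignment")
        genic = [i for i in idx if gene_assignment.get(marker_map.snp_id[i])]
        for i, j in combinations(genic, 2):
            gi = gene_assignment[marker_map.snp_id[i]]
            gj = gene_assignment[marker_map.snp_id[j]]
            if gi.isdisjoint(gj):
                yield i, j
    elif config.mode == "chrom_pair":
        c1, c2 = config.chrom_pair
        if c1 == c2:
            sub = [i for i in idx if marker_map.chromosome[i] == c1]
            yield from combinations(sub, 2)
        else:
            s1 = [i for i in idx if marker_map.chromosome[i] == c1]
            s2 = [i for i in idx if marker_map.chromosome[i] == c2]
            for i in s1:
                for j in s2:
                    yield (i, j) if i < j else (j, i)
    else:  # pair_list
        for a, b in config.pair_list:
            i, j = marker_map.index_of(a), marker_map.index_of(b)
            if keep[i] and keep[j]:
                yield (i, j) if i < j else (j, i)


@dataclass
class ScanResult:
    table: pd.DataFrame
    n_enumerated: int
    n_skipped_snps: int
    skipped_snps: list[str] = field(default_factory=list)


def _score_chunk(cohort: DspCohort, marker_map: MarkerMap, pairs, haldane):
    rows = []
    for i, j in pairs:
        r = gdsp_from_codes(
            cohort.aff[:, i], cohort.aff[:, j],
            cohort.unaff[:, i], cohort.unaff[:, j],
            snp1_id=marker_map.snp_id[i], snp2_id=marker_map.snp_id[j],
            haldane=haldane,
        )
        rows.append((
            marker_map.chromosome[i], r.snp1_id,
            marker_map.chromosome[j], r.snp2_id,
            r.k_used, r.log_or_case, r.log_or_control,
            r.var_log_or_case, r.g_dsp, r.p_value, r.status,
        ))
    return rows


def run_scan(
    cohort: DspCohort,
    marker_map: MarkerMap,
    config: ScanConfig,
    gene_assignment: dict[str, set[str]] | None = None,
) -> ScanResult:
    """Score every enumerated SNP pair; output order and content are
    independent of the worker count."""
    if cohort.k == 0:
        raise ValueError("empty cohort")
    maf = sib_minor_allele_freq(cohort)
    keep = np.isfinite(maf) & (maf >= config.maf_min) & (maf > 0) & (maf < 1)
    skipped = [marker_map.snp_id[i] for i in range(marker_map.n_snps) if not keep[i]]

    pairs = list(enumerate_pairs(marker_map, config, gene_assignment, keep))
    if config.n_workers == 1 or len(pairs) < 64:
        rows = _score_chunk(cohort, marker_map, pairs, config.haldane)
    else:
        n_chunks = config.n_workers * 4
        chunks = [pairs[i::n_chunks] for i in range(n_chunks)]
        results = Parallel(n_jobs=config.n_workers, backend="threading")(
            delayed(_score_chunk)(cohort, marker_map, c, config.haldane) for c in chunks
        )
        # merge back into enumeration order
        merged = {}
        for chunk, res in zip(chunks, results):
            merged.update(dict(zip(chunk, res)))
        rows = [merged[p] for p in pairs]

    table = pd.DataFrame(rows, columns=OUTPUT_COLUMNS)
    return ScanResult(table, n_enumerated=len(pairs), n_skipped_snps=len(skipped),
                      skipped_snps=skipped)


def write_results(result: ScanResult, path, report_threshold: float = 1.0) -> None:
    """Write the scan table as TSV; ``report_threshold`` keeps rows with
    p <= threshold (non-testable rows are always kept)."""
    df = result.table
    if report_threshold < 1.0:
        keep = (df["P"] <= report_threshold) | (df["STATUS"] != "OK")
        df = df[keep]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
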