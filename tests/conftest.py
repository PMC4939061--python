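"""Shared fixtures and an independent brute-force oracle.

The oracle code here deliberately re-derives everything from first
principles (explicit loops over label assignments, dose arithmetic written
out by hand) so it shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from gcore_dsp.genio import DspCohort
from gcore_dsp.simulator import PenetranceModel, SimDesign, haplotype_freqs, simulate_dsp_cohort


def iid_cohort(seed: int, k: int, probs=(0.25, 0.5, 0.25)) -> DspCohort:
    """Cohort with iid genotype codes (no sib correlation); fine for
    algebraic identities that hold for any configuration."""
    rng = np.random.default_rng(seed)
    codes = rng.choice([1, 2, 3], size=(2, k, 2), p=list(probs)).astype(np.int8)
    return DspCohort(codes[0], codes[1], [f"F{i}" for i in range(k)])


def sib_cohort(seed: int, k: int, maf: float = 0.4) -> DspCohort:
    """Realistic cohort: full sibs under the null, kinship correlation 0.5."""
    design = SimDesign(k, haplotype_freqs(maf, maf, 0.0), PenetranceModel(0.0), 0.5)
    return simulate_dsp_cohort(design, np.random.default_rng(seed))


# ---------------------------------------------------------------- oracle --

def oracle_allele_table(g1: int, g2: int) -> tuple[float, float, float, float]:
    """(a, b, c, d) allele-pair contribution of one individual, from scratch:
    a genotype code 1/2/3 carries 2/1/0 copies of the minor allele."""
    minor1 = {1: 2, 2: 1, 3: 0}[g1]
    minor2 = {1: 2, 2: 1, 3: 0}[g2]
    major1, major2 = 2 - minor1, 2 - minor2
    return (
        minor1 * minor2,  # A & B
        major1 * minor2,  # a & B
        minor1 * major2,  # A & b
        major1 * major2,  # a & b
    )


def oracle_log_or(cells) -> float:
    a, b, c, d = cells
    return math.log(a) - math.log(b) - math.log(c) + math.log(d)


def oracle_enumerate(cohort: DspCohort, snp1: int = 0, snp2: int = 1):
    """Enumerate all 2^k within-family label assignments by explicit loops.

    Returns a dict with the 9x9 cell-count covariance over ALL assignments
    and the log-OR moments over assignments with all eight cells positive.
    """
    pairs = []
    for s in range(cohort.k):
        ga = (int(cohort.aff[s, snp1]), int(cohort.aff[s, snp2]))
        gu = (int(cohort.unaff[s, snp1]), int(cohort.unaff[s, snp2]))
        if 0 in ga or 0 in gu:
            continue
        pairs.append((ga, gu))
    k = len(pairs)

    cell_counts = []  # 9-vector of affected-table cell counts per assignment
    lor_case, lor_ctrl = [], []
    for labels in itertools.product((0, 1), repeat=k):
        cells9 = [0] * 9
        case = [0.0] * 4
        ctrl = [0.0] * 4
        for (ga, gu), flip in zip(pairs, labels):
            aff_g, un_g = (gu, ga) if flip else (ga, gu)
            cells9[3 * (aff_g[0] - 1) + (aff_g[1] - 1)] += 1
            wa = oracle_allele_table(*aff_g)
            wu = oracle_allele_table(*un_g)
            for t in range(4):
                case[t] += wa[t]
                ctrl[t] += wu[t]
        cell_counts.append(cells9)
        if min(case) > 0 and min(ctrl) > 0:
            lor_case.append(oracle_log_or(case))
            lor_ctrl.append(oracle_log_or(ctrl))

    cells = np.array(cell_counts, dtype=float)
    lc = np.array(lor_case)
    lu = np.array(lor_ctrl)
    return {
        "cell_cov": np.cov(cells.T, bias=True),
        "var_log_or_case": lc.var() if lc.size else 0.0,
        "var_log_or_control": lu.var() if lu.size else 0.0,
        "cov_case_control": float(np.mean((lc - lc.mean()) * (lu - lu.mean()))) if lc.size else 0.0,
        "diff": lc - lu,
        "n_valid": int(lc.size),
        "n_total": 2**k,
    }


@pytest.fixture(scope="session")
def small_sib_cohort() -> DspCohort:
    return sib_cohort(2024, 8, maf=0.5)
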