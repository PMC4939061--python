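"""The discordant-sib-pair odds-ratio interaction statistic.

For a SNP pair, the log odds ratio of the collapsed affected allele table,
log(OR_case) = log a - log b - log c + log d, is contrasted with the same
quantity from the unaffected sibs. Under the null of no interaction the
affected label within each family is exchangeable between the two sibs
(a draw of 1 of 2 without replacement, i.e. the per-family cell counts
follow a multivariate hypergeometric distribution), which makes the two
log odds ratios perfectly anticorrelated:

    Cov(log OR_case, log OR_control) = -Var(log OR_case)
                                     = -Var(log OR_control)

so the variance of their difference is 4 * Var(log OR_case) and the test
statistic is

    G = [log(OR_case) - log(OR_control)] / sqrt(4 * Var(log OR_case))

referred to the standard normal (two-sided). Var(log OR_case) is computed
by the delta method: the collapsed cells (a, b, c, d) are linear in the
per-family genotype-cell counts, whose covariance under the label-swap
null is (1/4) * sum_s (e_u - e_v)(e_u - e_v)^T over discordant-genotype
families; the gradient of log OR is evaluated at the observed counts.

``permutation_oracle`` enumerates (or samples) the within-family label
swaps directly and serves as an independent check of the variance and of
the covariance identity above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .dsp_tables import (
    COLLAPSE_WEIGHTS,
    allele_pair_contributions,
    build_genotype_tables,
    collapse_to_allele_table,
)
from .genio import DspCohort

STATUS_OK = "OK"
ZERO_CELL = "NOT_TESTABLE(ZERO_CELL)"
DEGENERATE = "NOT_TESTABLE(DEGENERATE)"
NO_FAMILIES = "NOT_TESTABLE(NO_FAMILIES)"


class NotTestableError(ValueError):
    def __init__(self, status: str):
        super().__init__(status)
        self.status = status


@dataclass
class InteractionResult:
    """Outcome of the interaction test for one SNP pair."""

    snp1_id: str
    snp2_id: str
    k_used: int
    log_or_case: float
    log_or_control: float
    var_log_or_case: float
    g_dsp: float
    p_value: float
    status: str = STATUS_OK

    @property
    def testable(self) -> bool:
        return self.status == STATUS_OK


@dataclass
class FamilyConfig:
    """Per-family 3x3 cell indices of the affected (u) and unaffected (v) sib.

    ``u``/``v`` are (k,) arrays of flattened cell indices in 0..8
    (cell (i, j) of the genotype table -> 3*(i-1) + (j-1)).
    """

    u: np.ndarray
    v: np.ndarray

    @property
    def k(self) -> int:
        return len(self.u)


def family_config(cohort: DspCohort, snp1: int, snp2: int) -> FamilyConfig:
    """Cell-index configuration for a SNP pair, dropping missing families."""
    ga1, ga2 = cohort.aff[:, snp1], cohort.aff[:, snp2]
    gu1, gu2 = cohort.unaff[:, snp1], cohort.unaff[:, snp2]
    mask = (ga1 > 0) & (ga2 > 0) & (gu1 > 0) & (gu2 > 0)
    u = 3 * (ga1[mask].astype(np.int64) - 1) + (ga2[mask] - 1)
    v = 3 * (gu1[mask].astype(np.int64) - 1) + (gu2[mask] - 1)
    return FamilyConfig(u, v)


def odds_ratio(allele_table: np.ndarray) -> float:
    """ad/(bc) of a collapsed (a, b, c, d) table; all four cells must be > 0."""
    a, b, c, d = np.asarray(allele_table, dtype=float)
    if min(a, b, c, d) <= 0:
        raise NotTestableError(ZERO_CELL)
    return (a * d) / (b * c)


def null_cell_covariance(config: FamilyConfig) -> np.ndarray:
    """9x9 covariance of the affected-table cell counts under the null.

    Each family contributes (1/4)(e_u - e_v)(e_u - e_v)^T; families whose
    sibs share the same two-SNP genotype contribute zero.
    """
    k = config.k
    d = np.zeros((k, 9))
    rows = np.arange(k)
    np.add.at(d, (rows, config.u), 1.0)
    np.add.at(d, (rows, config.v), -1.0)
    return 0.25 * (d.T @ d)


def var_log_or_case(affected3x3: np.ndarray, config: FamilyConfig) -> float:
    """Delta-method variance of log OR_case under the label-swap null.

    The collapsed cells are linear in the affected-table cell counts; the
    log-OR gradient is evaluated at the null expectation of those cells
    (half the combined affected+unaffected table), which makes the variance
    identical for the case and control log odds ratios.
    """
    if min(collapse_to_allele_table(affected3x3)) <= 0:
        raise NotTestableError(ZERO_CELL)
    r_half = np.zeros(9)
    np.add.at(r_half, config.u, 0.5)
    np.add.at(r_half, config.v, 0.5)
    mid = COLLAPSE_WEIGHTS @ r_half
    grad = COLLAPSE_WEIGHTS.T @ (np.array([1.0, -1.0, -1.0, 1.0]) / mid)
    var = float(grad @ null_cell_covariance(config) @ grad)
    if var <= 0:
        raise NotTestableError(DEGENERATE)
    return var


def _log_or(cells: np.ndarray) -> float:
    a, b, c, d = cells
    return float(np.log(a) - np.log(b) - np.log(c) + np.log(d))


def gdsp_from_codes(
    ga1: np.ndarray,
    ga2: np.ndarray,
    gu1: np.ndarray,
    gu2: np.ndarray,
    *,
    snp1_id: str = "",
    snp2_id: str = "",
    haldane: bool = False,
) -> InteractionResult:
    """Compute the interaction statistic from per-family genotype codes.

    This is the vectorized core used by the scan engine and the simulation
    experiments; ``gdsp`` is the table-level entry point.
    """
    mask = (ga1 > 0) & (ga2 > 0) & (gu1 > 0) & (gu2 > 0)
    k_used = int(mask.sum())
    nan = float("nan")
    if k_used == 0:
        return InteractionResult(snp1_id, snp2_id, 0, nan, nan, nan, nan, nan, NO_FAMILIES)

    wu = allele_pair_contributions(ga1[mask], ga2[mask]).astype(float)
    wv = allele_pair_contributions(gu1[mask], gu2[mask]).astype(float)
    case = wu.sum(axis=0)
    ctrl = wv.sum(axis=0)
    if haldane:
        case = case + 0.5
        ctrl = ctrl + 0.5
    if min(case.min(), ctrl.min()) <= 0:
        return InteractionResult(snp1_id, snp2_id, k_used, nan, nan, nan, nan, nan, ZERO_CELL)

    delta = wu - wv
    cov4 = 0.25 * (delta.T @ delta)  # = W @ null_cell_covariance @ W.T
    # gradient at the null expectation (R/2 table): keeps the variance
    # identical for cases and controls, so |G| is exactly invariant under
    # swapping the affected/unaffected labels
    grad = np.array([1.0, -1.0, -1.0, 1.0]) / (0.5 * (case + ctrl))
    var = float(grad @ cov4 @ grad)
    lor_case = _log_or(case)
    lor_ctrl = _log_or(ctrl)
    if var <= 0:
        return InteractionResult(
            snp1_id, snp2_id, k_used, lor_case, lor_ctrl, var, nan, nan, DEGENERATE
        )
    g = (lor_case - lor_ctrl) / np.sqrt(4.0 * var)
    p = 2.0 * float(ndtr(-abs(g)))
    return InteractionResult(snp1_id, snp2_id, k_used, lor_case, lor_ctrl, var, float(g), p)


def gdsp(
    affected3x3: np.ndarray,
    unaffected3x3: np.ndarray,
    config: FamilyConfig,
    *,
    snp1_id: str = "",
    snp2_id: str = "",
    haldane: bool = False,
) -> InteractionResult:
    """Interaction statistic from the two genotype tables and the family config."""
    nan = float("nan")
    k_used = config.k
    case = collapse_to_allele_table(affected3x3).astype(float)
    ctrl = collapse_to_allele_table(unaffected3x3).astype(float)
    if haldane:
        case = case + 0.5
        ctrl = ctrl + 0.5
    if min(case.min(), ctrl.min()) <= 0:
        return InteractionResult(snp1_id, snp2_id, k_used, nan, nan, nan, nan, nan, ZERO_CELL)
    grad = COLLAPSE_WEIGHTS.T @ (np.array([1.0, -1.0, -1.0, 1.0]) / (0.5 * (case + ctrl)))
    var = float(grad @ null_cell_covariance(config) @ grad)
    lor_case = _log_or(case)
    lor_ctrl = _log_or(ctrl)
    if var <= 0:
        return InteractionResult(
            snp1_id, snp2_id, k_used, lor_case, lor_ctrl, var, nan, nan, DEGENERATE
        )
    g = (lor_case - lor_ctrl) / np.sqrt(4.0 * var)
    p = 2.0 * float(ndtr(-abs(g)))
    return InteractionResult(snp1_id, snp2_id, k_used, lor_case, lor_ctrl, var, float(g), p)


def score_pair(
    cohort: DspCohort,
    snp1: int | str,
    snp2: int | str,
    *,
    snp1_id: str = "",
    snp2_id: str = "",
    haldane: bool = False,
) -> InteractionResult:
    """Run the interaction test for one SNP pair of a cohort."""
    return gdsp_from_codes(
        cohort.aff[:, snp1],
        cohort.aff[:, snp2],
        cohort.unaff[:, snp1],
        cohort.unaff[:, snp2],
        snp1_id=snp1_id or str(snp1),
        snp2_id=snp2_id or str(snp2),
        haldane=haldane,
    )


@dataclass
class OracleResult:
    """Moments of the within-family label-swap null, by direct permutation."""

    mean_log_or_case: float
    var_log_or_case: float
    var_log_or_control: float
    cov_case_control: float
    p_empirical: float
    n_assignments: int
    n_valid: int  # assignments with all eight collapsed cells positive


MAX_EXHAUSTIVE_K = 20


def permutation_oracle(
    cohort: DspCohort,
    snp1: int,
    snp2: int,
    mode: str = "exhaustive",
    n_perm: int = 10000,
    seed: int | None = None,
) -> OracleResult:
    """Permutation reference for the null moments of the log odds ratios.

    Swaps the affected/unaffected labels within families: ``exhaustive``
    enumerates all 2^k assignments with equal weight (k <= 20),
    ``monte_carlo`` samples ``n_perm`` assignments. Assignments producing a
    zero collapsed cell are dropped from the moment computation; the
    empirical p is the fraction of valid assignments whose |log OR_case -
    log OR_control| is at least the observed value.
    """
    ga1, ga2 = cohort.aff[:, snp1], cohort.aff[:, snp2]
    gu1, gu2 = cohort.unaff[:, snp1], cohort.unaff[:, snp2]
    mask = (ga1 > 0) & (ga2 > 0) & (gu1 > 0) & (gu2 > 0)
    wu = allele_pair_contributions(ga1[mask], ga2[mask]).astype(float)
    wv = allele_pair_contributions(gu1[mask], gu2[mask]).astype(float)
    k = wu.shape[0]
    base = wv.sum(axis=0)
    total = base + wu.sum(axis=0)
    delta = wu - wv

    if mode == "exhaustive":
        if k > MAX_EXHAUSTIVE_K:
            raise ValueError(
                f"exhaustive enumeration limited to k <= {MAX_EXHAUSTIVE_K}, got {k}"
            )
        n = 1 << k
        bits = (np.arange(n)[:, None] >> np.arange(k)[None, :]) & 1
    elif mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        n = n_perm
        bits = rng.integers(0, 2, size=(n, k))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cases = base[None, :] + bits @ delta
    ctrls = total[None, :] - cases
    valid = (cases > 0).all(axis=1) & (ctrls > 0).all(axis=1)
    cases, ctrls = cases[valid], ctrls[valid]
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise NotTestableError(ZERO_CELL)

    sign = np.array([1.0, -1.0, -1.0, 1.0])
    lor_case = np.log(cases) @ sign
    lor_ctrl = np.log(ctrls) @ sign
    diff = lor_case - lor_ctrl

    observed = score_pair(cohort, snp1, snp2)
    if not observed.testable:
        raise NotTestableError(observed.status)
    obs_diff = observed.log_or_case - observed.log_or_control
    p_emp = float(np.mean(np.abs(diff) >= abs(obs_diff) - 1e-12))

    return OracleResult(
        mean_log_or_case=float(lor_case.mean()),
        var_log_or_case=float(lor_case.var()),
        var_log_or_control=float(lor_ctrl.var()),
        cov_case_control=float(np.cov(lor_case, lor_ctrl, bias=True)[0, 1]),
        p_empirical=p_emp,
        n_assignments=n,
        n_valid=n_valid,
    )
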