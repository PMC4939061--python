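"""The interaction statistic: variance model, oracle agreement, symmetries."""

import numpy as np
import pytest
from scipy.stats import norm

from gcore_dsp.dsp_tables import build_genotype_tables
from gcore_dsp.genio import DspCohort
from gcore_dsp.interaction_stat import (
    DEGENERATE,
    ZERO_CELL,
    FamilyConfig,
    NotTestableError,
    family_config,
    gdsp,
    null_cell_covariance,
    odds_ratio,
    permutation_oracle,
    score_pair,
    var_log_or_case,
)

from conftest import iid_cohort, oracle_enumerate, sib_cohort


def _cohort(aff_rows, unaff_rows):
    return DspCohort(
        np.array(aff_rows, dtype=np.int8),
        np.array(unaff_rows, dtype=np.int8),
        [f"F{i}" for i in range(len(aff_rows))],
    )


@pytest.mark.parametrize(
    "cells, expected", [((2, 1, 1, 2), 4.0), ((9, 9, 9, 9), 1.0)]
)
def test_odds_ratio_values(cells, expected):
    assert odds_ratio(np.array(cells)) == pytest.approx(expected)


def test_odds_ratio_zero_cell_not_testable():
    with pytest.raises(NotTestableError) as err:
        odds_ratio(np.array([20, 0, 0, 0]))
    assert err.value.status == ZERO_CELL


def test_cell_covariance_concordant_family_is_zero():
    cfg = FamilyConfig(np.array([0]), np.array([0]))  # both sibs (AA, BB)
    assert np.all(null_cell_covariance(cfg) == 0)


def test_cell_covariance_single_discordant_family():
    # affected (AA,BB) cell 0, unaffected (aa,bb) cell 8: one fair Bernoulli split
    cfg = FamilyConfig(np.array([0]), np.array([8]))
    cov = null_cell_covariance(cfg)
    expected = np.zeros((9, 9))
    expected[0, 0] = expected[8, 8] = 0.25
    expected[0, 8] = expected[8, 0] = -0.25
    assert np.allclose(cov, expected)


def test_cell_covariance_matches_exhaustive_enumeration():
    cohort = iid_cohort(11, 10)
    cfg = family_config(cohort, 0, 1)
    oracle = oracle_enumerate(cohort)
    assert np.allclose(null_cell_covariance(cfg), oracle["cell_cov"], atol=1e-12)


def test_variance_scaling_with_family_multiplicity():
    cohort = sib_cohort(40, 10, maf=0.5)
    aff, _, _ = build_genotype_tables(cohort, 0, 1)
    base = var_log_or_case(aff, family_config(cohort, 0, 1))
    for m in (2, 4):
        rep = DspCohort(
            np.tile(cohort.aff, (m, 1)), np.tile(cohort.unaff, (m, 1)),
            [f"F{i}" for i in range(m * cohort.k)],
        )
        aff_m, _, _ = build_genotype_tables(rep, 0, 1)
        v = var_log_or_case(aff_m, family_config(rep, 0, 1))
        assert v == pytest.approx(base / m, rel=1e-9)


def test_variance_degenerate_when_all_families_concordant():
    c = _cohort([[1, 2], [2, 2]], [[1, 2], [2, 2]])
    aff, _, _ = build_genotype_tables(c, 0, 1)
    with pytest.raises(NotTestableError) as err:
        var_log_or_case(aff, family_config(c, 0, 1))
    assert err.value.status in (DEGENERATE, ZERO_CELL)


def test_variance_tracks_exhaustive_permutation_variance():
    """Delta variance approximates the enumerated variance at k=8; the
    residual is the curvature of log at small cell counts, so the check is
    on the typical (median) relative error over cohorts."""
    errs = []
    for seed in range(60):
        cohort = sib_cohort(100 + seed, 8, maf=0.5)
        res = score_pair(cohort, 0, 1)
        if not res.testable:
            continue
        oracle = oracle_enumerate(cohort)
        if oracle["n_valid"] < oracle["n_total"] * 0.95:
            continue
        errs.append(
            abs(res.var_log_or_case - oracle["var_log_or_case"])
            / oracle["var_log_or_case"]
        )
        if len(errs) >= 15:
            break
    assert len(errs) >= 15
    assert np.median(errs) < 0.2


def test_gdsp_zero_when_tables_identical():
    # mirrored families: affected and unaffected genotype tables coincide
    aff = [[1, 1], [2, 2]]
    unaff = [[2, 2], [1, 1]]
    c = _cohort(aff, unaff)
    res = score_pair(c, 0, 1)
    assert res.testable
    assert res.g_dsp == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_gdsp_p_value_is_two_sided_normal_tail():
    cohort = sib_cohort(7, 60, maf=0.4)
    res = score_pair(cohort, 0, 1)
    assert res.testable
    assert res.p_value == pytest.approx(2 * norm.sf(abs(res.g_dsp)), rel=1e-12)


def test_gdsp_agrees_with_table_level_entry_point():
    cohort = sib_cohort(8, 30, maf=0.4)
    aff, unaff, _ = build_genotype_tables(cohort, 0, 1)
    via_tables = gdsp(aff, unaff, family_config(cohort, 0, 1))
    via_codes = score_pair(cohort, 0, 1)
    assert via_tables.g_dsp == pytest.approx(via_codes.g_dsp, rel=1e-12)
    assert via_tables.var_log_or_case == pytest.approx(via_codes.var_log_or_case, rel=1e-12)


def test_gdsp_matches_oracle_z_score():
    """G approximates the enumeration z-score (observed difference over the
    permutation standard deviation of the difference)."""
    cohort = sib_cohort(2024, 8, maf=0.5)
    res = score_pair(cohort, 0, 1)
    assert res.testable
    oracle = oracle_enumerate(cohort)
    z = (res.log_or_case - res.log_or_control) / np.sqrt(oracle["diff"].var())
    assert res.g_dsp == pytest.approx(z, rel=0.35)


# ------------------------------------------------------------- oracle op --

def test_permutation_oracle_concordant_cohort_degenerate():
    c = _cohort([[1, 2], [2, 1], [2, 2]], [[1, 2], [2, 1], [2, 2]])
    with pytest.raises(NotTestableError):
        permutation_oracle(c, 0, 1)


def test_permutation_oracle_matches_independent_enumeration():
    cohort = sib_cohort(55, 9, maf=0.5)
    if not score_pair(cohort, 0, 1).testable:
        pytest.skip("degenerate draw")
    o = permutation_oracle(cohort, 0, 1)
    ref = oracle_enumerate(cohort)
    assert o.n_valid == ref["n_valid"]
    assert o.var_log_or_case == pytest.approx(ref["var_log_or_case"], rel=1e-9)
    assert o.cov_case_control == pytest.approx(ref["cov_case_control"], rel=1e-9, abs=1e-12)


def test_permutation_oracle_case_control_variances_equal():
    # the valid label-swap set is closed under complementation, so the two
    # log odds ratios have exactly the same null distribution
    for seed in (1, 2, 3):
        cohort = sib_cohort(300 + seed, 10, maf=0.4)
        if not score_pair(cohort, 0, 1).testable:
            continue
        o = permutation_oracle(cohort, 0, 1)
        assert o.var_log_or_case == pytest.approx(o.var_log_or_control, rel=1e-9)


def test_permutation_oracle_monte_carlo_deterministic():
    cohort = sib_cohort(77, 15, maf=0.4)
    o1 = permutation_oracle(cohort, 0, 1, mode="monte_carlo", n_perm=500, seed=9)
    o2 = permutation_oracle(cohort, 0, 1, mode="monte_carlo", n_perm=500, seed=9)
    assert o1 == o2


def test_permutation_oracle_refuses_large_exhaustive():
    cohort = sib_cohort(78, 21, maf=0.4)
    with pytest.raises(ValueError, match="k <= 20"):
        permutation_oracle(cohort, 0, 1, mode="exhaustive")


# ----------------------------------------------------------- symmetries --

def _flip_snp(codes, j):
    out = codes.copy()
    m = out[:, j] > 0
    out[m, j] = 4 - out[m, j]
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_exact_symmetries(seed):
    cohort = sib_cohort(500 + seed, 50, maf=0.3)
    res = score_pair(cohort, 0, 1)
    if not res.testable:
        pytest.skip("degenerate draw")

    # swapping affected/unaffected labels in every family negates G exactly
    swapped = DspCohort(cohort.unaff.copy(), cohort.aff.copy(), cohort.family_ids)
    res_swap = score_pair(swapped, 0, 1)
    assert res_swap.g_dsp == pytest.approx(-res.g_dsp, rel=1e-12)
    assert res_swap.p_value == pytest.approx(res.p_value, rel=1e-12)

    # recoding minor<->major at one SNP negates G exactly
    flipped = DspCohort(_flip_snp(cohort.aff, 0), _flip_snp(cohort.unaff, 0), cohort.family_ids)
    res_flip = score_pair(flipped, 0, 1)
    assert res_flip.g_dsp == pytest.approx(-res.g_dsp, rel=1e-12)

    # SNP order is immaterial
    res_rev = score_pair(cohort, 1, 0)
    assert res_rev.g_dsp == pytest.approx(res.g_dsp, rel=1e-12)
    assert res_rev.var_log_or_case == pytest.approx(res.var_log_or_case, rel=1e-12)
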