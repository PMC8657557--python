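"""t-test/BH oracle parity, rescue-filter rules, planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import bh_reject, bh_stepup, pooled_ttest

from pemt import (
    SimulationConfig,
    annotate_genes,
    bh_fdr,
    generate_manifest,
    generate_methylation_dataset,
    identify_rescue_sites,
    run_qc,
    ttest_probes,
)
from conftest import build_dataset


def test_worked_example_matches_textbook_values(two_group_dataset):
    res = ttest_probes(two_group_dataset, "A", "B")
    row = res.iloc[0]
    # A=(0.1,0.2,0.3), B=(0.4,0.5,0.6): t(A vs B) = -3.674, delta_beta = +0.3
    assert row["t_statistic"] == pytest.approx(-3.674, abs=1e-3)
    assert row["degrees_of_freedom"] == 4
    assert row["p_value"] == pytest.approx(0.0213, abs=2e-4)
    assert row["delta_beta"] == pytest.approx(0.3)


def test_identical_groups_give_t0_p1():
    beta = pd.DataFrame(
        [[0.2, 0.4, 0.6, 0.2, 0.4, 0.6]], index=["p0"],
        columns=[f"A_{i}" for i in range(3)] + [f"B_{i}" for i in range(3)],
    )
    ds = build_dataset(beta, groups=["A"] * 3 + ["B"] * 3)
    res = ttest_probes(ds, "A", "B")
    assert res.loc["p0", "t_statistic"] == 0.0
    assert res.loc["p0", "p_value"] == 1.0


def test_zero_variance_cases_follow_convention():
    beta = pd.DataFrame(
        [[0.3, 0.3, 0.3, 0.3, 0.3, 0.3],   # equal means, zero variance
         [0.2, 0.2, 0.2, 0.7, 0.7, 0.7]],  # unequal means, zero variance
        index=["same", "shift"],
        columns=[f"A_{i}" for i in range(3)] + [f"B_{i}" for i in range(3)],
    )
    ds = build_dataset(beta, groups=["A"] * 3 + ["B"] * 3)
    res = ttest_probes(ds, "A", "B")
    assert res.loc["same", "p_value"] == 1.0 and not res.loc["same", "degenerate"]
    assert res.loc["shift", "p_value"] == 0.0 and res.loc["shift", "degenerate"]
    assert np.isneginf(res.loc["shift", "t_statistic"])  # A below B


def test_ttest_matches_bruteforce_oracle_on_random_probes():
    rng = np.random.default_rng(17)
    n = 1000
    beta = pd.DataFrame(
        rng.uniform(0.02, 0.98, size=(n, 8)),
        index=[f"cg{i:08d}" for i in range(n)],
        columns=[f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)],
    )
    ds = build_dataset(beta, groups=["A"] * 4 + ["B"] * 4)
    res = ttest_probes(ds, "A", "B")
    expected_q = bh_stepup(res["p_value"].to_numpy())
    for i, pid in enumerate(beta.index):
        t, df, p = pooled_ttest(beta.iloc[i, :4], beta.iloc[i, 4:])
        assert res.loc[pid, "t_statistic"] == pytest.approx(t, abs=1e-10)
        assert res.loc[pid, "degrees_of_freedom"] == df
        assert res.loc[pid, "p_value"] == pytest.approx(p, abs=1e-10)
        assert res.loc[pid, "q_value"] == pytest.approx(expected_q[i], abs=1e-10)


def test_type_one_error_rate_under_null():
    rng = np.random.default_rng(23)
    n = 10_000
    beta = pd.DataFrame(
        np.clip(rng.normal(0.5, 0.05, size=(n, 8)), 0, 1),
        index=[f"cg{i:08d}" for i in range(n)],
        columns=[f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)],
    )
    ds = build_dataset(beta, groups=["A"] * 4 + ["B"] * 4)
    res = ttest_probes(ds, "A", "B")
    rate = (res["p_value"] <= 0.05).mean()
    assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n)


def test_label_permutation_within_group_leaves_statistics_unchanged(
    two_group_dataset,
):
    res = ttest_probes(two_group_dataset, "A", "B")
    shuffled = two_group_dataset.beta[
        ["A_3", "A_1", "A_2", "B_2", "B_3", "B_1"]
    ]
    ds2 = build_dataset(shuffled, groups=["A"] * 3 + ["B"] * 3)
    res2 = ttest_probes(ds2, "A", "B")
    pd.testing.assert_frame_equal(res, res2)


def test_bh_worked_example_and_single_p():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([0.3]) == pytest.approx([0.3])
    with pytest.raises(ValueError):
        bh_fdr([])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        min_size=1,
        max_size=200,
    )
)
def test_bh_matches_stepup_oracle_and_rejection_set(p_values):
    q = bh_fdr(p_values)
    assert np.allclose(q, bh_stepup(p_values), atol=1e-12)
    # calls at 0.05 match the classical step-up rejection set
    assert set(np.flatnonzero(q <= 0.05)) == bh_reject(p_values, 0.05)
    # q is order-preserving in p
    order = np.argsort(p_values, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()


def _diff_frame(rows):
    df = pd.DataFrame(
        rows, columns=["delta_beta", "q_value"],
        index=[f"p{i}" for i in range(len(rows))],
    )
    return df


def test_rescue_rules_sign_and_strict():
    d1 = _diff_frame([(0.3, 0.01), (0.3, 0.01), (0.3, 0.01), (0.3, 0.2)])
    d2 = _diff_frame([(-0.3, 0.01), (0.2, 0.01), (-0.05, 0.01), (-0.3, 0.01)])
    sign = identify_rescue_sites(d1, d2, mode="sign")
    # p0: exact reversion; p1: same direction; p2: weak reversion;
    # p3: not significant in the first contrast
    assert list(sign.index) == ["p0", "p2"]
    strict = identify_rescue_sites(d1, d2, mode="strict", strict_tol=0.5)
    assert list(strict.index) == ["p0"]
    assert set(strict.index) <= set(sign.index)


def test_rescue_requires_matching_probe_sets():
    d1 = _diff_frame([(0.3, 0.01)])
    d2 = _diff_frame([(-0.3, 0.01), (0.1, 0.5)])
    with pytest.raises(ValueError, match="index"):
        identify_rescue_sites(d1, d2)


def test_planted_rescue_recovery_small_scale():
    cfg = SimulationConfig(
        n_probes=5000, n_differential=200, n_rescue=100,
        delta_beta=0.3, within_sd=0.03, seed=31,
    )
    man = generate_manifest(cfg)
    ds, truth = generate_methylation_dataset(man, cfg)
    filtered, _ = run_qc(ds, man, preset="full")
    d1 = ttest_probes(filtered, "C0", "Z0")
    d2 = ttest_probes(filtered, "Z0", "Z5")
    rescue = identify_rescue_sites(d1, d2, fdr=0.05, mode="sign")
    planted = set(truth.rescue_ids)
    called = set(rescue.index)
    recall = len(called & planted) / len(planted)
    fdr = len(called - planted) / max(len(called), 1)
    assert recall >= 0.9
    assert fdr <= 0.1
    # rescue set nested in both significant sets
    sig1 = set(d1.index[(d1["q_value"] <= 0.05) & (d1["delta_beta"] > 0)])
    sig2 = set(d2.index[(d2["q_value"] <= 0.05) & (d2["delta_beta"] < 0)])
    assert called <= sig1 & sig2


def test_annotate_genes_matches_bruteforce_join(small_manifest):
    sites = pd.DataFrame(index=small_manifest.index[:40])
    table = annotate_genes(sites, small_manifest)
    # independent join: plain dict accumulation
    expected: dict[str, list[str]] = {}
    for pid in sites.index:
        expected.setdefault(small_manifest.loc[pid, "gene"], []).append(pid)
    assert set(table["gene"]) == set(expected)
    for _, row in table.iterrows():
        assert row["n_sites"] == len(expected[row["gene"]])
        assert row["sites"].split(";") == expected[row["gene"]]
    # empty-symbol sites retained, two sites on one gene collapse to one row
    assert table["n_sites"].sum() == len(sites)
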