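"""QC cascade: stated rules, conservation, preset nesting, oracle parity."""

import numpy as np
import pandas as pd
import pytest
from oracles import qc_survivors

from pemt import (
    SimulationConfig,
    filter_annotation,
    filter_bead_count,
    filter_detection_p,
    generate_manifest,
    generate_methylation_dataset,
    run_qc,
)
from conftest import build_dataset


def _flat_manifest(probe_ids, **overrides):
    n = len(probe_ids)
    man = pd.DataFrame(
        {
            "design_type": ["II"] * n,
            "chrom": ["1"] * n,
            "pos": range(1, n + 1),
            "gene": [""] * n,
            "is_cpg": [True] * n,
            "is_snp_associated": [False] * n,
            "is_multimapping": [False] * n,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    for col, values in overrides.items():
        man[col] = values
    return man


def test_detection_p_any_sample_rule():
    beta = pd.DataFrame(
        0.5, index=["p0", "p1"], columns=[f"s_{i}" for i in range(16)]
    )
    detp = pd.DataFrame(0.0, index=beta.index, columns=beta.columns)
    detp.loc["p0", "s_3"] = 0.02  # one failing sample out of 16
    ds = build_dataset(beta, detp=detp, groups=["C0"] * 16)
    kept, removed = filter_detection_p(ds)
    assert removed == ["p0"]
    assert list(kept.probe_ids) == ["p1"]
    # all-passing detection p removes nothing
    kept2, removed2 = filter_detection_p(build_dataset(beta, groups=["C0"] * 16))
    assert removed2 == [] and kept2.n_probes == 2


def test_bead_count_boundary_is_inclusive():
    # 20 samples, exactly one below 3 beads: 1/20 = 5% >= 5% -> removed
    beta = pd.DataFrame(0.5, index=["p0", "p1"], columns=[f"s_{i}" for i in range(20)])
    beads = pd.DataFrame(10, index=beta.index, columns=beta.columns)
    beads.loc["p0", "s_0"] = 2
    ds = build_dataset(beta, beads=beads, groups=["C0"] * 20)
    _, removed = filter_bead_count(ds)
    assert removed == ["p0"]
    # 16 samples: 1/16 = 6.25% >= 5% -> removed as well
    beta16 = beta.iloc[:, :16]
    beads16 = beads.iloc[:, :16]
    ds16 = build_dataset(beta16, beads=beads16, groups=["C0"] * 16)
    _, removed16 = filter_bead_count(ds16)
    assert removed16 == ["p0"]


def test_detection_p_removal_count_matches_binomial_expectation():
    cfg = SimulationConfig(
        n_probes=20_000, fail_rate_detp=0.001, fail_rate_beads=0.0,
        seed=13,
    )
    man = generate_manifest(cfg)
    ds, _ = generate_methylation_dataset(man, cfg)
    _, removed = filter_detection_p(ds)
    p_fail = 1 - (1 - 0.001) ** 16
    expected = 20_000 * p_fail
    sigma = np.sqrt(20_000 * p_fail * (1 - p_fail))
    assert abs(len(removed) - expected) <= 3 * sigma


def test_annotation_filter_counts_first_failing_stage_only():
    ids = [f"p{i}" for i in range(4)]
    man = _flat_manifest(
        ids,
        is_cpg=[True, True, True, False],
        is_snp_associated=[False, True, False, False],
        chrom=["1", "X", "X", "1"],  # p1 is both snp and xy
    )
    beta = pd.DataFrame(0.5, index=ids, columns=["C0_1", "C0_2"])
    ds = build_dataset(beta, groups=["C0", "C0"])
    kept, removed = filter_annotation(ds, man)
    assert removed == {
        "non_cpg": ["p3"],
        "snp": ["p1"],
        "multimap": [],
        "xy": ["p2"],
    }
    assert list(kept.probe_ids) == ["p0"]
    all_removed = [pid for ids_ in removed.values() for pid in ids_]
    assert len(all_removed) == len(set(all_removed))  # disjoint stages


def test_annotation_filter_errors_on_probe_missing_from_manifest():
    ids = ["p0", "p1"]
    man = _flat_manifest(["p0"])
    beta = pd.DataFrame(0.5, index=ids, columns=["C0_1", "C0_2"])
    ds = build_dataset(beta, groups=["C0", "C0"])
    with pytest.raises(KeyError, match="p1"):
        filter_annotation(ds, man)


def test_raw_preset_is_identity(small_dataset, small_manifest):
    ds, _ = small_dataset
    out, report = run_qc(ds, small_manifest, preset="raw")
    pd.testing.assert_frame_equal(out.beta, ds.beta)
    assert report.stages == [] and report.n_surviving == ds.n_probes


@pytest.mark.parametrize("preset", ["raw", "full", "partial"])
def test_preset_survivors_match_exhaustive_oracle(preset, small_dataset,
                                                  small_manifest):
    ds, _ = small_dataset
    # oracle check on a 1000-probe slice to stay exhaustive but quick
    sub = ds.subset_probes(ds.probe_ids[:1000])
    out, report = run_qc(sub, small_manifest, preset=preset)
    assert set(out.probe_ids) == qc_survivors(sub, small_manifest, preset)
    # conservation: survivors + per-stage removals == input
    assert report.n_surviving + sum(report.removed_counts.values()) == 1000
    # idempotence
    out2, report2 = run_qc(out, small_manifest, preset=preset)
    assert list(out2.probe_ids) == list(out.probe_ids)
    assert report2.n_removed == 0


def test_preset_monotonicity_full_subset_partial_subset_raw(
    small_dataset, small_manifest
):
    ds, _ = small_dataset
    survivors = {
        preset: set(run_qc(ds, small_manifest, preset=preset)[0].probe_ids)
        for preset in ("raw", "partial", "full")
    }
    assert survivors["full"] <= survivors["partial"] <= survivors["raw"]
    # partial retains SNP/multimap/XY-flagged probes that pass the rest
    retained = survivors["partial"] - survivors["full"]
    flagged = small_manifest.loc[sorted(retained)]
    assert (
        flagged["is_snp_associated"]
        | flagged["is_multimapping"]
        | flagged["chrom"].isin(["X", "Y"])
    ).all()


def test_unknown_preset_and_empty_dataset_rejected(small_dataset,
                                                   small_manifest):
    ds, _ = small_dataset
    with pytest.raises(ValueError, match="preset"):
        run_qc(ds, small_manifest, preset="bogus")
    empty = ds.subset_probes([])
    with pytest.raises(ValueError, match="empty"):
        filter_detection_p(empty)
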