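"""Generator contracts: determinism, planted effects, flag fractions."""

import numpy as np
import pandas as pd
import pytest

from pemt import (
    GroundTruth,
    SimulationConfig,
    generate_assay_masks,
    generate_cell_population,
    generate_ellipse_outline,
    generate_manifest,
    generate_methylation_dataset,
)
from pemt.dataset import group_means


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SimulationConfig(frac_snp=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_differential=10, n_rescue=20)
    with pytest.raises(ValueError):
        SimulationConfig(type2_compression=0.0)
    with pytest.raises(ValueError):
        GroundTruth(differential_ids=("a",), rescue_ids=("b",))


def test_manifest_zero_fractions_survive_all_annotation_filters():
    cfg = SimulationConfig(
        n_probes=500, frac_non_cpg=0, frac_snp=0, frac_multimap=0, frac_xy=0,
        n_differential=0, n_rescue=0, seed=3,
    )
    man = generate_manifest(cfg)
    assert man["is_cpg"].all()
    assert not man["is_snp_associated"].any()
    assert not man["is_multimapping"].any()
    assert not man["chrom"].isin(["X", "Y"]).any()
    assert man.index.is_unique


def test_manifest_deterministic_under_fixed_seed():
    cfg = SimulationConfig(n_probes=1000, frac_non_cpg=0.1, seed=7,
                           n_differential=0, n_rescue=0)
    pd.testing.assert_frame_equal(generate_manifest(cfg), generate_manifest(cfg))


def test_manifest_flag_counts_within_binomial_bounds():
    n = 20_000
    cfg = SimulationConfig(n_probes=n, frac_snp=0.2, seed=11)
    man = generate_manifest(cfg)
    for frac, count in [
        (cfg.frac_non_cpg, (~man["is_cpg"]).sum()),
        (0.2, man["is_snp_associated"].sum()),
        (cfg.frac_multimap, man["is_multimapping"].sum()),
        (cfg.frac_xy, man["chrom"].isin(["X", "Y"]).sum()),
        (cfg.frac_type2, (man["design_type"] == "II").sum()),
    ]:
        bound = 3 * np.sqrt(n * frac * (1 - frac))
        assert abs(count - n * frac) <= max(bound, 3), (frac, count)


def test_noiseless_dataset_hits_planted_means_exactly():
    cfg = SimulationConfig(
        n_probes=2000, within_sd=0.0, fail_rate_detp=0.0, fail_rate_beads=0.0,
        type2_compression=1.0, n_differential=50, n_rescue=25, seed=5,
    )
    man = generate_manifest(cfg)
    ds, truth = generate_methylation_dataset(man, cfg)
    # every replicate equals its group mean exactly
    for g in cfg.groups:
        cols = ds.group_columns(g)
        assert (ds.beta[cols].nunique(axis=1) == 1).all()
    c0 = group_means(ds, "C0")
    z0 = group_means(ds, "Z0")
    z5 = group_means(ds, "Z5")
    c5 = group_means(ds, "C5")
    diff = list(truth.differential_ids)
    rescue = list(truth.rescue_ids)
    non_rescue = sorted(set(diff) - set(rescue))
    # planted hypermethylation and exact rescue symmetry
    assert np.allclose(z0[diff] - c0[diff], cfg.delta_beta)
    assert np.allclose(z5[rescue], c0[rescue])
    assert np.allclose(z5[non_rescue], z0[non_rescue])
    assert np.allclose((z5 - z0)[rescue], -(z0 - c0)[rescue])
    # C5 mirrors C0; non-differential probes identical across groups
    others = ds.probe_ids.difference(diff)
    assert np.allclose(c5[others], c0[others])
    assert np.allclose(z0[others], c0[others])


def test_dataset_ranges_and_determinism(small_manifest, small_config):
    ds, truth = generate_methylation_dataset(small_manifest, small_config)
    ds2, truth2 = generate_methylation_dataset(small_manifest, small_config)
    pd.testing.assert_frame_equal(ds.beta, ds2.beta)
    pd.testing.assert_frame_equal(ds.beads, ds2.beads)
    assert truth == truth2
    assert ((ds.beta.values >= 0) & (ds.beta.values <= 1)).all()
    assert ((ds.detp.values >= 0) & (ds.detp.values <= 1)).all()
    assert (ds.beads.values >= 0).all()
    assert np.issubdtype(ds.beads.values.dtype, np.integer)
    assert set(truth.rescue_ids) <= set(truth.differential_ids)


def test_non_differential_group_difference_within_standard_error(
    small_dataset,
):
    ds, truth = small_dataset
    c0, z0 = group_means(ds, "C0"), group_means(ds, "Z0")
    others = ds.probe_ids.difference(truth.differential_ids)
    # mean |Z0 - C0| over nulls: E|N(0, sd*sqrt(2/4))| = sd*sqrt(2/4)*sqrt(2/pi)
    sd_diff = 0.03 * np.sqrt(2 / 4)
    expected = sd_diff * np.sqrt(2 / np.pi)
    observed = (z0[others] - c0[others]).abs().mean()
    assert observed < expected + 3 * sd_diff / np.sqrt(len(others))


def test_planted_effect_recovered_within_three_standard_errors(small_dataset):
    ds, truth = small_dataset
    c0, z0 = group_means(ds, "C0"), group_means(ds, "Z0")
    delta = (z0 - c0)[list(truth.differential_ids)]
    # type II probes express 0.8 of the planted effect; either way the
    # per-probe estimate should sit within 3 SE of its planted value
    se = 0.03 * np.sqrt(2 / 4)
    assert ((delta - 0.3 * 0.8).abs() < 3 * se).mean() > 0.9
    assert (delta > 0.3 * 0.8 - 3 * se).all()


def test_mismatched_manifest_size_rejected(small_manifest):
    with pytest.raises(ValueError, match="manifest has"):
        generate_methylation_dataset(
            small_manifest, SimulationConfig(n_probes=10, n_differential=0,
                                             n_rescue=0)
        )


def test_ellipse_outline_shapes_and_errors():
    with pytest.raises(ValueError):
        generate_ellipse_outline(1.0, 2.0)  # minor > major
    with pytest.raises(ValueError):
        generate_ellipse_outline(2.0, 1.0, n_vertices=8)
    o = generate_ellipse_outline(3.0, 1.5, n_vertices=64)
    assert o.vertices.shape == (64, 2)
    o.validate()  # simple, positive area


def test_cell_population_reproducible_and_mix_respected():
    a, la = generate_cell_population(100, (0.5, 0.3, 0.2), seed=9)
    b, lb = generate_cell_population(100, (0.5, 0.3, 0.2), seed=9)
    assert la == lb
    assert all(np.array_equal(x.vertices, y.vertices) for x, y in zip(a, b))
    only_mes, labels = generate_cell_population(50, (0, 0, 1), seed=2)
    assert set(labels) == {"mesenchymal"}
    with pytest.raises(ValueError):
        generate_cell_population(10, (0.5, 0.2, 0.2))  # does not sum to 1


@pytest.mark.parametrize("kind", ["wound", "spheroid", "brdu"])
def test_assay_masks_are_binary_and_consistent_with_truth(kind):
    masks, truth = generate_assay_masks(kind, seed=4)
    for m in masks.values():
        assert set(np.unique(m.grid)) <= {0, 1}
    if kind == "wound":
        assert truth["closure_pct_t0"] == 0.0
        assert truth["closure_pct_t2"] > truth["closure_pct_t1"] > 0
    elif kind == "spheroid":
        assert truth["invasion_um2_t0"] == 0.0
        assert truth["invasion_um2_t2"] > truth["invasion_um2_t1"] > 0
    else:
        assert truth["brdu_pct"] == 25.0
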