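"""Shared fixtures: small synthetic datasets and hand-built edge cases."""

import numpy as np
import pandas as pd
import pytest

from pemt import (
    MethylationDataset,
    SimulationConfig,
    generate_manifest,
    generate_methylation_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_probes=2000,
        n_differential=40,
        n_rescue=20,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return generate_manifest(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_manifest, small_config):
    ds, truth = generate_methylation_dataset(small_manifest, small_config)
    return ds, truth


def build_dataset(beta, detp=None, beads=None, groups=None):
    """Hand-build a MethylationDataset from a beta DataFrame."""
    beta = pd.DataFrame(beta)
    if detp is None:
        detp = pd.DataFrame(0.0, index=beta.index, columns=beta.columns)
    if beads is None:
        beads = pd.DataFrame(10, index=beta.index, columns=beta.columns)
    if groups is None:
        groups = [c.rsplit("_", 1)[0] for c in beta.columns]
    samples = pd.DataFrame(
        {"group": groups, "replicate": range(1, len(beta.columns) + 1)},
        index=pd.Index(beta.columns, name="sample_id"),
    )
    return MethylationDataset(
        beta=beta,
        detp=pd.DataFrame(detp, index=beta.index, columns=beta.columns),
        beads=pd.DataFrame(beads, index=beta.index, columns=beta.columns),
        samples=samples,
    )


@pytest.fixture()
def two_group_dataset():
    """3 probes x (3 A + 3 B) with known values for t-test oracles."""
    rng = np.random.default_rng(7)
    beta = pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(3, 6)),
        index=[f"cg{i:08d}" for i in range(3)],
        columns=[f"A_{r}" for r in range(1, 4)] + [f"B_{r}" for r in range(1, 4)],
    )
    beta.iloc[0] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]  # worked textbook example
    return build_dataset(beta, groups=["A"] * 3 + ["B"] * 3)
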