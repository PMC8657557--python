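"""In-memory containers for probe-level methylation data.

A probe *manifest* is a :class:`pandas.DataFrame` indexed by ``probe_id``
with columns

``design_type``
    Infinium chemistry, ``"I"`` or ``"II"``.
``chrom``, ``pos``
    Genomic location; ``pos`` is 1-based.  Sex-chromosome membership is
    derived from ``chrom in {"X", "Y"}``.
``gene``
    Gene symbol, possibly empty.
``is_cpg``, ``is_snp_associated``, ``is_multimapping``
    Boolean annotation flags driving the QC filter cascade.

Beta values, detection p-values and bead counts live in three aligned
probes x samples DataFrames inside :class:`MethylationDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = (
    "design_type",
    "chrom",
    "pos",
    "gene",
    "is_cpg",
    "is_snp_associated",
    "is_multimapping",
)

GROUPS = ("C0", "C5", "Z0", "Z5")


def validate_manifest(manifest: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a manifest violates its contract."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if manifest.index.has_duplicates:
        dup = manifest.index[manifest.index.duplicated()][0]
        raise ValueError(f"duplicate probe_id in manifest: {dup!r}")
    bad = set(manifest["design_type"]) - {"I", "II"}
    if bad:
        raise ValueError(f"unknown design types: {sorted(bad)}")


@dataclass
class MethylationDataset:
    """Beta matrix plus per-cell QC metrics and the sample sheet.

    Parameters
    ----------
    beta, detp, beads
        Probes x samples DataFrames sharing index and columns: methylation
        beta values in [0, 1], detection p-values in [0, 1] and integer
        bead counts.
    samples
        DataFrame indexed by sample id with columns ``group`` (one of
        C0/C5/Z0/Z5 by default) and ``replicate``.
    """

    beta: pd.DataFrame
    detp: pd.DataFrame
    beads: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for name, m in (("detp", self.detp), ("beads", self.beads)):
            if not m.index.equals(self.beta.index) or not m.columns.equals(
                self.beta.columns
            ):
                raise ValueError(f"{name} matrix not aligned with beta matrix")
        missing = set(self.beta.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet missing entries for {sorted(missing)}")
        if "group" not in self.samples.columns:
            raise ValueError("samples sheet needs a 'group' column")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    def group_columns(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``, in sheet order."""
        cols = self.samples.index[self.samples["group"] == group]
        known = [c for c in cols if c in self.beta.columns]
        if not known:
            raise ValueError(f"no samples in group {group!r}")
        return known

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        """Row-subset all three matrices, preserving order of ``probe_ids``."""
        idx = pd.Index(probe_ids)
        return MethylationDataset(
            beta=self.beta.loc[idx],
            detp=self.detp.loc[idx],
            beads=self.beads.loc[idx],
            samples=self.samples,
        )

    def drop_probes(self, probe_ids) -> "MethylationDataset":
        keep = self.beta.index.difference(pd.Index(probe_ids), sort=False)
        return self.subset_probes(keep)


def group_means(ds: MethylationDataset, group: str) -> pd.Series:
    """Per-probe mean beta over the replicates of one group."""
    return ds.beta[ds.group_columns(group)].mean(axis=1)


def as_float_matrix(df: pd.DataFrame) -> np.ndarray:
    return np.asarray(df, dtype=float)
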