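"""EPIC probe quality-control filter cascade and the three QC presets.

The cascade mirrors standard ChAMP-style array QC, in a fixed order:

1. detection p-value  (probe fails if its fraction of samples with
   detp > 0.01 exceeds ``max_fail_fraction``; the default 0 removes a
   probe if *any* sample fails),
2. bead count         (fails if bead count < 3 in at least 5% of samples;
   the boundary is inclusive),
3. non-CpG probes,
4. SNP-associated probes,
5. multi-mapping probes,
6. X/Y-chromosome probes.

Three presets: ``raw`` (no filtering), ``full`` (all six stages) and
``partial`` (detection p, bead count and non-CpG only).  Each removed
probe is attributed to the first stage at which it fails, so per-stage
counts are disjoint and sum — together with the survivors — to the input
probe count.  Because counts are attributed to the first failing stage,
their split (not the survivor set) depends on the cascade order; the
order above is fixed and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from pemt.dataset import MethylationDataset, validate_manifest

PRESETS = {
    "raw": (),
    "full": ("detection_p", "bead_count", "non_cpg", "snp", "multimap", "xy"),
    "partial": ("detection_p", "bead_count", "non_cpg"),
}

ANNOTATION_STAGES = ("non_cpg", "snp", "multimap", "xy")


@dataclass
class QcReport:
    """Per-stage bookkeeping of one QC run."""

    preset: str
    n_input: int
    stages: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def removed_counts(self) -> dict[str, int]:
        return {name: len(ids) for name, ids in self.stages}

    @property
    def n_removed(self) -> int:
        return sum(len(ids) for _, ids in self.stages)

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "n_input": self.n_input,
            "n_surviving": self.n_surviving,
            "removed_counts": self.removed_counts,
            "removed_ids": {name: list(ids) for name, ids in self.stages},
        }


def _require_nonempty(ds: MethylationDataset) -> None:
    if ds.n_probes == 0 or ds.n_samples == 0:
        raise ValueError("empty methylation dataset")


def filter_detection_p(
    ds: MethylationDataset,
    threshold: float = 0.01,
    max_fail_fraction: float = 0.0,
) -> tuple[MethylationDataset, list[str]]:
    """Remove probes whose detection p-values fail in too many samples.

    A probe is removed iff the fraction of its samples with
    detp > ``threshold`` exceeds ``max_fail_fraction`` (strictly).  The
    default fraction of 0 is the any-sample rule: one failing sample
    removes the probe.
    """
    _require_nonempty(ds)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    fail_frac = (ds.detp > threshold).mean(axis=1)
    removed = ds.detp.index[fail_frac > max_fail_fraction]
    return ds.drop_probes(removed), list(removed)


def filter_bead_count(
    ds: MethylationDataset,
    min_beads: int = 3,
    max_fail_fraction: float = 0.05,
) -> tuple[MethylationDataset, list[str]]:
    """Remove probes with bead count below ``min_beads`` in at least
    ``max_fail_fraction`` of samples (inclusive boundary)."""
    _require_nonempty(ds)
    if min_beads < 1:
        raise ValueError("min_beads must be >= 1")
    fail_frac = (ds.beads < min_beads).mean(axis=1)
    removed = ds.beads.index[fail_frac >= max_fail_fraction]
    return ds.drop_probes(removed), list(removed)


def _annotation_failures(manifest: pd.DataFrame, stage: str) -> pd.Series:
    if stage == "non_cpg":
        return ~manifest["is_cpg"]
    if stage == "snp":
        return manifest["is_snp_associated"]
    if stage == "multimap":
        return manifest["is_multimapping"]
    if stage == "xy":
        return manifest["chrom"].isin(["X", "Y"])
    raise ValueError(f"unknown annotation stage {stage!r}")


def filter_annotation(
    ds: MethylationDataset,
    manifest: pd.DataFrame,
    which: tuple[str, ...] = ANNOTATION_STAGES,
) -> tuple[MethylationDataset, dict[str, list[str]]]:
    """Remove flagged probes, counting each under its first failing stage.

    Stages run in the order given (default non_cpg -> snp -> multimap ->
    xy); a probe flagged in several categories is counted only once.
    """
    _require_nonempty(ds)
    validate_manifest(manifest)
    missing = ds.probe_ids.difference(manifest.index)
    if len(missing) > 0:
        raise KeyError(f"probe {missing[0]!r} missing from manifest")
    unknown = set(which) - set(ANNOTATION_STAGES)
    if unknown:
        raise ValueError(f"unknown annotation stages: {sorted(unknown)}")
    out = ds
    removed: dict[str, list[str]] = {}
    for stage in which:
        fails = _annotation_failures(manifest.loc[out.probe_ids], stage)
        ids = list(out.probe_ids[fails.to_numpy()])
        removed[stage] = ids
        out = out.drop_probes(ids)
    return out, removed


def run_qc(
    ds: MethylationDataset,
    manifest: pd.DataFrame,
    preset: str = "full",
    detp_threshold: float = 0.01,
    detp_max_fail_fraction: float = 0.0,
    min_beads: int = 3,
    beads_max_fail_fraction: float = 0.05,
) -> tuple[MethylationDataset, QcReport]:
    """Run one of the three QC presets and return survivors plus report."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    _require_nonempty(ds)
    report = QcReport(preset=preset, n_input=ds.n_probes)
    out = ds
    stages = PRESETS[preset]
    for stage in stages:
        if stage == "detection_p":
            out, ids = filter_detection_p(
                out, threshold=detp_threshold,
                max_fail_fraction=detp_max_fail_fraction,
            )
            report.stages.append(("detection_p", ids))
        elif stage == "bead_count":
            out, ids = filter_bead_count(
                out, min_beads=min_beads,
                max_fail_fraction=beads_max_fail_fraction,
            )
            report.stages.append(("bead_count", ids))
        else:
            out, by_cat = filter_annotation(out, manifest, which=(stage,))
            report.stages.append((stage, by_cat[stage]))
    return out, report
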