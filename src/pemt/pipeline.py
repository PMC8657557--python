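"""End-to-end orchestration: QC -> (BMIQ) -> t-tests -> rescue -> genes.

A single :class:`PipelineConfig` describes one reproducible run, either
over files on disk or over a freshly simulated dataset.  Every run
writes, under its output directory: the filtered matrices, one
differential table per contrast, the rescue-site and gene tables, a QC
report, a funnel-count JSON (input probes -> QC survivors -> significant
per contrast -> rescue sites -> genes) and a plain-text log.  When
planted ground truth is available, recall and precision of the rescue
set are reported in the log and funnel.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from pemt import io as pio
from pemt.bmiq import bmiq_normalize
from pemt.dataset import MethylationDataset
from pemt.differential import annotate_genes, identify_rescue_sites, ttest_probes
from pemt.qc import PRESETS, run_qc
from pemt.synthetic import (
    GroundTruth,
    SimulationConfig,
    generate_manifest,
    generate_methylation_dataset,
)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    out_dir: str | Path = "pemt_run"
    # file inputs (ignored when simulate=True)
    manifest_path: str | None = None
    beta_path: str | None = None
    detp_path: str | None = None
    beads_path: str | None = None
    samples_path: str | None = None
    ground_truth_path: str | None = None
    # or simulate in-process
    simulate: bool = False
    simulation: SimulationConfig | None = None
    # analysis choices
    qc_preset: str = "partial"
    normalize: bool = True
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("C0", "Z0"), ("Z0", "Z5")]
    )
    fdr: float = 0.05
    rescue_mode: str = "sign"
    strict_tol: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.qc_preset not in PRESETS:
            raise ValueError(f"unknown QC preset {self.qc_preset!r}")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if self.rescue_mode not in ("sign", "strict"):
            raise ValueError(f"unknown rescue mode {self.rescue_mode!r}")
        if len(self.contrasts) != 2:
            raise ValueError(
                "rescue analysis needs exactly two contrasts "
                "(knockdown and drug), e.g. C0:Z0 and Z0:Z5"
            )
        if not self.simulate:
            for name in ("manifest_path", "beta_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when simulate=False")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        contrasts = raw.pop("contrasts", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if contrasts is not None:
            cfg.contrasts = [tuple(c.split(":")) if isinstance(c, str) else tuple(c)
                             for c in contrasts]
        return cfg


def _load_inputs(
    config: PipelineConfig,
) -> tuple[pd.DataFrame, MethylationDataset, GroundTruth | None]:
    if config.simulate:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        manifest = generate_manifest(sim)
        ds, truth = generate_methylation_dataset(manifest, sim)
        return manifest, ds, truth
    manifest = pio.read_manifest(config.manifest_path)
    ds = pio.read_dataset(
        config.beta_path, config.detp_path, config.beads_path, config.samples_path
    )
    truth = (
        pio.read_ground_truth(config.ground_truth_path)
        if config.ground_truth_path
        else None
    )
    return manifest, ds, truth


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full chain described by ``config``; returns the run dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"pemt pipeline run, seed={config.seed}",
        f"started {time.strftime('%Y-%m-%d %H:%M:%S')}",
    ]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    manifest, ds, truth = stage("load", _load_inputs, config)
    for ga, gb in config.contrasts:
        for g in (ga, gb):
            if g not in set(ds.samples["group"]):
                raise ValueError(f"contrast references unknown group {g!r}")
    log_lines.append(f"input probes: {ds.n_probes}, samples: {ds.n_samples}")

    ds_qc, report = stage("qc", run_qc, ds, manifest, preset=config.qc_preset)
    log_lines.append(
        f"QC preset {config.qc_preset!r}: {report.n_surviving} probes survive "
        f"({report.removed_counts})"
    )
    pio.write_json(report.to_dict(), out / "qc_report.json")

    if config.normalize:
        ds_qc = stage("bmiq", bmiq_normalize, ds_qc, manifest)
        log_lines.append("BMIQ normalization applied to type II probes")
    pio.write_matrix(ds_qc.beta, out / "beta_filtered.tsv")
    pio.write_matrix(ds_qc.detp, out / "detp_filtered.tsv")
    pio.write_matrix(ds_qc.beads, out / "beads_filtered.tsv")
    pio.write_sample_sheet(ds_qc.samples, out / "samples.csv")

    diffs = {}
    funnel = {
        "n_input_probes": int(ds.n_probes),
        "qc_preset": config.qc_preset,
        "n_qc_survivors": int(report.n_surviving),
        "seed": config.seed,
    }
    for ga, gb in config.contrasts:
        name = f"{ga}{gb}"
        diff = stage(f"ttest_{name}", ttest_probes, ds_qc, ga, gb)
        diffs[(ga, gb)] = diff
        n_sig = int((diff["q_value"] <= config.fdr).sum())
        funnel[f"n_significant_{name}"] = n_sig
        log_lines.append(
            f"contrast {ga} vs {gb}: {n_sig} probes at q <= {config.fdr}"
        )
        pio.write_table(diff, out / f"diff_{name}.tsv")

    (c1, c2) = config.contrasts
    rescue = stage(
        "rescue",
        identify_rescue_sites,
        diffs[c1],
        diffs[c2],
        fdr=config.fdr,
        mode=config.rescue_mode,
        strict_tol=config.strict_tol,
    )
    genes = stage("genes", annotate_genes, rescue, manifest)
    funnel["n_rescue_sites"] = int(len(rescue))
    funnel["n_rescue_genes"] = int((genes["gene"] != "").sum())
    log_lines.append(
        f"rescue ({config.rescue_mode} mode): {len(rescue)} sites, "
        f"{funnel['n_rescue_genes']} named genes"
    )
    pio.write_table(rescue, out / "rescue_sites.tsv")
    pio.write_table(genes, out / "rescue_genes.tsv", index=False)

    if truth is not None:
        planted = set(truth.rescue_ids)
        called = set(rescue.index)
        tp = len(planted & called)
        recall = tp / len(planted) if planted else float("nan")
        precision = tp / len(called) if called else 1.0
        funnel["rescue_recall"] = recall
        funnel["rescue_precision"] = precision
        log_lines.append(
            f"planted-truth comparison: recall={recall:.3f} "
            f"precision={precision:.3f} ({tp}/{len(planted)} planted recovered)"
        )

    pio.write_json(funnel, out / "funnel.json")
    log_lines.append(f"finished {time.strftime('%Y-%m-%d %H:%M:%S')}")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
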