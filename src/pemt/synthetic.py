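"""Synthetic EPIC-like methylation data, cell outlines and assay masks.

Everything downstream (QC, BMIQ, differential/rescue analysis, morphology,
assay quantification) is testable offline against the planted ground truth
these generators return.

The methylation generator emulates the study design: four groups — control
cells with DMSO (C0) or 5-azacytidine (C5), and Zeb1-knockdown cells with
DMSO (Z0) or 5-aza (Z5) — with four replicates each.  A configurable set
of probes is hypermethylated in Z0 relative to C0 (the knockdown effect);
a subset of those is "rescued" in Z5, i.e. demethylated back to the C0
baseline by the drug.  C5 is distributed identically to C0.  Type II
probes carry the Infinium compression bias toward 0.5 that BMIQ is meant
to undo, and sporadic detection-p / bead-count failures exercise the QC
cascade.

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pemt.assays import AssayMask
from pemt.dataset import GROUPS, MethylationDataset
from pemt.morphology import CellOutline

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_manifest",
    "generate_methylation_dataset",
    "generate_ellipse_outline",
    "generate_cell_population",
    "generate_assay_masks",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design constants for one synthetic methylation dataset.

    Defaults are a desk-scale rendition of the study chip: 20,000 probes
    with annotation-flag fractions matching the per-stage removal
    fractions of the real ~866k-probe EPIC cascade, 4 groups x 4
    replicates, 200 planted hypermethylated probes of which 100 are
    rescued by 5-aza, a planted effect of 0.3 beta with replicate noise
    SD 0.03, and type II compression c = 0.8.
    """

    n_probes: int = 20_000
    frac_non_cpg: float = 0.0035
    frac_snp: float = 0.114
    frac_multimap: float = 0.0001
    frac_xy: float = 0.02
    frac_type2: float = 0.84
    groups: tuple[str, ...] = GROUPS
    n_replicates: int = 4
    n_differential: int = 200
    n_rescue: int = 100
    delta_beta: float = 0.3
    within_sd: float = 0.03
    type2_compression: float = 0.8
    fail_rate_detp: float = 0.00025
    fail_rate_beads: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        props = {
            "frac_non_cpg": self.frac_non_cpg,
            "frac_snp": self.frac_snp,
            "frac_multimap": self.frac_multimap,
            "frac_xy": self.frac_xy,
            "frac_type2": self.frac_type2,
            "fail_rate_detp": self.fail_rate_detp,
            "fail_rate_beads": self.fail_rate_beads,
        }
        for name, p in props.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if not 0 <= self.n_rescue <= self.n_differential <= self.n_probes:
            raise ValueError(
                "need 0 <= n_rescue <= n_differential <= n_probes, got "
                f"{self.n_rescue}/{self.n_differential}/{self.n_probes}"
            )
        if not 0.0 < self.type2_compression <= 1.0:
            raise ValueError("type2_compression must lie in (0, 1]")
        if self.within_sd < 0:
            raise ValueError("within_sd must be non-negative")
        if self.n_replicates < 1 or not self.groups:
            raise ValueError("need at least one group and one replicate")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth labels for recovery tests."""

    differential_ids: tuple[str, ...]
    rescue_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not set(self.rescue_ids) <= set(self.differential_ids):
            raise ValueError("rescue_ids must be a subset of differential_ids")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


AUTOSOMES = [str(c) for c in range(1, 23)]


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Probe manifest with design types, locations, genes and QC flags.

    Non-CpG probes get ``ch.``-prefixed identifiers, CpG probes ``cg``
    ones, mirroring array naming conventions.  Flags are drawn
    independently per probe; sex-chromosome membership is encoded through
    ``chrom``.
    """
    rng = _rng(config.seed, 1)
    n = config.n_probes
    non_cpg = rng.random(n) < config.frac_non_cpg
    snp = rng.random(n) < config.frac_snp
    multimap = rng.random(n) < config.frac_multimap
    xy = rng.random(n) < config.frac_xy
    design = np.where(rng.random(n) < config.frac_type2, "II", "I")

    probe_ids = np.array(
        [
            ("ch." if non_cpg[i] else "cg") + f"{i:08d}"
            for i in range(n)
        ]
    )
    chrom = rng.choice(AUTOSOMES, size=n)
    chrom[xy] = rng.choice(["X", "Y"], size=int(xy.sum()))
    pos = rng.integers(1, 250_000_000, size=n)

    # ~3 probes per gene on average; ~20% of probes intergenic (no gene).
    n_genes = max(n // 3, 1)
    gene = np.array([f"G{g:05d}" for g in rng.integers(0, n_genes, size=n)])
    gene[rng.random(n) < 0.2] = ""

    manifest = pd.DataFrame(
        {
            "design_type": design,
            "chrom": chrom,
            "pos": pos,
            "gene": gene,
            "is_cpg": ~non_cpg,
            "is_snp_associated": snp,
            "is_multimapping": multimap,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return manifest


def _passes_annotation(manifest: pd.DataFrame) -> pd.Series:
    return (
        manifest["is_cpg"]
        & ~manifest["is_snp_associated"]
        & ~manifest["is_multimapping"]
        & ~manifest["chrom"].isin(["X", "Y"])
    )


def generate_methylation_dataset(
    manifest: pd.DataFrame, config: SimulationConfig
) -> tuple[MethylationDataset, GroundTruth]:
    """Beta/detp/bead matrices with planted differential and rescue probes.

    Baseline probe means are bimodal (0.5 Beta(2,10) + 0.5 Beta(10,2),
    the unmethylated/methylated peaks of real arrays).  Differential
    probes gain ``delta_beta`` in Z0; non-rescue differential probes keep
    the gain in Z5 while rescue probes return to the C0 baseline, so in
    the noiseless limit mean(Z5) - mean(Z0) = -(mean(Z0) - mean(C0))
    exactly.  C5 is distributed like C0.  Type II group means are
    compressed toward 0.5 by ``type2_compression`` before replicate noise
    is added; observed betas are clipped to [0, 1].

    Planted probes are drawn from probes that survive the annotation
    flags and whose baseline leaves room for the full effect
    (baseline <= 1 - delta_beta), so the planted truth is recoverable
    through the default QC chain without clipping distortion.
    """
    if len(manifest) != config.n_probes:
        raise ValueError(
            f"manifest has {len(manifest)} probes, config expects {config.n_probes}"
        )
    rng = _rng(config.seed, 2)
    n = config.n_probes
    n_samples = len(config.groups) * config.n_replicates

    methylated = rng.random(n) < 0.5
    baseline = np.where(
        methylated, rng.beta(10, 2, size=n), rng.beta(2, 10, size=n)
    )

    eligible = (
        _passes_annotation(manifest).to_numpy()
        & (baseline <= 1.0 - config.delta_beta)
    )
    n_eligible = int(eligible.sum())
    if n_eligible < config.n_differential:
        raise ValueError(
            f"only {n_eligible} probes eligible for planting, "
            f"need {config.n_differential}"
        )
    chosen = rng.choice(np.flatnonzero(eligible), size=config.n_differential,
                        replace=False)
    diff_idx = np.sort(chosen)
    rescue_idx = np.sort(rng.choice(diff_idx, size=config.n_rescue, replace=False))

    is_diff = np.zeros(n, dtype=bool)
    is_diff[diff_idx] = True
    is_rescue = np.zeros(n, dtype=bool)
    is_rescue[rescue_idx] = True

    # true group means, probes x groups (clipped; planting never errors)
    group_mean = {}
    for g in config.groups:
        m = baseline.copy()
        if g == "Z0":
            m = m + config.delta_beta * is_diff
        elif g == "Z5":
            m = m + config.delta_beta * (is_diff & ~is_rescue)
        group_mean[g] = np.clip(m, 0.0, 1.0)

    is_type2 = (manifest["design_type"] == "II").to_numpy()
    c = config.type2_compression
    sample_ids, groups_col, reps_col = [], [], []
    beta_cols = {}
    for g in config.groups:
        mu = group_mean[g]
        mu_obs = np.where(is_type2, 0.5 + c * (mu - 0.5), mu)
        for r in range(1, config.n_replicates + 1):
            sid = f"{g}_{r}"
            noise = (
                rng.normal(0.0, config.within_sd, size=n)
                if config.within_sd > 0
                else 0.0
            )
            beta_cols[sid] = np.clip(mu_obs + noise, 0.0, 1.0)
            sample_ids.append(sid)
            groups_col.append(g)
            reps_col.append(r)

    beta = pd.DataFrame(beta_cols, index=manifest.index)

    # detection p-values: ~0 for passing cells, Uniform(0.01, 1) for failures
    fail_p = rng.random((n, n_samples)) < config.fail_rate_detp
    detp = np.where(
        fail_p,
        rng.uniform(0.01, 1.0, size=(n, n_samples)),
        rng.uniform(0.0, 1e-3, size=(n, n_samples)),
    )
    # bead counts: Poisson around 12 floored at 3 for passing cells, 0-2 otherwise
    fail_b = rng.random((n, n_samples)) < config.fail_rate_beads
    beads = np.where(
        fail_b,
        rng.integers(0, 3, size=(n, n_samples)),
        3 + rng.poisson(9, size=(n, n_samples)),
    )

    samples = pd.DataFrame(
        {"group": groups_col, "replicate": reps_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ds = MethylationDataset(
        beta=beta,
        detp=pd.DataFrame(detp, index=manifest.index, columns=sample_ids),
        beads=pd.DataFrame(beads, index=manifest.index, columns=sample_ids),
        samples=samples,
    )
    truth = GroundTruth(
        differential_ids=tuple(manifest.index[diff_idx]),
        rescue_ids=tuple(manifest.index[rescue_idx]),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# cell outlines


def generate_ellipse_outline(
    semi_major: float,
    semi_minor: float,
    n_vertices: int = 360,
    rotation: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    cell_id: str = "cell",
) -> CellOutline:
    """Ordered, closed, non-self-intersecting polygon sampling an ellipse.

    The roundness score of the result approaches the axis ratio b/a as
    the vertex count grows.
    """
    if not semi_major >= semi_minor > 0:
        raise ValueError(
            f"need semi_major >= semi_minor > 0, got ({semi_major}, {semi_minor})"
        )
    if n_vertices < 16:
        raise ValueError("need at least 16 vertices")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = semi_major * np.cos(theta)
    y = semi_minor * np.sin(theta)
    cos_r, sin_r = np.cos(rotation), np.sin(rotation)
    pts = np.column_stack(
        [
            center[0] + cos_r * x - sin_r * y,
            center[1] + sin_r * x + cos_r * y,
        ]
    )
    return CellOutline(cell_id=cell_id, vertices=pts)


DEFAULT_AXIS_RATIO_PARAMS = {
    # (mean, sd) of the minor/major axis ratio per morphology class
    "epithelial": (0.85, 0.03),
    "mixed": (0.50, 0.06),
    "mesenchymal": (0.18, 0.03),
}

# Control cell lines (epithelial MDA-MB-468-like, mesenchymal
# fibroblast-like) are modelled with broader shape dispersion than the
# assay classes: the mean +/- SD cutoffs they yield then clear each assay
# class by more than two within-class SDs, i.e. the cutoffs are
# well-separated from the class distributions.
CONTROL_AXIS_RATIO_PARAMS = {
    "epithelial": (0.85, 0.08),
    "mixed": (0.50, 0.06),
    "mesenchymal": (0.18, 0.08),
}


def generate_cell_population(
    n_cells: int = 250,
    class_mix: dict[str, float] | tuple[float, float, float] = (0.25, 0.45, 0.30),
    axis_ratio_params: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_vertices: int = 180,
) -> tuple[list[CellOutline], list[str]]:
    """Outlines of a mixed population plus their true class labels.

    ``class_mix`` gives proportions over (epithelial, mixed, mesenchymal)
    and must sum to 1.  Axis ratios are drawn per class from truncated
    normals; cell size and orientation are random.  The default mix is a
    partial-EMT-like population dominated by mixed morphology.
    """
    if axis_ratio_params is None:
        axis_ratio_params = DEFAULT_AXIS_RATIO_PARAMS
    if not isinstance(class_mix, dict):
        class_mix = dict(zip(("epithelial", "mixed", "mesenchymal"), class_mix))
    p = np.array([class_mix.get(c, 0.0) for c in ("epithelial", "mixed", "mesenchymal")])
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError(f"class_mix must be non-negative and sum to 1, got {p}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    labels = rng.choice(("epithelial", "mixed", "mesenchymal"), size=n_cells, p=p)
    outlines: list[CellOutline] = []
    for i, lab in enumerate(labels):
        mean, sd = axis_ratio_params[lab]
        ratio = float(np.clip(rng.normal(mean, sd), 0.02, 1.0))
        a = rng.uniform(20.0, 40.0)
        outlines.append(
            generate_ellipse_outline(
                semi_major=a,
                semi_minor=ratio * a,
                n_vertices=n_vertices,
                rotation=rng.uniform(0.0, np.pi),
                center=(rng.uniform(0, 500), rng.uniform(0, 500)),
                cell_id=f"cell_{i:04d}",
            )
        )
    return outlines, list(labels)


# ---------------------------------------------------------------------------
# assay masks


def _disk_mask(shape: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return ((rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2).astype(np.uint8)


def generate_assay_masks(
    kind: str, params: dict | None = None, seed: int = 0
) -> tuple[dict[str, AssayMask], dict[str, float]]:
    """Time-indexed binary masks plus the true assay quantities.

    Truth values are computed from the masks themselves (integer pixel
    geometry), so quantifiers that read the masks back must reproduce
    them exactly.

    kind="wound"
        A confluent field with a vertical cell-free scratch whose width
        shrinks over timepoints; truth: percent closure per timepoint.
    kind="spheroid"
        A central occupied disk whose radius grows; truth: invasion area
        per timepoint in square microns.
    kind="brdu"
        A nuclei mask of disjoint 3x3 blobs and a BrdU mask marking a
        subset; truth: counts and positive percentage.
    """
    params = dict(params or {})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))

    if kind == "wound":
        h = int(params.get("height", 100))
        w = int(params.get("width", 200))
        widths = list(params.get("wound_widths", [60, 30, 15]))
        px = float(params.get("pixel_size_um", 1.0))
        if widths[0] <= 0:
            raise ValueError("initial wound width must be positive")
        masks, truth = {}, {}
        a0 = h * widths[0]
        for i, wd in enumerate(widths):
            grid = np.ones((h, w), dtype=np.uint8)
            if wd > 0:
                lo = (w - wd) // 2
                grid[:, lo : lo + wd] = 0
            label = f"t{i}"
            masks[label] = AssayMask(grid=grid, pixel_size_um=px, timepoint=label)
            wound_px = int((grid == 0).sum())
            truth[f"closure_pct_{label}"] = 100.0 * (a0 - wound_px) / a0
        return masks, truth

    if kind == "spheroid":
        size = int(params.get("size", 200))
        radii = list(params.get("radii", [30.0, 40.0, 48.0]))
        px = float(params.get("pixel_size_um", 1.0))
        masks, truth = {}, {}
        base = None
        for i, r in enumerate(radii):
            grid = _disk_mask((size, size), r)
            label = f"t{i}"
            masks[label] = AssayMask(grid=grid, pixel_size_um=px, timepoint=label)
            occupied = int(grid.sum())
            if base is None:
                base = occupied
            truth[f"invasion_um2_{label}"] = max(occupied - base, 0) * px**2
        return masks, truth

    if kind == "brdu":
        total = int(params.get("total_nuclei", 120))
        positive = int(params.get("brdu_positive", 30))
        if positive > total:
            raise ValueError("positive nuclei cannot exceed total")
        px = float(params.get("pixel_size_um", 1.0))
        # place nuclei as 3x3 blobs on a disjoint lattice
        per_row = int(np.ceil(np.sqrt(total)))
        size = per_row * 5 + 2
        nuclei = np.zeros((size, size), dtype=np.uint8)
        brdu = np.zeros_like(nuclei)
        pos_set = set(rng.choice(total, size=positive, replace=False).tolist())
        for k in range(total):
            r, c = divmod(k, per_row)
            rr, cc = 1 + 5 * r, 1 + 5 * c
            nuclei[rr : rr + 3, cc : cc + 3] = 1
            if k in pos_set:
                brdu[rr : rr + 3, cc : cc + 3] = 1
        masks = {
            "nuclei": AssayMask(grid=nuclei, pixel_size_um=px, timepoint="t0"),
            "brdu": AssayMask(grid=brdu, pixel_size_um=px, timepoint="t0"),
        }
        truth = {
            "total_nuclei": float(total),
            "brdu_positive": float(positive),
            "brdu_pct": 100.0 * positive / total,
        }
        return masks, truth

    raise ValueError(f"unknown assay kind {kind!r}")
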