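"""Plain-text readers and writers for every artifact the pipeline touches.

Conventions: probe x sample matrices are tab-separated with the probe id
in the first column; manifests, sample sheets, ground truth and outlines
are comma-separated; masks are whitespace-separated 0/1 grids (``.txt``)
or 0/255 PNG images; reports are JSON.  All writers go through a
temporary file renamed into place, so partially written outputs never
shadow complete ones.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from pemt.assays import AssayMask
from pemt.dataset import MethylationDataset, validate_manifest
from pemt.morphology import CellOutline
from pemt.synthetic import GroundTruth


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_matrix(df: pd.DataFrame, path) -> None:
    _atomic_write(Path(path), lambda fh: df.to_csv(fh, sep="\t", index_label="probe_id"))


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest)
    _atomic_write(Path(path), lambda fh: manifest.to_csv(fh, index_label="probe_id"))


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(
        path, index_col="probe_id", dtype={"chrom": str, "gene": str}
    )
    manifest["gene"] = manifest["gene"].fillna("")
    for col in ("is_cpg", "is_snp_associated", "is_multimapping"):
        manifest[col] = manifest[col].astype(bool)
    validate_manifest(manifest)
    return manifest


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    _atomic_write(Path(path), lambda fh: samples.to_csv(fh, index_label="sample_id"))


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_dataset(ds: MethylationDataset, out_dir) -> dict[str, Path]:
    """Write beta/detp/bead matrices and the sample sheet into a directory."""
    out = Path(out_dir)
    paths = {
        "beta": out / "beta.tsv",
        "detp": out / "detp.tsv",
        "beads": out / "beads.tsv",
        "samples": out / "samples.csv",
    }
    write_matrix(ds.beta, paths["beta"])
    write_matrix(ds.detp, paths["detp"])
    write_matrix(ds.beads, paths["beads"])
    write_sample_sheet(ds.samples, paths["samples"])
    return paths


def read_dataset(
    beta_path, detp_path=None, beads_path=None, samples_path=None
) -> MethylationDataset:
    """Assemble a dataset from matrix files.

    Missing detp/bead matrices (e.g. GEO series-matrix-style beta-only
    tables) default to all-passing values so the annotation-only filters
    still apply.
    """
    beta = read_matrix(beta_path)
    detp = (
        read_matrix(detp_path)
        if detp_path
        else pd.DataFrame(0.0, index=beta.index, columns=beta.columns)
    )
    beads = (
        read_matrix(beads_path)
        if beads_path
        else pd.DataFrame(100, index=beta.index, columns=beta.columns)
    )
    if samples_path:
        samples = read_sample_sheet(samples_path)
    else:
        # fall back to "<group>_<replicate>" column names
        parts = [c.rsplit("_", 1) for c in beta.columns]
        samples = pd.DataFrame(
            {"group": [p[0] for p in parts],
             "replicate": [int(p[1]) if len(p) > 1 else 1 for p in parts]},
            index=pd.Index(beta.columns, name="sample_id"),
        )
    return MethylationDataset(beta=beta, detp=detp, beads=beads, samples=samples)


def write_ground_truth(truth: GroundTruth, path) -> None:
    rescue = set(truth.rescue_ids)
    df = pd.DataFrame(
        {
            "probe_id": list(truth.differential_ids),
            "is_rescue": [pid in rescue for pid in truth.differential_ids],
        }
    )
    _atomic_write(Path(path), lambda fh: df.to_csv(fh, index=False))


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path)
    return GroundTruth(
        differential_ids=tuple(df["probe_id"]),
        rescue_ids=tuple(df.loc[df["is_rescue"].astype(bool), "probe_id"]),
    )


def write_outlines(outlines, path) -> None:
    rows = []
    for o in outlines:
        for j, (x, y) in enumerate(o.vertices):
            rows.append((o.cell_id, j, x, y))
    df = pd.DataFrame(rows, columns=["cell_id", "vertex_index", "x", "y"])
    _atomic_write(Path(path), lambda fh: df.to_csv(fh, index=False))


def read_outlines(path) -> list[CellOutline]:
    df = pd.read_csv(path)
    outlines = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("vertex_index")
        outlines.append(
            CellOutline(cell_id=str(cid), vertices=grp[["x", "y"]].to_numpy())
        )
    return outlines


def write_mask(mask: AssayMask, path) -> None:
    """Write a mask as a 0/1 text grid (.txt) or a 0/255 PNG."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(path, (mask.grid * 255).astype(np.uint8))
    else:
        _atomic_write(
            path,
            lambda fh: np.savetxt(fh, mask.grid, fmt="%d", delimiter=" "),
        )


def read_mask(path, pixel_size_um: float = 1.0, timepoint: str = "") -> AssayMask:
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        grid = (np.asarray(iio.imread(path)) > 127).astype(np.uint8)
        if grid.ndim == 3:
            grid = grid[..., 0]
    else:
        grid = np.loadtxt(path, dtype=int)
    return AssayMask(grid=grid, pixel_size_um=pixel_size_um, timepoint=timepoint)


def write_json(obj, path) -> None:
    _atomic_write(Path(path), lambda fh: json.dump(obj, fh, indent=2, sort_keys=True))


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Generic TSV writer for differential / rescue / gene tables."""
    _atomic_write(Path(path), lambda fh: df.to_csv(fh, sep="\t", index=index))


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
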