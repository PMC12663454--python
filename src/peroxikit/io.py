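"""Readers and writers for the tables, stacks and reports used by the
pipeline.  All writes are atomic (temp file in the destination directory,
then rename)."""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .hurdle import REQUIRED_COUNT_COLUMNS
from .imaging import ImageStack3D, SpotSet
from .viability import REQUIRED_PLATE_COLUMNS

__all__ = [
    "ParseError",
    "read_count_table",
    "write_count_table",
    "read_plate_table",
    "write_plate_table",
    "read_stack",
    "write_stack",
    "write_spotset_csv",
    "load_config",
    "write_json",
    "write_manifest",
    "atomic_write_text",
]


class ParseError(ValueError):
    pass


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a per-cell count table (CSV/TSV).

    Malformed rows are reported with their file line number (header is
    line 1)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no data rows") from None
    missing = [c for c in REQUIRED_COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if len(table) == 0:
        raise ParseError(f"{path}: no data rows")
    counts = pd.to_numeric(table["count"], errors="coerce")
    bad = table.index[counts.isna() | (counts != counts.round()) | (counts < 0)]
    if len(bad):
        line = int(bad[0]) + 2  # +1 header, +1 zero-based
        raise ParseError(
            f"{path}: line {line}: count {table.loc[bad[0], 'count']!r} "
            "is not a non-negative integer"
        )
    table["count"] = counts.astype(np.int64)
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    atomic_write_text(path, table.to_csv(index=False, sep=_sep_for(path)))


def read_plate_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no data rows") from None
    missing = [c for c in REQUIRED_PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if len(table) == 0:
        raise ParseError(f"{path}: no data rows")
    doses = pd.to_numeric(table["primary_dose"], errors="coerce")
    bad = table.index[doses.isna() | (doses < 0)]
    if len(bad):
        raise ParseError(f"{path}: line {int(bad[0]) + 2}: invalid primary_dose")
    table["primary_dose"] = doses
    return table


def write_plate_table(table: pd.DataFrame, path) -> None:
    atomic_write_text(path, table.to_csv(index=False, sep=_sep_for(path)))


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: ImageStack3D, path) -> None:
    """Write a stack as single-channel TIFF plus a voxel-size sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels.astype(np.float32), photometric="minisblack")
    atomic_write_text(
        _sidecar_path(path), json.dumps({"voxel_size_um": list(stack.voxel_size)})
    )


def read_stack(path, voxel_size=None) -> ImageStack3D:
    """Read a TIFF stack.

    Voxel size precedence: explicit argument > sidecar JSON > TIFF
    (ImageJ) metadata; an error is raised when none is available.  A 2-D
    image is promoted to a single-slice stack with a warning; multi-channel
    files are rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_voxel = None
        if voxel_size is None:
            ij = tif.imagej_metadata or {}
            page = tif.pages[0]
            res = page.resolution if hasattr(page, "resolution") else None
            if "spacing" in ij and res and res[0]:
                meta_voxel = (float(ij["spacing"]), 1.0 / res[1], 1.0 / res[0])
    if data.ndim == 2:
        warnings.warn("2-D image promoted to a single-slice stack", stacklevel=2)
        data = data[None, :, :]
    if data.ndim != 3:
        raise ParseError(
            f"{path}: expected a single-channel 3-D stack, got shape {data.shape}"
        )
    if voxel_size is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            voxel_size = tuple(json.loads(sidecar.read_text())["voxel_size_um"])
        elif meta_voxel is not None:
            voxel_size = meta_voxel
        else:
            raise ParseError(f"{path}: voxel size not given and not found in metadata")
    return ImageStack3D(voxels=np.asarray(data, dtype=float), voxel_size=tuple(voxel_size))


def write_labels(labels: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32), photometric="minisblack")


def write_spotset_csv(spots: SpotSet, path) -> None:
    assign = (
        spots.per_cell_assignment
        if spots.per_cell_assignment is not None
        else np.zeros(spots.n_spots, dtype=int)
    )
    df = pd.DataFrame(
        {
            "label": np.arange(1, spots.n_spots + 1),
            "z_um": spots.centroids_um[:, 0] if spots.n_spots else [],
            "y_um": spots.centroids_um[:, 1] if spots.n_spots else [],
            "x_um": spots.centroids_um[:, 2] if spots.n_spots else [],
            "volume_um3": spots.volumes_um3,
            "cell_id": assign,
        }
    )
    atomic_write_text(path, df.to_csv(index=False))


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file (keys = parameter fields)."""
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, cls=_JSONEncoder) + "\n")


def write_manifest(path, command: str, config: dict, seed, outputs: list[str]) -> None:
    """Run manifest: everything needed to reproduce the outputs byte-for-byte."""
    from . import __version__

    write_json(
        {
            "command": command,
            "version": __version__,
            "seed": seed,
            "config": config,
            "outputs": outputs,
        },
        path,
    )
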