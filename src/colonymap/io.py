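"""File formats: multi-page TIFF fields with JSON sidecars, CSV tables.

A field is stored as one multi-page TIFF (one page per channel, or per z
plane for volumetric channels) plus a sidecar ``<name>.json`` declaring
the page order, grid position, pixel size and z step.  All tables are
plain CSV with fixed column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import GridSpec
from .images import FieldImage, LabelMatrix


def write_field(field: FieldImage, path: str | Path) -> None:
    """Write one field as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    pages = []
    layout = []
    for name, arr in field.channels.items():
        if arr.ndim == 2:
            pages.append(arr)
            layout.append({"channel": name, "pages": 1})
        else:
            pages.extend(arr)
            layout.append({"channel": name, "pages": int(arr.shape[0])})
    tifffile.imwrite(path, np.stack(pages).astype(np.float32), photometric="minisblack")
    sidecar = {
        "layout": layout,
        "field_x": field.field_x,
        "field_y": field.field_y,
        "pixel_size_um": field.pixel_size_um,
        "z_step_um": field.z_step_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_field(path: str | Path) -> FieldImage:
    """Read a field written by :func:`write_field`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    channels = {}
    i = 0
    for entry in meta["layout"]:
        n = entry["pages"]
        chunk = data[i : i + n]
        channels[entry["channel"]] = chunk[0] if n == 1 else chunk
        i += n
    return FieldImage(
        channels,
        meta["field_x"],
        meta["field_y"],
        meta["pixel_size_um"],
        meta.get("z_step_um", 0.0),
    )


def write_labels(labels: LabelMatrix, path: str | Path) -> None:
    """Write a label matrix as 16-bit single-page TIFF."""
    data = labels.data
    if data.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; 16-bit TIFF cannot hold them")
    tifffile.imwrite(Path(path), data.astype(np.uint16), photometric="minisblack")
    Path(path).with_suffix(".json").write_text(
        json.dumps({"pixel_size_um": labels.pixel_size_um, "provenance": str(labels.provenance)})
    )


def read_labels(path: str | Path) -> LabelMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return LabelMatrix(
        tifffile.imread(path).astype(np.int32), meta["pixel_size_um"], meta["provenance"]
    )


def grid_to_json(grid: GridSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(grid.__dict__, indent=1))


def grid_from_json(path: str | Path) -> GridSpec:
    return GridSpec(**json.loads(Path(path).read_text()))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
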