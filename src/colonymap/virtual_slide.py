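"""Seamless region maps from overlapping per-field segmentations.

Rather than stitching raw pixels, per-field segmentation label matrices
are placed into a region label matrix using the known grid geometry, and
duplicate instances of objects that were segmented in two adjacent
overlapping fields are resolved by keeping the larger instance.  Provided
the overlap margin is at least twice the diameter of the largest cell,
every cell is fully contained in at least one field, so the larger
instance is always a complete segmentation of the object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import GridSpec
from .images import FieldImage, LabelMatrix


@dataclass(frozen=True)
class CellAddress:
    """Global address of one segmented cell within a region.

    ``global_label`` indexes the region label matrix; ``source_label`` is
    the label in the originating field's matrix.  Centroids are 0-based
    region pixel coordinates (y, x) and micrometres.
    """

    global_label: int
    region: int
    field_x: int
    field_y: int
    source_label: int
    centroid_y_px: float
    centroid_x_px: float
    centroid_y_um: float
    centroid_x_um: float
    colony_id: int = 0


def mosaic_fields(
    fields: list[FieldImage],
    grid: GridSpec,
    channel: str | None = None,
) -> dict[str, np.ndarray] | np.ndarray:
    """Assemble field images into a region image.

    Overlap pixels are owned by the field with the smaller grid index
    (fields are written in reverse row-major order so low indices land
    last): deterministic, and downstream analysis relies on label
    consensus rather than pixel blending.

    Returns a dict of channel -> region image, or a single array if
    ``channel`` is given.
    """
    by_pos = {(f.field_x, f.field_y): f for f in fields}
    for fx, fy in grid.iter_fields():
        if (fx, fy) not in by_pos:
            raise ValueError(f"missing field ({fx}, {fy}) in grid")
    ref = fields[0]
    names = [channel] if channel is not None else list(ref.channels)
    out: dict[str, np.ndarray] = {}
    for name in names:
        arr = ref.channel(name)
        shape = (grid.region_height, grid.region_width)
        if arr.ndim == 3:
            shape = (arr.shape[0],) + shape
        region = np.zeros(shape, dtype=arr.dtype)
        for fx, fy in reversed(list(grid.iter_fields())):
            f = by_pos[(fx, fy)]
            oy, ox = grid.field_origin(fx, fy)
            region[..., oy : oy + grid.field_height, ox : ox + grid.field_width] = f.channel(name)
        out[name] = region
    return out[channel] if channel is not None else out


def _objects_in_region_frame(
    lab: LabelMatrix, fx: int, fy: int, grid: GridSpec
) -> list[dict]:
    """Per-object slices, areas and centroids, shifted to region coords."""
    oy, ox = grid.field_origin(fx, fy)
    data = lab.data
    objs = []
    for sl, label in zip(ndimage.find_objects(data), range(1, int(data.max()) + 1)):
        if sl is None:
            continue
        mask = data[sl] == label
        area = int(mask.sum())
        cy, cx = ndimage.center_of_mass(mask)
        objs.append(
            dict(
                field=(fx, fy),
                label=label,
                area=area,
                mask=mask,
                y0=sl[0].start + oy,
                x0=sl[1].start + ox,
                cy=sl[0].start + cy + oy,
                cx=sl[1].start + cx + ox,
            )
        )
    return objs


def consensus_segmentation(
    field_labels: list[LabelMatrix],
    grid: GridSpec,
    max_cell_diameter_um: float,
) -> tuple[LabelMatrix, dict[tuple[int, int, int], int]]:
    """Merge per-field label matrices into one duplicate-free region matrix.

    Two instances from different fields are deemed the same physical
    object when their region-frame footprints share at least one pixel
    and their centroids lie within one maximum cell diameter (the
    centroid guard prevents chained merges of touching neighbours).  Of
    each correspondence group the largest-area instance is kept; area
    ties go to the instance from the lower grid index.  Correspondence is
    applied transitively, which also resolves 4-field corner overlaps.
    Objects touching the outermost 1-px frame of the region are
    discarded, as segmentations there are unreliable.

    Emits a warning when ``overlap < 2 * max_cell_diameter`` in pixels:
    below that margin a cell may straddle a field border without being
    fully contained in either field.

    Returns the region :class:`LabelMatrix` (labels 1..K, assigned in
    order of (fy, fx, source label) of the kept instance) and a mapping
    ``(fx, fy, source_label) -> global_label`` covering every kept
    instance; dropped duplicates map to the global label of their kept
    counterpart.
    """
    if not field_labels:
        raise ValueError("no field label matrices given")
    px = field_labels[0].pixel_size_um
    min_overlap = 2.0 * max_cell_diameter_um / px
    if grid.overlap < min_overlap and (grid.n_fields_x > 1 or grid.n_fields_y > 1):
        warnings.warn(
            f"overlap {grid.overlap} px is below 2 x max cell diameter "
            f"({min_overlap:.0f} px); cells may straddle field borders uncontained",
            stacklevel=2,
        )

    by_pos: dict[tuple[int, int], LabelMatrix] = {}
    for lm in field_labels:
        if not isinstance(lm.provenance, tuple):
            raise ValueError("field label matrices must carry (fx, fy) provenance")
        by_pos[lm.provenance] = lm
    for fx, fy in grid.iter_fields():
        if (fx, fy) not in by_pos:
            raise ValueError(f"missing label matrix for field ({fx}, {fy})")

    objs: list[dict] = []
    for (fx, fy), lm in sorted(by_pos.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        objs.extend(_objects_in_region_frame(lm, fx, fy, grid))

    # paint footprints onto an object-index canvas per parity to find overlaps
    H, W = grid.region_height, grid.region_width
    # union-find over object indices
    parent = list(range(len(objs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    max_d_px = max_cell_diameter_um / px
    # overlap detection: for each pair of objects from different fields with
    # intersecting bounding boxes, test pixel overlap of footprints
    for i in range(len(objs)):
        a = objs[i]
        ah, aw = a["mask"].shape
        for j in range(i + 1, len(objs)):
            b = objs[j]
            if a["field"] == b["field"]:
                continue
            bh, bw = b["mask"].shape
            y0 = max(a["y0"], b["y0"])
            x0 = max(a["x0"], b["x0"])
            y1 = min(a["y0"] + ah, b["y0"] + bh)
            x1 = min(a["x0"] + aw, b["x0"] + bw)
            if y0 >= y1 or x0 >= x1:
                continue
            if (a["cy"] - b["cy"]) ** 2 + (a["cx"] - b["cx"]) ** 2 > max_d_px**2:
                continue
            sub_a = a["mask"][y0 - a["y0"] : y1 - a["y0"], x0 - a["x0"] : x1 - a["x0"]]
            sub_b = b["mask"][y0 - b["y0"] : y1 - b["y0"], x0 - b["x0"] : x1 - b["x0"]]
            if np.any(sub_a & sub_b):
                union(i, j)

    # keep the largest instance per correspondence group
    groups: dict[int, list[int]] = {}
    for i in range(len(objs)):
        groups.setdefault(find(i), []).append(i)
    kept_for_group: dict[int, int] = {}
    for root, members in groups.items():
        # largest area; ties -> lower (fy, fx) then lower source label
        best = min(
            members,
            key=lambda i: (-objs[i]["area"], objs[i]["field"][1], objs[i]["field"][0], objs[i]["label"]),
        )
        kept_for_group[root] = best

    region = np.zeros((H, W), np.int32)
    mapping: dict[tuple[int, int, int], int] = {}
    next_label = 1
    kept_global: dict[int, int] = {}
    order = sorted(
        kept_for_group.items(),
        key=lambda kv: (objs[kv[1]]["field"][1], objs[kv[1]]["field"][0], objs[kv[1]]["label"]),
    )
    for root, i in order:
        o = objs[i]
        ys, xs = np.nonzero(o["mask"])
        ys = ys + o["y0"]
        xs = xs + o["x0"]
        # discard objects touching the outer border of the whole region
        if ys.min() == 0 or xs.min() == 0 or ys.max() == H - 1 or xs.max() == W - 1:
            kept_global[root] = 0
            continue
        region[ys, xs] = next_label
        kept_global[root] = next_label
        next_label += 1
    for i, o in enumerate(objs):
        g = kept_global.get(find(i), 0)
        if g:
            mapping[(o["field"][0], o["field"][1], o["label"])] = g

    return LabelMatrix(region, px, "region"), mapping


def assign_addresses(
    region_labels: LabelMatrix,
    colony_labels: LabelMatrix,
    region: int = 0,
    mapping: dict[tuple[int, int, int], int] | None = None,
) -> list[CellAddress]:
    """Address every cell in a region: centroid, source field, colony id.

    A cell's colony id is the colony label under its centroid pixel;
    centroids in background get colony id 0 — these are peripheral cells,
    loosely associated with the outside of a colony (distance-from-edge
    0).  When ``mapping`` from :func:`consensus_segmentation` is given,
    each address records the originating field and source label of the
    kept instance; otherwise field coordinates are (0, 0) and the source
    label equals the global label.
    """
    if region_labels.data.shape != colony_labels.data.shape:
        raise ValueError("region and colony label matrices must have the same shape")
    px = region_labels.pixel_size_um
    data = region_labels.data
    labels = region_labels.labels
    if labels.size == 0:
        return []
    cents = ndimage.center_of_mass(data > 0, data, labels)
    inv = {}
    if mapping:
        for (fx, fy, src), g in mapping.items():
            inv.setdefault(g, (fx, fy, src))
    out = []
    for label, (cy, cx) in zip(labels, cents):
        colony = int(colony_labels.data[int(round(cy)), int(round(cx))])
        fx, fy, src = inv.get(int(label), (0, 0, int(label)))
        out.append(
            CellAddress(
                global_label=int(label),
                region=region,
                field_x=fx,
                field_y=fy,
                source_label=src,
                centroid_y_px=float(cy),
                centroid_x_px=float(cx),
                centroid_y_um=float(cy) * px,
                centroid_x_um=float(cx) * px,
                colony_id=colony,
            )
        )
    return out
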