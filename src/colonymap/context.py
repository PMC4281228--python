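"""Spatial population context of cells within colonies.

Derives, for every segmented cell: the distance from its colony's edge
(Euclidean distance transform of the colony mask, 0 outside any colony),
membership in cell layers counted in units of one cell diameter from the
edge, the size class of its colony, and a local-density class obtained
by tiling each colony's bounding box into fixed-size windows and
classifying windows by contained cell count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import LabelMatrix

PERIPHERY = "periphery"
INTERIOR = "interior"

#: colony size classes by maximum edge distance (um): small < 150,
#: medium in [150, 300], large > 300
SIZE_EDGES_UM = (150.0, 300.0)

#: default density window dimensions, um (width x height)
DEFAULT_WINDOW_W_UM = 250.0
DEFAULT_WINDOW_H_UM = 192.0


@dataclass(frozen=True)
class DensityWindow:
    """One rectangular density window tiling a colony bounding box.

    Bounds are half-open ``[x0, x1) x [y0, y1)`` in um, region frame.
    """

    window_id: int
    colony_id: int
    x0_um: float
    y0_um: float
    x1_um: float
    y1_um: float
    count: int
    density_class: str | None = None


def distance_from_edge(
    colony_labels: LabelMatrix,
    centroids_um: np.ndarray,
) -> np.ndarray:
    """Distance of each centroid from its colony's edge, in um.

    Evaluates the per-colony Euclidean distance transform (distance to
    the edge of the pixel's own colony) at each centroid pixel.
    Centroids outside every colony (background) get exactly 0: such
    cells sit at, or peripheral to, a colony boundary.
    ``centroids_um`` is (n, 2) as (y_um, x_um) in the same frame as the
    label matrix.
    """
    from .segmentation import interior_distance

    px = colony_labels.pixel_size_um
    dist = interior_distance(colony_labels) * px
    pts = np.asarray(centroids_um, float).reshape(-1, 2)
    iy = np.clip((pts[:, 0] / px).round().astype(int), 0, dist.shape[0] - 1)
    ix = np.clip((pts[:, 1] / px).round().astype(int), 0, dist.shape[1] - 1)
    return dist[iy, ix]


def assign_layers(
    distances_um: np.ndarray,
    cell_diameter_um: float,
    n_layers: int = 3,
) -> np.ndarray:
    """Bin edge distances into periphery / Layer 1..n / interior.

    Distance 0 is the periphery (outside or at the colony edge); a
    distance in ``((k-1) d, k d]`` is Layer k — Layer 1 being the
    outermost ring of cells belonging to the colony — and anything
    beyond ``n_layers`` diameters is interior.
    """
    if cell_diameter_um <= 0:
        raise ValueError("cell diameter must be positive")
    d = np.asarray(distances_um, float)
    if d.size and d.min() < 0:
        raise ValueError("distances must be non-negative")
    k = np.ceil(d / cell_diameter_um).astype(int)
    out = np.where(d == 0, PERIPHERY, np.where(k > n_layers, INTERIOR, "")).astype(object)
    sel = (d > 0) & (k <= n_layers)
    out[sel] = [f"Layer {kk}" for kk in k[sel]]
    return out.astype(str)


def classify_colony_size(max_edge_distance_um: float) -> str:
    """Size class from the maximum cellular distance to the colony edge.

    small < 150 um, medium in [150, 300] um, large > 300 um.  Both
    boundaries belong to the medium class.
    """
    if max_edge_distance_um < 0:
        raise ValueError("distance must be non-negative")
    lo, hi = SIZE_EDGES_UM
    if max_edge_distance_um < lo:
        return "small"
    if max_edge_distance_um <= hi:
        return "medium"
    return "large"


def median_cell_diameter_um(areas_um2: np.ndarray) -> float:
    """Median equivalent diameter of segmented nuclei — the default
    layer width when no diameter is configured."""
    a = np.asarray(areas_um2, float)
    return float(np.median(2.0 * np.sqrt(a / np.pi)))


def density_windows(
    cells: pd.DataFrame,
    window_w_um: float = DEFAULT_WINDOW_W_UM,
    window_h_um: float = DEFAULT_WINDOW_H_UM,
    class_edges: tuple[float, float] | None = None,
) -> tuple[list[DensityWindow], pd.DataFrame]:
    """Tile each colony's bounding box into windows and classify density.

    ``cells`` needs columns colony_id, centroid_x_um, centroid_y_um.
    Each colony's centroid bounding box is tiled with non-overlapping
    windows of the given size (partial edge windows kept), window counts
    are computed, and windows are classed low / mixed / high by the two
    ``class_edges`` (count < e0 -> low, count > e1 -> high, else mixed).
    When edges are not given they default to the tertiles of the window
    counts over the whole sample.  Cells with colony id 0 (periphery)
    receive no density class.

    Returns the window list and a per-cell DataFrame aligned to
    ``cells.index`` with columns ``window_id`` (-1 when unassigned) and
    ``density_class`` (None when unassigned).
    """
    if window_w_um <= 0 or window_h_um <= 0:
        raise ValueError("window dimensions must be positive")
    windows: list[DensityWindow] = []
    cell_window = pd.Series(-1, index=cells.index, dtype=int)
    wid = 0
    for cid, grp in cells[cells.colony_id > 0].groupby("colony_id"):
        x0, x1 = grp.centroid_x_um.min(), grp.centroid_x_um.max()
        y0, y1 = grp.centroid_y_um.min(), grp.centroid_y_um.max()
        nx = max(1, int(np.ceil((x1 - x0) / window_w_um)))
        ny = max(1, int(np.ceil((y1 - y0) / window_h_um)))
        for j in range(ny):
            for i in range(nx):
                wx0, wy0 = x0 + i * window_w_um, y0 + j * window_h_um
                wx1, wy1 = wx0 + window_w_um, wy0 + window_h_um
                in_x = (grp.centroid_x_um >= wx0) & (grp.centroid_x_um < wx1)
                in_y = (grp.centroid_y_um >= wy0) & (grp.centroid_y_um < wy1)
                # rightmost/bottom cells sit exactly on the closed max bound
                if i == nx - 1:
                    in_x |= grp.centroid_x_um == x1
                if j == ny - 1:
                    in_y |= grp.centroid_y_um == y1
                inside = in_x & in_y
                idx = grp.index[inside]
                windows.append(
                    DensityWindow(wid, int(cid), wx0, wy0, wx1, wy1, int(inside.sum()))
                )
                cell_window.loc[idx] = wid
                wid += 1

    counts = np.array([w.count for w in windows], float)
    empty = pd.DataFrame(
        {"window_id": cell_window, "density_class": pd.Series(None, index=cells.index, dtype=object)}
    )
    if class_edges is None:
        if counts.size == 0:
            return windows, empty
        class_edges = tuple(np.quantile(counts, [1 / 3, 2 / 3]))
    e0, e1 = class_edges
    classed = []
    for w in windows:
        cls = "low" if w.count < e0 else ("high" if w.count > e1 else "mixed")
        classed.append(
            DensityWindow(
                w.window_id, w.colony_id, w.x0_um, w.y0_um, w.x1_um, w.y1_um, w.count, cls
            )
        )
    class_by_wid = {w.window_id: w.density_class for w in classed}
    per_cell = pd.DataFrame(
        {
            "window_id": cell_window,
            "density_class": cell_window.map(lambda i: class_by_wid.get(i)),
        }
    )
    return classed, per_cell


def equal_count_bins(distances_um: np.ndarray, k: int) -> np.ndarray:
    """Interval edges partitioning values into k near-equal-count bins.

    Edges are the empirical quantiles at i/k, i = 0..k; with heavy ties
    coincident edges are collapsed (with a warning), so fewer than k
    bins may result.  Per-bin counts differ by at most the number of
    ties at an edge.
    """
    x = np.asarray(distances_um, float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < k:
        raise ValueError(f"cannot form {k} bins from {x.size} values")
    edges = np.quantile(x, np.linspace(0, 1, k + 1))
    uniq = np.unique(edges)
    if uniq.size < edges.size:
        warnings.warn(
            f"collapsed {edges.size - uniq.size} duplicate bin edges (heavy ties)",
            stacklevel=2,
        )
        edges = uniq
    if edges.size < 2:  # all values identical: one degenerate bin
        edges = np.array([edges[0], edges[0]])
    return edges


def bin_index(distances_um: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign each value to a bin: edges half-open, last bin closed."""
    x = np.asarray(distances_um, float)
    idx = np.searchsorted(edges, x, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def attach_context(
    cells: pd.DataFrame,
    colony_labels: LabelMatrix,
    colony_max_edge_um: dict[int, float],
    cell_diameter_um: float | None = None,
    n_layers: int = 3,
    window_w_um: float = DEFAULT_WINDOW_W_UM,
    window_h_um: float = DEFAULT_WINDOW_H_UM,
    density_edges: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, list[DensityWindow]]:
    """Fill the context columns of a cell table in place of Nones.

    Adds distance_um, layer, size_class, window_id and density_class.
    The layer width defaults to the median equivalent diameter of the
    sample's nuclei.
    """
    out = cells.copy()
    cents = out[["centroid_y_um", "centroid_x_um"]].to_numpy()
    out["distance_um"] = distance_from_edge(colony_labels, cents)
    # cells recorded as background sit at distance 0 by definition
    out.loc[out.colony_id == 0, "distance_um"] = 0.0
    if cell_diameter_um is None:
        cell_diameter_um = median_cell_diameter_um(out.area_um2.to_numpy())
    out["layer"] = assign_layers(out.distance_um.to_numpy(), cell_diameter_um, n_layers)
    out["size_class"] = out.colony_id.map(
        lambda c: classify_colony_size(colony_max_edge_um[c]) if c in colony_max_edge_um else None
    )
    windows, per_cell = density_windows(out, window_w_um, window_h_um, density_edges)
    out["density_class"] = per_cell.density_class
    out["window_id"] = per_cell.window_id
    return out, windows
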