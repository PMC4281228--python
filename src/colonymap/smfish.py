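"""Single-molecule FISH spot detection across overlapping field grids.

Each mRNA spot is the diffraction-limited image of a single molecule.
Detection runs per z-stack: a morphological opening (white top-hat)
removes out-of-focus background, a Laplacian-of-Gaussian filter sharpens
candidate foci, and 3-D local maxima are scored by a statistic combining
the spot's 3-D curvature (how much it resembles a point source) with its
intensity above local background.  Because illumination and signal vary
between fields, per-field detection thresholds are equalized by
minimizing the squared (or absolute) differences of spot counts in the
physically shared margins of adjacent fields; the resulting threshold
matrix S = [s_xy] makes detection consistent across the whole region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import GridSpec
from .images import FieldImage, LabelMatrix

#: candidate table columns produced by :func:`detect_candidates`
CANDIDATE_COLUMNS = ("z_px", "y_px", "x_px", "statistic", "intensity", "field_x", "field_y")


@dataclass(frozen=True)
class SpotCandidate:
    """One candidate focus: position, score, peak intensity, field."""

    z_px: int
    y_px: int
    x_px: int
    statistic: float
    intensity: float
    field_x: int = 0
    field_y: int = 0


@dataclass
class ThresholdMatrix:
    """Per-field spot thresholds S = [s_xy] with equalization diagnostics.

    ``s[fy, fx]`` indexes the grid row-major; ``s0`` is the initial
    constant estimate from thresholding the combined candidates of all
    fields; ``objective`` / ``objective_initial`` are the margin-count
    error at S and at S0.
    """

    s: np.ndarray
    s0: float
    objective: float
    objective_initial: float
    norm: int

    def threshold(self, fx: int, fy: int) -> float:
        return float(self.s[fy, fx])


def preprocess_stack(
    stack: np.ndarray,
    open_radius_px: int = 3,
    log_sigma_px: float = 1.3,
    z_sigma_scale: float = 1.0,
) -> np.ndarray:
    """Background removal and spot sharpening for one z-stack.

    Subtracts a per-plane morphological opening (grey top-hat: the
    opening estimates the smooth out-of-focus background, so subtracting
    it leaves the diffraction-limited foci), then applies a Laplacian of
    Gaussian, negated so spots become positive peaks.  The axial LoG
    sigma is ``log_sigma_px * z_sigma_scale`` to account for anisotropic
    voxel spacing.

    Warns when ``open_radius_px`` is smaller than the spot radius: then
    the opening preserves the spots and the subtraction erases them.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("expected a 3-D stack with at least 3 z planes")
    if open_radius_px < 2.0 * log_sigma_px:
        warnings.warn(
            f"open_radius {open_radius_px} px < spot radius ~{2 * log_sigma_px:.1f} px: "
            "the top-hat may erase spots",
            stacklevel=2,
        )
    size = 2 * open_radius_px + 1
    opened = np.stack([ndimage.grey_opening(pl, size=(size, size)) for pl in stack])
    tophat = stack - opened
    sigma = (log_sigma_px * z_sigma_scale, log_sigma_px, log_sigma_px)
    return -ndimage.gaussian_laplace(tophat, sigma=sigma)


def detect_candidates(
    filtered: np.ndarray,
    raw: np.ndarray,
    floor: float | None = None,
    smooth_sigma_px: float = 1.0,
    field_x: int = 0,
    field_y: int = 0,
) -> pd.DataFrame:
    """Find and score candidate foci in a preprocessed stack.

    Candidates are 3-D local maxima (26-connectivity) of the filtered
    stack above a permissive ``floor`` (default: 2 standard deviations
    above the filtered stack's median — low enough to keep near-noise
    spots for the threshold-equalization stage).  Each candidate is
    scored by :func:`spot_statistic` on the raw stack.

    Returns a DataFrame with columns ``CANDIDATE_COLUMNS``, sorted by
    descending statistic.
    """
    filtered = np.asarray(filtered, float)
    raw = np.asarray(raw, float)
    if filtered.size == 0 or not np.any(filtered > 0):
        return pd.DataFrame(columns=list(CANDIDATE_COLUMNS))
    if floor is None:
        med = float(np.median(filtered))
        floor = med + 2.0 * float(filtered.std())
    maxima = (ndimage.maximum_filter(filtered, size=3, mode="nearest") == filtered) & (
        filtered > floor
    )
    zz, yy, xx = np.nonzero(maxima)
    if zz.size == 0:
        return pd.DataFrame(columns=list(CANDIDATE_COLUMNS))
    smooth = ndimage.gaussian_filter(raw, smooth_sigma_px)
    stats = np.empty(zz.size)
    intens = np.empty(zz.size)
    for i, (z, y, x) in enumerate(zip(zz, yy, xx)):
        stats[i], intens[i] = _statistic_at(smooth, (z, y, x))
    df = pd.DataFrame(
        dict(
            z_px=zz, y_px=yy, x_px=xx, statistic=stats, intensity=intens,
            field_x=field_x, field_y=field_y,
        )
    )
    df = df[df.statistic > 0].sort_values("statistic", ascending=False)
    return df.reset_index(drop=True)


def spot_statistic(
    raw: np.ndarray,
    filtered: np.ndarray,
    position: tuple[int, int, int],
    smooth_sigma_px: float = 1.0,
) -> float:
    """Point-source score of one candidate maximum.

    The statistic is the mean magnitude of the negative principal
    curvatures of the Gaussian-smoothed raw stack at the peak (the
    eigenvalues of the 3x3 second-derivative matrix over z, y, x)
    multiplied by the peak intensity above the local background.  It is
    strictly increasing in both sharpness and brightness, and scales as
    c^2 when the raw stack is multiplied by c.

    Raises ``ValueError`` if the position is not a local maximum of the
    filtered stack.
    """
    filtered = np.asarray(filtered, float)
    z, y, x = position
    neigh = filtered[
        max(0, z - 1) : z + 2, max(0, y - 1) : y + 2, max(0, x - 1) : x + 2
    ]
    if filtered[z, y, x] < neigh.max():
        raise ValueError(f"position {position} is not a local maximum")
    smooth = ndimage.gaussian_filter(np.asarray(raw, float), smooth_sigma_px)
    stat, _ = _statistic_at(smooth, position)
    return stat


def _statistic_at(smooth: np.ndarray, pos: tuple[int, int, int]) -> tuple[float, float]:
    """(curvature x intensity score, peak intensity above background)."""
    Z, H, W = smooth.shape
    z, y, x = int(pos[0]), int(pos[1]), int(pos[2])
    z = min(max(z, 1), Z - 2)
    y = min(max(y, 1), H - 2)
    x = min(max(x, 1), W - 2)
    v = smooth
    c = v[z, y, x]
    # 3x3 Hessian by central second differences
    hzz = v[z + 1, y, x] - 2 * c + v[z - 1, y, x]
    hyy = v[z, y + 1, x] - 2 * c + v[z, y - 1, x]
    hxx = v[z, y, x + 1] - 2 * c + v[z, y, x - 1]
    hzy = (v[z + 1, y + 1, x] - v[z + 1, y - 1, x] - v[z - 1, y + 1, x] + v[z - 1, y - 1, x]) / 4
    hzx = (v[z + 1, y, x + 1] - v[z + 1, y, x - 1] - v[z - 1, y, x + 1] + v[z - 1, y, x - 1]) / 4
    hyx = (v[z, y + 1, x + 1] - v[z, y + 1, x - 1] - v[z, y - 1, x + 1] + v[z, y - 1, x - 1]) / 4
    hess = np.array([[hzz, hzy, hzx], [hzy, hyy, hyx], [hzx, hyx, hxx]])
    eig = np.linalg.eigvalsh(hess)
    neg = eig[eig < 0]
    curvature = float(-neg.mean()) if neg.size else 0.0
    # local background: median of a box shell around the peak
    rb = 6
    z0, z1 = max(0, z - 2), min(Z, z + 3)
    y0, y1 = max(0, y - rb), min(H, y + rb + 1)
    x0, x1 = max(0, x - rb), min(W, x + rb + 1)
    box = v[z0:z1, y0:y1, x0:x1]
    inner = v[max(0, z - 1) : z + 2, max(0, y - 2) : y + 3, max(0, x - 2) : x + 3]
    bg = (np.sum(box) - np.sum(inner)) / max(box.size - inner.size, 1)
    intensity = max(float(c - bg), 0.0)
    return curvature * intensity, intensity


# ---------------------------------------------------------------------------
# threshold equalization across fields
# ---------------------------------------------------------------------------


def margin_counts(
    candidates: pd.DataFrame,
    grid: GridSpec,
    s: float,
) -> dict[str, int]:
    """Spot counts above threshold ``s`` in one field's four margins.

    Margins are the physically shared strips of width ``grid.overlap``:
    top (y < overlap), bottom (y >= field - overlap), left, right.
    ``candidates`` must be the single field's table.
    """
    if grid.overlap <= 0:
        raise ValueError("margin counts undefined for zero overlap")
    kept = candidates[candidates.statistic >= s]
    ov = grid.overlap
    return dict(
        top=int((kept.y_px < ov).sum()),
        bottom=int((kept.y_px >= grid.field_height - ov).sum()),
        left=int((kept.x_px < ov).sum()),
        right=int((kept.x_px >= grid.field_width - ov).sum()),
    )


def _margin_stats(candidates: pd.DataFrame, grid: GridSpec) -> dict[str, np.ndarray]:
    """Sorted statistic values per margin; counts above s follow by bisection."""
    ov = grid.overlap
    return {
        "top": np.sort(candidates.statistic[candidates.y_px < ov].to_numpy()),
        "bottom": np.sort(
            candidates.statistic[candidates.y_px >= grid.field_height - ov].to_numpy()
        ),
        "left": np.sort(candidates.statistic[candidates.x_px < ov].to_numpy()),
        "right": np.sort(
            candidates.statistic[candidates.x_px >= grid.field_width - ov].to_numpy()
        ),
    }


def _count_ge(sorted_vals: np.ndarray, s: float) -> int:
    return int(sorted_vals.size - np.searchsorted(sorted_vals, s, side="left"))


def margin_error(
    per_field: dict[tuple[int, int], dict[str, np.ndarray]],
    grid: GridSpec,
    S: np.ndarray,
    norm: int = 2,
) -> float:
    """Margin-count error E(S) over all adjacent field pairs.

    For each horizontally adjacent pair, the right-margin count of the
    left field is compared with the left-margin count of the right field
    (each at its own threshold); vertically, bottom against the
    neighbour's top.  Differences enter with power ``norm`` (2 = sum of
    squares, 1 = sum of absolute differences).
    """
    E = 0.0
    p = norm
    for fy in range(grid.n_fields_y):
        for fx in range(grid.n_fields_x):
            if fx + 1 < grid.n_fields_x:
                d = _count_ge(per_field[(fx, fy)]["right"], S[fy, fx]) - _count_ge(
                    per_field[(fx + 1, fy)]["left"], S[fy, fx + 1]
                )
                E += abs(d) ** p
            if fy + 1 < grid.n_fields_y:
                d = _count_ge(per_field[(fx, fy)]["bottom"], S[fy, fx]) - _count_ge(
                    per_field[(fx, fy + 1)]["top"], S[fy + 1, fx]
                )
                E += abs(d) ** p
    return float(E)


def initial_threshold(candidates: pd.DataFrame) -> float:
    """Constant initial estimate S0 from the combined candidate statistics.

    A single global cut separating the bright spot population from the
    noise candidates, on the pooled log statistics of all fields: the
    antimode of a two-component mixture fit when the distribution is
    bimodal, otherwise Otsu's threshold.  The mixture is preferred
    because noise candidates usually far outnumber spots and a
    variance-based split would land inside the noise bulk.
    """
    from skimage.filters import threshold_otsu

    from .gating import _fit_two_modes

    vals = candidates.statistic.to_numpy()
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("no candidates to threshold")
    if vals.size < 2 or np.ptp(vals) == 0:
        return float(vals[0])
    try:
        # noise candidates dominate: seed the high component far out in
        # the right tail so EM locks onto the spot population
        _, _, _, _, cross = _fit_two_modes(vals, "spot statistic", (0.5, 0.995))
        return float(np.exp(cross))
    except ValueError:
        return float(np.exp(threshold_otsu(np.log(vals))))


def equalize_thresholds(
    candidates: pd.DataFrame,
    grid: GridSpec,
    norm: int = 2,
    s0: float | None = None,
    max_sweeps: int = 50,
) -> ThresholdMatrix:
    """Equalize per-field detection thresholds via margin-count descent.

    Starting from the constant estimate ``S0``, cyclic coordinate
    descent minimizes the margin-count error ``E(S)``: each field's
    threshold in turn is set to the exact minimizer over the breakpoints
    of its (piecewise-constant) objective — the unique statistic values
    of its own margin candidates, plus S0 and a value above the maximum.
    Ties resolve to the threshold closest to S0 on the log scale (then
    the smaller), keeping the local adjustments anchored to the global
    estimate.  Terminates when a full sweep changes nothing or after
    ``max_sweeps``; the result never has a larger error than S0.

    ``candidates`` is the pooled table for all fields (columns include
    field_x, field_y, statistic, y_px, x_px).
    """
    if grid.n_fields_x * grid.n_fields_y < 2:
        raise ValueError("equalization needs at least a 1x2 grid")
    if candidates.empty:
        raise ValueError("no candidates in any field")
    per_field = {}
    for fx, fy in grid.iter_fields():
        sub = candidates[(candidates.field_x == fx) & (candidates.field_y == fy)]
        per_field[(fx, fy)] = _margin_stats(sub, grid)
    if s0 is None:
        s0 = initial_threshold(candidates)
    ny, nx = grid.n_fields_y, grid.n_fields_x
    S = np.full((ny, nx), float(s0))
    E0 = margin_error(per_field, grid, S, norm)

    breakpoints = {}
    for key, m in per_field.items():
        vals = np.concatenate([m[k] for k in ("top", "bottom", "left", "right")])
        vals = np.unique(vals)
        hi = (vals.max() if vals.size else s0) * 1.001 + 1.0
        breakpoints[key] = np.unique(np.concatenate([vals, [s0, hi]]))

    def _tiekey(s: float) -> tuple[float, float]:
        return abs(np.log(max(s, 1e-300)) - np.log(max(s0, 1e-300))), s

    for _ in range(max_sweeps):
        changed = False
        for fy in range(ny):
            for fx in range(nx):
                best_s, best_e = S[fy, fx], _local_error(per_field, grid, S, fx, fy, norm)
                for cand in breakpoints[(fx, fy)]:
                    if cand == S[fy, fx]:
                        continue
                    old = S[fy, fx]
                    S[fy, fx] = cand
                    e = _local_error(per_field, grid, S, fx, fy, norm)
                    S[fy, fx] = old
                    if e < best_e or (e == best_e and _tiekey(cand) < _tiekey(best_s)):
                        best_e, best_s = e, cand
                if best_s != S[fy, fx]:
                    S[fy, fx] = best_s
                    changed = True
        if not changed:
            break
    E = margin_error(per_field, grid, S, norm)
    return ThresholdMatrix(s=S, s0=float(s0), objective=E, objective_initial=E0, norm=norm)


def _local_error(per_field, grid: GridSpec, S, fx, fy, norm) -> float:
    """Terms of E(S) involving field (fx, fy) only."""
    p = norm
    E = 0.0
    for dx, dy, mine, theirs in (
        (1, 0, "right", "left"),
        (-1, 0, "left", "right"),
        (0, 1, "bottom", "top"),
        (0, -1, "top", "bottom"),
    ):
        ox, oy = fx + dx, fy + dy
        if 0 <= ox < grid.n_fields_x and 0 <= oy < grid.n_fields_y:
            d = _count_ge(per_field[(fx, fy)][mine], S[fy, fx]) - _count_ge(
                per_field[(ox, oy)][theirs], S[oy, ox]
            )
            E += abs(d) ** p
    return E


# ---------------------------------------------------------------------------
# masks, cell assignment, cross-field matching
# ---------------------------------------------------------------------------


def colony_mask_from_background(
    stack: np.ndarray,
    min_area_px: int = 256,
) -> np.ndarray:
    """Colony mask from diffuse RNA background staining.

    Maximum z-projection, Otsu threshold, hole filling; components below
    ``min_area_px`` are dropped so point sources and debris do not enter
    the mask.  A blank stack yields an empty mask.
    """
    from skimage.filters import threshold_otsu

    stack = np.asarray(stack, float)
    proj = stack.max(axis=0) if stack.ndim == 3 else stack
    if np.ptp(proj) == 0:
        return np.zeros(proj.shape, bool)
    mask = proj > threshold_otsu(proj)
    mask = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(mask)
    if n:
        areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_area_px) + 1
        mask = np.isin(lab, keep)
    return mask


def expand_nuclei_to_boundaries(
    nuclei_labels: LabelMatrix,
    colony_mask: np.ndarray,
) -> np.ndarray:
    """Approximate cell territories by expanding nucleus outlines.

    Nucleus labels are grown outward (watershed on the distance from the
    nearest nucleus) until they touch each other or the colony edge; the
    touch lines — points equidistant from two nuclei — become the cell
    boundaries.  Returns a label image of territories inside the mask.
    """
    from skimage.segmentation import watershed

    dist = ndimage.distance_transform_edt(nuclei_labels.data == 0)
    return watershed(dist, nuclei_labels.data, mask=np.asarray(colony_mask, bool))


def assign_spots_to_cells(
    spots: pd.DataFrame,
    nuclei_labels: LabelMatrix,
    colony_mask: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign each spot to the cell territory containing its (y, x).

    Spots outside the colony mask get cell id 0 (unassigned); a spot
    inside the mask but in a colony with no nuclei also gets 0, with a
    warning.  Returns the spot table with a ``cell_id`` column and the
    territory label image.
    """
    territories = expand_nuclei_to_boundaries(nuclei_labels, colony_mask)
    out = spots.copy()
    iy = np.clip(out.y_px.round().astype(int), 0, territories.shape[0] - 1)
    ix = np.clip(out.x_px.round().astype(int), 0, territories.shape[1] - 1)
    cid = territories[iy, ix]
    inside = np.asarray(colony_mask, bool)[iy, ix]
    cid = np.where(inside, cid, 0)
    if np.any(inside & (cid == 0)):
        warnings.warn(
            f"{int(np.sum(inside & (cid == 0)))} spots inside the mask fall in a "
            "colony without nuclei; left unassigned",
            stacklevel=2,
        )
    out["cell_id"] = cid
    return out, territories


def per_cell_counts(assigned: pd.DataFrame, labels: np.ndarray | None = None) -> pd.Series:
    """Spot count per cell id (excluding unassigned id 0)."""
    counts = assigned[assigned.cell_id > 0].groupby("cell_id").size()
    if labels is not None:
        counts = counts.reindex(np.asarray(labels), fill_value=0)
    counts.name = "n_spots"
    return counts


def match_spots_across_fields(
    spots: pd.DataFrame,
    grid: GridSpec,
    radius_px: float = 2.0,
    thresholds: ThresholdMatrix | None = None,
) -> pd.DataFrame:
    """Merge duplicate detections of one physical spot across fields.

    Spot positions are mapped to region coordinates via the field
    origins; pairs within ``radius_px`` (lateral) are considered the
    same physical spot and the higher-statistic instance is kept (ties:
    lower field index).  When a threshold matrix is given, each field's
    spots are first filtered by its equalized threshold.

    Returns the global table with columns region_y_px / region_x_px
    added and one row per physical spot.
    """
    df = spots.copy()
    if thresholds is not None:
        keep = np.zeros(len(df), bool)
        for i, row in enumerate(df.itertuples()):
            keep[i] = row.statistic >= thresholds.threshold(row.field_x, row.field_y)
        df = df[keep]
    if df.empty:
        return df.assign(region_y_px=[], region_x_px=[])
    oys = np.array([grid.field_origin(fx, fy)[0] for fx, fy in zip(df.field_x, df.field_y)])
    oxs = np.array([grid.field_origin(fx, fy)[1] for fx, fy in zip(df.field_x, df.field_y)])
    df = df.assign(region_y_px=df.y_px + oys, region_x_px=df.x_px + oxs)
    # greedy dedup: strongest spot claims its neighbourhood
    df = df.sort_values(
        ["statistic", "field_y", "field_x"], ascending=[False, True, True]
    ).reset_index(drop=True)
    pts = df[["region_y_px", "region_x_px"]].to_numpy(float)
    tree = cKDTree(pts)
    keep = np.ones(len(df), bool)
    for i in range(len(df)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(pts[i], radius_px):
            if j != i and keep[j] and j > i:
                keep[j] = False
    return df[keep].reset_index(drop=True)
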