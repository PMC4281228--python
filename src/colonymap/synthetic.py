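"""Synthetic ground-truth scenes of colony-structured cell cultures.

Generates the full hierarchy the analysis pipeline consumes: colonies as
smoothed random blobs, elliptical nuclei with cell-cycle-dependent stain
intensities, overlapping field grids with per-field gain/background, and
3-D z-stacks of diffraction-limited smFISH spots.  Every quantity is
recorded as truth so downstream stages can be scored exactly.

Intensity model
---------------
DNA-stain amplitude is proportional to DNA content: G1 cells carry 2N
content (relative 1.0), G2/M cells 4N (2.0), S-phase cells uniformly in
between.  The S-phase label (EdU) and the mitosis marker (pH3) are
bimodal: a bright mode for labelled cells and a dim mode for the rest.
Pluripotency-marker intensity is a two-component mixture whose negative
fraction may differ between the colony periphery and the interior.
Phase probabilities can be biased by spatial context (periphery /
outermost cell layer / interior) to plant spatial enrichment patterns.

Noise model: Poisson shot noise plus Gaussian read noise, applied after
per-field gain, as in a CCD camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec
from .images import FieldImage

PHASES = ("G1", "S", "G2", "M")

# relative DNA content by phase (2N = 1); S is drawn uniformly in (1, 2)
_DNA_CONTENT = {"G1": 1.0, "G2": 2.0, "M": 2.0}


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic colony scene.

    Lengths are micrometres, intensities arbitrary units.  Defaults give
    a culture-like scene: ~12 um nuclei in a few hundred-micron colonies,
    a (G1, S, G2, M) mixture of (0.4, 0.3, 0.25, 0.05), 2x DNA signal in
    G2/M versus G1, and a 10% marker-negative subpopulation.
    """

    scene_width_um: float = 600.0
    scene_height_um: float = 600.0
    pixel_size_um: float = 0.65
    n_colonies: int = 3
    cells_per_colony: int = 100
    colony_radius_um: float = 110.0
    colony_irregularity: float = 0.25
    cell_diameter_um: float = 12.0
    diameter_cv: float = 0.10
    max_axis_ratio: float = 1.6
    min_separation_frac: float = 0.75
    phase_probs: tuple[float, float, float, float] = (0.4, 0.3, 0.25, 0.05)
    periphery_fraction: float = 0.05
    periphery_phase_probs: tuple[float, float, float, float] | None = None
    layer1_phase_probs: tuple[float, float, float, float] | None = None
    layer1_depth_um: float | None = None  # default: one cell diameter
    dna_g1_intensity: float = 100.0
    dna_cv: float = 0.06
    edu_neg_intensity: float = 6.0
    edu_pos_intensity: float = 120.0
    edu_cv: float = 0.25
    ph3_neg_intensity: float = 5.0
    ph3_pos_intensity: float = 110.0
    ph3_cv: float = 0.25
    marker_pos_intensity: float = 100.0
    marker_neg_intensity: float = 8.0
    marker_cv: float = 0.25
    marker_neg_fraction: float = 0.10
    marker_neg_fraction_periphery: float | None = None
    background: float = 10.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        for name in ("phase_probs", "periphery_phase_probs", "layer1_phase_probs"):
            p = getattr(self, name)
            if p is None:
                continue
            if len(p) != 4 or any(q < 0 for q in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 4 non-negative values summing to 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene.

    ``cells`` columns: id, colony_id, x_um, y_um, diameter_um, axis_ratio,
    angle, phase, context, distance_um, dna, edu, ph3, marker.
    ``colonies`` maps colony id -> boundary polygon, an (n, 2) array of
    (y_um, x_um) vertices.  ``spots`` columns (smFISH scenes only):
    id, z_um, y_um, x_um, amplitude.
    """

    cells: pd.DataFrame
    colonies: dict[int, np.ndarray]
    colony_mask: np.ndarray
    params: SceneParams
    seed: int
    spots: pd.DataFrame | None = None

    @property
    def pixel_size_um(self) -> float:
        return self.params.pixel_size_um

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.colony_mask.shape

    def cells_in_bounds(self, margin_um: float = 0.0) -> pd.DataFrame:
        """Cells whose centroid lies at least ``margin_um`` inside the scene."""
        c = self.cells
        w, h = self.params.scene_width_um, self.params.scene_height_um
        keep = (
            (c.x_um >= margin_um)
            & (c.x_um < w - margin_um)
            & (c.y_um >= margin_um)
            & (c.y_um < h - margin_um)
        )
        return c[keep]


def _colony_blob(
    rng: np.random.Generator,
    radius_px: float,
    irregularity: float,
    shape: tuple[int, int],
    center_yx: tuple[float, float],
) -> np.ndarray:
    """One colony mask: low-pass-filtered noise thresholded around a center.

    Filtered Gaussian noise plus a radial ramp is thresholded at 0; the
    connected component containing the center is kept.  Produces smooth,
    generally non-convex blobs whose scale is set by ``radius_px``.
    """
    h, w = shape
    cy, cx = center_yx
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, sigma=radius_px / 2.5)
    noise /= max(noise.std(), 1e-12)
    # negative ramp outside radius_px; noise modulates the boundary
    fieldv = (1.0 - r / radius_px) + irregularity * 2.0 * noise
    mask = fieldv > 0
    mask = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros(shape, bool)
    want = lab[int(round(cy)), int(round(cx))]
    if want == 0:
        # center fell outside; keep the largest component
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        want = int(np.argmax(sizes)) + 1
    return lab == want


def _boundary_polygon(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Longest iso-contour of the mask, in (y_um, x_um)."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return np.zeros((0, 2))
    longest = max(contours, key=len)
    return longest * pixel_size_um


def _place_centroids(
    rng: np.random.Generator,
    mask: np.ndarray,
    n: int,
    min_sep_px: float,
) -> np.ndarray:
    """Hard-core sampling of ``n`` pixel positions inside ``mask``.

    Relaxes the separation constraint if the colony is too crowded, so the
    requested count is always honoured.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return np.zeros((0, 2))
    placed: list[tuple[float, float]] = []
    sep = min_sep_px
    attempts = 0
    while len(placed) < n:
        i = rng.integers(ys.size)
        cand = (float(ys[i]) + rng.random(), float(xs[i]) + rng.random())
        ok = all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= sep**2 for p in placed)
        if ok:
            placed.append(cand)
            attempts = 0
        else:
            attempts += 1
            if attempts > 200:
                sep *= 0.85  # crowded colony: relax packing
                attempts = 0
    return np.array(placed)


def generate_colony_scene(params: SceneParams, seed: int) -> SceneTruth:
    """Generate a deterministic ground-truth scene of colonies of nuclei.

    Colonies are placed on a jittered grid of centers, each drawn as a
    smoothed-noise blob.  Cells are scattered inside their colony with a
    hard-core minimum separation; a ``periphery_fraction`` of each
    colony's cells is placed just outside its boundary (these carry
    colony id 0 and context ``"periphery"``).  Phase labels are drawn
    from ``phase_probs``, optionally overridden for periphery and
    outermost-layer cells; per-channel true intensities follow the module
    intensity model.

    The same ``(params, seed)`` pair always yields identical truth.
    """
    rng = np.random.default_rng(seed)
    px = params.pixel_size_um
    h = int(round(params.scene_height_um / px))
    w = int(round(params.scene_width_um / px))
    r_px = params.colony_radius_um / px

    # --- colonies: jittered grid of centers, blob mask each -------------
    n_col = params.n_colonies
    ncols = int(math.ceil(math.sqrt(n_col)))
    nrows = int(math.ceil(n_col / ncols))
    centers = []
    pad = 1.15 * r_px
    for k in range(n_col):
        gy, gx = divmod(k, ncols)
        cy = (gy + 0.5) * h / nrows
        cx = (gx + 0.5) * w / ncols
        cy += rng.uniform(-0.08, 0.08) * h / nrows
        cx += rng.uniform(-0.08, 0.08) * w / ncols
        centers.append((np.clip(cy, pad, h - pad), np.clip(cx, pad, w - pad)))

    colony_mask = np.zeros((h, w), np.int32)
    polygons: dict[int, np.ndarray] = {}
    for cid, c in enumerate(centers, start=1):
        blob = _colony_blob(rng, r_px, params.colony_irregularity, (h, w), c)
        blob &= colony_mask == 0  # earlier colonies win contested pixels
        colony_mask[blob] = cid
        polygons[cid] = _boundary_polygon(colony_mask == cid, px)

    # distance-from-edge (px) of every pixel inside its colony
    dist_px = ndimage.distance_transform_edt(colony_mask > 0)

    # --- cells ----------------------------------------------------------
    d_px = params.cell_diameter_um / px
    rows = []
    next_id = 1
    for cid in range(1, n_col + 1):
        mask = colony_mask == cid
        n_inside = params.cells_per_colony
        n_peri = int(round(params.periphery_fraction * n_inside))
        n_inside -= n_peri
        # keep nuclei fully inside the colony: erode by one cell radius
        core = ndimage.binary_erosion(mask, iterations=max(1, int(d_px / 2)))
        if not core.any():
            core = mask
        pts = _place_centroids(rng, core, n_inside, params.min_separation_frac * d_px)
        # periphery: a ring just outside the colony boundary
        ring = ndimage.binary_dilation(mask, iterations=max(2, int(d_px))) & ~ndimage.binary_dilation(
            mask, iterations=max(1, int(d_px / 3))
        )
        ring &= colony_mask == 0
        pts_peri = (
            _place_centroids(rng, ring, n_peri, params.min_separation_frac * d_px)
            if n_peri and ring.any()
            else np.zeros((0, 2))
        )
        for (y, x), peripheral in [(p, False) for p in pts] + [(p, True) for p in pts_peri]:
            iy, ix = min(int(y), h - 1), min(int(x), w - 1)
            dist_um = 0.0 if peripheral else float(dist_px[iy, ix]) * px
            layer1_depth = params.layer1_depth_um or params.cell_diameter_um
            if peripheral:
                context = "periphery"
            elif dist_um <= layer1_depth:
                context = "layer1"
            else:
                context = "interior"
            probs = params.phase_probs
            if context == "periphery" and params.periphery_phase_probs is not None:
                probs = params.periphery_phase_probs
            elif context == "layer1" and params.layer1_phase_probs is not None:
                probs = params.layer1_phase_probs
            phase = PHASES[rng.choice(4, p=probs)]
            content = _DNA_CONTENT.get(phase) or rng.uniform(1.0, 2.0)  # S phase
            lo = lambda mean, cv: float(mean * rng.lognormal(-0.5 * math.log1p(cv**2), math.sqrt(math.log1p(cv**2))))
            dna = lo(params.dna_g1_intensity * content, params.dna_cv)
            edu = lo(
                params.edu_pos_intensity if phase == "S" else params.edu_neg_intensity,
                params.edu_cv,
            )
            ph3 = lo(
                params.ph3_pos_intensity if phase == "M" else params.ph3_neg_intensity,
                params.ph3_cv,
            )
            negfrac = params.marker_neg_fraction
            if peripheral and params.marker_neg_fraction_periphery is not None:
                negfrac = params.marker_neg_fraction_periphery
            marker_neg = rng.random() < negfrac
            marker = lo(
                params.marker_neg_intensity if marker_neg else params.marker_pos_intensity,
                params.marker_cv,
            )
            diam = params.cell_diameter_um * rng.lognormal(0.0, params.diameter_cv)
            rows.append(
                dict(
                    id=next_id,
                    colony_id=0 if peripheral else cid,
                    x_um=x * px,
                    y_um=y * px,
                    diameter_um=diam,
                    axis_ratio=rng.uniform(1.0, params.max_axis_ratio),
                    angle=rng.uniform(0, math.pi),
                    phase=phase,
                    context=context,
                    distance_um=dist_um,
                    dna=dna,
                    edu=edu,
                    ph3=ph3,
                    marker=marker,
                )
            )
            next_id += 1

    cells = pd.DataFrame(rows)
    return SceneTruth(
        cells=cells, colonies=polygons, colony_mask=colony_mask, params=params, seed=seed
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

CHANNELS = ("dna", "edu", "ph3", "marker")


def render_scene(scene: SceneTruth, channels: tuple[str, ...] = CHANNELS) -> dict[str, np.ndarray]:
    """Noiseless whole-scene rendering, one float image per channel.

    Nuclei are anisotropic 2-D Gaussians clipped at 2 sigma (an ellipse
    with diameter ~= 4 sigma along each axis), amplitude equal to the
    cell's true channel intensity.  No background is added here; gain,
    background and noise are per-field effects applied by
    :func:`render_fields`.
    """
    px = scene.pixel_size_um
    h, w = scene.shape_px
    out = {c: np.zeros((h, w)) for c in channels}
    for cell in scene.cells.itertuples():
        sig_major = cell.diameter_um / px / 4.0
        sig_minor = sig_major / cell.axis_ratio
        _stamp_gaussian2d(
            out,
            channels,
            cell,
            cy=cell.y_um / px,
            cx=cell.x_um / px,
            s1=sig_major,
            s2=sig_minor,
            theta=cell.angle,
        )
    return out


def _stamp_gaussian2d(out, channels, cell, cy, cx, s1, s2, theta, clip_sigma=2.0):
    h, w = next(iter(out.values())).shape
    ext = clip_sigma * s1
    y0, y1 = max(0, int(cy - ext)), min(h, int(cy + ext) + 2)
    x0, x1 = max(0, int(cx - ext)), min(w, int(cx + ext) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    q = (u / s1) ** 2 + (v / s2) ** 2
    g = np.exp(-0.5 * q)
    g[q > clip_sigma**2] = 0.0  # hard ellipse edge at clip_sigma
    for c in channels:
        out[c][y0:y1, x0:x1] += getattr(cell, c) * g


@dataclass(frozen=True)
class FieldEffects:
    """Per-field multiplicative gain and additive background offsets.

    ``gain[fy, fx]`` and ``background[fy, fx]``; either may be None for
    uniform 1.0 / 0.0.
    """

    gain: np.ndarray | None = None
    background: np.ndarray | None = None

    def at(self, fx: int, fy: int) -> tuple[float, float]:
        g = 1.0 if self.gain is None else float(self.gain[fy, fx])
        b = 0.0 if self.background is None else float(self.background[fy, fx])
        return g, b


def render_fields(
    scene: SceneTruth,
    grid: GridSpec,
    field_effects: FieldEffects | None = None,
    channels: tuple[str, ...] = CHANNELS,
    noise: bool | None = None,
    seed: int | None = None,
) -> list[FieldImage]:
    """Render the scene as an overlapping grid of field images.

    The whole scene is rendered once and cropped at each field origin, so
    shared margins of adjacent fields depict identical physical content
    before per-field gain/background and noise.  Noise (Poisson shot +
    Gaussian read, per the scene parameters) is applied independently per
    field, seeded from ``seed`` (default: scene seed + 1).

    Raises ``ValueError`` if the grid does not cover the scene.
    """
    p = scene.params
    px = p.pixel_size_um
    h, w = scene.shape_px
    if grid.region_width < w or grid.region_height < h:
        raise ValueError(
            f"grid region {grid.region_height}x{grid.region_width} px does not cover "
            f"scene {h}x{w} px"
        )
    canvas = render_scene(scene, channels)
    # pad canvas to the full region extent
    full = {
        c: np.zeros((grid.region_height, grid.region_width)) for c in channels
    }
    for c in channels:
        full[c][:h, :w] = canvas[c]

    if noise is None:
        noise = p.shot_noise or p.read_noise_sd > 0
    rng = np.random.default_rng(scene.seed + 1 if seed is None else seed)
    fields = []
    for fx, fy in grid.iter_fields():
        oy, ox = grid.field_origin(fx, fy)
        gain, bg = (field_effects or FieldEffects()).at(fx, fy)
        chans = {}
        for c in channels:
            img = full[c][oy : oy + grid.field_height, ox : ox + grid.field_width]
            img = gain * (img + p.background) + bg
            if noise:
                if p.shot_noise:
                    img = rng.poisson(np.clip(img, 0, None)).astype(float)
                if p.read_noise_sd > 0:
                    img = img + rng.normal(0.0, p.read_noise_sd, img.shape)
            chans[c] = img
        fields.append(FieldImage(chans, fx, fy, px))
    return fields


def render_truth_labels(scene: SceneTruth, grid: GridSpec):
    """Ground-truth per-field segmentation label matrices.

    Paints every cell's elliptical footprint (the 2-sigma clip of its
    Gaussian) into each field it intersects, clipped at the field
    borders — exactly what an ideal per-field segmenter would produce,
    including partial instances of cells straddling field boundaries.
    Labels are sequential per field.

    Returns ``(label_matrices, truth_ids)`` where ``truth_ids`` maps
    ``(fx, fy, local_label) -> cell id``.
    """
    from .images import LabelMatrix

    px = scene.pixel_size_um
    mats = []
    truth_ids: dict[tuple[int, int, int], int] = {}
    for fx, fy in grid.iter_fields():
        oy, ox = grid.field_origin(fx, fy)
        lab = np.zeros((grid.field_height, grid.field_width), np.int32)
        nxt = 1
        for cell in scene.cells.itertuples():
            cy, cx = cell.y_um / px - oy, cell.x_um / px - ox
            s1 = cell.diameter_um / px / 4.0
            s2 = s1 / cell.axis_ratio
            ext = 2.0 * s1
            if cy < -ext or cy >= grid.field_height + ext or cx < -ext or cx >= grid.field_width + ext:
                continue
            y0, y1 = max(0, int(cy - ext)), min(grid.field_height, int(cy + ext) + 2)
            x0, x1 = max(0, int(cx - ext)), min(grid.field_width, int(cx + ext) + 2)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            ct, st = math.cos(cell.angle), math.sin(cell.angle)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            footprint = (u / s1) ** 2 + (v / s2) ** 2 <= 4.0
            if not footprint.any():
                continue
            lab[y0:y1, x0:x1][footprint] = nxt
            truth_ids[(fx, fy, nxt)] = cell.id
            nxt += 1
        mats.append(LabelMatrix(lab, px, (fx, fy)))
    return mats, truth_ids


# ---------------------------------------------------------------------------
# smFISH z-stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmfishParams:
    """Parameters of a synthetic smFISH acquisition.

    Spots are diffraction-limited 3-D Gaussian point sources with
    log-normal amplitudes (producing a hard near-threshold population).
    ``spots_per_cell`` scatters a Poisson number of spots around each
    cell of an attached scene; without a scene, ``n_spots`` spots are
    placed uniformly inside the colony mask (or the whole region).
    A smooth linear gain gradient across the region emulates signal
    diminution in adjacent fields.
    """

    n_z: int = 12
    z_step_um: float = 0.4
    psf_sigma_xy_px: float = 1.3
    psf_sigma_z_px: float = 1.6
    spots_per_cell: float = 40.0
    n_spots: int | None = None
    amplitude: float = 60.0
    amplitude_sigma_log: float = 0.25
    background_in_colony: float = 25.0
    background_outside: float = 6.0
    gain_gradient_x: float = 0.0
    gain_gradient_y: float = 0.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    spot_scatter_um: float = 5.0
    min_spot_separation_px: float = 0.0

    def __post_init__(self) -> None:
        if self.psf_sigma_xy_px < 1.0 or self.psf_sigma_z_px < 1.0:
            raise ValueError("PSF sigma below 1 px is unresolvable")
        if self.n_z < 3:
            raise ValueError("need at least 3 z planes")


def generate_smfish_stack(
    params: SmfishParams,
    grid: GridSpec,
    seed: int,
    scene: SceneTruth | None = None,
    pixel_size_um: float = 0.13,
    field_effects: FieldEffects | None = None,
) -> tuple[list[FieldImage], pd.DataFrame]:
    """Render per-field 3-D z-stacks of smFISH spots with ground truth.

    Returns the list of field stacks (channel ``"fish"``) and the truth
    spot table with columns (id, z_um, y_um, x_um, amplitude, cell_id)
    in region coordinates.  Spots falling in the shared margin of
    adjacent fields are rendered in, and attributable to, both fields.
    """
    rng = np.random.default_rng(seed)
    px = scene.pixel_size_um if scene is not None else pixel_size_um
    H, W = grid.region_height, grid.region_width
    Z = params.n_z

    # --- truth spots (region px coords, sub-pixel) ----------------------
    rows = []
    sid = 1
    if scene is not None:
        scatter_px = params.spot_scatter_um / px
        for cell in scene.cells.itertuples():
            k = rng.poisson(params.spots_per_cell)
            for _ in range(k):
                y = cell.y_um / px + rng.normal(0, scatter_px)
                x = cell.x_um / px + rng.normal(0, scatter_px)
                if not (0 <= y < H and 0 <= x < W):
                    continue
                z = rng.uniform(1.5, Z - 2.5)
                amp = params.amplitude * rng.lognormal(0.0, params.amplitude_sigma_log)
                rows.append(dict(id=sid, z_px=z, y_px=y, x_px=x, amplitude=amp, cell_id=cell.id))
                sid += 1
        colony_mask = np.zeros((H, W), bool)
        h0, w0 = scene.shape_px
        colony_mask[:h0, :w0] = scene.colony_mask > 0
    else:
        n = 0 if params.n_spots is None else params.n_spots
        sep2 = params.min_spot_separation_px**2
        placed: list[tuple[float, float]] = []
        while len(placed) < n:
            y, x = rng.uniform(2, H - 2), rng.uniform(2, W - 2)
            if sep2 and any((y - py) ** 2 + (x - px_) ** 2 < sep2 for py, px_ in placed):
                continue
            placed.append((y, x))
            rows.append(
                dict(
                    id=sid,
                    z_px=rng.uniform(1.5, Z - 2.5),
                    y_px=y,
                    x_px=x,
                    amplitude=params.amplitude * rng.lognormal(0.0, params.amplitude_sigma_log),
                    cell_id=0,
                )
            )
            sid += 1
        colony_mask = np.ones((H, W), bool)

    spots = pd.DataFrame(
        rows, columns=["id", "z_px", "y_px", "x_px", "amplitude", "cell_id"]
    )

    # --- noiseless region volume ---------------------------------------
    vol = np.zeros((Z, H, W))
    sz, sxy = params.psf_sigma_z_px, params.psf_sigma_xy_px
    for s in spots.itertuples():
        _stamp_gaussian3d(vol, s.z_px, s.y_px, s.x_px, s.amplitude, sz, sxy)
    bg2d = np.where(colony_mask, params.background_in_colony, params.background_outside)
    # diffuse RNA background is smooth, not a hard step
    bg2d = ndimage.gaussian_filter(bg2d.astype(float), sigma=3.0)
    vol += bg2d[None, :, :]

    # smooth across-region gain surface evaluated per pixel
    gy = np.linspace(0, params.gain_gradient_y, H)
    gx = np.linspace(0, params.gain_gradient_x, W)
    gain2d = 1.0 + gy[:, None] + gx[None, :]

    fields: list[FieldImage] = []
    out_spots = []
    for fx, fy in grid.iter_fields():
        oy, ox = grid.field_origin(fx, fy)
        sub = vol[:, oy : oy + grid.field_height, ox : ox + grid.field_width]
        sub = sub * gain2d[None, oy : oy + grid.field_height, ox : ox + grid.field_width]
        if field_effects is not None:
            g, b = field_effects.at(fx, fy)
            sub = g * sub + b
        if params.shot_noise:
            sub = rng.poisson(np.clip(sub, 0, None)).astype(float)
        if params.read_noise_sd > 0:
            sub = sub + rng.normal(0.0, params.read_noise_sd, sub.shape)
        fields.append(
            FieldImage({"fish": sub}, fx, fy, px, z_step_um=params.z_step_um)
        )
        inside = (
            (spots.y_px >= oy)
            & (spots.y_px < oy + grid.field_height)
            & (spots.x_px >= ox)
            & (spots.x_px < ox + grid.field_width)
        )
        for s in spots[inside].itertuples():
            out_spots.append(
                dict(
                    id=s.id,
                    field_x=fx,
                    field_y=fy,
                    z_px=s.z_px,
                    y_px=s.y_px - oy,
                    x_px=s.x_px - ox,
                    region_y_px=s.y_px,
                    region_x_px=s.x_px,
                    amplitude=s.amplitude,
                    cell_id=s.cell_id,
                )
            )

    truth = pd.DataFrame(
        out_spots,
        columns=[
            "id", "field_x", "field_y", "z_px", "y_px", "x_px",
            "region_y_px", "region_x_px", "amplitude", "cell_id",
        ],
    )
    return fields, truth


def _stamp_gaussian3d(vol, z, y, x, amp, sz, sxy, ext_sigma=4.0):
    Z, H, W = vol.shape
    ez, exy = ext_sigma * sz, ext_sigma * sxy
    z0, z1 = max(0, int(z - ez)), min(Z, int(z + ez) + 2)
    y0, y1 = max(0, int(y - exy)), min(H, int(y + exy) + 2)
    x0, x1 = max(0, int(x - exy)), min(W, int(x + exy) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    g = np.exp(
        -0.5 * (((zz - z) / sz) ** 2 + ((yy - y) / sxy) ** 2 + ((xx - x) / sxy) ** 2)
    )
    vol[z0:z1, y0:y1, x0:x1] += amp * g
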