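"""End-to-end orchestration: fields in, relational CSV set out.

``run_pipeline`` ties the stages together: mosaic the DNA channel,
segment colonies and per-field nuclei, build the duplicate-free region
label matrix, extract features, attach spatial context, gate cell-cycle
phases, and estimate layer/bin frequencies with bootstrap CIs.  Outputs
are a relational CSV set (cells, colonies, windows, bins, layers) joined
by ids, plus a plain-text report logging every parameter and seed used.
Deterministic stages are bit-identical across reruns of one config.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import context as ctx
from . import gating, io, segmentation, smfish, virtual_slide
from .config import PipelineConfig
from .images import FieldImage, LabelMatrix

log = logging.getLogger("colonymap")


def load_fields(input_dir: str | Path, config: PipelineConfig) -> list[FieldImage]:
    """Read ``field_<fx>_<fy>.tif`` for every grid position; error names
    any missing field or channel."""
    input_dir = Path(input_dir)
    fields = []
    for fx, fy in config.grid.iter_fields():
        path = input_dir / f"field_{fx}_{fy}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing field ({fx}, {fy}): {path}")
        f = io.read_field(path)
        for role, name in config.channels.items():
            if name not in f.channels:
                raise KeyError(
                    f"field ({fx}, {fy}) lacks channel {name!r} (role {role!r})"
                )
        fields.append(f)
    return fields


def run_pipeline(
    config: PipelineConfig,
    fields: list[FieldImage],
    output_dir: str | Path | None = None,
) -> dict[str, object]:
    """Run the full 2-D analysis on a list of fields.

    Returns a dict with keys cells, colonies, windows, layer_freqs,
    bin_freqs (DataFrames), region_labels, colony_labels (LabelMatrix)
    and gates.  When ``output_dir`` is given the tables are also written
    as CSV, label matrices as 16-bit TIFF, and a report.txt logs all
    parameters.
    """
    grid, px = config.grid, config.pixel_size_um
    chan = config.channels

    # --- mosaics and colony segmentation -------------------------------
    mosaics = virtual_slide.mosaic_fields(fields, grid)
    colony_labels = segmentation.segment_colonies(
        mosaics[chan["dna"]], px, config.colony_sigma_px,
        config.colony_min_area_um2, config.colony_erode_px,
    )
    colonies = segmentation.colony_features(colony_labels)
    for c in colonies:
        c.size_class = ctx.classify_colony_size(c.max_edge_distance_um)
    colony_frame = segmentation.colonies_to_frame(colonies)

    # --- nuclei per field, consensus, addressing ------------------------
    field_labels = [
        segmentation.segment_nuclei(f, chan["dna"], config.nuclei) for f in fields
    ]
    region_labels, mapping = virtual_slide.consensus_segmentation(
        field_labels, grid, config.max_cell_diameter_um
    )
    addresses = virtual_slide.assign_addresses(region_labels, colony_labels, mapping=mapping)

    # --- features --------------------------------------------------------
    feature_channels = {
        role: mosaics[name] for role, name in chan.items() if mosaics[name].ndim == 2
    }
    records = segmentation.extract_features(region_labels, feature_channels, addresses)
    cells = segmentation.cells_to_frame(records)

    # --- context ---------------------------------------------------------
    max_edge = {c.colony_id: c.max_edge_distance_um for c in colonies}
    windows: list = []
    if len(cells):
        cells, windows = ctx.attach_context(
            cells,
            colony_labels,
            max_edge,
            cell_diameter_um=config.cell_diameter_um,
            n_layers=config.n_layers,
            window_w_um=config.window_w_um,
            window_h_um=config.window_h_um,
        )

    # --- gating ----------------------------------------------------------
    gates = None
    layer_freqs = bin_freqs = pd.DataFrame()
    if len(cells) and {"edu", "ph3"} <= set(chan):
        gates = gating.fit_cell_cycle_gates(
            cells["integrated_dna"].to_numpy(),
            cells["mean_edu"].to_numpy(),
            cells["mean_ph3"].to_numpy(),
        )
        cells["phase"] = gating.classify_phase(
            cells["integrated_dna"].to_numpy(),
            cells["mean_edu"].to_numpy(),
            cells["mean_ph3"].to_numpy(),
            gates,
        )
        classified = cells[cells.phase != gating.UNCLASSIFIED]
        if len(classified):
            layer_freqs = gating.bootstrap_frequencies(
                classified.phase.to_numpy(),
                classified.layer.to_numpy(),
                config.bootstrap_b,
                config.bootstrap_level,
                config.seed,
            )
            k = min(config.n_distance_bins, max(1, len(classified) // 50))
            edges = ctx.equal_count_bins(classified.distance_um.to_numpy(), k)
            bins = ctx.bin_index(classified.distance_um.to_numpy(), edges)
            bin_freqs = gating.bootstrap_frequencies(
                classified.phase.to_numpy(), bins, config.bootstrap_b,
                config.bootstrap_level, config.seed,
            )

    window_frame = pd.DataFrame(
        dict(
            window_id=w.window_id, colony_id=w.colony_id, x0_um=w.x0_um,
            y0_um=w.y0_um, x1_um=w.x1_um, y1_um=w.y1_um, count=w.count,
            density_class=w.density_class,
        )
        for w in windows
    )

    result = dict(
        cells=cells,
        colonies=colony_frame,
        windows=window_frame,
        layer_freqs=layer_freqs,
        bin_freqs=bin_freqs,
        region_labels=region_labels,
        colony_labels=colony_labels,
        gates=gates,
    )
    if output_dir is not None:
        _write_outputs(result, config, Path(output_dir))
    return result


def run_smfish(
    config: PipelineConfig,
    fields: list[FieldImage],
    nuclei_labels: LabelMatrix | None = None,
    channel: str = "fish",
) -> dict[str, object]:
    """smFISH branch: detect, equalize, match, and (optionally) assign.

    ``fields`` carry 3-D stacks in ``channel``.  Per field: top-hat +
    LoG preprocessing and candidate scoring; thresholds are equalized
    over the grid; duplicates in shared margins merged.  When a region
    nuclei label matrix is given, spots are assigned to cell territories
    within the colony mask of the mosaicked background staining.
    """
    grid = config.grid
    per_field = []
    for f in fields:
        stack = f.channel(channel)
        filt = smfish.preprocess_stack(
            stack, config.smfish_open_radius_px, config.smfish_log_sigma_px
        )
        per_field.append(
            smfish.detect_candidates(filt, stack, field_x=f.field_x, field_y=f.field_y)
        )
    candidates = pd.concat(per_field, ignore_index=True)
    thresholds = smfish.equalize_thresholds(candidates, grid, norm=config.smfish_norm)
    spots = smfish.match_spots_across_fields(
        candidates, grid, config.smfish_match_radius_px, thresholds
    )
    out: dict[str, object] = dict(candidates=candidates, thresholds=thresholds, spots=spots)
    if nuclei_labels is not None:
        proj = virtual_slide.mosaic_fields(fields, grid, channel)
        mask = smfish.colony_mask_from_background(proj)
        sp = spots
        if "region_y_px" in spots:
            sp = spots.assign(y_px=spots.region_y_px, x_px=spots.region_x_px)
        assigned, territories = smfish.assign_spots_to_cells(sp, nuclei_labels, mask)
        out.update(
            assigned=assigned,
            territories=territories,
            counts=smfish.per_cell_counts(assigned),
            colony_mask=mask,
        )
    return out


def _write_outputs(result: dict, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_table(result["cells"], outdir / "cells.csv")
    io.write_table(result["colonies"], outdir / "colonies.csv")
    io.write_table(result["windows"], outdir / "windows.csv")
    io.write_table(result["layer_freqs"], outdir / "layer_frequencies.csv")
    io.write_table(result["bin_freqs"], outdir / "bin_frequencies.csv")
    io.write_labels(result["region_labels"], outdir / "region_labels.tif")
    io.write_labels(result["colony_labels"], outdir / "colony_labels.tif")
    lines = [
        "colonymap pipeline report",
        f"grid: {config.grid}",
        f"pixel size: {config.pixel_size_um} um",
        f"channels: {config.channels}",
        f"colony segmentation: sigma={config.colony_sigma_px} px, "
        f"min_area={config.colony_min_area_um2} um2",
        f"nuclei: {config.nuclei}",
        f"bootstrap: B={config.bootstrap_b}, level={config.bootstrap_level}%, "
        f"seed={config.seed}",
        f"cells: {len(result['cells'])}",
        f"colonies: {len(result['colonies'])}",
        f"windows: {len(result['windows'])}",
    ]
    g = result.get("gates")
    if g is not None:
        lines.append(
            f"gates: 2N={g.dna_2n_center:.1f}, 4N={g.dna_4n_center:.1f}, "
            f"EdU>{g.edu_threshold:.2f}, pH3>{g.ph3_threshold:.2f}"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
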