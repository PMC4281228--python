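"""Pipeline configuration: one YAML/JSON document drives an end-to-end run.

Every threshold and seed actually used downstream is recorded here or in
the run log, because reproducibility of the adaptive stages depends on
parameter provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grid import GridSpec
from .segmentation import NucleiParams

#: channel roles the 2-D pipeline understands
KNOWN_ROLES = ("dna", "edu", "ph3", "marker", "fish")


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs.

    ``channels`` maps a role (``dna`` is mandatory) to the channel name
    used in the field files.  Lengths are micrometres; all seeds are
    integers.
    """

    grid: GridSpec
    pixel_size_um: float
    channels: dict[str, str] = field(default_factory=lambda: {"dna": "dna"})
    # colony segmentation
    colony_sigma_px: float = 20.0
    colony_min_area_um2: float = 2000.0
    colony_erode_px: int = 0
    # nuclei
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    max_cell_diameter_um: float = 20.0
    # context
    cell_diameter_um: float | None = None
    n_layers: int = 3
    n_distance_bins: int = 8
    window_w_um: float = 250.0
    window_h_um: float = 192.0
    # gating
    bootstrap_b: int = 1000
    bootstrap_level: float = 95.0
    seed: int = 0
    # smFISH
    smfish_open_radius_px: int = 3
    smfish_log_sigma_px: float = 1.3
    smfish_norm: int = 2
    smfish_match_radius_px: float = 2.0

    def __post_init__(self) -> None:
        if "dna" not in self.channels:
            raise ValueError("config must map the 'dna' channel role")
        if not float(self.seed) == int(self.seed):
            raise ValueError("seed must be an integer")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid"] = asdict(self.grid) if not isinstance(self.grid, dict) else self.grid
        d["nuclei"] = asdict(self.nuclei) if not isinstance(self.nuclei, dict) else self.nuclei
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["grid"] = GridSpec(**d["grid"])
        if "nuclei" in d:
            d["nuclei"] = NucleiParams(**d["nuclei"])
        return cls(**d)
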