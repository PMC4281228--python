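"""Image containers shared across the pipeline.

``FieldImage`` holds one grid position's pixels (multi-channel 2-D or a
3-D z-stack) together with its grid index and pixel size.  ``LabelMatrix``
is an integer segmentation image (0 = background) tagged with provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FieldImage:
    """One imaging field.

    Attributes
    ----------
    channels
        Mapping from channel role (e.g. ``"dna"``, ``"edu"``) to a 2-D
        array, or to a 3-D (z, y, x) stack for volumetric channels.
    field_x, field_y
        Grid index of the field within its region.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    z_step_um
        Axial spacing for 3-D channels (ignored for 2-D data).
    """

    channels: dict[str, np.ndarray]
    field_x: int
    field_y: int
    pixel_size_um: float
    z_step_um: float = 0.0

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel {role!r} not present; available: {sorted(self.channels)}"
            ) from None

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabelMatrix:
    """Integer label image; 0 is background, labels are positive.

    ``provenance`` identifies the source: a field grid index ``(fx, fy)``
    or the string ``"region"`` for mosaicked / consensus matrices.
    """

    data: np.ndarray
    pixel_size_um: float
    provenance: object = "region"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("label matrix must be 2-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label matrix must have an integer dtype")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present."""
        u = np.unique(self.data)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.labels.size)

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def copy(self) -> "LabelMatrix":
        return LabelMatrix(self.data.copy(), self.pixel_size_um, self.provenance)
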