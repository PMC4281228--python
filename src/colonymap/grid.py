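"""Field-grid geometry for overlapping tile acquisitions.

A region is imaged as a rectangular grid of M x N fields whose stage
positions are known to sub-pixel accuracy, with a fixed pixel overlap
between adjacent fields.  All pixel coordinates are 0-based and ordered
(row = y, col = x); physical positions are ``px * pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an M x N grid of overlapping imaging fields.

    Parameters
    ----------
    n_fields_x, n_fields_y
        Grid dimensions M (columns) and N (rows).
    field_width, field_height
        Field size in pixels.
    overlap
        Shared margin between adjacent fields, in pixels.  Must satisfy
        ``0 <= overlap < min(field_width, field_height)``.
    """

    n_fields_x: int
    n_fields_y: int
    field_width: int
    field_height: int
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.n_fields_x < 1 or self.n_fields_y < 1:
            raise ValueError("grid must contain at least one field")
        if self.field_width < 1 or self.field_height < 1:
            raise ValueError("field dimensions must be positive")
        if not 0 <= self.overlap < min(self.field_width, self.field_height):
            raise ValueError(
                f"overlap must be in [0, {min(self.field_width, self.field_height)}), "
                f"got {self.overlap}"
            )

    @property
    def step_x(self) -> int:
        """Origin spacing of horizontally adjacent fields (px)."""
        return self.field_width - self.overlap

    @property
    def step_y(self) -> int:
        return self.field_height - self.overlap

    @property
    def region_width(self) -> int:
        """Total mosaic width: M*(field - overlap) + overlap."""
        return self.n_fields_x * self.step_x + self.overlap

    @property
    def region_height(self) -> int:
        return self.n_fields_y * self.step_y + self.overlap

    def field_origin(self, fx: int, fy: int) -> tuple[int, int]:
        """Region-frame (y, x) origin of field (fx, fy)."""
        self._check_field(fx, fy)
        return fy * self.step_y, fx * self.step_x

    def iter_fields(self):
        """Yield (fx, fy) in row-major order (fy outer, fx inner)."""
        for fy in range(self.n_fields_y):
            for fx in range(self.n_fields_x):
                yield fx, fy

    def _check_field(self, fx: int, fy: int) -> None:
        if not (0 <= fx < self.n_fields_x and 0 <= fy < self.n_fields_y):
            raise ValueError(
                f"field ({fx}, {fy}) outside {self.n_fields_x} x {self.n_fields_y} grid"
            )


def to_global_coords(
    field_xy: tuple[int, int],
    local_yx: tuple[float, float],
    grid: GridSpec,
) -> tuple[float, float]:
    """Map a pixel position inside one field to region-frame coordinates.

    Adjacent-field representations of the same physical point map to the
    identical region coordinate because field origins are spaced exactly
    ``field - overlap`` pixels apart.

    Parameters
    ----------
    field_xy
        Grid index (fx, fy) of the field.
    local_yx
        Pixel position (y, x) inside the field; must lie within the field.
    grid
        Grid geometry.

    Returns
    -------
    (y, x) position in region pixel coordinates.
    """
    fx, fy = field_xy
    y, x = local_yx
    if not (0 <= y < grid.field_height and 0 <= x < grid.field_width):
        raise ValueError(f"local coordinates {local_yx} outside field bounds")
    oy, ox = grid.field_origin(fx, fy)
    return y + oy, x + ox


def to_local_coords(
    field_xy: tuple[int, int],
    global_yx: tuple[float, float],
    grid: GridSpec,
) -> tuple[float, float]:
    """Inverse of :func:`to_global_coords` for a given field."""
    fx, fy = field_xy
    oy, ox = grid.field_origin(fx, fy)
    y, x = global_yx[0] - oy, global_yx[1] - ox
    if not (0 <= y < grid.field_height and 0 <= x < grid.field_width):
        raise ValueError(
            f"global position {global_yx} does not fall inside field ({fx}, {fy})"
        )
    return y, x
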