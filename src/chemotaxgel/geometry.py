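"""Chamber geometry: well layout, raster masks and quadrant partitions.

The chamber holds a central (tumor) well surrounded by three outer (stromal)
wells on the vertices of an equilateral triangle. All physical coordinates
are in micrometres with the image convention: ``x`` increases with column,
``y`` increases with row (downward), origin at the top-left corner of the
chamber. A pixel ``(r, c)`` has its center at ``((c + 0.5) * pixel_size,
(r + 0.5) * pixel_size)``; mask membership is decided by a pixel-center test
so masks are deterministic.

Quadrants are named by intercardinal direction with NW the top-left block;
pixels on dividing lines are assigned by half-open intervals so the four
quadrants plus the central exclusion disk tile a square crop exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import tifffile
import yaml

__all__ = [
    "GeometryError",
    "ChamberLayout",
    "WELL_IDS",
    "QUADRANTS",
    "build_layout",
    "default_layout",
    "well_mask",
    "quadrant_masks",
    "central_exclusion_mask",
    "load_layout",
    "save_layout",
    "save_mask",
    "DESIGN_WELL_DIAMETER_UM",
    "FABRICATED_WELL_DIAMETER_UM",
    "WELL_SPACING_UM",
    "DEFAULT_EXTENT_UM",
]

# Chamber presets: 1.46 mm edge-to-edge spacing between the central pillar
# and each outer pillar; the mold design diameter is 1.2 mm while the
# fabricated pillars averaged 1.63 mm.
DESIGN_WELL_DIAMETER_UM = 1200.0
FABRICATED_WELL_DIAMETER_UM = 1630.0
WELL_SPACING_UM = 1460.0  # edge-to-edge
DEFAULT_EXTENT_UM = (10650.0, 9400.0)  # (width, height)

WELL_IDS = ("center", "outer0", "outer1", "outer2")
QUADRANTS = ("NW", "NE", "SW", "SE")


class GeometryError(ValueError):
    """A chamber layout or mask request violates a geometric constraint."""


@dataclass(frozen=True)
class ChamberLayout:
    """Positions and sizes of the four wells plus the raster calibration.

    Attributes
    ----------
    center_well_position, outer_well_positions:
        ``(x, y)`` well centers in µm (image convention, y down).
    well_radius:
        Radius of every well disk in µm.
    edge_to_edge_spacing:
        Gap between the central well rim and each outer well rim, µm.
    chamber_extent:
        ``(width, height)`` of the imaged chamber in µm.
    pixel_size:
        µm per pixel of rasters referring to this layout.
    orientation_deg:
        Bearing of the first outer well, clockwise from "north" (up).
    """

    center_well_position: tuple[float, float]
    outer_well_positions: tuple[tuple[float, float], ...]
    well_radius: float
    edge_to_edge_spacing: float
    chamber_extent: tuple[float, float]
    pixel_size: float = 1.0
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.well_radius < 0:
            raise GeometryError("well_radius must be non-negative")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        if len(self.outer_well_positions) != 3:
            raise GeometryError("exactly three outer wells are required")

    # -- lookups ---------------------------------------------------------
    def well_position(self, which: str) -> tuple[float, float]:
        """Physical (x, y) center of a well, µm."""
        if which == "center":
            return self.center_well_position
        if which.startswith("outer"):
            idx = int(which[5:])
            return self.outer_well_positions[idx]
        raise GeometryError(f"unknown well id {which!r}; use one of {WELL_IDS}")

    def well_center_px(self, which: str) -> tuple[float, float]:
        """Well center in fractional pixel-index coordinates ``(row, col)``."""
        x, y = self.well_position(which)
        return (y / self.pixel_size - 0.5, x / self.pixel_size - 0.5)

    @property
    def center_to_center(self) -> float:
        """Distance from the central well to each outer well center, µm."""
        return self.edge_to_edge_spacing + 2.0 * self.well_radius

    @property
    def well_radius_px(self) -> float:
        return self.well_radius / self.pixel_size

    def to_config(self) -> dict:
        return {
            "well_diameter_um": 2.0 * self.well_radius,
            "spacing_um": self.edge_to_edge_spacing,
            "edge_to_edge": True,
            "chamber_extent_um": list(self.chamber_extent),
            "pixel_size_um": self.pixel_size,
            "orientation_deg": self.orientation_deg,
        }


def _bearing_unit(theta_deg: float) -> tuple[float, float]:
    """Unit vector at a bearing measured clockwise from north (up)."""
    th = math.radians(theta_deg)
    return (math.sin(th), -math.cos(th))


def build_layout(
    well_diameter: float,
    spacing: float,
    chamber_extent: tuple[float, float],
    pixel_size: float = 1.0,
    orientation_deg: float = 0.0,
) -> ChamberLayout:
    """Construct the canonical 4-well layout.

    The outer wells sit on an equilateral triangle centered on the chamber
    center, the first one at ``orientation_deg`` clockwise from north.
    ``spacing`` is the edge-to-edge gap between the central well and each
    outer well.

    Raises
    ------
    GeometryError
        If the wells would touch, overlap, or exceed the chamber extent; the
        message names the violated constraint.
    """
    if well_diameter <= 0:
        raise GeometryError("infeasible geometry: well_diameter must be positive")
    if spacing <= 0:
        raise GeometryError(
            "infeasible geometry: wells touch or overlap (edge-to-edge spacing "
            "must be positive)"
        )
    width, height = float(chamber_extent[0]), float(chamber_extent[1])
    r = well_diameter / 2.0
    center = (width / 2.0, height / 2.0)
    c2c = spacing + well_diameter  # center-to-center distance
    outer = tuple(
        (
            center[0] + c2c * _bearing_unit(orientation_deg + k * 120.0)[0],
            center[1] + c2c * _bearing_unit(orientation_deg + k * 120.0)[1],
        )
        for k in range(3)
    )
    for name, (x, y) in [("center", center)] + [
        (f"outer{k}", p) for k, p in enumerate(outer)
    ]:
        if x - r < 0 or y - r < 0 or x + r > width or y + r > height:
            raise GeometryError(
                f"infeasible geometry: well {name!r} exceeds the chamber extent"
            )
    # Outer-outer separation is sqrt(3) * c2c; check anyway for safety.
    for i in range(3):
        for j in range(i + 1, 3):
            d = math.dist(outer[i], outer[j])
            if d <= 2 * r:
                raise GeometryError("infeasible geometry: outer wells overlap")
    return ChamberLayout(
        center_well_position=center,
        outer_well_positions=outer,
        well_radius=r,
        edge_to_edge_spacing=spacing,
        chamber_extent=(width, height),
        pixel_size=pixel_size,
        orientation_deg=orientation_deg,
    )


def default_layout(
    fabricated: bool = True,
    pixel_size: float = 10.0,
    orientation_deg: float = 0.0,
) -> ChamberLayout:
    """Layout preset using the fabricated (1.63 mm) or design (1.2 mm) wells."""
    d = FABRICATED_WELL_DIAMETER_UM if fabricated else DESIGN_WELL_DIAMETER_UM
    return build_layout(
        d,
        WELL_SPACING_UM,
        DEFAULT_EXTENT_UM,
        pixel_size=pixel_size,
        orientation_deg=orientation_deg,
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def _pixel_center_grids(shape: tuple[int, int], pixel_size: float):
    rows = (np.arange(shape[0]) + 0.5) * pixel_size
    cols = (np.arange(shape[1]) + 0.5) * pixel_size
    return rows[:, None], cols[None, :]


def well_mask(
    layout: ChamberLayout, image_shape: tuple[int, int], which: str
) -> np.ndarray:
    """Boolean raster of pixels whose center lies inside the well disk."""
    x, y = layout.well_position(which)
    r = layout.well_radius
    ps = layout.pixel_size
    h_um = image_shape[0] * ps
    w_um = image_shape[1] * ps
    if x - r < 0 or y - r < 0 or x + r > w_um or y + r > h_um:
        raise GeometryError(f"well {which!r} does not lie inside the raster")
    if r <= 0:
        return np.zeros(image_shape, dtype=bool)
    yy, xx = _pixel_center_grids(image_shape, ps)
    return (xx - x) ** 2 + (yy - y) ** 2 < r * r


def central_exclusion_mask(
    crop_shape: tuple[int, int], exclusion_radius: float
) -> np.ndarray:
    """Disk of pixels (center test, radius in px) around the crop center."""
    side = crop_shape[0]
    if crop_shape[0] != crop_shape[1]:
        raise GeometryError("crop must be square (1:1 ratio)")
    if exclusion_radius >= side / 2.0:
        raise GeometryError("exclusion_radius must be smaller than half the side")
    if exclusion_radius <= 0:
        return np.zeros(crop_shape, dtype=bool)
    rr = np.arange(side) + 0.5 - side / 2.0
    return (rr[:, None] ** 2 + rr[None, :] ** 2) < exclusion_radius**2


def quadrant_masks(
    crop_shape: tuple[int, int], exclusion_radius: float = 0.0
) -> dict[str, np.ndarray]:
    """Four intercardinal quadrant masks of a square crop, minus the central disk.

    The quadrants partition the crop exactly: they are pairwise disjoint and
    their union plus the excluded central disk covers every pixel once.
    NW is the top-left block (row and column pixel centers below the crop
    midline, half-open convention).
    """
    side = crop_shape[0]
    if crop_shape[0] != crop_shape[1]:
        raise GeometryError("crop must be square (1:1 ratio)")
    excl = central_exclusion_mask(crop_shape, exclusion_radius)
    centers = np.arange(side) + 0.5
    top = centers < side / 2.0
    left = centers < side / 2.0
    masks = {
        "NW": top[:, None] & left[None, :],
        "NE": top[:, None] & ~left[None, :],
        "SW": ~top[:, None] & left[None, :],
        "SE": ~top[:, None] & ~left[None, :],
    }
    return {name: m & ~excl for name, m in masks.items()}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit TIFF (foreground = 255)."""
    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))


def save_layout(path, layout: ChamberLayout) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout.to_config(), fh)


def load_layout(source) -> ChamberLayout:
    """Build a layout from a YAML/JSON config path or an already-parsed dict.

    Recognized keys: ``well_diameter_um``, ``spacing_um`` (edge-to-edge),
    ``chamber_extent_um``, ``pixel_size_um``, ``orientation_deg``.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    missing = [
        k for k in ("well_diameter_um", "spacing_um", "chamber_extent_um") if k not in cfg
    ]
    if missing:
        raise GeometryError(f"layout config missing keys: {missing}")
    return build_layout(
        float(cfg["well_diameter_um"]),
        float(cfg["spacing_um"]),
        tuple(float(v) for v in cfg["chamber_extent_um"]),
        pixel_size=float(cfg.get("pixel_size_um", 1.0)),
        orientation_deg=float(cfg.get("orientation_deg", 0.0)),
    )
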