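"""Template grid, action quantization, needle rasterization and core lengths.

A brachytherapy-style template of 13x13 holes at 5 mm pitch sits in the
transverse plane; needles travel along the image's third axis. Actions move
the current grid position by a continuous in-plane displacement in grid
steps, and a third component selects no-fire / fire-at-apex / fire-at-base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms_io import NEEDLE_AXIS, MaskVolume, PatientCase

__all__ = [
    "GRID_SIZE",
    "GRID_PITCH_MM",
    "DEFAULT_CORE_LENGTH_MM",
    "TemplateGrid",
    "Action",
    "NeedleRecord",
    "build_template_grid",
    "quantize_action",
    "depth_planes",
    "gland_depth_planes",
    "rasterize_needle",
    "intersection_length",
    "records_to_frame",
]

GRID_SIZE = 13
GRID_PITCH_MM = 5.0
CENTRE_INDEX = GRID_SIZE // 2  # node (6,6) is the grid centre

#: default biopsy core length; approximates a standard 20 mm sampling notch
DEFAULT_CORE_LENGTH_MM = 20.0

NO_FIRE = "no_fire"
APEX = "apex"
BASE = "base"


@dataclass(frozen=True)
class TemplateGrid:
    """13x13 template at 5 mm pitch centred on ``centre_mm`` (world x,y)."""

    centre_mm: tuple[float, float]
    n_rows: int = GRID_SIZE
    n_cols: int = GRID_SIZE
    pitch_mm: float = GRID_PITCH_MM
    axis: int = NEEDLE_AXIS

    def node(self, i: int, j: int) -> tuple[float, float]:
        """World (x, y) mm of grid node (i, j), i, j in 0..12."""
        half = self.n_rows // 2
        return (
            self.centre_mm[0] + (i - half) * self.pitch_mm,
            self.centre_mm[1] + (j - half) * self.pitch_mm,
        )

    def all_nodes(self) -> np.ndarray:
        """(n_rows*n_cols, 2) array of world node coordinates, row-major."""
        ii, jj = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        half = self.n_rows // 2
        x = self.centre_mm[0] + (ii - half) * self.pitch_mm
        y = self.centre_mm[1] + (jj - half) * self.pitch_mm
        return np.stack([x.ravel(), y.ravel()], axis=1)


@dataclass(frozen=True)
class Action:
    """Continuous agent action (dx, dy, dz).

    dx, dy are in-plane displacements in grid steps within (-10, +10);
    dz in [-1, 1] selects no-fire (dz < -1/3), fire at the apex depth
    (-1/3 <= dz < 1/3) or fire at the base depth (dz >= 1/3).
    """

    dx: float
    dy: float
    dz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)


@dataclass
class NeedleRecord:
    """Outcome of one environment step (one potential needle)."""

    step_index: int
    grid_node: tuple[int, int]
    depth_label: str  # "apex", "base" or "no_fire"
    fired: bool
    hit: bool
    ccl_mm: float
    inside_gland: bool
    node_xy_mm: tuple[float, float] = (np.nan, np.nan)
    reward: int = 0

    def __post_init__(self) -> None:
        if self.hit and not self.fired:
            raise ValueError("hit requires fired")
        if self.hit != (self.ccl_mm > 0):
            raise ValueError("ccl_mm > 0 must coincide with hit")


def build_template_grid(case: PatientCase) -> TemplateGrid:
    """Centre the template on the gland centroid projected onto the plane."""
    centroid = case.gland.centroid_mm()
    in_plane = [d for d in range(3) if d != NEEDLE_AXIS]
    return TemplateGrid(centre_mm=(centroid[in_plane[0]], centroid[in_plane[1]]))


def _round_half_away(x: float) -> int:
    """Round half away from zero, symmetric in sign (3.5 -> 4, -3.5 -> -4)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def quantize_action(
    a: Action, current_node: tuple[int, int]
) -> tuple[tuple[int, int], bool, str]:
    """Quantize a continuous action at the current node.

    Returns ``(new_node, fire, depth_label)``. In-plane components round to
    whole grid steps (half away from zero) and the node clamps into the grid.
    """
    arr = a.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite action {arr}")
    di, dj = _round_half_away(a.dx), _round_half_away(a.dy)
    i = int(np.clip(current_node[0] + di, 0, GRID_SIZE - 1))
    j = int(np.clip(current_node[1] + dj, 0, GRID_SIZE - 1))
    if a.dz < -1.0 / 3.0:
        return (i, j), False, NO_FIRE
    if a.dz < 1.0 / 3.0:
        return (i, j), True, APEX
    return (i, j), True, BASE


def depth_planes(case: PatientCase) -> tuple[float, float]:
    """Apex and base firing depths: 25% and 75% of the gland's axial extent.

    Returns world mm coordinates along the needle axis.
    """
    return gland_depth_planes(case.gland)


def gland_depth_planes(gland: MaskVolume) -> tuple[float, float]:
    """Depth planes computed directly from a gland mask (used by agents that
    only see the observed, possibly mis-registered, gland)."""
    idx = np.argwhere(gland.voxels > 0)[:, NEEDLE_AXIS]
    z = gland.origin[NEEDLE_AXIS] + idx * gland.spacing[NEEDLE_AXIS]
    zmin, zmax = float(z.min()), float(z.max())
    if zmax - zmin < gland.spacing[NEEDLE_AXIS]:
        raise ValueError("gland degenerate along the needle axis")
    extent = zmax - zmin
    return zmin + 0.25 * extent, zmin + 0.75 * extent


def rasterize_needle(
    node: tuple[int, int],
    depth_label: str,
    core_length_mm: float,
    case: PatientCase,
    grid: TemplateGrid | None = None,
    planes: tuple[float, float] | None = None,
) -> MaskVolume:
    """Rasterize a straight axis-aligned needle core as a binary mask.

    One-voxel-thick column at the node's world (x, y), spanning
    ``core_length_mm`` centred on the chosen depth plane and clipped to the
    image bounds. Voxels whose centres fall in the half-open interval
    [centre - L/2, centre + L/2) are set, so a 20 mm core at 1 mm spacing
    covers exactly 20 voxels when interior.
    """
    if core_length_mm <= 0:
        raise ValueError("core_length_mm must be positive")
    if grid is None:
        grid = build_template_grid(case)
    ref = case.gland
    x_mm, y_mm = grid.node(*node)
    in_plane = [d for d in range(3) if d != NEEDLE_AXIS]
    ix = int(round((x_mm - ref.origin[in_plane[0]]) / ref.spacing[in_plane[0]]))
    iy = int(round((y_mm - ref.origin[in_plane[1]]) / ref.spacing[in_plane[1]]))
    shape = ref.shape
    if not (0 <= ix < shape[in_plane[0]] and 0 <= iy < shape[in_plane[1]]):
        raise ValueError(f"grid node {node} falls outside the image field of view")

    apex_z, base_z = planes if planes is not None else depth_planes(case)
    centre_z = apex_z if depth_label == APEX else base_z
    sz = ref.spacing[NEEDLE_AXIS]
    z0 = ref.origin[NEEDLE_AXIS]
    k_lo = int(np.ceil((centre_z - core_length_mm / 2.0 - z0) / sz))
    k_hi = int(np.ceil((centre_z + core_length_mm / 2.0 - z0) / sz))  # exclusive
    k_lo = max(k_lo, 0)
    k_hi = min(k_hi, shape[NEEDLE_AXIS])
    voxels = np.zeros(shape, dtype=np.uint8)
    if k_hi > k_lo:
        sl = [0, 0, 0]
        sl[in_plane[0]] = ix
        sl[in_plane[1]] = iy
        sl[NEEDLE_AXIS] = slice(k_lo, k_hi)
        voxels[tuple(sl)] = 1
    return MaskVolume(voxels, ref.spacing, ref.origin)


def intersection_length(trajectory: MaskVolume, lesion: MaskVolume) -> float:
    """Length (mm) of the needle trajectory inside the lesion.

    Counts overlapping voxels and multiplies by the needle-axis spacing.
    """
    if trajectory.shape != lesion.shape:
        raise ValueError(
            f"shape mismatch {trajectory.shape} vs {lesion.shape}"
        )
    if trajectory.spacing != lesion.spacing:
        raise ValueError("spacing mismatch between trajectory and lesion")
    overlap = int(np.count_nonzero(trajectory.voxels & lesion.voxels))
    return overlap * trajectory.spacing[NEEDLE_AXIS]


def records_to_frame(records: list[NeedleRecord]):
    """Needle records as a DataFrame (step, i, j, depth_label, fired, hit, ccl_mm)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "step": [r.step_index for r in records],
            "i": [r.grid_node[0] for r in records],
            "j": [r.grid_node[1] for r in records],
            "depth_label": [r.depth_label for r in records],
            "fired": [r.fired for r in records],
            "hit": [r.hit for r in records],
            "ccl_mm": [r.ccl_mm for r in records],
        }
    )
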