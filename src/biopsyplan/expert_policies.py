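"""Clinically motivated demonstration policies and demonstration datasets.

Two fixed sampling strategies are provided:

* the *centre* policy targets the five template nodes closest to the lesion
  centroid — the strategy most commonly applied in practice;
* the *edge* policy targets the node nearest the centroid followed by four
  nodes at the boundary of the lesion's transverse projection along the
  +x, -x, +y and -y directions, spreading cores toward the lesion periphery.

Both are deterministic functions of the lesion mask and the grid. Rolling a
plan through a zero-mismatch environment yields state-action pairs used to
supervise behavioural cloning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import BiopsyEnv, Observation
from .geometry import (
    APEX,
    BASE,
    GRID_SIZE,
    Action,
    TemplateGrid,
    build_template_grid,
    gland_depth_planes,
)
from .phantoms_io import NEEDLE_AXIS, MaskVolume, PatientCase

__all__ = [
    "NeedlePlan",
    "DemoDataset",
    "centre_policy",
    "edge_policy",
    "plan_from_masks",
    "plan_to_demos",
    "ExpertAgent",
    "RandomPolicy",
    "NeverFirePolicy",
]

N_NEEDLES = 5
MAX_MOVE = 10  # largest in-plane displacement one action can express

#: dz values that quantize to each firing decision (mid-range representatives)
DZ_FOR = {"no_fire": -2.0 / 3.0, APEX: 0.0, BASE: 2.0 / 3.0}


@dataclass
class NeedlePlan:
    """Ordered list of (grid node, depth label) pairs; exactly 5 by default."""

    entries: list[tuple[tuple[int, int], str]]

    def __post_init__(self) -> None:
        for (i, j), depth in self.entries:
            if not (0 <= i < GRID_SIZE and 0 <= j < GRID_SIZE):
                raise ValueError(f"plan node ({i},{j}) outside the grid")
            if depth not in (APEX, BASE):
                raise ValueError(f"unknown depth label {depth!r}")

    @property
    def nodes(self) -> list[tuple[int, int]]:
        return [n for n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DemoDataset:
    """Paired (observation, action) demonstrations D = (s_0, a_0, ..., s_n, a_n)."""

    observations: list[Observation] = field(default_factory=list)
    actions: list[np.ndarray] = field(default_factory=list)
    case_ids: list[str] = field(default_factory=list)

    def extend(self, other: "DemoDataset") -> None:
        self.observations.extend(other.observations)
        self.actions.extend(other.actions)
        self.case_ids.extend(other.case_ids)

    def actions_array(self) -> np.ndarray:
        return np.stack(self.actions) if self.actions else np.empty((0, 3))

    def __len__(self) -> int:
        return len(self.actions)

    def save(self, path) -> None:
        """Write a compressed archive: observation channels, grid state and
        the paired actions."""
        arrays = {
            f"obs_{k}": o.channels() for k, o in enumerate(self.observations)
        }
        meta = np.array(
            [
                [*o.node, *o.grid.centre_mm, *o.gland.spacing, *o.gland.origin]
                for o in self.observations
            ],
            dtype=float,
        )
        np.savez_compressed(
            path,
            actions=self.actions_array(),
            case_ids=np.array(self.case_ids, dtype=str),
            meta=meta,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "DemoDataset":
        from .environment import Observation
        from .geometry import TemplateGrid

        data = np.load(path, allow_pickle=False)
        demos = cls()
        demos.actions = [a for a in data["actions"]]
        demos.case_ids = [str(c) for c in data["case_ids"]]
        meta = data["meta"]
        for k in range(len(demos.actions)):
            ch = data[f"obs_{k}"]
            node = (int(meta[k, 0]), int(meta[k, 1]))
            spacing = tuple(meta[k, 4:7])
            origin = tuple(meta[k, 7:10])
            masks = [
                MaskVolume((c > 0.5).astype(np.uint8), spacing, origin)
                for c in ch
            ]
            demos.observations.append(
                Observation(
                    gland=masks[0], lesion=masks[1],
                    needles=(masks[2], masks[3], masks[4]),
                    node=node,
                    grid=TemplateGrid(centre_mm=(meta[k, 2], meta[k, 3])),
                )
            )
        return demos


def _in_plane_axes() -> tuple[int, int]:
    return tuple(d for d in range(3) if d != NEEDLE_AXIS)  # type: ignore[return-value]


def _nearest_nodes(
    grid: TemplateGrid, point_xy: np.ndarray, k: int
) -> list[tuple[int, int]]:
    """The k grid nodes nearest a world (x, y) point.

    Ties broken lexicographically by (distance, i, j).
    """
    nodes = grid.all_nodes()
    d = np.hypot(nodes[:, 0] - point_xy[0], nodes[:, 1] - point_xy[1])
    ii, jj = np.divmod(np.arange(len(nodes)), grid.n_cols)
    order = np.lexsort((jj, ii, np.round(d, 9)))
    return [(int(ii[t]), int(jj[t])) for t in order[:k]]


def _depth_for(lesion_z_mm: float, gland: MaskVolume) -> str:
    apex_z, base_z = gland_depth_planes(gland)
    return APEX if abs(lesion_z_mm - apex_z) <= abs(lesion_z_mm - base_z) else BASE


def plan_from_masks(
    gland: MaskVolume,
    lesion: MaskVolume,
    grid: TemplateGrid,
    kind: str = "centre",
    n_needles: int = N_NEEDLES,
) -> NeedlePlan:
    """Build a centre or edge plan directly from (possibly observed) masks."""
    if lesion.voxels.sum() == 0:
        raise ValueError("cannot plan on an empty lesion")
    ax, ay = _in_plane_axes()
    centroid = lesion.centroid_mm()
    c_xy = np.array([centroid[ax], centroid[ay]])
    depth = _depth_for(centroid[NEEDLE_AXIS], gland)

    if kind == "centre":
        nodes = _nearest_nodes(grid, c_xy, n_needles)
        return NeedlePlan([(n, depth) for n in nodes])
    if kind != "edge":
        raise ValueError(f"unknown plan kind {kind!r}")

    centre_node = _nearest_nodes(grid, c_xy, 1)[0]
    entries = [(centre_node, depth)]
    used = {centre_node}
    for direction in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        bp = _boundary_point(lesion, c_xy, direction)
        node = _nearest_nodes(grid, bp, 1)[0]
        # duplicates step outward along the ray to the next unused node
        while node in used:
            stepped = (node[0] + direction[0], node[1] + direction[1])
            if not (0 <= stepped[0] < GRID_SIZE and 0 <= stepped[1] < GRID_SIZE):
                node = next(
                    n for n in _nearest_nodes(grid, bp, GRID_SIZE**2) if n not in used
                )
                break
            node = stepped
        used.add(node)
        entries.append((node, depth))
    return NeedlePlan(entries[:n_needles])


def _boundary_point(
    lesion: MaskVolume, centroid_xy: np.ndarray, direction: tuple[int, int]
) -> np.ndarray:
    """Boundary of the lesion's transverse projection along an axis ray.

    Walks from the centroid along +/-x or +/-y within the projection row or
    column through the centroid and returns the last occupied voxel centre in
    world (x, y). Falls back to the projection's global extreme if the
    centroid row/column is empty after rasterization.
    """
    ax, ay = _in_plane_axes()
    proj = lesion.voxels.any(axis=NEEDLE_AXIS)  # shape (nx, ny)
    nx, ny = proj.shape
    cix = int(round((centroid_xy[0] - lesion.origin[ax]) / lesion.spacing[ax]))
    ciy = int(round((centroid_xy[1] - lesion.origin[ay]) / lesion.spacing[ay]))
    cix = int(np.clip(cix, 0, nx - 1))
    ciy = int(np.clip(ciy, 0, ny - 1))
    if direction[0] != 0:
        line = proj[:, ciy]
        occupied = np.flatnonzero(line)
        if occupied.size == 0:
            occupied = np.flatnonzero(proj.any(axis=1))
        idx = occupied.max() if direction[0] > 0 else occupied.min()
        x = lesion.origin[ax] + idx * lesion.spacing[ax]
        return np.array([x, centroid_xy[1]])
    line = proj[cix, :]
    occupied = np.flatnonzero(line)
    if occupied.size == 0:
        occupied = np.flatnonzero(proj.any(axis=0))
    idx = occupied.max() if direction[1] > 0 else occupied.min()
    y = lesion.origin[ay] + idx * lesion.spacing[ay]
    return np.array([centroid_xy[0], y])


def centre_policy(case: PatientCase, grid: TemplateGrid | None = None) -> NeedlePlan:
    """Five grid nodes closest to the lesion centroid (in-plane distance)."""
    if grid is None:
        grid = build_template_grid(case)
    return plan_from_masks(case.gland, case.lesion, grid, kind="centre")


def edge_policy(case: PatientCase, grid: TemplateGrid | None = None) -> NeedlePlan:
    """Lesion-centre node plus four nodes at the projected lesion boundary."""
    if grid is None:
        grid = build_template_grid(case)
    return plan_from_masks(case.gland, case.lesion, grid, kind="edge")


def _actions_for_plan(
    plan: NeedlePlan, start_node: tuple[int, int]
) -> list[np.ndarray]:
    """Relative (dx, dy, dz) actions realizing a plan from a start node.

    Displacements beyond +/-10 nodes split into a no-fire move plus a fire
    step. Quantizing each emitted action round-trips exactly.
    """
    actions = []
    cur = start_node
    for (ti, tj), depth in plan.entries:
        while max(abs(ti - cur[0]), abs(tj - cur[1])) > MAX_MOVE:
            di = int(np.clip(ti - cur[0], -MAX_MOVE, MAX_MOVE))
            dj = int(np.clip(tj - cur[1], -MAX_MOVE, MAX_MOVE))
            actions.append(np.array([di, dj, DZ_FOR["no_fire"]], dtype=float))
            cur = (cur[0] + di, cur[1] + dj)
        actions.append(
            np.array([ti - cur[0], tj - cur[1], DZ_FOR[depth]], dtype=float)
        )
        cur = (ti, tj)
    return actions


def plan_to_demos(
    plan: NeedlePlan, case: PatientCase, env: BiopsyEnv | None = None
) -> DemoDataset:
    """Roll a plan through a zero-mismatch environment into (s, a) pairs."""
    if env is None:
        env = BiopsyEnv()
    if env.tre is not None or (env.deform is not None and env.deform.enabled):
        raise ValueError("demonstrations require a zero-mismatch environment")
    obs = env.reset(case)
    demos = DemoDataset()
    for a in _actions_for_plan(plan, obs.node):
        demos.observations.append(obs)
        demos.actions.append(a)
        demos.case_ids.append(case.case_id)
        obs, _, done, _ = env.step(Action(*a))
        if done:
            break
    return demos


class ExpertAgent:
    """Plan-following agent usable inside the environment.

    At episode start it plans from the *observed* gland and lesion (so a
    registration error displaces its whole plan), then replays the plan's
    actions; once the plan is exhausted it stops firing.
    """

    def __init__(self, kind: str = "centre"):
        if kind not in ("centre", "edge"):
            raise ValueError("kind must be 'centre' or 'edge'")
        self.kind = kind
        self._queue: list[np.ndarray] = []

    def begin_episode(self, obs: Observation) -> None:
        plan = plan_from_masks(obs.gland, obs.lesion, obs.grid, kind=self.kind)
        self._queue = _actions_for_plan(plan, obs.node)

    def __call__(self, obs: Observation) -> Action:
        if self._queue:
            return Action(*self._queue.pop(0))
        return Action(0.0, 0.0, DZ_FOR["no_fire"])


class RandomPolicy:
    """Uniform random actions over the action box (the RL baseline)."""

    def __init__(self, seed: int | None = None):
        self.rng = np.random.default_rng(seed)

    def __call__(self, obs: Observation) -> Action:
        dx, dy = self.rng.uniform(-10.0, 10.0, 2)
        dz = self.rng.uniform(-1.0, 1.0)
        return Action(float(dx), float(dy), float(dz))


class NeverFirePolicy:
    """Moves nowhere and never fires; useful as a degenerate reference."""

    def __call__(self, obs: Observation) -> Action:
        return Action(0.0, 0.0, DZ_FOR["no_fire"])
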