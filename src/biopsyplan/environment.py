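"""The biopsy-planning MDP.

State: five aligned binary channels — observed gland, observed lesion, and
the last three needle-trajectory masks. Action: continuous (dx, dy, dz)
moving the template position and deciding whether/where to fire. Reward:
+10 for a fired needle intersecting the lesion, -2 for a fired miss inside
the gland, -1 for not firing, -5 for a needle placed outside the gland.
Episodes cap at 20 steps and end early once five fired needles have hit.

Mismatch injection: a rigid registration error (TRE) perturbs only the
*observed* gland/lesion channels, while rewards are judged against the true
anatomy; free-form deformation perturbs the *true* anatomy each step (the
lesion genuinely moves) and the observation shows the deformed anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import geometry
from ._nn import adaptive_pool
from .geometry import (
    Action,
    DEFAULT_CORE_LENGTH_MM,
    NeedleRecord,
    TemplateGrid,
    build_template_grid,
    intersection_length,
    quantize_action,
    rasterize_needle,
)
from .mismatch import (
    DeformationConfig,
    TREConfig,
    densify,
    sample_deformation,
    sample_tre,
    translate_mask,
    warp_mask,
)
from .phantoms_io import MaskVolume, PatientCase

__all__ = [
    "RewardSpec",
    "Observation",
    "EpisodeResult",
    "BiopsyEnv",
    "run_episode",
]

MAX_STEPS = 20
NEEDLES_PER_PLAN = 5


@dataclass(frozen=True)
class RewardSpec:
    """Integer rewards for the four step outcomes."""

    hit: int = 10
    miss: int = -2
    no_fire: int = -1
    outside_gland: int = -5


@dataclass
class Observation:
    """What the agent sees at one time step."""

    gland: MaskVolume
    lesion: MaskVolume
    needles: tuple[MaskVolume, MaskVolume, MaskVolume]  # (N_t, N_{t-1}, N_{t-2})
    node: tuple[int, int]
    grid: TemplateGrid

    def channels(self) -> np.ndarray:
        """Stacked (5, *shape) float32 array: gland, lesion, N_t, N_t-1, N_t-2."""
        return np.stack(
            [
                self.gland.voxels,
                self.lesion.voxels,
                self.needles[0].voxels,
                self.needles[1].voxels,
                self.needles[2].voxels,
            ]
        ).astype(np.float32)


@dataclass
class EpisodeResult:
    """Full record of one episode."""

    case_id: str
    records: list[NeedleRecord]
    rewards: list[int]
    termination: str  # "max_steps" or "five_hits"

    @property
    def total_reward(self) -> int:
        return int(sum(self.rewards))

    @property
    def n_fired(self) -> int:
        return sum(r.fired for r in self.records)

    @property
    def n_hits(self) -> int:
        return sum(r.hit for r in self.records)

    def to_json(self) -> str:
        return json.dumps(
            {
                "case_id": self.case_id,
                "termination": self.termination,
                "total_reward": self.total_reward,
                "steps": [
                    {
                        "step": r.step_index,
                        "i": r.grid_node[0],
                        "j": r.grid_node[1],
                        "depth_label": r.depth_label,
                        "fired": bool(r.fired),
                        "hit": bool(r.hit),
                        "ccl_mm": float(r.ccl_mm),
                        "inside_gland": bool(r.inside_gland),
                        "node_x_mm": float(r.node_xy_mm[0]),
                        "node_y_mm": float(r.node_xy_mm[1]),
                        "reward": int(r.reward),
                    }
                    for r in self.records
                ],
            }
        )

    @staticmethod
    def from_json(s: str) -> dict:
        return json.loads(s)


def _resample_mask(mask: MaskVolume, shape: tuple[int, int, int]) -> MaskVolume:
    """Block-average downsampling with a low occupancy threshold (0.25) so
    one-voxel-thick needle channels survive the resolution change."""
    if mask.shape == tuple(shape):
        return mask
    pooled = adaptive_pool(mask.voxels, tuple(shape))
    spacing = tuple(
        sp * s / t for sp, s, t in zip(mask.spacing, mask.shape, shape)
    )
    return MaskVolume((pooled >= 0.25).astype(np.uint8), spacing, mask.origin)


class BiopsyEnv:
    """Episodic environment with a ``reset``/``step`` API.

    Parameters
    ----------
    core_length_mm:
        Biopsy core length; default 20 mm.
    tre, deform:
        Optional mismatch configurations; ``None`` disables each.
    observation_shape:
        If set, observation channels are resampled to this shape (the full
        resolution is always used for rewards and metrics).
    resample_tre_per_step:
        Draw a fresh TRE translation every step instead of one per episode.
    """

    def __init__(
        self,
        core_length_mm: float = DEFAULT_CORE_LENGTH_MM,
        reward_spec: RewardSpec = RewardSpec(),
        tre: TREConfig | None = None,
        deform: DeformationConfig | None = None,
        observation_shape: tuple[int, int, int] | None = None,
        max_steps: int = MAX_STEPS,
        needles_target: int = NEEDLES_PER_PLAN,
        resample_tre_per_step: bool = False,
    ) -> None:
        self.core_length_mm = core_length_mm
        self.reward_spec = reward_spec
        self.tre = tre
        self.deform = deform
        self.observation_shape = (
            tuple(observation_shape) if observation_shape else None
        )
        self.max_steps = max_steps
        self.needles_target = needles_target
        self.resample_tre_per_step = resample_tre_per_step
        self._case: PatientCase | None = None
        self._done = True

    # -- episode lifecycle -------------------------------------------------

    def reset(self, case: PatientCase, seed: int | None = None) -> Observation:
        """Start an episode on ``case``: node at the grid centre, empty
        needle history, mismatch state drawn from ``seed``."""
        if case is None:
            raise ValueError("a PatientCase is required")
        self._case = case
        self._rng = np.random.default_rng(seed)
        self._grid = build_template_grid(case)
        self._planes = geometry.depth_planes(case)
        self._node = (geometry.CENTRE_INDEX, geometry.CENTRE_INDEX)
        self._steps = 0
        self._hits = 0
        self._done = False
        self._records: list[NeedleRecord] = []
        self._rewards: list[int] = []
        self._termination = "max_steps"
        empty = MaskVolume(
            np.zeros(case.gland.shape, dtype=np.uint8),
            case.gland.spacing,
            case.gland.origin,
        )
        self._needle_history = [empty, empty.copy(), empty.copy()]
        self._true_gland = case.gland
        self._true_lesion = case.lesion
        self._accum_field = None
        self._anat_cache = None
        if self.observation_shape is not None:
            empty_obs = _resample_mask(empty, self.observation_shape)
            self._needle_history_obs = [empty_obs, empty_obs, empty_obs]
        self._draw_tre()
        self._refresh_observed()
        return self._observation()

    def step(self, action: Action) -> tuple[Observation, int, bool, dict]:
        """Apply one action; returns (observation, reward, done, info)."""
        if self._done or self._case is None:
            raise RuntimeError("step() called on a finished or unreset episode")
        if self.resample_tre_per_step:
            self._draw_tre()
        deformed = self._apply_deformation()
        if deformed or self.resample_tre_per_step:
            self._refresh_observed()

        node, fire, depth_label = quantize_action(action, self._node)
        self._node = node
        spec = self.reward_spec
        if fire:
            traj = rasterize_needle(
                node, depth_label, self.core_length_mm, self._case, self._grid,
                planes=self._planes,
            )
            inside = bool(
                np.count_nonzero(traj.voxels & self._true_gland.voxels)
            )
            ccl = intersection_length(traj, self._true_lesion)
            if not inside:
                reward, hit, ccl = spec.outside_gland, False, 0.0
            elif ccl > 0:
                reward, hit = spec.hit, True
            else:
                reward, hit = spec.miss, False
        else:
            traj = MaskVolume(
                np.zeros(self._case.gland.shape, dtype=np.uint8),
                self._case.gland.spacing,
                self._case.gland.origin,
            )
            inside, hit, ccl, reward = False, False, 0.0, spec.no_fire

        self._needle_history = [traj, self._needle_history[0], self._needle_history[1]]
        if self.observation_shape is not None:
            traj_obs = _resample_mask(traj, self.observation_shape)
            self._needle_history_obs = [
                traj_obs,
                self._needle_history_obs[0],
                self._needle_history_obs[1],
            ]
        self._steps += 1
        self._hits += int(hit)
        record = NeedleRecord(
            step_index=self._steps - 1,
            grid_node=node,
            depth_label=depth_label,
            fired=fire,
            hit=hit,
            ccl_mm=ccl,
            inside_gland=inside,
            node_xy_mm=self._grid.node(*node),
            reward=reward,
        )
        self._records.append(record)
        self._rewards.append(reward)

        if self._hits >= self.needles_target:
            self._done, self._termination = True, "five_hits"
        elif self._steps >= self.max_steps:
            self._done, self._termination = True, "max_steps"
        info = {"record": record, "hits": self._hits, "steps": self._steps}
        return self._observation(), reward, self._done, info

    def result(self) -> EpisodeResult:
        return EpisodeResult(
            case_id=self._case.case_id,
            records=list(self._records),
            rewards=list(self._rewards),
            termination=self._termination,
        )

    # -- mismatch ----------------------------------------------------------

    def _draw_tre(self) -> None:
        if self.tre is None or self.tre.level_mm == 0:
            self._tre_shift = None
        else:
            self._tre_shift = sample_tre(self.tre, self._rng)

    def _refresh_observed(self) -> None:
        """Recompute the observed anatomy (true anatomy plus TRE shift)."""
        gland, lesion = self._true_gland, self._true_lesion
        if self._tre_shift is not None:
            gland = translate_mask(gland, self._tre_shift["gland"])
            lesion = translate_mask(lesion, self._tre_shift["lesion"])
            if lesion.voxels.sum() == 0:  # shifted out of view; keep well-posed
                lesion = self._true_lesion
            if gland.voxels.sum() == 0:
                gland = self._true_gland
        self._observed_gland, self._observed_lesion = gland, lesion

    def _apply_deformation(self) -> bool:
        if self.deform is None or not self.deform.enabled:
            return False
        case = self._case
        shape = case.gland.shape
        spacing = case.gland.spacing
        extent = tuple((shape[d] - 1) * spacing[d] for d in range(3))
        fld = sample_deformation(
            self.deform.rate,
            self.deform.scale,
            self.deform.kernel_sigma_mm,
            extent,
            self._rng,
        )
        dense = densify(fld, shape, spacing)
        if self.deform.accumulate:
            self._accum_field = (
                dense if self._accum_field is None else self._accum_field + dense
            )
            dense = self._accum_field
        self._true_gland = warp_mask(case.gland, dense)
        self._true_lesion = warp_mask(case.lesion, dense)
        # a warp can push a small lesion entirely out of raster support;
        # fall back to the undeformed lesion to keep the episode well-posed
        if self._true_lesion.voxels.sum() == 0:
            self._true_lesion = case.lesion
        if self._true_gland.voxels.sum() == 0:
            self._true_gland = case.gland
        return True

    # -- observation -------------------------------------------------------

    def _observation(self) -> Observation:
        gland, lesion = self._observed_gland, self._observed_lesion
        needles = self._needle_history
        if self.observation_shape is not None:
            # anatomy channels change only under mismatch; cache by identity
            key = (id(gland), id(lesion))
            if self._anat_cache is None or self._anat_cache[0] != key:
                self._anat_cache = (
                    key,
                    _resample_mask(gland, self.observation_shape),
                    _resample_mask(lesion, self.observation_shape),
                )
            gland, lesion = self._anat_cache[1], self._anat_cache[2]
            needles = self._needle_history_obs
        return Observation(
            gland=gland,
            lesion=lesion,
            needles=(needles[0], needles[1], needles[2]),
            node=self._node,
            grid=self._grid,
        )


def run_episode(
    policy,
    case: PatientCase,
    env: BiopsyEnv | None = None,
    seed: int | None = None,
    **env_kwargs,
) -> EpisodeResult:
    """Roll one episode of ``policy`` (callable Observation -> Action).

    Policies with a ``begin_episode()`` method are notified at reset so that
    stateful agents (e.g. plan-following experts) can re-plan per episode.
    """
    if env is None:
        env = BiopsyEnv(**env_kwargs)
    obs = env.reset(case, seed=seed)
    if hasattr(policy, "begin_episode"):
        policy.begin_episode(obs)
    done = False
    while not done:
        action = policy(obs)
        obs, _, done, _ = env.step(action)
    return env.result()
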