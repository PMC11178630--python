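"""Behavioural cloning, PPO training and policy evaluation.

The policy maps the five observation channels to a continuous action
(dx, dy, dz). Channels are block-averaged to a coarse occupancy grid,
concatenated with the normalized current grid position, and fed to small
tanh MLPs: a policy trunk with a bounded (tanh) mean head plus a
state-independent log-std, and a separate value trunk of the same size, as
in the two-network actor-critic layout. Training is plain NumPy (the
networks are small enough that CPU matrix products dominate nothing).

Imitation learning minimises the mean squared error between demonstrated
and predicted actions. Reinforcement learning uses PPO: the clipped
surrogate, a value-function loss weighted by c1 and an entropy bonus
weighted by c2, with generalized advantage estimation. RL agents may start
from scratch or warm-start from a behaviourally cloned policy.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import MLP, Adam, adaptive_pool
from .environment import BiopsyEnv, Observation, run_episode
from .geometry import GRID_SIZE, Action
from .metrics import MetricsReport, build_report
from .mismatch import DeformationConfig, TREConfig
from .phantoms_io import PatientCase

__all__ = [
    "PolicyModel",
    "ILConfig",
    "PPOConfig",
    "behavioural_cloning",
    "ppo_train",
    "evaluate_policy",
    "clipped_surrogate",
]

LOG_2PI_E = float(np.log(2.0 * np.pi * np.e))


@dataclass
class ILConfig:
    """Behavioural-cloning schedule; defaults follow the study protocol
    (1000 epochs, Adam, learning rate 5e-4)."""

    epochs: int = 1000
    learning_rate: float = 5e-4
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class PPOConfig:
    """PPO schedule. Printed study defaults where available (lr 5e-5,
    20-step episodes, validation every 100 episodes); unprinted
    hyperparameters use widely adopted PPO values."""

    discount: float = 0.99
    clip_range: float = 0.2
    c1: float = 0.5  # value-loss weight
    c2: float = 0.01  # entropy weight
    learning_rate: float = 5e-5
    episodes: int = 2000
    max_steps: int = 20
    validation_interval: int = 100
    batch_episodes: int = 16
    update_epochs: int = 4
    minibatch_size: int = 64
    gae_lambda: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.discount <= 1):
            raise ValueError("discount must be in (0, 1]")
        if self.clip_range <= 0:
            raise ValueError("clip_range must be positive")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be non-negative")


class PolicyModel:
    """Gaussian policy plus value estimator over pooled mask observations.

    The mean is bounded by tanh to (-10, 10) in-plane and (-1, 1) in depth;
    sampling adds unbounded Gaussian noise (the environment's quantization
    clamps out-of-range draws). The log standard deviation is a learned
    state-independent parameter. Policy and value networks share the
    architecture but not the weights.
    """

    POOL_SHAPE = (8, 8, 4)
    ACTION_SCALE = np.array([10.0, 10.0, 1.0])
    #: gain on the pooled needle-history channels: a one-voxel-thick needle
    #: occupies ~1e-3 of a pooling block, far below the anatomy channels'
    #: occupancy; rescaling balances the feature magnitudes
    NEEDLE_GAIN = 50.0

    def __init__(
        self,
        hidden: tuple[int, ...] = (64, 64),
        seed: int = 0,
        zero_policy_head: bool = True,
        init_log_std: tuple[float, float, float] = (1.1, 1.1, -0.7),
    ):
        rng = np.random.default_rng(seed)
        n_feat = 5 * int(np.prod(self.POOL_SHAPE)) + 2
        sizes = (n_feat, *hidden)
        self.hidden = tuple(hidden)
        self.p_mlp = MLP(sizes + (3,), rng, zero_head=zero_policy_head)
        self.v_mlp = MLP(sizes + (1,), rng)
        self.log_std = np.array(init_log_std, dtype=float)
        self.train_log: list[dict] = []

    # -- parameters --------------------------------------------------------

    def params(self) -> dict[str, np.ndarray]:
        out = self.p_mlp.params("p_")
        out.update(self.v_mlp.params("v_"))
        out["log_std"] = self.log_std
        return out

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    def load_snapshot(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in self.params().items():
            v[...] = snap[k]

    def save(self, path) -> None:
        meta = {"hidden": list(self.hidden)}
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.params())

    @classmethod
    def load(cls, path) -> "PolicyModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        model = cls(hidden=tuple(meta["hidden"]))
        model.load_snapshot({k: data[k] for k in model.params()})
        return model

    # -- features and forward passes ---------------------------------------

    def featurize(self, obs: Observation) -> np.ndarray:
        """Pool the 5 channels to POOL_SHAPE and append the current node."""
        chans = obs.channels()
        pooled = [adaptive_pool(ch, self.POOL_SHAPE).ravel() for ch in chans]
        for k in (2, 3, 4):  # needle-history channels
            pooled[k] = np.minimum(pooled[k] * self.NEEDLE_GAIN, 1.0)
        half = GRID_SIZE // 2
        node = np.array(
            [(obs.node[0] - half) / half, (obs.node[1] - half) / half]
        )
        return np.concatenate(pooled + [node]).astype(float)

    def mean_forward(self, X: np.ndarray):
        raw, cache = self.p_mlp.forward(X)
        t = np.tanh(raw)
        return t * self.ACTION_SCALE, (cache, t)

    def mean_backward(self, dmean: np.ndarray, aux) -> dict[str, np.ndarray]:
        cache, t = aux
        draw = dmean * self.ACTION_SCALE * (1.0 - t**2)
        return {f"p_{k}": v for k, v in self.p_mlp.backward(draw, cache).items()}

    def value_forward(self, X: np.ndarray):
        v, cache = self.v_mlp.forward(X)
        return v[:, 0], cache

    def value_backward(self, dv: np.ndarray, cache) -> dict[str, np.ndarray]:
        return {
            f"v_{k}": g for k, g in self.v_mlp.backward(dv[:, None], cache).items()
        }

    # -- acting ------------------------------------------------------------

    def action_mean(self, obs: Observation) -> np.ndarray:
        mean, _ = self.mean_forward(self.featurize(obs)[None, :])
        return mean[0]

    def sample(self, obs: Observation, rng: np.random.Generator):
        """Stochastic action plus its log-density and the state value."""
        x = self.featurize(obs)[None, :]
        mean, _ = self.mean_forward(x)
        std = np.exp(self.log_std)
        a = mean[0] + std * rng.standard_normal(3)
        logp = self.log_prob(a[None, :], mean)[0]
        v, _ = self.value_forward(x)
        return a, float(logp), float(v[0]), x[0]

    def log_prob(self, actions: np.ndarray, means: np.ndarray) -> np.ndarray:
        std = np.exp(self.log_std)
        z = (actions - means) / std
        return -0.5 * (z**2).sum(axis=1) - self.log_std.sum() - 1.5 * np.log(
            2 * np.pi
        )

    def entropy(self) -> float:
        """Differential entropy of the Gaussian policy (state-independent)."""
        return float(self.log_std.sum() + 1.5 * LOG_2PI_E)

    def __call__(self, obs: Observation) -> Action:
        return Action(*self.action_mean(obs))


def behavioural_cloning(
    demos, model: PolicyModel, cfg: ILConfig = ILConfig()
) -> PolicyModel:
    """Minimise the MSE between demonstrated and predicted actions.

    Trains in place and returns the model; the per-epoch loss history is
    appended to ``model.train_log``. Raises on empty demonstrations or a
    non-finite loss.
    """
    if len(demos) == 0:
        raise ValueError("empty demonstration set")
    X = np.stack([model.featurize(o) for o in demos.observations])
    A = demos.actions_array()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.learning_rate)
    n = len(A)
    bs = cfg.batch_size or n
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        epoch_loss = 0.0
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            pred, aux = model.mean_forward(X[idx])
            err = pred - A[idx]
            loss = float((err**2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite imitation loss at epoch {epoch}"
                )
            grads = model.mean_backward(2.0 * err / err.size, aux)
            opt.step(model.params(), grads)
            epoch_loss += loss * len(idx) / n
        model.train_log.append({"epoch": epoch, "loss": epoch_loss})
    return model


def imitation_loss(demos, model: PolicyModel) -> float:
    """Current MSE of the model on a demonstration set."""
    X = np.stack([model.featurize(o) for o in demos.observations])
    A = demos.actions_array()
    pred, _ = model.mean_forward(X)
    return float(((pred - A) ** 2).mean())


def clipped_surrogate(ratio: np.ndarray, adv: np.ndarray, clip_range: float):
    """PPO clipped surrogate min(r*A, clip(r, 1-eps, 1+eps)*A).

    Returns the per-sample surrogate and the mask where the unclipped branch
    is active (through which the policy gradient flows). The ratio's
    contribution is thereby bounded within [1-eps, 1+eps] whenever clipping
    engages.
    """
    clipped = np.clip(ratio, 1.0 - clip_range, 1.0 + clip_range)
    surrogate = np.minimum(ratio * adv, clipped * adv)
    active = np.where(
        adv >= 0, ratio <= 1.0 + clip_range, ratio >= 1.0 - clip_range
    )
    return surrogate, active


def _gae(rewards, values, gamma, lam):
    """Generalized advantage estimation for one terminated episode."""
    T = len(rewards)
    adv = np.zeros(T)
    last = 0.0
    for t in range(T - 1, -1, -1):
        next_v = values[t + 1] if t + 1 < T else 0.0
        delta = rewards[t] + gamma * next_v - values[t]
        last = delta + gamma * lam * last
        adv[t] = last
    return adv


def ppo_train(
    env: BiopsyEnv,
    model: PolicyModel,
    cfg: PPOConfig,
    train_cases: list[PatientCase],
    val_cases: list[PatientCase],
):
    """PPO with clipped surrogate, value loss (weight c1) and entropy bonus
    (weight c2).

    Each episode interacts with a freshly sampled training case. Every
    ``validation_interval`` episodes the deterministic policy is evaluated on
    the validation cases and a parameter snapshot is kept whenever the mean
    validation episode reward improves on the best seen. Returns
    ``(model, log)`` where ``log`` is a DataFrame of episode, mean training
    reward and validation reward; the model is left at the best checkpoint.
    A non-finite loss aborts training and restores the last good checkpoint.
    """
    if not train_cases or not val_cases:
        raise ValueError("train and validation case lists must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.learning_rate)
    env.max_steps = cfg.max_steps

    log_rows: list[dict] = []
    best_val = -np.inf
    best_snap = model.snapshot()
    checkpoints: list[tuple[int, float]] = []
    recent_rewards: list[float] = []

    buf_X, buf_a, buf_logp, buf_adv, buf_ret = [], [], [], [], []
    episode = 0
    while episode < cfg.episodes:
        case = train_cases[rng.integers(len(train_cases))]
        obs = env.reset(case, seed=int(rng.integers(2**31 - 1)))
        xs, acts, logps, vals, rews = [], [], [], [], []
        done = False
        while not done:
            a, logp, v, x = model.sample(obs, rng)
            obs, r, done, _ = env.step(Action(*a))
            xs.append(x)
            acts.append(a)
            logps.append(logp)
            vals.append(v)
            rews.append(float(r))
        episode += 1
        recent_rewards.append(sum(rews))
        adv = _gae(np.array(rews), np.array(vals), cfg.discount, cfg.gae_lambda)
        buf_X.extend(xs)
        buf_a.extend(acts)
        buf_logp.extend(logps)
        buf_adv.extend(adv.tolist())
        buf_ret.extend((adv + np.array(vals)).tolist())

        if episode % cfg.batch_episodes == 0:
            ok = _ppo_update(model, opt, cfg, buf_X, buf_a, buf_logp, buf_adv, buf_ret, rng)
            buf_X, buf_a, buf_logp, buf_adv, buf_ret = [], [], [], [], []
            if not ok:
                model.load_snapshot(best_snap)
                break

        if episode % cfg.validation_interval == 0:
            val_reward = _mean_episode_reward(model, env, val_cases, seed=cfg.seed)
            train_reward = float(np.mean(recent_rewards))
            recent_rewards = []
            if val_reward > best_val:
                best_val = val_reward
                best_snap = model.snapshot()
                checkpoints.append((episode, val_reward))
            log_rows.append(
                {
                    "episode": episode,
                    "train_reward": train_reward,
                    "val_reward": val_reward,
                    "best_val": best_val,
                    "entropy": model.entropy(),
                }
            )

    model.load_snapshot(best_snap)
    log = pd.DataFrame(log_rows)
    log.attrs["checkpoints"] = checkpoints
    return model, log


def _ppo_update(model, opt, cfg, X, a, logp_old, adv, ret, rng) -> bool:
    X = np.stack(X)
    a = np.stack(a)
    logp_old = np.asarray(logp_old)
    adv = np.asarray(adv)
    ret = np.asarray(ret)
    if adv.std() > 0:
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)
    n = len(X)
    for _ in range(cfg.update_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.minibatch_size):
            idx = order[lo : lo + cfg.minibatch_size]
            xb, ab = X[idx], a[idx]
            advb, retb, lpo = adv[idx], ret[idx], logp_old[idx]

            mean, aux = model.mean_forward(xb)
            logp = model.log_prob(ab, mean)
            ratio = np.exp(np.clip(logp - lpo, -20, 20))
            surrogate, active = clipped_surrogate(ratio, advb, cfg.clip_range)
            v, vcache = model.value_forward(xb)
            v_err = v - retb
            loss = (
                -surrogate.mean()
                + cfg.c1 * 0.5 * (v_err**2).mean()
                - cfg.c2 * model.entropy()
            )
            if not np.isfinite(loss):
                return False

            m = len(idx)
            # d(-surrogate)/d logp: nonzero where the unclipped branch is taken
            dlogp = -(advb * ratio * active) / m
            std = np.exp(model.log_std)
            dmean = dlogp[:, None] * (ab - mean) / std**2
            grads = model.mean_backward(dmean, aux)
            # log-std: surrogate term + entropy bonus (dH/dlog_std = 1)
            z2 = ((ab - mean) / std) ** 2
            g_logstd = (dlogp[:, None] * (z2 - 1.0)).sum(axis=0) - cfg.c2
            grads["log_std"] = g_logstd
            grads.update(model.value_backward(cfg.c1 * v_err / m, vcache))
            opt.step(model.params(), grads)
    return True


def _mean_episode_reward(policy, env: BiopsyEnv, cases, seed: int = 0) -> float:
    totals = []
    for k, case in enumerate(cases):
        res = run_episode(policy, case, env=env, seed=seed * 100003 + k)
        totals.append(res.total_reward)
    return float(np.mean(totals))


def evaluate_policy(
    policy,
    cases: list[PatientCase],
    tre: TREConfig | None = None,
    deform: DeformationConfig | None = None,
    episodes_per_case: int = 1,
    seed: int = 0,
    label: str = "",
    **env_kwargs,
) -> MetricsReport:
    """Run episodes over a case list and aggregate outcome metrics.

    ``policy`` is any callable Observation -> Action (trained model, expert
    agent, or baseline). Deterministic policies with the same seed produce
    identical reports.
    """
    if not cases:
        raise ValueError("empty case list")
    env = BiopsyEnv(tre=tre, deform=deform, **env_kwargs)
    label_key = zlib.crc32(label.encode()) % (2**31)
    ss = np.random.SeedSequence([label_key, seed])
    child = ss.generate_state(len(cases) * episodes_per_case)
    results = []
    k = 0
    for case in cases:
        for _ in range(episodes_per_case):
            results.append(
                run_episode(policy, case, env=env, seed=int(child[k] % (2**31)))
            )
            k += 1
    return build_report(results, cases, label=label)
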