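"""Self-supervised training and per-pair instance optimization.

Two ways to use the registration model:

* ``train`` — fit the three sub-networks on a population of volumes by
  drawing random ordered pairs (every image serves as fixed and as moving,
  self-pairs included) and minimizing the multi-resolution bidirectional
  objective with Adam, batch size 1.
* ``register_pair`` — either a single feedforward pass of a trained model,
  or *instance optimization*: fresh network parameters fitted to one pair
  only, which is conventional iterative registration with a
  network-parameterized transform.

The paper-scale profile (176x192x176 volumes, 150k iterations) and the desk
profile (32-64^3 phantoms, hundreds of iterations) share every default other
than iteration count and input size.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from . import core, losses, network
from .core import (Volume, LabelMap, VelocityField, DisplacementField,
                   DEFAULT_SIGMA, DEFAULT_KSIZE, DEFAULT_STEPS)
from .losses import LossConfig, LossBreakdown, multires_loss
from .network import Subnetwork, build_subnetwork

__all__ = ["TrainConfig", "RegistrationResult", "Adam", "sample_pairs",
           "train", "register_pair", "sweep_lambda", "accumulated_velocity",
           "save_checkpoint", "load_checkpoint"]


def accumulated_velocity(per_level_svfs: list) -> VelocityField:
    """Sum the incremental velocities onto the finest level's grid."""
    vt = Tensor(per_level_svfs[0].data)
    for v in per_level_svfs[1:]:
        vt = core.upsample_t(vt, v.data.shape[1:]) + Tensor(v.data)
    return VelocityField(vt.data, level=len(per_level_svfs))


@dataclass
class TrainConfig:
    """Hyper-parameters of training / instance optimization."""

    lam: float = 0.35
    learning_rate: float = 1e-4
    batch_size: int = 1
    iterations: int = 150_000
    seed: int = 0
    levels: int = 3
    sigma: float = DEFAULT_SIGMA
    ksize: int = DEFAULT_KSIZE
    steps: int = DEFAULT_STEPS
    ncc_window: int | str = 9
    smooth_final: bool = True
    full_res_term: bool = True
    log_path: str | None = None
    checkpoint_path: str | None = None

    def __post_init__(self):
        # 0 is allowed for feedforward-only use of fresh parameters
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def loss_config(self) -> LossConfig:
        return LossConfig(lam=self.lam, ncc_window=self.ncc_window,
                          levels=self.levels, steps=self.steps,
                          sigma=self.sigma, ksize=self.ksize,
                          smooth_final=self.smooth_final,
                          full_res_term=self.full_res_term)

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset: 32-64^3 phantoms, hundreds of iterations.

        The learning rate is raised to 3e-3 so instance optimization
        converges within hundreds rather than tens of thousands of steps;
        everything else matches the full-scale profile.
        """
        kwargs = dict(iterations=300, learning_rate=3e-3)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class RegistrationResult:
    """Forward/inverse fields, per-level velocities, warped images, loss trace."""

    forward_field: DisplacementField
    inverse_field: DisplacementField
    per_level_svfs: list
    warped_moving: Volume
    warped_fixed: Volume
    loss_trace: list


class Adam:
    """Adam optimizer over autodiff tensors (beta 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = (p.data - self.lr * (m / bc1)
                      / (np.sqrt(v / bc2) + self.eps)).astype(np.float32)


def sample_pairs(dataset: list, seed: int | None = None):
    """Infinite stream of uniform ordered (fixed, moving) id pairs.

    Draws uniformly over all n^2 ordered pairs, self-pairs included, so every
    image serves as a fixed image. Reproducible under ``seed``.
    """
    ids = list(dataset)
    if not ids:
        raise ValueError("dataset must contain at least one id")
    rng = np.random.default_rng(seed)
    n = len(ids)

    def _stream():
        while True:
            i = int(rng.integers(n))
            j = int(rng.integers(n))
            yield ids[i], ids[j]

    return _stream()


# ---------------------------------------------------------------------------
# Pair preparation
# ---------------------------------------------------------------------------

class _Prepared:
    """Normalized, padded volume with its similarity pyramid."""

    def __init__(self, vol: Volume, levels: int):
        data = network.normalize_volume(vol.data)
        padded, self.crops = network.pad_to_divisible(data, 16)
        self.shape = vol.shape
        self.padded_shape = padded.shape
        self.pyramid = [v.data for v in
                        core.build_pyramid(Volume(padded), levels + 1)]
        self.full = padded


def _loss_for_pair(nets: list[Subnetwork], pf: _Prepared, pm: _Prepared,
                   cfg: LossConfig):
    state = network.forward_multires(
        pf.full, pm.full, nets, steps=cfg.steps, sigma=cfg.sigma,
        ksize=cfg.ksize, smooth_final=cfg.smooth_final, final_fields=False)
    return multires_loss(pf.pyramid, pm.pyramid, state.svfs, cfg)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(volumes: dict | list, cfg: TrainConfig, pairs=None):
    """Train the three sub-networks on a set of same-shaped volumes.

    ``volumes`` maps ids to :class:`Volume` (a list is keyed by index);
    ``pairs`` is an id-pair stream (defaults to :func:`sample_pairs` over all
    ids with ``cfg.seed``). Returns ``(nets, loss_log)`` and optionally
    writes a per-iteration CSV log and a final checkpoint.
    """
    if not isinstance(volumes, dict):
        volumes = {i: v for i, v in enumerate(volumes)}
    if not volumes:
        raise ValueError("no volumes given")
    shapes = {v.shape for v in volumes.values()}
    if len(shapes) != 1:
        raise ValueError(f"all volumes must share one shape, got {shapes}")
    if pairs is None:
        pairs = sample_pairs(sorted(volumes), seed=cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    nets = [build_subnetwork(l + 1, rng) for l in range(cfg.levels)]
    lcfg = cfg.loss_config()
    prepared = {k: _Prepared(v, cfg.levels) for k, v in volumes.items()}

    opt = Adam([p for net in nets for p in net.parameters()],
               lr=cfg.learning_rate)
    log: list[LossBreakdown] = []
    for it in range(cfg.iterations):
        fid, mid = next(pairs)
        opt.zero_grad()
        loss, bd = _loss_for_pair(nets, prepared[fid], prepared[mid], lcfg)
        if not np.isfinite(bd.total):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: {bd.as_row()}")
        loss.backward()
        opt.step()
        log.append(bd)

    if cfg.log_path:
        _write_loss_csv(cfg.log_path, log)
    if cfg.checkpoint_path:
        save_checkpoint(cfg.checkpoint_path, nets, cfg)
    return nets, log


def _write_loss_csv(path, log: list[LossBreakdown]) -> None:
    rows = [bd.as_row() for bd in log]
    keys = ["iteration"] + list(rows[0].keys()) if rows else ["iteration"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=keys)
        w.writeheader()
        for i, row in enumerate(rows):
            w.writerow({"iteration": i, **row})


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_pair(fixed: Volume, moving: Volume, weights="instance",
                  cfg: TrainConfig | None = None) -> RegistrationResult:
    """Register ``moving`` to ``fixed``.

    ``weights`` is a list of trained sub-networks, a checkpoint path, or
    ``"instance"`` to optimize fresh parameters on this pair alone for
    ``cfg.iterations`` (conventional pairwise registration).
    """
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    cfg = cfg or TrainConfig.desk()
    lcfg = cfg.loss_config()
    pf = _Prepared(fixed, cfg.levels)
    pm = _Prepared(moving, cfg.levels)

    log: list[LossBreakdown] = []
    if isinstance(weights, str) and weights == "instance":
        rng = np.random.default_rng(cfg.seed)
        nets = [build_subnetwork(l, rng) for l in (1, 2, 3)]
        opt = Adam([p for net in nets for p in net.parameters()],
                   lr=cfg.learning_rate)
        for it in range(cfg.iterations):
            opt.zero_grad()
            loss, bd = _loss_for_pair(nets, pf, pm, lcfg)
            if not np.isfinite(bd.total):
                raise RuntimeError(
                    f"non-finite loss at iteration {it}: {bd.as_row()}")
            loss.backward()
            opt.step()
            log.append(bd)
    elif isinstance(weights, (str, Path)):
        nets, _ = load_checkpoint(weights)
    else:
        nets = list(weights)

    state = network.forward_multires(
        pf.full, pm.full, nets, steps=cfg.steps, sigma=cfg.sigma,
        ksize=cfg.ksize, smooth_final=cfg.smooth_final)
    crops = pf.crops
    u_fwd = DisplacementField(network.crop_field(state.forward_field.data, crops))
    u_inv = DisplacementField(network.crop_field(state.inverse_field.data, crops))
    svfs = [VelocityField(v.data, level=l + 1)
            for l, v in enumerate(state.svfs)]
    return RegistrationResult(
        forward_field=u_fwd,
        inverse_field=u_inv,
        per_level_svfs=svfs,
        warped_moving=core.warp_volume(moving, u_fwd),
        warped_fixed=core.warp_volume(fixed, u_inv),
        loss_trace=log,
    )


def sweep_lambda(fixed: Volume, moving: Volume, labels_fixed: LabelMap,
                 labels_moving: LabelMap, values, cfg: TrainConfig | None = None
                 ) -> list[dict]:
    """Instance-optimize one pair per regularization weight.

    Reports mean Dice of the propagated labels and folding statistics for
    each lambda, mirroring validation-style hyper-parameter selection.
    """
    from . import evaluation

    cfg = cfg or TrainConfig.desk()
    rows = []
    for lam in values:
        run_cfg = TrainConfig(**{**asdict(cfg), "lam": float(lam)})
        res = register_pair(fixed, moving, "instance", run_cfg)
        rep = evaluation.evaluate_direction(
            res, labels_fixed, labels_moving, "forward",
            mask=evaluation.brain_mask(fixed))
        tv_final = losses.tv_regularizer(
            VelocityField(res.per_level_svfs[-1].data))
        rows.append({"lambda": float(lam), "mean_dice": rep.mean_dice,
                     "folding_count": rep.folding_count,
                     "folding_percent": rep.folding_percent,
                     "tv_finest": tv_final})
    return rows


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, nets: list[Subnetwork], cfg: TrainConfig) -> None:
    """Single archive holding all sub-network parameters plus the config."""
    import json

    arrays = {}
    for net in nets:
        for k, arr in net.state_arrays().items():
            arrays[f"net{net.level}/{k}"] = arr
    meta = {k: v for k, v in asdict(cfg).items()
            if isinstance(v, (int, float, str, bool, type(None)))}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        cfg = TrainConfig(**meta)
        nets = []
        levels = sorted({int(k.split("/")[0][3:]) for k in data.files
                         if k.startswith("net")})
        for level in levels:
            net = build_subnetwork(level, rng=0)
            state = {k.split("/", 1)[1]: data[k] for k in data.files
                     if k.startswith(f"net{level}/")}
            net.load_state_arrays(state)
            nets.append(net)
    return nets, cfg
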