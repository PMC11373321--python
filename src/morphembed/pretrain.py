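"""Teacher-student self-distillation pre-training on neuron morphology.

One augmented view of each neuron is encoded by the teacher; the same view,
additionally masked (node features replaced by a learned mask vector) or
cropped (subgraph sampling), is encoded by the student.  The student is
trained by gradient descent on

    w_c * consistency + w_r * reconstruction + w_k * koleo

where the consistency term is the cross-entropy between the centered,
temperature-sharpened teacher projection and the student projection; the
reconstruction term is the MSE of a node-level head predicting the original
features at masked positions; and the KoLeo term is the
Kozachenko-Leonenko differential-entropy regularizer that spreads the batch
of embeddings apart.  The teacher never receives gradients: it is an
exponential moving average of the student, with a running center of its
projections subtracted before sharpening to prevent collapse.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, as_tensor, gelu, log_softmax, softmax, wrap_params
from .augment import AugmentationConfig, augment, sample_subgraph
from .encoder import EncoderConfig, EncoderParams, EncoderCheckpoint, \
    forward, init_params
from .preprocess import FEATURE_DIM, FeatureGraph, center_tree, featurize
from .swc import NeuronTree


@dataclass
class PretrainConfig:
    steps: int = 300
    batch_size: int = 8
    ema_momentum: float = 0.996
    teacher_temperature: float = 0.04
    student_temperature: float = 0.1
    center_momentum: float = 0.9
    mask_fraction: float = 0.3
    crop_fraction: float = 0.6
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 0.1)
    projection_dim: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ema_momentum < 1.0:
            raise ValueError("ema_momentum must be in (0, 1)")
        if not 0.0 < self.center_momentum < 1.0:
            raise ValueError("center_momentum must be in (0, 1)")
        if self.teacher_temperature <= 0 or self.student_temperature <= 0:
            raise ValueError("temperatures must be positive")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be >= 0")


@dataclass
class PretrainState:
    """Student and teacher parameters plus the centering statistics."""

    student: dict[str, np.ndarray]   # encoder + proj head + recon head + mask
    teacher: dict[str, np.ndarray]   # encoder + proj head
    center: np.ndarray               # (projection_dim,)
    step: int
    enc_config: EncoderConfig
    config: PretrainConfig

    def encoder_checkpoint(self, which: str = "teacher") -> EncoderCheckpoint:
        source = self.teacher if which == "teacher" else self.student
        params = {k: v.copy() for k, v in source.items()
                  if not k.startswith(("proj.", "recon."))
                  and k != "mask_vector"}
        return EncoderCheckpoint(params=params, config=self.enc_config)


@dataclass
class StepRecord:
    step: int
    total: float
    consistency: float
    reconstruction: float
    koleo: float


# -- view construction -----------------------------------------------------

def make_views(tree: NeuronTree, aug: AugmentationConfig, cfg: PretrainConfig,
               seed: int) -> tuple[FeatureGraph, FeatureGraph, np.ndarray]:
    """One augmented teacher view and a masked-or-cropped student view.

    Both views derive from the same augmented tree.  With probability 1/2
    the student view is the teacher view with ceil(mask_fraction * n)
    non-root node features marked for replacement by the learned mask
    vector (the returned boolean mask); otherwise it is a subgraph crop at
    ``crop_fraction`` with an empty mask.
    """
    ss = np.random.SeedSequence(seed)
    s_aug, s_choice = (int(s.generate_state(1)[0]) for s in ss.spawn(2))
    rng = np.random.default_rng(s_choice)
    base = center_tree(augment(center_tree(tree),
                               AugmentationConfig(
                                   shift_sigma=aug.shift_sigma,
                                   rotate=aug.rotate,
                                   branch_delete_prob=aug.branch_delete_prob,
                                   subgraph_fraction=aug.subgraph_fraction,
                                   seed=s_aug)))
    teacher_view = featurize(base)
    n = teacher_view.n
    if rng.random() < 0.5 or n < 2:
        n_mask = min(int(np.ceil(cfg.mask_fraction * n)), n - 1)
        mask = np.zeros(n, dtype=bool)
        if n_mask > 0:
            rows = rng.choice(np.arange(1, n), size=n_mask, replace=False)
            mask[rows] = True
        return teacher_view, teacher_view, mask
    cropped = sample_subgraph(base, cfg.crop_fraction,
                              int(rng.integers(2 ** 31)))
    return teacher_view, featurize(cropped), np.zeros(len(cropped), dtype=bool)


# -- losses ----------------------------------------------------------------

def consistency_loss(teacher_proj, student_proj, cfg: PretrainConfig,
                     center: np.ndarray) -> Tensor:
    """Cross-entropy of student log-softmax against the centered, sharpened
    teacher distribution (gradient-detached), averaged over the batch."""
    t = np.asarray(teacher_proj.data if isinstance(teacher_proj, Tensor)
                   else teacher_proj, dtype=np.float64)
    logits = (t - center) / cfg.teacher_temperature
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    targets = e / e.sum(axis=-1, keepdims=True)
    sp = as_tensor(student_proj) * (1.0 / cfg.student_temperature)
    return -(Tensor(targets) * log_softmax(sp, axis=-1)).sum(axis=-1).mean()


def reconstruction_loss(predicted, target) -> Tensor:
    """Mean squared error at masked positions; zero for an empty mask."""
    pred = as_tensor(predicted)
    tgt = np.asarray(target.data if isinstance(target, Tensor) else target,
                     dtype=np.float64)
    if tgt.size == 0:
        return Tensor(0.0)
    diff = pred - Tensor(tgt)
    return (diff * diff).mean()


def koleo_loss(embeddings, eps: float = 1e-12) -> Tensor:
    """Kozachenko-Leonenko regularizer: -mean log nearest-neighbor distance
    of the L2-normalized rows.  Spread-out embeddings give a lower loss."""
    x = as_tensor(embeddings)
    b = x.shape[0]
    if b < 2:
        raise ValueError("koleo_loss needs a batch of at least 2")
    norm = ((x * x).sum(axis=-1, keepdims=True) + eps).sqrt()
    u = x / norm
    sq = (u * u).sum(axis=-1)
    d2 = sq.reshape(b, 1) + sq.reshape(1, b) - 2.0 * (u @ u.transpose(1, 0))
    d2 = d2 + Tensor(np.eye(b) * 1e6)        # exclude self-distance
    nearest = (d2.min(axis=-1) + eps).sqrt()
    return -(nearest + eps).log().mean()


def ema_update(teacher: dict[str, np.ndarray], student, m: float
               ) -> dict[str, np.ndarray]:
    """teacher <- m * teacher + (1 - m) * student, tensor by tensor."""
    out: dict[str, np.ndarray] = {}
    for k, t in teacher.items():
        s = student[k]
        s = s.data if isinstance(s, Tensor) else s
        if t.shape != s.shape:
            raise ValueError(f"shape mismatch for {k}")
        out[k] = m * t + (1.0 - m) * s
    return out


# -- heads -----------------------------------------------------------------

def _init_heads(rng: np.random.Generator, d: int, k: int) -> dict[str, np.ndarray]:
    scale = 1.0 / np.sqrt(d)
    return {
        "proj.w0": rng.normal(0.0, scale, size=(d, d)),
        "proj.b0": np.zeros(d),
        "proj.w1": rng.normal(0.0, scale, size=(d, k)),
        "proj.b1": np.zeros(k),
        "recon.w0": rng.normal(0.0, scale, size=(d, d)),
        "recon.b0": np.zeros(d),
        "recon.w1": rng.normal(0.0, scale, size=(d, FEATURE_DIM)),
        "recon.b1": np.zeros(FEATURE_DIM),
        "mask_vector": np.zeros(FEATURE_DIM),
    }


def _project(cls: Tensor, p: dict[str, Tensor]) -> Tensor:
    h = gelu(cls.reshape(1, -1) @ p["proj.w0"] + p["proj.b0"])
    return (h @ p["proj.w1"] + p["proj.b1"]).reshape(-1)


def _reconstruct(nodes: Tensor, p: dict[str, Tensor]) -> Tensor:
    h = gelu(nodes @ p["recon.w0"] + p["recon.b0"])
    return h @ p["recon.w1"] + p["recon.b1"]


_TEACHER_KEYS_EXCLUDED = ("recon.", )


def _teacher_subset(student: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in student.items()
            if not k.startswith(_TEACHER_KEYS_EXCLUDED) and k != "mask_vector"}


# -- training loop ---------------------------------------------------------

def pretrain(dataset: list[NeuronTree], cfg: PretrainConfig,
             enc_cfg: EncoderConfig, aug: AugmentationConfig,
             callback=None) -> tuple[PretrainState, list[StepRecord]]:
    """Run the self-distillation loop; deterministic under cfg.seed.

    ``callback(state)``, if given, is invoked after every optimizer step
    (used by tests to replay the EMA recursion).
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    w_c, w_r, w_k = cfg.loss_weights

    student_np = init_params(enc_cfg)
    student_np.update(_init_heads(np.random.default_rng(cfg.seed + 1),
                                  enc_cfg.d_model, cfg.projection_dim))
    student = wrap_params(student_np, requires_grad=True)
    teacher = _teacher_subset(student_np)
    center = np.zeros(cfg.projection_dim)
    optimizer = Adam(student, lr=cfg.learning_rate)

    log: list[StepRecord] = []
    for step in range(1, cfg.steps + 1):
        idx = rng.choice(len(dataset), size=cfg.batch_size,
                         replace=len(dataset) < cfg.batch_size)
        view_seeds = rng.integers(2 ** 31, size=cfg.batch_size)

        teacher_t = wrap_params(teacher, requires_grad=False)
        t_projs = []
        s_projs = []
        s_cls = []
        rec_pred = []
        rec_target = []
        for i, vs in zip(idx, view_seeds):
            t_view, s_view, mask = make_views(dataset[int(i)], aug, cfg,
                                              int(vs))
            t_cls, _ = forward(t_view, teacher_t, enc_cfg)
            t_projs.append(_project(t_cls, teacher_t).data)
            cls, nodes = forward(s_view, student, enc_cfg, mask=mask,
                                 mask_vector=student["mask_vector"])
            s_cls.append(cls.reshape(1, -1))
            s_projs.append(_project(cls, student).reshape(1, -1))
            if mask.any():
                # reconstruct per-view standardized features so the MSE is
                # O(1) regardless of the neuron's physical size
                mu = s_view.features.mean(axis=0)
                sd = np.maximum(s_view.features.std(axis=0), 1e-6)
                rec_pred.append(_reconstruct(nodes, student)[mask])
                rec_target.append((s_view.features[mask] - mu) / sd)

        teacher_proj = np.vstack(t_projs)
        student_proj = Tensor.cat(s_projs, axis=0)
        loss_c = consistency_loss(teacher_proj, student_proj, cfg, center)
        if rec_pred:
            loss_r = reconstruction_loss(Tensor.cat(rec_pred, axis=0),
                                         np.vstack(rec_target))
        else:
            loss_r = Tensor(0.0)
        loss_k = koleo_loss(Tensor.cat(s_cls, axis=0))
        total = w_c * loss_c + w_r * loss_r + w_k * loss_k

        parts = {"consistency": float(loss_c), "reconstruction": float(loss_r),
                 "koleo": float(loss_k)}
        for name, value in parts.items():
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite {name} loss at step {step}")

        optimizer.zero_grad()
        total.backward()
        optimizer.step()
        teacher = ema_update(teacher, student, cfg.ema_momentum)
        center = (cfg.center_momentum * center
                  + (1.0 - cfg.center_momentum) * teacher_proj.mean(axis=0))

        log.append(StepRecord(step, float(total), parts["consistency"],
                              parts["reconstruction"], parts["koleo"]))
        if callback is not None:
            # snapshot copies: the optimizer updates student arrays in place
            callback(PretrainState(
                student={k: t.data.copy() for k, t in student.items()},
                teacher={k: v.copy() for k, v in teacher.items()},
                center=center.copy(), step=step,
                enc_config=enc_cfg, config=cfg))
    state = PretrainState(student={k: t.data for k, t in student.items()},
                          teacher=teacher, center=center, step=cfg.steps,
                          enc_config=enc_cfg, config=cfg)
    return state, log
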