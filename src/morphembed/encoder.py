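"""Graph-transformer encoder with adjacency-gated attention and Laplacian PE.

The backbone embeds per-node features with a two-layer MLP, adds a linear
projection of Laplacian positional encodings, prepends a learnable [CLS]
token, and applies pre-norm transformer layers whose attention mixes
content similarity with graph structure:

    Attention(Q, K, V, A) = softmax(lambda * QK^T / sqrt(d_k) + gamma * A) V

where (lambda, gamma) = exp(W2 x) are positive per-token scalars predicted
from each query token, interpolating between vanilla dot-product attention
and adjacency-driven message passing.  The final-layer [CLS] row is the
graph-level representation.  Optional bottleneck adapters (zero-initialized
up-projection, so inserting them is an identity) sit beside each sublayer
for parameter-efficient fine-tuning.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from ._autodiff import Tensor, gelu, layer_norm, softmax, wrap_params
from .preprocess import FEATURE_DIM, FeatureGraph

EncoderParams = dict[str, np.ndarray]


@dataclass
class EncoderConfig:
    """Architecture hyperparameters; d_model must equal n_heads * d_k."""

    n_layers: int = 4
    d_model: int = 128
    n_heads: int = 4
    d_k: int = 32
    n_eigvecs: int = 16
    mlp_hidden: int = 256
    adapter_dim: int = 0
    coord_scale: float = 100.0   # µm; divides x,y,z so coords are O(1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model != self.n_heads * self.d_k:
            raise ValueError("d_model must equal n_heads * d_k")


# -- positional encoding ---------------------------------------------------

def laplacian_pe(adjacency: np.ndarray, k: int,
                 return_eigenvalues: bool = False):
    """Eigenvectors of the normalized graph Laplacian as positional encodings.

    L = I - D^{-1/2} A D^{-1/2}.  Returns the eigenvectors of the k smallest
    eigenvalues (ascending), each column's sign fixed so its
    largest-magnitude entry is positive (deterministic and, for graphs
    without eigenvalue degeneracy, independent of node order).  If k exceeds
    n the table is padded with zero columns.
    """
    A = np.asarray(adjacency, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    deg = A.sum(axis=1)
    inv_sqrt = np.zeros(n)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    L = np.eye(n) - (inv_sqrt[:, None] * A) * inv_sqrt[None, :]
    L = 0.5 * (L + L.T)
    m = min(k, n)
    if n <= 128 or m == n:
        vals, vecs = scipy.linalg.eigh(L)
        vals, vecs = vals[:m], vecs[:, :m]
    else:
        vals, vecs = scipy.linalg.eigh(L, subset_by_index=(0, m - 1))
    for j in range(m):
        v = vecs[:, j]
        # permutation-invariant sign: sign of sum of cubes when it is
        # decisively nonzero, else make the largest-magnitude entry positive
        s = float(np.sum(v ** 3))
        if abs(s) > 1e-9 * float(np.sum(v ** 2)) ** 1.5:
            flip = s < 0
        else:
            flip = v[np.argmax(np.abs(v))] < 0
        if flip:
            vecs[:, j] = -v
    if k > n:
        vecs = np.pad(vecs, ((0, 0), (0, k - n)))
        vals = np.pad(vals, (0, k - n))
    if return_eigenvalues:
        return vecs, vals
    return vecs


# -- parameters ------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = math.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def init_params(config: EncoderConfig) -> EncoderParams:
    """Seeded initialization.  The gate projection W2 starts at zero so
    lambda = gamma = 1 (balanced attention); adapter up-projections start at
    zero so a freshly inserted adapter is an exact identity."""
    rng = np.random.default_rng(config.seed)
    d, h = config.d_model, config.mlp_hidden
    p: EncoderParams = {
        "embed.w0": _glorot(rng, FEATURE_DIM, h),
        "embed.b0": np.zeros(h),
        "embed.w1": _glorot(rng, h, d),
        "embed.b1": np.zeros(d),
        "pe.w": _glorot(rng, config.n_eigvecs, d),
        "pe.b": np.zeros(d),
        "cls.token": rng.normal(0.0, 0.02, size=d),
        "cls.pos": rng.normal(0.0, 0.02, size=d),
    }
    for i in range(config.n_layers):
        L = f"layer{i}"
        p[f"{L}.ln1.g"] = np.ones(d)
        p[f"{L}.ln1.b"] = np.zeros(d)
        p[f"{L}.attn.w_qkv"] = _glorot(rng, d, 3 * d)
        p[f"{L}.attn.b_qkv"] = np.zeros(3 * d)
        p[f"{L}.attn.w_gate"] = np.zeros((d, 2))
        p[f"{L}.attn.b_gate"] = np.zeros(2)
        p[f"{L}.attn.w_out"] = _glorot(rng, d, d)
        p[f"{L}.attn.b_out"] = np.zeros(d)
        p[f"{L}.ln2.g"] = np.ones(d)
        p[f"{L}.ln2.b"] = np.zeros(d)
        p[f"{L}.ff.w0"] = _glorot(rng, d, h)
        p[f"{L}.ff.b0"] = np.zeros(h)
        p[f"{L}.ff.w1"] = _glorot(rng, h, d)
        p[f"{L}.ff.b1"] = np.zeros(d)
        if config.adapter_dim > 0:
            p.update(_adapter_block(rng, L, d, config.adapter_dim))
    return p


def _adapter_block(rng: np.random.Generator, layer: str, d: int,
                   a: int) -> EncoderParams:
    out: EncoderParams = {}
    for slot in ("ad_attn", "ad_ff"):
        out[f"{layer}.{slot}.w_down"] = _glorot(rng, d, a)
        out[f"{layer}.{slot}.b_down"] = np.zeros(a)
        out[f"{layer}.{slot}.w_up"] = np.zeros((a, d))
        out[f"{layer}.{slot}.b_up"] = np.zeros(d)
    return out


def add_adapters(params: EncoderParams, config: EncoderConfig,
                 adapter_dim: int) -> tuple[EncoderParams, EncoderConfig]:
    """Insert zero-initialized adapters into an adapter-free checkpoint.

    The returned parameters compute exactly the same function as the input.
    """
    if adapter_dim <= 0:
        raise ValueError("adapter_dim must be positive")
    cfg = EncoderConfig(**{**asdict(config), "adapter_dim": adapter_dim})
    rng = np.random.default_rng(config.seed + 1)
    out = dict(params)
    for i in range(config.n_layers):
        out.update(_adapter_block(rng, f"layer{i}", config.d_model, adapter_dim))
    return out, cfg


def is_adapter_param(name: str) -> bool:
    return ".ad_attn." in name or ".ad_ff." in name


# -- forward ---------------------------------------------------------------

def _adapter(x: Tensor, p: dict[str, Tensor], prefix: str) -> Tensor:
    down = gelu(x @ p[f"{prefix}.w_down"] + p[f"{prefix}.b_down"])
    return down @ p[f"{prefix}.w_up"] + p[f"{prefix}.b_up"]


def _graph_attention_t(x: Tensor, adjacency: np.ndarray,
                       p: dict[str, Tensor], layer: str,
                       config: EncoderConfig,
                       want_weights: bool = False):
    n = x.shape[0]
    h, dk, d = config.n_heads, config.d_k, config.d_model
    qkv = x @ p[f"{layer}.attn.w_qkv"] + p[f"{layer}.attn.b_qkv"]
    qkv = qkv.reshape(n, 3, h, dk).transpose(1, 2, 0, 3)  # (3, h, n, dk)
    q, k, v = qkv[0], qkv[1], qkv[2]
    gates = (x @ p[f"{layer}.attn.w_gate"] + p[f"{layer}.attn.b_gate"]).exp()
    lam = gates[:, 0].reshape(1, n, 1)
    gam = gates[:, 1].reshape(1, n, 1)
    scores = lam * (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(dk)) \
        + gam * Tensor(adjacency).reshape(1, n, n)
    weights = softmax(scores, axis=-1)           # (h, n, n), rows sum to 1
    out = (weights @ v).transpose(1, 0, 2).reshape(n, d)
    out = out @ p[f"{layer}.attn.w_out"] + p[f"{layer}.attn.b_out"]
    if want_weights:
        return out, weights
    return out


def graph_attention(x: np.ndarray, adjacency: np.ndarray,
                    params: EncoderParams | dict[str, Tensor],
                    config: EncoderConfig, layer: int = 0,
                    return_weights: bool = False):
    """One adjacency-gated attention sublayer on a token table (numpy in/out).

    ``adjacency`` must already include the [CLS] convention if a CLS row is
    present (weight 1 to itself, 0 elsewhere).  With ``return_weights`` the
    per-head attention matrices (rows are probability vectors) are returned
    alongside the output.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != adjacency.shape[0]:
        raise ValueError("token count and adjacency size disagree")
    if x.shape[1] != config.d_model:
        raise ValueError("token width and d_model disagree")
    pt = {k: (v if isinstance(v, Tensor) else Tensor(v))
          for k, v in params.items()}
    result = _graph_attention_t(Tensor(x), np.asarray(adjacency, float),
                                pt, f"layer{layer}", config,
                                want_weights=return_weights)
    if return_weights:
        out, weights = result
        return out.data, weights.data
    return result.data


def cls_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Extend a node adjacency with the CLS row/column (self-weight 1)."""
    n = adjacency.shape[0]
    ext = np.zeros((n + 1, n + 1))
    ext[0, 0] = 1.0
    ext[1:, 1:] = adjacency
    return ext


def forward(graph: FeatureGraph, params: dict[str, Tensor],
            config: EncoderConfig,
            mask: np.ndarray | None = None,
            mask_vector: Tensor | None = None) -> tuple[Tensor, Tensor]:
    """Full encoder pass; differentiable in ``params`` (and ``mask_vector``).

    Returns (cls_embedding, node_embeddings).  ``mask`` marks node rows
    whose raw features are replaced by the learned mask vector before
    embedding (used by self-supervised pre-training).
    """
    scaled = graph.features.copy()
    scaled[:, :3] /= config.coord_scale
    feats = Tensor(scaled)
    if mask is not None and mask.any():
        if mask_vector is None:
            raise ValueError("mask given but no mask_vector")
        m = mask.astype(np.float64)[:, None]
        feats = feats * Tensor(1.0 - m) + mask_vector.reshape(1, -1) * Tensor(m)
    h = gelu(feats @ params["embed.w0"] + params["embed.b0"])
    h = h @ params["embed.w1"] + params["embed.b1"]
    pe = laplacian_pe(graph.adjacency, config.n_eigvecs)
    h = h + Tensor(pe) @ params["pe.w"] + params["pe.b"]
    cls_row = (params["cls.token"] + params["cls.pos"]).reshape(1, -1)
    h = Tensor.cat([cls_row, h], axis=0)
    adj = cls_adjacency(graph.adjacency)
    for i in range(config.n_layers):
        L = f"layer{i}"
        z = layer_norm(h, params[f"{L}.ln1.g"], params[f"{L}.ln1.b"])
        sub = _graph_attention_t(z, adj, params, L, config)
        if f"{L}.ad_attn.w_down" in params:
            sub = sub + _adapter(z, params, f"{L}.ad_attn")
        h = h + sub
        z = layer_norm(h, params[f"{L}.ln2.g"], params[f"{L}.ln2.b"])
        sub = gelu(z @ params[f"{L}.ff.w0"] + params[f"{L}.ff.b0"])
        sub = sub @ params[f"{L}.ff.w1"] + params[f"{L}.ff.b1"]
        if f"{L}.ad_ff.w_down" in params:
            sub = sub + _adapter(z, params, f"{L}.ad_ff")
        h = h + sub
    return h[0], h[1:]


def encode(graph: FeatureGraph, params: EncoderParams,
           config: EncoderConfig) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode encoding: (cls_embedding, node_embeddings) as arrays."""
    cls_t, nodes_t = forward(graph, wrap_params(params, requires_grad=False),
                             config)
    return cls_t.data, nodes_t.data


# -- checkpointing ---------------------------------------------------------

@dataclass
class EncoderCheckpoint:
    params: EncoderParams
    config: EncoderConfig


def save_checkpoint(ckpt: EncoderCheckpoint, path: str | Path) -> None:
    """Write params as an .npz archive with a JSON config sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **ckpt.params)
    path.with_suffix(".json").write_text(
        json.dumps(asdict(ckpt.config), indent=2) + "\n")


def load_checkpoint(path: str | Path) -> EncoderCheckpoint:
    path = Path(path)
    config = EncoderConfig(**json.loads(path.with_suffix(".json").read_text()))
    with np.load(path.with_suffix(".npz")) as archive:
        params = {k: archive[k] for k in archive.files}
    reference = init_params(config)
    extra = {k for k in params if k not in reference and k != "mask_vector"
             and not k.startswith(("proj.", "recon."))}
    for k, v in reference.items():
        if k not in params:
            raise ValueError(f"checkpoint missing parameter {k}")
        if params[k].shape != v.shape:
            raise ValueError(
                f"checkpoint parameter {k} has shape {params[k].shape}, "
                f"config implies {v.shape}")
    if extra:
        raise ValueError(f"checkpoint has unexpected parameters: {sorted(extra)}")
    return EncoderCheckpoint(params=params, config=config)
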