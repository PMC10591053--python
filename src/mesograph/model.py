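"""The dual-branch cell-graph network.

Architecture: a purely local embedding of each cell's feature vector,
``K - 1`` stacked EdgeConv layers aggregating over graph neighbourhoods,
jumping-knowledge concatenation of all layer representations, and two
sigmoid prediction branches (sarcomatoid and epithelioid).  Each branch's
logit is modulated by scalars ``alpha`` and ``beta`` produced by small
MLPs from the core-level feature mean, letting the network calibrate per
core.  The bag score is the mean of per-cell branch differences:

    z_v^(s) = sigmoid(alpha_s * f_s(JK_v) + beta_s)
    Z       = mean_v (z_v^(s) - z_v^(e))

so Z lies in (-1, 1): negative = epithelioid-like, positive =
sarcomatoid-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (Tensor, concat, gather, relu, segment_sum, sigmoid,
                       softplus)
from .graphs import CoreGraph

__all__ = ["ModelConfig", "MLPParams", "ModelParams", "ScoreSet",
           "local_embed", "edgeconv_layer", "branch_score", "forward",
           "forward_tensors", "mlp_apply", "init_params"]


@dataclass(frozen=True)
class ModelConfig:
    """Widths of every sub-network.

    ``n_layers`` EdgeConv-style layers each producing a representation of
    width ``layer_dim``; the first layer is the local transformation.
    """

    input_dim: int
    n_layers: int = 5
    layer_dim: int = 10
    branch_hidden: int = 16
    modulation_hidden: int = 16

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if min(self.input_dim, self.layer_dim, self.branch_hidden,
               self.modulation_hidden) < 1:
            raise ValueError("all widths must be >= 1")

    @property
    def jk_dim(self) -> int:
        """Width of the jumping-knowledge concatenation, sum of d_k."""
        return self.n_layers * self.layer_dim


@dataclass
class MLPParams:
    """One-hidden-layer perceptron: ReLU hidden, linear output."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]


def _init_mlp(rng: np.random.Generator, d_in: int, d_hidden: int,
              d_out: int, out_bias: float = 0.0) -> MLPParams:
    # He initialisation for the ReLU hidden layer; biases get a small
    # random offset so no unit starts exactly on the ReLU kink
    w1 = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_hidden))
    w2 = rng.normal(0.0, np.sqrt(2.0 / d_hidden), (d_hidden, d_out))
    return MLPParams(
        w1=Tensor(w1, requires_grad=True),
        b1=Tensor(rng.normal(0.0, 0.01, (1, d_hidden)),
                  requires_grad=True),
        w2=Tensor(w2, requires_grad=True),
        b2=Tensor(out_bias + rng.normal(0.0, 0.01, (1, d_out)),
                  requires_grad=True),
    )


def mlp_apply(params: MLPParams, x: Tensor) -> Tensor:
    return relu(x @ params.w1 + params.b1) @ params.w2 + params.b2


@dataclass
class ModelParams:
    """All trainable parameters plus the configuration they realise."""

    config: ModelConfig
    layers: list[MLPParams]
    branch_s: MLPParams
    branch_e: MLPParams
    alpha_s: MLPParams
    beta_s: MLPParams
    alpha_e: MLPParams
    beta_e: MLPParams
    feature_names: list[str] = field(default_factory=list)

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for mlp in (*self.layers, self.branch_s, self.branch_e,
                    self.alpha_s, self.beta_s, self.alpha_e, self.beta_e):
            out.extend(mlp.tensors())
        return out


def init_params(config: ModelConfig, seed: int = 0,
                feature_names: list[str] | None = None) -> ModelParams:
    """Seeded parameter initialisation.

    Modulation networks start near the identity (alpha ~= 1, beta ~= 0)
    so early training behaves like an unmodulated branch.
    """
    rng = np.random.default_rng(seed)
    d = config.layer_dim
    layers = [_init_mlp(rng, config.input_dim, d, d)]
    for _ in range(1, config.n_layers):
        layers.append(_init_mlp(rng, 2 * d, d, d))
    mk_branch = lambda: _init_mlp(rng, config.jk_dim, config.branch_hidden, 1)
    # softplus(log(e - 1)) = 1, so the gain starts at 1
    alpha_bias = float(np.log(np.e - 1.0))
    mk_alpha = lambda: _init_mlp(rng, config.input_dim,
                                 config.modulation_hidden, 1,
                                 out_bias=alpha_bias)
    mk_beta = lambda: _init_mlp(rng, config.input_dim,
                                config.modulation_hidden, 1)
    return ModelParams(
        config=config,
        layers=layers,
        branch_s=mk_branch(), branch_e=mk_branch(),
        alpha_s=mk_alpha(), beta_s=mk_beta(),
        alpha_e=mk_alpha(), beta_e=mk_beta(),
        feature_names=list(feature_names or []),
    )


@dataclass
class ScoreSet:
    """Per-cell and bag-level outputs for one core.

    ``cell_score`` is z_s - z_e in (-1, 1); ``Z`` is its mean over the
    core and always equals ``Z_s - Z_e``.
    """

    core_id: str
    z_s: np.ndarray
    z_e: np.ndarray
    Z_s: float
    Z_e: float

    @property
    def cell_score(self) -> np.ndarray:
        return self.z_s - self.z_e

    @property
    def Z(self) -> float:
        return self.Z_s - self.Z_e


# ---------------------------------------------------------------------------
# forward pieces


def local_embed(x: Tensor | np.ndarray, params: MLPParams) -> Tensor:
    """First-layer update: a per-cell transformation using no edges."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.shape[1] != params.w1.shape[0]:
        raise ValueError("input width mismatch")
    return mlp_apply(params, x)


def _directed_with_self_pairs(edges: np.ndarray,
                              n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Directed edge arrays (dst v, src u); isolated nodes get (v, v)."""
    if edges.size:
        v_idx = np.concatenate([edges[:, 0], edges[:, 1]])
        u_idx = np.concatenate([edges[:, 1], edges[:, 0]])
    else:
        v_idx = np.zeros(0, dtype=np.int64)
        u_idx = np.zeros(0, dtype=np.int64)
    degree = np.zeros(n_nodes, dtype=np.int64)
    if v_idx.size:
        np.add.at(degree, v_idx, 1)
    isolated = np.flatnonzero(degree == 0)
    if isolated.size:
        v_idx = np.concatenate([v_idx, isolated])
        u_idx = np.concatenate([u_idx, isolated])
    return v_idx, u_idx


def edgeconv_layer(h: Tensor | np.ndarray, edges: np.ndarray, f) -> Tensor:
    """Neighbourhood update: mean over neighbours of f([h_v || h_v - h_u]).

    ``edges`` is the undirected (m, 2) pair list; both orientations are
    used.  Isolated nodes aggregate over the self pair (difference zero),
    so every cell keeps a representation.  ``f`` maps an (m, 2d) tensor
    to (m, d'); pass an :class:`MLPParams` or any Tensor-to-Tensor
    callable.
    """
    h = h if isinstance(h, Tensor) else Tensor(h)
    n = h.shape[0]
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.size and edges.max() >= n:
        raise ValueError("edge index out of range")
    v_idx, u_idx = _directed_with_self_pairs(edges, n)
    hv = gather(h, v_idx)
    hu = gather(h, u_idx)
    pair = concat([hv, hv - hu], axis=1)
    msg = mlp_apply(f, pair) if isinstance(f, MLPParams) else f(pair)
    summed = segment_sum(msg, v_idx, n)
    counts = np.bincount(v_idx, minlength=n).astype(np.float64)
    return summed * Tensor(1.0 / counts[:, None])


def branch_score(jk: Tensor, core_mean: Tensor, branch: MLPParams,
                 alpha_mlp: MLPParams, beta_mlp: MLPParams) -> Tensor:
    """Sigmoid branch output modulated by core-level scalars.

    alpha and beta are per-core scalars computed from the mean feature
    vector of the core; the branch logit is alpha * f(JK) + beta.  The
    gain alpha is passed through a softplus so it is strictly positive:
    calibration may rescale the shared cell score but never invert its
    polarity, which would make per-cell outputs meaningless under
    bag-level supervision.
    """
    if jk.shape[1] != branch.w1.shape[0]:
        raise ValueError("jumping-knowledge width mismatch")
    if core_mean.shape[1] != alpha_mlp.w1.shape[0]:
        raise ValueError("core-mean width mismatch")
    alpha = softplus(mlp_apply(alpha_mlp, core_mean))  # (1, 1) > 0
    beta = mlp_apply(beta_mlp, core_mean)
    return sigmoid(alpha * mlp_apply(branch, jk) + beta)


def forward_tensors(graph: CoreGraph,
                    params: ModelParams) -> tuple[Tensor, Tensor]:
    """Run the network, returning per-cell branch outputs as tensors."""
    if graph.n_cells == 0:
        raise ValueError("empty graph")
    if graph.node_features.shape[1] != params.config.input_dim:
        raise ValueError("feature schema does not match model input width")
    x = Tensor(graph.node_features)
    h = local_embed(x, params.layers[0])
    reps = [h]
    for layer in params.layers[1:]:
        h = edgeconv_layer(h, graph.edges, layer)
        reps.append(h)
    jk = concat(reps, axis=1)
    core_mean = x.mean_axis0()
    z_s = branch_score(jk, core_mean, params.branch_s,
                       params.alpha_s, params.beta_s)
    z_e = branch_score(jk, core_mean, params.branch_e,
                       params.alpha_e, params.beta_e)
    return z_s, z_e


def forward(graph: CoreGraph, params: ModelParams) -> ScoreSet:
    """Score one core; deterministic (no dropout or stochastic layers)."""
    z_s, z_e = forward_tensors(graph, params)
    zs = z_s.data.ravel()
    ze = z_e.data.ravel()
    return ScoreSet(core_id=graph.core_id, z_s=zs, z_e=ze,
                    Z_s=float(zs.mean()), Z_e=float(ze.mean()))
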