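"""Multimodal encoders and prediction head.

The forward path mirrors the architecture: a three-layer graph convolutional
encoder with symmetric degree normalization and a coordinate-wise max
readout turns a drug's molecular graph into an embedding h_d; a small CNN
(conv -> batch norm -> ReLU -> max pool, twice) turns the 30x30 expression
grid into a cell embedding h_c; an integration layer applies a shared
two-layer transform f_d to each drug and a single linear f_c to the cell and
concatenates them into z; a two-layer head maps z to the predicted synergy
score  y_hat = ReLU(z W1 + b1) W2 + b2.

Parameters are held in a flat dict and partitioned by name prefix:
``embed.*`` is the feature-embedding group (theta_E: GCN, CNN + batch-norm
scale/shift, integration) and ``head.*`` is the prediction group (theta_p).
Only theta_p adapts in the inner tier of meta-optimization, so the partition
is load-bearing and checked.

Everything is functional: forward passes take a parameter mapping, so an
adapted head can be swapped in without mutating the model state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem import MolecularGraph, N_FEATURES
from .data import ExpressionGrid, GRID_SIDE

ABLATIONS = ("none", "no_ml", "no_ft", "no_so", "no_pt")
BN_EPS = 1e-5
BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Sizes follow common graph-DTA-scale conventions; every value is
    overridable and nothing downstream depends on the defaults.
    """

    gcn_dims: tuple = (156, 312, 624)  # widths of the 3 GCN layers
    cnn_channels: tuple = (16, 32)
    cnn_kernel: int = 3
    cnn_pool: int = 2
    fd_hidden: int = 256  # f_d: FC1 width
    fd_out: int = 128  # f_d: per-drug output width
    fc_out: int = 128  # f_c: cell output width
    head_hidden: int = 256
    dropout: float = 0.2
    alpha: float = 0.01  # inner-tier learning rate
    beta: float = 0.001  # outer-tier learning rate
    inner_steps: int = 1
    first_order: bool = False  # drop second-order terms in the outer gradient

    def __post_init__(self):
        if len(self.gcn_dims) != 3:
            raise ValueError("gcn_dims must list 3 layer widths")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("learning rates alpha and beta must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    def cnn_flat_dim(self) -> int:
        side = GRID_SIDE
        for _ in self.cnn_channels:
            side = (side - self.cnn_kernel + 1) // self.cnn_pool
            if side < 1:
                raise ValueError("CNN reduces the grid below 1x1")
        return self.cnn_channels[-1] * side * side

    @property
    def z_dim(self) -> int:
        return 2 * self.fd_out + self.fc_out


def desk_config(**overrides) -> ModelConfig:
    """A small configuration for CPU-scale experiments."""
    base = dict(
        gcn_dims=(32, 32, 64),
        cnn_channels=(4, 8),
        fd_hidden=48,
        fd_out=24,
        fc_out=24,
        head_hidden=48,
        dropout=0.1,
    )
    base.update(overrides)
    return ModelConfig(**base)


@dataclass
class ModelState:
    """Parameters + batch-norm running statistics + stage/ablation flags."""

    config: ModelConfig
    params: dict  # name -> Tensor (trainable leaves)
    bn_running: dict  # name -> np.ndarray (non-trainable)
    stage: str = "init"
    ablation: str = "none"

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; one of {ABLATIONS}")

    # -- parameter partition ------------------------------------------------
    def theta_E_keys(self):
        return [k for k in self.params if k.startswith("embed.")]

    def theta_p_keys(self):
        return [k for k in self.params if k.startswith("head.")]

    def check_partition(self):
        e, p = set(self.theta_E_keys()), set(self.theta_p_keys())
        if e & p or (e | p) != set(self.params):
            raise AssertionError("theta_E/theta_p must partition the parameters")

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: ad.parameter(v.data) for k, v in self.params.items()},
            bn_running={k: v.copy() for k, v in self.bn_running.items()},
            stage=self.stage,
            ablation=self.ablation,
        )

    def with_flags(self, **kw) -> "ModelState":
        out = self.copy()
        for k, v in kw.items():
            setattr(out, k, v)
        return out


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_state(
    config: ModelConfig | None = None, seed: int = 0, ablation: str = "none"
) -> ModelState:
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    p, bn = {}, {}

    dims = (N_FEATURES,) + tuple(config.gcn_dims)
    for layer in range(3):
        p[f"embed.gcn.W{layer + 1}"] = ad.parameter(
            _glorot(rng, dims[layer], dims[layer + 1])
        )

    c_in = 1
    k = config.cnn_kernel
    for layer, c_out in enumerate(config.cnn_channels, start=1):
        p[f"embed.cnn.conv{layer}.W"] = ad.parameter(
            _glorot(rng, c_in * k * k, c_out)
        )
        p[f"embed.cnn.conv{layer}.b"] = ad.parameter(np.zeros((1, c_out)))
        p[f"embed.cnn.bn{layer}.gamma"] = ad.parameter(np.ones((1, c_out)))
        p[f"embed.cnn.bn{layer}.beta"] = ad.parameter(np.zeros((1, c_out)))
        bn[f"embed.cnn.bn{layer}.mean"] = np.zeros(c_out)
        bn[f"embed.cnn.bn{layer}.var"] = np.ones(c_out)
        c_in = c_out

    d3 = config.gcn_dims[-1]
    p["embed.fd.W1"] = ad.parameter(_glorot(rng, d3, config.fd_hidden))
    p["embed.fd.b1"] = ad.parameter(np.zeros((1, config.fd_hidden)))
    p["embed.fd.W2"] = ad.parameter(_glorot(rng, config.fd_hidden, config.fd_out))
    p["embed.fd.b2"] = ad.parameter(np.zeros((1, config.fd_out)))
    flat = config.cnn_flat_dim()
    p["embed.fc.W"] = ad.parameter(_glorot(rng, flat, config.fc_out))
    p["embed.fc.b"] = ad.parameter(np.zeros((1, config.fc_out)))

    p["head.W1"] = ad.parameter(_glorot(rng, config.z_dim, config.head_hidden))
    p["head.b1"] = ad.parameter(np.zeros((1, config.head_hidden)))
    p["head.W2"] = ad.parameter(_glorot(rng, config.head_hidden, 1))
    p["head.b2"] = ad.parameter(np.zeros((1, 1)))

    state = ModelState(config=config, params=p, bn_running=bn, ablation=ablation)
    state.check_partition()
    return state


# ---------------------------------------------------------------------------
# layers


def gcn_layer(node_feats, graph: MolecularGraph, W) -> Tensor:
    """One graph convolution: ReLU of degree-normalized neighborhood sums.

    Node u aggregates sum over v in N(u) and u itself of
    e_{v,u} / sqrt(D_v * D_u) * h_v with D_u = 1 + sum of incident edge
    weights, then applies the layer transform W and a ReLU.
    """
    h = ad.constant(node_feats)
    W = ad.constant(W)
    if h.shape[1] != W.shape[0]:
        raise ValueError(f"feature dim {h.shape[1]} does not match W {W.shape}")
    if h.shape[0] != graph.n_atoms:
        raise ValueError("node_feats rows must match the graph's atom count")
    a_hat = ad.constant(graph.norm_adjacency())
    return ad.relu(ad.matmul(ad.matmul(a_hat, h), W))


def encode_drug(graph: MolecularGraph, params, config: ModelConfig) -> Tensor:
    """Three stacked graph convolutions, then coordinate-wise max readout."""
    if graph.n_atoms == 0:
        raise ValueError("cannot encode an empty graph")
    h = ad.constant(graph.node_features)
    for layer in range(3):
        h = gcn_layer(h, graph, params[f"embed.gcn.W{layer + 1}"])
    return ad.reshape(ad.max_(h, axis=0), (1, config.gcn_dims[-1]))


def _batchnorm(x, gamma, beta, running_mean, running_var, training: bool):
    """Channel-wise batch norm on a (positions, channels) activation map.

    In training mode the statistics come from the current activations (and
    the running buffers are updated in place); in inference mode the frozen
    running statistics are used.
    """
    if training:
        mu = ad.mean(x, axis=0, keepdims=True)
        var = ad.mean(ad.pow_(ad.sub(x, mu), 2.0), axis=0, keepdims=True)
        running_mean *= 1.0 - BN_MOMENTUM
        running_mean += BN_MOMENTUM * mu.data.ravel()
        running_var *= 1.0 - BN_MOMENTUM
        running_var += BN_MOMENTUM * var.data.ravel()
    else:
        mu = ad.constant(running_mean.reshape(1, -1))
        var = ad.constant(running_var.reshape(1, -1))
    xn = ad.div(ad.sub(x, mu), ad.sqrt(ad.add(var, BN_EPS)))
    return ad.add(ad.mul(xn, gamma), beta)


def _maxpool(x, window: int) -> Tensor:
    c, h, w = x.shape
    x = ad.reshape(x, (c, h // window, window, w // window, window))
    x = ad.max_(x, axis=4)
    return ad.max_(x, axis=2)


def encode_cell(
    grid: ExpressionGrid | np.ndarray,
    params,
    config: ModelConfig,
    bn_running=None,
    training: bool = False,
) -> Tensor:
    """CNN encoder: per layer Pool(ReLU(BN(conv))), then flatten."""
    arr = grid.grid if isinstance(grid, ExpressionGrid) else np.asarray(grid)
    x = ad.reshape(ad.constant(arr), (1, GRID_SIDE, GRID_SIDE))
    k = config.cnn_kernel
    for layer, c_out in enumerate(config.cnn_channels, start=1):
        c_in, h, w = x.shape
        cols = ad.im2col(x, k, k)  # (h'*w', c_in*k*k)
        conv = ad.add(
            ad.matmul(cols, params[f"embed.cnn.conv{layer}.W"]),
            params[f"embed.cnn.conv{layer}.b"],
        )
        if training and bn_running is None:
            raise ValueError("training-mode batch norm needs running buffers")
        buffers = bn_running if bn_running is not None else {}
        conv = _batchnorm(
            conv,
            params[f"embed.cnn.bn{layer}.gamma"],
            params[f"embed.cnn.bn{layer}.beta"],
            buffers.get(f"embed.cnn.bn{layer}.mean", np.zeros(c_out)),
            buffers.get(f"embed.cnn.bn{layer}.var", np.ones(c_out)),
            training,
        )
        conv = ad.relu(conv)
        oh, ow = h - k + 1, w - k + 1
        x = ad.reshape(ad.transpose(conv), (c_out, oh, ow))
        x = _maxpool(x, config.cnn_pool)
    return ad.reshape(x, (1, config.cnn_flat_dim()))


def _dropout(x, rate: float, training: bool, rng) -> Tensor:
    if not training or rate == 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return ad.mul(x, ad.constant(mask))


def transform_drug(h_d, params, config: ModelConfig, training=False, rng=None):
    """f_d: FC2(ReLU(Dropout(FC1(h_d)))), shared across both drugs."""
    h = ad.add(ad.matmul(h_d, params["embed.fd.W1"]), params["embed.fd.b1"])
    h = _dropout(h, config.dropout, training, rng)
    h = ad.relu(h)
    return ad.add(ad.matmul(h, params["embed.fd.W2"]), params["embed.fd.b2"])


def transform_cell(h_c, params):
    """f_c: a single fully connected layer."""
    return ad.add(ad.matmul(h_c, params["embed.fc.W"]), params["embed.fc.b"])


def integrate(
    h_dA, h_dB, h_c, params, config: ModelConfig, training: bool = False, rng=None
) -> Tensor:
    """Joint embedding z = concat(f_d(h_dA), f_d(h_dB), f_c(h_c))."""
    if training and rng is None and config.dropout > 0:
        raise ValueError("training mode requires an rng for dropout")
    return ad.concat(
        [
            transform_drug(h_dA, params, config, training, rng),
            transform_drug(h_dB, params, config, training, rng),
            transform_cell(h_c, params),
        ],
        axis=1,
    )


def predict_head(z, params) -> Tensor:
    """y_hat = ReLU(z W1 + b1) W2 + b2, one score per row of z."""
    if z.shape[1] != params["head.W1"].shape[0]:
        raise ValueError(
            f"z dim {z.shape[1]} does not match head W1 {params['head.W1'].shape}"
        )
    h = ad.relu(ad.add(ad.matmul(z, params["head.W1"]), params["head.b1"]))
    return ad.add(ad.matmul(h, params["head.W2"]), params["head.b2"])


# ---------------------------------------------------------------------------
# batched forward


def embed_samples(
    samples,
    graphs: dict,
    grids: dict,
    params,
    state: ModelState,
    training: bool = False,
    rng=None,
) -> Tensor:
    """Joint embeddings for a batch of samples as an (m, z_dim) tensor.

    Each unique drug and cell line in the batch is encoded once and reused.
    """
    cfg = state.config
    drug_emb, fd_emb, cell_emb = {}, {}, {}
    for s in samples:
        for d in (s.drug_a, s.drug_b):
            if d not in fd_emb:
                drug_emb[d] = encode_drug(graphs[d], params, cfg)
                fd_emb[d] = transform_drug(drug_emb[d], params, cfg, training, rng)
        if s.cell_line not in cell_emb:
            h_c = encode_cell(
                grids[s.cell_line],
                params,
                cfg,
                bn_running=state.bn_running,
                training=training,
            )
            cell_emb[s.cell_line] = transform_cell(h_c, params)
    rows = [
        ad.concat([fd_emb[s.drug_a], fd_emb[s.drug_b], cell_emb[s.cell_line]], axis=1)
        for s in samples
    ]
    return ad.concat(rows, axis=0)


def forward_scores(
    samples,
    graphs: dict,
    grids: dict,
    params,
    state: ModelState,
    training: bool = False,
    rng=None,
) -> Tensor:
    """Predicted synergy scores, shape (m, 1)."""
    z = embed_samples(samples, graphs, grids, params, state, training, rng)
    return predict_head(z, params)
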