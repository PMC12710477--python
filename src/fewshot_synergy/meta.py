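"""Stage-wise training: pretraining, cross-tier meta-optimization, fine-tuning.

The strategy has three stages. (1) Cross-domain pretraining fits the whole
network to the base cell lines' samples by minimizing 1/2 * sum of squared
errors. (2) Episodic meta-optimization: each episode samples N few-shot
tasks from N distinct cell lines; the *inner tier* adapts only the
prediction head on each task's support set,

    theta'_j = (theta_E, theta_p - alpha * d L_support / d theta_p),

while the *outer tier* updates the full initialization from the summed
query losses,

    theta <- theta - beta * d/d theta  sum_j L_query(f_{theta'_j}),

where by default the gradient flows *through* the inner update (second
order); a first-order approximation is selectable. (3) Fine-tuning applies
the same selective inner step on a new cell line's support set and predicts
its query samples; the shared initialization is never mutated.

Ablation flags reroute the stages: ``no_ml`` drops meta-optimization (plain
supervised training, then the same test-time fine-tune), ``no_ft`` skips
test-time adaptation, ``no_so`` adapts all parameters in the inner tier
instead of the head only, ``no_pt`` skips pretraining. A zero-shot mode
disables the inner loop everywhere, so the outer tier minimizes the
unadapted query loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import Episode, FewShotTask, SynergyDataset
from .model import ModelState, embed_samples, forward_scores, predict_head

__all__ = [
    "mse_loss",
    "sse_half_loss",
    "pretrain",
    "build_episode",
    "inner_adapt",
    "outer_update",
    "meta_train",
    "fine_tune",
    "zero_shot_predict",
    "TrainLog",
]


def _targets(samples) -> np.ndarray:
    return np.array([[s.y] for s in samples], dtype=np.float64)


def mse_loss(pred: Tensor, y) -> Tensor:
    """Mean squared error, (1/m) * sum (y - y_hat)^2."""
    return ad.mean(ad.pow_(ad.sub(pred, ad.constant(np.asarray(y))), 2.0))


def sse_half_loss(pred: Tensor, y) -> Tensor:
    """Pretraining objective, (1/2) * sum (y_hat - y)^2."""
    return ad.mul(0.5, ad.sum_(ad.pow_(ad.sub(pred, ad.constant(np.asarray(y))), 2.0)))


@dataclass
class TrainLog:
    """Per-interval loss trajectory of a training stage."""

    stage: str
    losses: list = field(default_factory=list)

    def append(self, step: int, loss: float):
        self.losses.append({"step": int(step), "loss": float(loss)})

    def values(self):
        return [r["loss"] for r in self.losses]


class AdamOptimizer:
    """Adam on the raw parameter arrays (used for pretraining by default)."""

    def __init__(self, keys, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k].data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# stage 1: cross-domain pretraining


def pretrain(
    dataset: SynergyDataset,
    state: ModelState,
    epochs: int,
    batch_size: int = 128,
    seed: int = 0,
    lr: float = 1e-3,
    optimizer: str = "adam",
) -> tuple[ModelState, TrainLog]:
    """Joint gradient training of theta_E and theta_p on base-cell-line data.

    Minimizes the half-sum-of-squares objective by mini-batch descent.
    Returns a new state (stage ``pretrained``) and the loss trajectory; the
    input state is not mutated.
    """
    if not dataset.samples:
        raise ValueError("pretraining requires a nonempty sample list")
    if state.ablation == "no_pt":
        raise ValueError("pretraining is disabled under the no_pt ablation")
    out = state.copy()
    keys = list(out.params)
    ss = np.random.SeedSequence(seed)
    rng_batch, rng_drop = (np.random.default_rng(c) for c in ss.spawn(2))
    opt = AdamOptimizer(keys, lr=lr) if optimizer == "adam" else None
    log = TrainLog(stage="pretrain")
    samples = list(dataset.samples)
    for epoch in range(epochs):
        order = rng_batch.permutation(len(samples))
        epoch_loss = 0.0
        for start in range(0, len(samples), batch_size):
            batch = [samples[i] for i in order[start : start + batch_size]]
            pred = forward_scores(
                batch, dataset.graphs, dataset.grids, out.params, out,
                training=True, rng=rng_drop,
            )
            loss = sse_half_loss(pred, _targets(batch))
            grads = ad.grad(loss, [out.params[k] for k in keys])
            gd = {k: g.data for k, g in zip(keys, grads)}
            if opt is not None:
                opt.step(out.params, gd)
            else:
                for k in keys:
                    out.params[k].data -= lr * gd[k]
            epoch_loss += float(loss.data)
        log.append(epoch, epoch_loss / max(1, len(samples)))
    out.stage = "pretrained"
    return out, log


# ---------------------------------------------------------------------------
# episodic task sampling


def build_episode(pool: dict, N: int, K: int, Q: int, rng) -> Episode:
    """Sample N distinct cell lines, then K support + Q query samples each.

    Support and query are disjoint as drug-pair sets: K+Q distinct pairs are
    drawn without replacement within each cell line.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    by_pair = {}
    for cl, samples in pool.items():
        pairs = {}
        for s in samples:
            pairs.setdefault(s.pair, []).append(s)
        by_pair[cl] = pairs
    eligible = sorted(cl for cl, pairs in by_pair.items() if len(pairs) >= K + Q)
    if len(eligible) < N:
        short = sorted(
            (cl for cl in pool if cl not in eligible),
            key=lambda cl: len(by_pair[cl]),
        )
        worst = short[0] if short else "<none>"
        raise ValueError(
            f"need {N} cell lines with >= {K + Q} distinct drug pairs, "
            f"only {len(eligible)} available (e.g. {worst!r} is too small)"
        )
    chosen = rng.choice(len(eligible), size=N, replace=False)
    tasks = []
    for idx in sorted(chosen):
        cl = eligible[idx]
        pair_keys = sorted(by_pair[cl], key=sorted)
        pick = rng.choice(len(pair_keys), size=K + Q, replace=False)
        picked = []
        for j in pick:
            candidates = by_pair[cl][pair_keys[j]]
            picked.append(candidates[int(rng.integers(len(candidates)))])
        tasks.append(
            FewShotTask(cell_line=cl, support=picked[:K], query=picked[K:])
        )
    return Episode(tasks=tasks)


# ---------------------------------------------------------------------------
# inner tier


def inner_adapt(
    task: FewShotTask,
    state: ModelState,
    graphs: dict,
    grids: dict,
    create_graph: bool = False,
) -> tuple[dict, list]:
    """Task-specific adaptation on the support set.

    Returns a full parameter mapping in which only the prediction head has
    been stepped (theta_E entries are the *same* tensors as in ``state``);
    under the ``no_so`` ablation every parameter is stepped. With
    ``create_graph=True`` the adapted parameters stay differentiable with
    respect to the originals, which is what makes the outer-tier gradient
    second order.
    """
    cfg = state.config
    if cfg.alpha <= 0:
        raise ValueError("inner learning rate alpha must be positive")
    params = dict(state.params)
    adapt_keys = (
        list(state.params) if state.ablation == "no_so" else state.theta_p_keys()
    )
    y_s = _targets(task.support)
    support_losses = []
    for _ in range(cfg.inner_steps):
        pred = forward_scores(task.support, graphs, grids, params, state)
        loss = mse_loss(pred, y_s)
        grads = ad.grad(
            loss, [params[k] for k in adapt_keys], create_graph=create_graph
        )
        for k, g in zip(adapt_keys, grads):
            params[k] = ad.sub(params[k], ad.mul(cfg.alpha, g))
        support_losses.append(float(loss.data))
    return params, support_losses


def _task_query_loss(
    task: FewShotTask,
    state: ModelState,
    graphs: dict,
    grids: dict,
    create_graph: bool,
    training: bool = False,
    rng=None,
    zero_shot: bool = False,
) -> Tensor:
    """Query loss after inner adaptation (or without it in zero-shot mode).

    Head-only adaptation lets support and query share one embedding pass;
    full adaptation (``no_so``) re-embeds the query set with the adapted
    encoder parameters.
    """
    y_q = _targets(task.query)
    if zero_shot:
        pred = forward_scores(
            task.query, graphs, grids, state.params, state, training, rng
        )
        return mse_loss(pred, y_q)
    if state.ablation == "no_so":
        params, _ = inner_adapt(task, state, graphs, grids, create_graph)
        pred = forward_scores(task.query, graphs, grids, params, state, training, rng)
        return mse_loss(pred, y_q)
    m_s = len(task.support)
    z_all = embed_samples(
        list(task.support) + list(task.query),
        graphs, grids, state.params, state, training, rng,
    )
    z_s, z_q = z_all[:m_s], z_all[m_s:]
    params = dict(state.params)
    y_s = _targets(task.support)
    for _ in range(state.config.inner_steps):
        loss_s = mse_loss(predict_head(z_s, params), y_s)
        grads = ad.grad(
            loss_s,
            [params[k] for k in state.theta_p_keys()],
            create_graph=create_graph,
        )
        for k, g in zip(state.theta_p_keys(), grads):
            params[k] = ad.sub(params[k], ad.mul(state.config.alpha, g))
    return mse_loss(predict_head(z_q, params), y_q)


# ---------------------------------------------------------------------------
# outer tier


def outer_update(
    episode: Episode,
    state: ModelState,
    graphs: dict,
    grids: dict,
    rng=None,
    zero_shot: bool = False,
    training: bool = True,
    opt: AdamOptimizer | None = None,
) -> float:
    """One meta-update from an episode; mutates ``state`` in place.

    Accumulates the adapted query losses of all tasks and steps every
    parameter (theta_E and theta_p) by plain gradient descent with rate
    beta, differentiating through the inner update unless the configuration
    selects the first-order approximation. Returns the mean query loss.
    """
    if state.ablation == "no_ml":
        raise ValueError("meta-optimization is disabled under the no_ml ablation")
    if not episode.tasks:
        raise ValueError("episode must contain at least one task")
    create_graph = not state.config.first_order
    total = None
    for task in episode.tasks:
        lq = _task_query_loss(
            task, state, graphs, grids, create_graph,
            training=training, rng=rng, zero_shot=zero_shot,
        )
        total = lq if total is None else ad.add(total, lq)
    keys = list(state.params)
    grads = ad.grad(total, [state.params[k] for k in keys])
    if opt is not None:
        opt.step(state.params, {k: g.data for k, g in zip(keys, grads)})
    else:
        for k, g in zip(keys, grads):
            state.params[k].data -= state.config.beta * g.data
    return float(total.data) / len(episode.tasks)


def meta_train(
    dataset: SynergyDataset,
    state: ModelState,
    episodes: int,
    N: int,
    K: int,
    Q: int,
    seed: int = 0,
    zero_shot: bool = False,
    outer_optimizer: str = "sgd",
    log_every: int = 50,
) -> tuple[ModelState, TrainLog]:
    """Episodic meta-training loop: build_episode then outer_update.

    Returns a new state (stage ``meta_trained``) and the per-episode mean
    query-loss log; the input state is not mutated.
    """
    out = state.copy()
    out.stage = state.stage
    pool = dataset.pool()
    ss = np.random.SeedSequence(seed)
    rng_episode, rng_drop = (np.random.default_rng(c) for c in ss.spawn(2))
    opt = (
        AdamOptimizer(list(out.params), lr=out.config.beta)
        if outer_optimizer == "adam"
        else None
    )
    log = TrainLog(stage="meta_train")
    for ep in range(episodes):
        episode = build_episode(pool, N, K, Q, rng_episode)
        loss = outer_update(
            episode, out, dataset.graphs, dataset.grids,
            rng=rng_drop, zero_shot=zero_shot, opt=opt,
        )
        log.append(ep, loss)
    out.stage = "meta_trained"
    return out, log


# ---------------------------------------------------------------------------
# stage 3: few-shot fine-tuning / zero-shot prediction


def fine_tune(
    task: FewShotTask,
    state: ModelState,
    graphs: dict,
    grids: dict,
    allow_untrained: bool = False,
) -> tuple[np.ndarray, dict]:
    """Adapt the head on the task's support set and predict its query set.

    The original state is not mutated; returns (query predictions, adapted
    parameter mapping). Under the ``no_ft`` ablation no adaptation happens
    and the predictions equal :func:`zero_shot_predict`.
    ``allow_untrained`` admits an untrained state, used for baseline
    comparisons against a randomly initialized network.
    """
    if not allow_untrained and state.stage not in ("meta_trained", "pretrained"):
        raise ValueError(
            f"fine-tuning expects a trained state, got stage {state.stage!r}"
        )
    if state.ablation == "no_ft":
        return zero_shot_predict(task.query, state, graphs, grids), dict(state.params)
    params, _ = inner_adapt(task, state, graphs, grids, create_graph=False)
    pred = forward_scores(task.query, graphs, grids, params, state)
    return pred.data.ravel().copy(), params


def zero_shot_predict(
    samples, state: ModelState, graphs: dict, grids: dict
) -> np.ndarray:
    """Pure forward pass on bare query samples; no parameter change."""
    if isinstance(samples, FewShotTask):
        samples = samples.query
    pred = forward_scores(samples, graphs, grids, state.params, state)
    return pred.data.ravel().copy()
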