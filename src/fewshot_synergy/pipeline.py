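"""Stage orchestration: pretrain -> meta-optimize -> (fine-tune at test).

`run_training` routes the stages according to the ablation flag:

==========  ==============================================================
``none``    pretraining, then episodic meta-optimization (selective inner)
``no_ml``   supervised training only; test-time fine-tuning still applies
``no_ft``   full training; adaptation is skipped at test time
``no_so``   full training, but the inner tier adapts *all* parameters
``no_pt``   meta-optimization from random initialization (no pretraining)
==========  ==============================================================
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import SynergyDataset
from .meta import TrainLog, meta_train, pretrain
from .model import ModelConfig, ModelState, init_state


@dataclass(frozen=True)
class TrainSettings:
    """Stage sizes and seeds for one training run."""

    pretrain_epochs: int = 30
    batch_size: int = 128
    pretrain_lr: float = 1e-3
    episodes: int = 300
    N: int = 5  # tasks per episode
    K: int = 10  # support size
    Q: int = 10  # query size
    zero_shot: bool = False
    outer_optimizer: str = "sgd"
    supervised_epochs: int | None = None  # no_ml budget; default 2x pretrain

    def __post_init__(self):
        if self.K <= 0 or self.Q <= 0 or self.N <= 0:
            raise ValueError("N, K and Q must be positive")


def run_training(
    train_data: SynergyDataset,
    model_config: ModelConfig,
    settings: TrainSettings,
    ablation: str = "none",
    seed: int = 0,
) -> tuple[ModelState, dict]:
    """Train one model variant on base-cell-line data.

    Returns the trained state and a dict of stage logs. The same seed gives
    bit-identical parameters run to run.
    """
    state = init_state(model_config, seed=seed, ablation=ablation)
    logs: dict[str, TrainLog] = {}
    if ablation == "no_ml":
        epochs = (
            settings.supervised_epochs
            if settings.supervised_epochs is not None
            else 2 * settings.pretrain_epochs
        )
        state, logs["supervised"] = pretrain(
            train_data, state, epochs=epochs, batch_size=settings.batch_size,
            seed=seed, lr=settings.pretrain_lr,
        )
        return state, logs
    if ablation != "no_pt":
        state, logs["pretrain"] = pretrain(
            train_data, state, epochs=settings.pretrain_epochs,
            batch_size=settings.batch_size, seed=seed, lr=settings.pretrain_lr,
        )
    state, logs["meta_train"] = meta_train(
        train_data, state, episodes=settings.episodes,
        N=settings.N, K=settings.K, Q=settings.Q, seed=seed + 1,
        zero_shot=settings.zero_shot,
        outer_optimizer=settings.outer_optimizer,
    )
    return state, logs
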