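"""Benchmark experiments on synthetic worlds.

These functions package the study-level checks of the framework: the
rapid-adaptation benefit of meta-optimization over (a) no adaptation and
(b) an identically adapted random initialization; the ablation ordering of
the training stages; the dispersion-versus-error relation across meta-test
cell lines; and the split-protocol contrasts. Each takes a seed and
returns a plain dict of computed quantities, so the same code backs both
the test suite and the reproduction script.

Problem sizes are desk-scale: worlds of 15-30 cell lines and 40 drugs with
a few hundred meta-training episodes, which is where the properties of
interest already express themselves.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest

from .evaluation import (
    evaluate_fewshot,
    per_cellline_analysis,
    run_ablation,
    split_low_similarity,
    split_random,
)
from .model import desk_config, init_state
from .pipeline import TrainSettings, run_training
from .synthetic import SyntheticWorldConfig, make_world


def _eval_seeds(seed: int, repeats: int):
    return [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(repeats)
    ]


def meta_benefit_experiment(
    seed: int = 0,
    episodes: int = 300,
    K: int = 10,
    Q: int = 10,
    repeats: int = 20,
    n_tasks: int = 10,
    pretrain_epochs: int = 20,
) -> dict:
    """Meta-trained + adapted vs. unadapted vs. random-init + adapted.

    World: 40 drugs, 15 cell lines, shared_weight 0.8. Paired comparison
    over seeded evaluation repeats with one-sided sign tests.
    """
    world = make_world(SyntheticWorldConfig(seed=seed))
    split = split_random(
        world.dataset.grids.keys(), 0.8, seed=seed, grids=world.dataset.grids
    )
    train_data = world.dataset.restricted_to(split.train)
    cfg = desk_config()
    settings = TrainSettings(
        pretrain_epochs=pretrain_epochs, episodes=episodes, N=5, K=K, Q=Q,
        outer_optimizer="adam",
    )
    state, logs = run_training(train_data, cfg, settings, ablation="none", seed=seed)
    random_state = init_state(cfg, seed=seed + 7919)

    seeds = _eval_seeds(seed + 101, repeats)
    common = dict(K=K, Q=Q, n_tasks=n_tasks, repeats=repeats, repeat_seeds=seeds)
    rep_adapted = evaluate_fewshot(state, world.dataset, split, **common)
    rep_unadapted = evaluate_fewshot(
        state, world.dataset, split, adapt=False, **common
    )
    rep_random = evaluate_fewshot(
        state=random_state, dataset=world.dataset, split=split,
        allow_untrained=True, **common,
    )
    a = np.array([r["mse"] for r in rep_adapted.rows])
    u = np.array([r["mse"] for r in rep_unadapted.rows])
    rd = np.array([r["mse"] for r in rep_random.rows])
    wins_u = int((a < u).sum())
    wins_r = int((a < rd).sum())
    return {
        "adapted_mse": float(a.mean()),
        "unadapted_mse": float(u.mean()),
        "random_init_mse": float(rd.mean()),
        "wins_vs_unadapted": wins_u,
        "wins_vs_random": wins_r,
        "repeats": repeats,
        "sign_p_vs_unadapted": float(
            binomtest(wins_u, repeats, alternative="greater").pvalue
        ),
        "sign_p_vs_random": float(
            binomtest(wins_r, repeats, alternative="greater").pvalue
        ),
        "meta_loss_first50": float(np.mean(logs["meta_train"].values()[:50])),
        "meta_loss_last50": float(np.mean(logs["meta_train"].values()[-50:])),
    }


def ablation_experiment(
    seed: int = 0,
    episodes: int = 300,
    K: int = 10,
    Q: int = 10,
    repeats: int = 10,
    n_tasks: int = 10,
    pretrain_epochs: int = 20,
) -> dict:
    """Full model vs. each training-strategy ablation under shared seeds."""
    world = make_world(SyntheticWorldConfig(seed=seed))
    split = split_random(
        world.dataset.grids.keys(), 0.8, seed=seed, grids=world.dataset.grids
    )
    settings = TrainSettings(
        pretrain_epochs=pretrain_epochs, episodes=episodes, N=5, K=K, Q=Q,
        outer_optimizer="adam",
    )
    reports = run_ablation(
        world.dataset, split, ["no_ml", "no_ft", "no_so", "no_pt"],
        desk_config(), settings=settings, seed=seed, K=K, Q=Q,
        n_tasks=n_tasks, repeats=repeats,
    )
    return {name: rep.mean("mse") for name, rep in reports.items()}


def dispersion_error_experiment(
    seed: int = 0,
    episodes: int = 150,
    K: int = 10,
    Q: int = 10,
    n_tasks_per_line: int = 15,
    pretrain_epochs: int = 15,
) -> dict:
    """Per-line MSE vs. per-line score range on a dispersion-spread world."""
    world = make_world(
        SyntheticWorldConfig(
            n_cell_lines=30, samples_per_cell_line=80,
            dispersion_range=(0.4, 1.6), seed=seed,
        )
    )
    split = split_random(
        world.dataset.grids.keys(), 2 / 3, seed=seed, grids=world.dataset.grids
    )
    train_data = world.dataset.restricted_to(split.train)
    settings = TrainSettings(
        pretrain_epochs=pretrain_epochs, episodes=episodes, N=5, K=K, Q=Q,
        outer_optimizer="adam",
    )
    state, _ = run_training(train_data, desk_config(), settings, seed=seed)
    table, r, p = per_cellline_analysis(
        state, world.dataset, split, K=K, Q=Q,
        n_tasks_per_line=n_tasks_per_line, seed=seed + 5,
    )
    return {
        "pearson_r": float(r),
        "p_value": float(p),
        "n_cell_lines": int(len(table)),
        "mse_by_line": dict(zip(table["cell_line"], table["mse"])),
        "dispersion_by_line": dict(zip(table["cell_line"], table["dispersion"])),
    }


def split_protocol_experiment(seed: int = 0) -> dict:
    """Random 106-line split sizes + low-similarity vs. random range contrast."""
    lines_106 = [f"CL{i:03d}" for i in range(106)]
    s106 = split_random(lines_106, 0.8, seed=seed)
    world = make_world(
        SyntheticWorldConfig(
            n_drugs=12, n_cell_lines=30, samples_per_cell_line=30,
            cellline_similarity=0.5, seed=seed + 3,
        )
    )
    grids = world.dataset.grids
    low = split_low_similarity(grids, n_test=8)
    rand = split_random(grids.keys(), 1 - 8 / 30, seed=seed, grids=grids)
    lo_range = low.cross_similarity_range()
    rd_range = rand.cross_similarity_range()
    return {
        "random_106_train": len(s106.train),
        "random_106_test": len(s106.test),
        "lowsim_range_min": lo_range[0],
        "lowsim_range_max": lo_range[1],
        "random_range_min": rd_range[0],
        "random_range_max": rd_range[1],
    }
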