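"""Metrics, cell-line splitting protocols, and evaluation harnesses.

Regression quality is reported as MSE, Spearman rank correlation (SCC) and
the coefficient of determination R^2; thresholded classification quality as
ROC AUC and average-precision AUPR. Cell lines are split into meta-training
and meta-testing sets either uniformly at random or by average-linkage
hierarchical clustering on expression correlation, which yields test lines
transcriptomically dissimilar from training ones. The few-shot harness
repeatedly samples K-shot tasks from meta-test lines, adapts per task, and
pools query predictions per repeat (mean +/- SD across repeats).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import (
    average_precision_score,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)

from .data import FewShotTask, SynergyDataset, group_by_cell_line
from .meta import build_episode, fine_tune, zero_shot_predict
from .model import ModelState
from .pipeline import TrainSettings, run_training

REGRESSION_METRICS = ("mse", "scc", "r2")
ALL_METRICS = ("mse", "scc", "r2", "auc", "aupr")


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(y_true, y_pred, threshold: float = 0.0) -> dict:
    """One metrics row; AUC/AUPR are NaN-flagged if only one class remains
    after thresholding y_true."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length with n >= 2")
    row = {
        "mse": float(mean_squared_error(y_true, y_pred)),
        "scc": float(spearmanr(y_true, y_pred).statistic),
        "r2": float(r2_score(y_true, y_pred)),
        "n": int(y_true.size),
    }
    labels = (y_true > threshold).astype(int)
    if labels.min() == labels.max():
        row["auc"] = float("nan")
        row["aupr"] = float("nan")
        row["classification_defined"] = False
    else:
        row["auc"] = float(roc_auc_score(labels, y_pred))
        row["aupr"] = float(average_precision_score(labels, y_pred))
        row["classification_defined"] = True
    return row


@dataclass
class MetricsReport:
    """Per-repeat metric rows with mean +/- SD summaries."""

    rows: list = field(default_factory=list)
    n_tasks: int = 0
    n_repeats: int = 0
    per_cell_line: pd.DataFrame | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def mean(self, metric: str) -> float:
        return float(np.nanmean([r[metric] for r in self.rows]))

    def sd(self, metric: str) -> float:
        return float(np.nanstd([r[metric] for r in self.rows]))

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m)}
            for m in ALL_METRICS
            if self.rows and m in self.rows[0]
        }


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitSpec:
    """Meta-train / meta-test partition of the cell-line universe."""

    train: list
    test: list
    method: str
    similarity_matrix: np.ndarray | None = None
    labels: list | None = None  # row/col order of similarity_matrix

    def __post_init__(self):
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise ValueError(f"split is not disjoint: {sorted(overlap)[:5]}")
        if not self.train or not self.test:
            raise ValueError("both split sides must be nonempty")

    def check_partition(self, universe) -> None:
        if set(self.train) | set(self.test) != set(universe):
            raise AssertionError("split does not cover the cell-line universe")

    def cross_similarity_range(self) -> tuple:
        """(min, max) train-test similarity; needs the similarity matrix."""
        if self.similarity_matrix is None or self.labels is None:
            raise ValueError("split carries no similarity matrix")
        idx = {cl: i for i, cl in enumerate(self.labels)}
        rows = [idx[c] for c in self.train]
        cols = [idx[c] for c in self.test]
        block = self.similarity_matrix[np.ix_(rows, cols)]
        return float(block.min()), float(block.max())


def expression_similarity(grids: dict) -> tuple:
    """Pairwise Pearson correlation of flattened expression grids."""
    labels = sorted(grids)
    mat = np.stack([grids[cl].grid.ravel() for cl in labels])
    sim = np.corrcoef(mat)
    return sim, labels


def split_random(cell_lines, fraction: float = 0.8, seed: int = 0, grids=None) -> SplitSpec:
    """Uniform split; 106 lines at fraction 0.8 gives 85 train / 21 test."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    cell_lines = sorted(cell_lines)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cell_lines))
    n_train = int(round(fraction * len(cell_lines)))
    train = sorted(cell_lines[i] for i in order[:n_train])
    test = sorted(cell_lines[i] for i in order[n_train:])
    sim, labels = expression_similarity(grids) if grids else (None, None)
    return SplitSpec(
        train=train, test=test, method="random",
        similarity_matrix=sim, labels=labels,
    )


def split_low_similarity(grids: dict, n_test: int, method: str = "average") -> SplitSpec:
    """Cluster-based split that makes test lines dissimilar from train lines.

    Average-linkage hierarchical clustering on 1 - correlation distance;
    whole clusters move to the test side, most-dissimilar-first, until the
    test side holds at least ``n_test`` lines.
    """
    if n_test >= len(grids):
        raise ValueError("n_test must be smaller than the number of cell lines")
    sim, labels = expression_similarity(grids)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry for squareform
    z = linkage(squareform(dist, checks=False), method=method)
    n_clusters = max(2, len(labels) // 3)
    assignment = fcluster(z, t=n_clusters, criterion="maxclust")
    clusters = {c: np.flatnonzero(assignment == c) for c in np.unique(assignment)}

    test_idx: list[int] = []
    remaining = dict(clusters)
    while len(test_idx) < n_test and len(remaining) > 1:
        # move the cluster least similar to everything outside it
        def outside_similarity(members):
            outside = sorted(
                set(range(len(labels))) - set(members) - set(test_idx)
            )
            return sim[np.ix_(members, outside)].max() if outside else np.inf

        best = min(remaining, key=lambda c: outside_similarity(remaining[c]))
        test_idx.extend(int(i) for i in remaining.pop(best))
    train = sorted(labels[i] for i in range(len(labels)) if i not in set(test_idx))
    test = sorted(labels[i] for i in test_idx)
    return SplitSpec(
        train=train, test=test, method="low_similarity",
        similarity_matrix=sim, labels=labels,
    )


# ---------------------------------------------------------------------------
# harnesses


def _fingerprint(state: ModelState) -> str:
    h = hashlib.sha1()
    for k in sorted(state.params):
        h.update(k.encode())
        h.update(state.params[k].data.tobytes())
    for k in sorted(state.bn_running):
        h.update(state.bn_running[k].tobytes())
    return h.hexdigest()


def sample_test_tasks(
    dataset: SynergyDataset, cell_lines, K: int, Q: int, n_tasks: int, rng
) -> list:
    """n_tasks K-shot tasks drawn from the given (meta-test) cell lines."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pool = {
        cl: s for cl, s in group_by_cell_line(dataset.samples).items()
        if cl in set(cell_lines)
    }
    tasks = []
    while len(tasks) < n_tasks:
        n = min(len(pool), n_tasks - len(tasks))
        episode = build_episode(pool, N=n, K=K, Q=Q, rng=rng)
        tasks.extend(episode.tasks)
    return tasks[:n_tasks]


def evaluate_fewshot(
    state: ModelState,
    dataset: SynergyDataset,
    split: SplitSpec,
    K: int,
    Q: int,
    n_tasks: int = 20,
    repeats: int = 20,
    seed: int = 0,
    threshold: float = 0.0,
    repeat_seeds=None,
    allow_untrained: bool = False,
    adapt: bool = True,
) -> MetricsReport:
    """Repeated few-shot evaluation on meta-test cell lines.

    Per repeat: sample ``n_tasks`` tasks, fine-tune on each support set
    (or predict zero-shot when ``adapt`` is false), pool the query
    predictions, compute one metrics row. The shared initialization must be
    restored between tasks; this is asserted by hashing the state.
    """
    if repeat_seeds is None:
        repeat_seeds = [int(s.generate_state(1)[0] % 2**31)
                        for s in np.random.SeedSequence(seed).spawn(repeats)]
    if len(repeat_seeds) != repeats:
        raise ValueError("repeat_seeds must have one entry per repeat")
    before = _fingerprint(state)
    report = MetricsReport(n_tasks=n_tasks, n_repeats=repeats)
    for r, rs in enumerate(repeat_seeds):
        tasks = sample_test_tasks(dataset, split.test, K, Q, n_tasks, rs)
        y_true, y_pred = [], []
        for task in tasks:
            if adapt:
                pred, _ = fine_tune(
                    task, state, dataset.graphs, dataset.grids,
                    allow_untrained=allow_untrained,
                )
            else:
                pred = zero_shot_predict(task, state, dataset.graphs, dataset.grids)
            if _fingerprint(state) != before:
                raise AssertionError(
                    "shared initialization was mutated during evaluation"
                )
            y_true.extend(s.y for s in task.query)
            y_pred.extend(pred)
        row = compute_metrics(np.array(y_true), np.array(y_pred), threshold)
        row["repeat"] = r
        report.rows.append(row)
    return report


def per_cellline_analysis(
    state: ModelState,
    dataset: SynergyDataset,
    split: SplitSpec,
    K: int,
    Q: int,
    n_tasks_per_line: int = 20,
    seed: int = 0,
    dispersion: str = "range",
) -> tuple:
    """Per-meta-test-line mean task MSE vs. synergy-score dispersion.

    Returns ``(table, r, p)`` where r is the Pearson correlation between
    per-line MSE and per-line dispersion (score range by default, SD
    optionally). Lines with too few samples are excluded with a warning;
    the correlation is NaN-flagged when it is undefined (constant inputs).
    """
    if dispersion not in ("range", "sd"):
        raise ValueError("dispersion must be 'range' or 'sd'")
    pool = group_by_cell_line(dataset.samples)
    rows = []
    rng_master = np.random.SeedSequence(seed)
    for cl, child in zip(sorted(split.test), rng_master.spawn(len(split.test))):
        samples = pool.get(cl, [])
        if len({s.pair for s in samples}) < K + Q:
            warnings.warn(f"cell line {cl!r} has too few samples; excluded")
            continue
        rng = np.random.default_rng(child)
        mses = []
        for _ in range(n_tasks_per_line):
            episode = build_episode({cl: samples}, N=1, K=K, Q=Q, rng=rng)
            task = episode.tasks[0]
            pred, _ = fine_tune(task, state, dataset.graphs, dataset.grids)
            y = np.array([s.y for s in task.query])
            mses.append(float(np.mean((y - pred) ** 2)))
        ys = np.array([s.y for s in samples])
        disp = float(ys.max() - ys.min()) if dispersion == "range" else float(ys.std())
        rows.append({"cell_line": cl, "mse": float(np.mean(mses)), "dispersion": disp})
    table = pd.DataFrame(rows)
    if len(table) < 3 or table["mse"].std() == 0 or table["dispersion"].std() == 0:
        return table, float("nan"), float("nan")
    r, p = pearsonr(table["mse"], table["dispersion"])
    return table, float(r), float(p)


def run_ablation(
    dataset: SynergyDataset,
    split: SplitSpec,
    variants,
    model_config,
    settings: TrainSettings | None = None,
    seed: int = 0,
    K: int = 10,
    Q: int = 10,
    n_tasks: int = 20,
    repeats: int = 10,
) -> dict:
    """Train and evaluate the full model plus the requested ablations.

    Every variant trains with identical seeds and is evaluated on identical
    task samples, so differences are attributable to the variant alone.
    Returns {variant_name: MetricsReport} with the full model under
    ``"full"``.
    """
    known = {"no_ml", "no_ft", "no_so", "no_pt"}
    unknown = set(variants) - known
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}")
    settings = settings or TrainSettings()
    train_data = dataset.restricted_to(split.train)
    reports = {}
    eval_seeds = [int(s.generate_state(1)[0] % 2**31)
                  for s in np.random.SeedSequence(seed + 999).spawn(repeats)]
    for name in ["full", *variants]:
        ablation = "none" if name == "full" else name
        state, _ = run_training(
            train_data, model_config, settings, ablation=ablation, seed=seed
        )
        reports[name] = evaluate_fewshot(
            state, dataset, split, K=K, Q=Q, n_tasks=n_tasks, repeats=repeats,
            seed=seed, repeat_seeds=eval_seeds,
        )
    return reports
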