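"""Domain containers and text-format I/O.

Cell-line transcriptomes are handled as 30x30 grids over a fixed 900-gene
marker list; synergy observations are (drug pair, cell line, score) triples;
few-shot tasks bundle a support and a query set drawn from one cell line.

File formats are plain delimited text: an expression table (rows = cell
lines, columns = genes, header required), a marker list (one gene id per
line, exactly 900), a synergy table (drug_a, drug_b, cell_line, score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_SIDE = 30
N_MARKER_GENES = GRID_SIDE * GRID_SIDE  # 900


@dataclass
class ExpressionGrid:
    """One cell line's 900 marker-gene values arranged as a 30x30 matrix.

    ``grid[i, j]`` is the expression of ``gene_order[30*i + j]``.
    """

    cell_line_id: str
    grid: np.ndarray
    gene_order: list

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.shape != (GRID_SIDE, GRID_SIDE):
            raise ValueError(
                f"grid must be {GRID_SIDE}x{GRID_SIDE}, got {self.grid.shape}"
            )
        if len(self.gene_order) != N_MARKER_GENES:
            raise ValueError(f"gene_order must have {N_MARKER_GENES} entries")
        if len(set(self.gene_order)) != N_MARKER_GENES:
            raise ValueError("gene_order contains duplicates")

    def value_of(self, gene: str) -> float:
        k = self.gene_order.index(gene)
        return float(self.grid[k // GRID_SIDE, k % GRID_SIDE])


@dataclass(frozen=True)
class SynergySample:
    drug_a: str
    drug_b: str
    cell_line: str
    y: float

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValueError(f"drug pair must be distinct, got {self.drug_a} twice")
        if not np.isfinite(self.y):
            raise ValueError(f"synergy score must be finite, got {self.y}")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.drug_a, self.drug_b))


@dataclass
class FewShotTask:
    """K support samples and Q query samples from a single cell line."""

    cell_line: str
    support: list
    query: list

    def __post_init__(self):
        if not self.support or not self.query:
            raise ValueError("support and query must be nonempty")
        for s in list(self.support) + list(self.query):
            if s.cell_line != self.cell_line:
                raise ValueError(
                    f"sample cell line {s.cell_line!r} != task {self.cell_line!r}"
                )
        sup = {s.pair for s in self.support}
        qry = {s.pair for s in self.query}
        if sup & qry:
            raise ValueError("support and query share drug pairs")


@dataclass
class Episode:
    """One meta-iteration's batch of tasks from distinct cell lines."""

    tasks: list = field(default_factory=list)

    def __post_init__(self):
        if not self.tasks:
            raise ValueError("episode must contain at least one task")
        lines = [t.cell_line for t in self.tasks]
        if len(set(lines)) != len(lines):
            raise ValueError("cell lines within an episode must be distinct")


@dataclass
class SynergyDataset:
    """Drug graphs, cell-line grids and synergy samples, keyed by id."""

    graphs: dict  # drug_id -> MolecularGraph
    grids: dict  # cell_line_id -> ExpressionGrid
    samples: list  # of SynergySample

    def pool(self) -> dict:
        return group_by_cell_line(self.samples)

    def restricted_to(self, cell_lines) -> "SynergyDataset":
        keep = set(cell_lines)
        return SynergyDataset(
            graphs=self.graphs,
            grids={k: v for k, v in self.grids.items() if k in keep},
            samples=[s for s in self.samples if s.cell_line in keep],
        )


# ---------------------------------------------------------------------------
# grouping and I/O


def group_by_cell_line(samples) -> dict:
    pool: dict[str, list] = {}
    for s in samples:
        pool.setdefault(s.cell_line, []).append(s)
    return pool


def read_marker_list(path: str) -> list:
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    if len(genes) != N_MARKER_GENES:
        raise ValueError(
            f"marker list must contain {N_MARKER_GENES} genes, got {len(genes)}"
        )
    if len(set(genes)) != len(genes):
        raise ValueError("marker list contains duplicate gene ids")
    return genes


def read_expression_table(
    path: str, markers: list, standardize: bool = True, sep: str = "\t"
) -> dict:
    """Load cell-line profiles and arrange them on the marker-list grid.

    The table has cell lines as rows and genes as columns. Genes are
    per-gene standardized across cell lines (optional), then subset and
    ordered by the 900-gene marker list; listed genes missing from the table
    are filled with 0 (the post-standardization mean).
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if standardize:
        sd = df.std(axis=0, ddof=0).replace(0.0, 1.0)
        df = (df - df.mean(axis=0)) / sd
    values = np.zeros((df.shape[0], N_MARKER_GENES))
    present = [g for g in markers if g in df.columns]
    idx = {g: k for k, g in enumerate(markers)}
    sub = df[present].to_numpy(dtype=np.float64)
    for j, g in enumerate(present):
        values[:, idx[g]] = sub[:, j]
    return {
        str(cl): ExpressionGrid(
            cell_line_id=str(cl),
            grid=values[i].reshape(GRID_SIDE, GRID_SIDE),
            gene_order=list(markers),
        )
        for i, cl in enumerate(df.index)
    }


def read_synergy_table(path: str, sep: str = "\t") -> list:
    df = pd.read_csv(path, sep=sep)
    required = {"drug_a", "drug_b", "cell_line", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"synergy table needs columns {sorted(required)}")
    return [
        SynergySample(str(r.drug_a), str(r.drug_b), str(r.cell_line), float(r.y))
        for r in df.itertuples()
    ]


def write_synergy_table(samples, path: str, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {"drug_a": s.drug_a, "drug_b": s.drug_b, "cell_line": s.cell_line, "y": s.y}
            for s in samples
        ]
    ).to_csv(path, sep=sep, index=False)
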