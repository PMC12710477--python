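"""Synthetic benchmark worlds: drugs, cell-line profiles, synergy landscapes.

The generator emulates the structure of real drug-combination screens
without any downloads. A world consists of

* a drug library of valid small-molecule graphs, built by combining ring or
  chain scaffolds with common substituents and parsing the result;
* per-cell-line latent factor vectors whose pairwise correlation is
  controlled by ``cellline_similarity``, read out linearly into 900
  marker-gene values on the 30x30 grid;
* synergy scores composed of a *shared* smooth symmetric function of the two
  drugs' descriptors and a *cell-specific* function whose coefficients
  depend on the cell line's latent factors, mixed by ``shared_weight``,
  optionally rescaled per line so score dispersion spans
  ``dispersion_range``, plus Gaussian observation noise; the world's scores
  are standardized to zero mean and unit variance.

Drug descriptors entering the ground-truth functions are projections of
graph-level summaries of the same atom features the graph encoder sees, so
the encoders have genuine signal to extract. All randomness flows from one
root seed through named substreams.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .chem import MolecularGraph, graph_from_smiles
from .data import (
    ExpressionGrid,
    GRID_SIDE,
    N_MARKER_GENES,
    SynergyDataset,
    SynergySample,
)

SCAFFOLDS = [
    "c1ccc({R})cc1",
    "c1ccnc({R})c1",
    "c1ccc2[nH]c({R})cc2c1",
    "c1ccc2ncc({R})cc2c1",
    "c1cnc({R})cn1",
    "c1csc({R})c1",
    "c1coc({R})c1",
    "C1CCC({R})CC1",
    "C1CCN({R})CC1",
    "C1CCOC1{R}",
    "O=C(N{R})c1ccccc1",
    "O=C(O{R})C1CCCC1",
    "N#Cc1ccc({R})cc1",
    "OCc1ccc({R})cc1",
    "CC(C)({R})c1ccccc1",
    "O=S(=O)(N)c1ccc({R})cc1",
    "Clc1ccc({R})cc1",
    "Fc1ccc({R})cn1",
    "CC1CCC({R})CC1",
    "O=C1CCCC1{R}",
]
SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "N(C)C", "F", "Cl",
    "Br", "C#N", "C(=O)O", "C(=O)OC", "C(=O)N", "CO", "CN", "C=C", "S", "SC",
    "CF", "CCl", "CCO", "CCN",
]


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Study conditions for one synthetic world."""

    n_drugs: int = 40
    n_cell_lines: int = 15
    samples_per_cell_line: int = 120
    shared_weight: float = 0.8  # weight of the cross-cell-line component
    cellline_similarity: float = 0.5  # pairwise correlation of latent factors
    noise_sd: float = 0.1  # observation noise, standardized-score units
    dispersion_range: tuple | None = (0.5, 1.5)  # per-line score SD bounds
    expression_noise_sd: float = 0.05  # gene-readout noise
    latent_dim: int = 32
    descriptor_dim: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 2:
            raise ValueError("need at least 2 drugs")
        if self.samples_per_cell_line > comb(self.n_drugs, 2):
            raise ValueError(
                "samples_per_cell_line exceeds the number of distinct drug pairs"
            )
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        for name in ("shared_weight", "cellline_similarity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion_range is not None:
            lo, hi = self.dispersion_range
            if not 0 < lo <= hi:
                raise ValueError("dispersion_range must be 0 < lo <= hi")


@dataclass
class SyntheticWorld:
    """A generated benchmark with its ground-truth machinery."""

    config: SyntheticWorldConfig
    smiles: list  # [(drug_id, smiles)]
    dataset: SynergyDataset
    factors: dict  # cell_line_id -> latent vector
    descriptors: dict  # drug_id -> descriptor vector phi
    per_line_sd: dict  # cell_line_id -> noiseless score SD
    truth: object = field(repr=False, default=None)  # callable (a, b, cell) -> float


def _substreams(seed: int, n: int):
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# drugs


def candidate_smiles():
    for scaffold, sub in itertools.product(SCAFFOLDS, SUBSTITUENTS):
        yield scaffold.replace("{R}", sub)


def generate_drug_library(cfg: SyntheticWorldConfig):
    """Deterministically sample ``n_drugs`` valid molecules.

    Returns ``(graphs, smiles)`` with drug ids D000, D001, ... Candidates
    that rdkit rejects are skipped; canonical-SMILES duplicates are merged.
    """
    from rdkit import Chem

    (rng,) = _substreams(cfg.seed, 1)
    pool = list(candidate_smiles())
    order = rng.permutation(len(pool))
    graphs, smiles, seen = [], [], set()
    for idx in order:
        smi = pool[idx]
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        drug_id = f"D{len(graphs):03d}"
        graphs.append(graph_from_smiles(canon, drug_id))
        smiles.append((drug_id, canon))
        if len(graphs) == cfg.n_drugs:
            return graphs, smiles
    raise ValueError(
        f"scaffold library exhausted at {len(graphs)} molecules, "
        f"cannot provide {cfg.n_drugs}"
    )


def graph_summary(graph: MolecularGraph) -> np.ndarray:
    """Graph-level summary the ground truth is built from: per-column mean
    of the 78 atom features plus size/connectivity terms."""
    feats = graph.node_features
    return np.concatenate(
        [feats.mean(axis=0), [graph.n_atoms / 20.0, graph.n_bonds / 20.0]]
    )


# ---------------------------------------------------------------------------
# cell lines


def generate_cell_profiles(cfg: SyntheticWorldConfig):
    """Latent factors with controlled pairwise correlation + grid readouts.

    Each cell line's factor is t_c = sqrt(rho) u0 + sqrt(1-rho) v_c with u0
    a common unit vector and v_c per-line unit vectors orthogonal to u0, so
    the expected pairwise correlation is the configured similarity. Gene
    values are a fixed linear readout of the factors plus readout noise.
    """
    rng_f, rng_l, rng_n = _substreams(cfg.seed + 1, 3)
    p, rho = cfg.latent_dim, cfg.cellline_similarity
    u0 = rng_f.normal(size=p)
    u0 /= np.linalg.norm(u0)
    factors = {}
    for i in range(cfg.n_cell_lines):
        v = rng_f.normal(size=p)
        v -= (v @ u0) * u0
        v /= np.linalg.norm(v)
        factors[f"CL{i:02d}"] = np.sqrt(rho) * u0 + np.sqrt(1.0 - rho) * v
    loadings = rng_l.normal(size=(N_MARKER_GENES, p)) / np.sqrt(p)
    gene_order = [f"G{k:04d}" for k in range(N_MARKER_GENES)]
    grids = {}
    for cl, t in factors.items():
        values = loadings @ t + cfg.expression_noise_sd * rng_n.normal(
            size=N_MARKER_GENES
        )
        grids[cl] = ExpressionGrid(
            cell_line_id=cl,
            grid=values.reshape(GRID_SIDE, GRID_SIDE),
            gene_order=gene_order,
        )
    return grids, factors


def mean_pairwise_factor_correlation(factors: dict) -> float:
    """Mean cosine similarity over all cell-line factor pairs."""
    mat = np.stack(list(factors.values()))
    mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    sim = mat @ mat.T
    iu = np.triu_indices(len(mat), k=1)
    return float(sim[iu].mean())


# ---------------------------------------------------------------------------
# synergy landscape


class _GroundTruth:
    """Noiseless standardized synergy function y(drug_a, drug_b, cell)."""

    def __init__(self, cfg, descriptors, factors, coef, line_scale, affine):
        self.cfg = cfg
        self.descriptors = descriptors
        self.factors = factors
        self.coef = coef
        self.line_scale = line_scale  # cell_line -> (center, scale)
        self.affine = affine  # (global_mean, global_sd)

    def signal(self, drug_a: str, drug_b: str, cell_line: str) -> float:
        cfg, c = self.cfg, self.coef
        pa, pb = self.descriptors[drug_a], self.descriptors[drug_b]
        u, v = pa + pb, pa * pb  # symmetric in the pair
        g_sh = np.tanh(u @ c["a_sh"] + v @ c["b_sh"])
        g_sh = (g_sh - c["sh_mu"]) / c["sh_sd"]
        t = self.factors[cell_line]
        g_cell = np.tanh(u @ (c["Pa"] @ t) + v @ (c["Pb"] @ t))
        g_cell = (g_cell - c["cell_mu"]) / c["cell_sd"]
        raw = cfg.shared_weight * g_sh + (1.0 - cfg.shared_weight) * g_cell
        center, scale = self.line_scale[cell_line]
        mu, sd = self.affine
        return float(((raw - center) * scale + center - mu) / sd)

    def __call__(self, drug_a, drug_b, cell_line):
        return self.signal(drug_a, drug_b, cell_line)


def generate_synergy(
    cfg: SyntheticWorldConfig, library, grids: dict, factors: dict
):
    """Sample drug pairs per cell line and score them.

    Returns ``(samples, descriptors, per_line_sd, truth)``. Scores are the
    shared + cell-specific mixture, per-line rescaled onto evenly spaced
    target SDs spanning ``dispersion_range`` (when set), globally
    standardized, with Gaussian observation noise added on the standardized
    scale.
    """
    rng_proj, rng_coef, rng_pairs, rng_noise = _substreams(cfg.seed + 2, 4)
    graphs = {g.drug_id: g for g in library}
    drug_ids = sorted(graphs)
    summaries = np.stack([graph_summary(graphs[d]) for d in drug_ids])
    proj = rng_proj.normal(size=(summaries.shape[1], cfg.descriptor_dim))
    phi = summaries @ proj
    phi = (phi - phi.mean(axis=0)) / np.where(phi.std(axis=0) == 0, 1, phi.std(axis=0))
    descriptors = {d: phi[i] for i, d in enumerate(drug_ids)}

    q, p = cfg.descriptor_dim, cfg.latent_dim
    coef = {
        "a_sh": rng_coef.normal(size=q) / np.sqrt(q),
        "b_sh": rng_coef.normal(size=q) / np.sqrt(q),
        "Pa": rng_coef.normal(size=(q, p)) / np.sqrt(p),
        "Pb": rng_coef.normal(size=(q, p)) / np.sqrt(p),
    }

    cell_lines = sorted(factors)
    all_pairs = list(itertools.combinations(range(len(drug_ids)), 2))
    chosen = {}  # cell_line -> list of (drug_a, drug_b)
    for cl in cell_lines:
        pick = rng_pairs.choice(len(all_pairs), cfg.samples_per_cell_line, replace=False)
        chosen[cl] = [(drug_ids[all_pairs[k][0]], drug_ids[all_pairs[k][1]]) for k in pick]

    # standardize the two components over the sampled world
    def raw_components(cl, a, b):
        pa, pb = descriptors[a], descriptors[b]
        u, v = pa + pb, pa * pb
        g_sh = np.tanh(u @ coef["a_sh"] + v @ coef["b_sh"])
        t = factors[cl]
        g_cell = np.tanh(u @ (coef["Pa"] @ t) + v @ (coef["Pb"] @ t))
        return g_sh, g_cell

    sh_vals, cell_vals = [], []
    for cl in cell_lines:
        for a, b in chosen[cl]:
            g_sh, g_cell = raw_components(cl, a, b)
            sh_vals.append(g_sh)
            cell_vals.append(g_cell)
    coef["sh_mu"], coef["sh_sd"] = np.mean(sh_vals), max(np.std(sh_vals), 1e-9)
    coef["cell_mu"], coef["cell_sd"] = np.mean(cell_vals), max(np.std(cell_vals), 1e-9)

    w = cfg.shared_weight
    raw = {
        cl: np.array(
            [
                w * (raw_components(cl, a, b)[0] - coef["sh_mu"]) / coef["sh_sd"]
                + (1 - w)
                * (raw_components(cl, a, b)[1] - coef["cell_mu"])
                / coef["cell_sd"]
                for a, b in chosen[cl]
            ]
        )
        for cl in cell_lines
    }

    line_scale = {}
    if cfg.dispersion_range is None:
        for cl in cell_lines:
            line_scale[cl] = (0.0, 1.0)
    else:
        lo, hi = cfg.dispersion_range
        targets = np.linspace(lo, hi, len(cell_lines))
        for cl, target in zip(cell_lines, targets):
            sd = max(raw[cl].std(), 1e-9)
            line_scale[cl] = (float(raw[cl].mean()), float(target / sd))

    scaled = {
        cl: (raw[cl] - line_scale[cl][0]) * line_scale[cl][1] + line_scale[cl][0]
        for cl in cell_lines
    }
    pooled = np.concatenate([scaled[cl] for cl in cell_lines])
    affine = (float(pooled.mean()), float(max(pooled.std(), 1e-9)))

    samples, per_line_sd = [], {}
    for cl in cell_lines:
        z = (scaled[cl] - affine[0]) / affine[1]
        per_line_sd[cl] = float(z.std())
        noise = cfg.noise_sd * rng_noise.normal(size=len(z))
        for (a, b), y in zip(chosen[cl], z + noise):
            samples.append(SynergySample(a, b, cl, float(y)))

    truth = _GroundTruth(cfg, descriptors, factors, coef, line_scale, affine)
    return samples, descriptors, per_line_sd, truth


def make_world(cfg: SyntheticWorldConfig | None = None, **overrides) -> SyntheticWorld:
    """Generate a complete world from one root seed."""
    if cfg is None:
        cfg = SyntheticWorldConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    library, smiles = generate_drug_library(cfg)
    grids, factors = generate_cell_profiles(cfg)
    samples, descriptors, per_line_sd, truth = generate_synergy(
        cfg, library, grids, factors
    )
    dataset = SynergyDataset(
        graphs={g.drug_id: g for g in library}, grids=grids, samples=samples
    )
    return SyntheticWorld(
        config=cfg,
        smiles=smiles,
        dataset=dataset,
        factors=factors,
        descriptors=descriptors,
        per_line_sd=per_line_sd,
        truth=truth,
    )


def write_world(world: SyntheticWorld, out_dir: str) -> dict:
    """Write drugs.smi, expression.tsv, markers.txt, synergy.tsv."""
    import os

    import pandas as pd

    from .data import write_synergy_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "drugs": os.path.join(out_dir, "drugs.smi"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "markers": os.path.join(out_dir, "markers.txt"),
        "synergy": os.path.join(out_dir, "synergy.tsv"),
    }
    with open(paths["drugs"], "w") as fh:
        for drug_id, smi in world.smiles:
            fh.write(f"{drug_id}\t{smi}\n")
    some_grid = next(iter(world.dataset.grids.values()))
    genes = some_grid.gene_order
    with open(paths["markers"], "w") as fh:
        fh.write("\n".join(genes) + "\n")
    rows = {
        cl: g.grid.ravel() for cl, g in sorted(world.dataset.grids.items())
    }
    pd.DataFrame.from_dict(rows, orient="index", columns=genes).to_csv(
        paths["expression"], sep="\t", index_label="cell_line"
    )
    write_synergy_table(world.dataset.samples, paths["synergy"])
    return paths
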