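# fewshot-synergy

Few-shot prediction of drug-combination synergy in cancer cell lines, for
computational pharmacologists working with data-scarce cellular contexts
(rare cancers, newly profiled lines). Synergy screens cover common cell
lines densely but rare ones with only a handful of measured drug pairs;
models trained per cell line do not transfer, and pooled models ignore the
cell-specific component of synergy. This package treats each cell line as a
regression *task* and meta-learns an initialization that adapts to a new
line from K labeled drug pairs.

## Model

A drug pair (d_A, d_B) in cell line c is embedded and scored as

    h_d  = max-pool over atoms of a 3-layer GCN on the molecular graph,
           h_u^(l) = ReLU( W^(l) Σ_{v∈N(u)∪{u}} e_{vu}/√(D̂_v D̂_u) · h_v^(l-1) )
    h_c  = CNN on the 30×30 grid of 900 marker-gene expression values,
           per layer Pool(ReLU(BN(W*h + b)))
    z    = concat( f_d(h_dA), f_d(h_dB), f_c(h_c) )
    ŷ    = ReLU(z W₁ + b₁) W₂ + b₂

with atom features a fixed 78-dimensional encoding (element symbol,
heavy-neighbor count, implicit valence, hydrogen count, aromaticity).
Parameters are partitioned into the embedding group θ_E (GCN, CNN,
integration) and the prediction head θ_p.

Training is stage-wise:

1. **Pretraining** on data-rich cell lines, minimizing ½Σ(ŷ−y)².
2. **Cross-tier meta-optimization.** Each episode samples N cell-line
   tasks with K-shot support and Q-shot query sets. The inner tier adapts
   *only the head*: θ'_j = (θ_E, θ_p − α∇_{θ_p} L_support). The outer tier
   updates the whole initialization through the inner step:
   θ ← θ − β ∇_θ Σ_j L_query(f_{θ'_j})  (second-order by default).
3. **Fine-tuning** on a new line's K support samples (same selective rule),
   then prediction on its query pairs.

Ablation flags reproduce the variant studies (`no_ml`, `no_ft`, `no_so`,
`no_pt`) and a zero-shot mode disables adaptation everywhere.

Because no GPU deep-learning stack is assumed, the networks run on a small
numpy reverse-mode autodiff core (`fewshot_synergy.autodiff`) that supports
differentiating through gradients, so the second-order meta-update is exact.

A synthetic benchmark generator (`fewshot_synergy.synthetic`) creates
worlds with a controllable shared-vs-cell-specific synergy mixture,
cell-line similarity, per-line score dispersion and observation noise, in
the same text formats the real-data path reads (SMILES/SDF drug files,
expression table + 900-gene marker list, synergy table).

## Worked example

```python
import fewshot_synergy as fs
from fewshot_synergy.evaluation import evaluate_fewshot, split_random
from fewshot_synergy.pipeline import TrainSettings, run_training

world = fs.make_world(fs.SyntheticWorldConfig(seed=11))   # 40 drugs, 15 lines
split = split_random(world.dataset.grids.keys(), 0.8, seed=11,
                     grids=world.dataset.grids)
state, logs = run_training(world.dataset.restricted_to(split.train),
                           fs.desk_config(),
                           TrainSettings(pretrain_epochs=20, episodes=300,
                                         outer_optimizer="adam"),
                           seed=11)
rep = evaluate_fewshot(state, world.dataset, split, K=10, Q=10,
                       n_tasks=10, repeats=20, seed=77)
print(f"10-shot query MSE {rep.mean('mse'):.3f} ± {rep.sd('mse'):.3f}")
rep0 = evaluate_fewshot(state, world.dataset, split, K=10, Q=10,
                        n_tasks=10, repeats=20, seed=77, adapt=False)
print(f"unadapted   MSE {rep0.mean('mse'):.3f} ± {rep0.sd('mse'):.3f}")
```

prints (scores are standardized to unit variance, so an MSE of 1.0 is the
level of a constant predictor):

```
10-shot query MSE 0.183 ± 0.022
unadapted   MSE 0.208 ± 0.021
```

i.e. on held-out cell lines the meta-trained model explains most of the
score variance, and ten support pairs per line buy a further ~12% error
reduction over the unadapted meta-model. A randomly initialized network
fine-tuned identically stays near MSE 1.07.

The same workflow is scriptable: `fewshot-synergy simulate|featurize|
pretrain|metatrain|finetune|evaluate --config run.yaml` (see
`fewshot-synergy --help`).

## Layout

- `src/fewshot_synergy/chem.py` — molecular graphs, 78-dim atom features
- `src/fewshot_synergy/model.py` — encoders, integration, head (θ_E/θ_p)
- `src/fewshot_synergy/meta.py` — pretraining, episodic meta-optimization,
  fine-tuning, zero-shot
- `src/fewshot_synergy/synthetic.py` — benchmark world generator
- `src/fewshot_synergy/evaluation.py` — metrics, splits, harnesses, ablations
- `src/fewshot_synergy/autodiff.py` — numpy reverse-mode autodiff core
- `docs/methods.md` — modeling assumptions, defaults, limitations
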