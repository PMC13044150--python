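# atlasfuse

Multi-atlas graph-transformer classification of brain functional-connectivity
networks, with attentional atlas fusion and an interpretability pipeline.

## The problem

Case/control classification from resting-state fMRI usually starts from a
single brain parcellation (atlas): ROI time series become a Pearson
functional-connectivity (FC) matrix, the subject's connectome. But any one
atlas is a single, arbitrary resolution of the cortex; coarse anatomical
and fine connectivity-driven parcellations carry complementary signal, and
models built on one of them inherit its blind spots. `atlasfuse`
implements a framework that

* builds, per subject and per atlas, a KNN-sparsified graph from the FC
  matrix (K = 15 by default, signed-correlation ranking, union
  symmetrization, FC row profiles as node features);
* encodes each graph with a **structure-aware graph transformer (SAT)**:
  dense multi-head attention whose queries/keys come from per-node k-hop
  subgraph GNN embeddings, so attention is biased by local topology while
  value aggregation stays global;
* fuses the per-atlas embeddings with **lightweight attentional feature
  fusion (LAFF)**: one shared learned scorer per atlas embedding,
  softmax-normalized to simplex weights, weighted sum — linear cost in the
  number of atlases, and the weights are directly interpretable;
* trains with AdamW, cosine-annealed learning rate, label-smoothed
  cross-entropy under **nested stratified cross-validation** (inner-loop
  grid search by AUC, leakage guard on every run), reporting
  ACC/SEN/SPE/AUC as mean ± sd over outer folds;
* reports **interpretability outputs**: per-subject-averaged atlas fusion
  weights, top-10 ROIs per atlas by received attention mass, cross-atlas
  overlap of top regions, and FDR-corrected (Benjamini–Hochberg, q < 0.05)
  Welch t-tests on FC edges among the top ROIs;
* ships a **synthetic multi-atlas cohort generator** with planted
  hypo-/hyper-connectivity between latent signal sources, expressed
  consistently across parcellations — the whole pipeline is testable
  end-to-end with no data downloads.

The neural network runs on a small NumPy reverse-mode autodiff engine
included in the package; everything is CPU-only and deterministic given a
seed. See `docs/methods.md` for the model, its assumptions, and all
numerical choices.

## Worked example

Generate a planted-effect cohort (three toy atlases, hypo-connectivity
between two latent sources in cases), run nested cross-validation, and
inspect what the model found:

```python
from atlasfuse.experiments import (
    run_recovery_experiment, toy_train_config,
)

result = run_recovery_experiment(seed=0, train_config=toy_train_config(seed=0, epochs=20))
agg = result.metrics.aggregate()
print({m: f"{mean:.3f} +- {sd:.3f}" for m, (mean, sd) in agg.items()})
print(result.recall_per_atlas)
print(result.laff_mean_weights)
```

prints (about three minutes on one CPU):

```
{'acc': '0.992 +- 0.017', 'sen': '1.000 +- 0.000', 'spe': '0.983 +- 0.033', 'auc': '1.000 +- 0.000'}
{'toyA20': 1.0, 'toyB34': 1.0, 'toyC42': 1.0}
{'toyA20': 0.191, 'toyB34': 0.174, 'toyC42': 0.636}
```

Reading this: the planted effect (coupling −0.4 between two latent
sources, noise sd 0.5, 60 cases vs 60 controls) is essentially fully
recovered by the classifier (mean outer-fold ACC 0.992, AUC 1.0). The
consensus top-10 attention ranking (attention averaged over the five
outer-fold models) contains every planted ROI in every atlas (recall
1.0), and the 42-ROI atlas — engineered to carry the strongest planted
signal (5+5 ROIs on the affected sources) — receives the dominant mean
fusion weight (0.64). The edge statistics on the consensus top-10 find
exactly the planted bridge pairs: 4, 9 and 25 significant edges for the
three atlases, matching the 2×2, 3×3 and 5×5 planted ROI crossings.

The same pipeline is available from the shell:

```bash
atlasfuse simulate --scenario recovery --out cohort/

cat > toy.yaml <<'YAML'   # the defaults (200 epochs, 10 folds) suit full-size
epochs: 20                # parcellations; scale down for the toy cohort
learning_rate: 0.003
fusion_warmup_frac: 0.5
outer_folds: 5
n_layers: 2
hidden_dim: 16
n_heads: 2
gnn_layers: 1
knn_k: 8
YAML

atlasfuse train --config toy.yaml --timeseries-dir cohort/ \
    --phenotype cohort/phenotype.csv \
    --atlases toyA20,toyB34,toyC42 --seed 0 --out run/
atlasfuse evaluate --model run/model.npz --timeseries-dir cohort/ \
    --phenotype cohort/phenotype.csv --atlases toyA20,toyB34,toyC42 --knn-k 8
```

`train` writes `metrics.json` (per-fold detail, fold hashes, chosen
hyperparameters), a model checkpoint, and the atlas/ROI attention tables.

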