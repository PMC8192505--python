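# agbt

Molecular-property prediction from fused algebraic-graph and
bidirectional-transformer fingerprints.

Quantitative structure–activity models live or die by their molecular
representation. This package implements a framework that combines two
complementary representations and is aimed at computational chemists
building QSAR models for toxicity, partition/solvation and
permeability endpoints:

- **AG-FP** — *algebraic-graph fingerprints*. A molecule's 3D structure
  is decomposed into element-specific weighted colored subgraphs: for
  each unordered element pair (E₁, E₂) the atoms of those elements form
  a graph whose edges connect non-covalent contacts,
  ‖**r**ᵢ − **r**ⱼ‖ > rᵢ + rⱼ + σ (rᵢ the covalent radii, σ the
  dataset-wide radius spread), weighted by a radial basis kernel
  Ψ(d; η) — generalized exponential exp(−(d/η)^κ) or Lorentz
  1/(1 + (d/η)^ν) — at several characteristic distances η. The
  fingerprint collects the five statistics (sum, min, max, mean, std)
  of the nontrivial eigenvalues of each subgraph Laplacian and the
  positive eigenvalues of each adjacency matrix. With 9 elements
  (45 pairs), 4 kernels and both matrices this yields 45·4·2·5 = 1800
  components. The geometric rigidity index RI = Σᵢ μᵢ, with
  μᵢ = Σⱼ Ψ(i, j), satisfies RI = Tr L exactly, tying the geometric and
  spectral descriptions together.
- **BT-FP** — *bidirectional-transformer fingerprints*. Canonical
  SMILES strings are split into chemical symbols, wrapped in
  `<s>`/`</s>`, corrupted by mask / random-change / keep operations,
  and a transformer encoder (up to 256 symbols, 512-dimensional
  embeddings) is pre-trained to recover the original symbols. Two
  fine-tuning regimes follow: self-supervised on the task's SMILES
  (mask/keep only → BT-FP) or supervised through per-task heads on
  all labeled datasets jointly (→ BTₛ-FP). The fingerprint is the
  top-layer vector at the leading `<s>` symbol.
- **AGBT-FP** — a random forest ranks the concatenated 1800 + 512
  features by importance on the training split and the top 512 form
  the fused fingerprint, which feeds downstream GBDT, RF, and
  single-/multi-task neural network models. Final predictions average
  an ensemble of 20 seed-varied models; regression is scored by
  squared-Pearson R², RMSE and MAE, classification by accuracy and
  AUC-ROC, over repeated 8:1:1 random splits or a Bemis–Murcko
  scaffold split.

The transformer encoder and the neural-network models are implemented
in NumPy with hand-written backprop (gradients are verified against
finite differences in the test suite); RDKit handles SMILES and SDF
chemistry, scikit-learn the forest and boosting models. A fixtures
module generates toy molecules with idealized 3D coordinates, SMILES
corpora and synthetic labels, so the whole pipeline runs without any
external download.

## Worked example

```python
import numpy as np
from agbt.fixtures import make_toy_molecules, make_synthetic_property
from agbt.algebraic_graph import ag_feature_matrix
from agbt.fusion import FeatureMatrix, rank_importance, select_top_k
from agbt.downstream import ModelSpec, evaluate, split_random, train_model

mols = make_toy_molecules(300, seed=21)
prop = make_synthetic_property(mols, "linear_in_ag", noise_sd=0.0, seed=21)

ag = ag_feature_matrix(mols)            # 300 x 1800 named AG features
print(ag.shape)

ids = [m.id for m in mols]
y = {i: prop.labels[i] for i in ids}
plan = split_random(ids, seed=0)        # 240 / 30 / 30

X = FeatureMatrix.from_dataframe(ag, tag="AG")
ranking = rank_importance(X.rows(plan.train),
                          [y[i] for i in plan.train], n_trees=100, rf_seed=0)
print(ranking.ranking[0])

sel = select_top_k(ranking, k=512, provenance=X.provenance)
model = train_model(ModelSpec("gbdt", tasks=["y"],
                              hyperparameters={"n_estimators": 300}),
                    X.rows(plan.train).data[sel.selected].to_numpy(),
                    {"y": np.array([y[i] for i in plan.train])})
pred = model.predict(X.rows(plan.test).data[sel.selected].to_numpy())["y"]
report = evaluate(pred, [y[i] for i in plan.test], "regression")
print(round(report.r_squared, 4), round(report.rmse, 4))
```

Output:

```
(300, 1800)
('AG::HH::lor-k3-e2::laplacian::min', np.float64(0.3585818592202797))
0.9999 0.0301
```

The labels were generated as a linear combination of the C–C and C–O
rigidity indices at η = 6 Å. Many AG components co-vary with those
rigidity indices on these toy molecules (here an H–H Laplacian
statistic tops the ranking — hydrogen count tracks carbon count in
alkane-like templates), and the boosted model on the selected features
recovers the property on held-out molecules almost exactly
(squared-Pearson R² ≈ 1, RMSE ≈ 0.03 in label units).

The same steps are available from the shell:

```bash
agbt fixtures --kind molecules --n 50 --seed 1 --out mols.sdf
agbt inspect --structures mols.sdf --format sdf
agbt featurize-ag --structures mols.sdf --format sdf --out ag.csv
agbt lm-pretrain --corpus corpus.smi --out ckpt/ --epochs 10
agbt featurize-bt --ckpt ckpt/ --smiles corpus.smi --out bt.csv
agbt fuse --ag ag.csv --bt bt.csv --labels y.csv --k 512 --out selector.json
```

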