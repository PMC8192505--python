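# Methods

This note records the models implemented by `agbt`, the defaults and
conventions chosen where the design was genuinely open, and what the
bundled synthetic data does and does not exercise.

## Algebraic-graph fingerprints

For a molecule with atoms (rᵢ, αᵢ) — position in Å, element label — and
each unordered element pair (E₁, E₂) from the configured element set, a
weighted colored subgraph is built on the atoms of those two elements.
An edge joins an E₁-atom to an E₂-atom when the pair is beyond covalent
contact,

    ‖rᵢ − rⱼ‖ > rᵢ + rⱼ + σ,

so the descriptors capture non-covalent (van der Waals-range)
interactions. Edge weights come from a fast-decaying radial basis
kernel, either generalized exponential Ψ(d) = exp(−(d/η)^κ) or
generalized Lorentz Ψ(d) = 1/(1 + (d/η)^ν). Both satisfy Ψ(0) = 1 and
decrease strictly in d; η (Å) sets the interaction scale.

Conventions adopted:

- **Covalent radii.** H 0.31, C 0.76, N 0.71, O 0.66, S 1.05, P 1.07,
  F 0.57, Cl 1.02, Br 1.20 Å (single-bond covalent radii). With these,
  the distance constraint reads "beyond covalent contact plus a
  dataset-dependent margin".
- **σ** is one scalar per dataset: the population standard deviation of
  the atomic radii over all atoms of all molecules. The defining phrase
  for σ admits per-pair readings; the dataset-wide scalar is the
  simplest consistent one and a fixed numeric override is available in
  the configuration (`sigma_mode: fixed`).
- **Kernel set (4).** exponential κ=2 and Lorentz ν=3, each at η = 2 Å
  and η = 6 Å. Two scales make the descriptor multiscale (covalent-range
  vs longer-range structure); with 9 elements (45 pairs), 2 matrix kinds
  and 5 statistics this reproduces the 1800-component fingerprint
  length. All of this is configurable.
- **Rigidity index.** RI = Σᵢ μᵢ with μᵢ = Σⱼ Ψ(i,j) summed over *all*
  subgraph vertices, so each undirected edge contributes at both
  endpoints. Read literally for E₁ ≠ E₂, a one-sided sum would count
  each edge once and the identity RI = Tr L could not hold together
  with a symmetric L; the symmetric convention satisfies both, and the
  identity is exact in floating point (it is asserted to 1e−12 relative
  in the tests).
- **Spectra.** The Laplacian has off-diagonal −Ψ(i,j) and zero row
  sums; it is positive semi-definite with one zero eigenvalue per
  connected component. "Nontrivial" eigenvalues are all eigenvalues
  above τ = 1e−10 · max(1, λ_max) — i.e. *all* zero modes are dropped,
  not just the first, because disconnected subgraphs are common and
  spurious zeros would encode numerical noise as features. Adjacency
  statistics use the positive eigenvalues. An empty selection (edgeless
  subgraph) maps to exact zeros so every molecule yields a full-length
  vector.
- **Eigensolver.** Dense symmetric decomposition (`numpy.linalg.eigvalsh`);
  element-pair subgraphs of small molecules have at most tens to a few
  hundred vertices, where dense is both exact and fast.

Because every quantity depends on interatomic distances only, the
fingerprint is invariant to rigid motion and atom reordering; this is a
tested property (≤ 1e−8 max abs difference), not an assumption.

## Bidirectional-transformer fingerprints

SMILES strings are canonicalized (RDKit) and split into chemical
symbols by greedy longest match: bracket atoms `[...]`, two-letter
halogens Cl/Br, single-letter and aromatic organic-subset atoms, bond
symbols, ring-closure digits and `%NN`, parentheses and the dot.
Concatenating the tokens reproduces the string exactly. Sequences are
wrapped in `<s>`/`</s>` and capped at 256 symbols including specials.

Masked-symbol training selects each non-special position independently
with rate 0.15 and applies mask (p = 0.8), random symbol replacement
(p = 0.1), or no change (p = 0.1); targets are recorded at every
selected position. Self-supervised fine-tuning restricts the operations
to mask (0.8) and keep (0.2). The selection rate and mix follow
established masked-LM convention; they are configuration, not
contract.

The encoder is a pre-LayerNorm transformer: token plus learned position
embeddings, multi-head self-attention and ReLU feed-forward blocks with
residual connections, a final LayerNorm, and a linear vocabulary head
for the masked objective. It is implemented directly in NumPy with
hand-written backprop; the gradients are validated against central
finite differences in the test suite, which makes the training loop
trustworthy without relying on an autodiff framework. Optimization is
Adam. Two presets exist: *full scale* (256 symbols, 512-dim
embeddings, 6 layers, 8 heads, feed-forward 2048) and *test scale*
(64-dim, 2 layers, 2 heads, feed-forward 128) used for desk-scale
training runs; all contracts are architecture-independent.

Supervised fine-tuning attaches one linear head per task to the `<s>`
vector and trains all labeled datasets jointly — squared error for
regression, logistic loss for classification, missing labels masked
out of the loss with uniform task weighting. Heads are discarded at
extraction time. The fingerprint of a molecule is the deterministic
(no dropout, no corruption) top-layer vector at the `<s>` position:
`bt` flavor after self-supervised stages, `bt_s` after supervised
fine-tuning.

Checkpoints are directories holding a JSON manifest (architecture,
vocabulary, stage, seed, corpus digest, training curve) and the
parameter arrays; loading reproduces fingerprints bit-for-bit.

## Feature fusion

AG and BT matrices are concatenated column-wise over an identical
molecule-id set, ranked by random-forest importance against the
training labels, and the top k = 512 names form the fused selector.
Conventions: mean impurity decrease (deterministic given the forest
seed; permutation importance available as an option), 500 trees by
default, ties broken lexicographically by feature name, k clamped to
the number of features. The selector is fitted on training rows only
and applied unchanged to validation and test rows; this train-only
discipline is asserted in the tests. Fitting the selection once per
dataset would leak test information into the feature choice, so
per-training-split fitting is the only default offered.

## Downstream models and evaluation

- Splits: uniform random 8:1:1 (the repeat protocol uses seeds 0–9),
  or a deterministic Bemis–Murcko scaffold split that assigns whole
  scaffold groups — largest first, ties by scaffold string — to train
  until ≥ 80 %, then validation until ≥ 10 %, remainder test. A
  dataset whose scaffolds cannot fill all three partitions is rejected
  as degenerate.
- Models: scikit-learn gradient boosting and random forests (500
  estimators, fixed seeds, no hyperparameter search); single-task and
  multitask feed-forward networks (shared ReLU trunk, default hidden
  sizes 1024/512, dropout 0.1, per-task linear heads, missing-label
  masking, uniform task weights). Network inputs are standardized and
  regression targets standardized internally for stable optimization;
  the validation split drives early stopping (the role of the
  validation set was otherwise unspecified).
- Consensus: 20 models differing only in seed (seeds 0–19);
  predictions are arithmetic means (probabilities for classification,
  thresholded at 0.5 afterwards).
- Metrics: R² is the *squared Pearson correlation* — invariant under
  positive affine transforms of the predictions — with the coefficient
  of determination also reported to avoid ambiguity; RMSE and MAE in
  label units; accuracy at 0.5 and rank-based AUC-ROC for
  classification. Zero-variance inputs are rejected rather than
  silently returning NaN.

## Synthetic data

The fixtures module generates everything the tests and the acceptance
script consume:

- **Toy molecules** sampled from 22 templates (alkanes up to pentane,
  branched isomers, alcohols, an ether, amines, halides, thiols, a
  trimethyl-phosphate, benzene) with idealized coordinates: tetrahedral
  109.47° frames and standard single-bond lengths for acyclic
  skeletons laid out in anti (zig-zag) torsion, a regular hexagon for
  the aromatic ring. Each sample receives ±0.05 Å coordinate jitter, a
  random rotation + translation, and a random atom-order permutation.
- **SMILES corpora** from a small grammar: heteroatom chains of length
  2–12, optional substituent branches, optional 5/6-rings.
- **Labels**: `linear_in_ag` (y = 1.0·RI_CC + 1.5·RI_CO at η = 6 Å,
  exponential κ = 2, dataset σ, plus Gaussian noise), `atom_count`
  (heavy atoms plus noise), and `binary_threshold` (median split of
  the linear score). Ground-truth coefficients are recorded so
  recovery tests can check them.

All generators are byte-reproducible given (n, seed). What this data
does *not* emulate: realistic conformational diversity (one idealized
conformer per template), charged or exotic chemistry, the size and
label distributions of real toxicity/solvation benchmarks, or a
web-scale pre-training corpus. Passing tests therefore demonstrate
correctness of the machinery — constraint handling, spectral
invariants, training dynamics, leakage-safe selection — not predictive
accuracy on real endpoints.

## Problem sizes

The test suite and acceptance script run the pipeline at desk scale,
chosen so every stage still exercises its contract: 50–300 toy
molecules for featurization and end-to-end recovery, 500-string corpora
and 15-epoch test-scale pre-training for the language model, 20 seeded
repetitions for the fusion recovery rate. Scaling up changes runtimes,
not code paths.

## Known limitations

- The kernel parameters, masking percentages and network depths have
  no single canonical setting; the defaults here are chosen to realize
  the framework's fixed representation sizes (1800 / 512 / 512) while
  following standard masked-LM practice, and everything is overridable
  in configuration.
- The NumPy encoder trains on CPU; pre-training at the
  million-molecule scale is out of scope, although the contracts
  (determinism, loss decrease, extraction) are scale-free.
- SDF output writes coordinates and element symbols only (no bond
  block); it round-trips this package's readers but is not a general
  SDF editor.
- Aromatic tokens beyond `b c n o p s` and stereo bond symbols are
  tokenized but the toy corpus exercises only a subset of them.
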