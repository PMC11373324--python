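# Methods

## Model

A molecule is represented from three views. The 1D view segments the
canonical SMILES with a ranked substructure vocabulary by greedy
longest-prefix matching (characters outside the vocabulary fall back to
single-character unknown tokens; the spans always reassemble the input
exactly). A Transformer encodes the token sequence from the sum of a
substructure embedding and a learned positional embedding. The 2D view is
the heavy-atom bond graph: a Graph Isomorphism Network with learnable ε and
bond-type embeddings produces atom vectors, which enter a Transformer with
degree embeddings added to the input and an additive per-head shortest-path
-distance (SPD) bias inside every attention softmax — one learned scalar per
(head, SPD bucket), buckets 0..spd_max plus a dedicated bucket for
unreachable pairs so multi-fragment species (salts) featurize. The 3D view
is the conformer: SchNet continuous-filter convolutions over
Gaussian-basis-expanded interatomic distances produce atom vectors, which
enter a Transformer with a learned embedding of each atom's distance-row sum
added to the input and a per-head learned projection of the Gaussian-basis
pairwise-distance features as the attention bias. Only interatomic distances
ever enter the 3D path, so all 3D outputs are rigid-motion invariant by
construction, and every graph readout is an arithmetic mean over atoms, so
pooled representations are invariant to atom reindexing.

Each encoder reports a local representation (middle Transformer layer for
1D; the graph-encoder output for 2D/3D) and a global one (final layer).
Augmented views are built by masking item attributes only: the items with
the highest received attention (final layer, averaged over heads and
queries) are replaced by a reserved MASK token/atom type, while bonds, SPD,
coordinates and distances are left untouched so the structural attention
biases remain valid. At least one item is always masked so a positive pair
is never an identical copy.

The contrastive objective treats all six views of a molecule as positives of
one another. For anchor i and positive j of molecule a, the term is
−log(w·exp(z_i·z_j) / Σ_o exp(z_i·z_o)) with the denominator running over
every embedding of the *other* molecules in the batch; same-molecule
positives are excluded from the denominator. The batch loss is the mean over
molecules of the per-molecule double sum, which keeps magnitudes independent
of batch size. The per-pair-type weight sits inside the logarithm as an
additive −log w (the typeset form); since that makes w a per-type offset
rather than a gradient scale, a SupCon-style multiplicative mode
(`weight_mode="outside"`) is provided as an alternative. Pair types are the
C(6,2) = 15 unordered view pairs. Weights follow dynamic weight averaging:
at each epoch boundary the ratio of a type's mean loss over the two most
recent epochs is softmaxed across types and scaled to sum to K; the first
two periods use unit weights, a vanishing previous loss maps to ratio 1, and
each level (local, global) keeps its own weight state since the two levels
learn at different speeds. The hierarchical loss is
λ_local·AMC(local) + λ_global·AMC(global) with λ = 1, 1.

The transfer representation is [mean(local₁d, global₁d);
mean(local₂d, global₂d)] ∈ R^{2h}: 3D geometry shapes the 1D/2D encoders
during pre-training, but no coordinates are needed at transfer time.
Fine-tuning uses a 2-layer feed-forward head with masked binary
cross-entropy (missing multi-task labels drop out of the loss), scaffold
splitting, validation-AUC model selection, and either full encoder updates
(`mode="full"`) or a frozen-encoder probe (`mode="probe"`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| hidden_dim h | 128 | encoder width; must divide by n_heads |
| n_layers L | 4 | Transformer blocks per encoder; local layer = ⌈L/2⌉ |
| n_heads | 8 | attention heads (head_dim = h/n_heads) |
| proj_dim | 64 | contrastive embedding size; z is L2-normalized by default |
| gin_layers / schnet_interactions | 3 / 3 | message-passing depth |
| spd_max | 20 | SPD clip for the bias table (raw values are kept on the graph) |
| n_kernel | 32 | Gaussian kernels, centers even on [0, 10] Å, width = spacing |
| sum_dist_max | 256 Å | kernel support for the distance-row-sum embedding |
| cutoff | 10 Å | SchNet neighborhood radius |
| mask_ratio r | 25 % | fraction of items masked per augmentation |
| batch_size / epochs | 8 / 10 | toy-scale pre-training loop |
| lr | 1e−4 | Adam step size |
| temperature | 1.0 | divides z_i·z_j (1.0 reproduces the plain exp form) |

The distance-row sum of a molecule with tens of atoms is far outside the
[0, 10] Å pairwise range, so its Gaussian embedding uses its own, wider
support ([0, 256] Å); with the shared pairwise kernels the feature would be
identically zero. The masking percentage is a declared default — it is not a
published value — and can be overridden per view.

## Synthetic data

The fixtures corpus is a curated pool of 156 small drug-like molecules
(2–26 heavy atoms, 43 Bemis–Murcko scaffolds, heteroatoms, fused rings, and
salts that exercise the unreachable-SPD path). Coordinates come from a
seeded ETKDG distance-geometry embedding with an MMFF relaxation, computed
at run time, so a fixture spec reproduces bit-identical inputs without
shipping conformer files; the rare embedding failure falls back to a seeded
random cloud to preserve determinism. The toy vocabulary is mined from the
pool itself (all single characters plus the most frequent multi-character
substrings), so fixture tokenization never hits the unknown token and
genuinely merges characters. Label rules ("contains nitrogen",
"contains ring", size-above-median) are test instruments: they are
deliberately decodable from composition so separability checks have a known
answer, and passing them says nothing about real pharmacological endpoints.
Likewise the corpus is orders of magnitude smaller than a real pre-training
set, conformers are single low-effort embeddings rather than ensembles, and
no conclusions about benchmark accuracy transfer from it.

## Numerical choices

Everything runs in float64 on a small tape-based reverse-mode autodiff
engine written on NumPy (Tensor ops: broadcast arithmetic, batched matmul,
softmax with the standard max-shift, reductions, gather/scatter for
embeddings). Gradients of every composite used by the encoders are checked
against central differences in the test suite. Transformer blocks are
pre-norm; feed-forward width is 2h; attention logits are scaled by
1/√head_dim before the additive bias. Molecules are processed one at a time
inside a batch (exact, no padding), while the contrastive loss is joint over
the batch. Masking ranks break ties by ascending index; scores come from the
attention maps recorded during the same step's original-view forward pass,
which equals an extra no-gradient pass at the current parameters. Mean
pooling, L2 normalization with an 1e−12 floor, and the closed-form stable
softplus keep all paths finite; with unnormalized projections the exp of raw
dot products is taken as written and is only intended for small-scale use.
Checkpoints store every parameter table keyed by module path plus a JSON
header (format version, config, vocabulary, DWA states, epoch, seed) and
round-trip bit-exactly.

## Design decisions

* Greedy longest-prefix vocabulary application: deterministic and
  independent of vocabulary file order; the vocabulary-mining step itself
  (frequency-based pair merging over a large corpus) is out of scope and a
  toy vocabulary ships instead.
* GIN and SchNet follow their canonical published update rules (GIN without
  batch normalization — there is no batch dimension in per-molecule
  forwards; SchNet with shifted-softplus and a hard 10 Å cutoff).
* Attention importance is *received* attention in the final layer, averaged
  over heads and queries; scores then sum to 1 over items.
* Scaffold splitting assigns largest groups first (ties by scaffold SMILES),
  to train until its fraction is filled, then validation, then test; the
  procedure is fully deterministic, and the seed argument is recorded only
  for interface stability.
* The 1D positional embedding is learned (table of 256 positions); ESPF
  operates on the parser's canonical SMILES.
* Per-layer (not shared) bias parameters in both graph Transformers.
* The ablation axes — no pre-training, global-only loss, no 3D view (K drops
  to 6), uniform-random masking, fixed unit weights — are first-class
  configuration switches so each variant runs on the toy corpus.

## Limitations

Pure-NumPy training is single-threaded and desk-scale; corpus sizes beyond
a few thousand molecules call for a GPU framework. The DWA weight enters the
as-written loss as an additive constant, so with `weight_mode="as_written"`
it shapes the reported objective and the weight bookkeeping but not the
gradients of z; the "outside" mode is the one that changes optimization.
Multi-fragment molecules rely on the unreachable-SPD bucket rather than any
fragment-aware pooling. The bundled conformers are single embeddings, not
Boltzmann ensembles, and the fixtures' labels are synthetic instruments, so
quantitative claims on real benchmarks require pre-training on a real corpus
first.
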