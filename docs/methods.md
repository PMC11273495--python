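# Methods

## Problem setting

The package predicts links in a bipartite miRNA–disease graph. Inputs are a
binary association matrix `A ∈ {0,1}^{km×kd}` and three homogeneous
similarity networks per entity type. Known associations are positives; an
equal number of negatives is drawn uniformly from the zero cells (curated
MDA databases record only confirmed links, so zeros are "unknown", not
verified negatives — the uniform draw treats them interchangeably).
Splitting is stratified by label everywhere (8:2 train/test, then stratified
K folds over the training pairs) so the 1:1 class balance survives in every
partition. Negative sampling happens once per experiment, before splitting.

## Similarity networks

Each measure is the standard literature form, kept behind its own function
so variants can be swapped:

- **GIP kernel** `K(i,j) = exp(−γ‖IP(i)−IP(j)‖²)` over binary interaction
  profiles, bandwidth `γ = 1 / mean‖IP‖²`. An all-zero matrix leaves γ
  undefined and raises.
- **Wang semantic similarity** over the disease ontology DAG: ancestor
  contributions decay by 0.5 per edge (best path), and
  `sim(a,b) = Σ_{t∈Ta∩Tb}(Sa(t)+Sb(t)) / (ΣSa + ΣSb)`.
- **MISIM functional similarity**: best-match average of disease semantic
  similarities between the two miRNAs' associated-disease sets.
- **Sequence similarity**: global alignment score (match 1, mismatch 0,
  gap 0; Biopython `PairwiseAligner`) normalised by the geometric mean of
  the self-alignment scores; `T` and `U` are equivalent.
- **Target similarity**: Jaccard index over gene sets; two empty sets
  score 0.

All views are symmetric with unit diagonal and entries in [0,1]. Entities
lacking raw data for a view get an identity row/column so matrices stay
well-formed and the view attention can down-weight them. Any view may be
supplied as a precomputed matrix instead.

## Association masking

Masking is a training-time augmentation on each similarity network,
resampled every epoch (a fixed-mask mode exists for reproducibility
studies). Start nodes ~ Bernoulli(p = 0.3); walks take k = 8 steps with
restart probability c = 0.6. The restart returns the walker to the *start*
node (not the current one), so high `c` concentrates path coverage on the
start's neighbourhood; restart events emit the start node into the path, so
paths always have k+1 entries. Coverage is the union of path outer products,
symmetrised so undirected graphs stay undirected. Two application modes are
exact complements of each other: `complement` (default) removes the covered
entries, `literal` keeps only them. The elementwise-product formulation of
the mask admits both readings; removal matches the stated purpose of
suppressing noisy connections, so it is the default, and the two modes
reconstruct the input exactly (`literal + complement = A`), which the tests
exploit.

## Encoders

**Multi-view GCN.** Each view has its own two-layer GCN with symmetric
normalisation over the self-looped adjacency. Two choices depart from the
textbook layer and exist for a measured reason: similarity networks are
dense and, after degree normalisation, nearly uniform, so pure neighbour
averaging collapses all node embeddings onto a common vector within two
layers (on the synthetic benchmark the collapse left ~5% node-specific
signal and the model could not beat a degree-only baseline). The encoder
therefore (1) uses the node's similarity profile — its row of the view
matrix — projected by a learned map as the input features, and (2) adds an
identity residual around every propagation layer. View fusion is a per-node
softmax over per-view scalar scores from a shared scoring vector: the
simplest mechanism that lets the model weight views by relevance, and it
keeps the fused embedding inside the per-view convex hull.

**Supernode hypergraph.** A bank of q learned supernodes (randomly
initialised rows, trained end-to-end) mediates cross-type information flow.
The hypergraph is realised as an ordinary weighted graph on km+kd+q nodes:
entity–supernode edges are ReLU-clipped cosine similarities (clipping keeps
the degree normalisation real-valued; zero-norm rows get weight 0),
miRNA–disease edges are training positives at weight 1, and there are no
within-type or supernode–supernode edges. Held-out pairs are asserted absent
at assembly time — the leakage guard is structural, not procedural.

**GCN-Transformer encoder.** Each of the two layers runs: residual GCN
sublayer → multi-head self-attention → residual + LayerNorm → position-wise
FFN → residual + LayerNorm. Attention logits get an additive shortest-path
bias. Hop distances are computed on the unweighted support of the current
adjacency (Dijkstra on the sparse support), capped at 8, with unreachable
pairs at the cap. The default bias is a learnable scalar per integer
distance, per layer and head, initialised at −0.5·d so nearer nodes start
with more attention; adding the raw hop count instead (mode `raw`) is also
available, but note it *increases* attention to distant nodes, which runs
against the locality motivation for the bias. Because every supernode links
to every entity node, most distances saturate at 2, and the learnable form
lets heads sharpen or ignore that coarse signal.

## Scoring and loss

Each entity's two representations (multi-view embedding, hypergraph encoder
output) are fused by a learned two-way softmax. The fused vectors pass a
shared single-channel 1-D convolution (kernel 3, same padding,
identity-initialised); the Hadamard product of the two convolved vectors
feeds a one-layer FNN with sigmoid. Zero FNN weights therefore score every
pair at exactly 0.5.

The objective is `L = α·L_Dice + (1−α)·L_CE` with α = 0.8. Dice
(`1 − 2Σyŷ/(Σy+Σŷ)`) is an overlap measure in [0,1], robust to class
imbalance; cross-entropy matches the score distribution and speeds
convergence. Numerical choices: CE clips scores to `[1e−7, 1−1e−7]` with a
straight-through gradient inside the interval; the Dice smoothing term
defaults to 0 (the plain formula), in which case an all-zero `Σy+Σŷ` is an
error; cosine norms carry an `1e−12` floor; LayerNorm uses eps `1e−5`.

## Training protocol

Full-batch Adam (lr 1e−3, no weight decay) on the training pairs; per epoch
the masks are resampled, the homogeneous views re-encoded, the hypergraph
re-assembled from training positives, and one DCE gradient step taken.
Every random stream (initialisation, dropout, per-epoch mask seeds, fold
seeds) derives from a single integer seed, so identical seeds give bitwise
identical loss trajectories and metric reports. A non-finite loss aborts
with the recent trajectory. Evaluation always uses unmasked views with
dropout off, and refuses pairs that appeared in training. Classification
metrics threshold at 0.5; AUC is the rank statistic, AUPRC the
precision–recall step integral.

Ablations map to config alone: `HGT-A` skips masking, `HGT-B` sets c = 0,
`HGT-C` drops the attention/FFN half of each encoder layer (plain GCN),
`HGT-D` sets α = 0 (plain BCE).

## Synthetic benchmark

The generator emulates the statistical shape of curated MDA data:
nonnegative latent factors `U (km×rank)`, `V (kd×rank)` are drawn, `A = 1`
where `UVᵀ` exceeds its 80th percentile (≈20% density, matching the
approximately low-rank structure assumed across the MDA literature), then
cells flip independently at rate 0.05. The three views per entity are cosine
similarities of the factors under independent Gaussian perturbations
(sd 0.1) — three noisy-but-redundant views, which is precisely the regime
the view attention and masking stages are meant to handle. Defaults:
km = 100, kd = 60, rank = 5, seed 7. The generator returns the ground-truth
factors; a logistic model on them separates held-out cells with AUC > 0.9,
so the benchmark is learnable before the main model is blamed.

What the fixture does **not** emulate: HMDD-like degree heavy-tails,
ontology-structured disease semantics, real sequence composition, or
verified-negative annotations. Passing here demonstrates that the pipeline
recovers planted multi-view low-rank structure at desk scale — not
real-data performance.

## Configuration scales

`ModelConfig()` defaults to the published operating point: 4 attention
heads, 2 GCN / encoder layers, FFN width 2048, mask ratio 0.3, restart 0.6,
max path length 8, 64 supernodes, dropout 0.5, α 0.8, 200 epochs.
`ModelConfig.desk_scale()` sizes the model for the bundled benchmark
(embedding 48, FFN 256, 32 supernodes, dropout 0.1, 400 epochs): roughly
proportional to the 100×60 fixture versus the 853×591 matrix the full-size
settings target, and it is what the tests and `scripts/acceptance.py` use.

## Known limitations

- Full-batch training with a dense (km+kd+q)² adjacency: fine to a few
  thousand nodes, not beyond.
- The restart-walk mask is recomputed per epoch in Python; at paper-scale
  dimensions this dominates epoch time.
- The literal-vs-complement ambiguity of the mask product and the raw
  distance bias are shipped as options rather than resolved; defaults follow
  the noise-suppression reading.
- Wang similarity assumes a DAG; cycles in the ontology input are an error,
  not repaired.
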