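# Methods

## Model

`pathvae` is a conditional variational autoencoder whose latent dimension
equals the number of pathways surviving the overlap filter of the knowledge
base. The generative story: a cell's state is a vector of pathway
activities $z$; expression is a linear read-out of those activities plus a
gene baseline and a batch-specific per-gene offset, observed with Gaussian
noise on the log-normalized scale.

- **Encoder.** One hidden layer (ReLU, width `hidden_width`, default 256)
  over the concatenation of the expression vector and a one-hot batch
  indicator, with separate linear heads for $\mu$ and $\log\sigma^2$. Under
  `mask_both` the encoder is instead a single linear layer masked by
  $\hat A^\top$ feeding both heads, so each latent unit only sees its
  pathway's genes.
- **Decoder.** A single linear map $x' = z\,w_D + \beta + o_b$. Linearity is
  essential to the interpretability claim: with any hidden layer, $w_D$
  entries would stop being gene–pathway contributions.
- **Objective.** Squared reconstruction error (summed over genes, averaged
  over cells) + `beta_kl` × closed-form KL to $N(0, I)$ + `lambda_k` ×
  knowledge term. The reported total always equals the sum of its reported
  components.

### The knowledge term

The default coupling is the elementwise **distance** form
$L_k = \lVert w_D - \hat A\rVert_2$ (or $\lVert\cdot\rVert_1$), which drives
annotated weights toward 1 and unannotated weights toward 0. The
Hadamard-product forms $\lVert w_D * \hat A\rVert_{1,2}$ are kept as the
`literal_hadamard_*` modes; note they *shrink* in-pathway weights rather
than anchoring them, so they act as a structured sparsity penalty, not a
prior-matching one. Hard masking trusts the knowledge base completely;
the distance form lets the decoder keep weights outside the prior when the
data demand it, which is what makes the "novel gene" readout of the ranking
tables possible. The penalty covers only $w_D$ — biases and batch offsets
are technical parameters with no pathway meaning.

### Batch correction

The batch enters twice: as an encoder covariate (so the posterior can
discount batch-driven expression shifts) and as a per-batch per-gene decoder
offset (so the decoder, not $z$, explains them). Multiplicative per-gene
batch factors become approximately additive offsets after log transformation,
which is exactly what the decoder offset absorbs. Nothing *forces* $z$ to be
batch-free; mixing emerges because the offsets remove the incentive to spend
latent capacity on batch, and the KL term penalizes spending it anyway.

## Optimization and numerics

Adam (lr 1e-3, default), minibatch 128, 500 epochs by default. The default
is sized for studies of a few hundred to a few thousand cells, where an
epoch is only a handful of minibatches; what matters for convergence is
total gradient steps, and 500 epochs on the 800-cell default study is ~3500
steps. Parameter init is Glorot-normal from a single seeded generator that
also drives minibatch shuffling and reparameterization noise, so `fit` is
bit-reproducible given `seed`. $\log\sigma^2$ is clamped to $[-10, 10]$ with
zero gradient outside; `l2` gradients are safeguarded at distance ~0 by an
epsilon in the norm; a non-finite loss aborts with epoch/minibatch context.

## Preprocessing

The standard recipe, in fixed order: filter cells (≥ `min_genes` expressed
genes, default 600, inclusive), filter genes (expressed in ≥ `min_cells`
cells, default 3), per-cell total normalization to the median total, natural
log1p, then dispersion-based HVG selection (mean-binned z-scored dispersion,
20 bins, scanpy's "seurat" flavor) keeping the top 2000 by default, ties
broken by input gene order. Raw counts are retained in a layer so count-level
perturbations stay integer-valued. HVGs are selected globally, not per
batch. The genome-scale defaults are inappropriate for the small simulated
studies used in tests (200 genes — `min_genes=600` would delete every cell),
so those runs use `min_genes=0, n_top_hvg=200`; the 6000-gene simulation
used to exercise the HVG contract runs the defaults unchanged.

## Knowledge prior

GMT lines are name, description, then gene symbols. Matching is
case-insensitive via uppercase canonicalization. Pathways overlapping the
expression gene universe in fewer than `min_overlap` genes (default 5,
inclusive) are dropped — a latent dimension driven by one or two genes is
noise, not a pathway. Genes in no pathway keep all-zero adjacency columns;
they still must be reconstructed, and they are exactly the candidates the
ranking tables can flag as novel pathway members.

## Metrics

ARI uses the hypergeometric contingency closed form; NMI normalizes mutual
information by the geometric mean of the entropies (log base cancels);
degenerate single-category labelings return 1 only when both partitions are
the trivial one. Cell-type ASW is $(1 + \bar s)/2$ with $\bar s$ the mean
per-cell silhouette (Euclidean; singleton clusters score 0). Isolated-label
F1 treats the types present in the fewest batches as isolated (all types, if
tied), clusters the embedding by seeded k-means over a grid of cluster
counts ($\max(2, T-2) \dots T+2$ for $T$ types), and for each isolated label
takes the best F1 of cluster membership as a predictor of the label, over
clusters and grid; the score is the mean over isolated labels. ARI/NMI in
`evaluate_all` compare cell-type labels against seeded k-means with $k$ =
number of types; the report records the clustering configuration so a graph
clustering could be substituted.

## Annotation

KNN label transfer: majority vote among the k = 15 (default) Euclidean
nearest reference cells, ties broken by smaller summed distance, then
lexicographic label order. No distance weighting. The confusion matrix is
reported with lexicographically sorted axes.

## Synthetic data

The generator emulates the intended regime: $T$ cell types whose identity is
a sparse program over $P$ pathways, $B$ batches with multiplicative
log-normal per-gene factors, negative-binomial counts. Defaults: $P=10$,
$G=200$, $T=4$, $B=2$, 15 genes per pathway (disjoint blocks over a random
gene permutation; 50 genes stay unannotated), 3 pathways per type (one
anchor pathway unique to each type plus random extras, activities
$U(0.8, 1.5)$), gene baselines $U(\log 0.5, \log 3)$, batch factor
$\sigma = 0.7$ (strong enough that batches visibly separate in raw data,
which is the premise integration addresses), shared NB dispersion 10, 100
cells per type per batch. Perturbations: binomial count thinning, uniform or
stratified cell subsampling, and a per-batch cell-type holdout plan.

What the generator does **not** emulate: dropout beyond NB sampling,
ambient RNA, doublets, trajectories/continuous states, batch-by-type
interactions, or nonlinear batch distortions. Passing tests therefore show
the machinery is correct and the model recovers the structure it assumes;
they do not certify performance on real atlases.

## Design choices that were genuinely open

- Distance vs Hadamard knowledge form: distance as default (it is the one
  that anchors weights at the prior), Hadamard kept as explicit modes.
- Gaussian likelihood on log-normalized data rather than a count likelihood:
  keeps the decoder linear-interpretable and gradients simple; NB/ZINB
  likelihoods are out of scope.
- Conditional-VAE batch mechanism (covariate + decoder offset) over
  adversarial or MNN-style correction: simplest mechanism consistent with a
  linear decoder.
- `lambda_k = beta_kl = 1`, no KL annealing; `min_overlap = 5`; k-means as
  the clustering behind label-based metrics; global (not per-batch) HVGs.
- Embedding = posterior mean (noise-free), not a sample.

## Limitations

Training is single-threaded NumPy: fine for tens of thousands of cells and
a few hundred HVGs, not for atlas-scale runs. The linear decoder cannot
express saturating or interacting gene programs. Metrics that need a
clustering inherit k-means' spherical bias. The literal Hadamard modes exist
for completeness and are not recommended as defaults.
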