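# pathvae

Knowledge-regularized variational autoencoder for integrating multi-batch
single-cell RNA-seq data into an **interpretable** latent space in which
every dimension is a biological pathway.

## The problem

Cells measured on different platforms or in different labs carry batch
effects that mask biology. Integration methods remove them, but most produce
latent spaces whose axes mean nothing. `pathvae` fixes the latent dimension
to a set of pathways from a gene-set knowledge base (a GMT collection such
as MSigDB or WikiPathways) and couples the decoder to the pathway–gene
adjacency, so the embedding doubles as a per-cell pathway-activity table and
the decoder weights read as gene contributions to pathways — including genes
the knowledge base did not annotate.

## The model

For a log-normalized expression vector $x$ with batch indicator $b$, an
encoder (one hidden layer; $b$ appended to the input) produces a posterior
$q(z \mid x, b) = N(\mu, \sigma^2)$ over $z \in \mathbb{R}^P$, one dimension
per pathway. A **single linear decoder** reconstructs
$x' = z\,w_D + \beta + o_b$ with per-gene bias $\beta$ and a learned
per-batch per-gene offset $o_b$ (conditional-VAE batch correction). Training
minimizes

$$L = \underbrace{\lVert x - x' \rVert^2}_{\text{reconstruction}}
    + \beta_{KL}\, D_{KL}\!\big(q(z \mid x,b)\,\Vert\, N(0, I)\big)
    + \lambda_k\, L_k ,$$

where the knowledge term $L_k$ ties the $P \times G$ decoder weight matrix
$w_D$ to the binary pathway–gene adjacency $\hat A$. Supported couplings:

| mode | $L_k$ | effect |
|---|---|---|
| `l2` (default) / `l1` | $\lVert w_D - \hat A \rVert_{2}$ / $\lVert w_D - \hat A \rVert_1$ | pulls annotated weights toward 1, others toward 0 |
| `literal_hadamard_l1` / `_l2` | $\lVert w_D * \hat A \rVert_{1,2}$ (Hadamard) | shrinks in-pathway weights |
| `mask_decoder` / `mask_both` | — | off-pathway weights structurally zero (decoder, or both) |
| `none` | — | plain conditional VAE |

The posterior mean $\mu$ is the cell embedding; its columns are pathway
activities, subsets of pathway columns are themselves valid embeddings, and
sorting a row of $w_D$ ranks genes by their contribution to that pathway.

Everything is NumPy with hand-written gradients and Adam — no deep-learning
framework required.

## Worked example

The package ships a generator for multi-batch counts with known pathway
programs, batch effects and cell types, so the whole pipeline runs
self-contained:

```bash
cat > demo.yaml <<EOF
outdir: demo
seed: 1
min_genes: 0      # fixture-scaled: the simulated study has 200 genes
n_top_hvg: 200
EOF
pathvae simulate   --config demo.yaml   # 2 batches x 4 types x 100 cells
pathvae preprocess --config demo.yaml
pathvae train      --config demo.yaml   # l2 knowledge coupling
pathvae integrate  --config demo.yaml
pathvae evaluate   --config demo.yaml
pathvae annotate   --config demo.yaml
```

prints

```
      metric    value
         ari 1.000000
         nmi 1.000000
asw_celltype 0.752285
 isolated_f1 1.000000
  silhouette 0.504569
transfer accuracy 1.000 (reference 'batch0')
```

ARI/NMI of 1 mean k-means on the embedding recovers the four simulated cell
types exactly; isolated-label F1 of 1 means the batch-specific type kept its
own cluster; the cell-type silhouette of 0.50 (ASW 0.75 after rescaling to
[0, 1]) shows types stay compact and separated after the batches are mixed;
and KNN label transfer across batches annotates every held-out cell
correctly. `pathvae interpret` additionally writes the per-cell pathway
activities and per-pathway gene rankings with an `in_prior` flag marking
genes absent from the knowledge base.

The same objects are available as a library (`pathvae.make_truth`,
`simulate_counts`, `run_pipeline`, `PathwayVAE`, `evaluate_all`,
`knn_transfer`, `rank_genes_for_pathway`, …); see `docs/methods.md` for the
model details and design choices.

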