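"""Knowledge-regularized variational autoencoder for batch integration.

The encoder maps a cell's log-normalized expression (plus a one-hot batch
indicator) to the posterior N(mu, sigma^2) over a latent space with one
dimension per pathway.  The decoder is a *single linear layer* whose P x G
weight matrix w_D is directly comparable to the pathway-gene adjacency A, so
its entries read as gene contributions to pathways.  Batch effects are
handled conditionally: the indicator enters the encoder input and a learned
per-batch per-gene offset is added in the decoder.

The training objective is

    L = reconstruction + beta_kl * KL(q(z|x) || N(0, I)) + lambda_k * L_k

where the knowledge term L_k ties w_D to A.  Several couplings are
supported: the elementwise L1/L2 *distance* ||w_D - A|| (default ``l2``),
the literal Hadamard-product norms ||w_D * A||_1 / ||w_D * A||_2, hard
masking of the decoder (and optionally the encoder) by the adjacency so
off-pathway weights are structurally zero, or no coupling at all.

Everything is plain NumPy with hand-written gradients and an Adam optimizer;
runs are deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .knowledge import PathwayGeneMatrix

__all__ = [
    "TrainConfig",
    "EncoderOutput",
    "PathwayVAE",
    "reparameterize",
    "kl_divergence",
    "reconstruction_loss",
    "knowledge_penalty",
    "total_loss",
]

KNOWLEDGE_MODES = (
    "l1",
    "l2",
    "mask_decoder",
    "mask_both",
    "none",
    "literal_hadamard_l1",
    "literal_hadamard_l2",
)


@dataclass
class TrainConfig:
    """Hyperparameters of the model and its optimizer.

    knowledge_mode
        How the pathway prior constrains the decoder (see module docstring).
    lambda_k, beta_kl
        Nonnegative weights of the knowledge and KL terms.
    hidden_width
        Width of the encoder's single hidden layer (ignored under
        ``mask_both``, where the encoder is a masked linear layer).
    """

    knowledge_mode: str = "l2"
    lambda_k: float = 1.0
    beta_kl: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 500
    minibatch_size: int = 128
    hidden_width: int = 256
    seed: int = 0
    logvar_min: float = -10.0
    logvar_max: float = 10.0

    def __post_init__(self) -> None:
        if self.knowledge_mode not in KNOWLEDGE_MODES:
            raise ValueError(
                f"unknown knowledge_mode {self.knowledge_mode!r}; "
                f"expected one of {KNOWLEDGE_MODES}"
            )
        if self.lambda_k < 0 or self.beta_kl < 0:
            raise ValueError("lambda_k and beta_kl must be nonnegative")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.logvar_min >= self.logvar_max:
            raise ValueError("logvar_min must be below logvar_max")

    def to_dict(self) -> dict:
        return asdict(self)


class EncoderOutput(NamedTuple):
    """Posterior parameters per cell: mean and log-variance, cells x P."""

    mu: np.ndarray
    log_var: np.ndarray


# ---------------------------------------------------------------------------
# loss primitives (pure functions, unit-testable in isolation)
# ---------------------------------------------------------------------------


def reparameterize(out: EncoderOutput, noise: np.ndarray) -> np.ndarray:
    """z = mu + exp(log_var / 2) * noise, with standard-normal noise."""
    return out.mu + np.exp(0.5 * out.log_var) * noise


def kl_divergence(out: EncoderOutput) -> float:
    """Closed-form KL( N(mu, sigma^2) || N(0, 1) ), summed over latent
    dimensions and averaged over cells:

        0.5 * sum(mu^2 + sigma^2 - log sigma^2 - 1)
    """
    mu, log_var = out
    per_cell = 0.5 * np.sum(mu**2 + np.exp(log_var) - log_var - 1.0, axis=1)
    return float(per_cell.mean())


def reconstruction_loss(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean over cells of the summed squared error over genes (Gaussian
    likelihood with unit variance, up to constants)."""
    if x.shape != x_prime.shape:
        raise ValueError("x and x' must have the same shape")
    return float(np.sum((x - x_prime) ** 2, axis=1).mean())


def knowledge_penalty(
    w: np.ndarray, adjacency: PathwayGeneMatrix | np.ndarray, mode: str
) -> float:
    """The knowledge coupling L_k between decoder weights and the prior.

    ``l1`` / ``l2``: elementwise distance sum|w - A| resp. sqrt(sum (w-A)^2).
    ``literal_hadamard_l1`` / ``literal_hadamard_l2``: ||w * A||_1 / ||w * A||_2
    with * the Hadamard product.  Mask modes and ``none`` contribute 0 (the
    mask constraint is enforced structurally in the forward pass).
    """
    A = adjacency.matrix if isinstance(adjacency, PathwayGeneMatrix) else adjacency
    w = np.asarray(w)
    if w.shape != A.shape:
        raise ValueError(
            f"decoder weight shape {w.shape} does not match adjacency {A.shape}"
        )
    if mode in ("none", "mask_decoder", "mask_both"):
        return 0.0
    if mode == "l1":
        return float(np.abs(w - A).sum())
    if mode == "l2":
        return float(np.sqrt(((w - A) ** 2).sum()))
    if mode == "literal_hadamard_l1":
        return float(np.abs(w * A).sum())
    if mode == "literal_hadamard_l2":
        return float(np.sqrt(((w * A) ** 2).sum()))
    raise ValueError(f"unknown knowledge_mode {mode!r}")


def _knowledge_grad(w: np.ndarray, A: np.ndarray, mode: str) -> np.ndarray:
    if mode == "l1":
        return np.sign(w - A)
    if mode == "l2":
        norm = np.sqrt(((w - A) ** 2).sum())
        return (w - A) / max(norm, 1e-12)
    if mode == "literal_hadamard_l1":
        return np.sign(w) * A
    if mode == "literal_hadamard_l2":
        masked = w * A
        norm = np.sqrt((masked**2).sum())
        return masked * A / max(norm, 1e-12)
    return np.zeros_like(w)


def total_loss(
    x: np.ndarray,
    x_prime: np.ndarray,
    out: EncoderOutput,
    w: np.ndarray,
    adjacency: PathwayGeneMatrix | np.ndarray,
    config: TrainConfig,
) -> dict[str, float]:
    """Assemble the training objective; components reported separately."""
    rec = reconstruction_loss(x, x_prime)
    kl = kl_divergence(out)
    know = knowledge_penalty(w, adjacency, config.knowledge_mode)
    return {
        "reconstruction": rec,
        "kl": kl,
        "knowledge": know,
        "total": rec + config.beta_kl * kl + config.lambda_k * know,
    }


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


def _as_dense(X) -> np.ndarray:
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    return np.ascontiguousarray(X, dtype=np.float64)


class _Adam:
    """Minimal Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


class PathwayVAE:
    """The knowledge-regularized VAE.

    Construct with a :class:`PathwayGeneMatrix` and a :class:`TrainConfig`,
    then :meth:`fit` on a preprocessed (log-normalized, HVG-restricted)
    ``AnnData`` whose gene order matches the adjacency.  :meth:`transform`
    returns the posterior means as the pathway-named cell embedding.
    """

    def __init__(self, adjacency: PathwayGeneMatrix, config: TrainConfig | None = None):
        self.adjacency = adjacency
        self.config = config or TrainConfig()
        self.gene_symbols = list(adjacency.gene_symbols)
        self.pathway_names = list(adjacency.pathway_names)
        self.batch_categories: list[str] = []
        self.params: dict[str, np.ndarray] = {}
        self.loss_history: list[dict[str, float]] = []

    # -- construction ------------------------------------------------------

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_names)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    @property
    def masked(self) -> bool:
        return self.config.knowledge_mode in ("mask_decoder", "mask_both")

    def _init_params(self, n_batches: int, rng: np.random.Generator) -> None:
        G, P, H = self.n_genes, self.n_pathways, self.config.hidden_width
        B = n_batches

        def glorot(fan_in, fan_out, shape):
            return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), shape)

        p: dict[str, np.ndarray] = {}
        if self.config.knowledge_mode == "mask_both":
            # single linear encoder masked by A^T, separate heads
            p["Em"] = glorot(G, P, (G, P))
            p["Ev"] = glorot(G, P, (G, P))
            p["Um"] = np.zeros((B, P))
            p["Uv"] = np.zeros((B, P))
        else:
            D = G + B
            p["W1"] = glorot(D, H, (D, H))
            p["b1"] = np.zeros(H)
            p["Wm"] = glorot(H, P, (H, P))
            p["Wv"] = glorot(H, P, (H, P))
        p["bm"] = np.zeros(P)
        p["bv"] = np.zeros(P)
        p["Wd"] = glorot(P, G, (P, G))
        p["bg"] = np.zeros(G)
        p["O"] = np.zeros((B, G))
        self.params = p

    # -- forward pieces ----------------------------------------------------

    def _onehot(self, batch_idx: np.ndarray) -> np.ndarray:
        B = len(self.batch_categories)
        oh = np.zeros((len(batch_idx), B))
        valid = batch_idx >= 0
        oh[np.arange(len(batch_idx))[valid], batch_idx[valid]] = 1.0
        return oh

    def _batch_index(self, batch_labels, allow_unseen: bool = False) -> np.ndarray:
        lookup = {b: i for i, b in enumerate(self.batch_categories)}
        idx = np.empty(len(batch_labels), dtype=np.int64)
        for i, b in enumerate(batch_labels):
            j = lookup.get(str(b), -1)
            if j < 0 and not allow_unseen:
                raise ValueError(
                    f"unseen batch category {b!r}; known: {self.batch_categories}"
                )
            idx[i] = j
        return idx

    def _effective_wd(self) -> np.ndarray:
        wd = self.params["Wd"]
        return wd * self.adjacency.matrix if self.masked else wd

    @property
    def decoder_weights(self) -> np.ndarray:
        """Effective P x G decoder weight matrix w_D (masked if applicable)."""
        return self._effective_wd()

    def _encode_arrays(self, x: np.ndarray, bidx: np.ndarray):
        p, cfg = self.params, self.config
        oh = self._onehot(bidx)
        if cfg.knowledge_mode == "mask_both":
            maskT = self.adjacency.matrix.T
            mu = x @ (p["Em"] * maskT) + oh @ p["Um"] + p["bm"]
            lv_raw = x @ (p["Ev"] * maskT) + oh @ p["Uv"] + p["bv"]
            cache = {"x": x, "oh": oh}
        else:
            xin = np.hstack([x, oh])
            h_pre = xin @ p["W1"] + p["b1"]
            h = np.maximum(h_pre, 0.0)
            mu = h @ p["Wm"] + p["bm"]
            lv_raw = h @ p["Wv"] + p["bv"]
            cache = {"xin": xin, "h": h, "h_pre": h_pre}
        lv = np.clip(lv_raw, cfg.logvar_min, cfg.logvar_max)
        cache["clip_mask"] = (lv_raw > cfg.logvar_min) & (lv_raw < cfg.logvar_max)
        return EncoderOutput(mu=mu, log_var=lv), cache

    def _check_genes(self, adata_or_genes) -> None:
        genes = (
            list(adata_or_genes.var_names)
            if isinstance(adata_or_genes, AnnData)
            else list(adata_or_genes)
        )
        if genes != self.gene_symbols:
            raise ValueError(
                "gene order of the input does not match the model's training "
                "gene order; reorder the matrix to the adjacency gene universe"
            )

    # -- public API --------------------------------------------------------

    def encode(self, X, batch_labels, genes=None,
               allow_unseen_batch: bool = False) -> EncoderOutput:
        """Posterior mu and log sigma^2 per cell (deterministic)."""
        if isinstance(X, AnnData):
            self._check_genes(X)
            batch_labels = (
                X.obs["batch"].astype(str).to_numpy()
                if batch_labels is None
                else batch_labels
            )
            X = X.X
        elif genes is not None:
            self._check_genes(genes)
        x = _as_dense(X)
        if x.shape[1] != self.n_genes:
            raise ValueError(
                f"input has {x.shape[1]} genes; model expects {self.n_genes}"
            )
        bidx = self._batch_index(batch_labels, allow_unseen_batch)
        out, _ = self._encode_arrays(x, bidx)
        return out

    def decode(self, z: np.ndarray, batch_labels,
               allow_unseen_batch: bool = False) -> np.ndarray:
        """Linear reconstruction x' = z w_D + gene bias + batch offset."""
        z = np.asarray(z, dtype=np.float64)
        bidx = self._batch_index(batch_labels, allow_unseen_batch)
        offs = np.where(bidx[:, None] >= 0, self.params["O"][bidx], 0.0)
        return z @ self._effective_wd() + self.params["bg"] + offs

    def transform(self, X, batch_labels=None,
                  allow_unseen_batch: bool = False) -> pd.DataFrame:
        """Noise-free cell embedding: posterior means, pathway-named columns."""
        index = (
            pd.Index(X.obs_names, name="cell_id")
            if isinstance(X, AnnData)
            else None
        )
        out = self.encode(X, batch_labels, allow_unseen_batch=allow_unseen_batch)
        return pd.DataFrame(out.mu, columns=self.pathway_names, index=index)

    # -- training ----------------------------------------------------------

    def fit(self, adata: AnnData, batch_key: str = "batch") -> "PathwayVAE":
        """Mini-batch stochastic-gradient training for ``config.epochs``.

        Deterministic given ``config.seed``: parameter init, shuffling and
        the reparameterization noise all draw from one seeded generator.
        """
        cfg = self.config
        self._check_genes(adata)
        if batch_key not in adata.obs:
            raise ValueError(f"obs[{batch_key!r}] not found")
        labels = adata.obs[batch_key].astype(str).to_numpy()
        self.batch_categories = sorted(set(labels))
        rng = np.random.default_rng(cfg.seed)
        self._init_params(len(self.batch_categories), rng)
        self.loss_history = []
        if cfg.epochs == 0:
            return self

        x_all = _as_dense(adata.X)
        bidx_all = self._batch_index(labels)
        n = x_all.shape[0]
        opt = _Adam(self.params, cfg.learning_rate)

        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            sums = {"reconstruction": 0.0, "kl": 0.0, "knowledge": 0.0,
                    "total": 0.0}
            for start in range(0, n, cfg.minibatch_size):
                take = order[start:start + cfg.minibatch_size]
                comps = self._train_step(
                    x_all[take], bidx_all[take], rng, opt
                )
                if not np.isfinite(comps["total"]):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, minibatch "
                        f"starting at {start}: {comps}"
                    )
                for k in sums:
                    sums[k] += comps[k] * len(take)
            self.loss_history.append(
                {"epoch": epoch, **{k: v / n for k, v in sums.items()}}
            )
        return self

    def _train_step(self, x, bidx, rng, opt) -> dict[str, float]:
        p, cfg = self.params, self.config
        A = self.adjacency.matrix
        nb = x.shape[0]

        out, cache = self._encode_arrays(x, bidx)
        mu, lv = out
        eps = rng.standard_normal(mu.shape)
        z = mu + np.exp(0.5 * lv) * eps
        wd_eff = self._effective_wd()
        oh = self._onehot(bidx)
        xp = z @ wd_eff + p["bg"] + oh @ p["O"]

        comps = total_loss(x, xp, out, wd_eff, A, cfg)

        # --- backward ---
        dxp = 2.0 * (xp - x) / nb                         # d recon / d x'
        grads: dict[str, np.ndarray] = {}
        dWd_eff = z.T @ dxp
        grads["bg"] = dxp.sum(axis=0)
        grads["O"] = oh.T @ dxp
        dz = dxp @ wd_eff.T

        dmu = dz.copy()
        dlv = dz * eps * 0.5 * np.exp(0.5 * lv)
        # KL term (averaged over cells)
        dmu += cfg.beta_kl * mu / nb
        dlv += cfg.beta_kl * 0.5 * (np.exp(lv) - 1.0) / nb
        dlv *= cache["clip_mask"]                          # clamp has zero grad

        if cfg.knowledge_mode == "mask_both":
            maskT = A.T
            grads["Em"] = (cache["x"].T @ dmu) * maskT
            grads["Ev"] = (cache["x"].T @ dlv) * maskT
            grads["Um"] = cache["oh"].T @ dmu
            grads["Uv"] = cache["oh"].T @ dlv
        else:
            h = cache["h"]
            grads["Wm"] = h.T @ dmu
            grads["Wv"] = h.T @ dlv
            dh = dmu @ p["Wm"].T + dlv @ p["Wv"].T
            dh *= cache["h_pre"] > 0
            grads["W1"] = cache["xin"].T @ dh
            grads["b1"] = dh.sum(axis=0)
        grads["bm"] = dmu.sum(axis=0)
        grads["bv"] = dlv.sum(axis=0)

        if self.masked:
            grads["Wd"] = dWd_eff * A
        else:
            grads["Wd"] = dWd_eff + cfg.lambda_k * _knowledge_grad(
                p["Wd"], A, cfg.knowledge_mode
            )
        opt.step(p, grads)
        return comps

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint (npz): parameters, config, axis labels."""
        meta = {
            "config": self.config.to_dict(),
            "pathway_names": self.pathway_names,
            "gene_symbols": self.gene_symbols,
            "batch_categories": self.batch_categories,
            "loss_history": self.loss_history,
        }
        np.savez(
            path,
            _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            _adjacency=self.adjacency.matrix,
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PathwayVAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            adjacency = PathwayGeneMatrix(
                matrix=data["_adjacency"],
                pathway_names=meta["pathway_names"],
                gene_symbols=meta["gene_symbols"],
            )
            model = cls(adjacency, TrainConfig(**meta["config"]))
            model.batch_categories = meta["batch_categories"]
            model.loss_history = meta["loss_history"]
            model.params = {
                k: data[k] for k in data.files if not k.startswith("_")
            }
        return model
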