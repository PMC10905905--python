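"""Descriptor-pseudo-label pre-training of the GIN encoder.

The encoder plus a one-layer auxiliary head (representation → q) are trained
jointly to predict each molecule's pseudo-label z with the
eigenvalue-weighted squared error

    L(z, ẑ) = (1/q) · Σ_j λ_j (z_j − ẑ_j)²,

where λ_j is the variance explained by the j-th principal component, so
directions of descriptor space carrying more variance weigh more. The
auxiliary head is discarded after pre-training; only the encoder weights
transfer to the yield model.

Defaults follow the reference recipe: 10 epochs of Adam, batch size 128,
learning rate 5e-4, weight decay 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._autodiff import Tensor
from .featurize import MolecularGraph
from .gin import GINConfig, GINParameters, GraphBatch, gin_encode, save_checkpoint, _affine_init
from .optim import Adam
from .pseudolabels import PseudoLabelSet


def pretrain_loss(z, z_hat, eigenvalues) -> float:
    """Eigenvalue-weighted squared error for one molecule (plain arrays)."""
    z = np.asarray(z, dtype=float)
    z_hat = np.asarray(z_hat, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    if not (z.shape == z_hat.shape == lam.shape):
        raise ValueError("z, z_hat and eigenvalues must have identical length q")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    q = z.size
    return float(np.sum(lam * (z - z_hat) ** 2) / q)


@dataclass
class PretrainConfig:
    epochs: int = 10
    batch_size: int = 128
    learning_rate: float = 5e-4
    weight_decay: float = 1e-5
    normalize_eigenvalues: bool = False  # λ/Σλ instead of raw λ (off by default)
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 0 or min(
            self.learning_rate, self.weight_decay
        ) < 0:
            raise ValueError("pretraining hyperparameters must be nonnegative")


class PretrainHead:
    """One affine output layer, representation_dim → q."""

    def __init__(self, representation_dim: int, q: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        W, b = _affine_init(rng, representation_dim, q)
        self.params = {
            "head.W": Tensor(W, requires_grad=True),
            "head.b": Tensor(b, requires_grad=True),
        }
        self.q = q

    def __call__(self, rep: Tensor) -> Tensor:
        return rep @ self.params["head.W"] + self.params["head.b"]


@dataclass
class PretrainResults:
    """Outcome of a pre-training run: trained encoder, head, loss curve."""

    gin: GINParameters
    head: PretrainHead
    config: PretrainConfig
    loss_history: list[float]       # mean weighted loss per epoch
    initial_loss: float             # mean weighted loss before any update
    eigenvalues: np.ndarray

    def save(self, path) -> None:
        """Checkpoint the encoder (the transferable part) plus provenance."""
        save_checkpoint(
            path,
            self.gin,
            extra_arrays={
                "head.W": self.head.params["head.W"].value,
                "head.b": self.head.params["head.b"].value,
                "eigenvalues": self.eigenvalues,
            },
            extra_manifest={
                "phase": "pretrain",
                "pretrain_config": asdict(self.config),
                "q": int(self.eigenvalues.size),
            },
        )

    def summary(self) -> str:
        lines = [
            "Descriptor-pseudo-label pre-training",
            "====================================",
            f"epochs: {self.config.epochs}   batch size: {self.config.batch_size}   "
            f"lr: {self.config.learning_rate}   weight decay: {self.config.weight_decay}",
            f"q (pseudo-label dim): {self.eigenvalues.size}",
            f"encoder parameters: {self.gin.count_parameters():,}",
            f"initial weighted loss: {self.initial_loss:.4f}",
        ]
        for i, l in enumerate(self.loss_history, 1):
            lines.append(f"epoch {i:3d}  mean weighted loss {l:.4f}")
        return "\n".join(lines)


class PretrainModel:
    """Joint encoder + auxiliary head model for the descriptor pre-text task.

    Parameters
    ----------
    graphs : molecules of the pre-training corpus, aligned with `labels`
    labels : pseudo-label set (PCA scores + eigenvalues) for the same molecules
    gin_config : encoder architecture; node/edge dims must match the graphs
    """

    def __init__(
        self,
        graphs: list[MolecularGraph],
        labels: PseudoLabelSet,
        gin_config: GINConfig,
        config: PretrainConfig | None = None,
    ):
        if len(graphs) != labels.labels.shape[0]:
            raise ValueError("graphs and labels must align one-to-one")
        self.graphs = graphs
        self.labels = labels
        self.gin_config = gin_config
        self.config = config or PretrainConfig()

    def _batch_loss(self, gin, head, batch, z, lam_t, stochastic, rng) -> Tensor:
        rep, _, _ = gin_encode(batch, gin, stochastic=stochastic, rng=rng)
        z_hat = head(rep)
        diff = z_hat - Tensor(z)
        weighted = diff.square() * lam_t  # (B, q) * (q,)
        return weighted.sum() * (1.0 / (z.shape[0] * z.shape[1]))

    def fit(self) -> PretrainResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        gin = GINParameters(self.gin_config, seed=cfg.seed)
        head = PretrainHead(self.gin_config.representation_dim, self.labels.q,
                            seed=cfg.seed + 1)
        lam = self.labels.eigenvalues.astype(float)
        if cfg.normalize_eigenvalues:
            lam = lam / lam.sum()
        lam_t = Tensor(lam)

        all_params = {**gin.params, **head.params}
        opt = Adam(all_params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        n = len(self.graphs)
        Z = self.labels.labels

        full_batch = GraphBatch.from_graphs(self.graphs)
        initial_loss = float(
            self._batch_loss(gin, head, full_batch, Z, lam_t, False, None).value
        )

        history: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = GraphBatch.from_graphs([self.graphs[i] for i in idx])
                loss = self._batch_loss(
                    gin, head, batch, Z[idx], lam_t,
                    self.gin_config.dropout_rate > 0, rng,
                )
                opt.zero_grad()
                loss.backward()
                for k, t in all_params.items():
                    t.grad = t.grad if t.grad is not None else np.zeros_like(t.value)
                opt.step()
                epoch_losses.append(float(loss.value) * len(idx))
            history.append(sum(epoch_losses) / n)

        return PretrainResults(
            gin=gin,
            head=head,
            config=cfg,
            loss_history=history,
            initial_loss=initial_loss,
            eigenvalues=lam,
        )
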