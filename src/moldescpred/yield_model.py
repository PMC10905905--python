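"""Reaction-yield prediction model with heteroscedastic loss and MC-dropout.

A reaction (R, P) — a *set* of m reactant graphs plus one product graph —
is encoded molecule-by-molecule with a shared GIN. Reactant representations
are sum-pooled (order invariance is forced by the set semantics),
concatenated with the product representation, and passed through a
two-layer head that outputs the predictive mean μ̂ and log-variance
log σ̂² of the yield; σ̂² = exp(log σ̂²) is positive by construction.

Training minimizes the mixed homoscedastic/heteroscedastic objective

    L(y, μ̂, σ̂²) = (1−α)(y−μ̂)² + α[(y−μ̂)²/σ̂² + log σ̂²],

with Adam, batch size 128, weight decay 1e-5 and a staged learning rate
(5e-4, dropping to 5e-5 at epoch 400 and 5e-6 at epoch 450 over 500
epochs). At inference, predictions average T = 30 stochastic forward passes
with dropout active (MC dropout); yields are standardized internally and
predictions inverted back to the percent scale.

API follows the model/results convention: build a :class:`YieldModel` from
reaction records, call :meth:`~YieldModel.fit`, and use the returned
:class:`YieldResults` for prediction, evaluation and the summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error

from ._autodiff import Tensor, prelu, gather, segment_sum, concat
from .featurize import MolecularGraph
from .gin import (
    GINConfig,
    GINParameters,
    GraphBatch,
    gin_encode,
    load_checkpoint,
    save_checkpoint,
    _affine_init,
)
from .optim import Adam


@dataclass
class ReactionRecord:
    """One training/evaluation example: m reactant graphs, a product graph, a yield."""

    reactants: list[MolecularGraph]
    product: MolecularGraph
    yield_value: float
    id: str = ""

    def __post_init__(self):
        if len(self.reactants) < 1:
            raise ValueError("a reaction needs at least one reactant")

    @property
    def m(self) -> int:
        return len(self.reactants)


@dataclass
class YieldPrediction:
    """Predictive mean and variance on the percent yield scale."""

    mean: float
    variance: float
    mc_samples: list[float] | None = None


@dataclass
class FinetuneConfig:
    alpha: float = 0.1
    epochs: int = 500
    batch_size: int = 128
    weight_decay: float = 1e-5
    learning_rate: float = 5e-4
    lr_schedule: tuple[tuple[int, float], ...] = ((400, 5e-5), (450, 5e-6))
    mc_passes: int = 30
    yield_scaling: str = "standardize"  # or "raw"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        epochs_at = [e for e, _ in self.lr_schedule]
        if epochs_at != sorted(epochs_at) or len(set(epochs_at)) != len(epochs_at):
            raise ValueError("lr_schedule epochs must be strictly increasing")
        if self.yield_scaling not in ("standardize", "raw"):
            raise ValueError("yield_scaling must be 'standardize' or 'raw'")

    def lr_at(self, epoch: int) -> float:
        lr = self.learning_rate
        for at, value in self.lr_schedule:
            if epoch >= at:
                lr = value
        return lr


def finetune_loss(y: float, mu_hat: float, sigma2_hat: float, alpha: float) -> float:
    """Mixed homoscedastic/heteroscedastic objective for one reaction."""
    if sigma2_hat <= 0:
        raise ValueError("predictive variance must be positive")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    sq = (y - mu_hat) ** 2
    return (1 - alpha) * sq + alpha * (sq / sigma2_hat + math.log(sigma2_hat))


class YieldHead:
    """Reaction-level prediction head.

    Sum-pooled reactant representation ⊕ product representation (2×rep_dim)
    → one hidden PReLU layer (rep_dim, with dropout) → (μ̂, log σ̂²).
    """

    def __init__(self, representation_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        W1, b1 = _affine_init(rng, 2 * representation_dim, representation_dim)
        W2, b2 = _affine_init(rng, representation_dim, 2)
        self.params = {
            "yhead.W1": Tensor(W1, requires_grad=True),
            "yhead.b1": Tensor(b1, requires_grad=True),
            "yhead.a1": Tensor(np.array(0.25), requires_grad=True),
            "yhead.W2": Tensor(W2, requires_grad=True),
            "yhead.b2": Tensor(b2, requires_grad=True),
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.value.copy() for k, t in self.params.items()}


@dataclass
class _ReactionBatch:
    graphs: GraphBatch
    reactant_rows: np.ndarray      # molecule-row indices of all reactants
    reactant_rids: np.ndarray      # reaction id per reactant row
    product_rows: np.ndarray       # one molecule-row index per reaction
    num_reactions: int

    @classmethod
    def from_records(cls, records: list[ReactionRecord]) -> "_ReactionBatch":
        mols: list[MolecularGraph] = []
        r_rows, r_rids, p_rows = [], [], []
        for rid, rec in enumerate(records):
            for g in rec.reactants:
                r_rows.append(len(mols))
                r_rids.append(rid)
                mols.append(g)
            p_rows.append(len(mols))
            mols.append(rec.product)
        return cls(
            graphs=GraphBatch.from_graphs(mols),
            reactant_rows=np.asarray(r_rows, dtype=np.intp),
            reactant_rids=np.asarray(r_rids, dtype=np.intp),
            product_rows=np.asarray(p_rows, dtype=np.intp),
            num_reactions=len(records),
        )


def _head_forward(batch: _ReactionBatch, gin: GINParameters, head: YieldHead,
                  stochastic: bool, rng) -> tuple[Tensor, Tensor]:
    """Return (mu, logvar) tensors of shape (num_reactions,) each."""
    reps, _, _ = gin_encode(batch.graphs, gin, stochastic=stochastic, rng=rng)
    reac = segment_sum(gather(reps, batch.reactant_rows), batch.reactant_rids,
                       batch.num_reactions)
    prod = gather(reps, batch.product_rows)
    x = concat([reac, prod], axis=1)
    p = head.params
    hid = prelu(x @ p["yhead.W1"] + p["yhead.b1"], p["yhead.a1"])
    if stochastic and gin.config.dropout_rate > 0:
        mask = (rng.random(hid.shape) >= gin.config.dropout_rate) / (
            1.0 - gin.config.dropout_rate
        )
        hid = hid * Tensor(mask)
    out = hid @ p["yhead.W2"] + p["yhead.b2"]
    # split columns: mu = out[:, 0], logvar = out[:, 1]
    col_mu = Tensor(np.array([[1.0], [0.0]]))
    col_lv = Tensor(np.array([[0.0], [1.0]]))
    return out @ col_mu, out @ col_lv


def yield_forward(
    reaction: ReactionRecord,
    gin: GINParameters,
    head: YieldHead,
    stochastic: bool = False,
    rng: np.random.Generator | None = None,
) -> YieldPrediction:
    """Single-reaction forward pass on the head's native (scaled) yield scale."""
    batch = _ReactionBatch.from_records([reaction])
    mu, logvar = _head_forward(batch, gin, head, stochastic, rng)
    return YieldPrediction(mean=float(mu.value[0, 0]),
                           variance=float(np.exp(logvar.value[0, 0])))


def initialize_from_pretrained(
    checkpoint_path,
    gin_config: GINConfig,
    head_init_seed: int = 0,
) -> tuple[GINParameters, YieldHead]:
    """Encoder weights from the pre-training checkpoint (bit-exact), fresh head.

    The auxiliary pre-training head stored in the checkpoint is deliberately
    not loaded — it serves only the pre-text task.
    """
    gin, _, _ = load_checkpoint(checkpoint_path, expected_config=gin_config)
    head = YieldHead(gin_config.representation_dim, seed=head_init_seed)
    return gin, head


def initialize_from_scratch(
    gin_config: GINConfig, seed: int = 0
) -> tuple[GINParameters, YieldHead]:
    """All weights random: the no-pre-training baseline."""
    return GINParameters(gin_config, seed=seed), YieldHead(
        gin_config.representation_dim, seed=seed + 1
    )


class YieldModel:
    """Reaction-yield regression model built from reaction records.

    Parameters
    ----------
    records : training reactions with yields on the percent scale
    gin_config : encoder architecture (node/edge dims must match the graphs)
    config : optimisation and inference settings
    init : optional (GINParameters, YieldHead) pair, e.g. from
        :func:`initialize_from_pretrained`; default is from-scratch.
    """

    def __init__(
        self,
        records: list[ReactionRecord],
        gin_config: GINConfig,
        config: FinetuneConfig | None = None,
        init: tuple[GINParameters, YieldHead] | None = None,
    ):
        if not records:
            raise ValueError("training set must be nonempty")
        self.records = records
        self.gin_config = gin_config
        self.config = config or FinetuneConfig()
        self._init = init

    def _loss(self, batch, y_scaled, gin, head, stochastic, rng) -> Tensor:
        mu, logvar = _head_forward(batch, gin, head, stochastic, rng)
        alpha = self.config.alpha
        yt = Tensor(y_scaled[:, None])
        sq = (yt - mu).square()
        inv_var = (-logvar).exp()
        per = sq * (1 - alpha) + (sq * inv_var + logvar) * alpha
        return per.mean()

    def fit(self) -> "YieldResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        if self._init is not None:
            gin, head = self._init
        else:
            gin, head = initialize_from_scratch(self.gin_config, seed=cfg.seed)

        y = np.array([r.yield_value for r in self.records], dtype=float)
        if cfg.yield_scaling == "standardize":
            y_mean, y_sd = float(y.mean()), float(y.std())
            y_sd = y_sd if y_sd > 0 else 1.0
        else:
            y_mean, y_sd = 0.0, 1.0
        y_scaled = (y - y_mean) / y_sd

        all_params = {**gin.params, **head.params}
        opt = Adam(all_params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        n = len(self.records)
        history: list[float] = []
        for epoch in range(cfg.epochs):
            opt.lr = cfg.lr_at(epoch)
            order = rng.permutation(n)
            total = 0.0
            for bi, start in enumerate(range(0, n, cfg.batch_size)):
                idx = order[start : start + cfg.batch_size]
                batch = _ReactionBatch.from_records([self.records[i] for i in idx])
                loss = self._loss(
                    batch, y_scaled[idx], gin, head,
                    self.gin_config.dropout_rate > 0, rng,
                )
                if not np.isfinite(loss.value):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {bi}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.value) * len(idx)
            history.append(total / n)

        return YieldResults(
            model=self, gin=gin, head=head, config=cfg,
            loss_history=history, yield_mean=y_mean, yield_sd=y_sd,
        )


@dataclass
class YieldResults:
    """Fitted yield model: parameters, training curve, prediction/evaluation."""

    model: "YieldModel | None"
    gin: GINParameters
    head: YieldHead
    config: FinetuneConfig
    loss_history: list[float]
    yield_mean: float
    yield_sd: float

    # -- inference -------------------------------------------------------

    def _invert(self, mu: np.ndarray, var: np.ndarray):
        return mu * self.yield_sd + self.yield_mean, var * self.yield_sd**2

    def predict(
        self,
        records: list[ReactionRecord],
        T: int | None = None,
        seed: int = 0,
    ) -> list[YieldPrediction]:
        """MC-dropout prediction: average of T stochastic forward passes.

        The final point prediction ŷ is the arithmetic mean of the per-pass
        predictive means; per-pass values are retained in ``mc_samples``.
        The reported variance is the mean per-pass σ̂² (an extension — the
        reference procedure averages only the means). With T=None the
        configured number of passes (default 30) is used; with
        dropout_rate=0 all passes coincide with the deterministic forward.
        """
        T = self.config.mc_passes if T is None else T
        if T < 1:
            raise ValueError("T must be >= 1")
        rng = np.random.default_rng(seed)
        batch = _ReactionBatch.from_records(records)
        stochastic = self.gin.config.dropout_rate > 0
        mus, vars_ = [], []
        for _ in range(T):
            mu_t, lv_t = _head_forward(batch, self.gin, self.head, stochastic, rng)
            mu, var = self._invert(mu_t.value[:, 0], np.exp(lv_t.value[:, 0]))
            mus.append(mu)
            vars_.append(var)
        mus = np.stack(mus)      # (T, n)
        vars_ = np.stack(vars_)
        return [
            YieldPrediction(
                mean=float(mus[:, i].mean()),
                variance=float(vars_[:, i].mean()),
                mc_samples=mus[:, i].tolist(),
            )
            for i in range(len(records))
        ]

    def predict_deterministic(self, records: list[ReactionRecord]) -> list[YieldPrediction]:
        batch = _ReactionBatch.from_records(records)
        mu_t, lv_t = _head_forward(batch, self.gin, self.head, False, None)
        mu, var = self._invert(mu_t.value[:, 0], np.exp(lv_t.value[:, 0]))
        return [YieldPrediction(float(m), float(v)) for m, v in zip(mu, var)]

    def evaluate(
        self, records: list[ReactionRecord], T: int | None = None, seed: int = 0
    ) -> tuple[float, float, float | None]:
        preds = self.predict(records, T=T, seed=seed)
        return evaluate(
            [p.mean for p in preds], [r.yield_value for r in records]
        )

    # -- persistence and reporting ----------------------------------------

    def save(self, path) -> None:
        save_checkpoint(
            path,
            self.gin,
            extra_arrays={**self.head.state_dict(),
                          "yield_mean": np.array(self.yield_mean),
                          "yield_sd": np.array(self.yield_sd)},
            extra_manifest={"phase": "finetune",
                            "finetune_config": _config_dict(self.config)},
        )

    @classmethod
    def load(cls, path) -> "YieldResults":
        gin, extra, manifest = load_checkpoint(path)
        cfg_raw = dict(manifest["finetune_config"])
        cfg_raw["lr_schedule"] = tuple(tuple(x) for x in cfg_raw["lr_schedule"])
        cfg = FinetuneConfig(**cfg_raw)
        head = YieldHead(gin.config.representation_dim)
        for k, t in head.params.items():
            t.value = np.asarray(extra[k], dtype=np.float64).copy()
        return cls(
            model=None, gin=gin, head=head, config=cfg, loss_history=[],
            yield_mean=float(extra["yield_mean"]), yield_sd=float(extra["yield_sd"]),
        )

    def summary(self) -> str:
        c = self.config
        lines = [
            "Reaction-yield model (GIN encoder + heteroscedastic head)",
            "=========================================================",
            f"alpha: {c.alpha}   epochs: {c.epochs}   batch size: {c.batch_size}",
            f"lr: {c.learning_rate} (schedule {c.lr_schedule})   "
            f"weight decay: {c.weight_decay}",
            f"MC-dropout passes: {c.mc_passes}   dropout rate: "
            f"{self.gin.config.dropout_rate}",
            f"encoder parameters: {self.gin.count_parameters():,}",
            f"yield scaling: {c.yield_scaling} "
            f"(mean {self.yield_mean:.2f}, sd {self.yield_sd:.2f})",
        ]
        if self.loss_history:
            lines.append(
                f"training loss: {self.loss_history[0]:.4f} (epoch 1) → "
                f"{self.loss_history[-1]:.4f} (epoch {len(self.loss_history)})"
            )
        return "\n".join(lines)


def _config_dict(cfg: FinetuneConfig) -> dict:
    d = asdict(cfg)
    d["lr_schedule"] = [list(x) for x in cfg.lr_schedule]
    return d


def evaluate(predictions, truths) -> tuple[float, float, float | None]:
    """(RMSE, MAE, R²); R² is None when the truths are constant (SST = 0)."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape or predictions.size < 2:
        raise ValueError("predictions and truths must have equal length >= 2")
    rmse = float(np.sqrt(mean_squared_error(truths, predictions)))
    mae = float(mean_absolute_error(truths, predictions))
    sst = float(((truths - truths.mean()) ** 2).sum())
    if sst == 0.0:
        return rmse, mae, None
    sse = float(((truths - predictions) ** 2).sum())
    return rmse, mae, 1.0 - sse / sst
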