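"""Self-contained experiment drivers on synthetic corpora.

These functions wire the full method together at desk scale: descriptor
computation → filtering/standardization → PCA pseudo-labels → encoder
pre-training → yield-model fine-tuning → MC-dropout evaluation. They are
used by the integration tests, the command-line pipeline and the
reproduction script. Network widths and epoch counts here are reduced from
the full-scale recipe (hidden 64 instead of 300, representation 128
instead of 1024, tens of epochs) so a complete transfer experiment runs on
one CPU in minutes; the architecture and procedure are otherwise
identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SyntheticSpec, generate_synthetic_corpus
from .descriptors import compute_descriptors, filter_and_standardize
from .featurize import FeatureSchema, featurize_molecule, featurize_reaction
from .gin import GINConfig
from .pretrain import PretrainConfig, PretrainModel
from .pseudolabels import fit_pca, make_pseudo_labels
from .yield_model import (
    FinetuneConfig,
    ReactionRecord,
    YieldHead,
    YieldModel,
    initialize_from_scratch,
)


def small_gin_config(schema: FeatureSchema | None = None, dropout_rate: float = 0.1) -> GINConfig:
    """Reduced-width encoder for desk-scale experiments (same architecture)."""
    schema = schema or FeatureSchema()
    return GINConfig(
        node_feature_dim=schema.node_feature_dim,
        edge_feature_dim=schema.edge_feature_dim,
        num_layers=3,
        hidden_dim=64,
        representation_dim=128,
        dropout_rate=dropout_rate,
    )


def build_pseudolabels(
    smiles: list[str],
    explained_variance: float = 0.70,
    q_override: int | None = None,
    missing_threshold: int = 10,
):
    """Descriptor pipeline on a molecule list.

    Returns (labeler, label_set, kept_smiles, filter_report); molecules
    excluded for residual missing descriptors drop out of the corpus.
    """
    matrix = compute_descriptors(smiles)
    std, report = filter_and_standardize(matrix, missing_threshold=missing_threshold)
    labeler = fit_pca(std, explained_variance_target=explained_variance, q_override=q_override)
    labels = make_pseudo_labels(labeler, std)
    kept = [smiles[int(mid[3:])] for mid in std.molecule_ids]  # ids are "mol{i}"
    return labeler, labels, kept, report


def records_from_rows(
    rows: list[tuple[str, float]], schema: FeatureSchema | None = None
) -> list[ReactionRecord]:
    schema = schema or FeatureSchema()
    records = []
    for i, (rxn, y) in enumerate(rows):
        reactants, product = featurize_reaction(rxn, schema)
        records.append(ReactionRecord(reactants, product, float(y), id=f"rxn{i}"))
    return records


@dataclass
class TransferRunResult:
    """One pre-trained-vs-from-scratch comparison on a synthetic split."""

    rmse_pretrained: float
    rmse_scratch: float
    mae_pretrained: float
    mae_scratch: float
    r2_pretrained: float | None
    r2_scratch: float | None
    pretrain_initial_loss: float
    pretrain_final_loss: float


def transfer_run(
    seed: int,
    n_molecules: int = 300,
    n_reactions: int = 200,
    n_train: int = 100,
    pretrain_epochs: int = 15,
    finetune_epochs: int = 60,
    explained_variance: float = 0.70,
    noise_sd: float = 3.0,
    mc_passes: int = 10,
) -> TransferRunResult:
    """Run the full method once at one seed and compare to no pre-training.

    The pre-training corpus is the synthetic molecule set; reactions with
    descriptor-driven yields are split n_train / rest. Both models share
    architecture, optimizer settings and epoch budget; only the encoder
    initialization differs.
    """
    schema = FeatureSchema()
    spec = SyntheticSpec(
        num_molecules=n_molecules, num_reactions=n_reactions,
        noise_sd=noise_sd, seed=seed,
    )
    smiles, rows = generate_synthetic_corpus(spec)

    labeler, labels, kept, _ = build_pseudolabels(smiles, explained_variance)
    graphs = [featurize_molecule(s, schema) for s in kept]

    gin_cfg = small_gin_config(schema)
    pre_cfg = PretrainConfig(epochs=pretrain_epochs, seed=seed)
    pre = PretrainModel(graphs, labels, gin_cfg, pre_cfg).fit()

    records = records_from_rows(rows, schema)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]

    ft_cfg = FinetuneConfig(epochs=finetune_epochs, mc_passes=mc_passes, seed=seed)
    # pre-trained init: copy of the pre-trained encoder weights, fresh head
    from .gin import GINParameters

    pre_gin = GINParameters(gin_cfg, params=pre.gin.state_dict())
    head = YieldHead(gin_cfg.representation_dim, seed=seed + 1)
    fitted_pre = YieldModel(train, gin_cfg, ft_cfg, init=(pre_gin, head)).fit()
    fitted_scratch = YieldModel(
        train, gin_cfg, ft_cfg, init=initialize_from_scratch(gin_cfg, seed=seed)
    ).fit()

    rmse_p, mae_p, r2_p = fitted_pre.evaluate(test, seed=seed)
    rmse_s, mae_s, r2_s = fitted_scratch.evaluate(test, seed=seed)
    return TransferRunResult(
        rmse_pretrained=rmse_p, rmse_scratch=rmse_s,
        mae_pretrained=mae_p, mae_scratch=mae_s,
        r2_pretrained=r2_p, r2_scratch=r2_s,
        pretrain_initial_loss=pre.initial_loss,
        pretrain_final_loss=pre.loss_history[-1],
    )


def pretraining_benefit(
    base_seed: int = 1,
    n_seeds: int = 5,
    **transfer_kwargs,
) -> dict:
    """Directional transfer experiment over several seeds.

    Returns per-seed RMSEs for pre-trained and from-scratch initialization
    plus the mean difference and a standardized effect size
    (mean RMSE decrease / SD of the per-seed differences).
    """
    runs = [transfer_run(base_seed + i, **transfer_kwargs) for i in range(n_seeds)]
    rmse_pre = np.array([r.rmse_pretrained for r in runs])
    rmse_scr = np.array([r.rmse_scratch for r in runs])
    diffs = rmse_scr - rmse_pre  # positive = pre-training helps
    sd = diffs.std(ddof=1) if n_seeds > 1 else float("nan")
    return {
        "rmse_pretrained": rmse_pre.tolist(),
        "rmse_scratch": rmse_scr.tolist(),
        "mean_rmse_pretrained": float(rmse_pre.mean()),
        "mean_rmse_scratch": float(rmse_scr.mean()),
        "mean_rmse_decrease": float(diffs.mean()),
        "effect_size": float(diffs.mean() / sd) if sd and np.isfinite(sd) and sd > 0 else float("nan"),
        "runs": runs,
    }
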