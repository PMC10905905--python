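"""Reaction-dataset loading, split protocols, and synthetic corpora.

The loader reads high-throughput-experimentation benchmark CSVs (reaction
SMILES "r1.r2...>>product" plus a numeric percent yield) through a column
map, so the same code adapts to different release headers. Splits cover the
random train/test ratios used in benchmark studies (70/30 down to 2.5/97.5)
and named out-of-sample partitions supplied as plain index files; published
shuffle files override internal shuffling when provided.

The synthetic generator builds small valid molecules from a fragment
grammar (alkyl chains, aromatic/aliphatic rings, halides, amines, ethers,
nitriles, boronic-acid-like groups) and assembles reactions whose yield is
a fixed smooth function of graph-level quantities of the participants
(heavy-atom counts, aromatic-ring content, heteroatom fraction) plus
optional noise. Because those quantities are themselves molecular
descriptors, descriptor-based pre-training is informative for the synthetic
task by construction — which is what makes the transfer experiments
self-contained. Optional heteroscedastic noise grows with molecule size to
exercise the variance head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, rdBase

from .featurize import (
    FeatureSchema,
    FeaturizationError,
    featurize_reaction,
    sanitized_mol,
)
from .yield_model import ReactionRecord


# -- benchmark CSV loading ----------------------------------------------


DEFAULT_COLUMN_MAP = {"reaction": "reaction_smiles", "yield": "yield"}


@dataclass
class RejectionReport:
    """Rows the loader could not turn into records, with reasons."""

    rejected: list[tuple[str, str]] = field(default_factory=list)  # (row id, reason)

    def __len__(self) -> int:
        return len(self.rejected)


def load_reaction_csv(
    path,
    column_map: dict | None = None,
    schema: FeatureSchema | None = None,
) -> tuple[list[ReactionRecord], RejectionReport]:
    """One :class:`ReactionRecord` per CSV row; failures go to the report."""
    column_map = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    schema = schema or FeatureSchema()
    df = pd.read_csv(path)
    for key in ("reaction", "yield"):
        if column_map[key] not in df.columns:
            raise KeyError(
                f"column {column_map[key]!r} (mapped from {key!r}) not in CSV; "
                f"available: {list(df.columns)}"
            )
    records: list[ReactionRecord] = []
    report = RejectionReport()
    for i, row in df.iterrows():
        rid = str(row[column_map["id"]]) if "id" in column_map and column_map["id"] in df.columns else f"row{i}"
        y = row[column_map["yield"]]
        if pd.isna(y):
            report.rejected.append((rid, "missing yield"))
            continue
        try:
            reactants, product = featurize_reaction(str(row[column_map["reaction"]]), schema)
        except FeaturizationError as err:
            report.rejected.append((rid, str(err)))
            continue
        records.append(
            ReactionRecord(reactants=reactants, product=product,
                           yield_value=float(y), id=rid)
        )
    return records, report


def write_reaction_csv(path, rows: list[tuple[str, float]], column_map: dict | None = None) -> None:
    """Write (reaction_smiles, yield) rows with the mapped column headers."""
    column_map = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    pd.DataFrame(
        {column_map["reaction"]: [r for r, _ in rows],
         column_map["yield"]: [y for _, y in rows]}
    ).to_csv(path, index=False)


# -- split protocols -----------------------------------------------------


RANDOM_TRAIN_FRACTIONS = (0.70, 0.50, 0.30, 0.20, 0.10, 0.05, 0.025)


@dataclass
class SplitSpec:
    kind: str = "random_ratio"          # or "out_of_sample"
    train_fraction: float = 0.70
    test_name: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("random_ratio", "out_of_sample"):
            raise ValueError(f"unknown split kind {self.kind!r}")
        if self.kind == "random_ratio" and not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


def make_split(
    num_records: int,
    spec: SplitSpec,
    shuffle_order: np.ndarray | None = None,
    out_of_sample_tests: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (train indices, test indices); disjoint and exhaustive.

    For random ratios, train size is floor(fraction × N). A published
    ``shuffle_order`` (a permutation of 0..N-1) overrides internal
    shuffling. For out-of-sample splits, the named test-index array from
    ``out_of_sample_tests`` defines the test set.
    """
    all_idx = np.arange(num_records)
    if spec.kind == "out_of_sample":
        available = sorted((out_of_sample_tests or {}).keys())
        if spec.test_name not in (out_of_sample_tests or {}):
            raise KeyError(
                f"unknown out-of-sample split {spec.test_name!r}; available: {available}"
            )
        test = np.asarray(sorted(out_of_sample_tests[spec.test_name]), dtype=int)
        train = np.setdiff1d(all_idx, test)
        return train, test
    if shuffle_order is not None:
        order = np.asarray(shuffle_order, dtype=int)
        if sorted(order.tolist()) != all_idx.tolist():
            raise ValueError("shuffle_order must be a permutation of 0..N-1")
    else:
        order = np.random.default_rng(spec.seed).permutation(num_records)
    n_train = math.floor(spec.train_fraction * num_records)
    return order[:n_train].copy(), order[n_train:].copy()


def read_index_file(path) -> np.ndarray:
    """Plain index list, one integer per line."""
    with open(path) as fh:
        return np.array([int(line) for line in fh if line.strip()], dtype=int)


# -- synthetic corpus ----------------------------------------------------


_CORES = [
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1",
    "C1CCCCC1", "C1CCCC1", "C1CCOC1",
]
_SUBSTITUENTS = [
    "O", "N", "Cl", "Br", "F", "I", "OC", "N(C)C", "C(=O)O", "C#N", "B(O)O",
    "C(=O)C", "S", "OCC",
]


@dataclass
class SyntheticSpec:
    num_molecules: int = 500
    max_heavy_atoms: int = 24
    num_reactions: int = 300
    m_min: int = 2
    m_max: int = 4
    noise_sd: float = 3.0
    heteroscedastic: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.m_min > self.m_max or self.m_min < 1:
            raise ValueError("need 1 <= m_min <= m_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _random_smiles(rng: np.random.Generator, max_heavy: int) -> str:
    """One molecule from the fragment grammar, guaranteed to sanitize."""
    with rdBase.BlockLogs():
        while True:
            parts = []
            if rng.random() < 0.6:
                parts.append(str(rng.choice(_CORES)))
            parts.append("C" * int(rng.integers(1, 6)))
            for _ in range(int(rng.integers(0, 3))):
                parts.append(str(rng.choice(_SUBSTITUENTS)))
            smi = "".join(parts)
            mol = Chem.MolFromSmiles(smi)
            if mol is not None and 1 <= mol.GetNumAtoms() <= max_heavy:
                return Chem.MolToSmiles(mol)


def _graph_covariates(smiles: str) -> tuple[float, float, float]:
    """(heavy atoms, aromatic fraction, heteroatom fraction) of one molecule."""
    mol = sanitized_mol(smiles)
    n = mol.GetNumAtoms()
    arom = sum(a.GetIsAromatic() for a in mol.GetAtoms()) / n
    het = sum(a.GetSymbol() != "C" for a in mol.GetAtoms()) / n
    return float(n), float(arom), float(het)


def synthetic_yield_function(reactant_smiles: list[str], product_smiles: str) -> float:
    """Noise-free yield g(·): a fixed smooth function of graph covariates.

    Larger, more aromatic products and less heteroatom-loaded reactants give
    higher yields; the logistic squashes into (0, 100). All inputs are
    computable both from the graphs and from standard 2D descriptors, so
    descriptor pseudo-labels carry signal for this target.
    """
    n_p, arom_p, het_p = _graph_covariates(product_smiles)
    covs = [_graph_covariates(s) for s in reactant_smiles]
    n_r = float(np.mean([c[0] for c in covs]))
    het_r = float(np.mean([c[2] for c in covs]))
    score = (
        0.35 * (n_p - 10.0) / 5.0
        + 1.2 * arom_p
        - 1.5 * het_r
        - 0.8 * het_p
        + 0.15 * (n_r - 8.0) / 4.0
    )
    return 100.0 / (1.0 + math.exp(-score))


def generate_synthetic_corpus(
    spec: SyntheticSpec,
) -> tuple[list[str], list[tuple[str, float]]]:
    """(SMILES list, reaction rows) for a fully self-contained test corpus.

    Reaction rows are (reaction SMILES, yield) pairs with yields
    g(participants) + noise, clamped to [0, 100]. With the heteroscedastic
    flag, the noise SD scales with mean participant size (SD multiplied by
    mean heavy atoms / 10), so larger reactions are noisier.
    """
    rng = np.random.default_rng(spec.seed)
    smiles = [_random_smiles(rng, spec.max_heavy_atoms) for _ in range(spec.num_molecules)]
    rows: list[tuple[str, float]] = []
    for _ in range(spec.num_reactions):
        m = int(rng.integers(spec.m_min, spec.m_max + 1))
        reactants = [smiles[i] for i in rng.integers(0, len(smiles), size=m)]
        product = smiles[int(rng.integers(0, len(smiles)))]
        y = synthetic_yield_function(reactants, product)
        if spec.noise_sd > 0:
            sd = spec.noise_sd
            if spec.heteroscedastic:
                sizes = [_graph_covariates(s)[0] for s in reactants + [product]]
                sd = spec.noise_sd * float(np.mean(sizes)) / 10.0
            y += rng.normal(0.0, sd)
        y = float(np.clip(y, 0.0, 100.0))
        rows.append((".".join(reactants) + ">>" + product, y))
    return smiles, rows
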