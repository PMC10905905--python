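"""2D molecular descriptor computation, filtering and standardization.

Descriptors are computed with RDKit's registered 2D descriptor set (no 3D
geometry is used or assumed). The cleaning pipeline mirrors the standard
large-corpus recipe: drop descriptors with more than a fixed number of
missing values, drop descriptors that are constant, exclude molecules with
residual missing entries, then standardize each remaining descriptor to
mean 0 / SD 1 using population statistics of the fitting set. The fitted
statistics are stored in a :class:`DescriptorFilterReport` so held-out
molecules can be transformed with training statistics, never refitted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors as _rd_descriptors
from rdkit import rdBase

from .featurize import sanitized_mol


def descriptor_names() -> list[str]:
    """Ordered names of the 2D descriptor reference set."""
    return [name for name, _ in _rd_descriptors.descList]


@dataclass
class DescriptorMatrix:
    """num_molecules × num_descriptors real matrix with NaN as the missing marker."""

    values: np.ndarray
    descriptor_names: list[str]
    molecule_ids: list[str]

    def __post_init__(self):
        if self.values.shape != (len(self.molecule_ids), len(self.descriptor_names)):
            raise ValueError("values shape inconsistent with names/ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.descriptor_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorMatrix":
        return cls(df.to_numpy(dtype=np.float64), list(df.columns), [str(i) for i in df.index])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="molecule_id")

    @classmethod
    def from_csv(cls, path) -> "DescriptorMatrix":
        return cls.from_frame(pd.read_csv(path, index_col="molecule_id"))


@dataclass
class DescriptorFilterReport:
    """Everything needed to replay filtering + standardization on new molecules."""

    dropped_missing: list[str]
    dropped_constant: list[str]
    dropped_molecules: list[str]
    retained_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    missing_threshold: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "dropped_missing": self.dropped_missing,
                "dropped_constant": self.dropped_constant,
                "dropped_molecules": self.dropped_molecules,
                "retained_names": self.retained_names,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "missing_threshold": self.missing_threshold,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DescriptorFilterReport":
        raw = json.loads(text)
        raw["means"] = np.asarray(raw["means"], dtype=np.float64)
        raw["sds"] = np.asarray(raw["sds"], dtype=np.float64)
        return cls(**raw)


def compute_descriptors(smiles_list, molecule_ids=None) -> DescriptorMatrix:
    """One descriptor row per molecule; non-computable entries are NaN.

    A molecule on which the descriptor engine fails entirely yields a full
    row of NaN plus a warning, matching the "mark missing, never silently
    zero" contract.
    """
    names = descriptor_names()
    if molecule_ids is None:
        molecule_ids = [f"mol{i}" for i in range(len(smiles_list))]
    rows = np.full((len(smiles_list), len(names)), np.nan)
    with rdBase.BlockLogs():
        for i, smi in enumerate(smiles_list):
            try:
                mol = sanitized_mol(smi)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vals = _rd_descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
                rows[i] = [vals[n] for n in names]
            except Exception:
                warnings.warn(f"descriptor computation failed for {smi!r}; row set to missing")
    # +/-inf (e.g. overflowed topological indices) counts as missing too
    rows[~np.isfinite(rows)] = np.nan
    return DescriptorMatrix(rows, names, list(molecule_ids))


def filter_and_standardize(
    matrix: DescriptorMatrix, missing_threshold: int = 10
) -> tuple[DescriptorMatrix, DescriptorFilterReport]:
    """Apply the fixed cleaning order: missing-excess → constant → molecule
    exclusion → standardization (population SD).

    The missing threshold is an absolute row count (a column is dropped when
    strictly more than `missing_threshold` entries are missing).
    """
    if matrix.values.size == 0:
        raise ValueError("empty descriptor matrix")
    X = matrix.values
    names = np.asarray(matrix.descriptor_names)

    n_missing = np.isnan(X).sum(axis=0)
    missing_mask = n_missing > missing_threshold
    dropped_missing = names[missing_mask].tolist()
    X = X[:, ~missing_mask]
    names = names[~missing_mask]

    def _is_constant(col: np.ndarray) -> bool:
        finite = col[~np.isnan(col)]
        return finite.size == 0 or bool(np.all(finite == finite[0]))

    constant_mask = np.array([_is_constant(X[:, j]) for j in range(X.shape[1])])
    dropped_constant = names[constant_mask].tolist()
    X = X[:, ~constant_mask]
    names = names[~constant_mask]

    if X.shape[1] == 0:
        raise ValueError("all descriptor columns were dropped; check inputs/threshold")

    row_missing = np.isnan(X).any(axis=1)
    ids = np.asarray(matrix.molecule_ids)
    dropped_molecules = ids[row_missing].tolist()
    X = X[~row_missing]
    kept_ids = ids[~row_missing].tolist()

    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population SD: fixed for reproducibility
    if np.any(sds == 0):
        # can only happen when molecule exclusion makes a column constant
        sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds

    report = DescriptorFilterReport(
        dropped_missing=dropped_missing,
        dropped_constant=dropped_constant,
        dropped_molecules=dropped_molecules,
        retained_names=names.tolist(),
        means=means,
        sds=sds,
        missing_threshold=missing_threshold,
    )
    return DescriptorMatrix(Z, names.tolist(), kept_ids), report


def apply_standardization(
    matrix: DescriptorMatrix, report: DescriptorFilterReport
) -> DescriptorMatrix:
    """Project a new matrix onto the retained columns and standardize with the
    stored training statistics. Never refits; molecules with missing retained
    entries are excluded (consistent with the fitting rule)."""
    df = matrix.to_frame()
    missing_cols = [n for n in report.retained_names if n not in df.columns]
    if missing_cols:
        raise KeyError(f"matrix lacks retained descriptor columns: {missing_cols[:5]} ...")
    sub = df[report.retained_names]
    keep = ~sub.isna().any(axis=1)
    Z = (sub[keep].to_numpy(dtype=np.float64) - report.means) / report.sds
    return DescriptorMatrix(Z, list(report.retained_names), [str(i) for i in sub.index[keep]])


def destandardize(matrix: DescriptorMatrix, report: DescriptorFilterReport) -> DescriptorMatrix:
    """Inverse of :func:`apply_standardization` on the retained columns."""
    X = matrix.values * report.sds + report.means
    return DescriptorMatrix(X, list(matrix.descriptor_names), list(matrix.molecule_ids))
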