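"""SMILES → molecular-graph featurization.

Molecules are encoded as heavy-atom graphs: one node per non-hydrogen atom
(hydrogens appear only as an adjacent-H count feature on their neighbour),
and each chemical bond stored as two directed edge rows so that message
passing can aggregate incoming edges with a plain segment sum.

Node features cover eleven atom properties (type, formal charge, degree,
hybridization, adjacent hydrogens, valence, chirality, ring sizes,
acceptor/donor, aromaticity, ring membership); edge features cover bond
type, stereochemistry, ring membership and conjugation. Categorical
properties are one-hot with an overflow bucket; the remainder are binary
flags. The encoding is fully determined by a serializable
:class:`FeatureSchema`, so featurization is reproducible across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


# Elements common to cross-coupling benchmark chemistry, plus catalytic and
# organometallic species; unseen elements fall into the trailing "other"
# bucket instead of failing.
DEFAULT_ATOM_VOCABULARY = [
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si",
    "Pd", "Fe", "Sn", "K", "Na", "Cs", "Li", "Mg", "Cu", "Zn",
]

_HYBRIDIZATIONS = ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2"]
_CHIRALITY = ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW"]
_BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
_BOND_STEREO = ["STEREONONE", "STEREOZ", "STEREOE", "STEREOCIS", "STEREOTRANS", "STEREOANY"]


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed vocabularies defining the node/edge encoding.

    Every categorical block is one-hot over ``categories + [other]``; ring-size
    membership (sizes 3–8) and the boolean properties are single binary columns.
    """

    atom_vocabulary: tuple[str, ...] = tuple(DEFAULT_ATOM_VOCABULARY)
    formal_charges: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    degrees: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    hybridizations: tuple[str, ...] = tuple(_HYBRIDIZATIONS)
    num_hs: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    valences: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    chirality: tuple[str, ...] = tuple(_CHIRALITY)
    ring_sizes: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    bond_types: tuple[str, ...] = tuple(_BOND_TYPES)
    bond_stereo: tuple[str, ...] = tuple(_BOND_STEREO)

    # -- dimensions ------------------------------------------------------

    @property
    def node_onehot_blocks(self) -> list[tuple[str, int]]:
        """Name and width of each one-hot block in a node row, in order."""
        return [
            ("atom_type", len(self.atom_vocabulary) + 1),
            ("formal_charge", len(self.formal_charges) + 1),
            ("degree", len(self.degrees) + 1),
            ("hybridization", len(self.hybridizations) + 1),
            ("num_hs", len(self.num_hs) + 1),
            ("valence", len(self.valences) + 1),
            ("chirality", len(self.chirality) + 1),
        ]

    @property
    def node_flag_names(self) -> list[str]:
        return [f"ring{r}" for r in self.ring_sizes] + [
            "acceptor", "donor", "aromatic", "in_ring",
        ]

    @property
    def edge_onehot_blocks(self) -> list[tuple[str, int]]:
        return [
            ("bond_type", len(self.bond_types) + 1),
            ("stereo", len(self.bond_stereo) + 1),
        ]

    @property
    def node_feature_dim(self) -> int:
        return sum(w for _, w in self.node_onehot_blocks) + len(self.node_flag_names)

    @property
    def edge_feature_dim(self) -> int:
        return sum(w for _, w in self.edge_onehot_blocks) + 2  # + in_ring, conjugated

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        raw = json.loads(text)
        return cls(**{k: tuple(v) for k, v in raw.items()})


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one molecule.

    ``edge_index`` has shape (num_directed_edges, 2) with rows (src, dst):
    each bond j–k contributes rows (j, k) and (k, j) carrying identical
    features, so incoming messages for node j are the rows with dst == j.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    smiles: str

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[0]


def _onehot(value, categories) -> list[float]:
    row = [0.0] * (len(categories) + 1)
    try:
        row[list(categories).index(value)] = 1.0
    except ValueError:
        row[-1] = 1.0  # overflow bucket
    return row


def _atom_row(atom: Chem.Atom, mol: Chem.Mol, schema: FeatureSchema) -> list[float]:
    ri = mol.GetRingInfo()
    row: list[float] = []
    row += _onehot(atom.GetSymbol(), schema.atom_vocabulary)
    row += _onehot(atom.GetFormalCharge(), schema.formal_charges)
    row += _onehot(atom.GetDegree(), schema.degrees)
    row += _onehot(str(atom.GetHybridization()), schema.hybridizations)
    row += _onehot(atom.GetTotalNumHs(), schema.num_hs)
    row += _onehot(atom.GetTotalValence(), schema.valences)
    row += _onehot(str(atom.GetChiralTag()), schema.chirality)
    idx = atom.GetIdx()
    row += [1.0 if ri.IsAtomInRingOfSize(idx, r) else 0.0 for r in schema.ring_sizes]
    # Pharmacophore-style lone-pair/H rules: N or O with a lone pair accepts,
    # N or O carrying a hydrogen donates. Positively charged N has no lone pair.
    sym = atom.GetSymbol()
    is_no = sym in ("N", "O")
    acceptor = is_no and atom.GetFormalCharge() <= 0
    donor = is_no and atom.GetTotalNumHs() > 0
    row += [1.0 if acceptor else 0.0, 1.0 if donor else 0.0]
    row += [1.0 if atom.GetIsAromatic() else 0.0, 1.0 if atom.IsInRing() else 0.0]
    return row


def _bond_row(bond: Chem.Bond, schema: FeatureSchema) -> list[float]:
    row: list[float] = []
    row += _onehot(str(bond.GetBondType()), schema.bond_types)
    row += _onehot(str(bond.GetStereo()), schema.bond_stereo)
    row += [1.0 if bond.IsInRing() else 0.0, 1.0 if bond.GetIsConjugated() else 0.0]
    return row


def sanitized_mol(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES string, raising FeaturizationError on failure."""
    mol = Chem.MolFromSmiles(smiles)  # sanitizes by default
    if mol is None:
        raise FeaturizationError(f"SMILES failed to parse or sanitize: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise FeaturizationError(f"SMILES contains no heavy atoms: {smiles!r}")
    return mol


def featurize_molecule(smiles: str, schema: FeatureSchema | None = None) -> MolecularGraph:
    """Encode one molecule as a :class:`MolecularGraph`."""
    schema = schema or FeatureSchema()
    mol = sanitized_mol(smiles)

    nodes = np.array([_atom_row(a, mol, schema) for a in mol.GetAtoms()], dtype=np.float64)
    edges: list[tuple[int, int]] = []
    feats: list[list[float]] = []
    for bond in mol.GetBonds():
        j, k = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        row = _bond_row(bond, schema)
        edges += [(j, k), (k, j)]
        feats += [row, row]
    edge_index = (
        np.array(edges, dtype=np.intp) if edges else np.zeros((0, 2), dtype=np.intp)
    )
    edge_features = (
        np.array(feats, dtype=np.float64)
        if feats
        else np.zeros((0, schema.edge_feature_dim), dtype=np.float64)
    )
    return MolecularGraph(
        node_features=nodes,
        edge_index=edge_index,
        edge_features=edge_features,
        smiles=Chem.MolToSmiles(mol),
    )


def featurize_reaction(
    reaction_smiles: str, schema: FeatureSchema | None = None
) -> tuple[list[MolecularGraph], MolecularGraph]:
    """Encode a reaction SMILES "r1.r2...>>product" as (reactant graphs, product graph)."""
    schema = schema or FeatureSchema()
    parts = reaction_smiles.split(">>")
    if len(parts) != 2:
        raise FeaturizationError(
            f"reaction SMILES must contain exactly one '>>': {reaction_smiles!r}"
        )
    left, right = parts
    reactant_smiles = [s for s in left.split(".") if s]
    product_smiles = [s for s in right.split(".") if s]
    if not reactant_smiles:
        raise FeaturizationError(f"no reactants in {reaction_smiles!r}")
    if len(product_smiles) != 1:
        raise FeaturizationError(
            f"expected exactly one product, got {len(product_smiles)} in {reaction_smiles!r}"
        )
    try:
        reactants = [featurize_molecule(s, schema) for s in reactant_smiles]
        product = featurize_molecule(product_smiles[0], schema)
    except FeaturizationError as err:
        raise FeaturizationError(f"in reaction {reaction_smiles!r}: {err}") from err
    return reactants, product
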