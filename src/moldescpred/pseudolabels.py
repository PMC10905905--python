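"""PCA pseudo-labels for descriptor-based pre-training.

A :class:`PseudoLabeler` is fitted on the standardized descriptor matrix of a
molecule corpus: it holds the leading q principal components (eigenvectors of
the population covariance), their eigenvalues, and the clipping /
re-standardization statistics applied to the projected scores. Each molecule's
pseudo-label is its q-vector of clipped, re-standardized principal-component
scores; the eigenvalues travel with the labels because they weight the
pre-training loss.

q is chosen as the smallest dimensionality whose cumulative explained
variance reaches a target fraction (default 0.70), unless an explicit q is
given. Components are sign-fixed (largest-magnitude loading positive) so
fits are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .descriptors import DescriptorMatrix


@dataclass
class PseudoLabeler:
    components: np.ndarray          # (q, p), rows orthonormal
    eigenvalues: np.ndarray         # (q,), nonincreasing
    all_eigenvalues: np.ndarray     # (p,), for explained-variance queries
    explained_variance_target: float
    clip_multiplier: float
    score_sds: np.ndarray           # (q,) empirical SD of fitting-set scores
    post_clip_means: np.ndarray     # (q,)
    post_clip_sds: np.ndarray       # (q,)

    @property
    def q(self) -> int:
        return self.components.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.all_eigenvalues.sum()

    # -- persistence (JSON header + components payload in one document) --

    def to_json(self) -> str:
        return json.dumps(
            {
                "q": self.q,
                "explained_variance_target": self.explained_variance_target,
                "clip_multiplier": self.clip_multiplier,
                "eigenvalues": self.eigenvalues.tolist(),
                "all_eigenvalues": self.all_eigenvalues.tolist(),
                "score_sds": self.score_sds.tolist(),
                "post_clip_means": self.post_clip_means.tolist(),
                "post_clip_sds": self.post_clip_sds.tolist(),
                "components": self.components.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PseudoLabeler":
        raw = json.loads(text)
        return cls(
            components=np.asarray(raw["components"], dtype=np.float64),
            eigenvalues=np.asarray(raw["eigenvalues"], dtype=np.float64),
            all_eigenvalues=np.asarray(raw["all_eigenvalues"], dtype=np.float64),
            explained_variance_target=raw["explained_variance_target"],
            clip_multiplier=raw["clip_multiplier"],
            score_sds=np.asarray(raw["score_sds"], dtype=np.float64),
            post_clip_means=np.asarray(raw["post_clip_means"], dtype=np.float64),
            post_clip_sds=np.asarray(raw["post_clip_sds"], dtype=np.float64),
        )


@dataclass
class PseudoLabelSet:
    labels: np.ndarray              # (num_molecules, q)
    molecule_ids: list[str]
    eigenvalues: np.ndarray         # (q,) copied for loss weighting

    @property
    def q(self) -> int:
        return self.labels.shape[1]


def fit_pca(
    standardized_matrix: DescriptorMatrix,
    explained_variance_target: float = 0.70,
    q_override: int | None = None,
    clip_multiplier: float = 10.0,
) -> PseudoLabeler:
    """Fit principal components and clipping statistics on the fitting corpus.

    The eigendecomposition is done through the SVD of the centered data
    matrix (numerically stabler than forming the covariance); eigenvalues are
    singular values squared over n, i.e. eigenvalues of the population
    covariance of the standardized descriptors.
    """
    if not (0.0 < explained_variance_target <= 1.0):
        raise ValueError("explained_variance_target must be in (0, 1]")
    X = standardized_matrix.values
    if np.isnan(X).any():
        raise ValueError("standardized matrix must not contain missing values")
    n, p = X.shape
    Xc = X - X.mean(axis=0)  # already ~0 for a standardized fitting matrix
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / n
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]

    cumvar = np.cumsum(eigenvalues) / eigenvalues.sum()
    if q_override is not None:
        q = int(q_override)
        if not (1 <= q <= min(n, p)):
            raise ValueError(f"q_override must be in [1, {min(n, p)}]")
    else:
        q = int(np.searchsorted(cumvar, explained_variance_target - 1e-12) + 1)
    if n <= q:
        raise ValueError(f"need more molecules ({n}) than components ({q})")

    components = Vt[:q]
    scores = X @ components.T
    score_sds = scores.std(axis=0)
    bound = clip_multiplier * score_sds
    clipped = np.clip(scores, -bound, bound)
    post_clip_means = clipped.mean(axis=0)
    post_clip_sds = clipped.std(axis=0)

    return PseudoLabeler(
        components=components,
        eigenvalues=eigenvalues[:q],
        all_eigenvalues=eigenvalues,
        explained_variance_target=explained_variance_target,
        clip_multiplier=clip_multiplier,
        score_sds=score_sds,
        post_clip_means=post_clip_means,
        post_clip_sds=post_clip_sds,
    )


def make_pseudo_labels(
    labeler: PseudoLabeler, standardized_matrix: DescriptorMatrix
) -> PseudoLabelSet:
    """Project, clip at ±clip_multiplier fitting-set score SDs, and
    re-standardize with the stored fitting-set statistics."""
    X = standardized_matrix.values
    if X.shape[1] != labeler.components.shape[1]:
        raise ValueError(
            f"descriptor dimension {X.shape[1]} does not match labeler "
            f"({labeler.components.shape[1]})"
        )
    scores = X @ labeler.components.T
    bound = labeler.clip_multiplier * labeler.score_sds
    clipped = np.clip(scores, -bound, bound)
    labels = (clipped - labeler.post_clip_means) / labeler.post_clip_sds
    return PseudoLabelSet(
        labels=labels,
        molecule_ids=list(standardized_matrix.molecule_ids),
        eigenvalues=labeler.eigenvalues.copy(),
    )
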