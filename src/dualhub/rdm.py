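"""Representational dissimilarity matrices (RDMs).

Three constructors, matching the three information sources compared by the
pipeline:

* :func:`semantic_rdm` — one minus the cosine between per-concept semantic
  embedding vectors (word2vec-style).
* :func:`visual_rdm` — for each concept pair, the mean over all cross-concept
  image pairs of one minus the Pearson correlation between low-level visual
  feature vectors (C1-layer-style), averaged over the 4 exemplar images per
  concept.
* :func:`neural_rdm` — one minus the Pearson correlation between voxel
  activation patterns.

All RDMs are symmetric with an exactly-zero diagonal; correlation-distance
RDMs live in [0, 2].  The canonical vectorization used throughout the
codebase is the row-major lower triangle excluding the diagonal
(:func:`lower_triangle`), of length n(n-1)/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RDM",
    "semantic_rdm",
    "visual_rdm",
    "neural_rdm",
    "lower_triangle",
]


@dataclass
class RDM:
    """A labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"RDM values shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RDM contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("RDM is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("RDM diagonal is not exactly zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def vector(self) -> np.ndarray:
        """Row-major lower-triangle vectorization (diagonal excluded)."""
        return lower_triangle(self.values)

    def reorder(self, labels: Sequence[str]) -> "RDM":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(str(l)) for l in labels]
        return RDM(list(labels), self.values[np.ix_(idx, idx)], dict(self.meta))

    def permute(self, perm: np.ndarray) -> "RDM":
        """Apply one label permutation to rows and columns jointly.

        ``perm[i]`` gives the index of the concept that moves to slot ``i``;
        labels themselves are left in place (this is the label-reshuffling
        operation used by permutation inference).
        """
        perm = np.asarray(perm)
        if sorted(perm.tolist()) != list(range(self.n)):
            raise ValueError("permutation is not a bijection over labels")
        return RDM(self.labels, self.values[np.ix_(perm, perm)], dict(self.meta))

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", index_label="concept_id")
        sidecar = {"constructor": self.meta.get("constructor", "unknown"),
                   "parameters": self.meta.get("parameters", {})}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RDM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


def lower_triangle(values: np.ndarray) -> np.ndarray:
    """Row-major lower triangle of a square matrix, diagonal excluded."""
    values = np.asarray(values)
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j]


def semantic_rdm(vectors: np.ndarray, labels: Sequence[str] | None = None) -> RDM:
    """Cosine-distance RDM over per-concept semantic vectors.

    d_ij = 1 - cos(v_i, v_j).  Rows with zero norm are rejected because the
    cosine is undefined for them.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be a concepts x D matrix")
    n = vectors.shape[0]
    if labels is None:
        labels = [f"c{i:02d}" for i in range(n)]
    norms = np.linalg.norm(vectors, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"zero-norm semantic vector for concept(s): "
            f"{[str(labels[i]) for i in bad]}"
        )
    unit = vectors / norms[:, None]
    d = 1.0 - unit @ unit.T
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return RDM(list(labels), d, {"constructor": "semantic_rdm",
                                 "parameters": {"metric": "1 - cosine"}})


def _pearson_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between the rows of a matrix."""
    rows = np.asarray(rows, dtype=float)
    c = rows - rows.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(c, axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance vector in Pearson distance")
    c /= sd[:, None]
    return 1.0 - c @ c.T


def visual_rdm(exemplar_features: np.ndarray,
               labels: Sequence[str] | None = None) -> RDM:
    """Visual RDM from per-concept exemplar image features.

    ``exemplar_features`` has shape (concepts, n_exemplars, F).  For each
    concept pair i != j the dissimilarity is the mean over all
    n_exemplars**2 cross-concept image pairs of 1 - Pearson(img_a, img_b).
    The diagonal is fixed at 0 (diagonals never enter downstream
    correlations).
    """
    feats = np.asarray(exemplar_features, dtype=float)
    if feats.ndim != 3:
        raise ValueError("exemplar_features must be (concepts, exemplars, F)")
    n, k, _ = feats.shape
    if labels is None:
        labels = [f"c{i:02d}" for i in range(n)]
    flat = feats.reshape(n * k, -1)
    var = flat.var(axis=1)
    bad = np.flatnonzero(var == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance image feature vector at (concept, exemplar): "
            f"{[(str(labels[i // k]), int(i % k)) for i in bad]}"
        )
    dimg = _pearson_distance_matrix(flat)  # (n*k, n*k)
    # mean over the k x k cross-concept block for each concept pair
    d = dimg.reshape(n, k, n, k).mean(axis=(1, 3))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return RDM(list(labels), d, {"constructor": "visual_rdm",
                                 "parameters": {"metric": "mean 1 - Pearson",
                                                "n_exemplars": int(k)}})


class DegenerateRDMError(ValueError):
    """Raised when a neural RDM cannot be formed (too few usable voxels or a
    zero-variance pattern); callers map this to a missing value."""


def neural_rdm(beta_patterns: np.ndarray,
               labels: Sequence[str] | None = None,
               voxel_mask: np.ndarray | None = None) -> RDM:
    """Correlation-distance RDM between activation patterns.

    ``beta_patterns`` is a (concepts, voxels) matrix.  Voxels that are
    non-finite in any pattern are dropped; at least 2 usable voxels are
    required and every pattern must have nonzero variance across them.
    """
    p = np.asarray(beta_patterns, dtype=float)
    if p.ndim != 2:
        raise ValueError("beta_patterns must be (concepts, voxels)")
    if voxel_mask is not None:
        p = p[:, np.asarray(voxel_mask, dtype=bool)]
    usable = np.all(np.isfinite(p), axis=0)
    p = p[:, usable]
    if p.shape[1] < 2:
        raise DegenerateRDMError(
            f"only {p.shape[1]} usable voxel(s) in searchlight/ROI")
    n = p.shape[0]
    if labels is None:
        labels = [f"c{i:02d}" for i in range(n)]
    try:
        d = _pearson_distance_matrix(p)
    except ValueError as e:
        raise DegenerateRDMError(str(e)) from e
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return RDM(list(labels), d, {"constructor": "neural_rdm",
                                 "parameters": {"n_voxels": int(p.shape[1])}})
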