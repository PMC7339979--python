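"""Kernel construction for the bipartite cell-drug learning model.

Two bounded, provably positive-semidefinite similarity kernels carry the
heterogeneous data into a common representation: a *genomic* kernel between
cells (Jaccard similarity of mutated-gene sets over the panel) and a
*chemical* kernel between drugs (Tanimoto coefficient of fingerprint
bit-vectors — the same set statistic under its cheminformatics name).  A
Gaussian-on-binary (RBF) alternative is available behind the same interface.

A (cell, drug) pair is represented by concatenating the cell's similarity to
a list of anchor cells with the drug's similarity to a list of anchor drugs;
a new patient therefore enters purely through kernel rows against the
training anchors and needs no model refit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulate import fingerprint_matrix

__all__ = [
    "KernelMatrix",
    "PairFeatureSet",
    "binary_similarity",
    "genomic_kernel",
    "chemical_kernel",
    "pair_features",
    "build_pair_features",
]


@dataclass(frozen=True)
class KernelMatrix:
    """A labelled symmetric similarity matrix with entries in [0, 1]."""

    labels: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("kernel must be square and match its labels")
        object.__setattr__(self, "values", v)

    def validate(self, psd_tol: float = 1e-8) -> None:
        """Assert symmetry, unit diagonal, boundedness and PSD-ness."""
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("kernel is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("kernel diagonal is not 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("kernel entries outside [0, 1]")
        w = np.linalg.eigvalsh((v + v.T) / 2)
        if w.min() < -psd_tol:
            raise ValueError(f"kernel not PSD: min eigenvalue {w.min():.3e}")

    def row(self, label: str, anchors: Sequence[str]) -> np.ndarray:
        """Similarity of ``label`` to each anchor, in anchor order."""
        idx = {l: i for i, l in enumerate(self.labels)}
        if label not in idx:
            raise KeyError(f"unknown id {label!r}")
        missing = [a for a in anchors if a not in idx]
        if missing:
            raise KeyError(f"unknown anchor id(s) {missing}")
        return self.values[idx[label], [idx[a] for a in anchors]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def binary_similarity(
    X: np.ndarray,
    Y: Optional[np.ndarray] = None,
    kind: str = "jaccard",
    gamma: float = 1.0,
) -> np.ndarray:
    """Pairwise similarity between rows of binary matrices X and (optionally) Y.

    ``kind="jaccard"`` — |intersection| / |union| of the set bits, with the
    convention that two all-zero rows (identical empty sets) have similarity 1.
    ``kind="rbf"`` — exp(-gamma * squared Hamming distance), a
    Gaussian-on-binary alternative.
    """
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature-length mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if kind == "jaccard":
        inter = X @ Y.T
        union = X.sum(axis=1)[:, None] + Y.sum(axis=1)[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
        return sim
    if kind == "rbf":
        sq = (
            (X ** 2).sum(axis=1)[:, None]
            - 2.0 * (X @ Y.T)
            + (Y ** 2).sum(axis=1)[None, :]
        )
        return np.exp(-gamma * np.maximum(sq, 0.0))
    raise ValueError(f"unknown kernel kind {kind!r}")


def genomic_kernel(
    profiles: pd.DataFrame, kind: str = "jaccard", gamma: float = 1.0
) -> KernelMatrix:
    """Cell-cell similarity from binary mutation profiles on a shared panel."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    K = binary_similarity(profiles.to_numpy(), kind=kind, gamma=gamma)
    return KernelMatrix(tuple(profiles.index), K)


def chemical_kernel(
    drugs: pd.DataFrame, kind: str = "jaccard", gamma: float = 1.0
) -> KernelMatrix:
    """Drug-drug Tanimoto similarity from fingerprint bit-strings."""
    fps = fingerprint_matrix(drugs)
    K = binary_similarity(fps, kind=kind, gamma=gamma)
    return KernelMatrix(tuple(drugs.index), K)


def pair_features(
    cell: str,
    drug: str,
    Kg: KernelMatrix,
    Kc: KernelMatrix,
    anchors: Tuple[Sequence[str], Sequence[str]],
) -> np.ndarray:
    """Feature vector of one (cell, drug) pair: the cell's genomic-kernel row
    over the anchor cells concatenated with the drug's chemical-kernel row
    over the anchor drugs."""
    anchor_cells, anchor_drugs = anchors
    return np.concatenate([Kg.row(cell, anchor_cells), Kc.row(drug, anchor_drugs)])


@dataclass(frozen=True)
class PairFeatureSet:
    """Anchor-similarity features for a list of (cell, drug) pairs."""

    pairs: Tuple[Tuple[str, str], ...]
    X: np.ndarray
    anchor_cells: Tuple[str, ...]
    anchor_drugs: Tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        n_feat = len(self.anchor_cells) + len(self.anchor_drugs)
        if X.shape != (len(self.pairs), n_feat):
            raise ValueError(
                f"feature matrix shape {X.shape} does not match "
                f"{len(self.pairs)} pairs x {n_feat} anchors"
            )
        object.__setattr__(self, "X", X)


def build_pair_features(
    pairs: pd.DataFrame,
    Kg: KernelMatrix,
    Kc: KernelMatrix,
    anchor_cells: Optional[Sequence[str]] = None,
    anchor_drugs: Optional[Sequence[str]] = None,
) -> PairFeatureSet:
    """Vectorised anchor-similarity features for all rows of ``pairs``
    (columns ``cell_id``, ``drug_id``).  Anchors default to every entity in
    the respective kernel."""
    anchor_cells = tuple(anchor_cells if anchor_cells is not None else Kg.labels)
    anchor_drugs = tuple(anchor_drugs if anchor_drugs is not None else Kc.labels)
    g_idx = {l: i for i, l in enumerate(Kg.labels)}
    c_idx = {l: i for i, l in enumerate(Kc.labels)}
    try:
        rows_g = np.array([g_idx[c] for c in pairs["cell_id"]])
        rows_c = np.array([c_idx[d] for d in pairs["drug_id"]])
    except KeyError as err:
        raise KeyError(f"unknown id {err.args[0]!r}") from None
    cols_g = np.array([g_idx[a] for a in anchor_cells], dtype=int)
    cols_c = np.array([c_idx[a] for a in anchor_drugs], dtype=int)
    X = np.hstack(
        [
            Kg.values[np.ix_(rows_g, cols_g)] if len(pairs) else np.empty((0, len(cols_g))),
            Kc.values[np.ix_(rows_c, cols_c)] if len(pairs) else np.empty((0, len(cols_c))),
        ]
    )
    pair_ids = tuple(zip(pairs["cell_id"], pairs["drug_id"]))
    return PairFeatureSet(pair_ids, X, anchor_cells, anchor_drugs)
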