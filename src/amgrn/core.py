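"""Shared containers, errors and numerical helpers.

The central in-memory object is :class:`CountMatrix`, a sparse genes x cells
integer matrix with per-cell metadata (population, timepoint).  Downstream
modules work on dense cells x genes views produced by :func:`normalize_log1p`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("amgrn")


class AmgrnError(Exception):
    """Base class for package errors."""


class ConfigError(AmgrnError):
    """Invalid configuration."""


class GenerationError(AmgrnError):
    """Synthetic data could not be generated under the requested settings."""


class ParseError(AmgrnError):
    """A text input (BED/PWM/TSV) is malformed."""


# Fixed stage identifiers for seed fan-out: a single user seed is combined
# with a stage id so that adding or reordering stages never changes the
# random stream any other stage sees.
STAGE_IDS = {
    "truth": 11,
    "counts": 12,
    "sequences": 13,
    "topics": 21,
    "embedding": 22,
    "annotate": 23,
    "grn": 31,
    "perturb": 41,
    "pipeline": 51,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named stage, derived from one global seed."""
    if stage not in STAGE_IDS:
        raise ValueError(f"unknown stage {stage!r}; known: {sorted(STAGE_IDS)}")
    return np.random.default_rng([int(seed), STAGE_IDS[stage]])


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, genes x cells, with cell metadata.

    Parameters
    ----------
    counts:
        genes x cells sparse matrix of non-negative integers.
    gene_ids, cell_ids:
        Unique row / column identifiers.
    cell_meta:
        DataFrame indexed by ``cell_ids`` with at least the columns
        ``population`` and ``timepoint``.
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        g, c = self.counts.shape
        if g != len(self.gene_ids) or c != len(self.cell_ids):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != c:
            raise ValueError("duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        else:
            self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids, name="gene")

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([pos[c] for c in mask])
        cells = [self.cell_ids[i] for i in idx]
        return CountMatrix(
            self.counts[:, idx], self.gene_ids, cells, self.cell_meta.iloc[idx]
        )


def normalize_log1p(cm: CountMatrix, scale: float = 1e4) -> pd.DataFrame:
    """Counts-per-`scale` then log1p; returns dense cells x genes DataFrame."""
    X = cm.counts.T.astype(float).toarray()  # cells x genes
    libs = X.sum(axis=1, keepdims=True)
    libs[libs == 0] = 1.0
    return pd.DataFrame(
        np.log1p(X / libs * scale),
        index=pd.Index(cm.cell_ids, name="cell"),
        columns=cm.gene_index(),
    )


def pca_scores(X: np.ndarray, n_pcs: int, center: bool = True) -> np.ndarray:
    """Deterministic PCA via full SVD.

    Sign convention: each component is flipped so that its largest-magnitude
    gene loading is positive, making scores reproducible across runs and
    invariant to cell order.
    """
    X = np.asarray(X, dtype=float)
    n_pcs = int(n_pcs)
    if n_pcs < 1 or n_pcs > min(X.shape):
        raise ValueError(f"n_pcs={n_pcs} out of range for shape {X.shape}")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    return U * s


def zscore_columns(A: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores plus the (mean, sd) used; zero-variance columns map to 0."""
    A = np.asarray(A, dtype=float)
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=ddof)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (A - mu) / safe
    Z[:, sd == 0] = 0.0
    return Z, mu, sd
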