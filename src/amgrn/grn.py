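"""Context-specific gene-regulatory-network inference.

Expression is log-normalized, denoised by k-nearest-neighbor averaging in
principal-component space, and each gene is regressed on its candidate
regulators (the motif-derived base GRN restricts which TF -> target edges
may be fitted) with ridge regression and bootstrap bagging.  Edges are
retained when the bagged coefficient is stable in sign and large relative
to its bootstrap standard error.  Eigenvector centrality on the retained
network quantifies how embedded each TF is among other well-connected
regulators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core import CountMatrix, normalize_log1p, pca_scores, zscore_columns

logger = logging.getLogger("amgrn")


@dataclass
class BaseGRN:
    """Candidate TF -> target edges with optional motif/peak provenance."""

    edges: pd.DataFrame  # regulator, target [, motif, peak]

    def __post_init__(self):
        required = {"regulator", "target"}
        if not required.issubset(self.edges.columns):
            raise ValueError("BaseGRN edges need 'regulator' and 'target' columns")
        if self.edges.duplicated(subset=["regulator", "target"]).any():
            raise ValueError("duplicate candidate edges")

    @property
    def tf_list(self) -> list[str]:
        return sorted(self.edges["regulator"].unique())

    def candidates_for(self, target: str) -> list[str]:
        return sorted(self.edges.loc[self.edges["target"] == target, "regulator"])

    def to_tsv(self, path):
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BaseGRN":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class InferredGRN:
    """Fitted directed weighted network for one cell context.

    ``edges`` holds every base-GRN candidate with its bagged ridge
    coefficient (``coef`` on the expression scale, ``coef_std`` in
    standardized units), bootstrap standard error, sign stability and the
    retained flag.
    """

    context: str
    edges: pd.DataFrame
    fitted_genes: list[str]

    def retained(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]]

    def weight_matrix(self, genes: list[str] | None = None,
                      standardized: bool = False) -> pd.DataFrame:
        """Dense regulator x target matrix of retained coefficients."""
        genes = list(genes) if genes is not None else list(self.fitted_genes)
        pos = {g: i for i, g in enumerate(genes)}
        W = np.zeros((len(genes), len(genes)))
        col = "coef_std" if standardized else "coef"
        for _, e in self.retained().iterrows():
            if e["regulator"] in pos and e["target"] in pos:
                W[pos[e["regulator"]], pos[e["target"]]] = e[col]
        return pd.DataFrame(W, index=genes, columns=genes)

    def to_tsv(self, path):
        self.edges.to_csv(path, sep="\t", index=False)


def select_genes(counts: CountMatrix, n_hvg: int = 2500,
                 tf_list: list[str] = ()) -> list[str]:
    """Expressed genes ranked by log-normalized variance, unioned with TFs.

    Genes with zero total count are excluded even if named in ``tf_list``
    (logged, not fatal).  The returned order is the highly variable genes by
    descending variance (ties by gene id) followed by any remaining TFs.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    expressed = [g for g, t in zip(counts.gene_ids, totals) if t > 0]
    dropped_tfs = [t for t in tf_list if t not in set(expressed)]
    if dropped_tfs:
        logger.warning("TFs excluded by the expression filter: %s", dropped_tfs)
    X = normalize_log1p(counts)[expressed]
    var = X.var(axis=0, ddof=1)
    hvg = (pd.DataFrame({"var": var})
           .rename_axis("gene").reset_index()
           .sort_values(["var", "gene"], ascending=[False, True], kind="mergesort")
           ["gene"].head(n_hvg).tolist())
    extra = [t for t in tf_list if t in set(expressed) and t not in set(hvg)]
    return hvg + sorted(extra)


def knn_impute(counts: CountMatrix, genes: list[str], n_pcs: int = 47,
               k_frac: float = 0.025) -> pd.DataFrame:
    """KNN-average log-normalized expression in principal-component space.

    Cells are embedded with the first ``n_pcs`` principal components of the
    log1p-normalized selected genes; each cell's expression is replaced by
    the mean over its k nearest cells (self included), with
    k = max(1, round(k_frac * n_cells)).
    """
    if not (0 < k_frac <= 1):
        raise ValueError("k_frac must be in (0, 1]")
    X = normalize_log1p(counts)[list(genes)]
    n_cells = X.shape[0]
    n_pcs = int(min(n_pcs, min(X.shape)))
    k = max(1, int(round(k_frac * n_cells)))
    if k > n_cells:
        warnings.warn(f"k={k} exceeds n_cells={n_cells}; clamped")
        k = n_cells
    pcs = pca_scores(X.to_numpy(), n_pcs)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    imputed = X.to_numpy()[idx].mean(axis=1)
    return pd.DataFrame(imputed, index=X.index, columns=X.columns)


def fit_grn(
    imputed: pd.DataFrame,
    base: BaseGRN,
    context_mask,
    *,
    context_label: str = "",
    ridge_lambda: float = 1.0,
    n_bags: int = 20,
    retain_ratio: float = 2.0,
    sign_frac: float = 0.8,
    min_cells: int = 50,
    seed: int = 0,
) -> InferredGRN:
    """Bagged ridge regression of each target on its candidate regulators.

    For every target gene in the base GRN, the standardized imputed target
    is regressed on its standardized candidate TFs over the context cells,
    on ``n_bags`` bootstrap resamples.  The edge coefficient is the bagged
    mean; an edge is retained when |mean| / SE > ``retain_ratio`` and the
    coefficient sign agrees in at least ``sign_frac`` of the resamples.
    Coefficients are also reported on the expression scale
    (coef = coef_std * sd_target / sd_regulator), the scale used by the
    knockout propagation.  Deterministic given the seed and invariant to
    cell order (context cells are sorted by id).
    """
    mask = np.asarray(context_mask)
    if mask.dtype == bool:
        cells = imputed.index[mask]
    else:
        cells = pd.Index(mask)
    if len(cells) == 0:
        raise ValueError(f"context {context_label!r}: no cells after masking")
    if len(cells) < min_cells:
        raise ValueError(
            f"context {context_label!r}: {len(cells)} cells < floor {min_cells}"
        )
    sub = imputed.loc[sorted(cells)]
    genes = list(sub.columns)
    gene_set = set(genes)
    tfs = [t for t in base.tf_list if t in gene_set]
    edges = base.edges[(base.edges["regulator"].isin(gene_set))
                       & (base.edges["target"].isin(gene_set))]
    targets = sorted(edges["target"].unique())
    Z, mu, sd = zscore_columns(sub.to_numpy())
    sd_map = dict(zip(genes, sd))
    gpos = {g: i for i, g in enumerate(genes)}
    tf_pos = np.array([gpos[t] for t in tfs])
    dead_tfs = [t for t in tfs if sd_map[t] == 0]
    if dead_tfs:
        logger.warning("zero-variance regulators dropped: %s", dead_tfs)
    cand = {
        t: [r for r in sorted(edges.loc[edges["target"] == t, "regulator"])
            if sd_map[r] > 0 and r != t]
        for t in targets
    }
    tf_idx_local = {t: i for i, t in enumerate(tfs)}
    n = len(sub)
    rng = np.random.default_rng([seed, 7])
    Ztf = Z[:, tf_pos]                      # n x T
    Y = Z                                   # targets drawn from all columns
    B = int(n_bags)
    coefs = {t: np.zeros((B, len(cand[t]))) for t in targets}
    for b in range(B):
        rows = rng.integers(0, n, n)
        Zb = Ztf[rows]
        G = Zb.T @ Zb                       # T x T
        Hmat = Zb.T @ Y[rows]               # T x G
        for t in targets:
            regs = cand[t]
            if not regs:
                continue
            S = np.array([tf_idx_local[r] for r in regs])
            A = G[np.ix_(S, S)] + ridge_lambda * np.eye(len(S))
            coefs[t][b] = np.linalg.solve(A, Hmat[S, gpos[t]])
    rows_out = []
    for t in targets:
        regs = cand[t]
        C = coefs[t]
        for j, r in enumerate(regs):
            c = C[:, j]
            mean = float(c.mean())
            se = float(c.std(ddof=1) / np.sqrt(B)) if B > 1 else 0.0
            stab = float(max((c > 0).sum(), (c < 0).sum()) / B)
            ratio = abs(mean) / se if se > 0 else (np.inf if mean != 0 else 0.0)
            retained = bool(ratio > retain_ratio and stab >= sign_frac)
            coef_expr = mean * sd_map[t] / sd_map[r] if sd_map[r] > 0 else 0.0
            rows_out.append((r, t, coef_expr, mean, se, stab, retained))
    out = pd.DataFrame(
        rows_out,
        columns=["regulator", "target", "coef", "coef_std", "se",
                 "sign_stability", "retained"],
    )
    return InferredGRN(context=context_label, edges=out, fitted_genes=genes)


def fit_grn_by_context(
    imputed: pd.DataFrame,
    base: BaseGRN,
    cell_meta: pd.DataFrame,
    group_by: list[str] = ("population", "timepoint"),
    **kwargs,
) -> dict[tuple, InferredGRN]:
    """Fit one network per metadata group (population, population x timepoint, ...)."""
    out = {}
    meta = cell_meta.loc[imputed.index]
    for key, grp in meta.groupby(list(group_by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        label = "|".join(str(k) for k in key)
        out[key] = fit_grn(imputed, base, grp.index.to_numpy(),
                           context_label=label, **kwargs)
    return out


def eigenvector_centrality(
    grn: InferredGRN,
    *,
    mode: str = "undirected",
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> pd.Series:
    """Max-normalized eigenvector centrality of the retained network.

    Power iteration on the absolute-weight adjacency; by default the graph
    is treated as undirected (A + A^T), which keeps the leading eigenvector
    well-defined on networks that are not strongly connected.  ``mode`` may
    also be "left" or "right" for the directed variants.
    """
    genes = list(grn.fitted_genes)
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    A = np.zeros((n, n))
    for _, e in grn.retained().iterrows():
        A[pos[e["regulator"]], pos[e["target"]]] += abs(e["coef_std"])
    if mode == "undirected":
        A = A + A.T
    elif mode == "left":
        A = A.T
    elif mode != "right":
        raise ValueError(f"unknown mode {mode!r}")
    if not A.any():
        warnings.warn(f"context {grn.context!r}: no retained edges; zero centrality")
        return pd.Series(0.0, index=pd.Index(genes, name="gene"))
    # diagonal shift: keeps eigenvectors, makes the leading eigenvalue
    # strictly dominant (bipartite graphs otherwise oscillate forever)
    shift = 0.1 * float(A.sum(axis=1).max())
    A = A + shift * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = A @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w = w / norm
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    return pd.Series(v / v.max(), index=pd.Index(genes, name="gene"))


def centrality_contrast(
    tables: dict[tuple, pd.Series], tf_list: list[str]
) -> pd.DataFrame:
    """Mean TF centrality per context; NA (with a warning) when a context
    fitted no TFs."""
    rows = []
    for key, cent in tables.items():
        tfs = [t for t in tf_list if t in cent.index]
        if not tfs:
            warnings.warn(f"context {key}: no TFs in centrality table")
            mean = np.nan
        else:
            mean = float(cent.loc[tfs].mean())
        rows.append((*key, mean))
    ncol = max(len(k) for k in tables) if tables else 2
    names = ["population", "timepoint"][:ncol] or ["context"]
    return pd.DataFrame(rows, columns=names + ["mean_tf_centrality"])
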