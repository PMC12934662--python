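"""Multinomial topic modeling of single-cell counts by Poisson NMF.

The count matrix is factorized as X ~ Poisson(W H) with multiplicative
(EM) updates, then reparametrized to the grade-of-membership form: L
(cells x K, rows sum to 1) gives each cell's topic proportions and F
(genes x K, columns sum to 1) gives each topic's gene distribution.
Downstream utilities compute per-topic log fold changes against a
loadings-weighted baseline, ranked top-gene lists, hypergeometric gene-set
enrichment, marker-based population annotation and pseudobulk profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

from .core import CountMatrix, normalize_log1p, pca_scores

logger = logging.getLogger("amgrn")


@dataclass
class TopicModelFit:
    """Grade-of-membership factorization of a count matrix."""

    L: pd.DataFrame              # cells x K, rows sum to 1
    F: pd.DataFrame              # genes x K, columns sum to 1
    loglik_trace: np.ndarray     # Poisson log-likelihood (up to a constant)
    seed: int

    @property
    def K(self) -> int:
        return self.L.shape[1]

    def loadings(self, topic: int) -> pd.Series:
        return self.L.iloc[:, topic]


def poisson_loglik(X: np.ndarray, WH: np.ndarray, eps: float = 1e-12) -> float:
    """Poisson log-likelihood of X under mean WH, dropping the log(x!) term."""
    return float(np.sum(X * np.log(WH + eps) - WH))


def _anchor_init(X, K, rng):
    """Seed gene factors from K mutually distant cell profiles.

    k-means++-style seeding on row-normalized count profiles: anchoring
    each topic at an extreme cell starts EM inside the basin where distinct
    programs occupy distinct topics, instead of splitting the dominant one.
    """
    totals = X.sum(axis=1, keepdims=True)
    prof = X / np.where(totals > 0, totals, 1.0)
    n_cells, n_genes = X.shape
    chosen = [int(rng.integers(n_cells))]
    for _ in range(K - 1):
        d2 = np.min([((prof - prof[c]) ** 2).sum(axis=1) for c in chosen], axis=0)
        tot = d2.sum()
        if tot == 0:
            chosen.append(int(rng.integers(n_cells)))
        else:
            chosen.append(int(rng.choice(n_cells, p=d2 / tot)))
    H = prof[chosen] + 1e-4 / n_genes
    H = H / H.sum(axis=1, keepdims=True)
    W = np.ones((n_cells, K))
    s = np.sqrt(X.sum() / (W @ H).sum())
    return W * s, H * s


def _nmf_em(X, W, H, n_iter, eps):
    trace = np.empty(n_iter)
    for it in range(n_iter):
        WH = W @ H
        W *= (X / (WH + eps)) @ H.T / (H.sum(axis=1)[None, :] + eps)
        WH = W @ H
        H *= W.T @ (X / (WH + eps)) / (W.sum(axis=0)[:, None] + eps)
        trace[it] = poisson_loglik(X, W @ H, eps)
    return W, H, trace


def fit_topic_model(
    counts: CountMatrix,
    K: int,
    n_iter_main: int = 150,
    n_iter_refine: int = 150,
    seed: int = 0,
    n_starts: int = 5,
    eps: float = 1e-12,
) -> TopicModelFit:
    """Fit a K-topic model by multiplicative Poisson-NMF updates.

    ``n_starts`` random initializations are each run for ``n_iter_main``
    EM iterations; the best-likelihood incumbent then receives
    ``n_iter_refine`` further refinement iterations (multiplicative EM can
    stall in local optima that split a dominant program, so the fit is
    selected by likelihood across starts).  Each full iteration performs
    one EM update of the cell factors and one of the gene factors, so the
    recorded trace of the selected start is non-decreasing up to floating
    point error.  All-zero genes keep exactly zero factor mass.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    n_cells, n_genes = counts.n_cells, counts.n_genes
    if K > min(n_cells, n_genes):
        raise ValueError(f"K={K} exceeds min(cells, genes)={min(n_cells, n_genes)}")
    X = counts.counts.T.astype(float).toarray()  # cells x genes
    if X.sum() == 0:
        raise ValueError("count matrix is empty")
    best = None
    for start in range(n_starts):
        rng = np.random.default_rng([seed, start])
        W, H = _anchor_init(X, K, rng)
        W, H, tr = _nmf_em(X, W, H, n_iter_main, eps)
        if best is None or tr[-1] > best[2][-1]:
            best = (W, H, tr)
    W, H, trace_main = best
    W, H, trace_refine = _nmf_em(X, W, H, n_iter_refine, eps)
    trace = np.concatenate([trace_main, trace_refine])
    # multinomial reparametrization: F columns are topic gene distributions,
    # L rows are per-cell topic proportions (scale absorbed)
    s = H.sum(axis=1)  # per-topic scale
    F = (H / np.maximum(s[:, None], eps)).T
    Lm = W * s[None, :]
    row = Lm.sum(axis=1, keepdims=True)
    L = Lm / np.where(row > 0, row, 1.0)
    topic_names = [f"k{k + 1}" for k in range(K)]
    return TopicModelFit(
        L=pd.DataFrame(L, index=pd.Index(counts.cell_ids, name="cell"),
                       columns=topic_names),
        F=pd.DataFrame(F, index=counts.gene_index(), columns=topic_names),
        loglik_trace=trace,
        seed=seed,
    )


@dataclass
class TopicLFC:
    """log2 fold change of each topic's gene distribution vs a baseline.

    The baseline for gene j is the loadings-weighted mean of F_j across
    topics (weights = mean topic proportions over cells).  Genes with zero
    total factor mass (all-zero genes) are NA.
    """

    lfc: pd.DataFrame        # genes x K
    baseline: pd.Series      # per gene
    pseudocount: float


def gom_lfc(fit: TopicModelFit, topic: int | None = None,
            pseudocount: float = 1e-8) -> TopicLFC:
    """Grade-of-membership log fold changes, for all topics (or sliced to one)."""
    if topic is not None and not (0 <= topic < fit.K):
        raise IndexError(f"topic {topic} out of range for K={fit.K}")
    weights = fit.L.mean(axis=0).to_numpy()
    F = fit.F.to_numpy()
    baseline = F @ weights
    lfc = np.log2((F + pseudocount) / (baseline[:, None] + pseudocount))
    dead = F.sum(axis=1) == 0
    lfc[dead] = np.nan
    out = TopicLFC(
        lfc=pd.DataFrame(lfc, index=fit.F.index, columns=fit.F.columns),
        baseline=pd.Series(np.where(dead, np.nan, baseline), index=fit.F.index),
        pseudocount=pseudocount,
    )
    if topic is not None:
        out = TopicLFC(out.lfc.iloc[:, [topic]], out.baseline, pseudocount)
    return out


def top_genes(lfc: TopicLFC, topic: int | str, n: int = 1000) -> list[str]:
    """Genes ranked by descending LFC for one topic.

    Ties break by descending factor value proxy (the LFC numerator is
    monotone in F at fixed baseline, so baseline-adjusted LFC ties are
    resolved by gene id after LFC), then lexical gene id; NA genes excluded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    col = lfc.lfc.columns[topic] if isinstance(topic, int) else topic
    f_value = (2.0 ** lfc.lfc[col]) * (lfc.baseline + lfc.pseudocount)
    df = (pd.DataFrame({"lfc": lfc.lfc[col], "f": f_value})
          .dropna()
          .rename_axis("gene")
          .reset_index()
          .sort_values(["lfc", "f", "gene"], ascending=[False, False, True],
                       kind="mergesort"))
    return df["gene"].head(n).tolist()


def hypergeometric_enrichment(
    query: set, gene_sets: dict[str, set], universe: set
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with Benjamini-Hochberg control.

    Every set is intersected with the universe before testing; the query
    must already be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(query)
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & universe
        k = len(genes & query)
        p = float(hypergeom.sf(k - 1, M, len(genes), N)) if genes else 1.0
        rows.append((name, k, len(genes), M, min(max(p, 0.0), 1.0)))
    out = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                      "universe_size", "p_value"])
    out["p_adjusted"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def annotate_populations(
    counts: CountMatrix,
    marker_sets: dict[str, list[str]],
    k_clusters: int = 5,
    n_pcs: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Label cells by k-means clustering plus marker-set scoring.

    Cells are clustered with k-means (k-means++ init, fixed seed) on the
    top principal components of log1p-normalized counts.  Each cluster is
    scored by the mean normalized expression of each marker set; the
    top-scoring cluster per set receives that set's label and the rest are
    labelled "other".  The result is invariant to cell order (cells are
    sorted by id internally).
    """
    if counts.n_cells < k_clusters:
        raise ValueError(f"fewer cells ({counts.n_cells}) than clusters ({k_clusters})")
    missing = {name: [g for g in genes if g not in set(counts.gene_ids)]
               for name, genes in marker_sets.items()}
    missing = {k: v for k, v in missing.items() if v}
    if missing:
        raise ValueError(f"marker genes absent from data: {missing}")
    X = normalize_log1p(counts)
    order = np.argsort(np.asarray(counts.cell_ids))
    Xs = X.to_numpy()[order]
    n_pcs = min(n_pcs, min(Xs.shape) - 1)
    pcs = pca_scores(Xs, n_pcs)
    km = KMeans(n_clusters=k_clusters, init="k-means++", n_init=10,
                random_state=seed).fit(pcs)
    cluster = np.empty(counts.n_cells, dtype=int)
    cluster[order] = km.labels_
    labels = pd.Series("other", index=X.index, name="population")
    scores = {}
    for name, genes in marker_sets.items():
        marker_mean = X[list(genes)].mean(axis=1).to_numpy()
        scores[name] = np.array([marker_mean[cluster == c].mean()
                                 for c in range(k_clusters)])
    taken: set[int] = set()
    # assign in order of decreasing best score so two sets never claim
    # the same cluster
    for name in sorted(scores, key=lambda n: -np.nanmax(scores[n])):
        ranked = np.argsort(-scores[name])
        best = next(int(c) for c in ranked if int(c) not in taken)
        taken.add(best)
        labels.iloc[cluster == best] = name
    return labels


def pseudobulk(counts: CountMatrix, group_by: list[str]) -> pd.DataFrame:
    """Per-group mean of log1p counts-per-10k expression, groups x genes."""
    for key in group_by:
        if key not in counts.cell_meta.columns:
            raise KeyError(f"metadata key {key!r} not found")
    X = normalize_log1p(counts)
    groups = counts.cell_meta[list(group_by)]
    return X.groupby([groups[k] for k in group_by], observed=True).mean()
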