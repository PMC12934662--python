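"""In-silico TF knockout simulation and topic-gradient perturbation scores.

A knockout sets one TF's (imputed) expression to zero and propagates the
resulting expression delta through the retained network coefficients for a
few steps.  The per-cell delta is projected onto a 2D embedding by
correlating it with the expression differences toward each cell's
expression-space neighbors, giving a vector field of predicted cell
movement.  Smoothing each topic's loadings onto a grid over the embedding
and differentiating yields a topic gradient field; the mean dot product of
the perturbation field with a topic gradient is that TF's perturbation
score for the topic (negative = the knockout pushes cells away from the
program).  The (homeostasis, inflammation) score pair per TF, and its
Euclidean magnitude, summarize how destabilizing a single-TF knockout is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core import pca_scores
from .grn import InferredGRN
from .topics import TopicModelFit

logger = logging.getLogger("amgrn")


@dataclass
class KnockoutShift:
    """Per-cell expression shift after an in-silico TF knockout."""

    tf: str
    delta: pd.DataFrame          # cells x fitted genes
    n_propagation: int


def simulate_ko(
    imputed: pd.DataFrame,
    grn: InferredGRN,
    tf: str,
    n_propagation: int = 3,
) -> KnockoutShift:
    """Propagate a TF knockout through the retained network.

    The initial delta zeroes the TF (delta = -x_tf per cell).  Each step
    multiplies the current per-step delta by the coefficient matrix
    W[regulator, target]; after each step the cumulative simulated
    expression is clamped at >= 0 and the knocked-out TF is pinned at zero.
    With clamping inactive this equals the closed form
    sum_t dX0 W^t over a DAG.
    """
    if n_propagation < 1:
        raise ValueError("n_propagation must be >= 1")
    genes = list(imputed.columns)
    if tf not in genes or tf not in set(grn.fitted_genes):
        available = sorted(set(grn.edges["regulator"]))
        raise ValueError(f"TF {tf!r} not in network; available TFs: {available}")
    X = imputed.to_numpy()
    W = grn.weight_matrix(genes).to_numpy()
    j = genes.index(tf)
    x_tf = X[:, j]
    cur = np.zeros_like(X)
    cur[:, j] = -x_tf
    total = cur.copy()
    for _ in range(n_propagation):
        cur = cur @ W
        total = total + cur
        np.maximum(total, -X, out=total)   # simulated expression stays >= 0
        total[:, j] = -x_tf
    return KnockoutShift(tf=tf, delta=pd.DataFrame(total, index=imputed.index,
                                                   columns=imputed.columns),
                         n_propagation=n_propagation)


@dataclass
class GridSpec:
    """Regular grid over an embedding bounding box, with kernel bandwidth."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    size: int = 40
    bandwidth: float = 1.0

    @classmethod
    def from_embedding(cls, embedding: np.ndarray, size: int = 40,
                       bandwidth: float | None = None) -> "GridSpec":
        emb = np.asarray(embedding, dtype=float)
        xmin, ymin = emb.min(axis=0)
        xmax, ymax = emb.max(axis=0)
        if bandwidth is None:
            bandwidth = max(xmax - xmin, ymax - ymin) / 25.0
        if bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        return cls(xmin, xmax, ymin, ymax, size, bandwidth)

    def nodes(self) -> np.ndarray:
        xs = np.linspace(self.xmin, self.xmax, self.size)
        ys = np.linspace(self.ymin, self.ymax, self.size)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel()], axis=1)

    @property
    def spacing(self) -> tuple[float, float]:
        return ((self.xmax - self.xmin) / max(self.size - 1, 1),
                (self.ymax - self.ymin) / max(self.size - 1, 1))

    def matches(self, other: "GridSpec") -> bool:
        return (self.size == other.size
                and np.allclose(
                    [self.xmin, self.xmax, self.ymin, self.ymax, self.bandwidth],
                    [other.xmin, other.xmax, other.ymin, other.ymax, other.bandwidth]))


def smooth_to_grid(points: np.ndarray, values: np.ndarray, grid: GridSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel weighted average of per-point values onto grid nodes.

    Returns (smoothed values with shape (size*size, d), occupancy mask);
    nodes with no point within 2 * bandwidth are masked and zeroed.
    """
    points = np.asarray(points, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    nodes = grid.nodes()
    d2 = ((nodes[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * grid.bandwidth ** 2))
    mask = d2.min(axis=1) <= (2.0 * grid.bandwidth) ** 2
    wsum = w.sum(axis=1, keepdims=True)
    out = np.zeros((len(nodes), values.shape[1]))
    ok = mask & (wsum.ravel() > 0)
    out[ok] = (w[ok] @ values) / wsum[ok]
    return out, mask & (wsum.ravel() > 0)


@dataclass
class EmbeddingVectorField:
    """Per-cell 2D shift vectors and their grid-smoothed counterpart."""

    tf: str
    vectors: pd.DataFrame        # cells x 2
    grid: GridSpec
    grid_vectors: np.ndarray     # (size*size, 2)
    mask: np.ndarray             # (size*size,)


@dataclass
class TopicGradientField:
    """Grid-smoothed topic loading and its finite-difference gradient."""

    topic: str
    grid: GridSpec
    values: np.ndarray           # (size*size,)
    gradients: np.ndarray        # (size*size, 2)
    mask: np.ndarray


class ProjectionContext:
    """Precomputed geometry shared by all knockout projections on one
    cell subset: gene-centered expression, its Gram matrix, expression-space
    nearest neighbors and embedding unit vectors."""

    def __init__(self, imputed: pd.DataFrame, embedding: pd.DataFrame,
                 k_neighbors: int = 200, n_pcs: int = 47,
                 temperature: float = 0.05):
        if k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")
        self.cells = imputed.index
        self.genes = imputed.columns
        X = imputed.to_numpy()
        n = X.shape[0]
        k = min(k_neighbors, n - 1)
        self.temperature = float(temperature)
        self.Xc = X - X.mean(axis=1, keepdims=True)
        self.sqnorm = (self.Xc ** 2).sum(axis=1)
        self.gram = self.Xc @ self.Xc.T
        n_pcs = int(min(n_pcs, min(X.shape) - 1))
        pcs = pca_scores(X, max(n_pcs, 1))
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
        _, idx = nn.kneighbors(pcs)
        self.nbr = idx[:, 1:]                          # n x k, self excluded
        emb = embedding.loc[imputed.index].to_numpy()
        self.embedding = emb
        diff = emb[self.nbr] - emb[:, None, :]         # n x k x 2
        norm = np.linalg.norm(diff, axis=2, keepdims=True)
        self.unit = np.divide(diff, norm, out=np.zeros_like(diff),
                              where=norm > 0)
        self.mean_unit = self.unit.mean(axis=1)        # n x 2


def project_shift(
    shift: KnockoutShift,
    imputed: pd.DataFrame,
    embedding: pd.DataFrame,
    k_neighbors: int = 200,
    temperature: float = 0.05,
    context: ProjectionContext | None = None,
    grid: GridSpec | None = None,
) -> EmbeddingVectorField:
    """Project a knockout delta onto the 2D embedding.

    For each cell i, the delta is correlated (over genes) with the
    expression difference toward each of its k expression-space neighbors;
    correlations become transition probabilities through an exponential
    kernel and the cell's 2D vector is the probability-weighted mean of the
    unit vectors toward its neighbors, minus the unweighted mean (removing
    embedding-density bias).  Cells with an all-zero or constant delta get
    zero vectors.
    """
    ctx = context or ProjectionContext(imputed, embedding, k_neighbors=k_neighbors,
                                       temperature=temperature)
    D = shift.delta.loc[ctx.cells, ctx.genes].to_numpy()
    Dc = D - D.mean(axis=1, keepdims=True)
    dnorm = np.linalg.norm(Dc, axis=1)
    null_raw = np.linalg.norm(D, axis=1) < 1e-12
    null = dnorm < 1e-12
    if (null & ~null_raw).any():
        warnings.warn("constant nonzero delta: correlation undefined, zero vector")
    Zd = np.divide(Dc, dnorm[:, None], out=np.zeros_like(Dc),
                   where=dnorm[:, None] > 0)
    cross = Zd @ ctx.Xc.T                              # n x n
    selfdot = (Zd * ctx.Xc).sum(axis=1)
    numer = np.take_along_axis(cross, ctx.nbr, axis=1) - selfdot[:, None]
    g_at = np.take_along_axis(ctx.gram, ctx.nbr, axis=1)
    den2 = ctx.sqnorm[ctx.nbr] + ctx.sqnorm[:, None] - 2.0 * g_at
    denom = np.sqrt(np.maximum(den2, 0.0))
    corr = np.divide(numer, denom, out=np.zeros_like(numer), where=denom > 0)
    w = np.exp((corr - corr.max(axis=1, keepdims=True)) / ctx.temperature)
    p = w / w.sum(axis=1, keepdims=True)
    vec = (p[:, :, None] * ctx.unit).sum(axis=1) - ctx.mean_unit
    vec[null] = 0.0
    vectors = pd.DataFrame(vec, index=ctx.cells, columns=["dx", "dy"])
    gs = grid or GridSpec.from_embedding(ctx.embedding)
    grid_vec, mask = smooth_to_grid(ctx.embedding, vec, gs)
    return EmbeddingVectorField(tf=shift.tf, vectors=vectors, grid=gs,
                                grid_vectors=grid_vec, mask=mask)


def topic_gradient(
    fit: TopicModelFit,
    topic: int | str,
    embedding: pd.DataFrame,
    grid_size: int = 40,
    bandwidth: float | None = None,
    cells: pd.Index | None = None,
    grid: GridSpec | None = None,
) -> TopicGradientField:
    """Smooth a topic's loadings onto a grid and differentiate.

    Gradients use central finite differences on occupied nodes, falling
    back to one-sided differences at mask borders; masked nodes carry zero
    vectors and are excluded from downstream score sums.
    """
    col = fit.L.columns[topic] if isinstance(topic, int) else topic
    cells = cells if cells is not None else embedding.index
    loadings = fit.L.loc[cells, col].to_numpy()
    emb = embedding.loc[cells].to_numpy()
    gs = grid or GridSpec.from_embedding(emb, size=grid_size, bandwidth=bandwidth)
    if gs.bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    values, mask = smooth_to_grid(emb, loadings, gs)
    values = values.ravel()
    S = gs.size
    V = values.reshape(S, S)
    M = mask.reshape(S, S)
    dx, dy = gs.spacing
    grad = np.zeros((S, S, 2))
    for axis, h in ((0, dx), (1, dy)):
        fwd = np.zeros_like(M)
        bwd = np.zeros_like(M)
        vf = np.zeros_like(V)
        vb = np.zeros_like(V)
        sl_to = [slice(None)] * 2
        sl_from = [slice(None)] * 2
        sl_to[axis], sl_from[axis] = slice(0, S - 1), slice(1, S)
        fwd[tuple(sl_to)] = M[tuple(sl_from)]
        vf[tuple(sl_to)] = V[tuple(sl_from)]
        sl_to[axis], sl_from[axis] = slice(1, S), slice(0, S - 1)
        bwd[tuple(sl_to)] = M[tuple(sl_from)]
        vb[tuple(sl_to)] = V[tuple(sl_from)]
        g = np.zeros_like(V)
        both = M & fwd & bwd
        g[both] = (vf[both] - vb[both]) / (2 * h)
        fonly = M & fwd & ~bwd
        g[fonly] = (vf[fonly] - V[fonly]) / h
        bonly = M & ~fwd & bwd
        g[bonly] = (V[bonly] - vb[bonly]) / h
        grad[:, :, axis] = g
    return TopicGradientField(topic=str(col), grid=gs, values=values,
                              gradients=grad.reshape(S * S, 2), mask=mask)


def perturbation_score(field: EmbeddingVectorField,
                       grad: TopicGradientField) -> float:
    """Occupied-node mean dot product of the perturbation and gradient fields.

    Negative scores mean the knockout moves cells down the topic's gradient
    (away from that functional state).
    """
    if not field.grid.matches(grad.grid):
        raise ValueError("perturbation and gradient grids differ in geometry")
    joint = field.mask & grad.mask
    if not joint.any():
        raise ValueError("disjoint occupancy masks: no jointly occupied nodes")
    dots = (field.grid_vectors[joint] * grad.gradients[joint]).sum(axis=1)
    return float(dots.mean())


def tf_screen(
    imputed: pd.DataFrame,
    grn: InferredGRN,
    fit: TopicModelFit,
    embedding: pd.DataFrame,
    topics: tuple = (0, 1),
    tf_list: list[str] | None = None,
    n_propagation: int = 3,
    k_neighbors: int = 200,
    temperature: float = 0.05,
    grid_size: int = 40,
    bandwidth: float | None = None,
) -> pd.DataFrame:
    """Knockout -> projection -> score for every TF in the network.

    Returns one row per TF with the two topic scores (columns named
    ``score_<topic>``) and the Euclidean magnitude of the score vector.
    """
    homeo, inflam = topics
    tfs = tf_list if tf_list is not None else sorted(
        set(grn.edges["regulator"]) & set(imputed.columns))
    ctx = ProjectionContext(imputed, embedding, k_neighbors=k_neighbors,
                            temperature=temperature)
    gs = GridSpec.from_embedding(ctx.embedding, size=grid_size, bandwidth=bandwidth)
    g_h = topic_gradient(fit, homeo, embedding, cells=imputed.index, grid=gs)
    g_i = topic_gradient(fit, inflam, embedding, cells=imputed.index, grid=gs)
    rows = []
    for tf in tfs:
        shift = simulate_ko(imputed, grn, tf, n_propagation=n_propagation)
        fieldv = project_shift(shift, imputed, embedding, context=ctx, grid=gs)
        s_h = perturbation_score(fieldv, g_h)
        s_i = perturbation_score(fieldv, g_i)
        rows.append((tf, s_h, s_i, float(np.hypot(s_h, s_i))))
    return pd.DataFrame(
        rows, columns=["tf", f"score_{g_h.topic}", f"score_{g_i.topic}", "magnitude"]
    ).set_index("tf")
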