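"""Scoring of inference results against the planted ground truth.

These helpers close the loop between the synthetic generator and the
inference modules: Hungarian-matched cosine similarity for topic recovery,
AUROC of candidate-edge ranking for network recovery, and a correlation
based coefficient-error measure for the noise ladder.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import roc_auc_score

from .grn import InferredGRN
from .syndata import GroundTruth
from .topics import TopicModelFit


def match_topics(F_true: pd.DataFrame, F_est: pd.DataFrame
                 ) -> tuple[dict, np.ndarray]:
    """Optimal one-to-one matching of estimated to true topics.

    Returns (mapping true-name -> estimated-name, matched cosine
    similarities in true-topic order), maximizing total cosine similarity
    with the Hungarian algorithm.
    """
    A = F_true.loc[F_est.index].to_numpy().T      # K_true x genes
    B = F_est.to_numpy().T                        # K_est x genes
    An = A / np.linalg.norm(A, axis=1, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    C = An @ Bn.T
    rows, cols = linear_sum_assignment(-C)
    mapping = {F_true.columns[r]: F_est.columns[c] for r, c in zip(rows, cols)}
    return mapping, C[rows, cols]


def topic_recovery_cosine(truth: GroundTruth, fit: TopicModelFit) -> float:
    """Mean matched cosine between true and recovered topic gene distributions."""
    _, cos = match_topics(truth.topic_gene_dists, fit.F)
    return float(cos.mean())


def edge_recovery_auroc(grn: InferredGRN, truth: GroundTruth,
                        population: str) -> float:
    """AUROC of |bagged coefficient| ranking base candidates vs true edges."""
    true_pairs = set(map(tuple, truth.edges_for(population)[["regulator", "target"]]
                         .itertuples(index=False)))
    edges = grn.edges
    labels = [(r, t) in true_pairs for r, t in zip(edges["regulator"], edges["target"])]
    scores = edges["coef_std"].abs().to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("need both true and decoy candidates to compute AUROC")
    return float(roc_auc_score(labels, scores))


def edge_score_table(
    expression: pd.DataFrame,
    base,
    cell_meta: pd.DataFrame,
    population: str,
    seed: int = 0,
    min_cells: int = 50,
    **fit_kw,
) -> pd.DataFrame:
    """Per-candidate-edge scores aggregated over timepoint contexts.

    Networks are fitted separately per timepoint within the population (the
    contexts the study works with) and candidate edges are summarized by
    the mean standardized coefficient, its mean magnitude, and the fraction
    of contexts retaining the edge.
    """
    from .grn import fit_grn

    meta = cell_meta.loc[expression.index]
    meta = meta[meta["population"] == population]
    frames = []
    for tp, grp in meta.groupby("timepoint", observed=True):
        net = fit_grn(expression, base, grp.index.to_numpy(),
                      context_label=f"{population}|{tp}", seed=seed,
                      min_cells=min_cells, **fit_kw)
        frames.append(net.edges.set_index(["regulator", "target"])
                      [["coef_std", "retained"]].add_suffix(f"_{tp}"))
    joined = pd.concat(frames, axis=1)
    coef_cols = [c for c in joined.columns if c.startswith("coef_std")]
    ret_cols = [c for c in joined.columns if c.startswith("retained")]
    return pd.DataFrame({
        "coef_mean": joined[coef_cols].mean(axis=1),
        "abs_coef_mean": joined[coef_cols].abs().mean(axis=1),
        "retained_frac": joined[ret_cols].mean(axis=1),
    })


def candidate_auroc(table: pd.DataFrame, truth: GroundTruth,
                    population: str) -> float:
    """AUROC of aggregated |coefficient| ranking candidates vs true edges."""
    true_pairs = set(map(tuple, truth.edges_for(population)[["regulator", "target"]]
                         .itertuples(index=False)))
    labels = [rt in true_pairs for rt in table.index]
    if len(set(labels)) < 2:
        raise ValueError("need both true and decoy candidates to compute AUROC")
    return float(roc_auc_score(labels, table["abs_coef_mean"].to_numpy()))


def true_edge_miss_rate(table: pd.DataFrame, truth: GroundTruth,
                        population: str) -> float:
    """Fraction of planted edges not retained, averaged over contexts."""
    te = truth.edges_for(population).set_index(["regulator", "target"])
    common = table.index.intersection(te.index)
    if len(common) == 0:
        raise ValueError("no true edges among candidates")
    return float(1.0 - table.loc[common, "retained_frac"].mean())


def coefficient_error(grn: InferredGRN, truth: GroundTruth,
                      population: str) -> float:
    """1 - Pearson correlation between fitted and planted weights on true edges."""
    te = truth.edges_for(population).set_index(["regulator", "target"])["weight"]
    fitted = grn.edges.set_index(["regulator", "target"])["coef_std"]
    common = te.index.intersection(fitted.index)
    if len(common) < 3:
        raise ValueError("too few recovered true edges for a correlation")
    r = np.corrcoef(te.loc[common], fitted.loc[common])[0, 1]
    return float(1.0 - r)
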