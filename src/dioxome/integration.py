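"""Pathway–immune-marker integration via PC1 summaries and PLS.

Each enriched pathway is summarized per subject by the first principal
component of its significant features' standardized ln intensities.
Pathway scores (X) are then related to immune markers (Y) by a PLS2
regression on standardized matrices; the association score between
pathway j and marker k is the model-reconstructed cross-correlation

    S = X'·(X·B) / (n − 1),   B the n_comp-truncated PLS coefficients,

which equals the sample cross-correlation at full rank and approximates
it at low rank. Pairs with |score| > 0.3 and p < 0.05 (treating the
score as a correlation on n − 2 df) form a bipartite network partitioned
by multilevel community detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .network import detect_communities
from .tables import ConfigurationError, FeatureTable


@dataclass
class PathwayScoreMatrix:
    """Subjects × pathways PC1 scores with per-pathway PCA metadata."""

    scores: pd.DataFrame
    explained_variance: pd.Series
    loadings: dict[str, pd.Series]


def _pc1(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of a standardized matrix via SVD.

    Sign convention: the loading of largest magnitude is positive.
    Returns (scores, loadings, explained variance fraction).
    """
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    load = vt[0]
    if load[np.argmax(np.abs(load))] < 0:
        load = -load
        u0 = -u[:, 0]
    else:
        u0 = u[:, 0]
    scores = u0 * s[0]
    ev = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 1.0
    return scores, load, ev


def pathway_pc1_scores(
    metabolome: dict[str, FeatureTable],
    enriched: pd.DataFrame,
    sig_feature_map: dict[str, dict[str, list[str]]],
    subjects_subset: pd.Index,
) -> PathwayScoreMatrix:
    """PC1 score per subject for every passing enriched pathway.

    ``enriched`` is the merged enrichment table (needs pathway_id, mode,
    subclass, pass); ``sig_feature_map[pathway_id][mode]`` lists the
    significant features annotated to that pathway. Features are z-scored
    over the subject subset before PCA; a single-feature pathway's score
    is the standardized feature itself.
    """
    if len(subjects_subset) == 0:
        raise ConfigurationError("empty subject subset")
    score_cols: dict[str, np.ndarray] = {}
    ev: dict[str, float] = {}
    loadings: dict[str, pd.Series] = {}
    passing = enriched[enriched["pass"]] if "pass" in enriched else enriched
    for pid in dict.fromkeys(passing["pathway_id"]):
        cols: list[tuple[str, str]] = []
        for mode, feats in sig_feature_map.get(pid, {}).items():
            table = metabolome[mode]
            cols.extend((mode, f) for f in feats if f in table.intensities.columns)
        if not cols:
            warnings.warn(f"pathway {pid} has no significant features; skipped")
            continue
        mat = np.column_stack(
            [
                metabolome[mode].intensities.loc[subjects_subset, f].to_numpy(float)
                for mode, f in cols
            ]
        )
        sd = mat.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        z = (mat - mat.mean(axis=0)) / sd
        scores, load, frac = _pc1(z)
        score_cols[pid] = scores
        ev[pid] = frac
        loadings[pid] = pd.Series(load, index=[f"{m}:{f}" for m, f in cols])
    scores = pd.DataFrame(score_cols, index=subjects_subset)
    return PathwayScoreMatrix(
        scores=scores, explained_variance=pd.Series(ev, dtype=float), loadings=loadings
    )


def pls_association(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_comp: int = 3,
    score_threshold: float = 0.3,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PLS2 association scores between pathway scores and immune markers.

    Returns (score matrix pathways × markers, retained edge list with
    columns pathway_id, marker_id, score, p).
    """
    common = X.index.intersection(Y.index)
    if len(common) < 3:
        raise ConfigurationError("need at least 3 aligned subjects")
    Xv = X.loc[common].to_numpy(float)
    Yv = Y.loc[common].to_numpy(float)
    n = len(common)

    def standardize(a: np.ndarray) -> np.ndarray:
        sd = a.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return (a - a.mean(axis=0)) / sd

    Xs, Ys = standardize(Xv), standardize(Yv)
    max_rank = min(n - 1, Xs.shape[1])
    k = min(n_comp, max_rank)
    if k < n_comp:
        warnings.warn(f"n_comp reduced to {k} (rank limit)")
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(Xs, Ys)
    B = pls.coef_.T if pls.coef_.shape[0] == Ys.shape[1] else pls.coef_
    # reconstructed cross-correlation: X'(X B)/(n-1)
    S = Xs.T @ (Xs @ B) / (n - 1)
    S = np.clip(S, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = S * np.sqrt((n - 2) / (1.0 - S**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(S) >= 1.0, 0.0, p)

    scores = pd.DataFrame(S, index=X.columns, columns=Y.columns)
    pmat = pd.DataFrame(p, index=X.columns, columns=Y.columns)
    rows = []
    for pid in scores.index:
        for mk in scores.columns:
            s, pv = float(scores.loc[pid, mk]), float(pmat.loc[pid, mk])
            if abs(s) > score_threshold and pv < p_threshold:
                rows.append({"pathway_id": pid, "marker_id": mk, "score": s, "p": pv})
    edges = pd.DataFrame(rows, columns=["pathway_id", "marker_id", "score", "p"])
    return scores, edges


def build_integration_network(
    edges: pd.DataFrame,
    marker_categories: pd.Series | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Bipartite pathway–marker graph weighted by |score|, with communities."""
    g = nx.Graph()
    if len(edges) == 0:
        warnings.warn("no retained pathway–marker edges; empty network")
        return g
    for _, row in edges.iterrows():
        pid, mk = row["pathway_id"], row["marker_id"]
        g.add_node(pid, kind="pathway")
        cat = None
        if marker_categories is not None and mk in marker_categories.index:
            cat = marker_categories[mk]
        g.add_node(mk, kind="marker", **({"category": cat} if cat else {}))
        g.add_edge(pid, mk, weight=abs(float(row["score"])),
                   score=float(row["score"]), p=float(row["p"]))
    detect_communities(g, seed=seed)
    return g
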