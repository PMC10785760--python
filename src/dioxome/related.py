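"""Selection of dioxin(-like)-related compounds and the exposure network.

A suspected chlorinated compound is "related" to a targeted congener when
its abundance correlates positively with the congener's concentration
(Spearman rho > 0 with two-sided p < 0.002, the study's 20%
false-discovery threshold for this screen). Compounds related to at
least one PCDD / PCDF / PCB are the PCDD- / PCDF- / PCB-related sets
(overlap allowed). Targeted and related compounds together form a
correlation network partitioned into communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import detect_communities
from .tables import ALL_CONGENERS, ConfigurationError, ExposurePanel, SUBCLASS_OF


@dataclass
class RelatedCompoundSet:
    """Per-congener related compounds and the derived subclass sets."""

    per_congener: dict[str, list[tuple[str, float, float]]]  # (id, rho, p)
    subclass_sets: dict[str, set[str]]                       # PCDD/PCDF/PCB -> ids

    @property
    def all_compounds(self) -> set[str]:
        return set().union(*self.subclass_sets.values()) if self.subclass_sets else set()

    def compounds_for(self, congener: str) -> list[str]:
        return [cid for cid, _, _ in self.per_congener.get(congener, [])]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"congener": c, "cluster_id": cid, "spearman_r": r, "p": p}
            for c, lst in self.per_congener.items()
            for cid, r, p in lst
        ]
        return pd.DataFrame(rows, columns=["congener", "cluster_id", "spearman_r", "p"])


def _spearman_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho (midrank ties) and two-sided t-approximation p for all
    column pairs of x (n×p) against y (n×q)."""
    n = x.shape[0]
    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y, axis=0)
    rx = (rx - rx.mean(axis=0)) / rx.std(axis=0)
    ry = (ry - ry.mean(axis=0)) / ry.std(axis=0)
    rho = rx.T @ ry / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def spearman_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p (t approximation) for one pair."""
    rho, p = _spearman_matrix(x[:, None].astype(float), y[:, None].astype(float))
    return float(rho[0, 0]), float(p[0, 0])


def spearman_select(
    suspect_abundance: pd.DataFrame,
    panel: ExposurePanel,
    p_max: float = 0.002,
) -> tuple[RelatedCompoundSet, list[dict]]:
    """Select related compounds per targeted congener.

    ``suspect_abundance`` is subjects × suspected compounds; the panel
    must be LOD-imputed and aligned on subjects. A pair qualifies iff
    rho > 0 and two-sided p < p_max. Constant columns are skipped with a
    warning record.
    """
    if len(suspect_abundance) < 10:
        raise ConfigurationError("need at least 10 subjects")
    common = suspect_abundance.index.intersection(panel.subjects)
    if len(common) != len(suspect_abundance):
        raise ConfigurationError("suspects and panel not aligned on subjects")
    xs = suspect_abundance.loc[common]
    ys = panel.concentrations.loc[common]

    warn_log = []
    const_x = xs.std(axis=0) == 0
    const_y = ys.std(axis=0) == 0
    for cid in xs.columns[const_x]:
        warn_log.append({"id": str(cid), "reason": "constant_abundance"})
    for c in ys.columns[const_y]:
        warn_log.append({"id": str(c), "reason": "constant_congener"})
    xs = xs.loc[:, ~const_x]
    ys = ys.loc[:, ~const_y]

    per_congener: dict[str, list[tuple[str, float, float]]] = {c: [] for c in ys.columns}
    if xs.shape[1] and ys.shape[1]:
        rho, p = _spearman_matrix(xs.to_numpy(float), ys.to_numpy(float))
        sel = (rho > 0) & (p < p_max)
        for j, congener in enumerate(ys.columns):
            for i in np.flatnonzero(sel[:, j]):
                per_congener[congener].append(
                    (str(xs.columns[i]), float(rho[i, j]), float(p[i, j]))
                )

    subclass_sets: dict[str, set[str]] = {"PCDD": set(), "PCDF": set(), "PCB": set()}
    for congener, lst in per_congener.items():
        sub = SUBCLASS_OF.get(congener)
        if sub:
            subclass_sets[sub].update(cid for cid, _, _ in lst)
    return RelatedCompoundSet(per_congener=per_congener, subclass_sets=subclass_sets), warn_log


def build_exposure_network(
    panel: ExposurePanel,
    selected: RelatedCompoundSet,
    suspect_abundance: pd.DataFrame,
    p_max: float = 0.002,
) -> nx.Graph:
    """Correlation network over the 29 congeners and the related compounds.

    Any node pair (targeted–targeted, targeted–related, related–related)
    with Spearman rho > 0 and p < p_max gets an edge weighted by rho.
    """
    related_ids = sorted(selected.all_compounds)
    data = pd.concat(
        [panel.concentrations, suspect_abundance[related_ids]], axis=1
    )
    g = nx.Graph()
    for c in panel.concentrations.columns:
        g.add_node(c, kind="targeted", subclass=SUBCLASS_OF[c])
    for cid in related_ids:
        subclasses = [s for s, ids in selected.subclass_sets.items() if cid in ids]
        g.add_node(cid, kind="related", subclass="+".join(sorted(subclasses)))
    cols = list(data.columns)
    keep = data.std(axis=0) > 0
    data = data.loc[:, keep]
    cols = list(data.columns)
    if len(cols) >= 2:
        rho, p = _spearman_matrix(data.to_numpy(float), data.to_numpy(float))
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if rho[i, j] > 0 and p[i, j] < p_max:
                    g.add_edge(cols[i], cols[j], weight=float(rho[i, j]))
    return g


def community_network(graph: nx.Graph, seed: int = 0) -> tuple[nx.Graph, dict]:
    """Attach multilevel community labels to the exposure network."""
    labels = detect_communities(graph, seed=seed)
    return graph, labels
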