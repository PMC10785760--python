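"""Adduct annotation of m/z features and pathway over-representation.

Untargeted features carry no identity; a feature is annotated to a
putative metabolite when its observed m/z matches a standard adduct of
the metabolite's neutral monoisotopic mass within ±5 ppm. Pathway
over-representation of the significant putative metabolites against the
detected-metabolite universe is scored by the one-sided hypergeometric
tail, and calibrated against a resampling null that draws random feature
lists of the same size — preserving the many-to-many feature→metabolite
mapping, in the spirit of m/z-level pathway analysis. A pathway passes
at permutation p < 0.05 with at least four significant metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    ConfigurationError,
    FeatureTable,
    M_ACN,
    M_CL35,
    M_H2O,
    M_HAC,
    M_NA,
    PROTON,
)

# adduct name -> m/z as a function of neutral mass M
ADDUCTS: dict[str, dict[str, callable]] = {
    "HILICpos": {
        "M+H": lambda M: M + PROTON,
        "M+2H": lambda M: (M + 2 * PROTON) / 2,
        "M+ACN+2H": lambda M: (M + M_ACN + 2 * PROTON) / 2,
        "M+Na": lambda M: M + M_NA,
        "M+ACN+H": lambda M: M + M_ACN + PROTON,
        "M+ACN+Na": lambda M: M + M_ACN + M_NA,
        "2M+H": lambda M: 2 * M + PROTON,
        "M+H+H2O": lambda M: M + PROTON + M_H2O,
    },
    "C18neg": {
        "M-H": lambda M: M - PROTON,
        "M-H2O-H": lambda M: M - M_H2O - PROTON,
        "M+Na-2H": lambda M: M + M_NA - 2 * PROTON,
        "M+Cl": lambda M: M + M_CL35,
        "M+Hac-H": lambda M: M + M_HAC - PROTON,
        "2M-H": lambda M: 2 * M - PROTON,
    },
}


@dataclass
class PathwayDB:
    """pathway_id → metabolite ids, with neutral monoisotopic masses (Da)."""

    members: dict[str, set[str]]
    masses: dict[str, float]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PathwayDB":
        if (frame["neutral_mass"] <= 0).any():
            raise ConfigurationError("metabolite masses must be positive")
        members: dict[str, set[str]] = {}
        for pid, g in frame.groupby("pathway_id"):
            members[pid] = set(g["metabolite_id"])
        masses = dict(zip(frame["metabolite_id"], frame["neutral_mass"].astype(float)))
        return cls(members=members, masses=masses)

    @classmethod
    def read_tsv(cls, path) -> "PathwayDB":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def annotate_features(
    features: FeatureTable | pd.DataFrame,
    db: PathwayDB,
    mode: str | None = None,
    ppm: float = 5.0,
) -> pd.DataFrame:
    """Match features to putative metabolites through adduct arithmetic.

    Returns every qualifying (feature_id, metabolite_id, adduct, ppm_error)
    triple — the mapping is many-to-many in both directions.
    """
    if isinstance(features, FeatureTable):
        meta = features.features
        mode = features.mode
    else:
        meta = features
    if mode not in ADDUCTS:
        raise ConfigurationError(f"no adduct table for mode {mode!r}")

    met_ids = np.array(list(db.masses))
    masses = np.array([db.masses[m] for m in met_ids], dtype=float)

    # precompute sorted theoretical m/z of every (metabolite, adduct)
    theo_mz, theo_met, theo_adduct = [], [], []
    for name, fn in ADDUCTS[mode].items():
        mz = fn(masses)
        theo_mz.append(mz)
        theo_met.append(met_ids)
        theo_adduct.append(np.full(len(met_ids), name, dtype=object))
    theo_mz = np.concatenate(theo_mz)
    theo_met = np.concatenate(theo_met)
    theo_adduct = np.concatenate(theo_adduct)
    order = np.argsort(theo_mz)
    theo_mz, theo_met, theo_adduct = theo_mz[order], theo_met[order], theo_adduct[order]

    rows = []
    fids = meta.index.to_numpy()
    obs = meta["mz"].to_numpy(float)
    tol = ppm * 1e-6
    lo = np.searchsorted(theo_mz, obs * (1 - tol) - 1e-9, side="left")
    hi = np.searchsorted(theo_mz, obs * (1 + tol) + 1e-9, side="right")
    for i in range(len(fids)):
        for j in range(lo[i], hi[i]):
            err = (obs[i] - theo_mz[j]) / theo_mz[j] * 1e6
            if abs(err) <= ppm:
                rows.append(
                    {
                        "feature_id": fids[i],
                        "metabolite_id": theo_met[j],
                        "adduct": theo_adduct[j],
                        "ppm_error": float(err),
                    }
                )
    return pd.DataFrame(rows, columns=["feature_id", "metabolite_id", "adduct", "ppm_error"])


def _metabolites_of(annotations: pd.DataFrame, feature_ids) -> set[str]:
    sel = annotations[annotations["feature_id"].isin(set(feature_ids))]
    return set(sel["metabolite_id"])


def hypergeom_p(overlap: int, pathway_size: int, n_sig: int, n_universe: int) -> float:
    """One-sided tail P(X >= overlap) for overlap of a size-``n_sig`` draw
    with ``pathway_size`` successes in a universe of ``n_universe``."""
    return float(stats.hypergeom.sf(overlap - 1, n_universe, pathway_size, n_sig))


def enrich_pathways(
    sig_features: list[str],
    all_features: list[str],
    db: PathwayDB,
    annotations: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathway over-representation with a feature-resampling null.

    The universe is the set of metabolites matched by any retained
    feature; the significant set those matched by a significant feature.
    ``fisher_p`` is the hypergeometric tail; ``perm_p`` compares it with
    the fisher_p of ``n_perm`` random feature lists of the same size,
    with a pseudo-count: (1 + #{perm ≤ obs}) / (n_perm + 1). A pathway
    passes iff perm_p < alpha and overlap ≥ min_overlap.
    """
    sig_set = set(sig_features)
    if not sig_set <= set(all_features):
        raise ConfigurationError("sig_features must be a subset of all_features")
    universe = _metabolites_of(annotations, all_features)
    if not universe:
        raise ConfigurationError("empty metabolite universe")
    n_universe = len(universe)

    # feature -> metabolite incidence restricted to the universe
    feat_index = {f: i for i, f in enumerate(all_features)}
    met_index = {m: i for i, m in enumerate(sorted(universe))}
    incidence = np.zeros((len(all_features), len(met_index)), dtype=bool)
    ann = annotations[annotations["feature_id"].isin(feat_index)]
    for f, m in zip(ann["feature_id"], ann["metabolite_id"]):
        if m in met_index:
            incidence[feat_index[f], met_index[m]] = True

    pathway_cols: dict[str, np.ndarray] = {}
    detected_size: dict[str, int] = {}
    for pid, mets in db.members.items():
        det = [met_index[m] for m in mets if m in met_index]
        if det:
            mask = np.zeros(len(met_index), dtype=bool)
            mask[det] = True
            pathway_cols[pid] = mask
            detected_size[pid] = len(det)

    pid_list = list(pathway_cols)
    pw_matrix = np.column_stack(
        [pathway_cols[p] for p in pid_list]
    ).astype(np.int64)  # mets x pathways
    sizes = np.array([detected_size[p] for p in pid_list])

    def pathway_stats(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        mets = incidence[features].any(axis=0)
        n_sig_met = int(mets.sum())
        overlaps = mets.astype(np.int64) @ pw_matrix
        ps = stats.hypergeom.sf(overlaps - 1, n_universe, sizes, n_sig_met)
        return overlaps, ps, n_sig_met

    sig_idx = np.array([feat_index[f] for f in sig_set], dtype=int)
    obs_overlap, obs_p, n_sig_met = pathway_stats(sig_idx)

    rng = np.random.default_rng(seed)
    count_le = np.zeros(len(pid_list), dtype=int)
    n_all = len(all_features)
    k = len(sig_idx)
    for _ in range(n_perm):
        perm = rng.choice(n_all, size=k, replace=False) if k else np.array([], int)
        _, perm_ps, _ = pathway_stats(perm)
        count_le += perm_ps <= obs_p + 1e-12
    perm_p = (1.0 + count_le) / (n_perm + 1.0)

    out = pd.DataFrame(
        {
            "pathway_id": pid_list,
            "overlap": obs_overlap,
            "pathway_size": sizes,
            "fisher_p": obs_p,
            "perm_p": perm_p,
            "pass": (perm_p < alpha) & (obs_overlap >= min_overlap),
        }
    ).set_index("pathway_id")
    return out.sort_values(["perm_p", "fisher_p"])


def enrich_by_subclass(
    subclass_features: dict[str, dict[str, list[str]]],
    metabolome: dict[str, FeatureTable],
    db: PathwayDB,
    n_perm: int = 1000,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run enrichment once per subclass per mode; merge with provenance.

    Returns the merged long table (subclass, mode columns added) and the
    per-mode annotation tables used.
    """
    annotations = {
        mode: annotate_features(table, db) for mode, table in metabolome.items()
    }
    parts = []
    for si, (sub, per_mode) in enumerate(subclass_features.items()):
        for mi, (mode, sig) in enumerate(per_mode.items()):
            table = metabolome[mode]
            all_features = list(table.intensities.columns)
            if not sig:
                continue
            res = enrich_pathways(
                sig, all_features, db, annotations[mode],
                n_perm=n_perm, seed=seed + 13 * si + mi, **kwargs,
            )
            res = res.reset_index()
            res.insert(0, "subclass", sub)
            res.insert(1, "mode", mode)
            parts.append(res)
    cols = ["subclass", "mode", "pathway_id", "overlap", "pathway_size",
            "fisher_p", "perm_p", "pass"]
    merged = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=cols)
    return merged, annotations
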