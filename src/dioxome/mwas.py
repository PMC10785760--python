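"""Metabolome-wide association scan with covariate adjustment and BH-FDR.

Each metabolome feature's ln intensity is regressed one-by-one on the ln
concentration of a single exposure (a targeted congener or a related
chlorinated compound), adjusting for age, factory and BMI (model 1) or
additionally smoking status and alcohol intake (model 2). Within each
exposure and each acquisition mode, Benjamini–Hochberg step-up q-values
control the FDR at 20%. Features significant for a congener or for at
least one of its related compounds aggregate into per-subclass feature
sets, the input to pathway enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .related import RelatedCompoundSet
from .tables import ALL_CONGENERS, ConfigurationError, FeatureTable, SUBCLASS_OF


def _design_matrix(
    covariates: pd.DataFrame, model: int
) -> tuple[np.ndarray, list[str], list[str]]:
    """Covariate design (without the exposure column); drops collinear
    factory/smoking indicators for single-level subsets, with a warning."""
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    dropped: list[str] = []
    cols.append(covariates["age"].to_numpy(float))
    names.append("age")
    fac = (covariates["factory"] == "A").to_numpy(float)
    if 0 < fac.sum() < n:
        cols.append(fac)
        names.append("factory_A")
    else:
        dropped.append("factory")
    cols.append(covariates["bmi"].to_numpy(float))
    names.append("bmi")
    if model == 2:
        for level in ("former", "current"):
            ind = (covariates["smoking"] == level).to_numpy(float)
            if 0 < ind.sum() < n:
                cols.append(ind)
                names.append(f"smoking_{level}")
            else:
                dropped.append(f"smoking_{level}")
        cols.append(covariates["alcohol"].to_numpy(float))
        names.append("alcohol")
    return np.column_stack(cols), names, dropped


def run_mwas(
    features: FeatureTable,
    exposure: pd.Series,
    covariates: pd.DataFrame,
    model: int = 1,
) -> pd.DataFrame:
    """OLS scan of every feature on one ln exposure.

    ``features`` must hold ln intensities (post-preprocessing);
    ``exposure`` is the ln concentration aligned on subjects. Returns one
    row per feature: beta (per unit ln exposure on ln intensity), se, t
    and the two-sided p for the exposure coefficient.
    """
    if not features.is_log:
        raise ConfigurationError("run_mwas expects ln-scale intensities")
    subjects = features.intensities.index
    x = exposure.reindex(subjects).to_numpy(float)
    if np.isnan(x).any():
        raise ConfigurationError("exposure missing for some subjects")
    cov, names, dropped = _design_matrix(covariates.reindex(subjects), model)
    if dropped:
        warnings.warn(f"collinear terms dropped: {', '.join(dropped)}")
    X = np.column_stack([x, cov])
    n, p = X.shape
    if n <= p:
        raise ConfigurationError("more parameters than subjects")
    Y = features.intensities.to_numpy(float)

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta_all = XtX_inv @ (X.T @ Y)           # p x m
    resid = Y - X @ beta_all
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(XtX_inv[0, 0] * sigma2)
    beta = beta_all[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    from scipy import stats as _st

    pvals = 2.0 * _st.t.sf(np.abs(t), df=dof)
    return pd.DataFrame(
        {"beta": beta, "se": se, "t": t, "p": pvals},
        index=features.intensities.columns,
    )


def bh_adjust(p, fdr: float = 0.20) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and q < fdr flags."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < fdr


@dataclass
class MWASResults:
    """Full scan over exposures × modes.

    ``tables[(exposure_id, mode)]`` is the per-feature frame with columns
    beta, se, t, p, q, significant; ``exposure_kind[exposure_id]`` is
    "targeted" or "related".
    """

    tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    exposure_kind: dict[str, str] = field(default_factory=dict)
    fdr: float = 0.20

    def significant(self, exposure: str, mode: str) -> set[str]:
        tab = self.tables.get((exposure, mode))
        if tab is None:
            return set()
        return set(tab.index[tab["significant"]])

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for (exp, mode), tab in self.tables.items():
            t = tab.reset_index(names="feature_id")
            t.insert(0, "exposure", exp)
            t.insert(1, "mode", mode)
            parts.append(t)
        if not parts:
            return pd.DataFrame(
                columns=["exposure", "mode", "feature_id", "beta", "se", "t", "p",
                         "q", "significant"]
            )
        return pd.concat(parts, ignore_index=True)


def run_full_mwas(
    metabolome: dict[str, FeatureTable],
    panel_ln: pd.DataFrame,
    related_abundance: pd.DataFrame,
    covariates: pd.DataFrame,
    model: int = 1,
    fdr: float = 0.20,
) -> MWASResults:
    """Scan every targeted congener and related compound against both modes.

    ``panel_ln`` is subjects × congeners of ln concentrations (post LOD
    imputation); ``related_abundance`` is subjects × related compounds of
    raw abundances (ln-transformed here). BH is applied separately per
    exposure per mode.
    """
    results = MWASResults(fdr=fdr)
    exposures: list[tuple[str, pd.Series, str]] = []
    for c in panel_ln.columns:
        exposures.append((c, panel_ln[c], "targeted"))
    for cid in related_abundance.columns:
        exposures.append((cid, np.log(related_abundance[cid]), "related"))
    for exp_id, vec, kind in exposures:
        results.exposure_kind[exp_id] = kind
        for mode, table in metabolome.items():
            scan = run_mwas(table, vec, covariates, model=model)
            q, flags = bh_adjust(scan["p"].to_numpy(), fdr=fdr)
            scan = scan.assign(q=q, significant=flags)
            results.tables[(exp_id, mode)] = scan
    return results


@dataclass
class SubclassFeatureSets:
    """Aggregated significant-feature sets mirroring the study's summary table."""

    per_congener: pd.DataFrame   # congener x mode counts (targeted/related/total)
    targeted_sets: dict[tuple[str, str], set[str]]   # (subclass, mode)
    related_sets: dict[tuple[str, str], set[str]]
    union_sets: dict[tuple[str, str], set[str]]


def aggregate_subclass(
    results: MWASResults, related: RelatedCompoundSet, modes: tuple[str, ...] = ("C18neg", "HILICpos")
) -> SubclassFeatureSets:
    """Count significant features per congener and pool them per subclass.

    For each congener and mode: the features significant for the congener
    itself ("targeted"), those significant for at least one of its
    related compounds ("related"; NA when the congener has none), and
    their union ("total"). Subclass sets are unions over the subclass's
    congeners.
    """
    rows = []
    targeted_sets: dict[tuple[str, str], set[str]] = {}
    related_sets: dict[tuple[str, str], set[str]] = {}
    union_sets: dict[tuple[str, str], set[str]] = {}
    for sub in ("PCDD", "PCDF", "PCB"):
        for mode in modes:
            targeted_sets[(sub, mode)] = set()
            related_sets[(sub, mode)] = set()

    for congener in ALL_CONGENERS:
        sub = SUBCLASS_OF[congener]
        rel_ids = related.compounds_for(congener)
        row: dict = {"congener": congener, "subclass": sub}
        for mode in modes:
            tset = results.significant(congener, mode)
            if rel_ids:
                rset: set[str] = set()
                for cid in rel_ids:
                    rset |= results.significant(cid, mode)
                row[f"{mode}_related"] = len(rset)
            else:
                rset = set()
                row[f"{mode}_related"] = pd.NA   # no related compounds
            row[f"{mode}_targeted"] = len(tset)
            row[f"{mode}_total"] = len(tset | rset)
            targeted_sets[(sub, mode)] |= tset
            related_sets[(sub, mode)] |= rset
        rows.append(row)

    for key in targeted_sets:
        union_sets[key] = targeted_sets[key] | related_sets[key]

    for sub in ("PCDD", "PCDF", "PCB"):
        row = {"congener": f"total_{sub}", "subclass": sub}
        for mode in modes:
            row[f"{mode}_targeted"] = len(targeted_sets[(sub, mode)])
            row[f"{mode}_related"] = len(related_sets[(sub, mode)])
            row[f"{mode}_total"] = len(union_sets[(sub, mode)])
        rows.append(row)

    per_congener = pd.DataFrame(rows).set_index("congener")
    return SubclassFeatureSets(
        per_congener=per_congener,
        targeted_sets=targeted_sets,
        related_sets=related_sets,
        union_sets=union_sets,
    )


def categorize_features(
    sets: SubclassFeatureSets, modes: tuple[str, ...] = ("C18neg", "HILICpos")
) -> dict[str, dict[str, list[str]]]:
    """Per-subclass, per-mode significant feature lists (overlap allowed)."""
    return {
        sub: {mode: sorted(sets.union_sets[(sub, mode)]) for mode in modes}
        for sub in ("PCDD", "PCDF", "PCB")
    }
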