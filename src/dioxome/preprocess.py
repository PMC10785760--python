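"""Feature-table quality control and imputation.

Order of operations for an LC-HRMS table with triplicate injections:

1. :func:`filter_features` — drop features with high technical-replicate
   CV or low detection, then average replicates.
2. :func:`correct_batches` — ln-transform and standardize each analytical
   batch to the pooled per-feature mean/SD (a location/scale
   simplification of empirical-Bayes batch correction).
3. :func:`impute_left_censored` — fill detection-limit missingness with
   draws from the left tail of a per-feature normal fit.

The targeted congener panel is imputed separately with a censored
log-normal maximum-likelihood fit (:func:`impute_targeted_lod`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tables import ConfigurationError, ExposurePanel, FeatureTable


def filter_features(
    table: FeatureTable, cv_max: float = 1.0, min_detect: float = 0.6
) -> tuple[FeatureTable, list[dict]]:
    """Remove unreliable features and average technical replicates.

    A feature is removed when the median across subjects of its
    within-subject replicate CV (SD/mean of raw intensities) is
    ``>= cv_max``, or when it is detected (non-missing in at least one
    replicate) in fewer than ``min_detect`` of subjects. Surviving
    features are averaged over replicates; a subject with no detected
    replicate stays missing.

    Returns the averaged table and a removal log (one record per dropped
    feature with the offending statistic).
    """
    if not table.has_replicates:
        raise ConfigurationError("filter_features requires a replicate dimension")
    subjects = table.subjects
    grouped = table.intensities.groupby(level=0, sort=False)
    mean = grouped.mean().reindex(subjects)            # nan-aware
    sd = grouped.std(ddof=1).reindex(subjects)
    detected = grouped.count().reindex(subjects) > 0   # >=1 replicate present

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv = (sd / mean).median(axis=0, skipna=True)
    detect_frac = detected.mean(axis=0)

    removal_log = []
    keep = []
    for f in table.intensities.columns:
        if detect_frac[f] < min_detect:
            removal_log.append(
                {"feature_id": f, "reason": "low_detection",
                 "detect_frac": float(detect_frac[f])}
            )
        elif np.isfinite(cv[f]) and cv[f] >= cv_max:
            removal_log.append(
                {"feature_id": f, "reason": "high_cv", "median_cv": float(cv[f])}
            )
        else:
            keep.append(f)

    averaged = mean[keep].where(detected[keep])
    out = FeatureTable(
        features=table.features.loc[keep].copy(),
        intensities=averaged,
        mode=table.mode,
        batches=None if table.batches is None else table.batches.copy(),
        is_log=table.is_log,
    )
    return out, removal_log


def correct_batches(table: FeatureTable) -> tuple[FeatureTable, list[dict]]:
    """ln-transform and remove per-batch location/scale per feature.

    For every feature, each batch's ln intensities are standardized and
    rescaled to the pooled (all-subject) mean and SD, so between-batch
    shifts cancel while the overall level is preserved. Features constant
    within some batch are ln-transformed but otherwise passed through,
    with a warning record. Requires every batch to contain at least three
    subjects. Output intensities are on the natural-log scale.
    """
    if table.has_replicates:
        raise ConfigurationError("average replicates (filter_features) before batch correction")
    if table.batches is None:
        batches = pd.Series("B1", index=table.intensities.index)
    else:
        batches = table.batches.reindex(table.intensities.index)
    counts = batches.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ConfigurationError(
            f"batch(es) with fewer than 3 subjects: {', '.join(map(str, small.index))}"
        )

    ln = table.intensities if table.is_log else np.log(table.intensities)
    values = ln.to_numpy(float).copy()
    pooled_mean = np.nanmean(values, axis=0)
    pooled_sd = np.nanstd(values, axis=0, ddof=1)

    warn_log = []
    codes = batches.to_numpy()
    constant = np.zeros(values.shape[1], dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in counts.index:
            rows = codes == b
            bsd = np.nanstd(values[rows], axis=0, ddof=1)
            constant |= ~(bsd > 0)
    for j in np.flatnonzero(constant):
        warn_log.append(
            {"feature_id": str(ln.columns[j]), "reason": "constant_within_batch"}
        )

    adj = np.zeros_like(values) * np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in counts.index:
            rows = codes == b
            bmean = np.nanmean(values[rows], axis=0)
            bsd = np.nanstd(values[rows], axis=0, ddof=1)
            z = (values[rows] - bmean) / bsd
            adj[rows] = pooled_mean + pooled_sd * z
    adj[:, constant] = values[:, constant]

    out = FeatureTable(
        features=table.features.copy(),
        intensities=pd.DataFrame(adj, index=ln.index, columns=ln.columns),
        mode=table.mode,
        batches=batches,
        is_log=True,
    )
    return out, warn_log


def impute_left_censored(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Fill missing values with left-tail draws below the observed minimum.

    Per feature, a normal law is fitted to the observed ln intensities and
    missing entries are drawn from the fitted distribution truncated above
    at the observed feature minimum — the censoring geometry of
    detection-limit missingness. Observed entries are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    ln = table.intensities if table.is_log else np.log(table.intensities)
    values = ln.to_numpy(float).copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        miss = ~np.isfinite(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if len(obs) < 3:
            raise ConfigurationError(
                f"feature {ln.columns[j]!r} has fewer than 3 observed values; "
                "filter before imputing"
            )
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        lo = float(obs.min())
        if sd <= 0:
            draws = np.full(miss.sum(), lo - 1e-6)
        else:
            b = (lo - mu) / sd
            draws = stats.truncnorm.rvs(
                -np.inf, b, loc=mu, scale=sd, size=int(miss.sum()), random_state=rng
            )
            draws = np.minimum(draws, lo - 1e-12)
        col[miss] = draws
        values[:, j] = col
    out_int = pd.DataFrame(values, index=ln.index, columns=ln.columns)
    if not table.is_log:
        out_int = np.exp(out_int)
    return FeatureTable(
        features=table.features.copy(), intensities=out_int, mode=table.mode,
        batches=None if table.batches is None else table.batches.copy(),
        is_log=table.is_log,
    )


# ---------------------------------------------------------------------------
# Targeted panel: censored log-normal MLE
# ---------------------------------------------------------------------------

def _censored_lognormal_mle(obs: np.ndarray, n_cens: int, lod: float) -> tuple[float, float]:
    """MLE of (mu, sigma) of a log-normal from observed values plus
    ``n_cens`` observations known only to lie below ``lod``."""
    x = np.log(obs)
    log_lod = np.log(lod)
    mu0, sd0 = float(x.mean()), float(max(x.std(ddof=0), 1e-3))

    def nll(theta: np.ndarray) -> float:
        mu, log_sd = theta
        sd = np.exp(log_sd)
        ll = stats.norm.logpdf(x, mu, sd).sum()
        if n_cens:
            ll += n_cens * stats.norm.logcdf(log_lod, mu, sd)
        return -ll

    res = optimize.minimize(nll, np.array([mu0, np.log(sd0)]), method="Nelder-Mead")
    mu, sd = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, sd


def _lognormal_tail_mean(mu: float, sd: float, lod: float) -> float:
    """E[X | X < lod] for X ~ LogNormal(mu, sd)."""
    a = (np.log(lod) - mu) / sd
    num = stats.norm.cdf(a - sd)
    den = stats.norm.cdf(a)
    if den <= 0:
        return lod / 2.0
    return float(np.exp(mu + 0.5 * sd * sd) * num / den)


def impute_targeted_lod(panel: ExposurePanel) -> ExposurePanel:
    """Replace below-LOD congener values by their censored-MLE conditional mean.

    Per congener, a censored log-normal MLE is fitted to the observed
    values with the flagged count censored at the LOD, and every flagged
    cell is replaced by E[X | X < LOD] under the fitted law — a single
    maximum-likelihood fill-in strictly inside (0, LOD).
    """
    conc = panel.concentrations.copy()
    for c in conc.columns:
        flagged = panel.below_lod[c].to_numpy(bool)
        if not flagged.any():
            continue
        obs = conc.loc[~flagged, c].to_numpy(float)
        if len(obs) == 0:
            raise ConfigurationError(f"congener {c!r}: all values censored")
        lod = float(panel.lod[c])
        mu, sd = _censored_lognormal_mle(obs, int(flagged.sum()), lod)
        fill = _lognormal_tail_mean(mu, sd, lod)
        fill = min(max(fill, np.nextafter(0.0, 1.0)), np.nextafter(lod, 0.0))
        conc.loc[flagged, c] = fill
    return ExposurePanel(
        concentrations=conc, below_lod=panel.below_lod.copy(),
        lod=panel.lod.copy(), imputed=True,
    )
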