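"""Spectral clustering of GC-HRMS features and chlorine-envelope screening.

Electron-ionization GC-HRMS fragments every compound into several
features; features belonging to one compound co-elute and co-vary across
subjects. Features are therefore grouped by a combined
correlation/retention-time similarity (average-linkage hierarchical
clustering), and each resulting spectrum is screened for the M, M+2,
M+4, ... isotopologue series that chlorine produces: with n chlorines the
relative abundance of the M+2k peak is binomial,
C(n,k)·p35^(n−k)·p37^k, with p37/p35 ≈ 0.3198 per chlorine and a 37Cl−35Cl
spacing of 1.99705 Da. The estimated chlorine count is the best
least-squares binomial fit over n = 1..10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .tables import (
    ConfigurationError,
    DELTA_M_CL,
    FeatureTable,
    P_CL35,
    P_CL37,
)


@dataclass
class IsotopeConstants:
    """Chlorine isotope constants and matching tolerances."""

    delta_m: float = DELTA_M_CL        # 37Cl - 35Cl, Da
    p35: float = P_CL35
    p37: float = P_CL37
    mass_tol: float = 0.005            # Da, absolute isotope-link tolerance
    ratio_tol: float = 0.30            # relative intensity tolerance per peak
    max_cl: int = 10
    k_max: int = 4                     # envelope considered up to M+8

    def __post_init__(self) -> None:
        if abs(self.p35 + self.p37 - 1.0) > 1e-4:
            raise ConfigurationError("isotope abundances must sum to 1")


@dataclass
class SpectrumCluster:
    """A group of co-eluting, co-varying features treated as one compound."""

    cluster_id: str
    member_ids: list[str]
    rt: float                           # intensity-weighted mean, s
    peaks: pd.DataFrame                 # columns mz, rel_intensity (max = 1)
    abundance: pd.Series                # weight-averaged intensity per subject


@dataclass
class IsotopeEnvelope:
    """An accepted chlorine envelope within a spectrum cluster."""

    mono_mz: float
    matched: list[tuple[int, float, float]]   # (k, mz, relative intensity)
    n_cl: int
    fit_rss: float


def cluster_spectra(
    chem: FeatureTable,
    sigma_rt: float = 2.0,
    sigma_r: float = 0.5,
    cut: float = 0.5,
) -> tuple[list[SpectrumCluster], list[dict]]:
    """Group features into compound spectra.

    Pairwise similarity combines intensity correlation and co-elution:
    ``s = exp(−(1−r)²/(2σ_r²)) · exp(−(Δrt)²/(2σ_rt²))`` with r the Pearson
    correlation of ln intensities. Average-linkage clustering on distance
    1−s is cut at ``cut``. Zero-variance features are excluded with a
    warning record. Each cluster's abundance vector is the mean of member
    intensities weighted by each feature's mean intensity, and its peak
    list is normalized to a maximum relative intensity of 1.
    """
    if chem.intensities.isna().to_numpy().any():
        raise ConfigurationError("cluster_spectra requires complete intensities")
    ln = chem.intensities if chem.is_log else np.log(chem.intensities)
    values = ln.to_numpy(float)
    raw = chem.intensities.to_numpy(float) if not chem.is_log else np.exp(values)

    sd = values.std(axis=0)
    warn_log = []
    ok = sd > 0
    for f in ln.columns[~ok]:
        warn_log.append({"feature_id": str(f), "reason": "zero_variance"})
    cols = list(ln.columns[ok])
    if len(cols) < 2:
        raise ConfigurationError("need at least 2 usable features")
    values = values[:, ok]
    raw = raw[:, ok]
    rt = chem.features.loc[cols, "rt"].to_numpy(float)
    mz = chem.features.loc[cols, "mz"].to_numpy(float)

    r = np.corrcoef(values, rowvar=False)
    sim = np.exp(-((1.0 - r) ** 2) / (2.0 * sigma_r**2))
    drt = rt[:, None] - rt[None, :]
    sim *= np.exp(-(drt**2) / (2.0 * sigma_rt**2))
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)

    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=cut, criterion="distance")

    clusters = []
    weights_all = raw.mean(axis=0)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        w = weights_all[idx]
        abundance = (raw[:, idx] * w).sum(axis=1) / w.sum()
        rel = w / w.max()
        order = np.argsort(mz[idx])
        peaks = pd.DataFrame(
            {"mz": mz[idx][order], "rel_intensity": rel[order]},
            index=[cols[i] for i in idx[order]],
        )
        crt = float((rt[idx] * w).sum() / w.sum())
        clusters.append(
            SpectrumCluster(
                cluster_id=f"SC{lab:05d}",
                member_ids=[cols[i] for i in idx],
                rt=crt,
                peaks=peaks,
                abundance=pd.Series(abundance, index=ln.index),
            )
        )
    assert len({c.cluster_id for c in clusters}) == len(clusters)
    return clusters, warn_log


def theoretical_cl_envelope(n_cl: int, k_max: int = 4) -> np.ndarray:
    """Relative abundances of M+2k (k = 0..min(n_cl, k_max)), mono = 1."""
    if n_cl < 0:
        raise ConfigurationError("n_cl must be nonnegative")
    if n_cl == 0:
        return np.array([1.0])
    k = np.arange(0, min(n_cl, k_max) + 1)
    ab = stats.binom.pmf(k, n_cl, P_CL37)
    return ab / ab[0]


def detect_chlorine_envelopes(
    cluster: SpectrumCluster, consts: IsotopeConstants | None = None
) -> IsotopeEnvelope | None:
    """Screen one spectrum cluster for a chlorine isotope envelope.

    Every peak without a partner at mz − Δm_Cl is a candidate monoisotopic
    peak; peaks at mono + k·Δm_Cl (k ≤ k_max) within the mass tolerance
    are collected, requiring at least M+2. The chlorine count n̂ minimizes
    the squared deviation between observed and theoretical envelopes
    (normalized to mono = 1) over n = 1..max_cl, ties toward smaller n.
    The envelope is accepted only if the mean relative intensity residual
    over matched isotope peaks is within ``ratio_tol``.
    """
    consts = consts or IsotopeConstants()
    mz = cluster.peaks["mz"].to_numpy(float)
    inten = cluster.peaks["rel_intensity"].to_numpy(float)
    if len(mz) < 2:
        return None

    best: IsotopeEnvelope | None = None
    for i in range(len(mz)):
        # must not itself be an isotope peak of something lighter
        if np.any(np.abs(mz - (mz[i] - consts.delta_m)) <= consts.mass_tol):
            continue
        matched = []
        obs = [inten[i]]
        for k in range(1, consts.k_max + 1):
            target = mz[i] + k * consts.delta_m
            d = np.abs(mz - target)
            j = int(np.argmin(d))
            if d[j] <= consts.mass_tol:
                matched.append((k, float(mz[j]), float(inten[j] / inten[i])))
                obs.append(inten[j])
        if not matched or matched[0][0] != 1:
            continue  # M+2 required
        ks = np.array([0] + [k for k, _, _ in matched])
        obs_rel = np.array([1.0] + [r for _, _, r in matched])

        best_n, best_rss = None, np.inf
        for n in range(1, consts.max_cl + 1):
            theo_full = theoretical_cl_envelope(n, consts.k_max)
            if ks.max() >= len(theo_full):
                theo = np.array(
                    [theo_full[k] if k < len(theo_full) else 0.0 for k in ks]
                )
            else:
                theo = theo_full[ks]
            rss = float(((obs_rel - theo) ** 2).sum())
            if rss < best_rss - 1e-12:  # strict improvement; ties -> smaller n
                best_rss, best_n = rss, n
        theo_full = theoretical_cl_envelope(best_n, consts.k_max)
        rel_res = []
        for k, _, r_obs in matched:
            t = theo_full[k] if k < len(theo_full) else 0.0
            denom = max(t, 1e-12)
            rel_res.append(abs(r_obs - t) / denom)
        if float(np.mean(rel_res)) > consts.ratio_tol:
            continue
        cand = IsotopeEnvelope(
            mono_mz=float(mz[i]), matched=matched, n_cl=int(best_n),
            fit_rss=best_rss,
        )
        if (
            best is None
            or len(cand.matched) > len(best.matched)
            or (len(cand.matched) == len(best.matched) and cand.fit_rss < best.fit_rss)
        ):
            best = cand
    return best


def suspect_list(
    clusters: list[SpectrumCluster], consts: IsotopeConstants | None = None
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Tabulate clusters whose spectra carry an accepted chlorine envelope.

    Returns a table (cluster_id, mono_mz, n_cl, rt, n_peaks, fit_rss) and
    a map cluster_id → per-subject abundance vector for the suspects.
    """
    consts = consts or IsotopeConstants()
    rows = []
    abundances: dict[str, pd.Series] = {}
    for cl in clusters:
        env = detect_chlorine_envelopes(cl, consts)
        if env is None:
            continue
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "mono_mz": env.mono_mz,
                "n_cl": env.n_cl,
                "rt": cl.rt,
                "n_peaks": len(cl.peaks),
                "fit_rss": env.fit_rss,
            }
        )
        abundances[cl.cluster_id] = cl.abundance
    table = pd.DataFrame(
        rows, columns=["cluster_id", "mono_mz", "n_cl", "rt", "n_peaks", "fit_rss"]
    ).set_index("cluster_id")
    return table, abundances
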