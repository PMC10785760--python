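"""Seeded synthetic cohort emulating a two-factory occupational dioxin study.

Generates every input the analysis pipeline consumes — subject covariates,
the 29-congener targeted exposure panel, an untargeted GC-HRMS chemical
feature table with planted chlorine isotope envelopes, two LC-HRMS
metabolome feature tables with planted exposure effects concentrated in
designated pathways, a pathway database, and an immune-marker table driven
by latent factors shared with the planted pathway signals — together with
the ground truth needed to score every downstream stage.

The default configuration mirrors the study population it emulates:
137 male workers from two herbicide factories (A: n=76, mean age 69.0;
B: n=61, mean age 58.8), with factory A carrying a strongly elevated TCDD
distribution (median ~4.35 vs ~0.30 ppt) and occupational lag periods,
and PCB congeners correlated at Spearman r > 0.9.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .tables import (
    ALL_CONGENERS,
    CONGENERS,
    ConfigurationError,
    DELTA_M_C13,
    DELTA_M_CL,
    ExposurePanel,
    FeatureTable,
    M_CL35,
    P_CL35,
    P_CL37,
    PROTON,
    SUBCLASS_OF,
    validate_subjects,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Exposures that drive the planted metabolome effects, one per subclass.
DRIVER_CONGENERS = {"PCDD": "TCDD", "PCDF": "23478F", "PCB": "PCB126"}

IMMUNE_CATEGORIES = {
    "cytokine_growth_factor": 21,
    "hematologic": 23,
    "humoral": 7,
    "lymphoma": 3,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort, with study-scale defaults.

    The defaults are the conditions every acceptance-level check runs
    under; the full-scale variant (:func:`full_scale_config`) only raises
    feature counts.
    """

    # cohort
    n_A: int = 76
    n_B: int = 61
    age_mean: dict = field(default_factory=lambda: {"A": 69.0, "B": 58.8})
    age_sd: dict = field(default_factory=lambda: {"A": 7.7, "B": 9.0})
    bmi_mean: dict = field(default_factory=lambda: {"A": 26.9, "B": 27.1})
    bmi_sd: dict = field(default_factory=lambda: {"A": 3.0, "B": 3.6})
    alcohol_mean: float = 13.5
    alcohol_sd: float = 14.0
    smoking_probs: tuple = (0.18, 0.57, 0.25)  # never / former / current
    lag_range: tuple = (25.0, 45.0)            # factory-A lag period, years

    # targeted exposure panel
    tcdd_log_median: dict = field(default_factory=lambda: {"A": 1.47, "B": -1.20})
    congener_log_gm: float = 3.0               # ln ppt, other congeners
    congener_log_gsd: float = 0.8              # ln-scale SD of all congeners
    pcdd_factory_shift: float = 0.5            # ln-scale factory-A excess (PCDDs)
    subclass_rho: dict = field(
        default_factory=lambda: {"PCDD": 0.5, "PCDF": 0.2, "PCB": 0.92}
    )
    lod_quantile: float = 0.10                 # LOD at this background quantile

    # GC-HRMS chemical features
    n_chem_features: int = 800
    n_chlorinated: int = 60
    n_decoys: int = 200
    n_related: int = 30                        # chlorinated compounds tied to congeners
    related_r: float = 0.8                     # ln-scale correlation with congener
    chem_noise_sd: float = 0.05                # multiplicative intensity noise (ln)
    rt_jitter_sd: float = 0.2                  # within-compound RT jitter, s
    c13_distractor_frac: float = 0.5           # decoys carrying a 13C M+1 peak

    # metabolome
    n_metab_features: int = 1500               # per mode
    n_pathways: int = 25
    metabolites_per_pathway: int = 20
    n_affected_metabolites: int = 12           # per enriched pathway
    beta: float = 0.5                          # per unit ln-exposure on ln-intensity
    age_beta: float = 0.01
    bmi_beta: float = 0.02
    metab_noise_sd: float = 0.5                # biological noise, ln scale
    replicate_noise_sd: float = 0.08           # technical noise, ln scale
    n_replicates: int = 3
    n_batches: int = 2
    batch_effect_sd: float = 0.3               # per feature x batch shift, ln scale
    detected_null_frac: float = 0.3            # null features placed on db metabolites
    missing_rate: float = 0.08                 # left-censored fraction per feature
    frac_high_cv: float = 0.02
    frac_low_detect: float = 0.02

    # immune markers
    n_loaded_markers: int = 5                  # markers per latent pathway factor
    marker_loading: float = 0.8

    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_A, self.n_B, self.n_chem_features, self.n_chlorinated,
            self.n_decoys, self.n_related, self.n_metab_features,
            self.n_pathways, self.metabolites_per_pathway, self.n_replicates,
            self.n_batches,
        )
        if any(int(c) != c or c < 0 for c in counts):
            raise ConfigurationError("counts must be nonnegative integers")
        rates = (
            self.lod_quantile, self.missing_rate, self.detected_null_frac,
            self.frac_high_cv, self.frac_low_detect, self.c13_distractor_frac,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.n_related > self.n_chlorinated:
            raise ConfigurationError("n_related cannot exceed n_chlorinated")
        if not 0 <= self.related_r < 1:
            raise ConfigurationError("related_r must lie in [0, 1)")

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def full_scale_config(seed: int = 0) -> SimConfig:
    """Configuration at the scale of the emulated study's feature counts."""
    return SimConfig(
        n_chem_features=11000, n_chlorinated=499, n_decoys=3000, n_related=152,
        n_metab_features=7000, n_pathways=80, seed=seed,
    )


@dataclass
class GroundTruth:
    """Planted structure for scoring the pipeline against known truth."""

    chlorinated: dict = field(default_factory=dict)   # compound -> n_cl
    compound_features: dict = field(default_factory=dict)  # compound -> [feature]
    related: dict = field(default_factory=dict)       # congener -> [(compound, r)]
    affected: dict = field(default_factory=dict)      # mode -> feature -> info
    enriched_pathways: dict = field(default_factory=dict)  # pathway -> info
    marker_loadings: dict = field(default_factory=dict)    # pathway -> marker -> λ

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(**{f.name: getattr(self, f.name) for f in dataclasses.fields(self)})
        for f in dataclasses.fields(other):
            getattr(out, f.name).update(getattr(other, f.name))
        return out


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive stream per generator stage
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate the subject covariate table.

    Returns a DataFrame indexed by ``subject_id`` with factory, age, BMI,
    smoking status, alcohol intake (units/week) and, for factory-A workers,
    the occupational lag period (years since last exposure).
    """
    rng = _rng(config, 1)
    rows = []
    for factory, n in (("A", config.n_A), ("B", config.n_B)):
        age = rng.normal(config.age_mean[factory], config.age_sd[factory], n)
        age = np.clip(age, 30.0, None)
        bmi = np.clip(rng.normal(config.bmi_mean[factory], config.bmi_sd[factory], n), 15.0, None)
        alcohol = np.clip(rng.normal(config.alcohol_mean, config.alcohol_sd, n), 0.0, None)
        smoking = rng.choice(["never", "former", "current"], size=n, p=config.smoking_probs)
        if factory == "A":
            lag = rng.uniform(*config.lag_range, n)
        else:
            lag = np.zeros(n)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{factory}{i + 1:03d}",
                    "factory": factory,
                    "age": age[i],
                    "bmi": bmi[i],
                    "smoking": smoking[i],
                    "alcohol": alcohol[i],
                    "lag_years": lag[i],
                }
            )
    cols = ["factory", "age", "bmi", "smoking", "alcohol", "lag_years"]
    if not rows:
        subjects = pd.DataFrame(columns=cols, index=pd.Index([], name="subject_id"))
    else:
        subjects = pd.DataFrame(rows).set_index("subject_id")
    validate_subjects(subjects)
    return subjects


# ---------------------------------------------------------------------------
# Targeted exposure panel
# ---------------------------------------------------------------------------

def generate_targeted_exposures(subjects: pd.DataFrame, config: SimConfig) -> ExposurePanel:
    """Simulate the 29-congener lipid-adjusted panel (ppt).

    Marginals are log-normal; within-subclass dependence is imposed through
    an equicorrelated Gaussian copula, so rank correlations are preserved.
    TCDD is stochastically larger in factory A; the other PCDDs carry a
    smaller factory-A shift; PCDFs and PCBs are factory-neutral. Values
    below the per-congener LOD are flagged, not zeroed.
    """
    if len(subjects) == 0:
        raise ConfigurationError("subjects table is empty")
    rng = _rng(config, 2)
    n = len(subjects)
    is_a = (subjects["factory"] == "A").to_numpy()

    log_conc = {}
    for subclass, congeners in CONGENERS.items():
        rho = float(config.subclass_rho[subclass])
        common = rng.standard_normal(n)
        for c in congeners:
            eps = rng.standard_normal(n)
            z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * eps
            if c == "TCDD":
                mu = np.where(is_a, config.tcdd_log_median["A"], config.tcdd_log_median["B"])
            elif subclass == "PCDD":
                base = config.congener_log_gm + rng.normal(0.0, 0.3)
                mu = np.where(is_a, base + config.pcdd_factory_shift, base)
            else:
                mu = np.full(n, config.congener_log_gm + rng.normal(0.0, 0.3))
            log_conc[c] = mu + config.congener_log_gsd * z

    conc = pd.DataFrame(
        {c: np.exp(log_conc[c]) for c in ALL_CONGENERS}, index=subjects.index
    )
    # LOD fixed at a low quantile of the background (factory-B-like) law
    z_q = stats.norm.ppf(config.lod_quantile) if config.lod_quantile > 0 else -np.inf
    lod = {}
    for c in ALL_CONGENERS:
        if c == "TCDD":
            mu_bg = config.tcdd_log_median["B"]
        else:
            mu_bg = config.congener_log_gm
        lod[c] = float(np.exp(mu_bg + config.congener_log_gsd * z_q)) if np.isfinite(z_q) else 0.0
    lod = pd.Series(lod).reindex(ALL_CONGENERS)
    below = conc.lt(lod, axis=1)
    return ExposurePanel(concentrations=conc, below_lod=below, lod=lod)


# ---------------------------------------------------------------------------
# GC-HRMS chemical features with chlorine envelopes
# ---------------------------------------------------------------------------

def _envelope_rel(n_cl: int, k_max: int = 4) -> np.ndarray:
    """Relative M+2k abundances (mono = 1) for ``n_cl`` chlorines."""
    k = np.arange(0, min(n_cl, k_max) + 1)
    ab = stats.binom.pmf(k, n_cl, P_CL37)
    return ab / ab[0]


def generate_chem_features(
    subjects: pd.DataFrame, panel: ExposurePanel, config: SimConfig
) -> tuple[FeatureTable, GroundTruth]:
    """Simulate the untargeted GC-HRMS chemical feature table.

    Each planted chlorinated compound contributes a co-eluting peak group:
    the monoisotopic peak plus M+2k peaks whose relative abundances follow
    the binomial 35Cl/37Cl law for its true chlorine count. A configured
    subset of compound abundances is generated to correlate (on the ln
    scale) with chosen targeted congeners. Decoy compounds carry no
    chlorine envelope; half of them carry a small 13C M+1 distractor peak.
    """
    rng = _rng(config, 3)
    n = len(subjects)
    gt = GroundTruth()

    ln_panel = np.log(panel.concentrations.to_numpy(float))
    z_panel = (ln_panel - ln_panel.mean(axis=0)) / ln_panel.std(axis=0)

    # which chlorinated compounds track which congener
    related_idx = rng.choice(config.n_chlorinated, size=config.n_related, replace=False)
    congener_for = {}
    for j, ci in enumerate(related_idx):
        congener_for[ci] = ALL_CONGENERS[int(rng.integers(0, len(ALL_CONGENERS)))]

    feat_rows: list[dict] = []
    intensity_cols: dict[str, np.ndarray] = {}

    def add_feature(fid: str, mz: float, rt: float, values: np.ndarray) -> None:
        feat_rows.append({"feature_id": fid, "mz": mz, "rt": rt})
        intensity_cols[fid] = values

    fcount = 0

    def next_fid() -> str:
        nonlocal fcount
        fcount += 1
        return f"GC_F{fcount:05d}"

    # --- chlorinated compounds -------------------------------------------
    for ci in range(config.n_chlorinated):
        cid = f"CHL{ci + 1:03d}"
        n_cl = int(rng.integers(1, 9))
        mono = rng.uniform(120.0, 830.0)
        rt = rng.uniform(60.0, 1200.0)
        base = rng.normal(11.5, 1.0)  # ln abundance scale
        if ci in congener_for:
            cong = congener_for[ci]
            z = z_panel[:, ALL_CONGENERS.index(cong)]
            r = config.related_r
            ln_ab = base + 1.0 * (r * z + np.sqrt(1 - r * r) * rng.standard_normal(n))
            gt.related.setdefault(cong, []).append([cid, r])
        else:
            ln_ab = base + rng.standard_normal(n)
        abundance = np.exp(ln_ab)

        rel = _envelope_rel(n_cl)
        fids = []
        for k, r_k in enumerate(rel):
            noise = np.exp(rng.normal(0.0, config.chem_noise_sd, n))
            fid = next_fid()
            add_feature(
                fid,
                mono + k * DELTA_M_CL,
                rt + rng.normal(0.0, config.rt_jitter_sd),
                r_k * abundance * noise,
            )
            fids.append(fid)
        gt.chlorinated[cid] = n_cl
        gt.compound_features[cid] = fids

    # --- decoy compounds (no Cl envelope) --------------------------------
    for di in range(config.n_decoys):
        cid = f"DEC{di + 1:03d}"
        mono = rng.uniform(85.0, 845.0)
        rt = rng.uniform(60.0, 1200.0)
        abundance = np.exp(rng.normal(11.0, 1.0) + rng.standard_normal(n))
        fids = []
        fid = next_fid()
        add_feature(fid, mono, rt + rng.normal(0.0, config.rt_jitter_sd),
                    abundance * np.exp(rng.normal(0.0, config.chem_noise_sd, n)))
        fids.append(fid)
        if rng.random() < config.c13_distractor_frac:
            fid = next_fid()
            add_feature(
                fid, mono + DELTA_M_C13, rt + rng.normal(0.0, config.rt_jitter_sd),
                0.15 * abundance * np.exp(rng.normal(0.0, config.chem_noise_sd, n)),
            )
            fids.append(fid)
        gt.compound_features[cid] = fids

    # --- filler noise features up to the target feature count ------------
    while fcount < config.n_chem_features:
        mono = rng.uniform(85.0, 849.0)
        rt = rng.uniform(60.0, 1200.0)
        values = np.exp(rng.normal(10.0, 1.0) + rng.standard_normal(n))
        add_feature(next_fid(), mono, rt, values)

    features = pd.DataFrame(feat_rows).set_index("feature_id")
    intensities = pd.DataFrame(intensity_cols, index=subjects.index)
    table = FeatureTable(features=features, intensities=intensities, mode="GC")
    return table, gt


# ---------------------------------------------------------------------------
# Pathway database and metabolome
# ---------------------------------------------------------------------------

def generate_pathway_db(config: SimConfig) -> pd.DataFrame:
    """Synthetic pathway database: pathway_id, metabolite_id, neutral mass (Da)."""
    rng = _rng(config, 4)
    rows = []
    m = 0
    for p in range(config.n_pathways):
        pid = f"PW{p + 1:03d}"
        for _ in range(config.metabolites_per_pathway):
            m += 1
            rows.append(
                {
                    "pathway_id": pid,
                    "metabolite_id": f"MET{m:04d}",
                    "neutral_mass": float(rng.uniform(100.0, 900.0)),
                }
            )
    return pd.DataFrame(rows)


_MODE_ADDUCT = {"C18neg": -PROTON, "HILICpos": PROTON}


def generate_metabolome(
    subjects: pd.DataFrame,
    panel: ExposurePanel,
    config: SimConfig,
    pathway_db: pd.DataFrame | None = None,
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Simulate the C18-negative and HILIC-positive metabolome tables.

    One pathway per congener subclass is designated "enriched": a set of
    its metabolites receives features (placed at the M−H or M+H adduct
    m/z) whose ln intensity carries a linear effect of the subclass's
    driver exposure plus small age and BMI effects. Triplicate
    measurements carry technical noise and per-feature batch shifts; the
    lowest ``missing_rate`` of each feature's subject values are
    left-censored. Small fractions of deliberately bad features (high
    replicate CV; low detection) exercise the QC filters.
    """
    if pathway_db is None:
        pathway_db = generate_pathway_db(config)
    rng = _rng(config, 5)
    n = len(subjects)
    gt = GroundTruth()

    pathway_ids = list(dict.fromkeys(pathway_db["pathway_id"]))
    if len(pathway_ids) < len(DRIVER_CONGENERS):
        raise ConfigurationError("need at least one pathway per congener subclass")
    enriched = {}
    for i, (subclass, congener) in enumerate(DRIVER_CONGENERS.items()):
        pid = pathway_ids[i]
        enriched[pid] = {"subclass": subclass, "exposure": congener}
    gt.enriched_pathways = enriched

    ln_exposure = np.log(panel.concentrations.to_numpy(float))
    age = subjects["age"].to_numpy(float)
    bmi = subjects["bmi"].to_numpy(float)

    batch_labels = pd.Series(
        [f"B{(i % config.n_batches) + 1}" for i in range(n)], index=subjects.index,
        name="batch",
    )
    batch_codes = np.array([int(b[1:]) - 1 for b in batch_labels])

    mass_of = dict(zip(pathway_db["metabolite_id"], pathway_db["neutral_mass"]))
    members = {
        pid: list(g["metabolite_id"]) for pid, g in pathway_db.groupby("pathway_id")
    }

    tables = {}
    for mode in ("C18neg", "HILICpos"):
        offset = _MODE_ADDUCT[mode]
        feat_rows = []
        subject_means = np.empty((n, 0))
        affected_info = {}
        fnum = 0

        def fid() -> str:
            nonlocal fnum
            fnum += 1
            return f"{mode}_F{fnum:05d}"

        cols: list[str] = []
        mean_list: list[np.ndarray] = []

        # planted affected features, one per chosen metabolite of each pathway
        for pid, info in enriched.items():
            mets = members[pid]
            chosen = list(rng.choice(mets, size=min(config.n_affected_metabolites, len(mets)),
                                     replace=False))
            x = ln_exposure[:, ALL_CONGENERS.index(info["exposure"])]
            for met in chosen:
                f = fid()
                mz = mass_of[met] + offset
                base = rng.normal(9.0, 0.5)
                mu = (base + config.beta * x + config.age_beta * age
                      + config.bmi_beta * bmi
                      + rng.normal(0.0, config.metab_noise_sd, n))
                feat_rows.append({"feature_id": f, "mz": mz,
                                  "rt": rng.uniform(30.0, 600.0)})
                cols.append(f)
                mean_list.append(mu)
                affected_info[f] = {
                    "exposure": info["exposure"], "beta": config.beta,
                    "pathway": pid, "metabolite": met, "subclass": info["subclass"],
                }

        # null features: a fraction sit on (random) database metabolites so the
        # annotation universe is realistic; the rest at arbitrary m/z
        all_mets = list(mass_of)
        n_null = max(config.n_metab_features - fnum, 0)
        on_db = rng.random(n_null) < config.detected_null_frac
        for i in range(n_null):
            f = fid()
            if on_db[i]:
                met = all_mets[int(rng.integers(0, len(all_mets)))]
                mz = mass_of[met] + offset
            else:
                mz = rng.uniform(85.0, 1275.0)
            mz = float(np.clip(mz, 85.0, 1275.0))
            base = rng.normal(9.0, 1.0)
            mu = (base + config.age_beta * age + config.bmi_beta * bmi
                  + rng.normal(0.0, max(config.metab_noise_sd, 0.3), n))
            feat_rows.append({"feature_id": f, "mz": mz, "rt": rng.uniform(30.0, 600.0)})
            cols.append(f)
            mean_list.append(mu)

        mu_mat = np.column_stack(mean_list) if mean_list else np.empty((n, 0))
        m = mu_mat.shape[1]

        # replicate expansion with technical noise and per-feature batch shifts
        rep_sd = np.full(m, config.replicate_noise_sd)
        n_bad_cv = int(round(config.frac_high_cv * m))
        bad_cv_idx = rng.choice(m, size=n_bad_cv, replace=False) if n_bad_cv else np.array([], int)
        rep_sd[bad_cv_idx] = 1.5

        batch_shift = rng.normal(0.0, config.batch_effect_sd,
                                 size=(config.n_batches, m))
        reps = []
        index = []
        for r in range(config.n_replicates):
            noise = rng.normal(0.0, 1.0, size=(n, m)) * rep_sd
            ln_i = mu_mat + batch_shift[batch_codes, :] + noise
            reps.append(np.exp(ln_i))
            index.extend((s, r + 1) for s in subjects.index)
        values = np.vstack(reps)

        # left-censoring: per feature, subjects in the lowest missing_rate of
        # true means lose all replicates (below detection limit)
        if config.missing_rate > 0 and n > 0:
            k = int(np.floor(config.missing_rate * n))
            if k > 0:
                order = np.argsort(mu_mat, axis=0)
                for j in range(m):
                    low = order[:k, j]
                    for r in range(config.n_replicates):
                        values[r * n + low, j] = np.nan

        # low-detection features: drop to below the detection filter
        n_bad_det = int(round(config.frac_low_detect * m))
        if n_bad_det:
            bad_det_idx = rng.choice(
                np.setdiff1d(np.arange(m), bad_cv_idx), size=n_bad_det, replace=False
            )
            for j in bad_det_idx:
                drop = rng.choice(n, size=int(np.ceil(0.5 * n)), replace=False)
                for r in range(config.n_replicates):
                    values[r * n + drop, j] = np.nan

        intensities = pd.DataFrame(
            values,
            index=pd.MultiIndex.from_tuples(index, names=["subject_id", "replicate"]),
            columns=cols,
        ).sort_index()
        features = pd.DataFrame(feat_rows).set_index("feature_id")
        tables[mode] = FeatureTable(
            features=features, intensities=intensities, mode=mode,
            batches=batch_labels,
        )
        gt.affected[mode] = affected_info

    return tables["C18neg"], tables["HILICpos"], gt


# ---------------------------------------------------------------------------
# Immune markers
# ---------------------------------------------------------------------------

def marker_names() -> tuple[list[str], pd.Series]:
    prefixes = {"cytokine_growth_factor": "CYT", "hematologic": "HEM",
                "humoral": "HUM", "lymphoma": "LYM"}
    names, cats = [], []
    for cat, k in IMMUNE_CATEGORIES.items():
        for i in range(k):
            names.append(f"{prefixes[cat]}{i + 1:02d}")
            cats.append(cat)
    return names, pd.Series(cats, index=names, name="category")


def generate_immune_markers(
    subjects: pd.DataFrame,
    config: SimConfig,
    panel: ExposurePanel | None = None,
    ground_truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate 54 immune markers in 4 categories (21/23/7/3).

    Each enriched pathway's latent factor is the standardized ln
    concentration of its driver exposure — the same signal that drives the
    pathway's planted metabolome features — and a designated set of
    markers loads on it with loading ``marker_loading``; remaining
    markers are independent noise. With no panel (or zero loading) all
    markers are pure noise.

    Returns (marker table, category labels, ground truth with loadings).
    """
    if len(subjects) == 0:
        raise ConfigurationError("subjects table is empty")
    rng = _rng(config, 6)
    n = len(subjects)
    names, categories = marker_names()
    values = rng.standard_normal((n, len(names)))
    gt = ground_truth if ground_truth is not None else GroundTruth()

    lam = config.marker_loading
    if panel is not None and lam != 0.0 and gt.enriched_pathways:
        free = list(range(len(names)))
        for pid, info in gt.enriched_pathways.items():
            x = np.log(panel.concentrations[info["exposure"]].to_numpy(float))
            f = (x - x.mean()) / x.std()
            pick = rng.choice(len(free), size=min(config.n_loaded_markers, len(free)),
                              replace=False)
            chosen = [free[i] for i in sorted(pick)]
            for i in sorted(pick, reverse=True):
                free.pop(i)
            loadings = {}
            for j in chosen:
                values[:, j] = lam * f + np.sqrt(1 - lam * lam) * rng.standard_normal(n)
                loadings[names[j]] = lam
            gt.marker_loadings[pid] = loadings

    markers = pd.DataFrame(values, index=subjects.index, columns=names)
    return markers, categories, gt


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Everything the pipeline needs, generated from one seed."""

    config: SimConfig
    subjects: pd.DataFrame
    panel: ExposurePanel
    chem: FeatureTable
    c18neg: FeatureTable
    hilicpos: FeatureTable
    pathway_db: pd.DataFrame
    markers: pd.DataFrame
    marker_categories: pd.Series
    ground_truth: GroundTruth

    def write(self, outdir: Path | str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "sim_config.yaml")
        self.subjects.to_csv(outdir / "subjects.tsv", sep="\t")
        self.panel.write(outdir / "panel")
        self.chem.write(outdir / "chem")
        self.c18neg.write(outdir / "c18neg")
        self.hilicpos.write(outdir / "hilicpos")
        self.pathway_db.to_csv(outdir / "pathway_db.tsv", sep="\t", index=False)
        self.markers.to_csv(outdir / "immune_markers.tsv", sep="\t")
        self.marker_categories.to_csv(outdir / "marker_categories.tsv", sep="\t")
        self.ground_truth.to_json(outdir / "ground_truth.json")


def generate_study(config: SimConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study from a single configuration."""
    config = config if config is not None else SimConfig()
    subjects = generate_cohort(config)
    panel = generate_targeted_exposures(subjects, config)
    chem, gt_chem = generate_chem_features(subjects, panel, config)
    db = generate_pathway_db(config)
    c18, hilic, gt_met = generate_metabolome(subjects, panel, config, db)
    gt = gt_chem.merge(gt_met)
    markers, categories, gt = generate_immune_markers(subjects, config, panel, gt)
    return SyntheticStudy(
        config=config, subjects=subjects, panel=panel, chem=chem,
        c18neg=c18, hilicpos=hilic, pathway_db=db, markers=markers,
        marker_categories=categories, ground_truth=gt,
    )
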