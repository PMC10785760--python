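"""Shared data containers and physical constants.

The pipeline's interchange containers are thin wrappers around pandas
DataFrames: a :class:`FeatureTable` for untargeted feature matrices
(GC-HRMS chemical features and LC-HRMS metabolome features) and an
:class:`ExposurePanel` for the 29-congener targeted dioxin(-like) panel.
All tables serialize to TSV with a one-line header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Targeted congener panel: 7 PCDDs, 10 dioxin-like PCDFs, 12 dioxin-like PCBs
# --------------------------------------------------------------------------

CONGENERS: dict[str, tuple[str, ...]] = {
    "PCDD": ("TCDD", "12378D", "123478D", "123678D", "123789D", "1234678D", "OCDD"),
    "PCDF": (
        "2378F", "12378F", "23478F", "123478F", "123678F",
        "123789F", "234678F", "1234678F", "1234789F", "OCDF",
    ),
    "PCB": (
        "PCB77", "PCB81", "PCB126", "PCB169", "PCB105", "PCB114",
        "PCB118", "PCB123", "PCB156", "PCB157", "PCB167", "PCB189",
    ),
}

ALL_CONGENERS: tuple[str, ...] = tuple(
    c for sub in ("PCDD", "PCDF", "PCB") for c in CONGENERS[sub]
)

SUBCLASS_OF: dict[str, str] = {
    c: sub for sub, cs in CONGENERS.items() for c in cs
}

# m/z scan ranges per acquisition mode (Th)
SCAN_RANGE: dict[str, tuple[float, float]] = {
    "GC": (85.0, 850.0),
    "C18neg": (85.0, 1275.0),
    "HILICpos": (85.0, 1275.0),
}

# Monoisotopic masses (Da) used for isotope spacing and adduct arithmetic
PROTON = 1.007276
M_NA = 22.989770
M_CL35 = 34.968853
M_ACN = 41.026549       # acetonitrile CH3CN
M_HAC = 60.021129       # acetic acid CH3COOH
M_H2O = 18.010565
DELTA_M_CL = 1.99705    # 37Cl - 35Cl
DELTA_M_C13 = 1.00336   # 13C - 12C
P_CL35 = 0.7577
P_CL37 = 0.2423


class ConfigurationError(ValueError):
    """Raised when a configuration or precondition is violated."""


@dataclass
class FeatureTable:
    """An untargeted feature matrix with per-feature m/z and retention time.

    Parameters
    ----------
    features
        Indexed by ``feature_id``; columns ``mz`` (Th) and ``rt`` (seconds).
    intensities
        Wide matrix of raw or ln intensities. Rows are subjects (index
        ``subject_id``) or, before replicate averaging, a MultiIndex
        ``(subject_id, replicate)``. Columns are feature ids. ``NaN``
        marks a missing (undetected) value.
    mode
        One of ``GC``, ``C18neg``, ``HILICpos``.
    batches
        Optional per-subject batch label (analytical batch of the run).
    is_log
        True once intensities are on the natural-log scale.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    mode: str
    batches: pd.Series | None = None
    is_log: bool = False

    def __post_init__(self) -> None:
        if self.mode not in SCAN_RANGE:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        lo, hi = SCAN_RANGE[self.mode]
        mz = self.features["mz"].to_numpy(float)
        if len(mz) and (mz.min() < lo or mz.max() > hi):
            raise ConfigurationError(
                f"m/z outside {self.mode} scan range [{lo}, {hi}]"
            )
        if (self.features["rt"].to_numpy(float) < 0).any():
            raise ConfigurationError("negative retention time")
        if not self.features.index.is_unique:
            raise ConfigurationError("feature ids not unique")
        missing = set(self.intensities.columns) - set(self.features.index)
        if missing:
            raise ConfigurationError(f"intensity columns without metadata: {missing}")

    @property
    def has_replicates(self) -> bool:
        return isinstance(self.intensities.index, pd.MultiIndex)

    @property
    def subjects(self) -> pd.Index:
        if self.has_replicates:
            return self.intensities.index.get_level_values(0).unique()
        return self.intensities.index

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.intensities.copy(), self.mode,
            None if self.batches is None else self.batches.copy(), self.is_log,
        )

    # -- TSV round trip ----------------------------------------------------
    def write(self, prefix: Path | str) -> None:
        prefix = Path(prefix)
        self.features.to_csv(f"{prefix}_features.tsv", sep="\t")
        self.intensities.to_csv(f"{prefix}_intensities.tsv", sep="\t")
        if self.batches is not None:
            self.batches.rename("batch").to_csv(f"{prefix}_batches.tsv", sep="\t")


@dataclass
class ExposurePanel:
    """Targeted lipid-adjusted congener concentrations (ppt) with LOD handling.

    ``concentrations`` holds the measured (or imputed) value for every
    subject x congener cell; ``below_lod`` flags cells reported below the
    congener's limit of detection; ``lod`` is the per-congener LOD (ppt).
    Below-LOD cells retain the machine-read value until imputation.
    """

    concentrations: pd.DataFrame           # subjects x 29 congeners
    below_lod: pd.DataFrame                # same shape, bool
    lod: pd.Series                         # per congener
    imputed: bool = False

    def __post_init__(self) -> None:
        cols = tuple(self.concentrations.columns)
        if cols != ALL_CONGENERS:
            raise ConfigurationError("panel columns must be the 29 congeners in order")
        if (self.concentrations.to_numpy(float) < 0).any():
            raise ConfigurationError("negative concentration")

    @property
    def subjects(self) -> pd.Index:
        return self.concentrations.index

    def copy(self) -> "ExposurePanel":
        return ExposurePanel(
            self.concentrations.copy(), self.below_lod.copy(),
            self.lod.copy(), self.imputed,
        )

    def write(self, prefix: Path | str) -> None:
        prefix = Path(prefix)
        self.concentrations.to_csv(f"{prefix}_concentrations.tsv", sep="\t")
        self.below_lod.to_csv(f"{prefix}_below_lod.tsv", sep="\t")
        self.lod.rename("lod").to_csv(f"{prefix}_lod.tsv", sep="\t")


SMOKING_LEVELS = ("never", "former", "current")


def validate_subjects(subjects: pd.DataFrame) -> None:
    """Check the subject covariate table invariants."""
    required = {"factory", "age", "bmi", "smoking", "alcohol", "lag_years"}
    missing = required - set(subjects.columns)
    if missing:
        raise ConfigurationError(f"subject table missing columns: {sorted(missing)}")
    if not subjects.index.is_unique:
        raise ConfigurationError("subject ids not unique")
    if len(subjects) == 0:
        return
    if not set(subjects["factory"]) <= {"A", "B"}:
        raise ConfigurationError("factory must be 'A' or 'B'")
    if (subjects["age"] <= 0).any() or (subjects["bmi"] <= 0).any():
        raise ConfigurationError("age and bmi must be positive")
    if (subjects["lag_years"] < 0).any() or (subjects["alcohol"] < 0).any():
        raise ConfigurationError("lag_years and alcohol must be nonnegative")
    if not set(subjects["smoking"]) <= set(SMOKING_LEVELS):
        raise ConfigurationError("unknown smoking level")
    bad_lag = (subjects["factory"] == "B") & (subjects["lag_years"] > 0)
    if bad_lag.any():
        raise ConfigurationError("factory-B subjects must have lag_years 0")
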