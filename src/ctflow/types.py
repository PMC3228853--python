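"""Core domain containers.

All tabular data is held in pandas objects with explicit string labels:
CT-style matrices are assays (rows) x samples (columns), panels and sheets
are indexed by sample id. Containers validate their invariants on
construction so downstream code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

COHORT_PATIENT = "patient"
COHORT_CONTROL = "control"
COHORTS = (COHORT_PATIENT, COHORT_CONTROL)

STAGES = ("raw", "censored", "normalized")

#: sample-sheet columns with dedicated typing; everything else must be a 0/1 flag
SHEET_KNOWN_COLUMNS = ("cohort", "pain_nrs", "crps_type", "duration_years", "bmi")


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup}")


@dataclass
class CtMatrix:
    """CT values (PCR cycles) for assays x samples with a detection mask.

    ``ct`` may hold a numeric value in an undetected cell (e.g. after
    censoring, where the magnitude is retained but masked); every statistic
    downstream must go through :meth:`masked` so undetected cells are
    excluded.
    """

    ct: pd.DataFrame
    detected: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.ct.index.equals(self.detected.index) or not self.ct.columns.equals(
            self.detected.columns
        ):
            raise ValidationError("ct and detected must share identical index and columns")
        _check_unique(self.ct.index, "assay id")
        _check_unique(self.ct.columns, "sample id")
        self.ct = self.ct.astype(float)
        self.detected = self.detected.astype(bool)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ct.shape

    def masked(self) -> pd.DataFrame:
        """CT values with undetected cells replaced by NaN."""
        return self.ct.where(self.detected)

    def copy(self, stage: str | None = None) -> "CtMatrix":
        return CtMatrix(self.ct.copy(), self.detected.copy(), stage or self.stage)


@dataclass
class SampleSheet:
    """Per-sample cohort label plus clinical covariates.

    ``data`` is indexed by sample id and always carries the columns in
    :data:`SHEET_KNOWN_COLUMNS`; ``flags`` lists the extra binary (0/1)
    covariates (comorbidities, medication classes).
    """

    data: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample id")
        if "cohort" not in self.data.columns:
            raise ValidationError("sample sheet requires a 'cohort' column")
        bad = set(self.data["cohort"].unique()) - set(COHORTS)
        if bad:
            raise ValidationError(f"unknown cohort label(s): {sorted(bad)}")
        for col in SHEET_KNOWN_COLUMNS[1:]:
            if col not in self.data.columns:
                self.data[col] = np.nan
        pain = self.data["pain_nrs"]
        bad_pain = pain.dropna()[(pain.dropna() < 0) | (pain.dropna() > 10)]
        if len(bad_pain):
            raise ValidationError(
                f"pain_nrs outside 0-10 for sample(s) {list(bad_pain.index)}"
            )
        ctype = self.data["crps_type"].dropna()
        if not ctype.isin([1, 2]).all():
            raise ValidationError("crps_type must be 1 or 2 where present")
        dur = self.data["duration_years"].dropna()
        if (dur < 0).any():
            raise ValidationError("duration_years must be nonnegative")
        bmi = self.data["bmi"].dropna()
        if (bmi <= 0).any():
            raise ValidationError("bmi must be positive")
        for flag in self.flags:
            vals = self.data[flag].dropna()
            if not vals.isin([0, 1]).all():
                raise ValidationError(f"flag column {flag!r} must contain only 0/1/blank")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def patients(self) -> list[str]:
        return list(self.data.index[self.data["cohort"] == COHORT_PATIENT])

    @property
    def controls(self) -> list[str]:
        return list(self.data.index[self.data["cohort"] == COHORT_CONTROL])

    def cohort_samples(self, cohort: str) -> list[str]:
        if cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {cohort!r}")
        return list(self.data.index[self.data["cohort"] == cohort])

    def check_matches(self, ct: CtMatrix) -> None:
        missing = set(ct.sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"samples absent from sheet: {sorted(missing)}")


@dataclass
class AnalytePanel:
    """Analyte concentrations (pg/mL), samples x analytes; missing allowed."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample id")
        _check_unique(self.data.columns, "analyte name")
        self.data = self.data.astype(float)
        if (self.data < 0).any().any():
            bad = self.data.columns[(self.data < 0).any()].tolist()
            raise ValidationError(f"negative concentration(s) in analyte(s) {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ReferenceSet:
    """Endogenous-control assays selected for ΔCT computation."""

    assay_ids: list[str]
    per_sample_mean: pd.Series  # reference CT mean per sample (cycles)
    selection_sd: pd.Series  # per-assay SD used for ranking, indexed by assay

    def __post_init__(self) -> None:
        _check_unique(self.assay_ids, "reference assay id")
        missing = set(self.assay_ids) - set(self.selection_sd.index)
        if missing:
            raise ValidationError(f"selection_sd missing assay(s): {sorted(missing)}")


@dataclass
class DeltaCtMatrix:
    """ΔCT = CT(assay, sample) - reference mean(sample); mask inherited."""

    delta_ct: pd.DataFrame
    detected: pd.DataFrame
    reference: ReferenceSet

    def __post_init__(self) -> None:
        if not self.delta_ct.index.equals(self.detected.index) or not self.delta_ct.columns.equals(
            self.detected.columns
        ):
            raise ValidationError("delta_ct and detected must share index and columns")
        self.delta_ct = self.delta_ct.astype(float)
        self.detected = self.detected.astype(bool)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.delta_ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.delta_ct.columns)

    def masked(self) -> pd.DataFrame:
        return self.delta_ct.where(self.detected)


@dataclass
class ClusterResult:
    """k-group sample partition plus the orders needed for heatmap export."""

    k: int
    labels: pd.Series  # sample id -> group id in 1..k
    sample_order: list[str]
    assay_order: list[str]
    sample_linkage: np.ndarray
    assay_linkage: np.ndarray

    def __post_init__(self) -> None:
        groups = sorted(set(int(v) for v in self.labels))
        if groups != list(range(1, len(groups) + 1)):
            raise ValidationError(f"group ids must be 1..k with no gaps, got {groups}")

    def members(self, group: int) -> list[str]:
        if group not in set(int(v) for v in self.labels):
            raise ValidationError(f"unknown group id {group}")
        return list(self.labels.index[self.labels == group])
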