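"""Core data containers, table IO and cohort validation.

The pipeline operates on three tables: a proteins x samples intensity matrix
per quantification platform (TMT or LFQ), a per-sample metadata table linking
samples to patients, timepoints and batches (TMT plexes), and a long-format
clinical table with the motor score (HFMSE, 0-66) and routine CSF chemistry
per patient visit. Missing intensities are carried as NaN in memory and as
empty cells on disk -- never as numeric sentinels -- because downstream
imputation must distinguish "not observed" from zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PLATFORMS = ("TMT", "LFQ")
SCALES = ("raw", "log2", "vst", "zscore")

#: CSF sampling schedule in months after the first dose.
DEFAULT_SCHEDULE = (0, 2, 10, 18, 26, 34, 42)

HFMSE_MAX = 66

#: Columns required in a sample-metadata table.
META_COLUMNS = ("sample_id", "patient_id", "timepoint_months", "platform", "batch_id")

#: Cytology percentage columns use this prefix in clinical tables.
CYTOLOGY_PREFIX = "pct_"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# IntensityMatrix
# ---------------------------------------------------------------------------


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity matrix with an explicit missing mask.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by protein ID, columns by sample ID. NaN marks a
        missing (undetected) value.
    platform : str
        ``"TMT"`` or ``"LFQ"``.
    scale : str
        One of ``raw`` (nonnegative intensities), ``log2``, ``vst`` or
        ``zscore``.
    """

    data: pd.DataFrame
    platform: str
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        values = self.data.to_numpy(dtype=float)
        self.data = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        observed = ~np.isnan(values)
        if not np.isfinite(values[observed]).all():
            raise ValidationError("non-finite intensity values present")
        if self.scale == "raw" and observed.any() and np.nanmin(values) < 0:
            prot, samp = np.argwhere(np.where(observed, values, 0) < 0)[0]
            raise ValidationError(
                f"negative raw intensity at protein {self.data.index[prot]!r}, "
                f"sample {self.data.columns[samp]!r}"
            )

    # -- views ------------------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean proteins x samples frame, True where the value is missing."""
        return self.data.isna()

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def replace(self, data: pd.DataFrame | None = None, scale: str | None = None) -> "IntensityMatrix":
        """Return a copy with ``data`` and/or ``scale`` swapped out."""
        return IntensityMatrix(
            data=(self.data if data is None else data).copy(),
            platform=self.platform,
            scale=self.scale if scale is None else scale,
        )

    def select_proteins(self, proteins: Sequence) -> "IntensityMatrix":
        return self.replace(data=self.data.loc[list(proteins)])

    def select_samples(self, samples: Sequence) -> "IntensityMatrix":
        return self.replace(data=self.data[list(samples)])


def read_intensity_table(path: str | Path, platform: str) -> IntensityMatrix:
    """Read a tab-separated proteins x samples table.

    First column holds protein IDs, the header row holds sample IDs.
    Empty cells (or NA/NaN) denote missing values. Returns a raw-scale
    matrix; duplicate protein or sample IDs and negative values are
    rejected with an error naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA", "NaN"])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValidationError(
                f"{path.name}: non-numeric value in sample column {col!r}"
                + (f" at protein {bad.index[0]!r}" if len(bad) else "")
            )
    return IntensityMatrix(data=df, platform=platform, scale="raw")


def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with empty cells for missing values.

    Row and column order are preserved, so a write/read round-trip is
    lossless for values, mask and orderings.
    """
    matrix.data.to_csv(path, sep="\t", na_rep="", index_label="protein")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def check_sample_meta(meta: pd.DataFrame, schedule: Sequence[int] = DEFAULT_SCHEDULE) -> pd.DataFrame:
    """Validate a sample-metadata table and return it with canonical dtypes.

    Enforces: required columns present; unique sample_id; unique
    (patient_id, timepoint_months, platform); timepoints on the configured
    schedule; known platform labels.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"sample metadata missing columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["patient_id"] = meta["patient_id"].astype(str)
    meta["timepoint_months"] = meta["timepoint_months"].astype(int)
    meta["platform"] = meta["platform"].astype(str)
    meta["batch_id"] = meta["batch_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id in metadata: {dups}")
    bad_platform = set(meta["platform"]) - set(PLATFORMS)
    if bad_platform:
        raise ValidationError(f"unknown platforms in metadata: {sorted(bad_platform)}")
    key = meta[["patient_id", "timepoint_months", "platform"]]
    if key.duplicated().any():
        dups = key[key.duplicated()].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (patient, timepoint, platform): {dups}")
    off = sorted(set(meta["timepoint_months"]) - set(int(t) for t in schedule))
    if off:
        raise ValidationError(f"timepoints not on schedule {tuple(schedule)}: {off}")
    return meta


def read_sample_meta(path: str | Path, schedule: Sequence[int] = DEFAULT_SCHEDULE) -> pd.DataFrame:
    return check_sample_meta(pd.read_csv(path, sep="\t"), schedule=schedule)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def meta_for(meta: pd.DataFrame, matrix: IntensityMatrix) -> pd.DataFrame:
    """Metadata rows for the samples of ``matrix``, in matrix column order."""
    sub = meta.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in sub.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    out = sub.loc[matrix.sample_ids]
    out.index.name = "sample_id"
    return out.reset_index()


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------

CLINICAL_NUMERIC = (
    "hfmse",
    "qalb",
    "lactate",
    "glucose",
    "total_protein",
    "total_cells_per_100ul",
)

#: Units are metadata only; no conversion is ever applied (correlations of
#: within-patient changes are unit-invariant).
CLINICAL_UNITS = {
    "hfmse": "points",
    "qalb": "1e-3",
    "lactate": "mmol/L",
    "glucose": "mg/dL",
    "total_protein": "mg/L",
    "total_cells_per_100ul": "cells/100uL",
}


def check_clinical_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format clinical table (one row per patient visit)."""
    if clinical.empty and len(clinical.columns) == 0:
        logger.warning("clinical table is empty")
        return pd.DataFrame(columns=["patient_id", "timepoint_months", *CLINICAL_NUMERIC])
    for col in ("patient_id", "timepoint_months"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    clinical = clinical.copy()
    clinical["patient_id"] = clinical["patient_id"].astype(str)
    clinical["timepoint_months"] = clinical["timepoint_months"].astype(int)
    if clinical[["patient_id", "timepoint_months"]].duplicated().any():
        raise ValidationError("duplicate (patient, timepoint) rows in clinical table")
    if "hfmse" in clinical.columns:
        h = clinical["hfmse"].dropna()
        bad = h[(h < 0) | (h > HFMSE_MAX)]
        if len(bad):
            raise ValidationError(
                f"HFMSE outside [0, {HFMSE_MAX}] for patient "
                f"{clinical.loc[bad.index[0], 'patient_id']!r}: {bad.iloc[0]}"
            )
    for col in ("qalb", "lactate", "glucose", "total_protein", "total_cells_per_100ul"):
        if col in clinical.columns:
            v = clinical[col].dropna()
            if (v < 0).any():
                raise ValidationError(f"negative {col} value present")
    pct_cols = [c for c in clinical.columns if c.startswith(CYTOLOGY_PREFIX)]
    if pct_cols:
        pct = clinical[pct_cols]
        have = pct.notna().all(axis=1)
        sums = pct.loc[have].sum(axis=1)
        bad = sums[(sums - 100).abs() > 0.5]
        if len(bad):
            raise ValidationError(
                f"cytology percentages sum to {bad.iloc[0]:.2f} (not 100 +/- 0.5) "
                f"for patient {clinical.loc[bad.index[0], 'patient_id']!r}"
            )
    return clinical


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the tab-separated clinical table.

    Missing fields are allowed and stay NaN; an empty file yields an empty
    table with a logged warning.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    return check_clinical_table(df)


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def absolute_cell_counts(
    cytology_percent: Mapping[str, float], total_cells_per_100ul: float
) -> dict[str, float]:
    """Convert cytology percentages to absolute counts per 100 ul CSF.

    Each cell type's percentage is multiplied by the total cell count per
    100 ul; the resulting counts sum to the total within rounding of the
    percentages.
    """
    values = dict(cytology_percent)
    for name, pct in values.items():
        if pct < 0:
            raise ValidationError(f"negative cytology percentage for {name!r}")
    total_pct = sum(values.values())
    if total_pct > 100.5:
        raise ValidationError(f"cytology percentages sum to {total_pct:.2f} > 100.5")
    if total_cells_per_100ul < 0:
        raise ValidationError("negative total cell count")
    return {name: pct / 100.0 * total_cells_per_100ul for name, pct in values.items()}


# ---------------------------------------------------------------------------
# Cohort-level cross validation
# ---------------------------------------------------------------------------


@dataclass
class Issue:
    severity: str  # "error" | "warning" | "info"
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    def add(self, severity: str, code: str, message: str) -> None:
        self.issues.append(Issue(severity, code, message))

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"ok": self.ok, "issues": [asdict(i) for i in self.issues]}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def validate_cohort(
    matrices: IntensityMatrix | Iterable[IntensityMatrix],
    meta: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
) -> ValidationReport:
    """Cross-check intensity matrices, sample metadata and clinical records.

    Reports orphan samples (in a matrix but not the metadata, and vice
    versa), duplicate (patient, timepoint, platform) combinations, schedule
    violations and clinical visits without metadata. Never raises; returns
    a report with severity-tagged issues.
    """
    if isinstance(matrices, IntensityMatrix):
        matrices = [matrices]
    report = ValidationReport()
    try:
        meta = check_sample_meta(meta, schedule=schedule)
    except ValidationError as exc:
        report.add("error", "bad_metadata", str(exc))
        return report
    meta_ids = set(meta["sample_id"])
    seen: set[str] = set()
    for matrix in matrices:
        seen |= set(matrix.sample_ids)
        for sample in matrix.sample_ids:
            if sample not in meta_ids:
                report.add("error", "orphan_sample", f"sample {sample!r} in {matrix.platform} matrix but not in metadata")
        plat_meta = meta[meta["platform"] == matrix.platform]
        for sample in set(plat_meta["sample_id"]) - set(matrix.sample_ids):
            report.add("info", "unreferenced_meta", f"metadata sample {sample!r} absent from {matrix.platform} matrix")
    if clinical is not None and len(clinical):
        meta_visits = set(zip(meta["patient_id"], meta["timepoint_months"]))
        for _, row in clinical.iterrows():
            key = (str(row["patient_id"]), int(row["timepoint_months"]))
            if key not in meta_visits:
                report.add("info", "clinical_without_samples", f"clinical visit {key} has no proteomic sample")
    return report


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the analysis, with study defaults.

    ``sample_intensity_min`` is in the intensity table's arbitrary units and
    applies to TMT only; ``fdr_alpha``/``log2fc_min`` are the DEP-calling
    thresholds (strict ``<`` / ``>`` comparisons).
    """

    fdr_alpha: float = 0.05
    log2fc_min: float = 0.5
    sample_intensity_min: float = 225.0
    min_within_patient: int = 2
    min_patients: int = 2
    knn_k: int = 10
    cutoff_grid: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0)
    cutoff_min_covered: float = 0.5
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if self.log2fc_min < 0:
            raise ValidationError("log2fc_min must be >= 0")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        self.cutoff_grid = tuple(float(t) for t in self.cutoff_grid)
        self.schedule = tuple(int(t) for t in self.schedule)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
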