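"""Treatment-response marker analytics.

Four screens relate protein changes to the clinical course:

* per-patient regulation-direction consistency -- for each candidate
  protein and post-baseline timepoint, the fraction of evaluable patients
  whose change from baseline has the protein's cohort-level direction;
* a change-change correlation screen -- per protein, the Pearson
  correlation between within-patient intensity change and HFMSE change,
  pooled over all patient-timepoint pairs;
* the same Pearson machinery for the routine CSF parameters (qAlb,
  lactate, glucose, cytology counts) against HFMSE change;
* cutoff biomarker rules -- a threshold theta on the protein change that
  classifies visits into improved-or-stable (delta >= theta) versus
  not-improved-or-worse (delta <= -theta), abstaining in between, scored
  by concordance with the sign of the HFMSE change.

A hypergeometric enrichment test for user-supplied term -> protein
annotations completes the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .core import IntensityMatrix, ValidationError, meta_for
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

IMPROVED = "improved_or_stable"
NOT_IMPROVED = "not_improved_or_worse"
ABSTAIN = "abstain"


# ---------------------------------------------------------------------------
# Baseline deltas
# ---------------------------------------------------------------------------


def protein_deltas(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    baseline_month: int = 0,
    include_baseline: bool = False,
) -> pd.DataFrame:
    """Long table of within-patient changes from baseline.

    Columns: patient_id, timepoint_months, protein, delta. Baseline rows
    (delta identically zero) are excluded by default; pass
    ``include_baseline=True`` for the inclusive convention.
    """
    m = meta_for(meta, matrix)
    wide = matrix.data  # proteins x samples
    base_cols = m.loc[m["timepoint_months"] == baseline_month]
    base_map = dict(zip(base_cols["patient_id"], base_cols["sample_id"]))
    rows = []
    for _, r in m.iterrows():
        patient, t, sample = r["patient_id"], int(r["timepoint_months"]), r["sample_id"]
        if patient not in base_map:
            continue
        if t == baseline_month and not include_baseline:
            continue
        delta = wide[sample] - wide[base_map[patient]]
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": patient,
                    "timepoint_months": t,
                    "protein": wide.index,
                    "delta": delta.to_numpy(),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["patient_id", "timepoint_months", "protein", "delta"])
    return pd.concat(rows, ignore_index=True)


def clinical_deltas(
    clinical: pd.DataFrame,
    column: str,
    baseline_month: int = 0,
    include_baseline: bool = False,
) -> pd.DataFrame:
    """Within-patient change from baseline of one clinical column."""
    if column not in clinical.columns:
        raise ValidationError(f"clinical table has no column {column!r}")
    base = clinical.loc[
        clinical["timepoint_months"] == baseline_month, ["patient_id", column]
    ].set_index("patient_id")[column]
    out = clinical[["patient_id", "timepoint_months", column]].copy()
    out["delta"] = out[column].to_numpy() - base.reindex(out["patient_id"]).to_numpy()
    if not include_baseline:
        out = out[out["timepoint_months"] != baseline_month]
    return out.dropna(subset=["delta"])[["patient_id", "timepoint_months", "delta"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Consistency scores
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyMatrix:
    """Per (protein, post-baseline timepoint) regulation consistency."""

    fraction: pd.DataFrame  # proteins x timepoints, values in [0, 1]
    n_evaluable: pd.DataFrame  # matching patient counts

    def __post_init__(self) -> None:
        v = self.fraction.to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.any() and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValidationError("consistency fractions must lie in [0, 1]")


def consistency_scores(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    reference_signs: Mapping[str, int],
    baseline_month: int = 0,
) -> ConsistencyMatrix:
    """Fraction of patients changing in each protein's reference direction.

    For protein p and timepoint t > baseline, over the patients with data
    at both baseline and t: the fraction whose sign(value_t - value_0)
    equals the reference sign. A change of exactly zero counts as
    non-concordant. Proteins without a reference sign are skipped with a
    warning.
    """
    m = meta_for(meta, matrix)
    proteins = [p for p in matrix.protein_ids if p in reference_signs]
    skipped = [p for p in reference_signs if p not in set(matrix.protein_ids)]
    if skipped:
        logger.warning("reference proteins absent from matrix: %s", skipped)
    timepoints = sorted(t for t in set(m["timepoint_months"]) if t != baseline_month)
    frac = pd.DataFrame(np.nan, index=pd.Index(proteins, name="protein"), columns=timepoints)
    nev = pd.DataFrame(0, index=frac.index, columns=timepoints)
    base = m[m["timepoint_months"] == baseline_month].set_index("patient_id")["sample_id"]
    for t in timepoints:
        cur = m[m["timepoint_months"] == t].set_index("patient_id")["sample_id"]
        patients = [p for p in cur.index if p in base.index]
        if not patients:
            continue
        b_cols, t_cols = base[patients], cur[patients]
        for protein in proteins:
            bv = matrix.data.loc[protein, b_cols].to_numpy(dtype=float)
            tv = matrix.data.loc[protein, t_cols].to_numpy(dtype=float)
            ok = ~(np.isnan(bv) | np.isnan(tv))
            n = int(ok.sum())
            nev.loc[protein, t] = n
            if n:
                concordant = np.sign(tv[ok] - bv[ok]) == np.sign(reference_signs[protein])
                frac.loc[protein, t] = concordant.mean()
    frac.columns = [f"m{t}" for t in timepoints]
    nev.columns = frac.columns
    return ConsistencyMatrix(fraction=frac, n_evaluable=nev)


# ---------------------------------------------------------------------------
# Change-change Pearson correlations
# ---------------------------------------------------------------------------


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Two-sided Pearson correlation test: r, p (t distribution, n-2 df), n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError("Pearson test needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in a correlation input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def clinical_correlation(
    deltas_x: pd.DataFrame, deltas_y: pd.DataFrame, feature_column: str = "protein"
) -> pd.DataFrame:
    """Per-feature Pearson correlation of paired changes.

    ``deltas_x`` is long (patient_id, timepoint_months, <feature_column>,
    delta); ``deltas_y`` holds one delta per (patient, timepoint), e.g.
    the HFMSE change. Pairs are joined on (patient, timepoint); features
    with zero variance or fewer than 3 pairs are skipped with a log entry.
    BH FDR is computed across the reported features.
    """
    y = deltas_y.rename(columns={"delta": "delta_y"})[
        ["patient_id", "timepoint_months", "delta_y"]
    ]
    joined = deltas_x.merge(y, on=["patient_id", "timepoint_months"], how="inner")
    rows = []
    for feat, grp in joined.groupby(feature_column, sort=True):
        try:
            r, p, n = pearson_with_p(grp["delta"].to_numpy(), grp["delta_y"].to_numpy())
        except ValidationError as exc:
            logger.info("skipping feature %r: %s", feat, exc)
            continue
        rows.append((feat, r, p, n))
    out = pd.DataFrame(rows, columns=[feature_column, "r", "p", "n"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    else:
        out["fdr"] = []
    return out


def protein_hfmse_screen(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    clinical: pd.DataFrame,
    baseline_month: int = 0,
    include_baseline: bool = False,
) -> pd.DataFrame:
    """Correlate every protein's change with the HFMSE change (volcano surface)."""
    dx = protein_deltas(matrix, meta, baseline_month, include_baseline)
    dy = clinical_deltas(clinical, "hfmse", baseline_month, include_baseline)
    screen = clinical_correlation(dx, dy, feature_column="protein")
    return screen.sort_values("p", kind="stable").reset_index(drop=True)


ROUTINE_PARAMETERS = (
    "total_protein",
    "lactate",
    "glucose",
    "qalb",
    "macrophages_per_100ul",
    "monocytes_per_100ul",
    "lymphocytes_per_100ul",
)


def _with_absolute_counts(clinical: pd.DataFrame) -> pd.DataFrame:
    """Attach absolute cell counts per 100 ul derived from cytology percentages."""
    clinical = clinical.copy()
    for cell in ("macrophage", "monocyte", "lymphocyte"):
        pct = f"pct_{cell}"
        if pct in clinical.columns and "total_cells_per_100ul" in clinical.columns:
            clinical[f"{cell}s_per_100ul"] = (
                clinical[pct] / 100.0 * clinical["total_cells_per_100ul"]
            )
    return clinical


def routine_parameter_correlations(
    clinical: pd.DataFrame,
    parameters: Sequence[str] = ROUTINE_PARAMETERS,
    baseline_month: int = 0,
) -> pd.DataFrame:
    """Pearson correlations of routine CSF parameter changes with HFMSE change."""
    clinical = _with_absolute_counts(clinical)
    dy = clinical_deltas(clinical, "hfmse", baseline_month)
    frames = []
    for param in parameters:
        if param not in clinical.columns:
            logger.info("clinical parameter %r absent; skipped", param)
            continue
        dx = clinical_deltas(clinical, param, baseline_month)
        dx["parameter"] = param
        frames.append(dx)
    if not frames:
        return pd.DataFrame(columns=["parameter", "r", "p", "n", "fdr"])
    dx_all = pd.concat(frames, ignore_index=True)
    return clinical_correlation(dx_all, dy, feature_column="parameter")


# ---------------------------------------------------------------------------
# Cutoff biomarker rules
# ---------------------------------------------------------------------------


@dataclass
class CutoffRule:
    """Threshold rule on a protein change with its concordance."""

    threshold: float
    concordance: float | None
    abstention_rate: float
    n_evaluated: int
    confusion: dict = field(default_factory=dict)
    protein: str | None = None
    ties_flagged: int = 0  # visits with HFMSE change exactly 0 (assigned improved)
    #: "increase_improves": delta >= theta predicts improvement (the default);
    #: "decrease_improves": the rule was fit on the negated delta of a
    #: negatively coupled protein
    orientation: str = "increase_improves"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("cutoff threshold must be > 0")
        if self.concordance is not None and not (0.0 <= self.concordance <= 1.0):
            raise ValidationError("concordance must lie in [0, 1]")


def _join_deltas(protein_deltas: pd.DataFrame, hfmse_deltas: pd.DataFrame) -> pd.DataFrame:
    y = hfmse_deltas.rename(columns={"delta": "delta_hfmse"})[
        ["patient_id", "timepoint_months", "delta_hfmse"]
    ]
    x = protein_deltas.rename(columns={"delta": "delta_protein"})
    return x.merge(y, on=["patient_id", "timepoint_months"], how="inner")


def cutoff_classifier(
    protein_deltas: pd.DataFrame, hfmse_deltas: pd.DataFrame, theta: float
) -> CutoffRule:
    """Classify visits by a protein-change threshold and score concordance.

    Predicted improved-or-stable if delta >= theta, not-improved-or-worse
    if delta <= -theta, abstain otherwise. The clinical truth is
    improved-or-stable iff the HFMSE change is >= 0 (a change of exactly
    zero satisfies both clinical phrasings; it is assigned to
    improved-or-stable and counted in ``ties_flagged``). Concordance is
    computed over non-abstained visits only; only the sign of the HFMSE
    change is used.
    """
    if theta <= 0:
        raise ValidationError("theta must be > 0")
    joined = _join_deltas(protein_deltas, hfmse_deltas)
    dp = joined["delta_protein"].to_numpy(dtype=float)
    dh = joined["delta_hfmse"].to_numpy(dtype=float)
    pred = np.where(dp >= theta, IMPROVED, np.where(dp <= -theta, NOT_IMPROVED, ABSTAIN))
    truth = np.where(dh >= 0, IMPROVED, NOT_IMPROVED)
    used = pred != ABSTAIN
    n_used = int(used.sum())
    confusion = {
        "tp": int(((pred == IMPROVED) & (truth == IMPROVED)).sum()),
        "fp": int(((pred == IMPROVED) & (truth == NOT_IMPROVED)).sum()),
        "fn": int(((pred == NOT_IMPROVED) & (truth == IMPROVED)).sum()),
        "tn": int(((pred == NOT_IMPROVED) & (truth == NOT_IMPROVED)).sum()),
    }
    concordance = (
        float((pred[used] == truth[used]).mean()) if n_used else None
    )
    if concordance is None:
        logger.warning("all visits abstained at theta=%s; concordance undefined", theta)
    return CutoffRule(
        threshold=float(theta),
        concordance=concordance,
        abstention_rate=float(1.0 - n_used / len(pred)) if len(pred) else 1.0,
        n_evaluated=n_used,
        confusion=confusion,
        ties_flagged=int((dh == 0).sum()),
    )


def scan_cutoffs(
    protein_deltas: pd.DataFrame,
    hfmse_deltas: pd.DataFrame,
    grid: Sequence[float],
    min_covered: float = 0.5,
) -> CutoffRule:
    """Best cutoff on a grid: maximal concordance subject to a minimum
    non-abstained fraction; ties broken toward the smaller theta."""
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValidationError("empty cutoff grid")
    best: CutoffRule | None = None
    fallback: CutoffRule | None = None
    for theta in grid:
        rule = cutoff_classifier(protein_deltas, hfmse_deltas, theta)
        if fallback is None:
            fallback = rule
        if rule.concordance is None or (1.0 - rule.abstention_rate) < min_covered:
            continue
        if best is None or rule.concordance > best.concordance + 1e-12:
            best = rule
    return best if best is not None else fallback


class CutoffResponseClassifier(BaseEstimator):
    """Estimator facade: fit picks the best threshold, predict classifies.

    ``fit(X, y)`` takes protein changes ``X`` (1d) and HFMSE changes
    ``y``; with ``theta=None`` the grid scan selects ``theta_``.
    """

    def __init__(self, theta: float | None = None, grid: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 1.0), min_covered: float = 0.5):
        self.theta = theta
        self.grid = grid
        self.min_covered = min_covered

    @staticmethod
    def _frame(values: np.ndarray) -> pd.DataFrame:
        values = np.asarray(values, dtype=float).ravel()
        return pd.DataFrame(
            {
                "patient_id": [f"i{i}" for i in range(values.size)],
                "timepoint_months": 1,
                "delta": values,
            }
        )

    def fit(self, X, y):
        dx, dy = self._frame(X), self._frame(y)
        if self.theta is not None:
            rule = cutoff_classifier(dx, dy, self.theta)
        else:
            rule = scan_cutoffs(dx, dy, self.grid, self.min_covered)
        self.rule_ = rule
        self.theta_ = rule.threshold
        self.concordance_ = rule.concordance
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return np.where(
            x >= self.theta_, IMPROVED, np.where(x <= -self.theta_, NOT_IMPROVED, ABSTAIN)
        )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def enrichment_test(
    hits: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``hits`` per annotation term.

    For a term with K background members of which k are hits, with N
    background proteins and n hits overall, p is the upper-tail
    hypergeometric probability P(X >= k). Terms with empty background
    intersection are skipped; BH FDR is computed across the tested terms.
    """
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValidationError("hits must be a subset of the background")
    N, n = len(background), len(hits)
    rows = []
    for term in sorted(annotation):
        members = set(annotation[term]) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, K, k, K * n / N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "n_term", "overlap", "expected", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    else:
        out["fdr"] = []
    return out


def read_annotation(path) -> dict[str, set[str]]:
    """Read a two-column TSV (term, protein) into term -> protein sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "protein"], comment="#")
    return {term: set(grp["protein"].astype(str)) for term, grp in df.groupby("term")}
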