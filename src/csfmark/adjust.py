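"""Patient-effect removal, z-scoring, sample correlation and clustering.

Inter-patient heterogeneity dominates CSF protein profiles; before sample
correlation it is removed per protein by fitting a linear model with
timepoint indicators plus patient indicators and subtracting only the
fitted patient block. Retaining the timepoint indicators during the fit is
the defining contract: treatment signal is not absorbed into the removed
effects, so timepoint contrasts recomputed on adjusted data equal the
originals. Adjusted values are z-scored per protein, pairwise Pearson
correlations between samples are computed, and samples are ordered by
average-linkage hierarchical clustering on 1 - r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .core import IntensityMatrix, ValidationError, meta_for

logger = logging.getLogger(__name__)


def design_matrices(
    timepoints: np.ndarray, patients: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[int], list[str]]:
    """Timepoint-indicator block (all levels, no intercept) and
    patient-indicator block (first level dropped for identifiability)."""
    tp_levels = sorted(set(int(t) for t in timepoints))
    pat_levels = sorted(set(str(p) for p in patients))
    T = np.column_stack([(timepoints == t).astype(float) for t in tp_levels])
    P = np.column_stack(
        [(patients == p).astype(float) for p in pat_levels[1:]]
    ) if len(pat_levels) > 1 else np.zeros((len(patients), 0))
    return T, P, tp_levels, pat_levels


class PatientEffectRemover(BaseEstimator, TransformerMixin):
    """Subtract per-protein patient effects estimated jointly with
    timepoint effects.

    Fit solves, for every protein, OLS on ``[timepoint block | patient
    block]`` and stores the fitted patient contribution per sample (mean-
    centered across patients so the overall level is preserved).
    ``transform`` subtracts it. Applying the transform twice equals
    applying it once (the re-estimated patient effects of adjusted data
    are zero).
    """

    def fit(self, X, y=None, *, timepoints, patients):
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValidationError("patient-effect removal expects a complete (imputed) matrix")
        timepoints = np.asarray(timepoints)
        patients = np.asarray(patients).astype(str)
        T, P, tp_levels, pat_levels = design_matrices(timepoints, patients)
        D = np.hstack([T, P])
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            raise ValidationError(
                "confounded design: patient and timepoint indicators are collinear"
            )
        singletons = [p for p in pat_levels if (patients == p).sum() == 1]
        if singletons:
            logger.info("patients with a single sample (effect still estimable): %s", singletons)
        beta, *_ = np.linalg.lstsq(D, X.to_numpy(dtype=float), rcond=None)
        gamma = beta[T.shape[1]:, :]  # (n_patients - 1) x n_proteins
        gamma_full = np.vstack([np.zeros((1, gamma.shape[1])), gamma])
        gamma_full = gamma_full - gamma_full.mean(axis=0, keepdims=True)
        self.patient_levels_ = pat_levels
        self.patient_effects_ = pd.DataFrame(
            gamma_full, index=pat_levels, columns=X.columns
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, patients=None):
        X = pd.DataFrame(X)
        if patients is None:
            if X.shape[0] != getattr(self, "_fit_patients_", np.empty(0)).shape[0]:
                raise ValidationError("pass `patients` when transforming new samples")
            patients = self._fit_patients_
        patients = np.asarray(patients).astype(str)
        eff = self.patient_effects_.reindex(patients).to_numpy()
        eff = np.nan_to_num(eff)  # unseen patients: no adjustment
        return X - eff

    def fit_transform(self, X, y=None, *, timepoints, patients):
        self.fit(X, timepoints=timepoints, patients=patients)
        self._fit_patients_ = np.asarray(patients).astype(str)
        return self.transform(X, patients=patients)


def remove_patient_effect(matrix: IntensityMatrix, meta: pd.DataFrame) -> IntensityMatrix:
    """Remove inter-patient offsets from a complete proteins x samples matrix."""
    m = meta_for(meta, matrix)
    adjusted = PatientEffectRemover().fit_transform(
        matrix.data.T,
        timepoints=m["timepoint_months"].to_numpy(),
        patients=m["patient_id"].to_numpy(),
    )
    return matrix.replace(data=adjusted.T)


class ProteinZScorer(BaseEstimator, TransformerMixin):
    """Scale each protein (column) to mean 0, SD 1 across samples.

    Sample SD (n-1 denominator). Constant proteins are dropped with a
    logged warning.
    """

    def __init__(self, tol: float = 1e-12):
        self.tol = tol

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1)
        self.keep_ = self.sds_ > self.tol
        dropped = list(X.columns[~self.keep_])
        if dropped:
            logger.warning("dropping %d constant proteins: %s", len(dropped), dropped[:10])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        Z = (X - self.means_) / self.sds_
        return Z.loc[:, self.keep_]


def zscore_rows(matrix: IntensityMatrix) -> IntensityMatrix:
    """Z-score each protein across samples; drops constant proteins."""
    if matrix.missing_mask.any().any():
        raise ValidationError("z-scoring expects a complete matrix")
    z = ProteinZScorer().fit_transform(matrix.data.T)
    return matrix.replace(data=z.T, scale="zscore")


# ---------------------------------------------------------------------------
# Sample correlation and clustering
# ---------------------------------------------------------------------------


@dataclass
class CorrelationHeatmap:
    """Pairwise sample Pearson correlations plus optional clustering."""

    corr: pd.DataFrame
    linkage: np.ndarray | None = None
    leaf_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = self.corr.to_numpy()
        if c.shape[0] != c.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.nanmin(c) < -1 - 1e-10 or np.nanmax(c) > 1 + 1e-10:
            raise ValidationError("correlations must lie in [-1, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.corr.columns)

    def dendrogram_dict(self) -> dict:
        if self.linkage is None:
            return {}
        return {
            "merges": self.linkage[:, :2].astype(int).tolist(),
            "heights": self.linkage[:, 2].tolist(),
            "leaf_order": self.leaf_order,
        }


def sample_correlation(matrix: IntensityMatrix) -> CorrelationHeatmap:
    """All pairwise Pearson correlations between sample columns."""
    if matrix.n_proteins < 3:
        raise ValidationError("sample correlation needs at least 3 proteins")
    if matrix.missing_mask.any().any():
        raise ValidationError("sample correlation expects a complete matrix")
    c = np.corrcoef(matrix.values, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationHeatmap(
        corr=pd.DataFrame(c, index=matrix.sample_ids, columns=matrix.sample_ids)
    )


def hierarchical_cluster(
    heatmap: CorrelationHeatmap, method: str = "average"
) -> CorrelationHeatmap:
    """Agglomerative clustering of samples with distance ``1 - r``.

    Returns a new heatmap with the correlation matrix reordered to the
    dendrogram leaf order and the merge tree attached. Deterministic for a
    given input.
    """
    r = heatmap.corr.to_numpy()
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method=method)
    order = hierarchy.leaves_list(Z)
    ids = [heatmap.sample_ids[i] for i in order]
    return CorrelationHeatmap(
        corr=heatmap.corr.loc[ids, ids], linkage=Z, leaf_order=ids
    )


def pre_treatment_block_purity(
    heatmap: CorrelationHeatmap, pre_samples: set[str]
) -> float:
    """Fraction of pre-treatment samples captured by the best contiguous
    window of that size in the clustered leaf order (1.0 = one pure block)."""
    if not heatmap.leaf_order:
        raise ValidationError("cluster the heatmap before computing block purity")
    flags = np.array([s in pre_samples for s in heatmap.leaf_order], dtype=int)
    n_pre = flags.sum()
    if n_pre == 0:
        raise ValidationError("no pre-treatment samples in the heatmap")
    window = np.convolve(flags, np.ones(n_pre, dtype=int), mode="valid")
    return float(window.max() / n_pre)
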