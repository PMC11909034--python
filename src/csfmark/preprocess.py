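"""Preprocessing: sample QC, detection filtering, VST, kNN imputation.

The stages mirror a standard quantitative-proteomics workflow: (1) drop
samples whose summed intensity is far below the rest (failed labeling or
injection), (2) keep proteins detected in at least two samples within one
patient and in at least two patients, (3) variance-stabilize with a
per-sample robust affine calibration followed by a generalized log2, and
(4) impute remaining missing values from the k nearest proteins.

All transformers follow the scikit-learn estimator protocol and operate on
``X`` of shape (n_samples, n_proteins) with NaN for missing values; the
module-level functions are thin wrappers that accept the pipeline's
proteins x samples :class:`~csfmark.core.IntensityMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .core import IntensityMatrix, ValidationError, meta_for

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sample-level intensity filter
# ---------------------------------------------------------------------------


def filter_low_intensity_samples(
    matrix: IntensityMatrix, threshold: float = 225.0
) -> tuple[IntensityMatrix, list[str]]:
    """Remove samples whose summed non-missing raw intensity is below ``threshold``.

    The threshold is in the intensity table's arbitrary units. Returns the
    filtered matrix and the removed sample IDs (logged).
    """
    if matrix.scale != "raw":
        raise ValidationError("sample intensity filter expects a raw-scale matrix")
    totals = np.nansum(matrix.values, axis=0)
    keep = totals >= threshold
    removed = [s for s, k in zip(matrix.sample_ids, keep) if not k]
    if not keep.any():
        raise ValidationError("sample intensity filter would remove every sample")
    if removed:
        logger.info("removed %d low-intensity samples: %s", len(removed), removed)
    return matrix.select_samples(list(matrix.sample_ids[keep])), removed


# ---------------------------------------------------------------------------
# Detection filter
# ---------------------------------------------------------------------------


class DetectionFilter(BaseEstimator):
    """Keep proteins detected >= ``min_within_patient`` times within some
    patient and in >= ``min_patients`` distinct patients.

    "Detected" means non-missing. Fit learns a boolean ``support_`` over
    proteins; transform selects the surviving columns, order preserved.
    """

    def __init__(self, min_within_patient: int = 2, min_patients: int = 2):
        self.min_within_patient = min_within_patient
        self.min_patients = min_patients

    def fit(self, X, y=None, *, patients):
        X = pd.DataFrame(X)
        patients = np.asarray(patients)
        if len(patients) != X.shape[0]:
            raise ValidationError("one patient label per sample (row) is required")
        observed = X.notna().to_numpy()
        counts = (
            pd.DataFrame(observed, index=patients).groupby(level=0).sum().to_numpy()
        )  # patients x proteins
        enough_within = (counts >= self.min_within_patient).any(axis=0)
        enough_patients = (counts >= 1).sum(axis=0) >= self.min_patients
        self.support_ = enough_within & enough_patients
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = pd.DataFrame(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("transform input has a different protein count than fit")
        return X.loc[:, self.support_]


def filter_detection(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    min_within_patient: int = 2,
    min_patients: int = 2,
) -> IntensityMatrix:
    """Apply the detection rule to a proteins x samples matrix."""
    patients = meta_for(meta, matrix)["patient_id"].to_numpy()
    filt = DetectionFilter(min_within_patient, min_patients).fit(
        matrix.data.T, patients=patients
    )
    kept = matrix.protein_ids[filt.support_]
    if len(kept) == 0:
        logger.warning("detection filter removed every protein")
    return matrix.select_proteins(list(kept))


# ---------------------------------------------------------------------------
# Variance-stabilizing transformation
# ---------------------------------------------------------------------------


@dataclass
class VSTParams:
    """Fitted VST parameters: per-sample affine calibration and glog2 lambda."""

    offsets: pd.Series  # a_s per sample
    scales: pd.Series  # b_s per sample, > 0
    lambda_: float  # glog2 parameter, >= 0

    def __post_init__(self) -> None:
        if (self.scales <= 0).any():
            raise ValidationError("calibration scales must be positive")
        if self.lambda_ < 0:
            raise ValidationError("glog lambda must be >= 0")


def glog2(x: np.ndarray, lambda_: float) -> np.ndarray:
    """Generalized log2: ``log2((x + sqrt(x^2 + lambda^2)) / 2)``.

    Reduces to plain log2 for ``x >> lambda`` and stays finite at and below
    zero for ``lambda > 0``.
    """
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + lambda_ * lambda_)) / 2.0)


def _mean_sd_spearman(values: np.ndarray) -> float:
    """|Spearman rho| between per-protein (row) mean and SD, NaN-aware."""
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(~np.isnan(values), axis=1)
        means = np.nanmean(values, axis=1)
        sds = np.full(values.shape[0], np.nan)
        ok = n_obs >= 2
        sds[ok] = np.nanstd(values[ok], axis=1, ddof=1)
    use = ok & np.isfinite(means)
    if use.sum() < 3 or np.allclose(sds[use], sds[use][0]):
        return 0.0
    rho = stats.spearmanr(means[use], sds[use]).statistic
    return 0.0 if np.isnan(rho) else abs(float(rho))


class VSTNormalizer(BaseEstimator, TransformerMixin):
    """Robust per-sample calibration followed by a glog2 transformation.

    Each sample (row of ``X``) is affinely mapped so its median and MAD
    over proteins match the median sample's; ``glog2`` is then applied with
    a lambda chosen on a quantile grid of the calibrated intensities to
    minimize the |Spearman correlation| between per-protein mean and SD
    (ties broken toward the smaller lambda). Missing entries stay missing.

    Parameters
    ----------
    lambda_grid : sequence of float, optional
        Candidate lambdas. Default: 0 (if all calibrated values are
        positive) plus a 25-point geometric quantile grid.
    lambda_ : float, optional
        Fix lambda instead of selecting it.
    """

    def __init__(self, lambda_grid=None, lambda_=None):
        self.lambda_grid = lambda_grid
        self.lambda_ = lambda_

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _sample_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        meds = np.nanmedian(X, axis=1)
        mads = stats.median_abs_deviation(X, axis=1, nan_policy="omit")
        return meds, np.asarray(mads, dtype=float)

    def _calibrate(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        meds, mads = self._sample_stats(X)
        scales = np.where(mads > 0, self.reference_mad_ / np.where(mads > 0, mads, 1.0), 1.0)
        offsets = self.reference_median_ - scales * meds
        return offsets[:, None] + scales[:, None] * X, offsets, scales

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValidationError("VST needs at least 2 samples")
        values = X.to_numpy(dtype=float)
        meds, mads = self._sample_stats(values)
        self.reference_median_ = float(np.median(meds))
        self.reference_mad_ = float(np.median(mads[mads > 0])) if (mads > 0).any() else 1.0
        calibrated, offsets, scales = self._calibrate(values)
        self.offsets_ = pd.Series(offsets, index=X.index, name="offset")
        self.scales_ = pd.Series(scales, index=X.index, name="scale")

        if self.lambda_ is not None:
            self.lambda_fitted_ = float(self.lambda_)
        else:
            grid = self.lambda_grid
            if grid is None:
                pos = calibrated[np.isfinite(calibrated) & (calibrated > 0)]
                if pos.size == 0:
                    grid = [1.0]
                else:
                    lo = float(np.quantile(pos, 0.001))
                    hi = float(np.quantile(pos, 0.999))
                    grid = list(np.geomspace(max(lo, 1e-12), max(hi, 1e-9), 25))
                obs = calibrated[np.isfinite(calibrated)]
                if obs.size and obs.min() > 0:
                    grid = [0.0] + grid
            def best_of(candidates):
                best_lam, best_score = None, np.inf
                for lam in sorted(float(g) for g in candidates):
                    score = _mean_sd_spearman(glog2(calibrated, lam).T)
                    if score < best_score - 1e-12:
                        best_lam, best_score = lam, score
                return best_lam, best_score

            best_lam, _ = best_of(grid)
            if self.lambda_grid is None and best_lam is not None and best_lam > 0:
                # the |rho| minimum is a narrow dip; refine around the coarse hit
                refined, _ = best_of(np.geomspace(best_lam / 4.0, best_lam * 4.0, 41))
                best_lam = refined if refined is not None else best_lam
            self.lambda_fitted_ = best_lam if best_lam is not None else 0.0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        values = X.to_numpy(dtype=float)
        calibrated, _, _ = self._calibrate(values)
        out = np.where(np.isnan(calibrated), np.nan, glog2(calibrated, self.lambda_fitted_))
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    def params_(self) -> VSTParams:
        return VSTParams(
            offsets=self.offsets_, scales=self.scales_, lambda_=self.lambda_fitted_
        )


def vst_normalize(
    matrix: IntensityMatrix, lambda_grid=None, lambda_=None
) -> tuple[IntensityMatrix, VSTParams]:
    """Variance-stabilize a raw-scale proteins x samples matrix."""
    if matrix.scale != "raw":
        raise ValidationError(f"VST expects a raw-scale matrix, got {matrix.scale!r}")
    est = VSTNormalizer(lambda_grid=lambda_grid, lambda_=lambda_).fit(matrix.data.T)
    out = est.transform(matrix.data.T).T
    return matrix.replace(data=out, scale="vst"), est.params_()


# ---------------------------------------------------------------------------
# kNN imputation in protein space
# ---------------------------------------------------------------------------


class KNNProteinImputer(BaseEstimator, TransformerMixin):
    """Impute missing values from the k nearest proteins.

    For a missing entry (protein p, sample s): among proteins observed at
    s, the ``n_neighbors`` nearest to p -- Euclidean distance over samples
    observed in both rows, rescaled to the full sample count -- contribute
    an inverse-distance weighted mean of their values at s. When fewer
    than ``n_neighbors`` candidates exist, the protein's own observed mean
    is used. Distance ties are broken by protein ID lexicographic order,
    making the result deterministic. Observed entries are never altered.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None):
        if self.n_neighbors < 1:
            raise ValidationError("n_neighbors must be >= 1")
        X = pd.DataFrame(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        V = X.to_numpy(dtype=float).T  # proteins x samples
        n_prot, n_samp = V.shape
        observed = ~np.isnan(V)
        empty = ~observed.any(axis=1)
        if empty.any():
            raise ValidationError(
                f"protein {X.columns[np.flatnonzero(empty)[0]]!r} has no observed values"
            )
        if observed.all():
            return X.copy()

        ids = X.columns.astype(str)
        lexrank = np.empty(n_prot, dtype=int)
        lexrank[np.argsort(ids, kind="stable")] = np.arange(n_prot)

        A = np.where(observed, V, 0.0)
        M = observed.astype(float)
        B = (A * A) @ M.T
        shared = M @ M.T
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = np.maximum(B + B.T - 2.0 * (A @ A.T), 0.0)
            dist = np.sqrt(d2 * n_samp / shared)
        dist[shared == 0] = np.inf
        np.fill_diagonal(dist, np.inf)

        out = V.copy()
        prot_means = np.array([V[p, observed[p]].mean() for p in range(n_prot)])
        k = self.n_neighbors
        for s in range(n_samp):
            missing_rows = np.flatnonzero(~observed[:, s])
            if missing_rows.size == 0:
                continue
            cand = np.flatnonzero(observed[:, s])
            for p in missing_rows:
                dvec = dist[p, cand]
                finite = np.isfinite(dvec)
                if finite.sum() < k:
                    out[p, s] = prot_means[p]
                    continue
                fc = cand[finite]
                fd = dvec[finite]
                order = np.lexsort((lexrank[fc], fd))[:k]
                nn, nd = fc[order], fd[order]
                if nd[0] == 0.0:
                    zero = nn[nd == 0.0]
                    out[p, s] = V[zero, s].mean()
                else:
                    w = 1.0 / nd
                    out[p, s] = float(np.dot(w, V[nn, s]) / w.sum())
        return pd.DataFrame(out.T, index=X.index, columns=X.columns)


def knn_impute(matrix: IntensityMatrix, k: int = 10) -> IntensityMatrix:
    """Impute a transformed (vst-scale) proteins x samples matrix."""
    if matrix.scale == "raw":
        raise ValidationError("kNN imputation expects a variance-stabilized matrix")
    imputer = KNNProteinImputer(n_neighbors=k).fit(matrix.data.T)
    return matrix.replace(data=imputer.transform(matrix.data.T).T)


def preprocess_platform(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    sample_intensity_min: float = 225.0,
    min_within_patient: int = 2,
    min_patients: int = 2,
    knn_k: int = 10,
    apply_sample_filter: bool | None = None,
) -> tuple[IntensityMatrix, dict]:
    """Full preprocessing for one platform; returns the matrix and a log.

    The sample-total filter is applied to TMT only by default (where the
    study applied it); pass ``apply_sample_filter`` to override.
    """
    log: dict = {"platform": matrix.platform}
    if apply_sample_filter is None:
        apply_sample_filter = matrix.platform == "TMT"
    removed: list[str] = []
    if apply_sample_filter:
        matrix, removed = filter_low_intensity_samples(matrix, sample_intensity_min)
    log["removed_samples"] = removed
    before = list(matrix.protein_ids)
    matrix = filter_detection(matrix, meta, min_within_patient, min_patients)
    log["removed_proteins"] = sorted(set(before) - set(matrix.protein_ids))
    matrix, params = vst_normalize(matrix)
    log["vst_lambda"] = params.lambda_
    matrix = knn_impute(matrix, k=knn_k)
    log["n_proteins"] = matrix.n_proteins
    log["n_samples"] = matrix.n_samples
    return matrix, log
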