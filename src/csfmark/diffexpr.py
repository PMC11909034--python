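"""Patient-blocked differential expression with moderated t-statistics.

Every protein is fit by ordinary least squares on the no-intercept design
``~ 0 + timepoint + patient`` (one patient indicator dropped for
identifiability), so timepoint means are estimated within patients.
Residual variances are shrunk toward a pooled prior by empirical Bayes:
the prior degrees of freedom d0 and prior variance s0^2 are estimated by
matching the first two moments of log s^2 to a scaled-F sampling model via
digamma/trigamma equations, and the posterior variance

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces s^2 in the t-statistic, which then has d0 + d degrees of
freedom. All pairwise timepoint contrasts (later minus earlier, so
upregulation under therapy is positive) are tested; p-values are BH-
adjusted across proteins within each contrast; proteins with
FDR < 0.05 and |log2FC| > 0.5 (strict comparisons) are flagged as
differentially expressed (DEPs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .core import IntensityMatrix, ValidationError, meta_for
from .adjust import design_matrices

DEP_COLUMNS = ("protein", "contrast", "log2fc", "t", "p", "fdr", "is_dep", "direction")


# ---------------------------------------------------------------------------
# Per-protein OLS
# ---------------------------------------------------------------------------


@dataclass
class ProteinFitSet:
    """OLS results for all proteins on a shared design."""

    coef: pd.DataFrame  # proteins x design columns
    sigma2: pd.Series  # residual variance s^2 per protein
    df_resid: int  # d = n_samples - rank(design)
    design_columns: list[str]
    timepoint_levels: list[int]
    xtx_inv: np.ndarray  # (X'X)^-1 for contrast variances

    @property
    def proteins(self) -> pd.Index:
        return self.coef.index


def fit_protein_models(matrix: IntensityMatrix, meta: pd.DataFrame) -> ProteinFitSet:
    """OLS per protein on ``~ 0 + timepoint + patient``.

    Requires a complete (imputed) matrix with >= 2 timepoints and >= 2
    patients; a rank-deficient design beyond the standard single aliased
    patient indicator raises an error listing the aliased columns.
    """
    if matrix.missing_mask.any().any():
        raise ValidationError("differential expression expects a complete (imputed) matrix")
    m = meta_for(meta, matrix)
    timepoints = m["timepoint_months"].to_numpy()
    patients = m["patient_id"].to_numpy()
    if len(set(timepoints)) < 2:
        raise ValidationError("need >= 2 timepoints")
    if len(set(patients)) < 2:
        raise ValidationError("need >= 2 patients")
    T, P, tp_levels, pat_levels = design_matrices(timepoints, patients)
    D = np.hstack([T, P])
    columns = [f"tp{t}" for t in tp_levels] + [f"patient[{p}]" for p in pat_levels[1:]]
    n, p_cols = D.shape
    _, R, piv = linalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * max(n, p_cols) * np.finfo(float).eps).sum())
    if rank < p_cols:
        aliased = [columns[i] for i in piv[rank:]]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")
    if n <= p_cols:
        raise ValidationError("no residual degrees of freedom (n <= rank(design))")

    Y = matrix.values.T  # samples x proteins
    xtx = D.T @ D
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (D.T @ Y)
    resid = Y - D @ beta
    d = n - p_cols
    sigma2 = (resid * resid).sum(axis=0) / d
    return ProteinFitSet(
        coef=pd.DataFrame(beta.T, index=matrix.protein_ids, columns=columns),
        sigma2=pd.Series(sigma2, index=matrix.protein_ids, name="sigma2"),
        df_resid=d,
        design_columns=columns,
        timepoint_levels=tp_levels,
        xtx_inv=xtx_inv,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


@dataclass
class ModeratedFitSet:
    """Variance-moderated fits: prior (d0, s0^2) and posterior variances."""

    fits: ProteinFitSet
    prior_df: float  # d0
    prior_var: float  # s0^2
    s2_post: pd.Series

    @property
    def df_total(self) -> float:
        return self.prior_df + self.fits.df_resid


def moderate_variances(fits: ProteinFitSet, prior_df: float | None = None) -> ModeratedFitSet:
    """Estimate the variance prior and squeeze residual variances.

    ``prior_df`` overrides the estimated d0 (0 reproduces the classical
    per-protein t exactly). With no observable excess variability of
    log s^2 the d0 = infinity branch sets every posterior variance to the
    pooled mean without numerical failure.
    """
    s2 = fits.sigma2.to_numpy()
    d = fits.df_resid
    usable = s2 > 0
    if prior_df is None and usable.sum() < 10:
        raise ValidationError("need >= 10 proteins with positive residual variance")

    if prior_df is None:
        z = np.log(s2[usable])
        e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
        emean = float(e.mean())
        evar = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
        if evar > 0:
            d0 = 2.0 * trigamma_inverse(evar)
            s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0 = np.inf
            s02 = float(s2[usable].mean())
    else:
        d0 = float(prior_df)
        if np.isinf(d0):
            s02 = float(s2[usable].mean()) if usable.any() else 0.0
        elif d0 == 0 or not usable.any():
            s02 = 0.0 if not usable.any() else float("nan")
        else:
            z = np.log(s2[usable])
            e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
            s02 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    if d0 == 0:
        s2_post = s2.copy()
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
    return ModeratedFitSet(
        fits=fits,
        prior_df=d0,
        prior_var=s02,
        s2_post=pd.Series(s2_post, index=fits.proteins, name="s2_post"),
    )


# ---------------------------------------------------------------------------
# Contrasts, FDR, DEP calling
# ---------------------------------------------------------------------------


def contrast_label(earlier: int, later: int) -> str:
    return f"m{later}_vs_m{earlier}"


def test_contrasts(
    mfit: ModeratedFitSet, schedule: Sequence[int] | None = None
) -> pd.DataFrame:
    """Moderated t-tests for all pairwise timepoint contrasts.

    log2FC is the contrast estimate (later minus earlier timepoint) on the
    log2-compatible vst scale; p-values are two-sided from the t
    distribution with d0 + d degrees of freedom.
    """
    fits = mfit.fits
    levels = fits.timepoint_levels
    if schedule is not None:
        missing = sorted(set(int(t) for t in schedule) - set(levels))
        if missing:
            raise ValidationError(f"requested timepoints absent from the fit: {missing}")
        levels = [t for t in levels if t in set(int(x) for x in schedule)]
    beta = fits.coef.to_numpy()
    s2_post = mfit.s2_post.to_numpy()
    df_total = mfit.df_total
    frames = []
    for earlier, later in combinations(levels, 2):
        c = np.zeros(len(fits.design_columns))
        c[fits.design_columns.index(f"tp{later}")] = 1.0
        c[fits.design_columns.index(f"tp{earlier}")] = -1.0
        est = beta @ c
        v_c = float(c @ fits.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(s2_post * v_c)
            t = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.where(est == 0, 0.0, np.inf * np.sign(est)))
            p = np.where(
                np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df_total)
            )
        frames.append(
            pd.DataFrame(
                {
                    "protein": fits.proteins,
                    "contrast": contrast_label(earlier, later),
                    "log2fc": est,
                    "t": t,
                    "p": p,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


test_contrasts.__test__ = False  # statistical test, not a pytest case


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_fdr(table: pd.DataFrame, scope: str = "per_contrast") -> pd.DataFrame:
    """Attach BH-adjusted FDR to a contrast table.

    ``per_contrast`` (default, mirroring the referenced package) adjusts
    across proteins within each contrast; ``global`` adjusts across the
    whole table.
    """
    table = table.copy()
    if scope == "per_contrast":
        table["fdr"] = table.groupby("contrast")["p"].transform(lambda s: bh_adjust(s.to_numpy()))
    elif scope == "global":
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    else:
        raise ValidationError(f"unknown FDR scope {scope!r}")
    return table


def call_deps(
    table: pd.DataFrame, fdr_alpha: float = 0.05, log2fc_min: float = 0.5
) -> pd.DataFrame:
    """Flag DEPs: FDR < alpha AND |log2FC| > threshold (both strict)."""
    table = table.copy()
    if "fdr" not in table.columns:
        raise ValidationError("run adjust_fdr before calling DEPs")
    table["is_dep"] = (table["fdr"] < fdr_alpha) & (table["log2fc"].abs() > log2fc_min)
    table["direction"] = np.where(
        table["log2fc"] > 0, "up", np.where(table["log2fc"] < 0, "down", "none")
    )
    return table


def dep_summary(table: pd.DataFrame) -> pd.DataFrame:
    """DEP counts per contrast and direction (the pairwise-DEP surface)."""
    deps = table[table["is_dep"]]
    out = (
        deps.groupby(["contrast", "direction"]).size().unstack(fill_value=0).reset_index()
    )
    for col in ("up", "down"):
        if col not in out.columns:
            out[col] = 0
    out["total"] = out["up"] + out["down"]
    return out[["contrast", "up", "down", "total"]]


def differential_expression(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    fdr_alpha: float = 0.05,
    log2fc_min: float = 0.5,
    prior_df: float | None = None,
    fdr_scope: str = "per_contrast",
) -> pd.DataFrame:
    """Full DEP pipeline: OLS, moderation, contrasts, FDR, calling."""
    fits = fit_protein_models(matrix, meta)
    mfit = moderate_variances(fits, prior_df=prior_df)
    table = test_contrasts(mfit)
    table = adjust_fdr(table, scope=fdr_scope)
    return call_deps(table, fdr_alpha=fdr_alpha, log2fc_min=log2fc_min)


class PairwiseModeratedTest(BaseEstimator):
    """Estimator facade over the DEP pipeline.

    ``fit(X, timepoints=..., patients=...)`` with X of shape
    (n_samples, n_proteins) populates ``results_`` (the DEP table),
    ``prior_df_``, ``prior_var_`` and ``coef_``.
    """

    def __init__(
        self,
        fdr_alpha: float = 0.05,
        log2fc_min: float = 0.5,
        prior_df: float | None = None,
        fdr_scope: str = "per_contrast",
    ):
        self.fdr_alpha = fdr_alpha
        self.log2fc_min = log2fc_min
        self.prior_df = prior_df
        self.fdr_scope = fdr_scope

    def fit(self, X, y=None, *, timepoints, patients, platform: str = "TMT"):
        X = pd.DataFrame(X)
        meta = pd.DataFrame(
            {
                "sample_id": X.index.astype(str),
                "patient_id": patients,
                "timepoint_months": timepoints,
                "platform": platform,
                "batch_id": "na",
            }
        )
        matrix = IntensityMatrix(
            X.T.set_axis(X.index.astype(str), axis=1), platform=platform, scale="vst"
        )
        fits = fit_protein_models(matrix, meta)
        mfit = moderate_variances(fits, prior_df=self.prior_df)
        table = adjust_fdr(test_contrasts(mfit), scope=self.fdr_scope)
        self.results_ = call_deps(table, self.fdr_alpha, self.log2fc_min)
        self.coef_ = fits.coef
        self.prior_df_ = mfit.prior_df
        self.prior_var_ = mfit.prior_var
        self.s2_post_ = mfit.s2_post
        return self
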