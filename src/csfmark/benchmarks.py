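"""Simulation benchmarks: recovery, calibration and structure checks.

These routines run the full pipeline on synthetic cohorts with known
ground truth and measure how well it recovers the planted structure:
planted-DEP recovery and false-discovery control, variance-stabilization
efficacy, imputation accuracy, prior-parameter recovery for the variance
moderation, and the qualitative cohort structure (pre-treatment sample
cluster, platform depth relationship, dominant-protein rank stability).

Problem sizes: calibration benchmarks use 500 proteins / 12 patients /
5 timepoints; recovery and structure benchmarks use 600 TMT (180 LFQ)
proteins / 12 patients / 7 timepoints -- the cohort's statistical
structure at a size that keeps repeated end-to-end runs cheap. The noise
model is always the generator's default.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .adjust import (
    hierarchical_cluster,
    pre_treatment_block_purity,
    remove_patient_effect,
    sample_correlation,
    zscore_rows,
)
from .diffexpr import (
    ModeratedFitSet,
    ProteinFitSet,
    contrast_label,
    differential_expression,
    moderate_variances,
)
from .markers import clinical_deltas, protein_deltas, protein_hfmse_screen, scan_cutoffs
from .preprocess import knn_impute, preprocess_platform, vst_normalize
from .simulate import SimConfig, mask_missing, simulate_cohort, simulate_null

#: oracle cutoff scan: dense theta grid, rule must still cover >= 30% of visits
CUTOFF_GRID = tuple(np.round(np.arange(0.1, 1.55, 0.1), 2))
CUTOFF_MIN_COVERED = 0.3


def scaled_config(n_timepoints: int = 7, n_proteins: int = 600, n_patients: int = 12, **overrides) -> SimConfig:
    """Default study structure scaled down for repeated benchmark runs."""
    full = SimConfig()
    schedule = full.schedule[:n_timepoints]
    counts = tuple(
        max(int(round(c * n_patients / full.n_patients)), 2)
        for c in full.patients_per_timepoint[:n_timepoints]
    )
    counts = (n_patients,) * min(3, n_timepoints) + counts[3:]
    n_lfq = max(int(round(n_proteins * full.n_proteins_lfq / full.n_proteins_tmt)), 20)
    n_shared = max(int(round(n_lfq * full.n_shared / full.n_proteins_lfq)), 10)
    params = dict(
        n_patients=n_patients,
        schedule=schedule,
        patients_per_timepoint=counts,
        n_proteins_tmt=n_proteins,
        n_proteins_lfq=n_lfq,
        n_shared=n_shared,
        n_planted_deps=min(full.n_planted_deps, n_proteins // 10),
    )
    params.update(overrides)
    return SimConfig(**params)


def _seed_stream(seed: int, n: int) -> list[int]:
    return [(seed * 1000 + i) % (2**31 - 1) for i in range(n)]


# ---------------------------------------------------------------------------
# Calibration and recovery benchmarks
# ---------------------------------------------------------------------------


def prior_recovery(
    seed: int, d0: float = 4.0, s02: float = 2.0, n_proteins: int = 2000, df_resid: int = 16
) -> tuple[float, float]:
    """Recover (d0, s0^2) from variances simulated under the scaled-F model.

    True protein variances are drawn from the scaled inverse chi-square
    prior, observed s^2 from the chi-square sampling layer with
    ``df_resid`` degrees of freedom; returns the moment estimates.
    """
    rng = np.random.default_rng(seed)
    sigma2 = d0 * s02 / rng.chisquare(d0, n_proteins)
    s2 = sigma2 * rng.chisquare(df_resid, n_proteins) / df_resid
    fits = ProteinFitSet(
        coef=pd.DataFrame(index=pd.RangeIndex(n_proteins)),
        sigma2=pd.Series(s2),
        df_resid=df_resid,
        design_columns=[],
        timepoint_levels=[],
        xtx_inv=np.zeros((0, 0)),
    )
    mfit: ModeratedFitSet = moderate_variances(fits)
    return float(mfit.prior_df), float(mfit.prior_var)


def null_fdr(seed: int, n_seeds: int = 20) -> dict:
    """Empirical false-discovery proportion on null cohorts.

    For each seed a null cohort (500 proteins, 12 patients, 5 timepoints,
    no planted effects) is simulated, preprocessed and tested; FDP is
    V/max(R,1) per contrast family (every discovery on a null cohort is
    false). Returns the mean FDP over all (seed, contrast) families, the
    per-seed means and their Monte-Carlo margin (2 x SE, floored at 0.02).
    """
    config = scaled_config(n_timepoints=5, n_proteins=500)
    per_seed = []
    total_deps = 0
    for s in _seed_stream(seed, n_seeds):
        tmt, _, meta, _, _ = simulate_null(config, seed=s)
        processed, _ = preprocess_platform(tmt, meta)
        table = differential_expression(processed, meta)
        fdp_per_contrast = table.groupby("contrast")["is_dep"].agg(lambda x: float(x.any()))
        per_seed.append(float(fdp_per_contrast.mean()))
        total_deps += int(table["is_dep"].sum())
    per_seed_arr = np.asarray(per_seed)
    se = per_seed_arr.std(ddof=1) / math.sqrt(len(per_seed_arr)) if len(per_seed_arr) > 1 else 0.0
    return {
        "mean_fdp": float(per_seed_arr.mean()),
        "per_seed": per_seed,
        "margin": max(2.0 * float(se), 0.02),
        "total_false_deps": total_deps,
        "n_seeds": n_seeds,
    }


def recovery_benchmark(seed: int, n_seeds: int = 5) -> dict:
    """Planted-effect recovery through the full pipeline.

    Per seed: fraction of planted DEPs flagged (correct direction) at the
    baseline-to-onset-month contrast; fraction of planted clinically
    coupled proteins ranking in the top 5% by |r| of the change-change
    screen; and the grid-scan cutoff concordance of the planted
    positive-slope coupled proteins.
    """
    config = scaled_config(n_timepoints=7, n_proteins=600)
    recoveries, top5_fracs, concordances = [], [], []
    for s in _seed_stream(seed, n_seeds):
        tmt, _, meta, clinical, truth = simulate_cohort(config, seed=s)
        processed, _ = preprocess_platform(tmt, meta)
        table = differential_expression(processed, meta)
        label = contrast_label(0, config.dep_onset_month)
        sub = table[table["contrast"] == label].set_index("protein")
        hits = 0
        for _, row in truth.dep_effects.iterrows():
            p = row["protein"]
            if p in sub.index and sub.loc[p, "is_dep"]:
                direction = "up" if row["sign"] > 0 else "down"
                hits += int(sub.loc[p, "direction"] == direction)
        recoveries.append(hits / len(truth.dep_effects))

        screen = protein_hfmse_screen(processed, meta, clinical)
        n_top = max(int(np.ceil(0.05 * len(screen))), 1)
        top = set(screen.reindex(screen["r"].abs().sort_values(ascending=False).index)["protein"].head(n_top))
        coupled = truth.coupled_proteins & set(screen["protein"])
        top5_fracs.append(len(coupled & top) / max(len(coupled), 1))

        dy = clinical_deltas(clinical, "hfmse")
        dx_all = protein_deltas(processed, meta)
        pos = truth.coupled[truth.coupled["slope"] > 0]["protein"]
        per_protein = []
        for p in pos:
            if p not in set(processed.protein_ids):
                continue
            rule = scan_cutoffs(
                dx_all[dx_all["protein"] == p], dy, CUTOFF_GRID, min_covered=CUTOFF_MIN_COVERED
            )
            if rule.concordance is not None:
                per_protein.append(rule.concordance)
        concordances.append(float(np.mean(per_protein)) if per_protein else np.nan)
    return {
        "dep_recovery": float(np.mean(recoveries)),
        "dep_recovery_per_seed": recoveries,
        "coupled_top5_fraction": float(np.mean(top5_fracs)),
        "cutoff_concordance": float(np.nanmean(concordances)),
        "n_seeds": n_seeds,
    }


def vst_benchmark(seed: int) -> tuple[float, float]:
    """Mean-SD Spearman rho on the raw scale vs after the VST (default cohort)."""
    from .preprocess import _mean_sd_spearman, filter_detection, filter_low_intensity_samples
    from scipy import stats as _stats

    tmt, _, meta, _, _ = simulate_cohort(SimConfig(), seed=seed)
    filtered, _ = filter_low_intensity_samples(tmt)
    filtered = filter_detection(filtered, meta)
    raw = filtered.values
    means = np.nanmean(raw, axis=1)
    sds = np.nanstd(raw, axis=1, ddof=1)
    rho_raw = float(_stats.spearmanr(means, sds).statistic)
    normalized, _ = vst_normalize(filtered)
    rho_vst = _mean_sd_spearman(normalized.values)
    return rho_raw, rho_vst


def imputation_benchmark(seed: int, mask_rate: float = 0.05) -> tuple[float, float]:
    """Masked-entry RMSE of kNN vs protein-mean imputation (default cohort).

    A complete cohort (missing rate 0) is variance-stabilized, 5% of
    entries are masked at random, and both imputers are scored against
    the hidden truth.
    """
    config = dataclasses.replace(SimConfig(), missing_rate=0.0, n_low_quality_samples=0)
    tmt, _, meta, _, _ = simulate_cohort(config, seed=seed)
    normalized, _ = vst_normalize(tmt)
    masked = mask_missing(normalized, mask_rate, "MAR", seed=seed + 1)
    hidden = masked.missing_mask.to_numpy()
    truth_vals = normalized.values[hidden]

    imputed = knn_impute(masked, k=10)
    rmse_knn = float(np.sqrt(np.mean((imputed.values[hidden] - truth_vals) ** 2)))

    row_means = np.nanmean(masked.values, axis=1)
    mean_imputed = np.where(hidden, row_means[:, None], masked.values)
    rmse_mean = float(np.sqrt(np.mean((mean_imputed[hidden] - truth_vals) ** 2)))
    return rmse_knn, rmse_mean


def structure_benchmark(seed: int) -> dict:
    """Qualitative figure surfaces on one scaled end-to-end run.

    Returns the pre-treatment cluster block purity, the median TMT
    abundance rank of LFQ-covered vs TMT-only proteins, and whether the
    planted dominant protein holds rank 1 at every timepoint.
    """
    config = scaled_config(n_timepoints=7, n_proteins=600)
    tmt, lfq, meta, clinical, truth = simulate_cohort(config, seed=seed)
    processed, _ = preprocess_platform(tmt, meta)
    adjusted = remove_patient_effect(processed, meta)
    z = zscore_rows(adjusted)
    heatmap = hierarchical_cluster(sample_correlation(z))
    meta_idx = meta.set_index("sample_id")
    pre = {
        s
        for s in heatmap.sample_ids
        if meta_idx.loc[s, "timepoint_months"] == 0
    }
    purity = pre_treatment_block_purity(heatmap, pre)

    from .crossplatform import rank_intensity, top_rank_trajectory

    ranks = rank_intensity(processed, highlight=set(lfq.protein_ids))
    med_shared = float(ranks.loc[ranks["highlighted"], "rank"].median())
    med_only = float(ranks.loc[~ranks["highlighted"], "rank"].median())
    trajectory = top_rank_trajectory(processed, meta, k=10).set_index("protein")
    dominant_first = bool((trajectory.loc[truth.dominant_protein] == 1).all())
    return {
        "block_purity": purity,
        "median_rank_lfq_covered": med_shared,
        "median_rank_tmt_only": med_only,
        "dominant_rank1_all_timepoints": dominant_first,
    }
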