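"""Synthetic longitudinal dual-platform CSF proteomics cohorts.

Generates paired TMT/LFQ intensity matrices, sample metadata, clinical
records and a ground-truth object for a nusinersen-style treatment cohort:
24 patients sampled at months 0, 2, 10, 18, 26, 34 and 42 with monotone
dropout (24, 24, 24, 20, 17, 14, 11 patients per timepoint), ~1,674 TMT
proteins of which the top-abundance 429 are also seen by the shallower
LFQ platform (441 proteins total), patient-level heterogeneity, per-patient
TMT plex batch effects, latent co-regulation factors, a mean-variance
coupled noise model, missing-at-random values, planted treatment-responsive
proteins and planted protein trajectories coupled to the HFMSE motor score.

The noise model is, on the raw scale,

    intensity = 2^(mu_p + patient + batch + factors + effect) * e^eps + delta

with log-normal multiplicative noise ``eps`` and additive noise ``delta``
(clipped at zero), so per-protein SD grows with the mean and a glog-type
variance-stabilizing transformation is the appropriate normalizer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SCHEDULE,
    HFMSE_MAX,
    IntensityMatrix,
    ValidationError,
    check_sample_meta,
)

MISSING_MECHANISMS = ("MAR", "intensity_dependent")

#: Mean HFMSE improvement over baseline at each scheduled month.
DEFAULT_HFMSE_DRIFT = {0: 0.0, 2: 1.1, 10: 2.2, 18: 1.6, 26: 1.4, 34: 2.6, 42: 2.1}


@dataclass
class SimConfig:
    """Cohort generator configuration with the study's structure as defaults."""

    n_patients: int = 24
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    #: patients still sampled at each scheduled timepoint (monotone dropout)
    patients_per_timepoint: tuple[int, ...] = (24, 24, 24, 20, 17, 14, 11)

    n_proteins_tmt: int = 1674
    n_proteins_lfq: int = 441
    n_shared: int = 429

    #: baseline log2 abundance range (~20 log2 units of dynamic range)
    log2_abundance_range: tuple[float, float] = (4.0, 24.0)
    patient_sd: float = 0.5  # per-(protein, patient) random effect, log2 units
    batch_sd: float = 0.3  # per-(protein, plex) effect, log2; one TMT plex per patient
    n_factors: int = 3  # latent per-visit factors -> protein co-regulation
    factor_loading_sd: float = 0.15
    multiplicative_sd: float = 0.15  # natural-log scale
    additive_sd: float = 50.0  # raw intensity units

    missing_rate: float = 0.08
    missing_mechanism: str = "MAR"

    n_planted_deps: int = 40
    dep_log2fc: float = 1.5
    dep_onset_month: int = 10
    #: fraction of the full effect already present at post-baseline months
    #: before onset (treatment effects begin with the first post-baseline
    #: visit; pre-therapy samples then separate from all treated samples)
    dep_early_fraction: float = 1.0
    #: fraction of planted DEPs drawn from the LFQ-covered (shared) stratum
    dep_shared_fraction: float = 0.6
    #: minimum baseline log2 abundance for a protein to carry a planted
    #: effect (below this the additive-noise floor makes fold changes
    #: unquantifiable by construction)
    dep_min_abundance: float = 9.0

    #: broad sub-threshold proteome response: a random protein subset gets a
    #: persistent N(0, broad_shift_sd) log2 shift at treated visits -- the
    #: "general shift of protein composition" that separates pre-therapy
    #: samples without reaching the DEP thresholds
    broad_shift_fraction: float = 0.25
    broad_shift_sd: float = 0.3

    n_coupled: int = 10
    coupling_slope: float = 0.2  # log2 units per HFMSE point
    coupling_positive_fraction: float = 0.7
    coupling_noise_sd: float = 0.15

    hfmse_baseline_mean: float = 23.0
    hfmse_baseline_sd: float = 15.0
    hfmse_drift: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_HFMSE_DRIFT))
    hfmse_response_scale_sd: float = 0.8  # patient-level responder heterogeneity
    hfmse_visit_sd: float = 2.0

    n_low_quality_samples: int = 2  # planted low-total TMT samples
    low_quality_total: float = 100.0

    clinical_baselines: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "qalb": (6.5, 1.5),
            "lactate": (1.7, 0.2),
            "glucose": (62.0, 7.0),
            "total_protein": (450.0, 90.0),
        }
    )
    #: slope of each routine parameter per HFMSE point of change
    #: (qAlb, lactate, glucose inversely track improvement; total protein
    #: is left uncoupled as a null parameter)
    clinical_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"qalb": -0.08, "lactate": -0.015, "glucose": -0.5}
    )
    clinical_noise: Mapping[str, float] = field(
        default_factory=lambda: {
            "qalb": 0.3,
            "lactate": 0.06,
            "glucose": 2.0,
            "total_protein": 25.0,
        }
    )
    lymphocyte_coupling: float = -0.4  # percent points per HFMSE point
    macrophage_trend: float = 0.08  # percent points per month under therapy

    def __post_init__(self) -> None:
        self.schedule = tuple(int(t) for t in self.schedule)
        self.patients_per_timepoint = tuple(int(c) for c in self.patients_per_timepoint)
        if len(self.patients_per_timepoint) != len(self.schedule):
            raise ValidationError("patients_per_timepoint must match schedule length")
        if self.patients_per_timepoint[0] != self.n_patients:
            raise ValidationError("all patients must be sampled at baseline")
        if any(
            a < b
            for a, b in zip(self.patients_per_timepoint, self.patients_per_timepoint[1:])
        ):
            raise ValidationError("dropout counts must be non-increasing")
        if self.n_shared > min(self.n_proteins_tmt, self.n_proteins_lfq):
            raise ValidationError("n_shared exceeds a platform's protein count")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in MISSING_MECHANISMS:
            raise ValidationError(f"unknown missing mechanism {self.missing_mechanism!r}")
        n_eligible_needed = self.n_planted_deps + self.n_coupled
        if n_eligible_needed > self.n_proteins_tmt:
            raise ValidationError("more planted proteins than proteins simulated")

    @property
    def n_samples_per_platform(self) -> int:
        return int(sum(self.patients_per_timepoint))

    def patient_ids(self) -> list[str]:
        return [f"SMA{i + 1:02d}" for i in range(self.n_patients)]

    def visits(self) -> list[tuple[int, int]]:
        """(patient index, timepoint) pairs, patient-major order.

        Patient ``i`` is observed at timepoint ``j`` iff
        ``i < patients_per_timepoint[j]`` -- monotone dropout, patients
        leave and never return.
        """
        out = []
        for i in range(self.n_patients):
            for j, t in enumerate(self.schedule):
                if i < self.patients_per_timepoint[j]:
                    out.append((i, t))
        return out


@dataclass
class GroundTruth:
    """Planted effects of a simulated cohort, for recovery testing."""

    dep_effects: pd.DataFrame  # protein, sign, log2fc, onset_month, early_fraction, shared
    coupled: pd.DataFrame  # protein, slope
    broad_shifts: pd.DataFrame  # protein, shift (sub-threshold treatment response)
    low_quality_samples: list[str]
    dominant_protein: str
    missing_mechanism: str
    patient_effects: pd.DataFrame  # proteins x patients, log2 offsets
    batch_effects: pd.DataFrame  # proteins x plexes, log2 offsets
    hfmse_baseline: pd.Series  # per patient

    @property
    def dep_proteins(self) -> set[str]:
        return set(self.dep_effects["protein"])

    @property
    def coupled_proteins(self) -> set[str]:
        return set(self.coupled["protein"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dep_effects": self.dep_effects.to_dict(orient="list"),
            "coupled": self.coupled.to_dict(orient="list"),
            "broad_shifts": self.broad_shifts.to_dict(orient="list"),
            "low_quality_samples": self.low_quality_samples,
            "dominant_protein": self.dominant_protein,
            "missing_mechanism": self.missing_mechanism,
            "hfmse_baseline": self.hfmse_baseline.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _sample_id(patient: str, timepoint: int, platform: str) -> str:
    return f"{patient}_m{timepoint:02d}_{platform}"


def _simulate_hfmse(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Integer HFMSE trajectories for every scheduled visit of every patient."""
    base = np.clip(
        np.round(rng.normal(config.hfmse_baseline_mean, config.hfmse_baseline_sd, config.n_patients)),
        0,
        HFMSE_MAX,
    )
    resp = rng.normal(1.0, config.hfmse_response_scale_sd, config.n_patients)
    rows = []
    for i, t in config.visits():
        drift = float(config.hfmse_drift.get(t, 0.0))
        noise = rng.normal(0.0, config.hfmse_visit_sd) if t > 0 else 0.0
        score = np.clip(np.round(base[i] + resp[i] * drift + noise), 0, HFMSE_MAX)
        rows.append((i, t, int(score)))
    df = pd.DataFrame(rows, columns=["patient_index", "timepoint_months", "hfmse"])
    df["baseline"] = base[df["patient_index"].to_numpy()].astype(int)
    return df


def _effect_ramp(t: int, config: SimConfig) -> float:
    if t <= 0:
        return 0.0
    if t < config.dep_onset_month:
        return config.dep_early_fraction
    return 1.0


def simulate_cohort(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[IntensityMatrix, IntensityMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a paired TMT/LFQ cohort with known ground truth.

    Returns ``(tmt, lfq, meta, clinical, truth)``. Deterministic given
    ``(config, seed)``: the same inputs produce bit-identical outputs.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    patients = config.patient_ids()
    visits = config.visits()  # (patient index, timepoint)
    n_visits = len(visits)
    visit_index = {v: k for k, v in enumerate(visits)}

    # ------------------------------------------------------------------ ids
    n_tmt = config.n_proteins_tmt
    tmt_ids = ["ALB"] + [f"P{i:04d}" for i in range(2, n_tmt + 1)]
    lo, hi = config.log2_abundance_range
    mu_tmt = np.empty(n_tmt)
    mu_tmt[0] = hi + 2.0  # dominant albumin-like protein, above everything
    mu_tmt[1:] = rng.uniform(lo, hi, n_tmt - 1)

    order = np.lexsort((np.array(tmt_ids), -mu_tmt))
    shared_idx = np.sort(order[: config.n_shared])
    shared_ids = [tmt_ids[i] for i in shared_idx]

    n_lfq_only = config.n_proteins_lfq - config.n_shared
    lfq_only_ids = [f"L{i:03d}" for i in range(1, n_lfq_only + 1)]
    mu_lfq_only = rng.uniform(hi - 8.0, hi, n_lfq_only)

    master_ids = tmt_ids + lfq_only_ids
    mu = np.concatenate([mu_tmt, mu_lfq_only])
    n_master = len(master_ids)
    row_of = {p: i for i, p in enumerate(master_ids)}

    # ----------------------------------------------------------- random fx
    patient_eff = rng.normal(0.0, config.patient_sd, (n_master, config.n_patients))
    plexes = [f"plex_{p}" for p in patients]  # one TMT plex per patient series
    batch_eff = rng.normal(0.0, config.batch_sd, (n_master, config.n_patients))
    loadings = rng.normal(0.0, config.factor_loading_sd, (n_master, config.n_factors))
    scores = rng.normal(0.0, 1.0, (config.n_factors, n_visits))

    # ------------------------------------------------------------- planting
    shared_set = set(shared_ids)
    eligible = [
        i
        for i, p in enumerate(master_ids)
        if p != "ALB" and i < n_tmt and mu[i] >= config.dep_min_abundance
    ]
    eligible_shared = [i for i in eligible if master_ids[i] in shared_set]
    eligible_tmt_only = [i for i in eligible if master_ids[i] not in shared_set]

    n_dep_shared = min(
        int(round(config.dep_shared_fraction * config.n_planted_deps)), len(eligible_shared)
    )
    n_dep_only = min(config.n_planted_deps - n_dep_shared, len(eligible_tmt_only))
    dep_rows = sorted(
        list(rng.choice(eligible_shared, n_dep_shared, replace=False))
        + list(rng.choice(eligible_tmt_only, n_dep_only, replace=False))
    )
    dep_signs = rng.choice([-1.0, 1.0], len(dep_rows))

    remaining_shared = sorted(set(eligible_shared) - set(dep_rows))
    n_coupled = min(config.n_coupled, len(remaining_shared))
    coupled_rows = sorted(rng.choice(remaining_shared, n_coupled, replace=False))
    coupled_signs = np.where(
        rng.random(n_coupled) < config.coupling_positive_fraction, 1.0, -1.0
    )
    coupled_slopes = coupled_signs * config.coupling_slope

    # --------------------------------------------------------------- hfmse
    hfmse = _simulate_hfmse(config, rng)
    dhf = (hfmse["hfmse"] - hfmse["baseline"]).to_numpy(dtype=float)

    # -------------------------------------------------- per-visit effects
    effect = np.zeros((n_master, n_visits))
    ramp = np.array([_effect_ramp(t, config) for _, t in visits])
    for row, sign in zip(dep_rows, dep_signs):
        effect[row, :] = sign * config.dep_log2fc * ramp
    for row, slope in zip(coupled_rows, coupled_slopes):
        noise = rng.normal(0.0, config.coupling_noise_sd, n_visits)
        effect[row, :] = slope * dhf + np.where(ramp > 0, noise, 0.0)

    broad_rows: np.ndarray = np.array([], dtype=int)
    broad_shifts = np.array([])
    if config.broad_shift_fraction > 0 and config.broad_shift_sd > 0:
        taken = set(dep_rows) | set(coupled_rows) | {0}
        pool = np.array([i for i in range(n_master) if i not in taken])
        n_broad = min(int(round(config.broad_shift_fraction * n_master)), pool.size)
        broad_rows = np.sort(rng.choice(pool, n_broad, replace=False))
        broad_shifts = rng.normal(0.0, config.broad_shift_sd, n_broad)
        effect[broad_rows, :] += broad_shifts[:, None] * (ramp > 0)

    # ----------------------------------------------------- signal assembly
    visit_patient = np.array([i for i, _ in visits])
    log2_signal = (
        mu[:, None]
        + patient_eff[:, visit_patient]
        + loadings @ scores
        + effect
    )

    def _measure(rows: np.ndarray, with_batch: bool) -> np.ndarray:
        sig = log2_signal[rows]
        if with_batch:
            sig = sig + batch_eff[np.ix_(rows, visit_patient)]
        raw = np.power(2.0, sig)
        if config.multiplicative_sd > 0:
            raw = raw * np.exp(rng.normal(0.0, config.multiplicative_sd, raw.shape))
        if config.additive_sd > 0:
            raw = raw + rng.normal(0.0, config.additive_sd, raw.shape)
        return np.maximum(raw, 0.0)

    tmt_rows = np.array([row_of[p] for p in tmt_ids])
    lfq_rows = np.array([row_of[p] for p in shared_ids + lfq_only_ids])
    raw_tmt = _measure(tmt_rows, with_batch=True)
    raw_lfq = _measure(lfq_rows, with_batch=False)

    sample_ids_tmt = [_sample_id(patients[i], t, "TMT") for i, t in visits]
    sample_ids_lfq = [_sample_id(patients[i], t, "LFQ") for i, t in visits]

    # ------------------------------------------------- low-quality samples
    low_quality: list[str] = []
    if config.n_low_quality_samples > 0:
        candidates = [k for k, (_, t) in enumerate(visits) if t > 0]
        chosen = sorted(rng.choice(candidates, config.n_low_quality_samples, replace=False))
        for k in chosen:
            total = raw_tmt[:, k].sum()
            if total > 0:
                raw_tmt[:, k] *= config.low_quality_total / total
            low_quality.append(sample_ids_tmt[k])

    tmt = IntensityMatrix(
        pd.DataFrame(raw_tmt, index=tmt_ids, columns=sample_ids_tmt), platform="TMT"
    )
    lfq = IntensityMatrix(
        pd.DataFrame(raw_lfq, index=shared_ids + lfq_only_ids, columns=sample_ids_lfq),
        platform="LFQ",
    )

    if config.missing_rate > 0:
        tmt = _mask_with_rng(tmt, config.missing_rate, config.missing_mechanism, rng)
        lfq = _mask_with_rng(lfq, config.missing_rate, config.missing_mechanism, rng)

    # ------------------------------------------------------------ metadata
    meta_rows = []
    for k, (i, t) in enumerate(visits):
        meta_rows.append((sample_ids_tmt[k], patients[i], t, "TMT", plexes[i]))
    for k, (i, t) in enumerate(visits):
        meta_rows.append((sample_ids_lfq[k], patients[i], t, "LFQ", "lfq_run1"))
    meta = check_sample_meta(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "patient_id", "timepoint_months", "platform", "batch_id"],
        ),
        schedule=config.schedule,
    )

    # ------------------------------------------------------------ clinical
    cb = config.clinical_baselines
    base_clin = {
        name: np.maximum(rng.normal(m, s, config.n_patients), 0.05 * m)
        for name, (m, s) in cb.items()
    }
    base_cells = np.maximum(rng.poisson(250, config.n_patients), 20)
    clin_rows = []
    for k, (i, t) in enumerate(visits):
        row: dict[str, object] = {
            "patient_id": patients[i],
            "timepoint_months": t,
            "hfmse": int(hfmse["hfmse"].iloc[k]),
        }
        d = dhf[k]
        for name in cb:
            slope = float(config.clinical_coupling.get(name, 0.0))
            noise = rng.normal(0.0, float(config.clinical_noise.get(name, 0.0))) if t > 0 else 0.0
            row[name] = max(float(base_clin[name][i] + slope * d + noise), 0.0)
        lym = 72.0 + config.lymphocyte_coupling * d + (rng.normal(0.0, 2.0) if t > 0 else 0.0)
        mono = 24.0 + rng.normal(0.0, 2.0)
        mac = 3.0 + config.macrophage_trend * t + abs(rng.normal(0.0, 1.0))
        parts = np.maximum(np.array([lym, mono, mac]), 0.2)
        parts = parts / parts.sum() * 100.0
        row["pct_lymphocyte"], row["pct_monocyte"], row["pct_macrophage"] = parts.round(6)
        row["total_cells_per_100ul"] = int(
            max(np.round(base_cells[i] * (1.0 + 0.1 * rng.normal())), 5)
        )
        clin_rows.append(row)
    clinical = pd.DataFrame(clin_rows)

    truth = GroundTruth(
        dep_effects=pd.DataFrame(
            {
                "protein": [master_ids[r] for r in dep_rows],
                "sign": dep_signs.astype(int),
                "log2fc": config.dep_log2fc,
                "onset_month": config.dep_onset_month,
                "early_fraction": config.dep_early_fraction,
                "shared": [master_ids[r] in shared_set for r in dep_rows],
            }
        ),
        coupled=pd.DataFrame(
            {"protein": [master_ids[r] for r in coupled_rows], "slope": coupled_slopes}
        ),
        broad_shifts=pd.DataFrame(
            {"protein": [master_ids[r] for r in broad_rows], "shift": broad_shifts}
        ),
        low_quality_samples=low_quality,
        dominant_protein="ALB",
        missing_mechanism=config.missing_mechanism,
        patient_effects=pd.DataFrame(patient_eff, index=master_ids, columns=patients),
        batch_effects=pd.DataFrame(batch_eff, index=master_ids, columns=plexes),
        hfmse_baseline=pd.Series(
            hfmse.drop_duplicates("patient_index")["baseline"].to_numpy(),
            index=patients,
            name="hfmse_baseline",
        ),
    )
    return tmt, lfq, meta, clinical, truth


def simulate_null(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[IntensityMatrix, IntensityMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Cohort with zero planted effects (type-I error testing)."""
    config = config or SimConfig()
    null_config = dataclasses.replace(
        config, n_planted_deps=0, n_coupled=0, broad_shift_fraction=0.0
    )
    return simulate_cohort(null_config, seed)


# ---------------------------------------------------------------------------
# Missing-value masking
# ---------------------------------------------------------------------------


def mask_missing(
    matrix: IntensityMatrix,
    rate: float,
    mechanism: str = "MAR",
    seed: int = 0,
) -> IntensityMatrix:
    """Mask values so the overall missing fraction reaches ``rate``.

    ``MAR`` masks uniformly at random, independent of intensity.
    ``intensity_dependent`` masks low-intensity cells preferentially
    (logistic weight in log2 intensity, weighted sampling without
    replacement). The achieved overall fraction equals
    ``round(rate * n_cells)`` cells exactly.
    """
    if not (0.0 <= rate < 1.0):
        raise ValidationError("missing rate must lie in [0, 1)")
    if mechanism not in MISSING_MECHANISMS:
        raise ValidationError(f"unknown missing mechanism {mechanism!r}")
    if rate == 0.0:
        return matrix.replace()
    return _mask_with_rng(matrix, rate, mechanism, np.random.default_rng(seed))


def _mask_with_rng(
    matrix: IntensityMatrix, rate: float, mechanism: str, rng: np.random.Generator
) -> IntensityMatrix:
    values = matrix.values.copy()
    flat = values.ravel()
    observed = np.flatnonzero(~np.isnan(flat))
    target = int(round(rate * flat.size))
    n_new = target - (flat.size - observed.size)
    if n_new <= 0:
        return matrix.replace()
    if mechanism == "MAR":
        chosen = rng.choice(observed, n_new, replace=False)
    else:
        lx = np.log2(flat[observed] + 1.0)
        center = np.quantile(lx, 0.3)
        weights = 1.0 / (1.0 + np.exp((lx - center) / 1.5))
        # Efraimidis-Spirakis weighted sampling without replacement
        keys = rng.exponential(size=observed.size) / weights
        chosen = observed[np.argpartition(keys, n_new - 1)[:n_new]]
    flat[chosen] = np.nan
    return matrix.replace(
        data=pd.DataFrame(
            flat.reshape(values.shape), index=matrix.protein_ids, columns=matrix.sample_ids
        )
    )


def write_cohort(
    outdir: str | Path,
    tmt: IntensityMatrix,
    lfq: IntensityMatrix,
    meta: pd.DataFrame,
    clinical: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort in the TSV formats the readers accept."""
    from .core import write_clinical_table, write_intensity_table, write_sample_meta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tmt": outdir / "intensities_tmt.tsv",
        "lfq": outdir / "intensities_lfq.tsv",
        "meta": outdir / "sample_meta.tsv",
        "clinical": outdir / "clinical.tsv",
    }
    write_intensity_table(tmt, paths["tmt"])
    write_intensity_table(lfq, paths["lfq"])
    write_sample_meta(meta, paths["meta"])
    write_clinical_table(clinical, paths["clinical"])
    if truth is not None:
        paths["truth"] = outdir / "ground_truth.json"
        truth.to_json(paths["truth"])
    return paths
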