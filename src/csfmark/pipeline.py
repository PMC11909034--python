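"""End-to-end orchestration: simulate/load -> preprocess -> correlate ->
differential expression -> cross-platform -> response markers.

Every stage's parameters and every written file's SHA-256 checksum are
recorded in a run manifest, so identical (config, seed) runs produce
identical checksum sets for all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    AnalysisConfig,
    IntensityMatrix,
    read_clinical_table,
    read_intensity_table,
    read_sample_meta,
    validate_cohort,
    write_intensity_table,
)
from .adjust import (
    CorrelationHeatmap,
    hierarchical_cluster,
    remove_patient_effect,
    sample_correlation,
    zscore_rows,
)
from .crossplatform import (
    OverlapReport,
    intersect_deps,
    overlap_identified,
    rank_intensity,
    top_rank_trajectory,
)
from .diffexpr import dep_summary, differential_expression
from .markers import (
    ConsistencyMatrix,
    clinical_deltas,
    consistency_scores,
    protein_deltas,
    protein_hfmse_screen,
    routine_parameter_correlations,
    scan_cutoffs,
)
from .preprocess import preprocess_platform
from .simulate import GroundTruth, SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    checksums: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def record_file(self, label: str, path: Path) -> None:
        self.checksums[label] = hashlib.sha256(path.read_bytes()).hexdigest()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass
class PipelineResult:
    tmt: IntensityMatrix
    lfq: IntensityMatrix
    meta: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth | None
    processed: dict[str, IntensityMatrix]
    adjusted: dict[str, IntensityMatrix]
    heatmaps: dict[str, CorrelationHeatmap]
    dep_tables: dict[str, pd.DataFrame]
    overlap: OverlapReport
    dep_overlap: OverlapReport
    rank_table: pd.DataFrame
    top_trajectory: pd.DataFrame
    consistency: ConsistencyMatrix | None
    screen: pd.DataFrame
    routine: pd.DataFrame
    cutoff_rules: list
    manifest: RunManifest


def run_pipeline(
    config: AnalysisConfig | None = None,
    sim_config: SimConfig | None = None,
    seed: int | None = None,
    inputs: dict[str, str | Path] | None = None,
    outdir: str | Path | None = None,
    n_cutoff_candidates: int = 5,
) -> PipelineResult:
    """Run the full analysis from a simulated or on-disk cohort.

    Either ``inputs`` (paths ``tmt``, ``lfq``, ``meta``, ``clinical``) or a
    simulation (``sim_config`` and/or ``seed``) must be supplied. Stage
    failures raise :class:`PipelineError` naming the stage.
    """
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    manifest = RunManifest(
        config={
            "analysis": dataclasses.asdict(config),
            "simulation": dataclasses.asdict(sim_config) if sim_config else None,
            "inputs": {k: str(v) for k, v in inputs.items()} if inputs else None,
        },
        seed=seed,
        started=time.time(),
    )
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - report stage and cause
                raise PipelineError(name, exc) from exc
            manifest.stages.append({"stage": name, "seconds": round(time.time() - t0, 3)})
            return result

        return wrap

    # ------------------------------------------------------------- inputs
    def _load():
        if inputs is not None:
            for key in ("tmt", "lfq", "meta", "clinical"):
                if key not in inputs:
                    raise ValueError(f"missing input path {key!r}")
                if not Path(inputs[key]).exists():
                    raise FileNotFoundError(f"input file not found: {inputs[key]}")
            tmt = read_intensity_table(inputs["tmt"], platform="TMT")
            lfq = read_intensity_table(inputs["lfq"], platform="LFQ")
            meta = read_sample_meta(inputs["meta"], schedule=config.schedule)
            clinical = read_clinical_table(inputs["clinical"])
            return tmt, lfq, meta, clinical, None
        return simulate_cohort(sim_config or SimConfig(schedule=config.schedule), seed=seed)

    tmt, lfq, meta, clinical, truth = stage("inputs")(_load)

    report = validate_cohort([tmt, lfq], meta, clinical, schedule=config.schedule)
    if not report.ok:
        raise PipelineError("validate", ValueError(report.to_json()))

    # --------------------------------------------------------- preprocess
    processed: dict[str, IntensityMatrix] = {}
    logs = {}
    for matrix in (tmt, lfq):
        def _pre(m=matrix):
            return preprocess_platform(
                m,
                meta,
                sample_intensity_min=config.sample_intensity_min,
                min_within_patient=config.min_within_patient,
                min_patients=config.min_patients,
                knn_k=config.knn_k,
            )
        processed[matrix.platform], logs[matrix.platform] = stage(f"preprocess_{matrix.platform}")(_pre)

    # ---------------------------------------------- correlation structure
    adjusted: dict[str, IntensityMatrix] = {}
    heatmaps: dict[str, CorrelationHeatmap] = {}
    for platform, m in processed.items():
        def _adj(m=m):
            adj = remove_patient_effect(m, meta)
            z = zscore_rows(adj)
            return adj, hierarchical_cluster(sample_correlation(z))
        adjusted[platform], heatmaps[platform] = stage(f"correlate_{platform}")(_adj)

    # ------------------------------------------------------ diff expression
    dep_tables = {
        platform: stage(f"dep_{platform}")(
            lambda m=m: differential_expression(
                m, meta, fdr_alpha=config.fdr_alpha, log2fc_min=config.log2fc_min
            )
        )
        for platform, m in processed.items()
    }

    # ------------------------------------------------------ cross-platform
    def _cross():
        overlap = overlap_identified(tmt.protein_ids, lfq.protein_ids)
        ranks = rank_intensity(processed["TMT"], highlight=set(lfq.protein_ids))
        trajectory = top_rank_trajectory(processed["TMT"], meta, k=10)
        dep_overlap = intersect_deps(dep_tables["TMT"], dep_tables["LFQ"])
        return overlap, ranks, trajectory, dep_overlap

    overlap, rank_table, top_trajectory, dep_overlap = stage("compare_platforms")(_cross)

    # ------------------------------------------------------------- markers
    def _markers():
        signs = {p: 1 for p in dep_overlap.shared_up}
        signs.update({p: -1 for p in dep_overlap.shared_down})
        consistency = (
            consistency_scores(processed["TMT"], meta, signs) if signs else None
        )
        screen = protein_hfmse_screen(processed["TMT"], meta, clinical)
        routine = routine_parameter_correlations(clinical)
        rules = []
        if len(screen):
            dy = clinical_deltas(clinical, "hfmse")
            dx_all = protein_deltas(processed["TMT"], meta)
            screen_r = screen.set_index("protein")["r"]
            for protein in screen["protein"].head(n_cutoff_candidates):
                dx = dx_all[dx_all["protein"] == protein]
                if screen_r.loc[protein] < 0:
                    # negatively coupled: a decrease predicts improvement
                    dx = dx.assign(delta=-dx["delta"])
                rule = scan_cutoffs(dx, dy, config.cutoff_grid, config.cutoff_min_covered)
                rule.protein = protein
                rule.orientation = (
                    "decrease_improves" if screen_r.loc[protein] < 0 else "increase_improves"
                )
                rules.append(rule)
        return consistency, screen, routine, rules

    consistency, screen, routine, cutoff_rules = stage("markers")(_markers)

    # -------------------------------------------------------------- output
    if out is not None:
        def _write():
            report.to_json(out / "validation.json")
            manifest.record_file("validation", out / "validation.json")
            for platform, m in processed.items():
                path = out / f"processed_{platform.lower()}.tsv"
                write_intensity_table(m, path)
                manifest.record_file(f"processed_{platform}", path)
                (out / f"preprocess_{platform.lower()}.json").write_text(
                    json.dumps(logs[platform], indent=2)
                )
            for platform, hm in heatmaps.items():
                hm.corr.to_csv(out / f"correlation_{platform.lower()}.tsv", sep="\t")
                (out / f"dendrogram_{platform.lower()}.json").write_text(
                    json.dumps(hm.dendrogram_dict(), indent=2)
                )
                manifest.record_file(f"correlation_{platform}", out / f"correlation_{platform.lower()}.tsv")
            for platform, table in dep_tables.items():
                path = out / f"dep_{platform.lower()}.tsv"
                table.to_csv(path, sep="\t", index=False)
                manifest.record_file(f"dep_{platform}", path)
                dep_summary(table).to_csv(out / f"dep_summary_{platform.lower()}.tsv", sep="\t", index=False)
            overlap.to_json(out / "overlap.json")
            dep_overlap.to_json(out / "dep_overlap.json")
            manifest.record_file("dep_overlap", out / "dep_overlap.json")
            rank_table.to_csv(out / "rank_intensity.tsv", sep="\t", index=False)
            top_trajectory.to_csv(out / "top_rank_trajectory.tsv", sep="\t", index=False)
            if consistency is not None:
                consistency.fraction.to_csv(out / "consistency.tsv", sep="\t")
                manifest.record_file("consistency", out / "consistency.tsv")
            screen.to_csv(out / "hfmse_screen.tsv", sep="\t", index=False)
            manifest.record_file("hfmse_screen", out / "hfmse_screen.tsv")
            routine.to_csv(out / "routine_correlations.tsv", sep="\t", index=False)
            rules_payload = [dataclasses.asdict(r) for r in cutoff_rules]
            (out / "cutoff_rules.json").write_text(json.dumps(rules_payload, indent=2))
            manifest.record_file("cutoff_rules", out / "cutoff_rules.json")

        stage("write_outputs")(_write)

    manifest.finished = time.time()
    if out is not None:
        manifest.to_json(out / "manifest.json")

    return PipelineResult(
        tmt=tmt,
        lfq=lfq,
        meta=meta,
        clinical=clinical,
        truth=truth,
        processed=processed,
        adjusted=adjusted,
        heatmaps=heatmaps,
        dep_tables=dep_tables,
        overlap=overlap,
        dep_overlap=dep_overlap,
        rank_table=rank_table,
        top_trajectory=top_trajectory,
        consistency=consistency,
        screen=screen,
        routine=routine,
        cutoff_rules=cutoff_rules,
        manifest=manifest,
    )
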