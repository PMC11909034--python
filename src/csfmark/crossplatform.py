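"""Cross-platform analytics: protein overlap, abundance ranks, DEP intersection.

The two quantification methods see different depths of the CSF proteome:
the LFQ shotgun approach captures only the high-abundance stratum, while
TMT labeling reaches lower-abundance proteins. These operations quantify
that relationship (identified-protein overlap, rank-intensity structure,
top-abundance rank trajectories over time) and intersect the two
platforms' DEP calls requiring a consistent regulation direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import IntensityMatrix, ValidationError, meta_for


@dataclass
class OverlapReport:
    """Identified-protein and DEP overlap between the platforms."""

    n_tmt_only: int
    n_lfq_only: int
    n_shared: int
    shared_ids: list[str]
    shared_up: list[str] = field(default_factory=list)
    shared_down: list[str] = field(default_factory=list)
    conflicting: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.shared_up) & set(self.shared_down):
            raise ValidationError("a protein cannot be both shared-up and shared-down")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def overlap_identified(tmt_ids: Iterable[str], lfq_ids: Iterable[str]) -> OverlapReport:
    """Exact set intersection and differences of identified proteins."""
    tmt, lfq = set(tmt_ids), set(lfq_ids)
    shared = tmt & lfq
    return OverlapReport(
        n_tmt_only=len(tmt - lfq),
        n_lfq_only=len(lfq - tmt),
        n_shared=len(shared),
        shared_ids=sorted(shared),
    )


def rank_intensity(
    matrix: IntensityMatrix, highlight: Iterable[str] | None = None
) -> pd.DataFrame:
    """Proteins ranked by mean non-missing intensity, descending.

    Ties are broken by protein ID (ascending) so the ranking is
    deterministic. ``highlight`` flags a protein subset (e.g. the
    LFQ-covered proteins on the TMT ranking).
    """
    means = matrix.data.mean(axis=1, skipna=True)
    df = pd.DataFrame({"protein": matrix.protein_ids, "mean_intensity": means.to_numpy()})
    df = df.sort_values(
        ["mean_intensity", "protein"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    hl = set(highlight) if highlight is not None else set()
    df["highlighted"] = df["protein"].isin(hl)
    return df


def top_rank_trajectory(
    matrix: IntensityMatrix, meta: pd.DataFrame, k: int = 10
) -> pd.DataFrame:
    """Per-timepoint abundance ranks of the overall top-k proteins.

    Rows are the k most abundant proteins overall; columns are timepoints;
    entries are each protein's rank among all proteins by per-timepoint
    mean intensity. Invariant to sample order.
    """
    if k > matrix.n_proteins:
        raise ValidationError(f"k={k} exceeds the {matrix.n_proteins} proteins present")
    m = meta_for(meta, matrix)
    overall = rank_intensity(matrix)
    top = overall["protein"].head(k).tolist()
    out = pd.DataFrame(index=pd.Index(top, name="protein"))
    for t in sorted(set(m["timepoint_months"])):
        cols = m.loc[m["timepoint_months"] == t, "sample_id"]
        sub = matrix.select_samples(list(cols))
        ranked = rank_intensity(sub).set_index("protein")["rank"]
        out[f"m{t}"] = ranked.reindex(top).to_numpy()
    return out.reset_index()


def intersect_deps(
    tmt_table: pd.DataFrame, lfq_table: pd.DataFrame, mode: str = "same_contrast"
) -> OverlapReport:
    """Direction-consistent DEP intersection across platforms.

    A protein is shared-up if it is flagged as an upregulated DEP in both
    platforms for at least one common contrast (``same_contrast``, the
    strict default) or for any contrast in each platform
    (``any_contrast``); analogously for shared-down. Proteins that are
    DEPs in both platforms only with conflicting directions are reported
    separately.
    """
    if mode not in ("same_contrast", "any_contrast"):
        raise ValidationError(f"unknown intersection mode {mode!r}")
    common = set(tmt_table["contrast"]) & set(lfq_table["contrast"])
    if not common:
        raise ValidationError("no common contrasts between the platforms")

    def dep_pairs(table: pd.DataFrame) -> pd.DataFrame:
        deps = table[table["is_dep"]]
        if mode == "same_contrast":
            deps = deps[deps["contrast"].isin(common)]
        return deps[["protein", "contrast", "direction"]]

    t, l = dep_pairs(tmt_table), dep_pairs(lfq_table)
    up: set[str] = set()
    down: set[str] = set()
    if mode == "same_contrast":
        merged = t.merge(l, on=["protein", "contrast"], suffixes=("_tmt", "_lfq"))
        up = set(merged.loc[(merged["direction_tmt"] == "up") & (merged["direction_lfq"] == "up"), "protein"])
        down = set(merged.loc[(merged["direction_tmt"] == "down") & (merged["direction_lfq"] == "down"), "protein"])
    else:
        for direction, bucket in (("up", up), ("down", down)):
            bucket |= set(t.loc[t["direction"] == direction, "protein"]) & set(
                l.loc[l["direction"] == direction, "protein"]
            )
    conflicting = sorted((up & down) | _conflicts(t, l, mode))
    up -= set(conflicting)
    down -= set(conflicting)

    tmt_ids = set(tmt_table["protein"])
    lfq_ids = set(lfq_table["protein"])
    shared = tmt_ids & lfq_ids
    return OverlapReport(
        n_tmt_only=len(tmt_ids - lfq_ids),
        n_lfq_only=len(lfq_ids - tmt_ids),
        n_shared=len(shared),
        shared_ids=sorted(shared),
        shared_up=sorted(up),
        shared_down=sorted(down),
        conflicting=conflicting,
    )


def _conflicts(t: pd.DataFrame, l: pd.DataFrame, mode: str) -> set[str]:
    """Proteins DEP in both platforms but only with opposite directions."""
    if mode == "same_contrast":
        merged = t.merge(l, on=["protein", "contrast"], suffixes=("_tmt", "_lfq"))
        opposing = merged["direction_tmt"] != merged["direction_lfq"]
        agreeing = set(merged.loc[~opposing, "protein"])
        return set(merged.loc[opposing, "protein"]) - agreeing
    both = set(t["protein"]) & set(l["protein"])
    out = set()
    for p in both:
        dt = set(t.loc[t["protein"] == p, "direction"])
        dl = set(l.loc[l["protein"] == p, "direction"])
        if not (dt & dl):
            out.add(p)
    return out
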