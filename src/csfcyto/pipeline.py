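"""End-to-end pipeline: simulate -> gate -> summarize -> score -> compare -> ROC.

Also home of the run manifest: a YAML snapshot of the configuration, seed,
produced files and per-stage wall-clock, sufficient to reproduce a run
byte-for-byte (timings aside).
"""

from __future__ import annotations

import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, DonorRecord, config_to_dict
from .gating import (GateTree, PopulationCounts, ThresholdSet, apply_gate_tree,
                     counts_frame, default_gate_tree, estimate_thresholds)
from .metrics import donor_values, population_table
from .roc import ROCResult, roc_curve, roc_table
from .scores import score_cohort
from .simulate import metadata_frame, simulate_cohort
from .stats import compare_groups

#: The three diagnostic contrasts (positive class first).
CONTRASTS: dict[str, tuple[str, ...]] = {
    "MS-vs-MOGAD": ("MOGAD",),
    "MS-vs-otherADS": ("otherADS",),
    "MS-vs-MOGAD/otherADS": ("MOGAD", "otherADS"),
}

ADS_GROUPS = ("MS", "MOGAD", "otherADS")
CONTROL_GROUPS = ("NIND", "PIND", "AIE", "IDWM")
LINEAGE_FEATURES = ("T", "CD14myeloid", "NK", "DC", "PMN", "B")


def gate_cohort(matrices: list[pd.DataFrame], donor_ids: list[str],
                tree: GateTree, threshold_method: str = "fixed",
                fixed_thresholds: ThresholdSet | None = None
                ) -> list[PopulationCounts]:
    """Gate each donor's events; thresholds re-estimated per donor when
    ``threshold_method='midpoint-mixture'``."""
    out = []
    for donor_id, events in zip(donor_ids, matrices):
        thresholds = estimate_thresholds(events, method=threshold_method,
                                         fixed_values=fixed_thresholds)
        out.append(apply_gate_tree(events, tree, thresholds, donor_id=donor_id))
    return out


def with_pooled_ads(values: pd.DataFrame, label: str = "ADS") -> pd.DataFrame:
    """Append duplicate rows of the MS/MOGAD/otherADS donors under one label."""
    pooled = values[values["group"].isin(ADS_GROUPS)].copy()
    pooled["group"] = label
    return pd.concat([values, pooled], ignore_index=True)


def default_comparisons(table: pd.DataFrame, donors: list[DonorRecord],
                        scores: pd.DataFrame, bh: bool = False) -> pd.DataFrame:
    """The comparison battery appropriate for the groups present.

    Pooled-ADS vs each control group on lineage absolute counts; MS vs MOGAD
    vs other ADS on B/ASC/CD14 frequencies and counts plus the AMR and coNCS.
    """
    present = {d.group for d in donors}
    frames = []
    if present & set(ADS_GROUPS):
        controls = [g for g in CONTROL_GROUPS if g in present]
        for feature in LINEAGE_FEATURES:
            values = with_pooled_ads(donor_values(table, donors, feature,
                                                  "cells_per_ml"))
            pairs = [("ADS", g) for g in controls]
            if pairs:
                frames.append(compare_groups(values, f"{feature}_cells_per_ml",
                                             pairs, bh=bh))
    ads_pairs = [(a, b) for a, b in
                 (("MS", "MOGAD"), ("MS", "otherADS"), ("MOGAD", "otherADS"))
                 if a in present and b in present]
    if ads_pairs:
        for pop in ("B", "ASC", "CD14myeloid"):
            for measure in ("pct_leukocytes", "cells_per_ml"):
                values = donor_values(table, donors, pop, measure)
                frames.append(compare_groups(values, f"{pop}_{measure}",
                                             ads_pairs, bh=bh))
        for score in ("amr", "concs"):
            values = scores.rename(columns={score: "value"})[
                ["donor_id", "group", "value"]]
            frames.append(compare_groups(values, score, ads_pairs, bh=bh))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def score_rocs(scores: pd.DataFrame) -> list[ROCResult]:
    """ROC per contrast per score (AMR, coNCS), MS as the positive class."""
    results = []
    present = set(scores["group"])
    for contrast, negatives in CONTRASTS.items():
        if "MS" not in present or not present.issuperset(negatives):
            continue
        sub = scores[scores["group"].isin(("MS",) + negatives)]
        labels = (sub["group"] == "MS").to_numpy()
        for score in ("amr", "concs"):
            results.append(roc_curve(sub[score].to_numpy(), labels,
                                     contrast=contrast, score_name=score))
    return results


def run_all(config: CohortConfig, out_dir, threshold_method: str = "fixed",
            bh: bool = False, write_events: bool = True,
            nind_mean_pmn_pct: float | None = None) -> dict:
    """Run the full pipeline and write every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    timings: dict[str, float] = {}

    def _write(frame: pd.DataFrame, name: str) -> None:
        frame.to_csv(out / name, index=False)
        files.append(name)

    t0 = time.perf_counter()
    records, matrices = simulate_cohort(config)
    metadata = metadata_frame(records)
    _write(metadata, "metadata.csv")
    if write_events:
        (out / "events").mkdir(exist_ok=True)
        for rec, events in zip(records, matrices):
            events.to_csv(out / "events" / f"{rec.donor_id}.csv", index=False)
            files.append(f"events/{rec.donor_id}.csv")
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tree = default_gate_tree()
    counts = gate_cohort(matrices, [r.donor_id for r in records], tree,
                         threshold_method)
    _write(counts_frame(counts), "counts.csv")
    timings["gate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = population_table(counts, records, tree)
    _write(table, "population_table.csv")
    timings["summarize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if nind_mean_pmn_pct is None and "NIND" not in {r.group for r in records}:
        raise ValueError("scoring needs the NIND PMN mean: include the NIND "
                         "group or supply nind_mean_pmn_pct")
    scores = score_cohort(table, records, nind_mean_pmn_pct=nind_mean_pmn_pct)
    _write(scores, "scores.csv")
    timings["score"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comparisons = default_comparisons(table, records, scores, bh=bh)
    if not comparisons.empty:
        _write(comparisons, "comparisons.csv")
    timings["compare"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rocs = score_rocs(scores) if not scores.empty else []
    for r in rocs:
        slug = r.contrast.replace("/", "+")
        _write(r.frame(), f"roc_{slug}_{r.score_name}.csv")
    if rocs:
        _write(roc_table(rocs), "roc_summary.csv")
    timings["roc"] = time.perf_counter() - t0

    manifest = {
        "csfcyto_version": __version__,
        "master_seed": config.master_seed,
        "threshold_method": threshold_method,
        "config": config_to_dict(config),
        "outputs": files,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return {"records": records, "matrices": matrices, "counts": counts,
            "table": table, "scores": scores, "comparisons": comparisons,
            "rocs": rocs, "manifest": manifest}
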