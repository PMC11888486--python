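"""Frequencies and absolute counts derived from gated population counts.

Every population gets its count, its frequency as a percent of its parent,
of CD45+ leukocytes and — where the population sits inside the lymphocyte
compartment (T u B u NK) — of lymphocytes; T-lineage subsets additionally
get a percent-of-CD3+ column.  Absolute counts (cells/mL) anchor the
percent-of-leukocytes frequency to the hemocytometer cell concentration.
Zero denominators yield a frequency of 0 (logged), so downstream composite
scores can apply their zero rules without special-casing missing values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import DonorRecord
from .gating import GateTree, PopulationCounts

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["donor_id", "population", "count", "pct_parent",
                 "pct_leukocytes", "pct_lymphocytes", "pct_T", "cells_per_ml"]


def _pct(count: int, denom: int, what: str, donor: str) -> float:
    if denom == 0:
        if count == 0:
            return 0.0
        logger.warning("donor %s: zero %s denominator; frequency reported as 0",
                       donor, what)
        return 0.0
    return 100.0 * count / denom


def cells_per_ml(frequency_of_leukocytes: float, concentration: float) -> float:
    """Absolute count: (%) of leukocytes x concentration (cells/uL) x 1000."""
    if not (0.0 <= frequency_of_leukocytes <= 100.0):
        raise ValueError("frequency must be in [0, 100]")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return frequency_of_leukocytes / 100.0 * concentration * 1000.0


def frequencies(counts: PopulationCounts, tree: GateTree) -> pd.DataFrame:
    """Per-population frequency rows (no absolute counts) for one donor."""
    for name in tree.names:
        if name not in counts.counts:
            raise ValueError(f"counts are missing population {name!r}; "
                             "were they produced by this tree?")
    leuk = counts["leukocytes"]
    lymph = counts["lymphocytes"] if "lymphocytes" in tree else 0
    rows = []
    for pop in tree:
        c = counts[pop.name]
        parent_count = counts[pop.parent] if pop.parent is not None else c
        ancestors = tree.ancestors(pop.name)
        in_lymph = pop.name == "lymphocytes" or any(
            a in ("T", "B", "NK") or a == "lymphocytes" for a in ancestors
        ) or pop.name in ("T", "B", "NK")
        in_t = pop.name == "T" or "T" in ancestors
        rows.append({
            "donor_id": counts.donor_id,
            "population": pop.name,
            "count": c,
            "pct_parent": _pct(c, parent_count, "parent", counts.donor_id),
            "pct_leukocytes": _pct(c, leuk, "leukocyte", counts.donor_id),
            "pct_lymphocytes": _pct(c, lymph, "lymphocyte", counts.donor_id)
            if in_lymph else np.nan,
            "pct_T": _pct(c, counts["T"], "T-cell", counts.donor_id)
            if in_t else np.nan,
        })
    return pd.DataFrame(rows)


def population_table(counts_list: list[PopulationCounts],
                     donors: list[DonorRecord],
                     tree: GateTree) -> pd.DataFrame:
    """Tidy per-donor, per-population table with frequencies and cells/mL."""
    by_id = {d.donor_id: d for d in donors}
    frames = []
    for counts in counts_list:
        if counts.donor_id not in by_id:
            raise ValueError(f"no metadata for donor {counts.donor_id!r}")
        f = frequencies(counts, tree)
        conc = by_id[counts.donor_id].concentration
        f["cells_per_ml"] = [cells_per_ml(p, conc) for p in f["pct_leukocytes"]]
        frames.append(f)
    table = pd.concat(frames, ignore_index=True)
    return table[TABLE_COLUMNS]


def donor_values(table: pd.DataFrame, donors: list[DonorRecord],
                 population: str, measure: str) -> pd.DataFrame:
    """(donor_id, group, value) frame for one population/measure pair."""
    if measure not in table.columns:
        raise ValueError(f"unknown measure {measure!r}")
    sub = table[table["population"] == population]
    if sub.empty:
        raise ValueError(f"unknown population {population!r}")
    groups = pd.DataFrame({"donor_id": [d.donor_id for d in donors],
                           "group": [d.group for d in donors]})
    out = sub.merge(groups, on="donor_id")[["donor_id", "group", measure]]
    return out.rename(columns={measure: "value"})


def cohort_summary(table: pd.DataFrame, donors: list[DonorRecord],
                   measure: str, population: str, group: str) -> dict[str, float]:
    """Median and range of one measure over the donors of one group.

    The even-n median is the mean of the two central order statistics.
    """
    values = donor_values(table, donors, population, measure)
    values = values[values["group"] == group]["value"]
    if values.empty:
        raise ValueError(f"no donors in group {group!r}")
    return {"median": float(values.median()),
            "min": float(values.min()),
            "max": float(values.max()),
            "n": int(values.shape[0])}
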