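"""Per-donor discriminative scores for neuroinflammatory CSF.

* AMR — ratio of antibody-secreting-cell (ASC) to CD14+ myeloid frequencies,
  both expressed as percent of CD45+ leukocytes.  An elevated AMR is the
  MS-discriminating signal.
* coNCS — CSF-only neuroinflammatory composite score:
  ``(cells/uL + 1) * B%lymphocytes * 100 / (CD14%leukocytes * NKT%lymphocytes)``,
  set to exactly 0 whenever any numerator or denominator factor is 0.
* NCS — the full composite score, which divides the coNCS by the paired
  blood CD56dim NK frequency; absent (not zero) when no blood value exists.
* PMN flag — granulocyte frequency above twice the mean NIND PMN frequency,
  a rule that argues against MS and toward MOGAD / other ADS.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohort import DonorRecord

#: Sentinel for an infinite AMR (ASC present, CD14 absent); ranks above every
#: finite score in ROC construction.
AMR_SENTINEL = math.inf


def _check_pct(name: str, value: float) -> None:
    if value < 0 or value > 100:
        raise ValueError(f"{name} = {value} is outside [0, 100]")


def compute_amr(asc_pct: float, cd14_pct: float) -> float:
    """ASC-to-CD14+-myeloid frequency ratio (same denominator for both)."""
    _check_pct("asc_pct", asc_pct)
    _check_pct("cd14_pct", cd14_pct)
    if asc_pct == 0:
        return 0.0
    if cd14_pct == 0:
        return AMR_SENTINEL
    return asc_pct / cd14_pct


def compute_concs(concentration: float, b_pct: float, cd14_pct: float,
                  nkt_pct: float) -> float:
    """CSF-only neuroinflammatory composite score with its zero rules."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    for name, v in (("b_pct", b_pct), ("cd14_pct", cd14_pct), ("nkt_pct", nkt_pct)):
        _check_pct(name, v)
    if b_pct == 0 or cd14_pct == 0 or nkt_pct == 0:
        return 0.0
    return (concentration + 1.0) * b_pct * 100.0 / (cd14_pct * nkt_pct)


def compute_ncs(concentration: float, b_pct: float, cd14_pct: float,
                nkt_pct: float, blood_cd56dim_pct: float | None) -> float | None:
    """Full composite score; ``None`` blood input yields an absent score."""
    if blood_cd56dim_pct is None:
        return None
    _check_pct("blood_cd56dim_pct", blood_cd56dim_pct)
    base = compute_concs(concentration, b_pct, cd14_pct, nkt_pct)
    if base == 0.0 or blood_cd56dim_pct == 0:
        return 0.0
    return base / blood_cd56dim_pct


def pmn_flag(pmn_pct: float, nind_mean_pmn_pct: float) -> bool:
    """Strictly above twice the mean NIND PMN frequency."""
    if nind_mean_pmn_pct < 0:
        raise ValueError("NIND mean PMN frequency must be non-negative")
    _check_pct("pmn_pct", pmn_pct)
    return pmn_pct > 2.0 * nind_mean_pmn_pct


def nind_mean_pmn(table: pd.DataFrame, donors: list[DonorRecord]) -> float:
    """Mean PMN % of leukocytes over the NIND donors of this run."""
    nind = {d.donor_id for d in donors if d.group == "NIND"}
    if not nind:
        raise ValueError("no NIND donors present; supply the PMN mean explicitly")
    sub = table[(table["population"] == "PMN") & table["donor_id"].isin(nind)]
    return float(sub["pct_leukocytes"].mean())


def score_cohort(table: pd.DataFrame, donors: list[DonorRecord],
                 blood_cd56dim: dict[str, float] | None = None,
                 nind_mean_pmn_pct: float | None = None) -> pd.DataFrame:
    """Score records for every donor from the tidy population table.

    ``blood_cd56dim`` optionally maps donor_id to the paired blood CD56dim NK
    frequency (% of blood lymphocytes); donors without a value get an absent
    (NaN) full NCS.  The NIND PMN mean is computed from the run's own NIND
    donors unless supplied.
    """
    if nind_mean_pmn_pct is None:
        nind_mean_pmn_pct = nind_mean_pmn(table, donors)
    blood_cd56dim = blood_cd56dim or {}

    def pick(donor_id: str, population: str, measure: str) -> float:
        sub = table[(table["donor_id"] == donor_id)
                    & (table["population"] == population)]
        return float(sub[measure].iloc[0])

    rows = []
    for d in donors:
        asc = pick(d.donor_id, "ASC", "pct_leukocytes")
        cd14 = pick(d.donor_id, "CD14myeloid", "pct_leukocytes")
        b_lymph = pick(d.donor_id, "B", "pct_lymphocytes")
        nkt = pick(d.donor_id, "NKT", "pct_lymphocytes")
        pmn = pick(d.donor_id, "PMN", "pct_leukocytes")
        amr = compute_amr(asc, cd14)
        ncs = compute_ncs(d.concentration, b_lymph, cd14, nkt,
                          blood_cd56dim.get(d.donor_id))
        rows.append({
            "donor_id": d.donor_id,
            "group": d.group,
            "amr": amr,
            "amr_is_sentinel": math.isinf(amr),
            "concs": compute_concs(d.concentration, b_lymph, cd14, nkt),
            "ncs": np.nan if ncs is None else ncs,
            "pmn_flag": pmn_flag(pmn, nind_mean_pmn_pct),
        })
    return pd.DataFrame(rows)
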